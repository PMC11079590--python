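"""End-to-end study orchestration.

Runs, in order: (1) exposure → outcome MR with every estimator and the
full sensitivity battery; (2) the proteome-wide step-1 screen with FDR;
(3) the step-2 screen on the FDR hits with the direction-consistency
filter; (4) product-of-coefficients mediation for every surviving
protein; (5) reverse MR from the outcome back to each survivor; (6)
cis-pQTL colocalization of each survivor with the outcome.  Results are
collected into a :class:`ReportBundle` of tidy tables plus a JSON
provenance sidecar (config hash, seed, package version), and each
stochastic stage derives its seed as ``seed + fixed stage offset`` so
adding a stage never perturbs earlier ones.  A stage that fails or
receives no input is recorded with an explicit status and downstream
dependent stages are skipped, not crashed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping


import pandas as pd
import yaml

from . import __version__
from .coloc import ColocResult, RegionStats, coloc_abf
from .estimators import or_from_logodds
from .instruments import (
    EmptyInstrumentSetError,
    InstrumentSet,
    LDMatrix,
    select_instruments,
)
from .screening import (
    MediationResult,
    MRReport,
    ScreenResult,
    mediation,
    reverse_mr,
    run_mr_battery,
    screen_step1,
    screen_step2,
)
from .sumstats import (
    InputError,
    SummaryStats,
    TraitInfo,
    TraitType,
    harmonize,
    read_sumstats,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "run_study", "load_inputs"]

# fixed offsets: stage seeds stay put when stages are added
STAGE_SEED_OFFSETS = {
    "main_mr": 11,
    "screen1": 23,
    "screen2": 37,
    "mediation": 53,
    "reverse_mr": 71,
    "coloc": 89,
}


@dataclass
class PipelineConfig:
    """All file paths and thresholds for one pipeline run.

    ``exposure_instruments`` may list variant ids explicitly (the usual
    drug-target situation, where the instrument list comes from prior
    work); when absent, instruments are selected from the exposure
    summary statistics with the standard criteria.
    """

    exposure: str
    outcome: str
    panel_manifest: str
    traits: str
    exposure_instruments: list[str] | None = None
    ld_matrix: str | None = None
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    ld_r2_max: float = 0.001
    window_bp: int = 10_000_000
    cis_window_bp: int = 500_000
    fdr_alpha: float = 0.05
    h4_threshold: float = 0.70
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    palindrome_eaf_window: float = 0.08
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    strict_sensitivity: bool = False
    base_dir: str = "."

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        bounds = {
            "p_threshold": (0.0, 1.0),
            "maf_min": (0.0, 0.5),
            "ld_r2_max": (0.0, 1.0),
            "fdr_alpha": (0.0, 1.0),
            "h4_threshold": (0.0, 1.0),
            "palindrome_eaf_window": (0.0, 0.5),
        }
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.setdefault("base_dir", str(path.parent))
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else Path(self.base_dir) / q


@dataclass
class StageStatus:
    stage: str
    status: str  # ok | empty | skipped | failed
    detail: str = ""


@dataclass
class ReportBundle:
    main_mr: pd.DataFrame
    heterogeneity: pd.DataFrame
    screen1: pd.DataFrame
    screen2: pd.DataFrame
    mediation_table: pd.DataFrame
    reverse_mr_table: pd.DataFrame
    coloc_table: pd.DataFrame
    stages: list[StageStatus]
    provenance: dict
    main_report: MRReport | None = None
    mediation_results: dict[str, MediationResult] = field(default_factory=dict)
    coloc_results: dict[str, ColocResult] = field(default_factory=dict)

    _tables = (
        ("main_mr", "main_mr.tsv"),
        ("heterogeneity", "heterogeneity.tsv"),
        ("screen1", "screen_step1.tsv"),
        ("screen2", "screen_step2.tsv"),
        ("mediation_table", "mediation.tsv"),
        ("reverse_mr_table", "reverse_mr.tsv"),
        ("coloc_table", "coloc.tsv"),
    )

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._tables:
            df: pd.DataFrame = getattr(self, attr)
            df.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
        status = pd.DataFrame(
            [(s.stage, s.status, s.detail) for s in self.stages],
            columns=["stage", "status", "detail"],
        )
        status.to_csv(outdir / "stages.tsv", sep="\t", index=False)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        return outdir


def _estimates_frame(report: MRReport, pair_label: str) -> pd.DataFrame:
    rows = []
    for name, est in report.estimates.items():
        orp, orl, orh = or_from_logodds(est.beta, est.se)
        rows.append(
            {
                "pair": pair_label,
                "method": name,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "or_point": orp,
                "or_low": orl,
                "or_high": orh,
            }
        )
    return pd.DataFrame(rows)


def _het_frame(report: MRReport, pair_label: str) -> pd.DataFrame:
    rows = []
    for name, het in report.heterogeneity.items():
        rows.append(
            {
                "pair": pair_label,
                "method": name,
                "Q": het.Q,
                "df": het.df,
                "q_pval": het.q_pval,
                "i2": het.i2,
            }
        )
    if report.egger_fit is not None:
        rows.append(
            {
                "pair": pair_label,
                "method": "egger_intercept",
                "Q": report.egger_fit.intercept,
                "df": 0,
                "q_pval": report.egger_fit.intercept_p,
                "i2": 0.0,
            }
        )
    if report.presso is not None:
        rows.append(
            {
                "pair": pair_label,
                "method": "presso_global",
                "Q": report.presso.global_rss,
                "df": 0,
                "q_pval": report.presso.global_pval,
                "i2": 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["pair", "method", "Q", "df", "q_pval", "i2"])


def _screen_frame(res: ScreenResult) -> pd.DataFrame:
    rows = []
    for r in res.rows:
        rows.append(
            {
                "protein_id": r.protein_id,
                "method": r.estimate.method,
                "n_snp": r.estimate.n_snp,
                "beta": r.estimate.beta,
                "se": r.estimate.se,
                "pval": r.estimate.pval,
                "q_value": r.q_value,
                "passes_fdr": r.passes_fdr,
                "direction_consistent": r.direction_consistent,
                "effects_model": r.effects_model,
                "q_pval": r.q_pval,
                "i2": r.i2,
                "egger_intercept_p": r.egger_intercept_p,
                "presso_global_p": r.presso_global_p,
            }
        )
    cols = [
        "protein_id", "method", "n_snp", "beta", "se", "pval", "q_value",
        "passes_fdr", "direction_consistent", "effects_model", "q_pval",
        "i2", "egger_intercept_p", "presso_global_p",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class StudyInputs:
    """In-memory inputs of one study run."""

    exposure: SummaryStats
    outcome: SummaryStats
    panel: Mapping[str, SummaryStats]
    manifest: pd.DataFrame  # protein_id, gene_chrom, gene_tss
    exposure_instruments: list[str] | None = None
    ld: LDMatrix | None = None


def load_inputs(cfg: PipelineConfig) -> StudyInputs:
    """Load every referenced file of a config into memory."""
    traits_df = pd.read_csv(cfg.resolve(cfg.traits), sep="\t")
    traits: dict[str, TraitInfo] = {}
    for row in traits_df.itertuples(index=False):
        n_cases = None if pd.isna(row.n_cases) or row.n_cases == "" else int(row.n_cases)
        sd_y = None if pd.isna(row.sd_y) or row.sd_y == "" else float(row.sd_y)
        traits[str(row.trait_id)] = TraitInfo(
            str(row.trait_id), TraitType(row.trait_type), int(row.n_total), n_cases, sd_y
        )
    exposure = read_sumstats(cfg.resolve(cfg.exposure), traits["exposure"])
    outcome = read_sumstats(cfg.resolve(cfg.outcome), traits["outcome"])
    manifest = pd.read_csv(cfg.resolve(cfg.panel_manifest), sep="\t", dtype={"gene_chrom": str})
    manifest["protein_id"] = manifest["protein_id"].astype(str)
    base = cfg.resolve(cfg.panel_manifest).parent
    panel = {}
    for row in manifest.itertuples(index=False):
        pid = str(row.protein_id)
        trait = traits.get(pid, TraitInfo(pid, TraitType.quantitative, 0, sd_y=1.0))
        panel[pid] = read_sumstats(base / row.file, trait)
    ld = LDMatrix.from_pairs_tsv(cfg.resolve(cfg.ld_matrix)) if cfg.ld_matrix else None
    return StudyInputs(
        exposure=exposure,
        outcome=outcome,
        panel=panel,
        manifest=manifest,
        exposure_instruments=cfg.exposure_instruments,
        ld=ld,
    )


def run_study(inputs: StudyInputs, cfg: PipelineConfig) -> ReportBundle:
    """Execute all six stages on in-memory inputs."""
    stages: list[StageStatus] = []
    seeds = {k: cfg.seed + off for k, off in STAGE_SEED_OFFSETS.items()}
    empty = pd.DataFrame()

    # --- stage 1: exposure -> outcome ------------------------------------
    main_report: MRReport | None = None
    main_mr = empty
    het_tab = empty
    try:
        if inputs.exposure_instruments:
            exp_inst_ids = list(inputs.exposure_instruments)
        else:
            exp_inst_ids = select_instruments(
                inputs.exposure,
                p_threshold=cfg.p_threshold,
                maf_min=cfg.maf_min,
                ld=inputs.ld,
                ld_r2_max=cfg.ld_r2_max,
                window_bp=cfg.window_bp,
            ).variant_ids
        exp_inst = select_instruments(
            inputs.exposure.subset(exp_inst_ids),
            p_threshold=cfg.p_threshold,
            maf_min=cfg.maf_min,
            ld=inputs.ld,
            ld_r2_max=cfg.ld_r2_max,
            window_bp=cfg.window_bp,
        )
        exp_sub = inputs.exposure.subset(exp_inst.variant_ids)
        pairs = harmonize(exp_sub, inputs.outcome, cfg.palindrome_eaf_window)
        main_report = run_mr_battery(
            pairs, seed=seeds["main_mr"], n_boot=cfg.n_boot, n_sim=cfg.n_sim
        )
        main_mr = _estimates_frame(main_report, "exposure->outcome")
        het_tab = _het_frame(main_report, "exposure->outcome")
        stages.append(StageStatus("main_mr", "ok", f"{main_report.n_snp} instruments"))
    except (InputError, EmptyInstrumentSetError) as exc:
        stages.append(StageStatus("main_mr", "failed", str(exc)))

    # --- stage 2: proteome-wide screen -----------------------------------
    screen1_res: ScreenResult | None = None
    screen1_tab = empty
    if main_report is None:
        stages.append(StageStatus("screen1", "skipped", "main MR failed"))
    else:
        try:
            screen1_res = screen_step1(
                exp_inst,
                inputs.exposure,
                inputs.panel,
                fdr_alpha=cfg.fdr_alpha,
                n_sim=cfg.n_sim,
                seed=seeds["screen1"],
                strict=cfg.strict_sensitivity,
                palindrome_eaf_window=cfg.palindrome_eaf_window,
            )
            screen1_tab = _screen_frame(screen1_res)
            stages.append(
                StageStatus(
                    "screen1", "ok" if screen1_res.passing() else "empty",
                    f"{len(screen1_res.passing())}/{len(screen1_res)} pass FDR",
                )
            )
        except InputError as exc:
            stages.append(StageStatus("screen1", "failed", str(exc)))

    # --- stage 3: driven proteins -> outcome ------------------------------
    screen2_res: ScreenResult | None = None
    screen2_tab = empty
    manifest_idx = inputs.manifest.set_index("protein_id")
    if screen1_res is None or not screen1_res.passing():
        stages.append(StageStatus("screen2", "skipped", "no step-1 survivors"))
    else:
        inst_sets: dict[str, InstrumentSet] = {}
        for row in screen1_res.passing():
            pid = row.protein_id
            # the protein's own pQTLs, excluding the exposure's instruments
            prot = inputs.panel[pid]
            own = prot.df.loc[
                ~prot.df["variant_id"].isin(exp_inst.variant_ids)
            ].reset_index(drop=True)
            try:
                inst_sets[pid] = select_instruments(
                    SummaryStats(prot.trait, own),
                    p_threshold=cfg.p_threshold,
                    maf_min=cfg.maf_min,
                    ld=inputs.ld,
                    ld_r2_max=cfg.ld_r2_max,
                    window_bp=cfg.window_bp,
                )
            except EmptyInstrumentSetError:
                continue
        if not inst_sets:
            stages.append(StageStatus("screen2", "empty", "no protein has pQTL instruments"))
        else:
            screen2_res = screen_step2(
                inst_sets,
                inputs.panel,
                inputs.outcome,
                fdr_alpha=cfg.fdr_alpha,
                n_sim=cfg.n_sim,
                seed=seeds["screen2"],
                strict=cfg.strict_sensitivity,
                palindrome_eaf_window=cfg.palindrome_eaf_window,
            )
            screen2_tab = _screen_frame(screen2_res)
            stages.append(
                StageStatus(
                    "screen2", "ok" if screen2_res.passing() else "empty",
                    f"{len(screen2_res.passing())}/{len(screen2_res)} pass FDR",
                )
            )

    survivors: list[str] = []
    if screen2_res is not None and screen1_res is not None:
        step1_by_id = {r.protein_id: r for r in screen1_res.rows}
        for row in screen2_res.passing():
            if row.direction_consistent is False:
                continue  # opposite IVW/Egger sign invalidates the claim
            survivors.append(row.protein_id)

    # --- stage 4: mediation ----------------------------------------------
    mediation_results: dict[str, MediationResult] = {}
    med_rows = []
    if main_report is None or not survivors:
        stages.append(StageStatus("mediation", "skipped", "no surviving mediator"))
    else:
        total = main_report.primary
        step2_by_id = {r.protein_id: r for r in screen2_res.rows}
        for pid in survivors:
            a = step1_by_id[pid].estimate
            b = step2_by_id[pid].estimate
            try:
                med = mediation(total, a, b)
            except InputError as exc:
                stages.append(StageStatus("mediation", "failed", f"{pid}: {exc}"))
                continue
            mediation_results[pid] = med
            med_rows.append(
                {
                    "protein_id": pid,
                    "total_beta": med.total,
                    "direct_a_beta": med.direct_a,
                    "direct_b_beta": med.direct_b,
                    "indirect_beta": med.indirect,
                    "indirect_se": med.indirect_se,
                    "indirect_p": med.indirect_p,
                    "indirect_low": med.indirect_low,
                    "indirect_high": med.indirect_high,
                    "proportion": med.proportion,
                    "proportion_low": med.proportion_low,
                    "proportion_high": med.proportion_high,
                }
            )
        if mediation_results:
            stages.append(
                StageStatus("mediation", "ok", f"{len(mediation_results)} mediator(s)")
            )
    mediation_table = pd.DataFrame(
        med_rows,
        columns=[
            "protein_id", "total_beta", "direct_a_beta", "direct_b_beta",
            "indirect_beta", "indirect_se", "indirect_p", "indirect_low",
            "indirect_high", "proportion", "proportion_low", "proportion_high",
        ],
    )

    # --- stage 5: reverse MR ----------------------------------------------
    rev_rows = []
    if not survivors:
        stages.append(StageStatus("reverse_mr", "skipped", "no surviving mediator"))
    else:
        for pid in survivors:
            try:
                rep = reverse_mr(
                    inputs.outcome,
                    inputs.panel[pid],
                    p_threshold=cfg.p_threshold,
                    ld=inputs.ld,
                    seed=seeds["reverse_mr"],
                    n_boot=cfg.n_boot,
                    n_sim=cfg.n_sim,
                    palindrome_eaf_window=cfg.palindrome_eaf_window,
                    maf_min=cfg.maf_min,
                    ld_r2_max=cfg.ld_r2_max,
                    window_bp=cfg.window_bp,
                )
                df = _estimates_frame(rep, f"outcome->{pid}")
                df.insert(0, "protein_id", pid)
                rev_rows.append(df)
            except (InputError, EmptyInstrumentSetError) as exc:
                stages.append(StageStatus("reverse_mr", "failed", f"{pid}: {exc}"))
        if rev_rows:
            stages.append(StageStatus("reverse_mr", "ok", f"{len(rev_rows)} protein(s)"))
    reverse_table = (
        pd.concat(rev_rows, ignore_index=True) if rev_rows else pd.DataFrame()
    )

    # --- stage 6: cis-pQTL colocalization ---------------------------------
    coloc_results: dict[str, ColocResult] = {}
    coloc_rows = []
    if not survivors:
        stages.append(StageStatus("coloc", "skipped", "no surviving mediator"))
    else:
        for pid in survivors:
            try:
                res = _cis_coloc(inputs, cfg, pid, manifest_idx)
            except InputError as exc:
                stages.append(StageStatus("coloc", "failed", f"{pid}: {exc}"))
                continue
            coloc_results[pid] = res
            coloc_rows.append(
                {
                    "protein_id": pid,
                    "n_variants": res.n_variants,
                    "pp_h0": res.pp[0],
                    "pp_h1": res.pp[1],
                    "pp_h2": res.pp[2],
                    "pp_h3": res.pp[3],
                    "pp_h4": res.pp[4],
                    "h4_significant": res.h4_significant,
                }
            )
        if coloc_results:
            stages.append(StageStatus("coloc", "ok", f"{len(coloc_results)} region(s)"))
    coloc_table = pd.DataFrame(
        coloc_rows,
        columns=[
            "protein_id", "n_variants", "pp_h0", "pp_h1", "pp_h2",
            "pp_h3", "pp_h4", "h4_significant",
        ],
    )

    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "version": __version__,
    }
    return ReportBundle(
        main_mr=main_mr,
        heterogeneity=het_tab,
        screen1=screen1_tab,
        screen2=screen2_tab,
        mediation_table=mediation_table,
        reverse_mr_table=reverse_table,
        coloc_table=coloc_table,
        stages=stages,
        provenance=provenance,
        main_report=main_report,
        mediation_results=mediation_results,
        coloc_results=coloc_results,
    )


def _cis_coloc(
    inputs: StudyInputs, cfg: PipelineConfig, pid: str, manifest_idx: pd.DataFrame
) -> ColocResult:
    """Colocalize the protein's cis region with the outcome."""
    if pid not in manifest_idx.index:
        raise InputError(f"{pid} missing from panel manifest")
    gchrom = str(manifest_idx.loc[pid, "gene_chrom"])
    tss = int(manifest_idx.loc[pid, "gene_tss"])
    prot = inputs.panel[pid]
    cis_mask = (prot.df["chrom"] == gchrom) & (
        (prot.df["pos"] - tss).abs() <= cfg.cis_window_bp
    )
    cis = prot.df.loc[cis_mask]
    if cis.empty:
        raise InputError(f"{pid}: no variant in the cis window")
    cis_ss = SummaryStats(prot.trait, cis.reset_index(drop=True))
    pairs = harmonize(cis_ss, inputs.outcome, cfg.palindrome_eaf_window)
    if len(pairs) < 1:
        raise InputError(f"{pid}: no cis variant shared with the outcome")
    df = pairs.df
    r1 = RegionStats(
        prot.trait,
        df["variant_id"].tolist(),
        df["beta_exp"].to_numpy(),
        df["se_exp"].to_numpy(),
        df["eaf_exp"].to_numpy(),
    )
    r2 = RegionStats(
        inputs.outcome.trait,
        df["variant_id"].tolist(),
        df["beta_out"].to_numpy(),
        df["se_out"].to_numpy(),
        df["eaf_exp"].to_numpy(),
    )
    return coloc_abf(
        r1, r2, cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12, cfg.h4_threshold
    )


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Load the config's inputs and execute the full study."""
    return run_study(load_inputs(cfg), cfg)
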