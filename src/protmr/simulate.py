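"""Synthetic GWAS summary statistics with known ground truth.

Every stage of the proteome-wide drug-target MR pipeline is exercised on
simulated data whose causal structure is known exactly, emulating the
statistical shape of the real study design: a drug-target exposure
instrumented by a handful of common variants at biobank sample size, a
many-protein plasma panel of rank-normalized protein levels measured in
~35k individuals, and a large binary case/control outcome (~47k cases /
930k controls) analyzed on the log-odds scale.

The sampling model is the standard large-sample one: for a standardized
quantitative trait the per-variant standard error is
se = 1/√(2·n·eaf·(1−eaf)); for a binary trait the effective sample size
carries the case fraction φ, se = 1/√(2·n·φ(1−φ)·eaf·(1−eaf)).  Observed
betas are drawn normal(true beta, se), so the generated (beta, se, p)
triples are exactly internally consistent and the R²/F instrument
formulas hold by construction.

:func:`simulate_mediation_scenario` builds the full three-trait causal
chain exposure → mediator protein → outcome with a direct (unmediated)
path, plus a panel of null proteins, each protein with its own pQTLs
(one cis, the rest trans).  :func:`simulate_coloc_region` draws two
traits' z-scores over an LD-correlated region for colocalization tests.
All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz

from .coloc import RegionStats
from .instruments import LDMatrix
from .sumstats import (
    CANONICAL_COLUMNS,
    COMPLEMENT,
    SummaryStats,
    TraitInfo,
    TraitType,
    write_sumstats,
)

__all__ = [
    "ScenarioConfig",
    "RegionConfig",
    "ScenarioTruth",
    "MediationScenario",
    "simulate_gwas",
    "simulate_mediation_scenario",
    "simulate_coloc_region",
    "write_scenario",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _se_model(eaf: np.ndarray, trait: TraitInfo) -> np.ndarray:
    """Large-sample SE of a per-allele GWAS effect for this trait."""
    het = 2.0 * trait.n_total * eaf * (1.0 - eaf)
    if trait.trait_type is TraitType.binary:
        phi = trait.case_fraction
        het = het * phi * (1.0 - phi)
    return 1.0 / np.sqrt(het)


def _draw_alleles(rng: np.random.Generator, k: int, p_palindromic: float = 0.10):
    """Deterministic allele assignment; ~10% palindromic pairs to exercise
    strand resolution during harmonization."""
    pal = rng.random(k) < p_palindromic
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    for i in range(k):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def simulate_gwas(
    true_betas: Sequence[float],
    eaf: Sequence[float],
    n: int,
    trait: TraitInfo,
    seed: int,
    *,
    variant_ids: Sequence[str] | None = None,
    chrom: Sequence[str] | None = None,
    pos: Sequence[int] | None = None,
    effect_allele: Sequence[str] | None = None,
    other_allele: Sequence[str] | None = None,
) -> SummaryStats:
    """Draw one trait's observed summary statistics around true effects."""
    true_betas = np.asarray(true_betas, float)
    eaf = np.asarray(eaf, float)
    if true_betas.size != eaf.size:
        raise ValueError("true_betas and eaf must have equal length")
    k = true_betas.size
    if trait.n_total != n:
        trait = TraitInfo(trait.trait_id, trait.trait_type, n, trait.n_cases, trait.sd_y)
    rng = np.random.default_rng(seed)
    se = _se_model(eaf, trait)
    beta = rng.normal(true_betas, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1}" for i in range(k)]
    if chrom is None:
        chrom = ["1"] * k
    if pos is None:
        pos = (np.arange(k) * 12_000_000 + 1_000_000).tolist()
    if effect_allele is None or other_allele is None:
        effect_allele, other_allele = _draw_alleles(rng, k)
    df = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "chrom": list(map(str, chrom)),
            "pos": list(map(int, pos)),
            "effect_allele": list(effect_allele),
            "other_allele": list(other_allele),
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        },
        columns=CANONICAL_COLUMNS,
    )
    return SummaryStats.from_frame(trait, df, check_zp=False)


def _scramble_orientation(ss: SummaryStats, rng: np.random.Generator) -> SummaryStats:
    """Randomly swap allele orientation / strand per variant.

    The information content is unchanged — harmonization against the
    original orientation must undo every flip — but downstream code can no
    longer assume all traits report the same effect allele.
    """
    df = ss.df.copy()
    swap = rng.random(len(df)) < 0.5
    strand = rng.random(len(df)) < 0.5
    ea = df["effect_allele"].to_numpy(object)
    oa = df["other_allele"].to_numpy(object)
    ea2, oa2 = ea.copy(), oa.copy()
    ea2[swap], oa2[swap] = oa[swap], ea[swap]
    pal = np.array(
        [frozenset((a, b)) in (frozenset("AT"), frozenset("CG")) for a, b in zip(ea2, oa2)]
    )
    flip = strand & ~pal
    ea2[flip] = [COMPLEMENT[a] for a in ea2[flip]]
    oa2[flip] = [COMPLEMENT[a] for a in oa2[flip]]
    df["effect_allele"], df["other_allele"] = ea2, oa2
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    return SummaryStats(ss.trait, df)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the three-trait mediation scenario.

    Defaults mirror the design being emulated: six exposure instruments at
    biobank scale, a plasma-protein panel of 35,559 individuals, a binary
    outcome of 47,309 cases / 930,014 controls, mediator chain
    β1 = 0.96 (exposure→protein), β2 = −0.21 (protein→outcome) and direct
    path β_direct = −0.62, so the total effect is β3 = −0.8216 and the
    mediated proportion β1·β2/β3 ≈ 0.245.  The panel defaults to 200
    proteins, a desk-scale stand-in for a full proteome panel.
    """

    n_exposure_instruments: int = 6
    exposure_n: int = 450_000
    panel_size: int = 200
    mediator_index: int = 0
    beta_exposure_mediator: float = 0.96
    beta_mediator_outcome: float = -0.21
    beta_direct: float = -0.62
    outcome_cases: int = 47_309
    outcome_controls: int = 930_014
    protein_n: int = 35_559
    n_pqtl_per_protein: int = 8
    pleiotropy_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.40)
    n_null_background: int = 40
    cis_f_target: float = 87.0
    cis_region_size: int = 15
    cis_ld_decay: float = 4.0
    n_outcome_loci: int = 12
    beta_outcome_feedback: float = 0.0
    seed: int = 0

    @property
    def beta_total(self) -> float:
        return self.beta_direct + self.beta_exposure_mediator * self.beta_mediator_outcome

    @property
    def mediated_proportion(self) -> float:
        return self.beta_exposure_mediator * self.beta_mediator_outcome / self.beta_total


@dataclass(frozen=True)
class ScenarioTruth:
    beta1: float
    beta2: float
    beta_direct: float
    beta_total: float
    proportion: float
    mediator_id: str
    exposure_instrument_ids: tuple[str, ...]
    mediator_pqtl_ids: tuple[str, ...]
    cis_pqtl_id: str


@dataclass
class MediationScenario:
    exposure: SummaryStats
    panel: dict[str, SummaryStats]
    outcome: SummaryStats
    manifest: pd.DataFrame  # protein_id, gene_chrom, gene_tss
    truth: ScenarioTruth
    config: ScenarioConfig


_PQTL_CHROMS = [str(c) for c in range(1, 23) if c not in (2, 16)]


def simulate_mediation_scenario(cfg: ScenarioConfig) -> MediationScenario:
    """Generate exposure, protein-panel and outcome summary statistics.

    Exposure instruments live on chromosome 16 spaced beyond the pruning
    window; each protein gets one cis-pQTL at its gene TSS (effect sized
    to an expected F near ``cis_f_target``) and trans-pQTLs spread across
    other chromosomes.  Only the mediator protein responds to the
    exposure instruments (slope β1) and only its pQTLs affect the outcome
    (slope β2); the exposure acts on the outcome through the direct path
    β_direct plus the mediated path, with optional per-instrument
    directional pleiotropy of SD ``pleiotropy_sd``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
    if not (0 <= cfg.mediator_index < cfg.panel_size):
        raise ValueError("mediator_index out of range")
    if cfg.beta_total == 0:
        raise ValueError("total effect is zero; mediated proportion undefined")

    exp_trait = TraitInfo("exposure", TraitType.quantitative, cfg.exposure_n, sd_y=1.0)
    out_trait = TraitInfo(
        "outcome",
        TraitType.binary,
        cfg.outcome_cases + cfg.outcome_controls,
        n_cases=cfg.outcome_cases,
    )

    # --- master variant table -------------------------------------------
    n_inst = cfg.n_exposure_instruments
    inst_ids = [f"rs_exp{i + 1}" for i in range(n_inst)]
    inst_chrom = ["16"] * n_inst
    inst_pos = [5_000_000 + 12_000_000 * i for i in range(n_inst)]
    inst_eaf = rng.uniform(lo, hi, n_inst)
    # instruments are ascertained as genome-wide significant in the source
    # study: size true effects relative to their sampling SE (z ~ 7-12,
    # hence F roughly 50-150, comfortably past the weak-instrument bound)
    inst_beta = (
        rng.uniform(7.0, 12.0, n_inst)
        * _se_model(inst_eaf, exp_trait)
        * rng.choice([-1.0, 1.0], n_inst)
    )

    bg_ids = [f"rs_bg{i + 1}" for i in range(cfg.n_null_background)]
    bg_chrom = ["2"] * cfg.n_null_background
    bg_pos = [3_000_000 + 12_000_000 * i for i in range(cfg.n_null_background)]
    bg_eaf = rng.uniform(lo, hi, cfg.n_null_background)

    protein_ids = [f"P{i + 1:04d}" for i in range(cfg.panel_size)]
    mediator_id = protein_ids[cfg.mediator_index]

    gene_chrom, gene_tss = [], []
    pqtl_meta: dict[str, dict] = {}
    for p_idx, pid in enumerate(protein_ids):
        gchrom = _PQTL_CHROMS[p_idx % len(_PQTL_CHROMS)]
        tss = 15_000_000 + 40_000_000 * (p_idx // len(_PQTL_CHROMS))
        gene_chrom.append(gchrom)
        gene_tss.append(tss)
        ids, chroms, poss = [], [], []
        for j in range(cfg.n_pqtl_per_protein):
            ids.append(f"rs_{pid}_q{j + 1}")
            if j == 0:  # cis-pQTL at the TSS
                chroms.append(gchrom)
                poss.append(tss + int(rng.integers(-400_000, 400_001)))
            else:  # trans, far from the gene and from each other
                chroms.append(_PQTL_CHROMS[(p_idx + 3 * j) % len(_PQTL_CHROMS)])
                poss.append(200_000_000 + 15_000_000 * j + int(rng.integers(0, 2_000_000)))
        eafs = rng.uniform(lo, hi, cfg.n_pqtl_per_protein)
        effects = rng.uniform(0.15, 0.30, cfg.n_pqtl_per_protein) * rng.choice(
            [-1.0, 1.0], cfg.n_pqtl_per_protein
        )
        # size the cis effect so its expected F is near the target
        prot_trait = TraitInfo(pid, TraitType.quantitative, cfg.protein_n, sd_y=1.0)
        se_cis = _se_model(np.array([eafs[0]]), prot_trait)[0]
        effects[0] = np.sign(effects[0]) * np.sqrt(cfg.cis_f_target) * se_cis

        # LD-correlated cis region around the causal cis-pQTL, so regional
        # colocalization has something to work with; marginal effect at a
        # neighbor is r * beta_causal rescaled by the allele-frequency
        # heterozygosity ratio (single-causal-variant LD algebra)
        n_nb = max(0, cfg.cis_region_size - 1)
        center = cfg.cis_region_size // 2
        offsets = np.array([d for d in range(-center, cfg.cis_region_size - center) if d != 0])
        nb_ids = [f"rs_{pid}_cis{j + 1}" for j in range(n_nb)]
        nb_pos = [poss[0] + int(d) * 25_000 for d in offsets]
        nb_eaf = rng.uniform(lo, hi, n_nb)
        r_c = np.exp(-np.abs(offsets) / max(cfg.cis_ld_decay, 1e-12))
        het_c = 2.0 * eafs[0] * (1.0 - eafs[0])
        het_nb = 2.0 * nb_eaf * (1.0 - nb_eaf)
        nb_effects = r_c * effects[0] * np.sqrt(het_c / het_nb)
        pqtl_meta[pid] = {
            "ids": ids, "chrom": chroms, "pos": poss, "eaf": eafs, "effects": effects,
            "region_ids": nb_ids, "region_chrom": [gchrom] * n_nb,
            "region_pos": nb_pos, "region_eaf": nb_eaf, "region_effects": nb_effects,
        }

    # --- outcome-specific loci (for reverse MR) ---------------------------
    hf_ids = [f"rs_out{i + 1}" for i in range(cfg.n_outcome_loci)]
    hf_chrom = ["16"] * cfg.n_outcome_loci
    hf_pos = [100_000_000 + 12_000_000 * i for i in range(cfg.n_outcome_loci)]
    hf_eaf = rng.uniform(lo, hi, cfg.n_outcome_loci)
    hf_beta = rng.uniform(0.08, 0.15, cfg.n_outcome_loci) * rng.choice(
        [-1.0, 1.0], cfg.n_outcome_loci
    )

    # --- master allele registry ------------------------------------------
    # one variant = one allele pair, shared by every trait that carries it;
    # per-trait presentation is scrambled afterwards
    all_ids = (
        inst_ids
        + bg_ids
        + hf_ids
        + [v for pid in protein_ids for v in pqtl_meta[pid]["ids"] + pqtl_meta[pid]["region_ids"]]
    )
    reg_ea, reg_oa = _draw_alleles(rng, len(all_ids))
    registry = {vid: (reg_ea[i], reg_oa[i]) for i, vid in enumerate(all_ids)}

    def alleles_for(ids: list[str]) -> tuple[list[str], list[str]]:
        pairs = [registry[v] for v in ids]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    # --- exposure trait --------------------------------------------------
    exp_ids = inst_ids + bg_ids
    exp_true = np.concatenate([inst_beta, np.zeros(cfg.n_null_background)])
    ea, oa = alleles_for(exp_ids)
    exposure = simulate_gwas(
        exp_true,
        np.concatenate([inst_eaf, bg_eaf]),
        cfg.exposure_n,
        exp_trait,
        int(rng.integers(2**31)),
        variant_ids=exp_ids,
        chrom=inst_chrom + bg_chrom,
        pos=inst_pos + bg_pos,
        effect_allele=ea,
        other_allele=oa,
    )

    # --- protein panel ----------------------------------------------------
    panel: dict[str, SummaryStats] = {}
    for pid in protein_ids:
        meta = pqtl_meta[pid]
        is_mediator = pid == mediator_id
        inst_effect = (
            cfg.beta_exposure_mediator * inst_beta
            if is_mediator
            else rng.normal(0.0, cfg.pleiotropy_sd, n_inst)
        )
        feedback = cfg.beta_outcome_feedback if is_mediator else 0.0
        ids = inst_ids + meta["ids"] + meta["region_ids"] + hf_ids
        true = np.concatenate(
            [inst_effect, meta["effects"], meta["region_effects"], feedback * hf_beta]
        )
        eafs = np.concatenate([inst_eaf, meta["eaf"], meta["region_eaf"], hf_eaf])
        prot_trait = TraitInfo(pid, TraitType.quantitative, cfg.protein_n, sd_y=1.0)
        ea, oa = alleles_for(ids)
        ss = simulate_gwas(
            true,
            eafs,
            cfg.protein_n,
            prot_trait,
            int(rng.integers(2**31)),
            variant_ids=ids,
            chrom=inst_chrom + meta["chrom"] + meta["region_chrom"] + hf_chrom,
            pos=inst_pos + meta["pos"] + meta["region_pos"] + hf_pos,
            effect_allele=ea,
            other_allele=oa,
        )
        panel[pid] = _scramble_orientation(ss, rng)

    # --- outcome ----------------------------------------------------------
    pleio = rng.normal(0.0, cfg.pleiotropy_sd, n_inst)
    out_ids = list(exp_ids) + hf_ids
    out_chrom = inst_chrom + bg_chrom + hf_chrom
    out_pos = inst_pos + bg_pos + hf_pos
    out_eaf = list(inst_eaf) + list(bg_eaf) + list(hf_eaf)
    out_true = (
        list(cfg.beta_total * inst_beta + pleio)
        + [0.0] * cfg.n_null_background
        + list(hf_beta)
    )
    for pid in protein_ids:
        meta = pqtl_meta[pid]
        out_ids += meta["ids"] + meta["region_ids"]
        out_chrom += meta["chrom"] + meta["region_chrom"]
        out_pos += meta["pos"] + meta["region_pos"]
        out_eaf += list(meta["eaf"]) + list(meta["region_eaf"])
        slope = cfg.beta_mediator_outcome if pid == mediator_id else 0.0
        out_true += list(slope * meta["effects"]) + list(slope * meta["region_effects"])
    ea, oa = alleles_for(out_ids)
    outcome = simulate_gwas(
        np.array(out_true),
        np.array(out_eaf),
        out_trait.n_total,
        out_trait,
        int(rng.integers(2**31)),
        variant_ids=out_ids,
        chrom=out_chrom,
        pos=out_pos,
        effect_allele=ea,
        other_allele=oa,
    )
    outcome = _scramble_orientation(outcome, rng)

    manifest = pd.DataFrame(
        {"protein_id": protein_ids, "gene_chrom": gene_chrom, "gene_tss": gene_tss}
    )
    med_meta = pqtl_meta[mediator_id]
    truth = ScenarioTruth(
        beta1=cfg.beta_exposure_mediator,
        beta2=cfg.beta_mediator_outcome,
        beta_direct=cfg.beta_direct,
        beta_total=cfg.beta_total,
        proportion=cfg.mediated_proportion,
        mediator_id=mediator_id,
        exposure_instrument_ids=tuple(inst_ids),
        mediator_pqtl_ids=tuple(med_meta["ids"]),
        cis_pqtl_id=med_meta["ids"][0],
    )
    return MediationScenario(exposure, panel, outcome, manifest, truth, cfg)


@dataclass(frozen=True)
class RegionConfig:
    """Study conditions for an LD-correlated two-trait region.

    LD decays exponentially with variant index distance,
    r_ij = exp(−|i−j|/ld_decay); equal causal indices simulate a shared
    causal variant, distinct ones two independent signals; lambda is the
    causal variant's expected z-score (non-centrality).
    """

    n_variants: int = 100
    ld_decay: float = 10.0
    causal_index_1: int | None = None  # defaults to the middle variant
    causal_index_2: int | None = None
    lambda_1: float = 8.0
    lambda_2: float = 8.0
    n_1: int = 35_559
    n_2: int = 977_323
    case_fraction_2: float | None = 47_309 / 977_323
    seed: int = 0


def simulate_coloc_region(
    cfg: RegionConfig,
) -> tuple[RegionStats, RegionStats, LDMatrix]:
    """Draw two traits' region statistics under the single-causal model.

    Per trait the z-score vector is multivariate normal with mean
    λ·Σ[:, causal] and covariance Σ (the LD matrix); betas and SEs are
    back-computed through the standardized-trait SE model so the pair
    (beta, se) carries exactly the drawn z.
    """
    k = cfg.n_variants
    c1 = k // 2 if cfg.causal_index_1 is None else cfg.causal_index_1
    c2 = k // 2 if cfg.causal_index_2 is None else cfg.causal_index_2
    for c in (c1, c2):
        if not (0 <= c < k):
            raise ValueError("causal index out of range")
    rng = np.random.default_rng(cfg.seed)
    idx = np.arange(k)
    sigma = toeplitz(np.exp(-idx / max(cfg.ld_decay, 1e-12)))
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = sigma + 1e-8 * np.eye(k)  # jitter for numerical PD
        L = np.linalg.cholesky(sigma)
    ids = [f"rs_region{i + 1}" for i in range(k)]
    eaf = rng.uniform(0.10, 0.90, k)

    trait1 = TraitInfo("region_trait1", TraitType.quantitative, cfg.n_1, sd_y=1.0)
    if cfg.case_fraction_2 is None:
        trait2 = TraitInfo("region_trait2", TraitType.quantitative, cfg.n_2, sd_y=1.0)
    else:
        trait2 = TraitInfo(
            "region_trait2",
            TraitType.binary,
            cfg.n_2,
            n_cases=int(round(cfg.case_fraction_2 * cfg.n_2)),
        )

    def draw(lam: float, causal: int, trait: TraitInfo) -> RegionStats:
        z = lam * sigma[:, causal] + L @ rng.standard_normal(k)
        se = _se_model(eaf, trait)
        return RegionStats(trait, list(ids), z * se, se, eaf)

    r1 = draw(cfg.lambda_1, c1, trait1)
    r2 = draw(cfg.lambda_2, c2, trait2)
    ld = LDMatrix(list(ids), sigma)
    return r1, r2, ld


# ---------------------------------------------------------------------------
# Scenario persistence (canonical TSV layout consumed by the pipeline)


def write_scenario(scenario: MediationScenario, outdir: str | Path) -> Path:
    """Write a scenario directory: exposure/outcome/panel TSVs, manifest,
    trait metadata and the ground-truth record."""
    outdir = Path(outdir)
    (outdir / "panel").mkdir(parents=True, exist_ok=True)
    write_sumstats(scenario.exposure, outdir / "exposure.tsv")
    write_sumstats(scenario.outcome, outdir / "outcome.tsv")
    manifest = scenario.manifest.copy()
    files = []
    for pid in manifest["protein_id"]:
        rel = f"panel/{pid}.tsv"
        write_sumstats(scenario.panel[pid], outdir / rel)
        files.append(rel)
    manifest.insert(1, "file", files)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    traits = []
    for ss in [scenario.exposure, scenario.outcome, *scenario.panel.values()]:
        t = ss.trait
        traits.append(
            {
                "trait_id": t.trait_id,
                "trait_type": t.trait_type.value,
                "n_total": t.n_total,
                "n_cases": "" if t.n_cases is None else t.n_cases,
                "sd_y": "" if t.sd_y is None else t.sd_y,
            }
        )
    pd.DataFrame(traits).to_csv(outdir / "traits.tsv", sep="\t", index=False)

    tr = scenario.truth
    pd.DataFrame(
        [
            {
                "beta1": tr.beta1,
                "beta2": tr.beta2,
                "beta_direct": tr.beta_direct,
                "beta_total": tr.beta_total,
                "proportion": tr.proportion,
                "mediator_id": tr.mediator_id,
                "exposure_instruments": ",".join(tr.exposure_instrument_ids),
                "mediator_pqtls": ",".join(tr.mediator_pqtl_ids),
                "cis_pqtl": tr.cis_pqtl_id,
            }
        ]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.12g")
    return outdir
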