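"""Proteome-wide two-step screening, mediation and reverse MR.

The two-step design asks whether a drug-target exposure acts on a
disease outcome through circulating proteins:

* **step 1** — exposure → each protein in the panel, using the exposure's
  instruments; Benjamini–Hochberg FDR across the panel marks the
  exposure-driven proteins;
* **step 2** — each driven protein → outcome, instrumented by the
  protein's own pQTLs; FDR again, plus a direction-consistency check
  (IVW and Egger slopes must agree in sign — a disagreement invalidates
  the causal claim, so the protein is excluded from mediation);
* **mediation** — product of coefficients: the indirect effect is
  β1·β2 (exposure→protein times protein→outcome) with a delta-method SE,
  and the mediated proportion is β1·β2/β3 relative to the total effect,
  with a three-term delta-method CI;
* **reverse MR** — outcome → protein with the outcome's own genome-wide
  instruments, to rule out reverse causation.

:func:`run_mr_battery` bundles every estimator with the full sensitivity
battery for a single harmonized trait pair and backs both the reverse MR
and the pipeline's headline fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
from zlib import crc32

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import (
    EggerFit,
    MREstimate,
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
)
from .instruments import InstrumentSet, LDMatrix, select_instruments
from .sensitivity import (
    HeterogeneityReport,
    LooRow,
    PressoResult,
    RadialResult,
    choose_effects_model,
    cochran_q,
    leave_one_out,
    mr_presso,
    radial_ivw,
)
from .sumstats import HarmonizedPairs, InputError, SummaryStats, harmonize

__all__ = [
    "ScreenRow",
    "ScreenResult",
    "MediationResult",
    "MRReport",
    "bh_fdr",
    "screen_step1",
    "screen_step2",
    "direction_consistency",
    "mediation",
    "reverse_mr",
    "run_mr_battery",
]

_Z95 = 1.959963984540054


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q


def _stable_seed(seed: int, label: str) -> int:
    """Deterministic per-item seed, independent of iteration order."""
    return (seed + crc32(label.encode())) % (2**31)


@dataclass
class ScreenRow:
    protein_id: str
    estimate: MREstimate
    q_value: float
    passes_fdr: bool
    direction_consistent: bool | None = None
    effects_model: str = "fixed"
    q_pval: float | None = None
    i2: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None


@dataclass
class ScreenResult:
    rows: list[ScreenRow]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def passing(self) -> list[ScreenRow]:
        return [r for r in self.rows if r.passes_fdr]

    def __len__(self) -> int:
        return len(self.rows)


def _fit_protein(
    pairs: HarmonizedPairs, *, n_sim: int, seed: int
) -> tuple[MREstimate, dict]:
    """IVW with the heterogeneity-selected effects model plus recorded
    sensitivity flags for one trait pair."""
    k = len(pairs)
    flags: dict = {
        "effects_model": "fixed",
        "q_pval": None,
        "i2": None,
        "egger_intercept_p": None,
        "presso_global_p": None,
        "egger_fit": None,
    }
    if k >= 2:
        het = cochran_q(pairs, "ivw")
        flags["effects_model"] = choose_effects_model(het)
        flags["q_pval"], flags["i2"] = het.q_pval, het.i2
    est = ivw(pairs, flags["effects_model"]) if k >= 2 else wald_ratio(pairs)
    if k >= 3:
        fit = egger(pairs)
        flags["egger_fit"] = fit
        flags["egger_intercept_p"] = fit.intercept_p
    if k >= 4:
        flags["presso_global_p"] = mr_presso(pairs, n_sim=n_sim, seed=seed).global_pval
    return est, flags


def _sensitivity_clean(flags: dict, alpha: float = 0.05) -> bool:
    for key in ("egger_intercept_p", "presso_global_p", "q_pval"):
        if flags[key] is not None and flags[key] < alpha:
            return False
    return True


def screen_step1(
    exposure_instruments: InstrumentSet,
    exposure_ss: SummaryStats,
    panel: Mapping[str, SummaryStats],
    *,
    fdr_alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
    strict: bool = False,
    palindrome_eaf_window: float = 0.08,
) -> ScreenResult:
    """Exposure → every panel protein, with FDR across the panel.

    Sensitivity gates (Egger intercept, global pleiotropy test, Cochran Q)
    are recorded per protein; under ``strict`` a protein failing any gate
    is excluded from the FDR-passing set.
    """
    if not panel:
        raise InputError("empty protein panel")
    exp_sub = exposure_ss.subset(exposure_instruments.variant_ids)
    rows_raw: list[tuple[str, MREstimate, dict]] = []
    skipped: list[tuple[str, str]] = []
    for pid in sorted(panel):
        try:
            pairs = harmonize(exp_sub, panel[pid], palindrome_eaf_window)
        except InputError as exc:
            skipped.append((pid, str(exc)))
            continue
        if len(pairs) < 1:
            skipped.append((pid, "no overlapping instrument after harmonization"))
            continue
        est, flags = _fit_protein(
            pairs, n_sim=n_sim, seed=_stable_seed(seed, f"step1:{pid}")
        )
        rows_raw.append((pid, est, flags))
    if not rows_raw:
        return ScreenResult([], skipped)
    q = bh_fdr([est.pval for _, est, _ in rows_raw])
    rows = []
    for (pid, est, flags), qv in zip(rows_raw, q):
        ok = qv < fdr_alpha
        if strict and not _sensitivity_clean(flags):
            ok = False
        rows.append(
            ScreenRow(
                protein_id=pid,
                estimate=est,
                q_value=float(qv),
                passes_fdr=bool(ok),
                effects_model=flags["effects_model"],
                q_pval=flags["q_pval"],
                i2=flags["i2"],
                egger_intercept_p=flags["egger_intercept_p"],
                presso_global_p=flags["presso_global_p"],
            )
        )
    return ScreenResult(rows, skipped)


def direction_consistency(ivw_est: MREstimate, egger_fit: EggerFit) -> bool:
    """True iff the IVW and Egger slopes agree in sign (zero counts as
    inconsistent) — a disagreement invalidates the causal direction."""
    s1, s2 = np.sign(ivw_est.beta), np.sign(egger_fit.slope.beta)
    if s1 == 0 or s2 == 0:
        return False
    return bool(s1 == s2)


def screen_step2(
    protein_instrument_sets: Mapping[str, InstrumentSet],
    protein_ss: Mapping[str, SummaryStats],
    outcome_ss: SummaryStats,
    *,
    fdr_alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int = 0,
    strict: bool = False,
    palindrome_eaf_window: float = 0.08,
) -> ScreenResult:
    """Each step-1 survivor → outcome, instrumented by its own pQTLs."""
    rows_raw: list[tuple[str, MREstimate, dict, bool | None]] = []
    skipped: list[tuple[str, str]] = []
    for pid in sorted(protein_instrument_sets):
        inst = protein_instrument_sets[pid]
        try:
            sub = protein_ss[pid].subset(inst.variant_ids)
            pairs = harmonize(sub, outcome_ss, palindrome_eaf_window)
        except (InputError, KeyError) as exc:
            skipped.append((pid, str(exc)))
            continue
        if len(pairs) < 1:
            skipped.append((pid, "no overlapping instrument after harmonization"))
            continue
        est, flags = _fit_protein(
            pairs, n_sim=n_sim, seed=_stable_seed(seed, f"step2:{pid}")
        )
        consistent = (
            direction_consistency(est, flags["egger_fit"])
            if flags["egger_fit"] is not None
            else None
        )
        rows_raw.append((pid, est, flags, consistent))
    if not rows_raw:
        return ScreenResult([], skipped)
    q = bh_fdr([est.pval for _, est, _, _ in rows_raw])
    rows = []
    for (pid, est, flags, consistent), qv in zip(rows_raw, q):
        ok = qv < fdr_alpha
        if strict and not _sensitivity_clean(flags):
            ok = False
        rows.append(
            ScreenRow(
                protein_id=pid,
                estimate=est,
                q_value=float(qv),
                passes_fdr=bool(ok),
                direction_consistent=consistent,
                effects_model=flags["effects_model"],
                q_pval=flags["q_pval"],
                i2=flags["i2"],
                egger_intercept_p=flags["egger_intercept_p"],
                presso_global_p=flags["presso_global_p"],
            )
        )
    return ScreenResult(rows, skipped)


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients mediation with delta-method inference.

    ``total`` is β3 (exposure→outcome), ``direct_a`` β1 (exposure→
    mediator), ``direct_b`` β2 (mediator→outcome); the indirect effect is
    β1·β2 and the mediated proportion β1·β2/β3.
    """

    total: float
    direct_a: float
    direct_b: float
    indirect: float
    indirect_se: float
    indirect_p: float
    indirect_low: float
    indirect_high: float
    proportion: float
    proportion_se: float
    proportion_low: float
    proportion_high: float


def mediation(
    total: MREstimate, direct_a: MREstimate, direct_b: MREstimate
) -> MediationResult:
    """Two-step mediation arithmetic from three independent MR estimates.

    The indirect-effect SE uses the independent-samples delta method
    √(β1²·se2² + β2²·se1²) (no covariance term: the three fits come from
    non-overlapping samples); the proportion CI uses the full three-term
    gradient of β1·β2/β3.
    """
    b1, s1 = direct_a.beta, direct_a.se
    b2, s2 = direct_b.beta, direct_b.se
    b3, s3 = total.beta, total.se
    if b3 == 0:
        raise InputError("total effect is zero; mediated proportion undefined")
    indirect = b1 * b2
    ind_se = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    if ind_se == 0:
        ind_p = 0.0 if indirect != 0 else 1.0
    else:
        ind_p = float(2.0 * stats.norm.sf(abs(indirect / ind_se)))
    prop = indirect / b3
    grad = np.array([b2 / b3, b1 / b3, -indirect / b3**2])
    prop_se = float(np.sqrt(np.sum(grad**2 * np.array([s1, s2, s3]) ** 2)))
    return MediationResult(
        total=b3,
        direct_a=b1,
        direct_b=b2,
        indirect=indirect,
        indirect_se=ind_se,
        indirect_p=ind_p,
        indirect_low=indirect - _Z95 * ind_se,
        indirect_high=indirect + _Z95 * ind_se,
        proportion=prop,
        proportion_se=prop_se,
        proportion_low=prop - _Z95 * prop_se,
        proportion_high=prop + _Z95 * prop_se,
    )


@dataclass
class MRReport:
    """All estimators plus the full sensitivity battery for one pair."""

    estimates: dict[str, MREstimate]
    effects_model: str
    heterogeneity: dict[str, HeterogeneityReport]
    egger_fit: EggerFit | None
    presso: PressoResult | None
    radial: RadialResult | None
    loo: list[LooRow]
    n_snp: int

    @property
    def primary(self) -> MREstimate:
        """The headline estimate: IVW (Wald ratio for a single SNP)."""
        for name in ("ivw", "wald_ratio"):
            if name in self.estimates:
                return self.estimates[name]
        raise KeyError("no primary estimate")


def run_mr_battery(
    pairs: HarmonizedPairs,
    *,
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> MRReport:
    """Every applicable estimator and diagnostic for one harmonized pair
    set; estimators demanding more instruments than available are omitted
    rather than failing."""
    k = len(pairs)
    if k < 1:
        raise InputError("no harmonized pairs")
    estimates: dict[str, MREstimate] = {}
    heterogeneity: dict[str, HeterogeneityReport] = {}
    egger_fit = None
    presso = None
    radial = None
    loo: list[LooRow] = []
    effects_model = "fixed"
    if k == 1:
        estimates["wald_ratio"] = wald_ratio(pairs)
    else:
        het = cochran_q(pairs, "ivw")
        heterogeneity["ivw"] = het
        effects_model = choose_effects_model(het)
        est = ivw(pairs, effects_model)
        estimates["ivw"] = MREstimate("ivw", est.beta, est.se, est.pval, est.n_snp)
        radial = radial_ivw(pairs)
    if k >= 3:
        egger_fit = egger(pairs)
        estimates["egger"] = egger_fit.slope
        heterogeneity["egger"] = cochran_q(pairs, "egger")
        estimates["weighted_median"] = weighted_median(
            pairs, n_boot=n_boot, seed=_stable_seed(seed, "wm")
        )
        estimates["simple_mode"] = mode_estimate(
            pairs, weighted=False, n_boot=n_boot, seed=_stable_seed(seed, "sm")
        )
        estimates["weighted_mode"] = mode_estimate(
            pairs, weighted=True, n_boot=n_boot, seed=_stable_seed(seed, "wmode")
        )
        loo = leave_one_out(pairs, effects_model)
    if k >= 4:
        presso = mr_presso(pairs, n_sim=n_sim, seed=_stable_seed(seed, "presso"))
    return MRReport(
        estimates=estimates,
        effects_model=effects_model,
        heterogeneity=heterogeneity,
        egger_fit=egger_fit,
        presso=presso,
        radial=radial,
        loo=loo,
        n_snp=k,
    )


def reverse_mr(
    outcome_ss: SummaryStats,
    mediator_ss: SummaryStats,
    p_threshold: float = 5e-8,
    *,
    ld: LDMatrix | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
    palindrome_eaf_window: float = 0.08,
    **select_kwargs,
) -> MRReport:
    """Outcome → mediator MR with the outcome's own instruments.

    Selects genome-wide-significant, pruned instruments from the outcome
    summary statistics and runs the full estimator + sensitivity battery
    against the mediator.
    """
    inst = select_instruments(outcome_ss, p_threshold=p_threshold, ld=ld, **select_kwargs)
    sub = outcome_ss.subset(inst.variant_ids)
    pairs = harmonize(sub, mediator_ss, palindrome_eaf_window)
    if len(pairs) < 1:
        raise InputError("no outcome instrument overlaps the mediator data")
    return run_mr_battery(pairs, seed=seed, n_boot=n_boot, n_sim=n_sim)
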