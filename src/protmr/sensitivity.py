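"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

An MR estimate is only credible when the instruments tell a consistent
story.  This module implements the standard battery:

* :func:`cochran_q` — Cochran's Q about the IVW (or Egger) fit and the
  I² index; substantial heterogeneity is flagged when the Q p-value is
  below 0.05 *and* I² exceeds 50%, the rule :func:`choose_effects_model`
  uses to switch the IVW fit from fixed to random effects;
* :func:`egger_intercept_test` — directional-pleiotropy flag from the
  Egger intercept;
* :func:`mr_presso` — simulation-based residual-sum-of-squares global
  pleiotropy test with per-variant outlier p-values (Bonferroni);
* :func:`radial_ivw` — radial (modified second-stage) regression whose
  per-variant Q contributions sum exactly to Cochran's IVW Q, with
  chi-square outlier flags;
* :func:`leave_one_out` — influence of each single instrument on the
  pooled IVW estimate.

All stochastic diagnostics are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, EggerFit, egger, ivw, _ratios_weights
from .sumstats import HarmonizedPairs, InputError

__all__ = [
    "HeterogeneityReport",
    "PressoResult",
    "RadialResult",
    "LooRow",
    "cochran_q",
    "choose_effects_model",
    "egger_intercept_test",
    "mr_presso",
    "radial_ivw",
    "leave_one_out",
]


@dataclass(frozen=True)
class HeterogeneityReport:
    method: str  # "ivw" or "egger"
    Q: float
    df: int
    q_pval: float
    i2: float  # percentage in [0, 100]


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    n_sim: int
    seed: int


@dataclass(frozen=True)
class RadialResult:
    contributions: dict[str, float]
    outlier_ids: list[str]
    total_Q: float


@dataclass(frozen=True)
class LooRow:
    excluded_id: str
    estimate: MREstimate


def _i2(Q: float, df: int) -> float:
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def cochran_q(pairs: HarmonizedPairs, method: str = "ivw") -> HeterogeneityReport:
    """Cochran's Q and I² about the IVW mean or the Egger line.

    Q = Σ wᵢ (rᵢ − fittedᵢ)² with wᵢ the inverse Wald-ratio variance;
    df = k−1 (IVW) or k−2 (Egger); I² = max(0, (Q − df)/Q)·100.
    """
    k = len(pairs)
    r, w = _ratios_weights(pairs)
    if method == "ivw":
        if k < 2:
            raise InputError("cochran_q(ivw) needs at least 2 pairs")
        beta = float(np.sum(w * r) / np.sum(w))
        fitted = np.full(k, beta)
        df = k - 1
    elif method == "egger":
        if k < 3:
            raise InputError("cochran_q(egger) needs at least 3 pairs")
        fit = egger(pairs)
        # Egger line in oriented space: y = a + b|x|; back to ratio space
        x = pairs.beta_exp
        fitted = fit.slope.beta + fit.intercept / np.abs(x)
        df = k - 2
    else:
        raise ValueError(f"unknown method {method!r}")
    Q = float(np.sum(w * (r - fitted) ** 2))
    q_pval = float(stats.chi2.sf(Q, df)) if Q > 0 else 1.0
    return HeterogeneityReport(method, Q, df, q_pval, _i2(Q, df))


def choose_effects_model(het: HeterogeneityReport) -> str:
    """``random`` iff substantial heterogeneity (Q p < 0.05 and I² > 50%)."""
    return "random" if (het.q_pval < 0.05 and het.i2 > 50.0) else "fixed"


def egger_intercept_test(fit: EggerFit, alpha: float = 0.05) -> bool:
    """True when the Egger intercept flags directional pleiotropy."""
    return fit.intercept_p < alpha


def mr_presso(
    pairs: HarmonizedPairs,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-of-squares global test with outlier search.

    The observed statistic is the weighted sum of each variant's squared
    residual about the IVW fit that *excludes* that variant.  Its null
    distribution is built from ``n_sim`` parametric simulations redrawing
    every (x, y) from normal(fitted, se); the global p-value uses add-one
    smoothing, per-variant outlier p-values come from each variant's own
    simulated residual distribution with a Bonferroni adjustment.
    """
    k = len(pairs)
    if k < 4:
        raise InputError(f"mr_presso needs at least 4 pairs, got {k}")
    ids = pairs.variant_ids
    x, sx, y, sy = pairs.beta_exp, pairs.se_exp, pairs.beta_out, pairs.se_out
    if np.any(x == 0):
        raise InputError("exposure beta is zero for at least one variant")
    w = 1.0 / sy**2

    def loo_slopes(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        sxy = np.sum(w * X * Y, axis=-1, keepdims=True)
        sxx = np.sum(w * X * X, axis=-1, keepdims=True)
        return (sxy - w * X * Y) / (sxx - w * X * X)

    b_loo = loo_slopes(x[None, :], y[None, :])[0]
    obs_res = w * (y - b_loo * x) ** 2
    rss_obs = float(np.sum(obs_res))

    rng = np.random.default_rng(seed)
    X = rng.normal(x, sx, size=(n_sim, k))
    Y = rng.normal(b_loo * x, sy, size=(n_sim, k))
    B = loo_slopes(X, Y)
    res = w * (Y - B * X) ** 2
    rss = res.sum(axis=1)
    global_pval = float((1 + np.sum(rss >= rss_obs)) / (n_sim + 1))

    outlier_pvals: dict[str, float] = {}
    outlier_ids: list[str] = []
    for i, vid in enumerate(ids):
        p = float((1 + np.sum(res[:, i] >= obs_res[i])) / (n_sim + 1))
        p_adj = min(1.0, k * p)
        outlier_pvals[vid] = p_adj
        if p_adj < outlier_alpha:
            outlier_ids.append(vid)
    return PressoResult(rss_obs, global_pval, outlier_ids, outlier_pvals, n_sim, seed)


def radial_ivw(pairs: HarmonizedPairs, alpha: float = 0.05) -> RadialResult:
    """First-order radial regression with per-variant Q contributions.

    Regressing rᵢ√wᵢ on √wᵢ through the origin recovers the IVW slope;
    each variant's squared radial residual is its contribution to
    Cochran's Q (the contributions sum to Q exactly).  Variants whose
    contribution exceeds the χ²(1) upper quantile at ``alpha``/k are
    flagged as outliers.
    """
    k = len(pairs)
    if k < 2:
        raise InputError(f"radial_ivw needs at least 2 pairs, got {k}")
    r, w = _ratios_weights(pairs)
    slope = float(np.sum(w * r) / np.sum(w))
    contrib = w * (r - slope) ** 2
    thresh = float(stats.chi2.isf(alpha / k, df=1))
    ids = pairs.variant_ids
    outliers = [vid for vid, c in zip(ids, contrib) if c > thresh]
    return RadialResult(dict(zip(ids, map(float, contrib))), outliers, float(contrib.sum()))


def leave_one_out(
    pairs: HarmonizedPairs, effects_model: str | None = None
) -> list[LooRow]:
    """IVW re-estimated k times, excluding one instrument at a time.

    Uses the effects model the full fit selects (Q/I² rule) unless one is
    given explicitly.
    """
    k = len(pairs)
    if k < 3:
        raise InputError(f"leave_one_out needs at least 3 pairs, got {k}")
    if effects_model is None:
        effects_model = choose_effects_model(cochran_q(pairs, "ivw"))
    rows = []
    for vid in pairs.variant_ids:
        sub = pairs.drop_variants([vid])
        rows.append(LooRow(vid, ivw(sub, effects_model)))
    return rows
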