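"""Two-sample MR point estimators.

All estimators consume :class:`~protmr.sumstats.HarmonizedPairs` — per
variant i an exposure effect x_i (se sx_i) and an outcome effect y_i
(se sy_i) aligned to the same effect allele — and summarize the per-SNP
Wald ratios r_i = y_i / x_i:

* ``wald_ratio``       — single-instrument ratio, se = sy/|x| (first-order delta);
* ``ivw``              — inverse-variance-weighted mean of the ratios,
  fixed effects or multiplicative random effects (SE inflated by
  √max(1, Q/(k−1)), so it reduces exactly to fixed effects when the
  instruments are homogeneous);
* ``egger``            — weighted regression of y on x with a free
  intercept (average directional pleiotropy), t inference with k−2 df;
* ``weighted_median``  — the ratio at cumulative normalized weight 0.5,
  consistent when up to half the weight comes from invalid instruments;
* ``mode_estimate``    — simple/weighted mode via a normal-kernel density
  over the ratios (Silverman bandwidth × phi).

Bootstrap standard errors (weighted median and modes) use a seeded
parametric bootstrap redrawing every (x_i, y_i) from its sampling
distribution.  Binary outcomes are analyzed on the log-odds scale and
reported also as odds ratios via ``or_from_logodds``.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy import stats

from .sumstats import HarmonizedPairs, InputError

__all__ = [
    "MREstimate",
    "EggerFit",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "or_from_logodds",
]


def or_from_logodds(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect to an OR with a 95% Wald interval."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.959963984540054 * se)),
        float(np.exp(beta + 1.959963984540054 * se)),
    )


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int

    @property
    def or_point(self) -> float:
        return or_from_logodds(self.beta, self.se)[0]

    @property
    def or_low(self) -> float:
        return or_from_logodds(self.beta, self.se)[1]

    @property
    def or_high(self) -> float:
        return or_from_logodds(self.beta, self.se)[2]

    @property
    def ci_low(self) -> float:
        return self.beta - 1.959963984540054 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + 1.959963984540054 * self.se


@dataclass(frozen=True)
class EggerFit:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _ratios_weights(pairs: HarmonizedPairs) -> tuple[np.ndarray, np.ndarray]:
    x, sx, y, sy = pairs.beta_exp, pairs.se_exp, pairs.beta_out, pairs.se_out
    if np.any(x == 0):
        bad = pairs.variant_ids[int(np.argmax(x == 0))]
        raise InputError(f"exposure beta is zero for variant {bad!r}")
    r = y / x
    w = (x / sy) ** 2  # inverse Wald-ratio variance, first order
    return r, w


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(pairs: HarmonizedPairs) -> MREstimate:
    """Single-instrument causal estimate y/x with first-order delta SE."""
    if len(pairs) != 1:
        raise InputError(f"wald_ratio expects exactly 1 pair, got {len(pairs)}")
    x = float(pairs.beta_exp[0])
    if x == 0:
        raise InputError("exposure beta is zero")
    beta = float(pairs.beta_out[0]) / x
    se = float(pairs.se_out[0]) / abs(x)
    return MREstimate("wald_ratio", beta, se, _norm_p(beta / se), 1)


def ivw(pairs: HarmonizedPairs, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    With a single pair this is exactly the Wald ratio.  ``random`` applies
    multiplicative overdispersion: the fixed-effects SE is inflated by
    √max(1, Q/(k−1)) so the two models coincide under homogeneity.
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    k = len(pairs)
    if k == 0:
        raise InputError("no harmonized pairs")
    if k == 1:
        est = wald_ratio(pairs)
        return MREstimate(f"ivw_{effects_model}", est.beta, est.se, est.pval, 1)
    r, w = _ratios_weights(pairs)
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if effects_model == "random":
        q = float(np.sum(w * (r - beta) ** 2))
        se *= float(np.sqrt(max(1.0, q / (k - 1))))
    return MREstimate(f"ivw_{effects_model}", beta, se, _norm_p(beta / se), k)


def egger(pairs: HarmonizedPairs) -> EggerFit:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept estimating average directional pleiotropy.

    Every pair is first oriented so the exposure effect is positive (the
    fit is then invariant to joint sign flips, as it must be — the choice
    of effect allele is arbitrary).  Weights are 1/se_out²; inference uses
    the t distribution with k−2 df, and both SEs carry the multiplicative
    overdispersion factor √max(1, Q/(k−2)).
    """
    k = len(pairs)
    if k < 3:
        raise InputError(f"egger needs at least 3 pairs, got {k}")
    x, y, sy = pairs.beta_exp, pairs.beta_out, pairs.se_out
    if np.any(x == 0):
        raise InputError("exposure beta is zero for at least one variant")
    sgn = np.sign(x)
    xs, ys = np.abs(x), y * sgn
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), xs])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * ys)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = ys - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (k - 2))
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))
    df = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(coef[1] / se[1]), df))
    p_int = float(2.0 * stats.t.sf(abs(coef[0] / se[0]), df))
    slope = MREstimate("egger", float(coef[1]), float(se[1]), p_slope, k)
    return EggerFit(slope, float(coef[0]), float(se[0]), p_int)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation between order statistics.

    The cumulative normalized weight is evaluated at mid-step positions
    (cumsum(w) − w/2) / Σw, the standard convention under which equal
    weights reproduce the ordinary sample median.
    """
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(p, 0.5, side="left"))
    return float(r[j - 1] + (0.5 - p[j - 1]) / (p[j] - p[j - 1]) * (r[j] - r[j - 1]))


def _bootstrap_se(pairs: HarmonizedPairs, stat, n_boot: int, seed: int) -> float:
    """SD of a ratio statistic over a parametric bootstrap of the pairs."""
    rng = np.random.default_rng(seed)
    k = len(pairs)
    bx = rng.normal(pairs.beta_exp, pairs.se_exp, size=(n_boot, k))
    by = rng.normal(pairs.beta_out, pairs.se_out, size=(n_boot, k))
    bx = np.where(bx == 0, 1e-300, bx)
    sy = pairs.se_out
    vals = np.empty(n_boot)
    for b in range(n_boot):
        vals[b] = stat(by[b] / bx[b], (bx[b] / sy) ** 2)
    return float(np.std(vals, ddof=1))


def weighted_median(
    pairs: HarmonizedPairs, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator (valid if ≤50% of weight is pleiotropic)."""
    k = len(pairs)
    if k < 3:
        raise InputError(f"weighted_median needs at least 3 pairs, got {k}")
    r, w = _ratios_weights(pairs)
    beta = _weighted_median(r, w)
    se = _bootstrap_se(pairs, _weighted_median, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _norm_p(beta / se), k)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    k = ratios.size
    mean = np.sum(weights * ratios) / np.sum(weights)
    s = float(np.sqrt(np.sum(weights * (ratios - mean) ** 2) / np.sum(weights)))
    h = phi * 1.06 * s * k ** (-0.2)
    if h == 0.0:  # all ratios identical
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 2 * h, ratios.max() + 2 * h, 1024)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    pairs: HarmonizedPairs,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple (uniform-weight) or weighted mode of the Wald ratios.

    The mode is the argmax of a normal-kernel density over the ratios with
    Silverman bandwidth 1.06·s·k^(−1/5) scaled by ``phi`` (the main tuning
    knob); s is the weighted SD of the ratios when ``weighted``.
    """
    k = len(pairs)
    if k < 3:
        raise InputError(f"mode_estimate needs at least 3 pairs, got {k}")
    r, w = _ratios_weights(pairs)
    uw = np.ones(k)

    def stat(ratios, weights):
        return _kde_mode(ratios, weights if weighted else np.ones(ratios.size), phi)

    beta = _kde_mode(r, w if weighted else uw, phi)
    se = _bootstrap_se(pairs, stat, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    if se == 0:
        return MREstimate(method, beta, np.finfo(float).tiny, 0.0, k)
    return MREstimate(method, beta, se, _norm_p(beta / se), k)
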