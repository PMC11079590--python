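"""MR estimators against hand arithmetic and independent regression oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from protmr.estimators import (
    _weighted_median,
    egger,
    ivw,
    mode_estimate,
    or_from_logodds,
    wald_ratio,
    weighted_median,
)
from protmr.sumstats import HarmonizedPairs, InputError


def pairs_of(bx, sx, by, sy):
    return HarmonizedPairs.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_hand_example(self):
        p = pairs_of([0.1], [0.01], [-0.05], [0.02])
        est = wald_ratio(p)
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome_gives_zero_effect_p_one(self):
        est = wald_ratio(pairs_of([0.1], [0.01], [0.0], [0.02]))
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_ratio_invariant_to_common_scaling(self):
        a = wald_ratio(pairs_of([0.1], [0.01], [-0.05], [0.02]))
        b = wald_ratio(pairs_of([0.3], [0.03], [-0.15], [0.06]))
        assert a.beta == pytest.approx(b.beta)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(pairs_of([0.0], [0.01], [0.1], [0.02]))


class TestIVW:
    def test_hand_example_two_equal_weight_ratios(self):
        # ratios 1 and 3, Wald SE 1 each: beta 2, se 1/sqrt(2)
        p = pairs_of([1.0, 1.0], [0.0001, 0.0001], [1.0, 3.0], [1.0, 1.0])
        est = ivw(p, "fixed")
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.7071067811865476, rel=1e-9)

    def test_dominant_weight_pulls_to_that_ratio(self):
        p = pairs_of([1.0, 1.0], [1e-6, 1e-6], [1.0, 3.0], [1e-6, 10.0])
        assert ivw(p, "fixed").beta == pytest.approx(1.0, abs=1e-6)

    def test_single_pair_reduces_to_wald_ratio(self):
        p = pairs_of([0.1], [0.01], [-0.05], [0.02])
        est = ivw(p, "fixed")
        w = wald_ratio(p)
        assert (est.beta, est.se) == (w.beta, w.se)

    def test_matches_wls_no_intercept_oracle(self, rng):
        for _ in range(20):
            k = 20
            x = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
            sx = rng.uniform(0.001, 0.01, k)
            sy = rng.uniform(0.005, 0.05, k)
            y = rng.normal(0.4 * x, sy)
            est = ivw(pairs_of(x, sx, y, sy), "fixed")
            oracle = sm.WLS(y, x, weights=1.0 / sy**2).fit()
            assert est.beta == pytest.approx(float(oracle.params[0]), abs=1e-10)

    def test_random_effects_reduce_to_fixed_under_homogeneity(self):
        x = np.array([0.1, 0.12, 0.15, 0.2])
        y = 0.5 * x
        p = pairs_of(x, 0.001 * np.ones(4), y, 0.01 * np.ones(4))
        f, r = ivw(p, "fixed"), ivw(p, "random")
        assert r.se == pytest.approx(f.se)  # Q ~ 0 -> floor at 1

    def test_random_effects_inflate_se_under_heterogeneity(self):
        x = np.ones(4)
        y = np.array([0.0, 1.0, 2.0, 3.0])
        p = pairs_of(x, 1e-4 * np.ones(4), y, 0.01 * np.ones(4))
        assert ivw(p, "random").se > 10 * ivw(p, "fixed").se


class TestEgger:
    def test_exact_line_recovered(self):
        x = np.array([0.1, 0.2, 0.3])
        y = 0.5 * x  # exact, zero intercept
        fit = egger(pairs_of(x, 0.01 * np.ones(3), y, 0.02 * np.ones(3)))
        assert fit.slope.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_lands_in_intercept(self, rng):
        k = 30
        x = rng.uniform(0.05, 0.3, k)
        sy = rng.uniform(0.005, 0.02, k)
        c = 0.07
        y = 0.5 * x + c + rng.normal(0, sy) * 0.0
        fit = egger(pairs_of(x, 0.001 * np.ones(k), y, sy))
        assert fit.intercept == pytest.approx(c, abs=1e-10)
        assert fit.slope.beta == pytest.approx(0.5, abs=1e-10)
        # independent WLS-with-intercept oracle
        X = sm.add_constant(x)
        oracle = sm.WLS(y, X, weights=1.0 / sy**2).fit()
        assert fit.intercept == pytest.approx(float(oracle.params[0]), abs=1e-10)
        assert fit.slope.beta == pytest.approx(float(oracle.params[1]), abs=1e-10)

    def test_invariant_to_joint_sign_flip_of_any_pair(self, concordant_pairs):
        base = egger(concordant_pairs)
        df = concordant_pairs.df.copy()
        df.loc[2, ["beta_exp", "beta_out"]] *= -1
        flipped = egger(HarmonizedPairs(df, concordant_pairs.exposure_trait,
                                        concordant_pairs.outcome_trait))
        assert flipped.slope.beta == pytest.approx(base.slope.beta, rel=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, rel=1e-12)

    def test_requires_three_pairs(self):
        with pytest.raises(InputError):
            egger(pairs_of([0.1, 0.2], [0.01, 0.01], [0.1, 0.2], [0.02, 0.02]))


class TestWeightedMedian:
    def test_equal_weights_give_sample_median(self):
        p = pairs_of([1, 1, 1], [1e-4] * 3, [1.0, 2.0, 9.0], [1.0, 1.0, 1.0])
        assert weighted_median(p, n_boot=50, seed=1).beta == pytest.approx(2.0)

    def test_dominant_weight_pulls_to_that_ratio(self):
        # nearly all weight on the last ratio; the interpolating convention
        # approaches the dominant ratio as its mass share grows
        p = pairs_of([1, 1, 1], [1e-4] * 3, [1.0, 2.0, 5.0], [10.0, 10.0, 0.1])
        assert weighted_median(p, n_boot=50, seed=1).beta == pytest.approx(5.0, abs=0.01)

    def test_matches_cumulative_scan_oracle(self, rng):
        for _ in range(50):
            k = 5
            r = rng.normal(0, 2, k)
            w = rng.uniform(0.1, 5, k)
            mine = _weighted_median(r, w)
            # independent scan: walk sorted ratios accumulating mid-step mass
            order = np.argsort(r)
            rs, ws = r[order], w[order]
            cum = 0.0
            total = ws.sum()
            pts = []
            for i in range(k):
                pts.append((cum + ws[i] / 2) / total)
                cum += ws[i]
            if pts[0] >= 0.5:
                expect = rs[0]
            elif pts[-1] <= 0.5:
                expect = rs[-1]
            else:
                j = next(i for i in range(k) if pts[i] >= 0.5)
                frac = (0.5 - pts[j - 1]) / (pts[j] - pts[j - 1])
                expect = rs[j - 1] + frac * (rs[j] - rs[j - 1])
            assert mine == pytest.approx(expect, rel=1e-12)

    def test_bootstrap_se_reproducible(self, concordant_pairs):
        a = weighted_median(concordant_pairs, n_boot=200, seed=42)
        b = weighted_median(concordant_pairs, n_boot=200, seed=42)
        assert a.se == b.se


class TestModes:
    def test_degenerate_identical_ratios(self):
        p = pairs_of([1, 1, 1], [1e-4] * 3, [0.7, 0.7, 0.7], [0.1, 0.1, 0.1])
        assert mode_estimate(p, n_boot=50, seed=1).beta == pytest.approx(0.7)

    def test_simple_mode_tracks_cluster_not_mean(self):
        p = pairs_of([1] * 4, [1e-4] * 4, [1.0, 1.0, 1.0, 5.0], [0.5] * 4)
        est = mode_estimate(p, weighted=False, n_boot=50, seed=1)
        assert abs(est.beta - 1.0) < 0.5  # near 1, far from the mean 2

    def test_weighted_mode_follows_dominant_weight(self):
        p = pairs_of([1] * 4, [1e-4] * 4, [1.0, 1.0, 1.0, 5.0], [5.0, 5.0, 5.0, 0.01])
        est = mode_estimate(p, weighted=True, n_boot=50, seed=1)
        assert abs(est.beta - 5.0) < 0.5

    def test_mode_matches_grid_density_oracle(self, rng):
        k = 7
        r = rng.normal(1.0, 0.5, k)
        p = pairs_of(np.ones(k), 1e-6 * np.ones(k), r, np.ones(k))
        est = mode_estimate(p, weighted=False, n_boot=10, seed=1)
        s = r.std()
        h = 1.06 * s * k ** (-0.2)
        grid = np.linspace(r.min() - 2 * h, r.max() + 2 * h, 20001)
        dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2).sum(axis=1)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=2 * (grid[1] - grid[0]) + 1e-3)


class TestORScale:
    def test_headline_or_values(self):
        assert or_from_logodds(-0.82, 0.2755)[0] == pytest.approx(0.44, abs=0.005)
        assert or_from_logodds(-0.21, 0.05)[0] == pytest.approx(0.81, abs=0.005)

    def test_null_is_symmetric_on_log_scale(self):
        point, lo, hi = or_from_logodds(0.0, 0.1)
        assert point == 1.0
        assert np.log(lo) == pytest.approx(-np.log(hi))

    def test_estimate_exposes_consistent_or_fields(self):
        p = pairs_of([0.1], [0.01], [-0.05], [0.02])
        est = wald_ratio(p)
        assert est.or_point == pytest.approx(np.exp(est.beta))
        assert est.or_low < est.or_point < est.or_high


class TestSharedProperties:
    def test_all_estimators_invariant_to_pair_order(self, concordant_pairs):
        df = concordant_pairs.df.sample(frac=1, random_state=5).reset_index(drop=True)
        shuffled = HarmonizedPairs(df, concordant_pairs.exposure_trait,
                                   concordant_pairs.outcome_trait)
        assert ivw(shuffled, "fixed").beta == pytest.approx(
            ivw(concordant_pairs, "fixed").beta, rel=1e-12)
        assert egger(shuffled).slope.beta == pytest.approx(
            egger(concordant_pairs).slope.beta, rel=1e-12)
        assert weighted_median(shuffled, n_boot=10, seed=1).beta == pytest.approx(
            weighted_median(concordant_pairs, n_boot=10, seed=1).beta, rel=1e-12)

    def test_ci_coverage_without_pleiotropy(self, rng):
        """95% CIs of all five estimators cover the true slope >= 90% of the
        time on clean simulations."""
        beta = 0.3
        R = 200
        cover = dict.fromkeys(
            ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"], 0
        )
        for rep in range(R):
            k = 10
            x = rng.uniform(0.05, 0.15, k)
            sx = np.full(k, 0.002)
            sy = np.full(k, 0.01)
            p = pairs_of(rng.normal(x, sx), sx, rng.normal(beta * x, sy), sy)
            ests = {
                "ivw": ivw(p, "fixed"),
                "egger": egger(p).slope,
                "weighted_median": weighted_median(p, n_boot=200, seed=rep),
                "simple_mode": mode_estimate(p, weighted=False, n_boot=200, seed=rep),
                "weighted_mode": mode_estimate(p, weighted=True, n_boot=200, seed=rep),
            }
            for name, est in ests.items():
                if est.ci_low <= beta <= est.ci_high:
                    cover[name] += 1
        for name, c in cover.items():
            assert c / R >= 0.90, f"{name} coverage {c / R}"
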