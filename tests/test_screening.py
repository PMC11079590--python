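"""FDR control, two-step screening, mediation arithmetic and reverse MR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protmr.estimators import EggerFit, MREstimate
from protmr.instruments import select_instruments
from protmr.screening import (
    bh_fdr,
    direction_consistency,
    mediation,
    reverse_mr,
    run_mr_battery,
    screen_step1,
    screen_step2,
)
from protmr.simulate import simulate_gwas
from protmr.sumstats import (
    HarmonizedPairs,
    InputError,
    SummaryStats,
    TraitInfo,
    harmonize,
)


def est(beta, se, method="ivw", pval=None):
    from scipy import stats

    pval = pval if pval is not None else float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(method, beta, se, pval, 5)


def egger_fit(slope_beta):
    return EggerFit(est(slope_beta, 0.1, "egger"), 0.0, 0.01, 0.9)


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.5]), [0.02, 0.5])

    def test_singleton_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=5000))
    def test_matches_independent_stepup_oracle(self, pvals):
        q = bh_fdr(pvals)
        # independently coded step-up with monotonicity enforcement
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(q, expect, rtol=1e-12)
        assert np.all(q >= p - 1e-15)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestDirectionConsistency:
    def test_opposite_signs_invalidate(self):
        assert direction_consistency(est(-0.94, 0.3), egger_fit(0.3)) is False

    def test_agreeing_signs_pass(self):
        assert direction_consistency(est(0.96, 0.3), egger_fit(0.9)) is True

    def test_zero_egger_slope_counts_as_inconsistent(self):
        assert direction_consistency(est(0.96, 0.3), egger_fit(0.0)) is False


QT = TraitInfo("exposure", "quantitative", 450_000, sd_y=1.0)


def _instrumented_exposure(rng, k=6):
    eaf = rng.uniform(0.1, 0.4, k)
    beta = rng.uniform(0.02, 0.035, k)
    ss = simulate_gwas(beta, eaf, 450_000, QT, seed=17)
    return ss, beta, eaf


class TestScreenStep1:
    def test_true_mediators_flagged_and_fdr_controls_nulls(self, rng):
        """200-protein panel, 10 with a true effect at high power: every true
        mediator is flagged, false flags stay near the FDR budget."""
        exp_ss, inst_beta, inst_eaf = _instrumented_exposure(rng)
        inst = select_instruments(exp_ss)
        panel = {}
        true_ids = set()
        for i in range(200):
            pid = f"P{i:03d}"
            slope = 0.9 if i < 10 else 0.0
            if slope:
                true_ids.add(pid)
            trait = TraitInfo(pid, "quantitative", 35_559, sd_y=1.0)
            panel[pid] = simulate_gwas(
                slope * inst_beta, inst_eaf, 35_559, trait, seed=1000 + i,
                variant_ids=exp_ss.variant_ids,
                effect_allele=exp_ss.df.effect_allele.tolist(),
                other_allele=exp_ss.df.other_allele.tolist(),
            )
        res = screen_step1(inst, exp_ss, panel, seed=5)
        assert len(res) == 200 and not res.skipped
        flagged = {r.protein_id for r in res.passing()}
        assert true_ids <= flagged
        assert len(flagged - true_ids) <= 3  # ~FDR-level false flags

    def test_single_null_protein_q_equals_p(self, rng):
        exp_ss, inst_beta, inst_eaf = _instrumented_exposure(rng)
        inst = select_instruments(exp_ss)
        trait = TraitInfo("P0", "quantitative", 35_559, sd_y=1.0)
        panel = {"P0": simulate_gwas(
            0.0 * inst_beta, inst_eaf, 35_559, trait, seed=2,
            variant_ids=exp_ss.variant_ids,
            effect_allele=exp_ss.df.effect_allele.tolist(),
            other_allele=exp_ss.df.other_allele.tolist(),
        )}
        res = screen_step1(inst, exp_ss, panel, seed=5)
        row = res.rows[0]
        assert row.q_value == pytest.approx(row.estimate.pval)
        assert not row.passes_fdr

    def test_row_count_is_panel_minus_skips(self, rng):
        exp_ss, inst_beta, inst_eaf = _instrumented_exposure(rng)
        inst = select_instruments(exp_ss)
        trait = TraitInfo("Px", "quantitative", 35_559, sd_y=1.0)
        good = simulate_gwas(
            0.0 * inst_beta, inst_eaf, 35_559, trait, seed=2,
            variant_ids=exp_ss.variant_ids,
            effect_allele=exp_ss.df.effect_allele.tolist(),
            other_allele=exp_ss.df.other_allele.tolist(),
        )
        disjoint = simulate_gwas([0.1], [0.3], 35_559, trait, seed=3,
                                 variant_ids=["rs_unrelated"])
        res = screen_step1(inst, exp_ss, {"Pgood": good, "Pbad": disjoint}, seed=5)
        assert len(res) == 1
        assert [pid for pid, _ in res.skipped] == ["Pbad"]


class TestScreenStep2AndPipelineChain(object):
    def test_mediator_flagged_with_negative_beta(self, small_scenario):
        sc = small_scenario
        pid = sc.truth.mediator_id
        med_ss = sc.panel[pid]
        own = med_ss.df.loc[
            ~med_ss.df.variant_id.isin(sc.truth.exposure_instrument_ids)
        ].reset_index(drop=True)
        inst = select_instruments(SummaryStats(med_ss.trait, own))
        res = screen_step2({pid: inst}, {pid: med_ss}, sc.outcome, seed=3)
        (row,) = res.rows
        assert row.passes_fdr
        assert row.estimate.beta < 0  # true beta2 = -0.21
        assert row.direction_consistent is True

    def test_empty_input_yields_empty_result(self, small_scenario):
        res = screen_step2({}, {}, small_scenario.outcome, seed=3)
        assert res.rows == [] and res.skipped == []


class TestMediation:
    def test_headline_arithmetic(self):
        med = mediation(
            est(-0.82, 0.2755, "ivw"), est(0.96, 0.3087, "ivw"), est(-0.21, 0.0536, "ivw")
        )
        assert med.indirect == pytest.approx(-0.2016)
        assert round(med.indirect, 2) == -0.20
        assert med.proportion * 100 == pytest.approx(24.6, abs=0.05)

    def test_null_first_leg_gives_zero_indirect_and_proportion(self):
        med = mediation(est(-0.8, 0.2), est(0.0, 0.3), est(-0.2, 0.05))
        assert med.indirect == 0.0 and med.proportion == 0.0

    def test_zero_total_effect_rejected(self):
        with pytest.raises(InputError):
            mediation(est(0.0, 0.2, pval=1.0), est(0.9, 0.3), est(-0.2, 0.05))

    def test_delta_se_matches_parametric_bootstrap(self, rng):
        """Indirect-effect delta SE within 10% of a 1e5-draw bootstrap SD."""
        for _ in range(5):
            b1, s1 = rng.normal(0, 1), rng.uniform(0.05, 0.3)
            b2, s2 = rng.normal(0, 1), rng.uniform(0.05, 0.3)
            med = mediation(est(-0.8, 0.2), est(b1, s1), est(b2, s2))
            draws = rng.normal(b1, s1, 100_000) * rng.normal(b2, s2, 100_000)
            boot_sd = draws.std(ddof=1)
            # delta method is first-order: agreement degrades when betas are
            # small relative to their SEs, so require moderate signal
            if abs(b1) > 2 * s1 and abs(b2) > 2 * s2:
                assert med.indirect_se == pytest.approx(boot_sd, rel=0.10)

    def test_proportion_ci_brackets_point(self):
        med = mediation(est(-0.82, 0.2755), est(0.96, 0.3087), est(-0.21, 0.0536))
        assert med.proportion_low < med.proportion < med.proportion_high


OUT_TRAIT = TraitInfo("hf", "binary", 977_323, n_cases=47_309)
MED_TRAIT = TraitInfo("prot", "quantitative", 35_559, sd_y=1.0)


def _reverse_dataset(rng, feedback, seed):
    """12 outcome loci; mediator responds with slope `feedback`."""
    k = 12
    eaf = rng.uniform(0.1, 0.4, k)
    beta_out = rng.uniform(0.08, 0.15, k)
    out = simulate_gwas(beta_out, eaf, 977_323, OUT_TRAIT, seed=seed)
    med = simulate_gwas(
        feedback * beta_out, eaf, 35_559, MED_TRAIT, seed=seed + 1,
        variant_ids=out.variant_ids,
        effect_allele=out.df.effect_allele.tolist(),
        other_allele=out.df.other_allele.tolist(),
    )
    return out, med


class TestReverseMR:
    def test_recovers_simulated_feedback(self, rng):
        out, med = _reverse_dataset(rng, feedback=-0.18, seed=100)
        rep = reverse_mr(out, med, seed=1, n_boot=100, n_sim=200)
        ivw = rep.primary
        assert ivw.ci_low <= -0.18 <= ivw.ci_high
        assert ivw.beta == pytest.approx(-0.18, abs=0.08)

    def test_null_feedback_ci_covers_zero_at_nominal_rate(self, rng):
        covered = 0
        for rep_i in range(20):
            out, med = _reverse_dataset(rng, feedback=0.0, seed=200 + 7 * rep_i)
            rep = reverse_mr(out, med, seed=1, n_boot=50, n_sim=100)
            if rep.primary.ci_low <= 0.0 <= rep.primary.ci_high:
                covered += 1
        assert covered >= 17  # ~95% nominal with Monte-Carlo slack

    def test_no_instruments_is_explicit_error(self, rng):
        eaf = rng.uniform(0.1, 0.4, 5)
        out = simulate_gwas(np.zeros(5), eaf, 10_000, MED_TRAIT, seed=9)
        med = simulate_gwas(np.zeros(5), eaf, 10_000, MED_TRAIT, seed=10,
                            variant_ids=out.variant_ids)
        with pytest.raises(InputError):
            reverse_mr(out, med, seed=1)


class TestBattery:
    def test_full_battery_on_adequate_pairs(self, small_scenario):
        sc = small_scenario
        exp = sc.exposure.subset(sc.truth.exposure_instrument_ids)
        pairs = harmonize(exp, sc.outcome)
        rep = run_mr_battery(pairs, seed=1, n_boot=100, n_sim=200)
        assert set(rep.estimates) == {
            "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"
        }
        assert rep.presso is not None and rep.radial is not None
        assert len(rep.loo) == len(pairs)
        # battery is seeded: identical calls agree bit-exactly
        rep2 = run_mr_battery(pairs, seed=1, n_boot=100, n_sim=200)
        assert rep2.estimates["weighted_median"].se == rep.estimates["weighted_median"].se

    def test_single_instrument_battery_is_wald_only(self, small_scenario):
        sc = small_scenario
        exp = sc.exposure.subset(sc.truth.exposure_instrument_ids[:1])
        pairs = harmonize(exp, sc.outcome)
        rep = run_mr_battery(pairs, seed=1)
        assert list(rep.estimates) == ["wald_ratio"]
        assert rep.presso is None and rep.loo == []
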