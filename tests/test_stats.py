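"""Statistical core: paired t, Wilcoxon, Shapiro-Wilk, Holm, Cohen's d."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import hippasym as ha
from hippasym.simulate import default_cohort_spec, simulate_cohort


class TestPairedTTest:
    def test_identical_samples_give_t0_p1(self, rng):
        x = rng.normal(size=12)
        assert ha.paired_ttest(x, x) == (0.0, 1.0)

    def test_closed_form_example(self):
        # d = (1,2,3): t = mean/ (sd/sqrt(3)) = 2/(1/sqrt(3)) = 2*sqrt(3)
        t, p = ha.paired_ttest([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), df=2), abs=1e-12)
        assert p == pytest.approx(0.0742, abs=5e-5)

    def test_matches_scipy_oracle(self, rng):
        for n in (5, 12, 36):
            x, y = rng.normal(size=n), rng.normal(size=n)
            t, p = ha.paired_ttest(x, y)
            ref = sps.ttest_rel(y, x)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_spread_nonzero_mean_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            t, p = ha.paired_ttest([1.0, 2.0], [2.0, 3.0])
        assert np.isinf(t) and p == 0.0

    def test_pvalues_uniform_under_gaussian_null(self, rng):
        ps = np.array([ha.paired_ttest(rng.normal(size=10), rng.normal(size=10))[1]
                       for _ in range(2000)])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ha.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_n6_all_positive_exact_tail(self):
        # one-sided tail of the maximal statistic is 1/2^6, doubled
        w, p = ha.wilcoxon_signed_rank(np.zeros(6), np.arange(1.0, 7.0))
        assert w == 21.0
        assert p == pytest.approx(1 / 32, abs=1e-15)

    @pytest.mark.parametrize("n", [5, 8, 10, 12])
    def test_matches_exhaustive_enumeration(self, n, rng):
        # brute-force null: every sign assignment of the observed ranks
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)  # continuous: no zeros/ties a.s.
        w_obs, p = ha.wilcoxon_signed_rank(x, y)
        ranks = sps.rankdata(np.abs(y - x))
        w_all = np.array([
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ])
        cdf = np.mean(w_all <= w_obs)
        sf = np.mean(w_all >= w_obs)
        assert p == pytest.approx(min(1.0, 2 * min(cdf, sf)), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for n in (7, 15, 24):
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            _, p = ha.wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(y, x, zero_method="wilcox", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_for_large_n(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0.3, 1.0, size=60)
        _, p = ha.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(y, x, zero_method="wilcox", method="approx",
                           correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zeros_dropped_before_ranking(self):
        # the pair with zero difference must not contribute to the statistic
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 3.0, 5.0, 2.0, 9.0, 7.5, 10.0])
        w_with, _ = ha.wilcoxon_signed_rank(x, y)
        w_without, _ = ha.wilcoxon_signed_rank(x[1:], y[1:])
        assert w_with == w_without


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ha.shapiro_wilk(np.full(10, 3.3))

    def test_bounds_on_n(self, rng):
        with pytest.raises(ValueError):
            ha.shapiro_wilk([1.0, 2.0])

    def test_null_uniformity(self, rng):
        ps = np.array([ha.shapiro_wilk(rng.normal(size=100))[1]
                       for _ in range(500)])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_exponential(self, rng):
        rejections = sum(ha.shapiro_wilk(rng.exponential(size=50))[1] < 0.01
                        for _ in range(100))
        assert rejections >= 95


class TestHolmBonferroni:
    def test_hand_computed_step_down(self):
        assert np.allclose(ha.holm_bonferroni([0.01, 0.04]), [0.02, 0.04])
        assert np.allclose(ha.holm_bonferroni([0.04, 0.01]), [0.04, 0.02])

    def test_single_p_unchanged(self):
        assert ha.holm_bonferroni([0.37]) == pytest.approx([0.37])

    def test_capped_at_one(self):
        out = ha.holm_bonferroni([0.5, 0.6, 0.9])
        assert (out <= 1.0).all()
        assert sorted(out) == list(out)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ha.holm_bonferroni([0.1, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_bounded_by_raw_and_bonferroni(self, ps):
        out = ha.holm_bonferroni(ps)
        raw = np.asarray(ps)
        bonf = np.minimum(1.0, raw * len(raw))
        assert (out >= raw - 1e-12).all()
        assert (out <= bonf + 1e-12).all()

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_step_down_definition(self, ps):
        # corrected_(i) = max_{j<=i} (m-j+1) p_(j), capped at 1
        raw = np.asarray(ps)
        m = len(raw)
        order = np.argsort(raw, kind="stable")
        expect = np.empty(m)
        running = 0.0
        for i, idx in enumerate(order):
            running = max(running, (m - i) * raw[idx])
            expect[idx] = min(1.0, running)
        assert np.allclose(ha.holm_bonferroni(raw), expect)


class TestCohensD:
    def test_constant_shift_degenerate_in_diff_sd_mode(self):
        x = np.arange(10.0)  # exact floats, so x + 3 - x is exactly constant
        with pytest.raises(ValueError, match="zero denominator"):
            ha.cohens_d_paired(x, x + 3.0, mode="diff_sd")

    def test_pooled_mode_analytic_limit(self, rng):
        x = rng.normal(size=200_000)
        d = ha.cohens_d_paired(x, x + 0.5, mode="pooled_sd")
        assert d == pytest.approx(0.5, abs=0.01)

    def test_both_modes_match_manual_oracle(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        diff = y - x
        assert ha.cohens_d_paired(x, y, "diff_sd") == pytest.approx(
            diff.mean() / diff.std(ddof=1), abs=1e-12)
        pooled = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        assert ha.cohens_d_paired(x, y, "pooled_sd") == pytest.approx(
            diff.mean() / pooled, abs=1e-12)


class TestCompareSequences:
    def test_identical_sequences_all_p_one_no_d(self, healthy_cohort):
        # replace the second sequence with an exact copy of the first
        df = healthy_cohort.records.copy()
        tse = df[df["sequence"] == "T2_TSE"].copy()
        drb = tse.copy()
        drb["sequence"] = "T2_TSE_DRB"
        cohort = ha.CohortTable(pd.concat([tse, drb], ignore_index=True))
        table = ha.compare_sequences(cohort, side="both")
        assert (table.rows["corrected_p"] == 1.0).all()
        assert table.rows["cohens_d"].isna().all()
        assert table.variance_test["right"][1] == 1.0

    def test_family_sizes(self, healthy_cohort):
        assert ha.compare_sequences(healthy_cohort, side="both").family_size == 44
        assert ha.compare_sequences(healthy_cohort, side="right").family_size == 22

    def test_label_symmetry(self, healthy_cohort):
        fwd = ha.compare_sequences(healthy_cohort, side="right")
        rev = ha.compare_sequences(healthy_cohort, side="right",
                                   sequence_a="T2_TSE_DRB", sequence_b="T2_TSE")
        assert np.allclose(fwd.rows["mean_diff"], -rev.rows["mean_diff"])
        assert np.allclose(fwd.rows["raw_p"], rev.rows["raw_p"])
        assert np.allclose(fwd.rows["corrected_p"], rev.rows["corrected_p"])

    def test_mean_diff_recomputes(self, healthy_cohort):
        table = ha.compare_sequences(healthy_cohort, side="both")
        assert np.allclose(table.rows["mean_diff"],
                           table.rows["mean_vol_b"] - table.rows["mean_vol_a"],
                           atol=1e-9)

    def test_familywise_error_under_null(self, hierarchy):
        # no systematic shift between sequences: Holm keeps FWER <= alpha
        effects = {r: (0.0, sd) for r, (_, sd)
                   in default_cohort_spec().sequence_effects.items()}
        n_reps, hits = 150, 0
        for rep in range(n_reps):
            spec = default_cohort_spec(n_healthy=20, seed=30_000 + rep,
                                       sequence_effects=effects)
            table = ha.compare_sequences(simulate_cohort(spec), side="right")
            hits += int((table.rows["corrected_p"] < 0.05).any())
        assert hits / n_reps <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_incomplete_pairing_rejected(self, healthy_cohort):
        df = healthy_cohort.records
        broken = df[~((df["subject_id"] == "H001")
                      & (df["sequence"] == "T2_TSE_DRB"))]
        with pytest.raises(ValueError, match="pairing"):
            ha.compare_sequences(ha.CohortTable(broken), side="right")
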