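"""Group statistics against published values and hand computations."""
import numpy as np
import pytest

from zebratrain import (InvalidConfigError, UndefinedMetricError, correlate,
                        fi_slope, one_way_anova, paired_t, pearson_chi2,
                        two_sample_t, washin_effect, aggregate_by_lobule)
import pandas as pd


class TestTwoSampleT:
    def test_summaries_match_raw_samples_exactly(self, rng):
        a = rng.normal(10, 2, 20)
        b = rng.normal(12, 3, 25)
        from_raw = two_sample_t(a, b)
        from_sum = two_sample_t((a.mean(), a.std(ddof=1), int(a.size)),
                                (b.mean(), b.std(ddof=1), int(b.size)))
        assert from_raw.value == pytest.approx(from_sum.value, rel=1e-12)
        assert from_raw.df == from_sum.df == 43

    def test_identical_groups_give_zero(self):
        assert two_sample_t((5.0, 1.0, 10), (5.0, 1.0, 10)).value == 0.0

    def test_one_tailed_halves_p(self):
        two = two_sample_t((10.0, 2.0, 12), (11.5, 2.0, 12))
        one = two_sample_t((10.0, 2.0, 12), (11.5, 2.0, 12), one_tailed=True)
        assert one.p == pytest.approx(two.p / 2)

    def test_small_groups_rejected(self):
        with pytest.raises(InvalidConfigError):
            two_sample_t([1.0], [2.0, 3.0])


class TestPairedT:
    def test_no_change_gives_zero(self):
        x = [5.0, 6.0, 7.0]
        assert paired_t(x, x).value == 0.0

    def test_hand_computed_value(self):
        # diffs {2, 1, 3}: mean 2, sd 1, t = 2/(1/sqrt(3)) = 2 sqrt(3)
        res = paired_t([5.0, 6.0, 7.0], [3.0, 5.0, 4.0])
        assert res.value == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_constant_nonzero_difference_flagged_degenerate(self):
        res = paired_t([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])
        assert res.degenerate and np.isinf(res.value)

    def test_length_mismatch(self):
        with pytest.raises(InvalidConfigError):
            paired_t([1.0, 2.0], [1.0])


class TestPearsonChi2:
    def test_hand_computed_2x2(self):
        # E = [[2.5, 7.5], [2.5, 7.5]] -> chi2 = 20/3
        res = pearson_chi2([[5, 5], [0, 10]])
        assert res.value == pytest.approx(20 / 3)
        assert res.df == 1

    def test_identical_proportions_give_zero(self):
        assert pearson_chi2([[10, 20], [20, 40]]).value == pytest.approx(0.0)

    def test_invariant_under_transposition(self):
        t = np.array([[17, 30], [6, 51]])
        assert pearson_chi2(t).value == pytest.approx(pearson_chi2(t.T).value)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidConfigError):
            pearson_chi2([[0, 0], [5, 10]])


class TestCorrelate:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert correlate(x, [2.0, 4.0, 9.0, 11.0]).value == pytest.approx(1.0)
        assert correlate(x, [11.0, 9.0, 4.0, 2.0]).value == pytest.approx(-1.0)

    def test_spearman_hand_value(self):
        # sum d^2 = 2 -> rho = 1 - 6*2/(4*15) = 0.8
        assert correlate([1, 2, 3, 4], [1, 3, 2, 4]).value == pytest.approx(0.8)

    def test_pearson_on_collinear_points(self):
        res = correlate([0.0, 1.0, 2.0], [1.0, 3.0, 5.0], method="pearson")
        assert res.value == pytest.approx(1.0)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedMetricError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_hand_computed_f(self):
        # SS_between = 6, SS_within = 6, df (2, 6) -> F = 3
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.value == pytest.approx(3.0)
        assert res.df == (2, 6)

    def test_identical_groups_near_zero_f(self):
        g = [1.0, 2.0, 3.0]
        assert one_way_anova([g, g, g]).value == pytest.approx(0.0)

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1.2, 12)
        f = one_way_anova([a, b]).value
        t = two_sample_t(a, b).value
        assert f == pytest.approx(t ** 2, rel=1e-9)

    def test_posthoc_tables(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 2.0)]
        tuk = one_way_anova(groups, posthoc="tukey").extra["posthoc"]
        bon = one_way_anova(groups, posthoc="bonferroni").extra["posthoc"]
        assert len(tuk) == len(bon) == 3
        assert (bon["p_adj"] <= 1.0).all()
        with pytest.raises(InvalidConfigError):
            one_way_anova(groups, posthoc="scheffe")


class TestWashinEffect:
    def test_constant_rate_is_zero(self):
        t = np.arange(0.0, 600.0, 0.02)
        assert washin_effect(t, 120.0, duration_s=600.0) == pytest.approx(0.0, abs=0.1)

    def test_rate_halving_is_fifty_percent(self):
        t = np.concatenate([np.arange(0.0, 120.0, 0.02),
                            np.arange(120.0, 600.0, 0.04)])
        assert washin_effect(t, 120.0, duration_s=600.0) == pytest.approx(50.0, abs=0.2)

    def test_insufficient_coverage(self):
        with pytest.raises(UndefinedMetricError):
            washin_effect(np.arange(0, 300, 0.02), 60.0)  # pre window cut
        with pytest.raises(UndefinedMetricError):
            washin_effect(np.arange(0, 300, 0.02), 120.0, duration_s=300.0)

    def test_zero_pre_rate_undefined(self):
        with pytest.raises(UndefinedMetricError):
            washin_effect(np.arange(200.0, 540.0, 0.1), 120.0, duration_s=600.0)


class TestFISlope:
    def test_proportional_rates(self):
        c = np.array([0.1, 0.3, 0.5, 0.7])
        assert fi_slope(c, 100 * c) == pytest.approx(100.0)

    def test_collinear_hand_value(self):
        assert fi_slope([0.1, 0.2, 0.3], [10, 30, 50]) == pytest.approx(200.0)

    def test_zero_rates(self):
        assert fi_slope([0.1, 0.2, 0.3], [0, 0, 0]) == pytest.approx(0.0)

    def test_constant_currents_rejected(self):
        with pytest.raises(InvalidConfigError):
            fi_slope([0.2, 0.2, 0.2], [1, 2, 3])


class TestLobuleAggregation:
    def make_metrics(self):
        return pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(6)],
            "lobule": ["I", "I", "V", "V", "X", "X"],
            "ss_rate_hz": [100.0, 90.0, 70.0, 75.0, 50.0, 52.0],
            "cf_pause_ms": [8.0, 9.0, 12.0, 11.0, 15.0, 16.0],
            "ss_mean_cv2": [0.5, 0.55, 0.5, 0.52, 0.5, 0.49],
        })

    def test_single_lobule_mean(self):
        df = self.make_metrics().iloc[:2]
        agg = aggregate_by_lobule(df)
        assert len(agg) == 1
        assert agg.loc[0, "ss_rate_mean"] == pytest.approx(95.0)
        assert agg.loc[0, "n_cells"] == 2

    def test_monotone_rates_vs_intensity_correlate(self):
        intensity = pd.DataFrame({"lobule": ["I", "V", "X"],
                                  "normalized_intensity": [0.9, 0.7, 0.4]})
        agg = aggregate_by_lobule(self.make_metrics(), intensity)
        res = correlate(agg["normalized_intensity"], agg["ss_rate_mean"])
        assert res.value == pytest.approx(1.0)  # weaker staining = higher rate

    def test_empty_rejected(self):
        with pytest.raises(InvalidConfigError):
            aggregate_by_lobule(pd.DataFrame())
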