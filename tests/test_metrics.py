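"""Per-cell metric definitions against hand-computed and analytic oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zebratrain import (InvalidConfigError, SpikeTrainRecording,
                        UndefinedMetricError, apply_inclusion_criteria,
                        climbing_fiber_pause, compute_cell_metrics,
                        firing_rate, isi_cv, mean_cv2, stability_profile)
from conftest import poisson_train


class TestFiringRate:
    def test_count_over_duration(self):
        assert firing_rate(np.linspace(0.1, 59.9, 120), 60.0) == pytest.approx(2.0)

    def test_empty_train_is_zero(self):
        assert firing_rate([], 10.0) == 0.0

    def test_rate_times_duration_is_count(self, rng):
        t = poisson_train(rng, 40.0, 500)
        dur = t[-1] + 0.5
        assert firing_rate(t, dur) * dur == pytest.approx(t.size, abs=1e-9)


class TestCV:
    def test_regular_train_zero(self):
        assert isi_cv(np.arange(50) * 0.015625) == 0.0

    def test_two_isis_hand_value(self):
        # ISIs {1, 3}: sample SD sqrt(2), mean 2
        assert isi_cv([0.0, 1.0, 4.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_poisson_cv_is_one(self, rng):
        t = poisson_train(rng, 50.0, 10_000)
        assert isi_cv(t) == pytest.approx(1.0, abs=0.05)

    def test_too_few_events(self):
        with pytest.raises(UndefinedMetricError):
            isi_cv([0.0, 1.0])


class TestMeanCV2:
    def test_regular_train_zero(self):
        assert mean_cv2(np.arange(200) * 0.015625) == 0.0

    def test_single_pair_hand_value(self):
        # ISIs {1, 3}: 2|3-1|/(3+1) = 1
        with pytest.warns(UserWarning):
            assert mean_cv2([0.0, 1.0, 4.0]) == pytest.approx(1.0)

    def test_poisson_expectation_is_one(self, rng):
        # with U = ISI_n/(ISI_n + ISI_{n+1}) ~ Uniform(0,1), E[2|1-2U|] = 1
        t = poisson_train(rng, 50.0, 10_000)
        assert mean_cv2(t) == pytest.approx(1.0, abs=0.05)

    def test_too_few_events(self):
        with pytest.raises(UndefinedMetricError):
            mean_cv2([0.0, 1.0])

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_time_rescaling(self, seed, scale):
        t = poisson_train(np.random.default_rng(seed), 50.0, 50)
        with pytest.warns(UserWarning):
            assert mean_cv2(t * scale) == pytest.approx(mean_cv2(t), rel=1e-9)


def brute_force_cf_pause_ms(ss, cs):
    """Independent oracle: explicit double loop over CS and SS events."""
    best = None
    for c in cs:
        later = [s for s in ss if s > c]
        if later:
            lat = min(later) - c
            best = lat if best is None else min(best, lat)
    if best is None:
        raise UndefinedMetricError("oracle: undefined")
    return best * 1e3


class TestClimbingFiberPause:
    def test_single_cs(self):
        assert climbing_fiber_pause([0.010, 0.020, 0.030], [0.012]) == pytest.approx(8.0)

    def test_minimum_over_cs(self):
        assert climbing_fiber_pause([0.010, 0.020, 0.030],
                                    [0.012, 0.025]) == pytest.approx(5.0)

    def test_mean_mode(self):
        assert climbing_fiber_pause([0.010, 0.020, 0.030], [0.012, 0.025],
                                    mode="mean") == pytest.approx((8.0 + 5.0) / 2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            ss = np.sort(rng.uniform(0, 1, rng.integers(2, 30)))
            cs = np.sort(rng.uniform(0, 1, rng.integers(1, 6)))
            try:
                expected = brute_force_cf_pause_ms(ss, cs)
            except UndefinedMetricError:
                with pytest.raises(UndefinedMetricError):
                    climbing_fiber_pause(ss, cs)
                continue
            assert climbing_fiber_pause(ss, cs) == expected

    def test_enforced_pause_is_floor(self, base_cell):
        pause = climbing_fiber_pause(base_cell.ss_times, base_cell.cs_times)
        rate = firing_rate(base_cell.ss_times, base_cell.duration)
        assert 10.0 <= pause <= 10.0 + 3e3 / rate

    def test_undefined_without_cs(self):
        with pytest.raises(UndefinedMetricError):
            climbing_fiber_pause([0.1, 0.2], [])
        with pytest.raises(UndefinedMetricError):
            climbing_fiber_pause([0.1], [0.5])


class TestStabilityProfile:
    def test_constant_rate_unflagged(self):
        t = np.arange(0.0, 120.0, 0.02)
        prof = stability_profile(t, 120.0)
        assert prof.bin_rates_hz.size == 4
        assert np.allclose(prof.normalized, 1.0, atol=0.01)
        assert not prof.flagged.any()

    def test_rate_step_is_flagged(self):
        t = np.concatenate([np.arange(0.0, 60.0, 0.02),
                            np.arange(60.0, 120.0, 0.01)])
        prof = stability_profile(t, 120.0)
        assert prof.flagged.any()

    def test_partial_trailing_bin_dropped(self):
        prof = stability_profile(np.arange(0.0, 100.0, 0.1), 100.0)
        assert prof.bin_rates_hz.size == 3

    def test_short_recording_undefined(self):
        with pytest.raises(UndefinedMetricError):
            stability_profile(np.arange(0.0, 50.0, 0.1), 50.0)


def _rec(context, duration, ss=None, amp=None):
    ss = np.arange(0.01, duration, 0.02) if ss is None else np.asarray(ss)
    return SpikeTrainRecording(
        cell_id="c", zebrin_identity="unknown", lobule="X", context=context,
        duration=duration, ss_times=ss, cs_times=np.array([duration / 2]),
        amplitude_series=amp)


class TestInclusionCriteria:
    def test_in_vivo_short_recording(self):
        ok, reasons = apply_inclusion_criteria(_rec("in_vivo", 100.0))
        assert not ok and reasons == ("duration",)

    def test_in_vivo_unstable_amplitude(self):
        amp = np.column_stack([np.linspace(0, 130, 14),
                               np.linspace(1.0, 0.5, 14)])
        ok, reasons = apply_inclusion_criteria(_rec("in_vivo", 130.0, amp=amp))
        assert not ok and "amplitude" in reasons

    def test_in_vitro_high_cv_excluded(self, rng):
        # gamma shape 4 has CV 0.5 > 0.2
        from conftest import poisson_train
        isi = rng.gamma(4.0, 1 / (4 * 50.0), 7000)
        t = np.cumsum(isi)
        t = t[t < 130.0]
        ok, reasons = apply_inclusion_criteria(_rec("in_vitro", 130.0, ss=t))
        assert not ok and "CV" in reasons

    def test_in_vitro_rate_drift_excluded(self):
        # 50 Hz in the first 30 s, 65 Hz in the last 30 s: 30% change
        t = np.concatenate([np.arange(0.0, 90.0, 1 / 50.0),
                            np.arange(90.0, 120.0, 1 / 65.0)])
        ok, reasons = apply_inclusion_criteria(_rec("in_vitro", 120.0, ss=t))
        assert "rate_change" in reasons

    def test_in_vitro_regular_stable_included(self):
        ok, reasons = apply_inclusion_criteria(_rec("in_vitro", 120.0))
        assert ok, reasons

    def test_drug_context_60s_threshold(self):
        assert apply_inclusion_criteria(_rec("drug", 61.0))[0]
        assert not apply_inclusion_criteria(_rec("washin", 50.0))[0]

    def test_unknown_context_rejected(self):
        rec = _rec("in_vivo", 130.0)
        rec.context = "bogus"
        with pytest.raises(InvalidConfigError):
            apply_inclusion_criteria(rec)


def test_compute_cell_metrics_bundle(base_cell):
    m = compute_cell_metrics(base_cell)
    assert m.ss_rate_hz == pytest.approx(base_cell.n_ss / 120.0)
    assert m.cs_rate_hz == pytest.approx(base_cell.n_cs / 120.0)
    assert 0.0 < m.ss_mean_cv2 < 2.0
    assert m.cf_pause_ms >= 10.0
    assert m.included
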