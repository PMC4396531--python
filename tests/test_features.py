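"""PSTH construction, latency/decay measures, local response probability."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsdyn.errors import ConfigError, DataFormatError
from nsdyn.features import (
    build_psth,
    decay_duration,
    latency,
    local_probabilities,
    local_response_probability,
    moving_average,
)
from nsdyn.types import PSTH, SpikeTrainSet
from nsdyn.workflows import feature_recovery_run


def psth_from(smooth5=None, smooth_wide=None):
    n = 1500
    z = np.zeros(n)
    return PSTH(
        stim_time=0.0,
        raw=z,
        smooth5=z if smooth5 is None else np.asarray(smooth5, float),
        smooth_wide=z if smooth_wide is None else np.asarray(smooth_wide, float),
        wide_width_ms=50,
    )


class TestSmoothing:
    def test_impulse_spreads_over_window(self):
        x = np.zeros(21)
        x[10] = 5.0
        s = moving_average(x, 5)
        np.testing.assert_allclose(s[8:13], 1.0)
        assert s[:8].sum() == 0 and s[13:].sum() == 0

    def test_zero_input_stays_zero(self):
        assert not moving_average(np.zeros(100), 31).any()

    @given(st.integers(1, 4))
    def test_mass_conserved_up_to_edge_truncation(self, k):
        # shrinking edge windows re-weight only the outermost ~w bins
        rng = np.random.default_rng(k)
        x = rng.uniform(0, 2, 200)
        w = 2 * k + 3
        s = moving_average(x, w)
        assert abs(s.sum() - x.sum()) <= w * x.max()


class TestBuildPsth:
    def spikes(self, rel_ms, stim=10.0, duration=20.0):
        t = stim + np.asarray(rel_ms, float) / 1000.0
        return SpikeTrainSet(np.zeros(t.size, int), np.sort(t), duration, 1)

    def test_raw_counts_per_ms_bin(self):
        p = build_psth(self.spikes([100.2, 100.7, 250.0]), 10.0)
        assert p.raw[100] == 2.0
        assert p.raw[250] == 1.0
        assert p.raw.sum() == 3.0

    def test_window_overrunning_recording_is_an_error(self):
        with pytest.raises(DataFormatError, match="truncated"):
            build_psth(self.spikes([100.0], stim=19.0, duration=20.0), 19.0)

    @pytest.mark.parametrize("wide", [29, 101])
    def test_wide_width_bounds_enforced(self, wide):
        with pytest.raises(ConfigError):
            build_psth(self.spikes([100.0]), 10.0, wide_width_ms=wide)


class TestLatency:
    def triangular(self, center, height=1.0):
        y = np.zeros(1500)
        w = 30
        y[center - w : center + w + 1] = height * (
            1 - np.abs(np.arange(-w, w + 1)) / (w + 1)
        )
        return y

    def test_unique_maximum(self):
        assert latency(psth_from(self.triangular(120))) == 120.5

    def test_plateau_resolves_to_earliest_bin(self):
        y = np.zeros(1500)
        y[90:100] = np.linspace(0.1, 0.9, 10)
        y[100:105] = 1.0
        y[105:115] = np.linspace(0.9, 0.1, 10)
        assert latency(psth_from(y)) == 100.5

    def test_small_early_peak_skipped_by_prominence_rule(self):
        y = self.triangular(140, 1.0) + self.triangular(80, 0.4)
        assert latency(psth_from(y), prominence_frac=0.5) == 140.5
        # global mode behaves the same here; a qualifying early peak differs
        y2 = self.triangular(140, 1.0) + self.triangular(80, 0.6)
        assert latency(psth_from(y2), prominence_frac=0.5) == 80.5
        assert latency(psth_from(y2), prominence_frac=None) == 140.5

    def test_all_zero_trace_is_an_error(self):
        with pytest.raises(DataFormatError, match="no response content"):
            latency(psth_from())

    def test_invariant_under_uniform_rescaling(self):
        y = self.triangular(140, 1.0) + self.triangular(80, 0.6)
        assert latency(psth_from(y)) == latency(psth_from(10.0 * y))


class TestDecay:
    def exp_fall(self, peak_bin, tau_ms, height=1.0):
        y = np.zeros(1500)
        t = np.arange(1500 - peak_bin)
        y[peak_bin:] = height * np.exp(-t / tau_ms)
        y[:peak_bin] = np.linspace(0, height, peak_bin, endpoint=False)
        return y

    def test_decay_is_first_drop_below_floor_minus_latency(self):
        y = np.zeros(1500)
        y[100:300] = 1.0  # drops below 0.15 at bin 300
        d, censored = decay_duration(psth_from(smooth_wide=y), 100.5, 0.15)
        assert d == 200.0
        assert not censored

    def test_never_dropping_trace_is_censored(self):
        y = np.full(1500, 0.5)
        d, censored = decay_duration(psth_from(smooth_wide=y), 120.5, 0.15)
        assert censored
        assert d == 1500 - 120.5

    def test_latency_bin_below_floor_gives_zero_decay(self):
        y = np.full(1500, 0.01)
        d, censored = decay_duration(psth_from(smooth_wide=y), 100.5, 0.15)
        assert d == 0.0 and not censored

    def test_not_invariant_under_rescaling(self):
        y = self.exp_fall(100, 80.0, 1.0)
        d1, _ = decay_duration(psth_from(smooth_wide=y), 100.5, 0.15)
        d2, _ = decay_duration(psth_from(smooth_wide=3 * y), 100.5, 0.15)
        assert d2 > d1


class TestLocalProbability:
    def test_all_neighbors_successful(self):
        s = np.ones(21, bool)
        assert local_response_probability(s, 10, 10) == 1.0

    def test_half_neighbors_successful(self):
        s = np.zeros(21, bool)
        s[:10] = True  # 10 of the 20 neighbors of index 10
        assert local_response_probability(s, 10, 10) == 0.5

    def test_edge_truncates_denominator(self):
        s = np.zeros(11, bool)
        s[1:7] = True  # index 0 sees 10 following, 6 successes
        assert local_response_probability(s, 0, 10) == 0.6

    def test_index_stimulus_is_excluded(self):
        s = np.zeros(21, bool)
        s[10] = True
        assert local_response_probability(s, 10, 10) == 0.0

    def test_too_few_stimuli_is_an_error(self):
        with pytest.raises(DataFormatError):
            local_response_probability(np.array([True]), 0, 10)

    @given(st.integers(0, 40))
    def test_vectorized_matches_scalar(self, idx):
        rng = np.random.default_rng(7)
        s = rng.random(41) < 0.4
        vec = local_probabilities(s, 10)
        assert vec[idx] == pytest.approx(local_response_probability(s, idx, 10))


def test_zero_noise_end_to_end_feature_recovery():
    """Programmed latency/decay are recovered within the smoothing tolerances."""
    table = feature_recovery_run(11, latency_ms=120.0, decay_ms=300.0, n_responses=60)
    assert len(table) >= 55
    assert np.all(np.abs(table["latency_ms"] - 120.0) <= 3.0)
    assert np.all(np.abs(table["decay_ms"] - 300.0) <= 25.0)
    assert not table["censored_decay"].any()
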