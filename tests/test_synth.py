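"""Generator contracts: reproducibility, refractoriness, latent modes, truth I/O."""
import numpy as np
import pytest

from nsdyn.errors import ConfigError
from nsdyn.synth import (
    SynthConfig,
    _calibrated_latent_exponent,
    fractional_gaussian_noise,
    generate_latent,
    generate_recording,
    read_truth,
    write_truth,
)


class TestReproducibility:
    def test_identical_config_gives_bit_identical_outputs(self):
        cfg = SynthConfig(duration=300.0, seed=5)
        s1, st1, t1 = generate_recording(cfg)
        s2, st2, t2 = generate_recording(cfg)
        np.testing.assert_array_equal(s1.times, s2.times)
        np.testing.assert_array_equal(s1.electrode_ids, s2.electrode_ids)
        np.testing.assert_array_equal(st1.onsets, st2.onsets)
        np.testing.assert_array_equal(t1.ns_peak_times, t2.ns_peak_times)

    def test_different_seed_differs(self):
        s1, _, _ = generate_recording(SynthConfig(duration=300.0, seed=5))
        s2, _, _ = generate_recording(SynthConfig(duration=300.0, seed=6))
        assert s1.n_spikes != s2.n_spikes or not np.array_equal(s1.times, s2.times)


class TestRefractoriness:
    @pytest.mark.parametrize("spont", [False, True])
    def test_no_two_true_peaks_closer_than_refractory(self, spont):
        cfg = SynthConfig(duration=1800.0, spontaneous=spont, seed=9)
        _, _, truth = generate_recording(cfg)
        gaps = np.diff(truth.ns_peak_times)
        assert gaps.size > 3
        assert gaps.min() >= cfg.refractory

    def test_threshold_minus_inf_means_every_stimulus_responds(self):
        cfg = SynthConfig(duration=300.0, response_threshold=-np.inf, seed=2)
        _, stims, truth = generate_recording(cfg)
        assert truth.table["responded"].all()
        assert truth.ns_peak_times.size == len(stims)


class TestLatent:
    def test_infinite_time_constant_freezes_the_ou_trace(self):
        cfg = SynthConfig(latent_tau=np.inf)
        rng = np.random.default_rng(0)
        e, i = generate_latent(cfg, rng, 100, 5.0)
        assert np.ptp(e) == 0.0 and np.ptp(i) == 0.0

    def test_coupled_latents_are_mirror_images(self):
        cfg = SynthConfig(coupled_latents=True)
        e, i = generate_latent(cfg, np.random.default_rng(1), 50, 5.0)
        np.testing.assert_array_equal(i, -e)

    def test_oscillatory_mode_carries_the_programmed_period(self):
        cfg = SynthConfig(latent_mode="oscillatory", osc_period_responses=40)
        _, i = generate_latent(cfg, np.random.default_rng(3), 400, 5.0)
        spec = np.abs(np.fft.rfft(i - i.mean()))
        assert np.argmax(spec) == 10  # 400 / 40 cycles

    def test_fgn_has_unit_variance_and_positive_memory(self):
        x = fractional_gaussian_noise(8192, 0.85, np.random.default_rng(4))
        assert x.var() == pytest.approx(1.0, abs=0.1)
        lag1 = np.mean(x[:-1] * x[1:])
        assert lag1 == pytest.approx(2**1.7 / 2 - 1, abs=0.1)  # gamma(1) for H=0.85

    @pytest.mark.parametrize("h", [0.4, 1.0])
    def test_hurst_outside_open_interval_rejected(self, h):
        with pytest.raises(ConfigError):
            fractional_gaussian_noise(64, h, np.random.default_rng(0))

    @pytest.mark.parametrize("beta", [0.0, 1.0])
    def test_target_exponent_bounds_enforced(self, beta):
        with pytest.raises(ConfigError):
            SynthConfig(latent_mode="fgn", target_ff_exponent=beta)

    def test_calibration_is_monotone_and_warns_at_the_ceiling(self):
        lo = _calibrated_latent_exponent(0.3, spontaneous=False)
        hi = _calibrated_latent_exponent(0.64, spontaneous=False)
        assert 0 < lo < hi < 1
        with pytest.warns(UserWarning, match="ceiling"):
            _calibrated_latent_exponent(0.89, spontaneous=True)


class TestEnvelope:
    def test_amplitude_below_floor_is_undetectable(self):
        with pytest.raises(ConfigError, match="undetectable"):
            SynthConfig(amplitude=0.1)

    def test_refractory_longer_than_period_warns(self):
        with pytest.warns(UserWarning, match="refractory"):
            SynthConfig(stim_rate=1.0, refractory=2.0)


class TestTruthIO:
    def test_round_trip_identity(self, tmp_path):
        _, _, truth = generate_recording(SynthConfig(duration=300.0, seed=1))
        write_truth(truth, tmp_path / "truth.tsv")
        back = read_truth(tmp_path / "truth.tsv")
        np.testing.assert_array_equal(
            back.table["responded"].to_numpy(), truth.table["responded"].to_numpy()
        )
        np.testing.assert_allclose(back.ns_peak_times, truth.ns_peak_times, atol=1e-6)

    def test_failed_rows_carry_na(self, tmp_path):
        cfg = SynthConfig(duration=300.0, response_threshold=10.0, seed=1)
        _, _, truth = generate_recording(cfg)
        write_truth(truth, tmp_path / "truth.tsv")
        body = (tmp_path / "truth.tsv").read_text()
        assert "NA" in body

    def test_spontaneous_times_serialized_sorted(self, tmp_path):
        _, _, truth = generate_recording(
            SynthConfig(duration=600.0, spontaneous=True, seed=3)
        )
        write_truth(truth, tmp_path / "truth.tsv")
        back = read_truth(tmp_path / "truth.tsv")
        assert np.all(np.diff(back.spontaneous_times) > 0)
        assert back.spontaneous_times.size == truth.spontaneous_times.size
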