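"""Probabilistic amplitude demodulation and the cascade."""

import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfiltfilt

from amcascade import PadConfig, band_limit_check, pad_cascade, pad_demodulate
from amcascade.pad import AmHierarchy, PadError, default_cascade_configs
from amcascade.audio import SpeechSample, zscore_normalize


def _zscore(y):
    return (y - y.mean()) / y.std()


class TestPadDemodulate:
    def test_constant_amplitude_noise_gives_flat_modulator(self, rng):
        y = _zscore(rng.standard_normal(10000))
        d = pad_demodulate(y, 1000.0, PadConfig(target_rate_hz=4.0))
        cv = d.modulator_signal.std() / d.modulator_signal.mean()
        assert cv < 0.1

    def test_sinusoidal_envelope_recovered(self, rng):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        env = 1.0 + 0.9 * np.sin(2 * np.pi * 2.0 * t)
        y = _zscore(env * rng.standard_normal(t.size))
        d = pad_demodulate(y, fs, PadConfig(target_rate_hz=4.0))
        r = np.corrcoef(d.modulator_signal, env)[0, 1]
        assert r >= 0.9

    def test_fast_am_relegated_to_carrier(self, rng):
        # envelope at 8 Hz but cutoff at 4 Hz: the 8 Hz AM must not appear
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 8.0 * t)
        y = _zscore(env * rng.standard_normal(t.size))
        d = pad_demodulate(y, fs, PadConfig(target_rate_hz=4.0))
        m = d.modulator - d.modulator.mean()
        p = np.abs(np.fft.rfft(m)) ** 2
        f = np.fft.rfftfreq(m.size, d=1.0 / d.latent_grid_hz)
        frac_above = p[f > 4.0].sum() / p[f > 0].sum()
        assert frac_above < 0.05

    def test_reconstruction_identity(self, rng):
        y = _zscore(rng.standard_normal(5000))
        d = pad_demodulate(y, 1000.0, PadConfig(target_rate_hz=4.0))
        np.testing.assert_allclose(d.modulator_signal * d.carrier, y, atol=1e-10)
        assert d.reconstruction_error <= 1e-6

    def test_modulator_strictly_positive(self, rng):
        y = _zscore(rng.standard_normal(4000))
        d = pad_demodulate(y, 1000.0, PadConfig(target_rate_hz=8.0))
        assert np.all(d.modulator > 0)
        assert np.all(d.modulator_signal > 0)

    def test_scale_covariance(self, rng):
        fs = 1000.0
        t = np.arange(int(6 * fs)) / fs
        env = 1.0 + 0.7 * np.sin(2 * np.pi * 2.0 * t)
        y = env * rng.standard_normal(t.size)
        cfg = PadConfig(target_rate_hz=4.0)
        d1 = pad_demodulate(y, fs, cfg)
        d2 = pad_demodulate(3.0 * y, fs, cfg)
        ratio = d2.modulator_signal / d1.modulator_signal
        assert np.median(np.abs(ratio - 3.0)) < 0.1
        np.testing.assert_allclose(d1.carrier, d2.carrier, atol=0.05)

    def test_objective_trace_nondecreasing(self, rng):
        fs = 1000.0
        t = np.arange(int(6 * fs)) / fs
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 3.0 * t)
        y = _zscore(env * rng.standard_normal(t.size))
        d = pad_demodulate(y, fs, PadConfig(target_rate_hz=4.0))
        trace = d.objective_trace
        assert np.all(np.diff(trace) >= -1e-9 * np.maximum(1, np.abs(trace[:-1])))

    def test_nonfinite_signal_rejected(self):
        y = np.zeros(5000)
        y[10] = np.nan
        with pytest.raises(PadError, match="non-finite"):
            pad_demodulate(y, 1000.0, PadConfig(target_rate_hz=4.0))

    def test_too_short_signal_rejected(self, rng):
        with pytest.raises(PadError, match="2 s"):
            pad_demodulate(rng.standard_normal(500), 1000.0,
                           PadConfig(target_rate_hz=4.0))

    def test_parameter_recovery_on_generative_model(self, rng):
        """Sampling from the model itself (smooth log-envelope, white
        carrier), the MAP modulator tracks the truth: median r >= 0.9."""
        fs = 500.0
        n = int(10 * fs)
        sos = butter(4, 2.0, fs=fs, btype="lowpass", output="sos")
        rs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            x = sosfiltfilt(sos, g.standard_normal(n))
            x = x / x.std() * 0.7
            m = np.exp(x)
            y = _zscore(m * g.standard_normal(n))
            d = pad_demodulate(y, fs, PadConfig(target_rate_hz=4.0))
            rs.append(np.corrcoef(d.modulator_signal, m)[0, 1])
        assert np.median(rs) >= 0.9

    def test_agrees_with_hilbert_envelope_in_easy_limit(self, rng):
        """Band-limited envelope far below the cutoff + white carrier: PAD
        must agree with the low-passed Hilbert magnitude (independent
        oracle) at r >= 0.95."""
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * t)
        y = _zscore(env * rng.standard_normal(t.size))
        d = pad_demodulate(y, fs, PadConfig(target_rate_hz=8.0))
        sos = butter(4, 4.0, fs=fs, btype="lowpass", output="sos")
        oracle = sosfiltfilt(sos, np.abs(hilbert(y)))
        r = np.corrcoef(d.modulator_signal, oracle)[0, 1]
        assert r >= 0.95

    def test_chunked_long_signal_consistent(self, rng):
        fs = 500.0
        t = np.arange(int(25 * fs)) / fs  # forces 10-s chunking
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 2.0 * t)
        y = _zscore(env * rng.standard_normal(t.size))
        d = pad_demodulate(y, fs, PadConfig(target_rate_hz=4.0))
        r = np.corrcoef(d.modulator_signal, env)[0, 1]
        assert r >= 0.9
        assert d.reconstruction_error <= 1e-6


class TestCascade:
    def test_band_edges_and_positivity(self, nested_hierarchy):
        edges = [(b[1], b[2]) for b in nested_hierarchy.bands]
        assert edges == [(0.0, 1.0), (1.0, 4.0), (4.0, 12.0), (12.0, 40.0)]
        for _name, _lo, _hi, env in nested_hierarchy.bands:
            assert np.all(env > 0)

    def test_product_reconstructs_input(self, nested_hierarchy):
        assert nested_hierarchy.reconstruction_error <= 1e-3

    def test_envelope_recovery_against_ground_truth(
        self, nested_sample, nested_hierarchy
    ):
        for band in ("delta", "theta_alpha", "beta_gamma"):
            est = nested_hierarchy.envelope(band)
            tru = nested_sample.truth[band]
            n = min(est.size, tru.size)
            r = np.corrcoef(est[:n], tru[:n])[0, 1]
            assert r >= 0.8, f"{band}: r={r:.3f}"

    def test_pure_fast_noise_gives_flat_envelopes(self, rng):
        fs = 4000.0
        y = rng.standard_normal(int(10 * fs))
        sample = SpeechSample(
            sample_id="noise", waveform=y, rate_hz=fs, role="respondent",
            group="NT", direction_label="NT_speech", dyad_id="d0",
        )
        h = pad_cascade(zscore_normalize(sample))
        for name in ("delta", "theta_alpha", "beta_gamma"):
            env = h.envelope(name)
            assert env.std() / env.mean() < 0.15, name

    def test_carrier_recursion_also_reconstructs(self, nested_sample):
        h = pad_cascade(
            zscore_normalize(nested_sample.sample), recursion="carrier"
        )
        assert h.reconstruction_error <= 1e-3

    def test_wrong_config_count_rejected(self, nested_sample):
        with pytest.raises(PadError):
            pad_cascade(
                zscore_normalize(nested_sample.sample),
                configs=[PadConfig(target_rate_hz=40.0)],
            )


class TestBandLimitCheck:
    def _hierarchy_with_delta(self, env, grid=160.0):
        n = env.size
        flat = np.ones(n)
        bands = [
            ("low_delta", 0.0, 1.0, flat),
            ("delta", 1.0, 4.0, env),
            ("theta_alpha", 4.0, 12.0, flat),
            ("beta_gamma", 12.0, 40.0, flat),
        ]
        return AmHierarchy(
            bands=bands, final_carrier=np.ones(n), source_sample_id="x",
            env_grid_hz=grid, signal_rate_hz=4000.0, reconstruction_error=0.0,
        )

    def test_in_band_tone_not_flagged(self):
        t = np.arange(1600) / 160.0
        h = self._hierarchy_with_delta(1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t))
        rep = band_limit_check(h)
        assert rep["delta"]["out_of_band_fraction"] < 0.01
        assert not rep["delta"]["flagged"]

    def test_out_of_band_tone_flagged(self):
        t = np.arange(1600) / 160.0
        h = self._hierarchy_with_delta(1.0 + 0.5 * np.sin(2 * np.pi * 20.0 * t))
        rep = band_limit_check(h)
        assert rep["delta"]["out_of_band_fraction"] > 0.99
        assert rep["delta"]["flagged"]

    def test_cascade_output_unflagged(self, nested_hierarchy):
        rep = band_limit_check(nested_hierarchy)
        assert not any(v["flagged"] for v in rep.values()), rep


class TestPadConfig:
    def test_latent_grid_default_is_4x_target(self):
        cfg = PadConfig(target_rate_hz=10.0)
        assert cfg.latent_grid_hz == 40.0

    def test_insufficient_latent_grid_rejected(self):
        with pytest.raises(PadError):
            PadConfig(target_rate_hz=10.0, latent_grid_hz=20.0)

    def test_default_cascade_is_fast_to_slow(self):
        cutoffs = [c.target_rate_hz for c in default_cascade_configs()]
        assert cutoffs == [40.0, 12.0, 4.0, 1.0]
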