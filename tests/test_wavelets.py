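"""Wavelet decomposition, reconstruction and strain/EOG separation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eogkit import (WaveletConfig, reconstruct, separate_components,
                    wavelet_decompose)
from eogkit.synth import _plateau, _raised_cosine_pulse

FS = 250.0


def compound_signal(seed, n=1000):
    """Non-overlapping saccade pulse + strain plateau at generator scales."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / FS
    plat_dur = rng.uniform(1.5, 2.2)
    plat_onset = rng.uniform(0.3, max(0.35, 4.0 - plat_dur - 1.0))
    pulse_dur = rng.uniform(0.15, 0.35)
    pulse_onset = rng.uniform(plat_onset + plat_dur + 0.3, 4.0 - pulse_dur - 0.2)
    pulse = _raised_cosine_pulse(t, pulse_onset, pulse_dur,
                                 rng.uniform(500, 600) * rng.choice([-1, 1]))
    plateau = _plateau(t, plat_onset, plat_dur, 500.0 * rng.choice([-1, 1]), 0.5)
    return pulse, plateau


class TestDecomposeReconstruct:
    def test_zero_signal_all_zero_coefficients(self):
        pyr = wavelet_decompose(np.zeros(1024), WaveletConfig())
        assert all(np.all(c == 0) for c in pyr)

    def test_impulse_energy_conservation(self):
        """Orthogonal family: Parseval holds for a unit impulse."""
        x = np.zeros(1024)
        x[500] = 1.0
        pyr = wavelet_decompose(x, WaveletConfig())
        energy = sum(float(np.sum(c ** 2)) for c in pyr)
        assert energy == pytest.approx(1.0, abs=1e-8)

    def test_constant_series_details_vanish(self):
        pyr = wavelet_decompose(np.full(1024, 5.0), WaveletConfig())
        for detail in pyr[1:]:
            assert np.max(np.abs(detail)) < 1e-8

    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1024)
        cfg = WaveletConfig()
        assert np.max(np.abs(reconstruct(wavelet_decompose(x, cfg), cfg,
                                         length=1024) - x)) < 1e-8

    def test_all_zero_pyramid_reconstructs_zero(self):
        cfg = WaveletConfig()
        pyr = [np.zeros_like(c) for c in wavelet_decompose(np.ones(1024), cfg)]
        assert np.all(reconstruct(pyr, cfg, length=1024) == 0)

    def test_approximation_only_is_lowpass(self):
        """Keeping only cA_N concentrates the spectrum below fs/2^(N+1)."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=2048)
        cfg = WaveletConfig(levels=6)
        pyr = wavelet_decompose(x, cfg)
        pyr = [pyr[0]] + [np.zeros_like(c) for c in pyr[1:]]
        smooth = reconstruct(pyr, cfg, length=2048)
        spectrum = np.abs(np.fft.rfft(smooth)) ** 2
        freqs = np.fft.rfftfreq(2048, 1 / FS)
        band_edge = FS / 2 ** (cfg.levels + 1)
        in_band = spectrum[freqs <= band_edge].sum()
        assert in_band / spectrum.sum() >= 0.9

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            wavelet_decompose(np.zeros(30), WaveletConfig(levels=6))

    def test_inconsistent_pyramid_rejected(self):
        cfg = WaveletConfig()
        pyr = wavelet_decompose(np.zeros(1024), cfg)
        with pytest.raises(ValueError):
            reconstruct(pyr[:-1], cfg)


class TestSeparation:
    def test_zero_signal_zero_components(self):
        s, e = separate_components(np.zeros(1024), WaveletConfig())
        assert np.all(s == 0) and np.all(e == 0)

    def test_slow_drift_goes_to_strain_component(self):
        t = np.arange(1000) / FS
        drift = np.sin(2 * np.pi * 0.2 * t)
        s, e = separate_components(drift, WaveletConfig(), sampling_rate=FS)
        assert np.sum(s ** 2) / np.sum(drift ** 2) >= 0.95

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_component_recovery_correlation(self, seed):
        pulse, plateau = compound_signal(seed)
        s, e = separate_components(pulse + plateau, WaveletConfig(),
                                   sampling_rate=FS)
        assert np.corrcoef(s, plateau)[0, 1] >= 0.9
        assert np.corrcoef(e, pulse)[0, 1] >= 0.9

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2 ** 20))
    def test_additivity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=300.0, size=1024)
        s, e = separate_components(x, WaveletConfig(), sampling_rate=FS)
        assert np.max(np.abs(s + e - x)) < 1e-6

    def test_split_level_monotonicity(self):
        """Raising split_level never increases strain-component energy."""
        pulse, plateau = compound_signal(9)
        x = pulse + plateau
        energies = []
        for split in range(1, 7):
            s, _ = separate_components(
                x, WaveletConfig(levels=6, split_level=split), sampling_rate=FS)
            energies.append(float(np.sum(s ** 2)))
        assert all(e1 >= e2 - 1e-6 for e1, e2 in zip(energies, energies[1:]))

    def test_channel_assignment_on_noise_free_trials(self, noise_free_config,
                                                     pipeline_config):
        """Events appear in the correct component in >= 99% of 100 trials."""
        from eogkit import generate_trial, process_trace
        correct = 0
        for i in range(100):
            state = ("left", "right", "up", "down")[i % 4]
            tr = generate_trial(state, noise_free_config, seed=5000 + i)
            pt = process_trace(tr, pipeline_config)
            if state in ("left", "right"):
                correct += bool(pt.eog_events) and not pt.strain_events
            else:
                correct += bool(pt.strain_events) and not pt.eog_events
        assert correct >= 99

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WaveletConfig(levels=4, split_level=5)
        with pytest.raises(ValueError):
            WaveletConfig(threshold_mode="medium")
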