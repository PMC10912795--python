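"""Coherence, phase/amplitude extraction, modulation index, comodulogram."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perictal.connectivity import (
    MIConfig,
    band_coherence,
    band_mi,
    comodulogram,
    extract_amplitude,
    extract_phase,
    modulation_index,
    msc,
)
from perictal.errors import InsufficientDataError, ValidationError
from perictal.io import BandDef, THETA
from perictal.spectral import WelchConfig
from perictal.synth import gen_coherent_pair, gen_pac_signal

FS = 1000.0


def brute_force_mi(phase, amp, n_bins=18):
    """Independent reference MI: explicit per-bin means and entropy."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for lo, hi in zip(edges, edges[1:]):
        sel = (phase >= lo) & (phase < hi) if hi < np.pi else (phase >= lo) & (phase <= hi)
        means.append(amp[sel].mean())
    p = np.array(means) / np.sum(means)
    h = -sum(pi * np.log(pi) for pi in p if pi > 0)
    return (np.log(n_bins) - h) / np.log(n_bins)


class TestMsc:
    def test_identical_signals(self, rng):
        x = rng.standard_normal(int(30 * FS))
        cs = msc(x, x, FS)
        np.testing.assert_allclose(cs.msc, 1.0, atol=1e-10)

    def test_independent_noise(self):
        """Band MSC of independent noise equals the estimator bias.

        With 90%-overlapping windows the effective number of independent
        windows is ≈ segment/window = 5, not the raw window count, so the
        bias floor is ≈ 1/5 · (overlap correction) ≈ 0.12 (Monte-Carlo
        value frozen here), not 1/41.
        """
        vals = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x, y = rng.standard_normal((2, int(30 * FS)))
            vals.append(band_coherence(msc(x, y, FS), THETA))
        assert np.mean(vals) == pytest.approx(0.116, abs=0.03)

    def test_shared_source_closed_form(self):
        """λ=0.8 pair model: theta-band MSC ≈ λ⁴ = 0.4096 (20 seeds)."""
        vals = []
        for s in range(20):
            y1, y2 = gen_coherent_pair(0.8, THETA, 20, 30, FS, np.random.default_rng(s))
            vals.append(band_coherence(msc(y1, y2, FS), THETA))
        assert np.mean(vals) == pytest.approx(0.8**4, abs=0.08)

    def test_bounded_and_symmetric(self, rng):
        x, y = rng.standard_normal((2, int(10 * FS)))
        a, b = msc(x, y, FS), msc(y, x, FS)
        assert np.all((a.msc >= 0) & (a.msc <= 1))
        np.testing.assert_allclose(a.msc, b.msc, atol=1e-12)

    def test_single_window_rejected(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(ValidationError):
            msc(x, x, FS, WelchConfig(window_s=1.0, overlap_frac=0.0))


class TestPhaseAmplitude:
    def test_phase_advances_linearly(self):
        t = np.arange(int(30 * FS)) / FS
        ph = extract_phase(np.sin(2 * np.pi * 8 * t), FS, BandDef("t", 6, 10))
        slope = np.polyfit(np.arange(ph.size) / FS, np.unwrap(ph), 1)[0] / (2 * np.pi)
        assert slope == pytest.approx(8.0, rel=1e-3)

    def test_phase_histogram_uniform(self):
        """Phase of a sinusoid over whole cycles is uniform across the 18
        bins within 2% (frequency incommensurate with fs)."""
        f = 8.1
        t = np.arange(int(40 * FS)) / FS
        ph = extract_phase(np.sin(2 * np.pi * f * t), FS, BandDef("t", 6, 10))
        n_keep = int(np.floor(ph.size * f / FS) * FS / f)
        h, _ = np.histogram(ph[:n_keep], bins=18, range=(-np.pi, np.pi))
        np.testing.assert_allclose(h, n_keep / 18, rtol=0.02)

    def test_matches_quadrature_arctangent(self):
        """Analytic-signal phase equals atan2 of an independently built
        quadrature pair (FFT 90° shift of the same band-passed signal)."""
        from perictal.connectivity import bandpass

        f = 8.0
        t = np.arange(int(20 * FS)) / FS
        filt = bandpass(np.sin(2 * np.pi * f * t), FS, 6, 10)
        ph = extract_phase(np.sin(2 * np.pi * f * t), FS, BandDef("t", 6, 10),
                           edge_trim_s=2.0)
        # oracle quadrature: rotate every positive-frequency component by −90°
        spec = np.fft.rfft(filt)
        quad = np.fft.irfft(spec * -1j, n=filt.size)
        k = int(2.0 * FS)
        oracle = np.arctan2(quad, filt)[k:-k]
        err = np.angle(np.exp(1j * (ph - oracle)))
        assert np.max(np.abs(err)) < 1e-6

    def test_phase_of_pure_tone(self):
        """Extracted phase tracks the true tone phase to a few mrad after
        the filter transient has decayed."""
        f = 8.0
        t = np.arange(int(20 * FS)) / FS
        ph = extract_phase(np.sin(2 * np.pi * f * t), FS, BandDef("t", 6, 10),
                           edge_trim_s=2.0)
        k = int(2.0 * FS)
        oracle = np.arctan2(-np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t))[k:-k]
        err = np.angle(np.exp(1j * (ph - oracle)))
        assert np.max(np.abs(err)) < 5e-3

    def test_modulated_envelope_min_max(self):
        """χ=1 modulation: envelope minimum < 5% of maximum."""
        x = gen_pac_signal(8, 80, 1.0, 10.0, 30.0, FS)
        env = extract_amplitude(x, FS, BandDef("g", 62, 98))
        assert env.min() / env.max() < 0.05

    def test_constant_carrier_flat_envelope(self):
        t = np.arange(int(30 * FS)) / FS
        env = extract_amplitude(np.sin(2 * np.pi * 80 * t), FS, BandDef("g", 62, 98))
        assert np.std(env) / np.mean(env) < 0.05

    def test_zero_signal(self):
        env = extract_amplitude(np.zeros(int(10 * FS)), FS, BandDef("g", 62, 98))
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        from perictal.errors import FilterError
        with pytest.raises(FilterError):
            extract_phase(np.zeros(int(10 * FS)), FS, BandDef("x", 400, 600))


class TestModulationIndex:
    def test_constant_amplitude_is_zero(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 20000)
        assert modulation_index(ph, np.ones_like(ph)) == 0.0

    def test_single_bin_concentration_is_one(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 20000)
        amp = np.where((ph >= 0) & (ph < 2 * np.pi / 18), 1.0, 0.0)
        assert modulation_index(ph, amp) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            ph = rng.uniform(-np.pi, np.pi, 5000)
            amp = rng.gamma(2.0, 1.0, 5000)
            assert modulation_index(ph, amp) == pytest.approx(
                brute_force_mi(ph, amp), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(1e-6, 1e6))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(42)
        ph = rng.uniform(-np.pi, np.pi, 3000)
        amp = rng.gamma(2.0, 1.0, 3000)
        assert modulation_index(ph, c * amp) == pytest.approx(
            modulation_index(ph, amp), abs=1e-12)

    def test_monotone_in_modulation_depth(self):
        """Mean MI strictly increases with generator χ (10 seeds)."""
        chis = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for chi in chis:
            vals = [
                band_mi(
                    gen_pac_signal(8, 80, chi, 10.0, 20.0, FS,
                                   np.random.default_rng(s), noise_rms=1.0),
                    gen_pac_signal(8, 80, chi, 10.0, 20.0, FS,
                                   np.random.default_rng(s), noise_rms=1.0),
                    FS, BandDef("th", 6, 10), BandDef("g", 60, 100))
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_empty_bin_rejected(self):
        ph = np.full(100, 0.1)  # all phases in one bin
        with pytest.raises(InsufficientDataError):
            modulation_index(ph, np.ones(100))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            modulation_index(np.zeros(10), np.zeros(9))


class TestComodulogram:
    def test_default_grid_dimensions(self):
        cfg = MIConfig()
        assert cfg.phase_centers.size == 23   # 1–12 Hz, 0.5 Hz step
        assert cfg.amp_centers.size == 44     # 35–250 Hz, 5 Hz step
        assert cfg.n_bins == 18

    def test_peak_recovery(self):
        """PAC at (8 Hz, 80 Hz), χ=0.9: comodulogram argmax within 1 Hz /
        10 Hz of the true coupling (10 seeds)."""
        hits = 0
        for s in range(10):
            x = gen_pac_signal(8, 80, 0.9, 10.0, 30.0, FS,
                               np.random.default_rng(s), noise_rms=1.0)
            pf, af, _ = comodulogram(x, x, FS).peak()
            if abs(pf - 8.0) <= 1.0 and abs(af - 80.0) <= 10.0:
                hits += 1
        assert hits >= 9

    def test_uncoupled_signal_flat(self):
        x = gen_pac_signal(8, 80, 0.0, 10.0, 30.0, FS,
                           np.random.default_rng(0), noise_rms=1.0)
        cm = comodulogram(x, x, FS)
        assert cm.mi.max() < 0.01

    def test_nyquist_guard(self):
        x = np.zeros(int(30 * FS))
        with pytest.raises(ValidationError):
            comodulogram(x, x, 500.0)  # 250 Hz + bandwidth ≥ Nyquist

    def test_too_short_segment(self):
        with pytest.raises(ValidationError):
            comodulogram(np.zeros(100), np.zeros(100), FS)
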