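"""Ground-truth properties of the synthetic LFP generator."""

import numpy as np
import pytest
import scipy.signal

from perictal.errors import ValidationError
from perictal.io import BandDef, Recording, THETA
from perictal.spectral import WelchConfig, integrate_density, welch_psd
from perictal.synth import (
    BackgroundSpec,
    OscillationSpec,
    PacSpec,
    PairCouplingSpec,
    SeizureSpec,
    SynthSpec,
    assemble_recording,
    gen_background,
    gen_bandlimited,
    gen_coherent_pair,
    gen_pac_signal,
)

FS = 1000.0


def _psd(x, fs=FS):
    return welch_psd(Recording(x[None, :], fs, ("HC",)))


class TestBackground:
    def test_white_noise_limit_flat_psd(self):
        """α=0 gives white noise: Welch PSD flat within 3 dB over 1 Hz–fs/4."""
        psds = [
            _psd(gen_background(30, FS, 0.0, 10.0, np.random.default_rng(s))).density[0]
            for s in range(10)
        ]
        d = np.mean(psds, axis=0)
        f = _psd(gen_background(30, FS, 0.0, 10.0, np.random.default_rng(0))).freqs
        sel = (f >= 1) & (f <= FS / 4)
        ratio_db = 10 * np.log10(d[sel] / np.median(d[sel]))
        assert np.abs(ratio_db).max() < 3.0

    def test_pink_noise_slope(self):
        """α=1: log–log PSD slope in [−1.2, −0.8] over 1–100 Hz (20-seed avg)."""
        psds = []
        for s in range(20):
            x = gen_background(30, FS, 1.0, 50.0, np.random.default_rng(s))
            p = _psd(x)
            psds.append(p.density[0])
        d, f = np.mean(psds, axis=0), p.freqs
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[sel]), np.log10(d[sel]), 1)[0]
        assert -1.2 < slope < -0.8

    @pytest.mark.parametrize("exponent", [0.0, 0.5, 1.0, 2.0])
    def test_exact_rms_and_zero_mean(self, exponent):
        x = gen_background(10, FS, exponent, 37.0, np.random.default_rng(3))
        assert np.sqrt(np.mean(x**2)) == pytest.approx(37.0, rel=1e-9)
        assert abs(x.mean()) < 1e-9 * 37.0

    def test_determinism(self):
        a = gen_background(5, FS, 1.0, 50.0, np.random.default_rng(9))
        b = gen_background(5, FS, 1.0, 50.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_bad_parameters(self):
        with pytest.raises(ValidationError):
            gen_background(1, FS, np.nan, 10.0, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            gen_background(1, FS, 1.0, -1.0, np.random.default_rng(0))


class TestPacSignal:
    def test_envelope_tracks_slow_phase(self):
        """χ=1, ε=0: analytic envelope at f_amp correlates r>0.9 with the
        slow sinusoid."""
        fs, f_p, f_a = 1000.0, 8.0, 80.0
        x = gen_pac_signal(f_p, f_a, 1.0, 10.0, 20.0, fs)
        sos = scipy.signal.butter(4, [f_a - 15, f_a + 15], btype="bandpass", fs=fs, output="sos")
        env = np.abs(scipy.signal.hilbert(scipy.signal.sosfiltfilt(sos, x)))
        t = np.arange(x.size) / fs
        slow = np.sin(2 * np.pi * f_p * t)
        k = int(fs)  # trim filter edges
        r = np.corrcoef(env[k:-k], slow[k:-k])[0, 1]
        assert r > 0.9

    def test_envelope_depth_matches_chi(self):
        for chi in (0.0, 0.5, 1.0):
            x = gen_pac_signal(8, 80, chi, 10.0, 5.0, FS)
            # reconstruct the known envelope analytically and check depth
            t = np.arange(x.size) / FS
            env = 10.0 * (1 + chi * np.sin(2 * np.pi * 8 * t)) / (1 + chi)
            depth = (env.max() - env.min()) / (env.max() + env.min())
            # sampled sinusoid extrema miss ±1 by O((f/fs)²)
            assert depth == pytest.approx(chi, abs=1e-3)

    def test_nyquist_guard(self):
        with pytest.raises(ValidationError):
            gen_pac_signal(8, 600, 0.5, 10, 1, FS)
        with pytest.raises(ValidationError):
            gen_pac_signal(80, 8, 0.5, 10, 1, FS)


class TestCoherentPair:
    def test_identical_signal_limit(self):
        y1, y2 = gen_coherent_pair(1.0, THETA, 20, 30, FS, np.random.default_rng(0))
        np.testing.assert_allclose(y1, y2)

    def test_independence_limit(self):
        y1, y2 = gen_coherent_pair(0.0, THETA, 20, 30, FS, np.random.default_rng(1))
        assert abs(np.corrcoef(y1, y2)[0, 1]) < 0.1

    def test_equal_power(self):
        # finite-sample rms of 8 Hz-wide noise over 30 s has ~3% sd
        y1, y2 = gen_coherent_pair(0.8, THETA, 20, 30, FS, np.random.default_rng(2))
        assert np.std(y1) == pytest.approx(np.std(y2), rel=0.12)
        assert np.std(y1) == pytest.approx(20.0, rel=0.1)


class TestAssemble:
    def test_no_seizures_stationary(self):
        spec = SynthSpec(duration_s=20, fs=FS, seed=0,
                         background=BackgroundSpec(0.5, 50.0))
        rec, events = assemble_recording(spec)
        assert events == []
        # variance stable across 10 non-overlapping windows
        chunks = rec.channel("HC").reshape(10, -1)
        v = chunks.var(axis=1)
        assert v.max() / v.min() < 1.2 / 0.8

    def test_ictal_power_gain(self):
        """Power gain g=10 gives an ictal/pre-ictal broadband power ratio
        in [5, 15] (measured directly on the samples)."""
        spec = SynthSpec(
            duration_s=60, fs=FS, seed=1,
            background=BackgroundSpec(1.0, 50.0),
            seizures=(SeizureSpec(onset_s=30, duration_s=10, broadband_gain=10.0,
                                  spike_rms=0.0),),
        )
        rec, events = assemble_recording(spec)
        pre = rec.slice(20, 30).channel("HC").var()
        ictal = rec.slice(30, 40).channel("HC").var()
        assert 5 < ictal / pre < 15

    def test_ground_truth_events_exact(self):
        spec = SynthSpec(duration_s=100, fs=FS, seed=2,
                         seizures=(SeizureSpec(10, 5), SeizureSpec(50, 8)))
        _, events = assemble_recording(spec)
        assert [(e.onset_s, e.termination_s, e.score) for e in events] == [
            (10, 15, 4), (50, 58, 4)]

    def test_determinism_bit_identical(self):
        spec = SynthSpec(duration_s=10, fs=FS, seed=5,
                         oscillations=(OscillationSpec(THETA, 20.0),),
                         pac=PacSpec(8, 80, 15, 0.5, noise_rms=1.0),
                         pair_coupling=PairCouplingSpec(0.6, THETA, 10.0))
        r1, _ = assemble_recording(spec)
        r2, _ = assemble_recording(spec)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_component_powers_add(self):
        """Independent components: total variance ≈ Σ component variances
        within 10% (averaged over seeds)."""
        ratios = []
        for seed in range(8):
            base = dict(duration_s=20, fs=FS, seed=seed)
            full, _ = assemble_recording(SynthSpec(
                **base, background=BackgroundSpec(1.0, 40.0),
                oscillations=(OscillationSpec(THETA, 20.0),),
                pair_coupling=PairCouplingSpec(0.6, THETA, 15.0)))
            parts = [
                assemble_recording(SynthSpec(**base, background=BackgroundSpec(1.0, 40.0),
                                             pac=PacSpec(carrier_rms=0.0)))[0],
                assemble_recording(SynthSpec(**base,
                                             background=BackgroundSpec(1.0, 1e-12),
                                             oscillations=(OscillationSpec(THETA, 20.0),),
                                             pac=PacSpec(carrier_rms=0.0)))[0],
                assemble_recording(SynthSpec(**base,
                                             background=BackgroundSpec(1.0, 1e-12),
                                             pair_coupling=PairCouplingSpec(0.6, THETA, 15.0),
                                             pac=PacSpec(carrier_rms=0.0)))[0],
            ]
            total = full.channel("HC").var()
            ratios.append(sum(p.channel("HC").var() for p in parts) / total)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_overlapping_seizures_rejected(self):
        with pytest.raises(ValidationError):
            SynthSpec(duration_s=60, seizures=(SeizureSpec(10, 10), SeizureSpec(15, 5)))

    def test_spec_dict_round_trip(self):
        spec = SynthSpec(duration_s=10, fs=FS, seed=5,
                         oscillations=(OscillationSpec(THETA, 20.0),),
                         seizures=(SeizureSpec(2, 3),))
        assert SynthSpec.from_dict(spec.to_dict()) == spec
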