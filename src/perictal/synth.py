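"""Synthetic two-channel LFP generator with known ground truth.

Every downstream stage of the pipeline (detection, stimulation,
spectral/coherence/PAC analysis, group statistics) is tested against
signals produced here, because their statistical structure is known by
construction:

* 1/f^α background noise with a target RMS;
* band-limited oscillations (delta/theta/gamma);
* a phase–amplitude-coupled component whose modulation depth χ is an
  explicit parameter, so PAC recovery can be checked quantitatively;
* a band-limited source shared between the two channels with mixing
  weight λ, which gives a closed-form magnitude-squared coherence of λ⁴;
* scheduled ictal events: an additive flat-spectrum discharge component
  raises total broadband power by a factor g ≥ 1 and a periodic
  spike–wave train is superimposed;
* no behavioral modeling — Racine scores on generated events are fixed
  at 4.

All generators are deterministic given (spec, seed); per-component
substreams are derived from the single global seed so adding one
component never perturbs another.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import HC, MPFC, BandDef, Recording, SeizureEvent

# fixed substream tags: (component, channel) -> independent RNG
_STREAMS = {
    "background": 1,
    "oscillation": 2,
    "pac": 3,
    "pair": 4,
    "seizure": 5,
}


def _rng(seed: int, component: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[component], int(index)])


@dataclasses.dataclass(frozen=True)
class BackgroundSpec:
    exponent: float = 1.0  # α in 1/f^α
    rms: float = 50.0      # µV


@dataclasses.dataclass(frozen=True)
class OscillationSpec:
    band: BandDef = dataclasses.field(default_factory=lambda: BandDef("theta", 4.0, 12.0))
    rms: float = 20.0


@dataclasses.dataclass(frozen=True)
class PacSpec:
    f_phase: float = 8.0
    f_amp: float = 80.0
    carrier_rms: float = 15.0
    depth: float = 0.0       # χ ∈ [0, 1]
    noise_rms: float = 0.0   # ε, small white noise added to the PAC signal


@dataclasses.dataclass(frozen=True)
class PairCouplingSpec:
    lam: float = 0.0         # λ ∈ [0, 1] shared-source mixing weight
    band: BandDef = dataclasses.field(default_factory=lambda: BandDef("theta", 4.0, 12.0))
    rms: float = 20.0


@dataclasses.dataclass(frozen=True)
class SeizureSpec:
    """One scheduled ictal event.

    ``broadband_gain`` is a *power* gain: inside the event a flat-spectrum
    (white) discharge component with power (g−1)× the background power is
    added, so total broadband power rises by the factor g.  A flat
    spectrum — not an amplified 1/f background — is what keeps every
    short epoch's power elevated, the way sustained population spiking
    does; a purely slow-wave boost would dip to zero at each slow-wave
    zero crossing.
    """

    onset_s: float
    duration_s: float
    broadband_gain: float = 10.0
    spikewave_hz: float = 3.0
    spike_rms: float = 150.0


@dataclasses.dataclass(frozen=True)
class ArtifactSpec:
    a0: float = 500.0   # µV pulse amplitude
    tau_s: float = 3e-3  # discharge time constant


@dataclasses.dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic two-channel recording."""

    duration_s: float = 60.0
    fs: float = 10_000.0
    seed: int = 0
    background: BackgroundSpec = dataclasses.field(default_factory=BackgroundSpec)
    oscillations: tuple[OscillationSpec, ...] = ()
    pac: PacSpec = dataclasses.field(default_factory=PacSpec)
    pair_coupling: PairCouplingSpec = dataclasses.field(default_factory=PairCouplingSpec)
    seizures: tuple[SeizureSpec, ...] = ()
    artifact: ArtifactSpec = dataclasses.field(default_factory=ArtifactSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.pac.depth <= 1:
            raise ValidationError(f"PAC depth must be in [0,1], got {self.pac.depth}")
        if not 0 <= self.pair_coupling.lam <= 1:
            raise ValidationError(f"λ must be in [0,1], got {self.pair_coupling.lam}")
        ivs = sorted((s.onset_s, s.onset_s + s.duration_s) for s in self.seizures)
        for s in self.seizures:
            if s.broadband_gain < 1:
                raise ValidationError("broadband gain must be >= 1")
            if s.onset_s < 0 or s.onset_s + s.duration_s > self.duration_s:
                raise ValidationError(
                    f"seizure [{s.onset_s}, {s.onset_s + s.duration_s}) outside recording"
                )
        for (a0, a1), (b0, _) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValidationError("seizure intervals overlap")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        if "background" in d and isinstance(d["background"], dict):
            d["background"] = BackgroundSpec(**d["background"])
        if "pac" in d and isinstance(d["pac"], dict):
            d["pac"] = PacSpec(**d["pac"])
        if "pair_coupling" in d and isinstance(d["pair_coupling"], dict):
            pc = dict(d["pair_coupling"])
            if isinstance(pc.get("band"), dict):
                pc["band"] = BandDef(**pc["band"])
            d["pair_coupling"] = PairCouplingSpec(**pc)
        if "oscillations" in d:
            oscs = []
            for o in d["oscillations"]:
                if isinstance(o, dict):
                    o = dict(o)
                    if isinstance(o.get("band"), dict):
                        o["band"] = BandDef(**o["band"])
                    o = OscillationSpec(**o)
                oscs.append(o)
            d["oscillations"] = tuple(oscs)
        if "seizures" in d:
            d["seizures"] = tuple(
                SeizureSpec(**s) if isinstance(s, dict) else s for s in d["seizures"]
            )
        if "artifact" in d and isinstance(d["artifact"], dict):
            d["artifact"] = ArtifactSpec(**d["artifact"])
        return cls(**d)


def _scale_to_rms(x: np.ndarray, rms: float) -> np.ndarray:
    x = x - x.mean()
    cur = np.sqrt(np.mean(x**2))
    if cur == 0:
        return x
    return x * (rms / cur)


def gen_background(
    duration_s: float,
    fs: float,
    exponent: float,
    rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean 1/f^α noise, scaled to an exact target RMS.

    Gaussian white noise is shaped in the frequency domain by
    ``|f|^(-α/2)`` (flat below 0.5 Hz to keep total power finite), so the
    average periodogram falls off with log–log slope −α over the band
    where the shaping is active.
    """
    if not np.isfinite(exponent) or not np.isfinite(rms):
        raise ValidationError("background parameters must be finite")
    if not 0 <= exponent <= 2:
        raise ValidationError(f"exponent must be in [0,2], got {exponent}")
    if rms <= 0:
        raise ValidationError(f"rms must be > 0, got {rms}")
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    if exponent == 0:
        return _scale_to_rms(white, rms)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_floor = 0.5
    shape = np.ones_like(f)
    active = f >= f_floor
    shape[active] = (f[active] / f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0  # zero-mean
    return _scale_to_rms(np.fft.irfft(spec * shape, n=n), rms)


def gen_bandlimited(
    band: BandDef,
    rms: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise (brick-wall in frequency), exact RMS."""
    if band.f_hi > fs / 2:
        raise ValidationError(f"band {band} exceeds Nyquist {fs / 2}")
    n = int(round(duration_s * fs))
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= band.f_lo) & (f < band.f_hi)
    return _scale_to_rms(np.fft.irfft(spec * mask, n=n), rms)


def gen_pac_signal(
    f_phase: float,
    f_amp: float,
    depth: float,
    carrier_rms: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator | None = None,
    noise_rms: float = 0.0,
) -> np.ndarray:
    """Phase–amplitude-coupled test signal with known modulation depth.

    Returns ``s(t) = A(t)·sin(2π f_amp t) + sin(2π f_phase t) + ε(t)``
    with envelope ``A(t) = carrier_rms·(1 + χ·sin(2π f_phase t))/(1+χ)``:
    the fast carrier's amplitude peaks at a fixed phase of the slow
    rhythm, and the envelope modulation depth (max−min)/(max+min) equals
    χ exactly.
    """
    if not f_phase < f_amp:
        raise ValidationError(f"need f_phase < f_amp, got {f_phase} >= {f_amp}")
    if f_amp >= fs / 2:
        raise ValidationError(f"f_amp={f_amp} at or above Nyquist {fs / 2}")
    if not 0 <= depth <= 1:
        raise ValidationError(f"depth must be in [0,1], got {depth}")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    slow = np.sin(2 * np.pi * f_phase * t)
    envelope = carrier_rms * (1.0 + depth * slow) / (1.0 + depth)
    out = envelope * np.sin(2 * np.pi * f_amp * t) + slow
    if noise_rms > 0:
        if rng is None:
            raise ValidationError("noise_rms > 0 requires an rng")
        out = out + noise_rms * rng.standard_normal(n)
    return out


def gen_coherent_pair(
    lam: float,
    band: BandDef,
    rms: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two channels sharing a band-limited source with weight λ.

    ``y_i = λ·s + sqrt(1−λ²)·n_i`` with s, n₁, n₂ independent equal-power
    band-limited noises.  The cross-spectrum is λ²·S_s while each
    auto-spectrum is λ²·S_s + (1−λ²)·S_n = S, so the expected
    magnitude-squared coherence inside the band is λ⁴.
    """
    if not 0 <= lam <= 1:
        raise ValidationError(f"λ must be in [0,1], got {lam}")
    s = gen_bandlimited(band, rms, duration_s, fs, rng)
    n1 = gen_bandlimited(band, rms, duration_s, fs, rng)
    n2 = gen_bandlimited(band, rms, duration_s, fs, rng)
    w = np.sqrt(1.0 - lam**2)
    return lam * s + w * n1, lam * s + w * n2


def spike_wave_train(
    duration_s: float,
    fs: float,
    rate_hz: float,
    spike_rms: float,
) -> np.ndarray:
    """Periodic spike–wave complexes: sharp spike then a slower wave.

    Each complex is a narrow positive Gaussian spike (σ = 8 ms) followed
    by a broader negative wave (σ = 50 ms), repeating at ``rate_hz``;
    the whole train is scaled to ``spike_rms``.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    period = 1.0 / rate_hz
    tau = np.mod(t, period)  # time within each complex
    spike = np.exp(-0.5 * ((tau - 0.03) / 0.008) ** 2)
    wave = -0.5 * np.exp(-0.5 * ((tau - 0.16) / 0.05) ** 2)
    return _scale_to_rms(spike + wave, spike_rms)


def assemble_recording(spec: SynthSpec) -> tuple[Recording, list[SeizureEvent]]:
    """Build the two-channel recording described by ``spec``.

    Per channel, the signal is the sum of an independent 1/f background,
    independent band-limited oscillations, the PAC component (slow phase
    rhythm on HC; amplitude-modulated fast carrier, driven by that same
    phase, on both channels), and the shared λ-mixed source.  Inside each
    scheduled seizure a white discharge component raising broadband power
    by ``broadband_gain`` and a spike–wave train are added on both
    channels.  Ground-truth events are exactly the scheduled intervals.
    """
    fs, dur, seed = spec.fs, spec.duration_s, spec.seed
    n = int(round(dur * fs))
    chans = {HC: np.zeros(n), MPFC: np.zeros(n)}

    backgrounds = {}
    for ci, label in enumerate(chans):
        bg = gen_background(
            dur, fs, spec.background.exponent, spec.background.rms, _rng(seed, "background", ci)
        )
        backgrounds[label] = bg

    for oi, osc in enumerate(spec.oscillations):
        for ci, label in enumerate(chans):
            chans[label] += gen_bandlimited(
                osc.band, osc.rms, dur, fs, _rng(seed, "oscillation", 100 * oi + ci)
            )

    pac = spec.pac
    if pac.carrier_rms > 0:
        t = np.arange(n) / fs
        slow = np.sin(2 * np.pi * pac.f_phase * t)
        envelope = pac.carrier_rms * (1.0 + pac.depth * slow) / (1.0 + pac.depth)
        carrier = envelope * np.sin(2 * np.pi * pac.f_amp * t)
        chans[HC] += slow * pac.carrier_rms + carrier
        chans[MPFC] += carrier
        if pac.noise_rms > 0:
            for ci, label in enumerate(chans):
                chans[label] += pac.noise_rms * _rng(seed, "pac", ci).standard_normal(n)

    pc = spec.pair_coupling
    if pc.lam > 0 and pc.rms > 0:
        y1, y2 = gen_coherent_pair(pc.lam, pc.band, pc.rms, dur, fs, _rng(seed, "pair"))
        chans[HC] += y1
        chans[MPFC] += y2

    events = []
    for si, sz in enumerate(sorted(spec.seizures, key=lambda s: s.onset_s)):
        i0 = int(round(sz.onset_s * fs))
        i1 = int(round((sz.onset_s + sz.duration_s) * fs))
        train = spike_wave_train(sz.duration_s, fs, sz.spikewave_hz, sz.spike_rms)
        ictal_rms = spec.background.rms * np.sqrt(sz.broadband_gain - 1.0)
        for ci, label in enumerate(chans):
            if ictal_rms > 0:
                discharge = _rng(seed, "seizure", 100 * si + ci).standard_normal(i1 - i0)
                chans[label][i0:i1] += ictal_rms * discharge
            chans[label][i0:i1] += train[: i1 - i0]
        events.append(SeizureEvent(sz.onset_s, sz.onset_s + sz.duration_s, score=4))

    for label in chans:
        chans[label] += backgrounds[label]

    samples = np.vstack([chans[HC], chans[MPFC]])
    return Recording(samples, fs, (HC, MPFC)), events
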