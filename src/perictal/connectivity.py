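"""Inter-regional coherence and phase–amplitude coupling (PAC).

Coherence is the Welch magnitude-squared coherence
``|S_xy|² / (S_xx · S_yy)``, estimated with the same windowing as the
PSDs; band coherence is the mean over the band's frequency bins.

PAC is quantified by the Kullback–Leibler modulation index of Tort:
the slow rhythm's instantaneous phase (zero-phase band-pass + analytic
signal) is binned into eighteen 20° intervals, the fast rhythm's
envelope is averaged in each bin, and the MI is the KL divergence of
that normalized phase–amplitude profile from uniform, divided by
log(n_bins) so MI ∈ [0, 1].  Comodulograms scan phase frequencies
1–12 Hz in 0.5 Hz steps against amplitude frequencies 35–250 Hz; the
amplitude filter is kept wide enough (≥ 1.5× the highest phase
frequency) for the modulation sidebands to pass.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from .errors import FilterError, InsufficientDataError, ValidationError
from .io import BandDef
from .spectral import WelchConfig


@dataclasses.dataclass(frozen=True)
class CoherenceSpectrum:
    freqs: np.ndarray
    msc: np.ndarray
    pair: tuple[str, str] = ("x", "y")


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    wcfg: WelchConfig = WelchConfig(),
    pair: tuple[str, str] = ("x", "y"),
) -> CoherenceSpectrum:
    """Magnitude-squared coherence of two equal-length segments.

    Requires at least two Welch windows — the coherence of a single
    window is identically one and carries no information.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("segments must have equal length")
    nper = wcfg.nperseg(x.size, fs)
    hop = nper - wcfg.noverlap(nper)
    n_windows = 1 + (x.size - nper) // hop
    if n_windows < 2:
        raise ValidationError(
            f"only {n_windows} Welch window(s); coherence needs >= 2"
        )
    freqs, c = scipy.signal.coherence(
        x, y, fs=fs, window=wcfg.taper, nperseg=nper,
        noverlap=wcfg.noverlap(nper), detrend=wcfg.detrend,
    )
    return CoherenceSpectrum(freqs, np.clip(c, 0.0, 1.0), pair)


def band_coherence(cs: CoherenceSpectrum, band: BandDef) -> float:
    """Mean MSC over frequency bins in ``[f_lo, f_hi)``."""
    sel = (cs.freqs >= band.f_lo) & (cs.freqs < band.f_hi)
    if not sel.any():
        raise ValidationError(f"no coherence bins inside {band}")
    return float(cs.msc[sel].mean())


# ---------------------------------------------------------------------------
# band-pass filtering and analytic-signal decomposition
# ---------------------------------------------------------------------------

_MIN_F_LO = 0.1  # Hz floor so very low phase bands keep a valid passband


def bandpass(x: np.ndarray, fs: float, f_lo: float, f_hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward–backward, SOS)."""
    f_lo = max(f_lo, _MIN_F_LO)
    if not f_lo < f_hi:
        raise FilterError(f"degenerate band [{f_lo}, {f_hi}]")
    if f_hi >= fs / 2:
        raise FilterError(f"band edge {f_hi} Hz at or above Nyquist {fs / 2} Hz")
    sos = scipy.signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(x, float))


def _trim(n: int, fs: float, edge_trim_s: float) -> slice:
    k = int(round(edge_trim_s * fs))
    if 2 * k >= n:
        raise ValidationError(f"edge trim {edge_trim_s}s leaves no samples")
    return slice(k, n - k) if k else slice(None)


def extract_phase(
    x: np.ndarray, fs: float, band: BandDef, edge_trim_s: float = 1.0
) -> np.ndarray:
    """Instantaneous phase (rad, wrapped to [−π, π)) of a band.

    Zero-phase band-pass, analytic-signal angle, then the first and last
    ``edge_trim_s`` are discarded to suppress filter transients.
    """
    filt = bandpass(x, fs, band.f_lo, band.f_hi)
    phase = np.angle(scipy.signal.hilbert(filt))
    return phase[_trim(phase.size, fs, edge_trim_s)]


def extract_amplitude(
    x: np.ndarray, fs: float, band: BandDef, edge_trim_s: float = 1.0
) -> np.ndarray:
    """Instantaneous amplitude envelope (µV) of a band; trims as above."""
    filt = bandpass(x, fs, band.f_lo, band.f_hi)
    env = np.abs(scipy.signal.hilbert(filt))
    return env[_trim(env.size, fs, edge_trim_s)]


# ---------------------------------------------------------------------------
# modulation index and comodulogram
# ---------------------------------------------------------------------------


def modulation_index(phase: np.ndarray, amp: np.ndarray, n_bins: int = 18) -> float:
    """Tort phase–amplitude modulation index.

    Phases are binned into ``n_bins`` equal intervals over [−π, π); the
    mean amplitude per bin, normalized to sum one, gives a distribution
    P whose Shannon entropy H yields ``MI = (log n − H) / log n``.
    MI is 0 for a phase-independent amplitude and 1 when all amplitude
    concentrates in a single bin.
    """
    phase, amp = np.asarray(phase, float), np.asarray(amp, float)
    if phase.shape != amp.shape:
        raise ValidationError("phase and amplitude series must have equal length")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    idx = _phase_bins(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise InsufficientDataError(
            f"{(counts == 0).sum()} of {n_bins} phase bins empty — MI undefined"
        )
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    p = sums / counts
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    mi = (np.log(n_bins) - h) / np.log(n_bins)
    return float(np.clip(mi, 0.0, 1.0))


def _phase_bins(phase: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)  # phase == +π folds into the last bin


@dataclasses.dataclass(frozen=True)
class MIConfig:
    """Comodulogram grid and filter settings.

    Phase axis 1–12 Hz in 0.5 Hz steps (23 centers, ±1 Hz band each);
    amplitude axis 35–250 Hz in 5 Hz steps (44 centers), each with
    half-bandwidth ``max(10, 1.5 × highest phase frequency)`` so the
    modulation sidebands survive the filter.
    """

    n_bins: int = 18
    phase_lo: float = 1.0
    phase_hi: float = 12.0
    phase_step: float = 0.5
    phase_bw: float = 1.0  # half-bandwidth, Hz
    amp_lo: float = 35.0
    amp_hi: float = 250.0
    amp_step: float = 5.0
    amp_bw: float | None = None  # None -> max(10, 1.5 * phase_hi)
    edge_trim_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")

    @property
    def phase_centers(self) -> np.ndarray:
        n = int(round((self.phase_hi - self.phase_lo) / self.phase_step)) + 1
        return self.phase_lo + self.phase_step * np.arange(n)

    @property
    def amp_centers(self) -> np.ndarray:
        n = int(round((self.amp_hi - self.amp_lo) / self.amp_step)) + 1
        return self.amp_lo + self.amp_step * np.arange(n)

    @property
    def amp_halfband(self) -> float:
        return self.amp_bw if self.amp_bw is not None else max(10.0, 1.5 * self.phase_hi)


@dataclasses.dataclass(frozen=True)
class Comodulogram:
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray  # (n_phase, n_amp)
    phase_source: str = "x"
    amp_source: str = "y"

    def peak(self) -> tuple[float, float, float]:
        """(phase_freq, amp_freq, MI) at the comodulogram maximum."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j]), float(self.mi[i, j])


def comodulogram(
    phase_sig: np.ndarray,
    amp_sig: np.ndarray,
    fs: float,
    cfg: MIConfig = MIConfig(),
    phase_source: str = "x",
    amp_source: str = "y",
) -> Comodulogram:
    """MI at every (phase frequency, amplitude frequency) grid point.

    ``phase_sig`` and ``amp_sig`` may be the same channel (within-region
    PAC) or different channels (inter-regional PAC — e.g. hippocampal
    phase driving prefrontal gamma amplitude).
    """
    phase_sig, amp_sig = np.asarray(phase_sig, float), np.asarray(amp_sig, float)
    if phase_sig.shape != amp_sig.shape:
        raise ValidationError("segments must have equal length")
    min_len = 10.0 / cfg.phase_centers[0] * fs
    if phase_sig.size < min_len:
        raise ValidationError(
            f"segment shorter than 10 cycles of {cfg.phase_centers[0]} Hz"
        )
    if cfg.amp_centers[-1] + cfg.amp_halfband >= fs / 2:
        raise ValidationError(
            f"amplitude grid reaches {cfg.amp_centers[-1] + cfg.amp_halfband} Hz, "
            f">= Nyquist {fs / 2} Hz"
        )
    # filter each axis once, then pair by binning (cheap)
    bins = []
    for fp in cfg.phase_centers:
        ph = extract_phase(
            phase_sig, fs, BandDef("ph", fp - cfg.phase_bw, fp + cfg.phase_bw),
            cfg.edge_trim_s,
        )
        bins.append(_phase_bins(ph, cfg.n_bins))
    envs = [
        extract_amplitude(
            amp_sig, fs, BandDef("amp", fa - cfg.amp_halfband, fa + cfg.amp_halfband),
            cfg.edge_trim_s,
        )
        for fa in cfg.amp_centers
    ]
    logn = np.log(cfg.n_bins)
    mi = np.empty((len(bins), len(envs)))
    for i, idx in enumerate(bins):
        counts = np.bincount(idx, minlength=cfg.n_bins)
        if (counts == 0).any():
            raise InsufficientDataError("empty phase bin in comodulogram")
        for j, env in enumerate(envs):
            p = np.bincount(idx, weights=env, minlength=cfg.n_bins) / counts
            p = p / p.sum()
            nz = p[p > 0]
            mi[i, j] = (logn + np.sum(nz * np.log(nz))) / logn
    return Comodulogram(
        cfg.phase_centers, cfg.amp_centers, np.clip(mi, 0.0, 1.0),
        phase_source, amp_source,
    )


def band_mi(
    phase_sig: np.ndarray,
    amp_sig: np.ndarray,
    fs: float,
    phase_band: BandDef,
    amp_band: BandDef,
    n_bins: int = 18,
    edge_trim_s: float = 1.0,
) -> float:
    """Band-level MI with single band-wide filters.

    This is the statistic behind bar-graph comparisons such as delta
    phase (1–4 Hz) × gamma amplitude (50–250 Hz).
    """
    ph = extract_phase(phase_sig, fs, phase_band, edge_trim_s)
    env = extract_amplitude(amp_sig, fs, amp_band, edge_trim_s)
    return modulation_index(ph, env, n_bins)
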