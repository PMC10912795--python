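"""Domain types and file I/O for two-channel LFP experiments.

In memory a recording is a ``(n_channels, n_samples)`` float64 array in
microvolts (µV) plus a sampling rate and ordered channel labels.  On disk
recordings are EDF (European Data Format); seizure annotations and
stimulation pulse logs are plain CSV with a header row.

Conventions used throughout the package:

* time is in seconds (float), relative to an arbitrary origin ``t0``;
* samples are 0-based, and every time interval is half-open ``[start, end)``
  so segment boundaries are never double-counted;
* amplitude is always µV — no silent unit conversions anywhere.

EDF reading goes through :mod:`mne`; writing uses a small 16-bit EDF
serializer in this module (one data record per second where the duration
is a whole number of seconds, a single record otherwise).
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, FormatError, ValidationError

#: Acquisition default — signals digitized at 10 kHz.
DEFAULT_FS = 10_000.0

#: Conventional channel labels for the two recorded regions.
HC, MPFC = "HC", "mPFC"


@dataclasses.dataclass(frozen=True)
class Recording:
    """Multi-channel LFP time series.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` float array, µV.
    fs
        Sampling rate in Hz, > 0.
    channels
        Ordered channel labels, one per row of ``samples``.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if arr.ndim != 2 or arr.shape[1] < 1:
            raise ValidationError("samples must be (n_channels, n_samples) with >= 1 sample")
        if len(self.channels) != arr.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} labels for {arr.shape[0]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recorded duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise ValidationError(
                f"channel {label!r} not in {self.channels}"
            ) from None
        return self.samples[idx]

    def slice(self, t_start: float, t_end: float) -> "Recording":
        """Half-open time slice ``[t_start, t_end)`` as a new Recording.

        Endpoints are mapped to sample indices by rounding
        ``(t - t0) * fs`` to the nearest integer, so two adjacent slices
        concatenate exactly to the enclosing slice.  Out-of-range requests
        raise :class:`BoundsError` — never silent truncation.
        """
        if not (t_start < t_end):
            raise ValidationError(f"need t_start < t_end, got [{t_start}, {t_end})")
        i0 = int(np.floor((t_start - self.t0) * self.fs + 0.5))
        i1 = int(np.floor((t_end - self.t0) * self.fs + 0.5))
        if i0 < 0 or i1 > self.n_samples:
            raise BoundsError(
                f"slice [{t_start}, {t_end}) outside recording "
                f"[{self.t0}, {self.t_end})"
            )
        return Recording(self.samples[:, i0:i1], self.fs, self.channels, t0=t_start)

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with the sample array replaced."""
        return Recording(samples, self.fs, self.channels, self.t0)


@dataclasses.dataclass(frozen=True, order=True)
class SeizureEvent:
    """Annotated ictal interval.

    ``onset_s``/``termination_s`` are relative to the recording origin;
    ``score`` is the 0–5 modified Racine behavioral severity.
    """

    onset_s: float
    termination_s: float
    score: int = 4

    def __post_init__(self) -> None:
        if not self.termination_s > self.onset_s:
            raise ValidationError(
                f"termination ({self.termination_s}) must exceed onset ({self.onset_s})"
            )
        if int(self.score) != self.score or not 0 <= self.score <= 5:
            raise ValidationError(f"Racine score must be an integer in 0..5, got {self.score}")

    @property
    def duration_s(self) -> float:
        return self.termination_s - self.onset_s


@dataclasses.dataclass(frozen=True)
class StimPulse:
    """A single stimulation pulse (square, monophasic)."""

    time_s: float
    package_idx: int
    width_s: float = 1e-4
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValidationError(f"width_s must be > 0, got {self.width_s}")
        if self.package_idx < 0:
            raise ValidationError("package_idx must be >= 0")


@dataclasses.dataclass(frozen=True)
class BandDef:
    """Named frequency band ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValidationError(f"need 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi})")


# Band definitions: delta below 4 Hz (0.5 Hz detrending floor), theta
# 4–12 Hz, gamma 30–150 Hz with slow/middle/fast sub-bands chosen to
# straddle neither 50 nor 60 Hz line frequency.
DELTA = BandDef("delta", 0.5, 4.0)
THETA = BandDef("theta", 4.0, 12.0)
GAMMA = BandDef("gamma", 30.0, 150.0)
SLOW_GAMMA = BandDef("slow_gamma", 30.0, 55.0)
MIDDLE_GAMMA = BandDef("middle_gamma", 55.0, 95.0)
FAST_GAMMA = BandDef("fast_gamma", 95.0, 150.0)
STANDARD_BANDS = (DELTA, THETA, GAMMA)
GAMMA_SUBBANDS = (SLOW_GAMMA, MIDDLE_GAMMA, FAST_GAMMA)


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics to fit the fixed-width ascii field
        s = f"{float(value):.{max(width - 8, 0)}e}" if width >= 9 else s[:width]
    if len(s) > width:
        raise FormatError(f"EDF field {value!r} does not fit in {width} chars")
    return s.ljust(width).encode("ascii")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to a 16-bit EDF file.

    Physical range is set per channel to the sample extrema (symmetric),
    so amplitudes round-trip to within one 16-bit quantization step.
    """
    path = Path(path)
    n_sig = len(rec.channels)
    fs = rec.fs
    # one record per second when everything divides evenly, else a single
    # record holding the whole signal (EDF permits fractional durations)
    if fs == int(fs) and rec.n_samples % int(fs) == 0 and rec.n_samples > int(fs):
        spr = int(fs)  # samples per record
        n_records = rec.n_samples // spr
        rec_dur = 1.0
    else:
        spr = rec.n_samples
        n_records = 1
        rec_dur = rec.n_samples / fs
    peaks = np.maximum(np.max(np.abs(rec.samples), axis=1), 1e-6)
    phys_min, phys_max = -peaks, peaks

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)          # patient id
    header += _edf_field("Startdate X X X X", 80)  # recording id
    dt = datetime.datetime(2000, 1, 1)
    header += _edf_field(dt.strftime("%d.%m.%y"), 8)
    header += _edf_field(dt.strftime("%H.%M.%S"), 8)
    header += _edf_field(256 * (1 + n_sig), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(f"{rec_dur:g}", 8)
    header += _edf_field(n_sig, 4)
    for label in rec.channels:
        header += _edf_field(label, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_sig))       # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(n_sig))
    header += b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_max)
    header += b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(n_sig))
    header += b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(n_sig))
    header += b"".join(_edf_field("", 80) for _ in range(n_sig))       # prefilter
    header += b"".join(_edf_field(spr, 8) for _ in range(n_sig))
    header += b"".join(_edf_field("", 32) for _ in range(n_sig))

    # physical -> digital, per channel
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round(
        (rec.samples - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within each record


def read_recording(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (samples in µV).

    Raises :class:`FormatError` on malformed files or files with no
    signals, and on layouts with unequal per-channel sampling rates.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"not a readable EDF file: {path} ({exc})") from exc
    if len(raw.ch_names) == 0:
        raise FormatError(f"EDF file has no signals: {path}")
    data = raw.get_data() * 1e6  # mne returns SI volts; we store µV
    return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names), t0=0.0)


# ---------------------------------------------------------------------------
# CSV annotation / log I/O
# ---------------------------------------------------------------------------


def read_events(path: str | Path) -> list[SeizureEvent]:
    """Read seizure annotations (columns onset_s, termination_s, score).

    Events are returned sorted by onset; overlapping events are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"onset_s", "termination_s", "score"}
    if not required.issubset(df.columns):
        raise FormatError(f"events CSV must have columns {sorted(required)}")
    events = []
    for row in df.itertuples(index=False):
        score = row.score
        if float(score) != int(score):
            raise ValidationError(f"non-integer Racine score: {score}")
        events.append(SeizureEvent(float(row.onset_s), float(row.termination_s), int(score)))
    events.sort(key=lambda e: e.onset_s)
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.termination_s:
            raise ValidationError(f"overlapping events at {a.onset_s}s and {b.onset_s}s")
    return events


def write_events(events: list[SeizureEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.onset_s, e.termination_s, e.score) for e in events],
        columns=["onset_s", "termination_s", "score"],
    ).to_csv(path, index=False)


def read_stim_log(path: str | Path) -> list[StimPulse]:
    """Read a stimulation pulse log (time_s, package_idx, width_s, amplitude)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "package_idx", "width_s", "amplitude"}
    if not required.issubset(df.columns):
        raise FormatError(f"stim log CSV must have columns {sorted(required)}")
    pulses = [
        StimPulse(float(r.time_s), int(r.package_idx), float(r.width_s), float(r.amplitude))
        for r in df.itertuples(index=False)
    ]
    return sorted(pulses, key=lambda p: p.time_s)


def write_stim_log(pulses: list[StimPulse], path: str | Path) -> None:
    pd.DataFrame(
        [(p.time_s, p.package_idx, p.width_s, p.amplitude) for p in pulses],
        columns=["time_s", "package_idx", "width_s", "amplitude"],
    ).to_csv(path, index=False)
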