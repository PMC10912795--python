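"""Low-frequency DBS scheduling, artifact injection and artifact removal.

The stimulation pattern is four packages of 200 monophasic square pulses
(0.1 ms wide) delivered at 1 Hz, packages separated by 5-minute
intervals.  "5-minute intervals" is ambiguous between a gap after each
package and a start-to-start spacing; both interpretations are
implemented and the gap-after-package-end reading is the default.

For synthetic data the stimulator's passive charge-balancing is modeled
as the recorded artifact: a square pulse followed by an opposite-sign
exponential discharge whose integral cancels the pulse's (net charge
zero).  Artifact samples are bin-averaged integrals of that continuous
waveform, so charge balance holds on the sample grid at any sampling
rate, including rates where the pulse is narrower than one sample.

Artifact removal is blank-and-interpolate: a short window after each
pulse is replaced by linear interpolation between the boundary samples.
At 1 Hz stimulation a 10 ms blank discards 1% of the data.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

from .errors import BoundsError, ScheduleError, ValidationError
from .io import Recording, StimPulse
from .synth import ArtifactSpec


@dataclasses.dataclass(frozen=True)
class StimProtocol:
    """Pulse-train protocol constants (defaults follow the published pattern)."""

    n_packages: int = 4
    pulses_per_package: int = 200
    pulse_rate_hz: float = 1.0
    pulse_width_s: float = 1e-4
    inter_package_gap_s: float = 300.0
    interval_mode: Literal["gap-after-package-end", "start-to-start"] = (
        "gap-after-package-end"
    )

    def __post_init__(self) -> None:
        if self.n_packages < 1 or self.pulses_per_package < 1:
            raise ValidationError("package and pulse counts must be >= 1")
        if self.pulse_rate_hz <= 0 or self.pulse_width_s <= 0:
            raise ValidationError("rates and widths must be > 0")

    @property
    def package_span_s(self) -> float:
        """First-to-last pulse time within one package."""
        return (self.pulses_per_package - 1) / self.pulse_rate_hz


@dataclasses.dataclass(frozen=True)
class StimEpisode:
    """One closed-loop stimulation episode: all pulses of all packages."""

    t_trigger_s: float
    pulses: tuple[StimPulse, ...]
    t_end_s: float


def schedule_episode(
    t_trigger: float, protocol: StimProtocol = StimProtocol(), amplitude: float = 1.0
) -> StimEpisode:
    """Lay out the full pulse schedule of one episode.

    Under ``gap-after-package-end`` package p+1 starts
    ``inter_package_gap_s`` after the last pulse of package p; under
    ``start-to-start`` the package *starts* are spaced by the gap and a
    package longer than the gap raises :class:`ScheduleError`.
    """
    if t_trigger < 0:
        raise ValidationError("t_trigger must be >= 0")
    span = protocol.package_span_s
    if protocol.interval_mode == "start-to-start":
        if protocol.n_packages > 1 and span + protocol.pulse_width_s > protocol.inter_package_gap_s:
            raise ScheduleError(
                f"package span {span:g}s does not fit start-to-start gap "
                f"{protocol.inter_package_gap_s:g}s"
            )
        starts = [t_trigger + p * protocol.inter_package_gap_s for p in range(protocol.n_packages)]
    else:
        starts = [
            t_trigger + p * (span + protocol.inter_package_gap_s)
            for p in range(protocol.n_packages)
        ]
    pulses = []
    for p, start in enumerate(starts):
        for k in range(protocol.pulses_per_package):
            pulses.append(
                StimPulse(
                    time_s=start + k / protocol.pulse_rate_hz,
                    package_idx=p,
                    width_s=protocol.pulse_width_s,
                    amplitude=amplitude,
                )
            )
    return StimEpisode(t_trigger, tuple(pulses), pulses[-1].time_s)


def _artifact_bin_means(
    n_bins: int, dt: float, offset_s: float, width_s: float, a0: float, tau_s: float
) -> np.ndarray:
    """Average of the continuous artifact waveform over each sample bin.

    Waveform (t measured from pulse onset): ``a0`` for t in [0, w), then
    ``-a_d·exp(-(t-w)/τ)`` with ``a_d = a0·w/τ`` so the discharge integral
    cancels the pulse integral.  Using bin averages instead of point
    samples makes the discrete sum of samples·dt equal the continuous
    integral, preserving charge balance at any fs.
    """
    a_d = a0 * width_s / tau_s
    edges = offset_s + np.arange(n_bins + 1) * dt
    # integral of the square-pulse part over [0, t]
    sq = a0 * np.clip(edges, 0.0, width_s)
    # integral of the exponential part over [w, t]
    te = np.clip(edges - width_s, 0.0, None)
    ex = -a_d * tau_s * (1.0 - np.exp(-te / tau_s))
    cum = sq + ex
    return np.diff(cum) / dt


def inject_artifacts(
    rec: Recording,
    pulses: Sequence[StimPulse],
    artifact: ArtifactSpec = ArtifactSpec(),
    channel: str = "HC",
) -> Recording:
    """Add the stimulation artifact waveform at each pulse time.

    Only ``channel`` (the stimulated electrode) is modified.  A pulse
    whose waveform would extend past the recording end raises
    :class:`BoundsError`.
    """
    if artifact.a0 == 0 or not pulses:
        return rec
    ci = rec.channels.index(channel)
    out = rec.samples.copy()
    dt = 1.0 / rec.fs
    max_width = max(p.width_s for p in pulses)
    n_tail = int(np.ceil((8.0 * artifact.tau_s + max_width) / dt)) + 1
    for p in pulses:
        i0 = int(np.floor((p.time_s - rec.t0) * rec.fs))
        if i0 < 0 or p.time_s + p.width_s > rec.t_end:
            raise BoundsError(f"pulse at {p.time_s}s outside recording")
        i1 = min(i0 + n_tail, rec.n_samples)
        offset = rec.t0 + i0 * dt - p.time_s  # bin start relative to pulse onset
        out[ci, i0:i1] += _artifact_bin_means(
            i1 - i0, dt, offset, p.width_s, artifact.a0, artifact.tau_s
        )
    return rec.with_samples(out)


def remove_artifacts(
    rec: Recording, pulses: Sequence[StimPulse], blank_s: float = 0.01
) -> Recording:
    """Blank-and-interpolate stimulation artifacts on all channels.

    Samples in ``[time_s, time_s + blank_s)`` around each pulse are
    replaced by linear interpolation between the samples bordering the
    window; contiguous or overlapping windows are merged first.  The
    operation is idempotent (boundary samples are untouched) and exact
    for affine signals.
    """
    if not pulses:
        return rec
    if blank_s <= 0:
        raise ValidationError("blank_s must be > 0")
    times = sorted(p.time_s for p in pulses)
    # merge to half-open sample-index windows
    windows: list[list[int]] = []
    for t in times:
        i0 = int(np.floor((t - rec.t0) * rec.fs))
        i1 = int(np.ceil((t + blank_s - rec.t0) * rec.fs))
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
        if i1 <= i0:
            continue
        if windows and i0 <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], i1)
        else:
            windows.append([i0, i1])
    if len(windows) == 1 and windows[0][0] <= 0 and windows[0][1] >= rec.n_samples:
        raise ValidationError("blank window covers the entire recording")
    out = rec.samples.copy()
    for i0, i1 in windows:
        left = max(i0 - 1, 0)
        right = min(i1, rec.n_samples - 1)
        w = np.linspace(0.0, 1.0, i1 - i0 + 2)[1:-1] if i1 > i0 else np.empty(0)
        for c in range(out.shape[0]):
            y0, y1 = out[c, left], out[c, right]
            out[c, i0:i1] = y0 + (y1 - y0) * w
    return rec.with_samples(out)
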