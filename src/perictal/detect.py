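"""Online seizure-onset detection from windowed LFP power.

The detector mimics a responsive ("closed-loop") stimulator: the signal
is cut into short non-overlapping epochs (10 ms by default), the mean
squared amplitude of each epoch is compared to a baseline power obtained
by averaging over a long trailing window (10 s by default), and a
seizure onset is declared when 100 consecutive epochs each exceed
``threshold_k`` times the baseline.  The pass is strictly causal: only
past epochs enter the baseline, the baseline is frozen while a candidate
run of supra-threshold epochs is in progress (so ictal power never
inflates it), and epochs inside caller-supplied exclusion intervals
(e.g. stimulation periods) are ignored entirely.  During the
post-detection refractory period no detection can fire but the baseline
keeps adapting, so a sustained shift in ambient power yields exactly one
detection rather than one per refractory cycle.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import Recording, SeizureEvent


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """Tunable constants of the power-threshold detector.

    ``epoch_s``/``n_consecutive``/``baseline_s`` default to the published
    protocol (10 ms epochs, 100 consecutive epochs, 10 s baseline);
    ``threshold_k`` is the power ratio an epoch must exceed and is a free
    parameter of this implementation.
    """

    epoch_s: float = 0.01
    n_consecutive: int = 100
    baseline_s: float = 10.0
    threshold_k: float = 4.0
    refractory_s: float = 60.0
    channel: str = "HC"

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be > 0")
        if self.n_consecutive < 1:
            raise ValidationError("n_consecutive must be >= 1")
        if self.baseline_s < self.epoch_s:
            raise ValidationError("baseline_s must be >= epoch_s")
        if self.threshold_k <= 1:
            raise ValidationError("threshold_k must be > 1")


@dataclasses.dataclass(frozen=True)
class Detection:
    """One detector firing: back-dated onset time and the baseline used."""

    t_detect_s: float
    baseline_power: float


def epoch_power(x: np.ndarray, fs: float, epoch_s: float) -> np.ndarray:
    """Mean squared amplitude per non-overlapping epoch (µV²).

    The trailing partial epoch is discarded, so the output has
    ``floor(len(x) / (epoch_s * fs))`` entries.
    """
    x = np.asarray(x, dtype=np.float64)
    n_per = int(round(epoch_s * fs))
    if n_per < 1 or n_per > x.size:
        raise ValidationError(
            f"epoch of {n_per} samples invalid for series of {x.size}"
        )
    m = x.size // n_per
    return np.mean(x[: m * n_per].reshape(m, n_per) ** 2, axis=1)


def detect_onsets(
    rec: Recording,
    cfg: DetectorConfig = DetectorConfig(),
    exclusions: Sequence[tuple[float, float]] = (),
) -> list[Detection]:
    """Single causal pass of the power-threshold detector over a recording.

    Parameters
    ----------
    rec
        Recording containing ``cfg.channel``.
    cfg
        Detector constants.
    exclusions
        Half-open ``(start_s, end_s)`` intervals (absolute time) whose
        epochs are skipped entirely — they neither update the baseline
        nor count toward a candidate run (a run in progress is reset).

    Returns
    -------
    list of :class:`Detection`, sorted in time.  ``t_detect_s`` is
    back-dated to the first epoch of the qualifying run.  After each
    detection the detector is refractory for ``cfg.refractory_s``.
    """
    x = rec.channel(cfg.channel)
    if rec.duration <= cfg.baseline_s:
        raise ValidationError(
            f"recording ({rec.duration:g} s) must exceed baseline_s ({cfg.baseline_s:g} s)"
        )
    powers = epoch_power(x, rec.fs, cfg.epoch_s)
    n_base = int(round(cfg.baseline_s / cfg.epoch_s))
    epoch_starts = rec.t0 + np.arange(powers.size) * cfg.epoch_s

    # epoch i excluded iff its start falls in any exclusion interval
    excluded = np.zeros(powers.size, dtype=bool)
    for a, b in exclusions:
        excluded |= (epoch_starts >= a) & (epoch_starts < b)

    detections: list[Detection] = []
    ring = np.empty(n_base)  # circular buffer of baseline epoch powers
    ring_n = 0               # filled entries
    ring_pos = 0
    ring_sum = 0.0
    run_len = 0
    run_start_t = 0.0
    frozen_baseline = 0.0
    refractory_until = -np.inf

    def push_baseline(p: float) -> None:
        nonlocal ring_n, ring_pos, ring_sum
        if ring_n < n_base:
            ring[ring_pos] = p
            ring_sum += p
            ring_n += 1
        else:
            ring_sum += p - ring[ring_pos]
            ring[ring_pos] = p
        ring_pos = (ring_pos + 1) % n_base

    for i in range(powers.size):
        t_i = epoch_starts[i]
        if excluded[i]:
            run_len = 0
            continue
        p = powers[i]
        if t_i < refractory_until:
            # no detections while refractory, but the baseline keeps
            # adapting so a sustained power shift does not retrigger
            run_len = 0
            push_baseline(p)
            continue
        if run_len > 0:
            baseline = frozen_baseline
        else:
            if ring_n < n_base:
                baseline = ring_sum / ring_n if ring_n else np.inf
            else:
                baseline = ring_sum / n_base
        if ring_n >= n_base and p > cfg.threshold_k * baseline:
            if run_len == 0:
                run_start_t = t_i
                frozen_baseline = baseline
            run_len += 1
            if run_len >= cfg.n_consecutive:
                detections.append(Detection(run_start_t, frozen_baseline))
                refractory_until = t_i + cfg.epoch_s + cfg.refractory_s
                run_len = 0
            continue  # supra-threshold epochs never enter the baseline
        run_len = 0
        push_baseline(p)  # sub-threshold epoch -> update trailing baseline

    return detections


def detection_metrics(
    detections: Sequence[Detection],
    truth: Sequence[SeizureEvent],
    tolerance_s: float,
    total_duration_s: float,
) -> dict:
    """Sensitivity, false-detection rate and latency against ground truth.

    A detection is a true positive if its time falls in
    ``[onset, onset + tolerance_s]`` of an unmatched truth event; each
    event is matched at most once (greedy, in time order).
    """
    if tolerance_s <= 0:
        raise ValidationError("tolerance_s must be > 0")
    truth = sorted(truth, key=lambda e: e.onset_s)
    matched = [False] * len(truth)
    latencies = []
    n_false = 0
    for det in sorted(detections, key=lambda d: d.t_detect_s):
        hit = None
        for j, ev in enumerate(truth):
            if not matched[j] and ev.onset_s <= det.t_detect_s <= ev.onset_s + tolerance_s:
                hit = j
                break
        if hit is None:
            n_false += 1
        else:
            matched[hit] = True
            latencies.append(det.t_detect_s - truth[hit].onset_s)
    sensitivity = (sum(matched) / len(truth)) if truth else float("nan")
    return {
        "sensitivity": sensitivity,
        "false_detections_per_hour": n_false / (total_duration_s / 3600.0),
        "median_latency_s": float(np.median(latencies)) if latencies else float("nan"),
        "n_true_positive": sum(matched),
        "n_false_positive": n_false,
    }
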