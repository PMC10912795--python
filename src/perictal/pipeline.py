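"""End-to-end orchestration: generate → closed loop → metrics → statistics.

The pipeline ties the pieces together the way the original experiment
ran: a recording with scheduled seizures is produced by the generator,
the online detector watches the hippocampal channel, every detection
triggers a stimulation episode whose artifacts are injected into the
recording, artifacts are removed again before analysis, and every
analyzable seizure contributes band powers, band coherences and band
MIs to tidy tables that feed the group statistics.

The "intervention model" is an explicit simulation knob: seizures that
overlap a stimulation episode get their ground-truth duration
multiplied by ``duration_shortening_factor`` — bookkeeping that lets
before/during/after seizure accounting be exercised, not a claim about
biology.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import MIConfig, band_coherence, band_mi, msc
from .detect import Detection, DetectorConfig, detect_onsets
from .errors import BoundsError, InsufficientDataError, ValidationError
from .io import (
    DELTA,
    GAMMA,
    GAMMA_SUBBANDS,
    HC,
    MPFC,
    STANDARD_BANDS,
    THETA,
    BandDef,
    Recording,
    SeizureEvent,
    StimPulse,
)
from .spectral import (
    SegmentationConfig,
    WelchConfig,
    band_power_table,
    post_pre_ratio,
    segment_around_seizure,
)
from .stats import compare_groups
from .stim import StimProtocol, inject_artifacts, remove_artifacts, schedule_episode
from .synth import ArtifactSpec, SynthSpec, assemble_recording

logger = logging.getLogger("perictal")

#: Gamma band used for the band-level MI bar statistics (figure-level
#: convention: 50–250 Hz), distinct from the 30–150 Hz power band.
MI_GAMMA = BandDef("gamma_mi", 50.0, 250.0)
MI_DELTA = BandDef("delta_mi", 1.0, 4.0)
MI_THETA = BandDef("theta_mi", 4.0, 12.0)

PERIOD_TAGS = ("before", "during", "after")


@dataclasses.dataclass(frozen=True)
class InterventionModel:
    """Simulated effect of stimulation on seizure duration."""

    duration_shortening_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.duration_shortening_factor <= 1:
            raise ValidationError("shortening factor must be in (0, 1]")


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    synth: SynthSpec = dataclasses.field(default_factory=SynthSpec)
    detector: DetectorConfig = dataclasses.field(default_factory=DetectorConfig)
    protocol: StimProtocol = dataclasses.field(default_factory=StimProtocol)
    intervention: InterventionModel = dataclasses.field(default_factory=InterventionModel)
    segmentation: SegmentationConfig = dataclasses.field(default_factory=SegmentationConfig)
    welch: WelchConfig = dataclasses.field(default_factory=WelchConfig)
    mi: MIConfig = dataclasses.field(default_factory=MIConfig)
    detector_enabled: bool = True
    seed: int = 0


@dataclasses.dataclass
class ClosedLoopResult:
    recording: Recording            # with stimulation artifacts injected
    detections: list[Detection]
    episodes: list                  # StimEpisode per accepted detection
    pulses: list[StimPulse]
    events: list[SeizureEvent]      # post-intervention ground truth


def run_closed_loop(
    rec: Recording,
    events: Sequence[SeizureEvent],
    cfg: ExperimentConfig,
) -> ClosedLoopResult:
    """Run detector + stimulation scheduler causally over a recording.

    Detections falling inside an already-scheduled episode are dropped
    (the stimulator is busy); accepted episodes have their artifacts
    injected on the detector channel.  Seizures overlapping any episode
    are shortened by the intervention factor in the returned event list.
    """
    if not cfg.detector_enabled:
        return ClosedLoopResult(rec, [], [], [], list(events))
    detections = detect_onsets(rec, cfg.detector)
    episodes = []
    accepted = []
    for det in detections:
        if episodes and det.t_detect_s < episodes[-1].t_end_s:
            continue  # stimulator busy
        try:
            ep = schedule_episode(det.t_detect_s, cfg.protocol)
        except ValidationError:
            continue
        # keep only pulses inside the recording
        pulses_in = tuple(p for p in ep.pulses if p.time_s + p.width_s <= rec.t_end)
        if not pulses_in:
            continue
        episodes.append(
            dataclasses.replace(ep, pulses=pulses_in, t_end_s=pulses_in[-1].time_s)
        )
        accepted.append(det)
    pulses = [p for ep in episodes for p in ep.pulses]
    stim_rec = inject_artifacts(rec, pulses, cfg.synth.artifact, channel=cfg.detector.channel)

    factor = cfg.intervention.duration_shortening_factor
    new_events = []
    for ev in events:
        stimulated = any(
            ep.t_trigger_s < ev.termination_s and ev.onset_s < ep.t_end_s for ep in episodes
        )
        if stimulated and factor < 1.0:
            new_events.append(
                SeizureEvent(ev.onset_s, ev.onset_s + factor * ev.duration_s, ev.score)
            )
        else:
            new_events.append(ev)
    return ClosedLoopResult(stim_rec, accepted, episodes, pulses, new_events)


def seizure_accounting(
    events_by_period: Mapping[str, Sequence[SeizureEvent]],
    behavioral_durations: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Seizure count and mean durations per experimental period.

    Periods are the stimulation timeline: before / during / after the
    stimulation week.  Mean durations of empty periods are reported as
    missing, never as zero.
    """
    rows = []
    for period, evs in events_by_period.items():
        if period not in PERIOD_TAGS:
            raise ValidationError(f"unknown period tag {period!r}; expected {PERIOD_TAGS}")
        durs = [e.duration_s for e in evs]
        beh = list(behavioral_durations[period]) if behavioral_durations else durs
        rows.append(
            {
                "period": period,
                "n_seizures": len(evs),
                "mean_discharge_duration_s": float(np.mean(durs)) if durs else np.nan,
                "mean_behavioral_duration_s": float(np.mean(beh)) if beh else np.nan,
            }
        )
    return pd.DataFrame(rows)


def seizure_metric_table(
    rec: Recording,
    events: Sequence[SeizureEvent],
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    wcfg: WelchConfig = WelchConfig(),
    include_subbands: bool = True,
    compute_mi: bool = True,
    mi_edge_trim_s: float = 0.5,
) -> pd.DataFrame:
    """All per-seizure metrics in one tidy table.

    Columns: seizure_id, period, metric, channel(s), band, value.
    Metrics: band power per channel, HC–mPFC band coherence (delta,
    theta), and band MI for both directions (HC phase → mPFC amplitude
    and the reverse) plus within-region MI, for delta and theta phase
    against 50–250 Hz gamma amplitude.  MI on the 5-s ictal segment uses
    a shorter edge trim than the default 1 s so data survives.
    """
    bands = list(STANDARD_BANDS) + (list(GAMMA_SUBBANDS) if include_subbands else [])
    skipped: list[tuple[int, str]] = []

    pow_df = band_power_table(
        rec, events, bands, seg_cfg, wcfg,
        on_skip=lambda i, why: skipped.append((i, why)),
    )
    pow_df = pow_df.rename(columns={"power_uv2": "value"})
    pow_df["metric"] = "band_power"

    rows = []
    for si, ev in enumerate(events):
        if any(s[0] == si for s in skipped):
            continue
        segs = segment_around_seizure(rec, ev, seg_cfg)
        for period, seg in segs.items():
            hc, pf = seg.channel(HC), seg.channel(MPFC)
            cs = msc(hc, pf, seg.fs, wcfg, pair=(HC, MPFC))
            for band in (DELTA, THETA):
                rows.append(
                    {
                        "seizure_id": si, "period": period, "channel": f"{HC}-{MPFC}",
                        "band": band.name, "metric": "coherence",
                        "value": band_coherence(cs, band),
                    }
                )
            if not compute_mi:
                continue
            trim = min(mi_edge_trim_s, seg.duration / 4)
            pairs = {
                (HC, MPFC): (hc, pf),
                (MPFC, HC): (pf, hc),
                (HC, HC): (hc, hc),
                (MPFC, MPFC): (pf, pf),
            }
            for (ph_src, amp_src), (ph_sig, amp_sig) in pairs.items():
                for phase_band in (MI_DELTA, MI_THETA):
                    try:
                        mi_val = band_mi(
                            ph_sig, amp_sig, seg.fs, phase_band, MI_GAMMA,
                            edge_trim_s=trim,
                        )
                    except (InsufficientDataError, ValidationError) as exc:
                        logger.warning("seizure %d %s MI skipped: %s", si, period, exc)
                        continue
                    rows.append(
                        {
                            "seizure_id": si, "period": period,
                            "channel": f"{ph_src}->{amp_src}",
                            "band": phase_band.name.replace("_mi", "") + "_gamma",
                            "metric": "mi", "value": mi_val,
                        }
                    )
    other = pd.DataFrame(
        rows, columns=["seizure_id", "period", "channel", "band", "metric", "value"]
    )
    for si, why in skipped:
        logger.warning("seizure %d skipped: %s", si, why)
    cols = ["seizure_id", "period", "channel", "band", "metric", "value"]
    return pd.concat([pow_df[cols], other[cols]], ignore_index=True)


def run_analysis(
    cfg: ExperimentConfig,
    rec: Recording,
    events: Sequence[SeizureEvent],
    pulses: Sequence[StimPulse] = (),
) -> dict:
    """Metric tables + post/pre ratios for one subject's recording.

    Stimulation artifacts (if a pulse log is supplied) are removed by
    blank-and-interpolate before any metric is computed.
    """
    if pulses:
        rec = remove_artifacts(rec, pulses)
    metrics = seizure_metric_table(rec, events, cfg.segmentation, cfg.welch)
    if metrics.empty:
        raise ValidationError("no analyzable seizures — all windows out of bounds")
    ratios = post_pre_ratio(
        metrics[metrics.metric == "band_power"].drop(columns="metric"), "value"
    )
    return {"metrics": metrics, "post_pre_ratio": ratios}


def group_statistics(metric_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """ANOVA + Tukey across groups for every (metric, period, channel, band).

    ``metric_tables`` maps group label → tidy metric table (as produced
    by :func:`seizure_metric_table`).  Returns a long table with one row
    per Tukey pair plus the omnibus F/p.
    """
    keys = ["metric", "period", "channel", "band"]
    all_keys = pd.concat(
        [t[keys].drop_duplicates() for t in metric_tables.values()]
    ).drop_duplicates()
    out_rows = []
    for _, key in all_keys.iterrows():
        groups = {}
        for gname, table in metric_tables.items():
            sel = (table[keys] == key.values).all(axis=1)
            vals = table.loc[sel, "value"].to_numpy()
            if vals.size >= 2:
                groups[gname] = vals
        if len(groups) < 2:
            continue
        res = compare_groups(groups)
        for _, pair in res["tukey"].iterrows():
            out_rows.append(
                {
                    **dict(zip(keys, key.values)),
                    "F": res["anova"]["F"],
                    "df_between": res["anova"]["df_between"],
                    "df_within": res["anova"]["df_within"],
                    "p_anova": res["anova"]["p"],
                    "group_a": pair.group_a,
                    "group_b": pair.group_b,
                    "mean_diff": pair.mean_diff,
                    "p_tukey": pair.p_adj,
                }
            )
    return pd.DataFrame(out_rows)


def write_manifest(cfg: ExperimentConfig, path: str | Path, outputs: Sequence[str] = ()) -> None:
    """JSON manifest from which every output can be regenerated."""
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _cfg_to_dict(cfg),
        "outputs": list(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def read_manifest(path: str | Path) -> ExperimentConfig:
    d = json.loads(Path(path).read_text())["config"]
    return _cfg_from_dict(d)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _cfg_to_dict(cfg: ExperimentConfig) -> dict:
    return dataclasses.asdict(cfg)


def _cfg_from_dict(d: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a (possibly partial) plain dict."""
    d = dict(d)
    builders = {
        "synth": SynthSpec.from_dict,
        "detector": lambda v: DetectorConfig(**v),
        "protocol": lambda v: StimProtocol(**v),
        "intervention": lambda v: InterventionModel(**v),
        "segmentation": lambda v: SegmentationConfig(**v),
        "welch": lambda v: WelchConfig(**v),
        "mi": lambda v: MIConfig(**v),
    }
    for key, build in builders.items():
        if key in d and isinstance(d[key], dict):
            d[key] = build(d[key])
    return ExperimentConfig(**d)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict[str, Path]:
    """Full deterministic run: generate, closed loop, analyze, write CSVs.

    Returns the mapping of logical output name → written path.  Rerunning
    with the same config writes byte-identical files.
    """
    from .io import write_events, write_recording, write_stim_log

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
    rec, events = assemble_recording(synth)
    loop = run_closed_loop(rec, events, cfg)
    analysis = run_analysis(cfg, loop.recording, loop.events, loop.pulses)

    paths = {
        "recording": out / "recording.edf",
        "events": out / "events.csv",
        "stim_log": out / "stim_log.csv",
        "detections": out / "detections.csv",
        "metrics": out / "metrics.csv",
        "post_pre_ratio": out / "post_pre_ratio.csv",
        "manifest": out / "manifest.json",
    }
    write_recording(loop.recording, paths["recording"])
    write_events(loop.events, paths["events"])
    write_stim_log(loop.pulses, paths["stim_log"])
    pd.DataFrame(
        [(d.t_detect_s, d.baseline_power) for d in loop.detections],
        columns=["t_detect_s", "baseline_power"],
    ).to_csv(paths["detections"], index=False)
    analysis["metrics"].to_csv(paths["metrics"], index=False)
    analysis["post_pre_ratio"].to_csv(paths["post_pre_ratio"], index=False)
    write_manifest(cfg, paths["manifest"], [p.name for p in paths.values()])
    return paths
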