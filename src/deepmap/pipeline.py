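"""End-to-end orchestration: stimuli -> capture -> EPs -> DeEP -> map.

Stages run in the order of the clinical workflow. Every early-termination
path — no extra-stimulus, indeterminate capture, insufficient or unstable
S1 EPs, absent S2 EP — is a typed outcome recorded in the structured run
log (one JSON-serializable entry per decision), never an exception, and
produces no DeEP for its scope. Identical inputs, config and seed give
byte-identical results files; timestamps live only in the log header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .capture import CaptureResult, confirm_capture, extract_beat_segments
from .config import PipelineConfig
from .core import (DeEPPoint, EvokedPotential, Outcome, PaceTrain, Recording,
                   StabilityResult)
from .deep import apply_display_threshold, compute_deep
from .ep import assess_stability, detect_s1_eps, detect_s2_ep
from .stimulus import classify_train, detect_pacing_artifacts

__all__ = ["PipelineResult", "run_pipeline", "write_results", "read_results"]


@dataclass
class PipelineResult:
    points: list[DeEPPoint]
    train: Optional[PaceTrain]
    capture: Optional[CaptureResult]
    log: list[dict] = field(default_factory=list)
    disposition: Outcome = Outcome.OK

    def channel_outcome(self, channel: str) -> Optional[str]:
        for entry in self.log:
            if entry.get("scope") == channel and "outcome" in entry:
                return entry["outcome"]
        return None


def run_pipeline(recording: Recording,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full DeEP detection workflow on one recording.

    Returns every per-electrode DeEP point (with displayed flags applied)
    and a structured log carrying exactly one terminal disposition for
    the train plus one outcome per bipolar channel.
    """
    if config is None:
        config = PipelineConfig()
    log: list[dict] = []

    def note(stage: str, scope: str, outcome: Outcome | None = None,
             **extra) -> None:
        entry: dict = {"stage": stage, "scope": scope}
        if outcome is not None:
            entry["outcome"] = outcome.value
        entry.update(extra)
        log.append(entry)

    events = detect_pacing_artifacts(recording, config.stimulus)
    note("stimulus-detection", "train", n_events=len(events),
         times_ms=[round(e.time, 3) for e in events])
    if len(events) < 3:
        note("terminal", "train", Outcome.NO_S2,
             detail="fewer than 3 pacing artifacts detected")
        return PipelineResult(points=[], train=None, capture=None, log=log,
                              disposition=Outcome.NO_S2)

    train = classify_train(events, config.stimulus)
    if not train.has_s2:
        note("terminal", "train", Outcome.NO_S2,
             detail="no qualifying extra-stimulus interval; "
                    "no DeEP calculation performed")
        return PipelineResult(points=[], train=train, capture=None, log=log,
                              disposition=Outcome.NO_S2)
    note("train-classification", "train",
         s1_interval_ms=round(train.s1_interval, 3),
         n_s1=len(train.s1_times),
         s2_coupling_ms=round(train.s2_coupling_interval, 3))

    beats = extract_beat_segments(recording, train, config.capture)
    cap = confirm_capture(beats, config.capture)
    note("capture-confirmation", "train",
         scores=[round(s, 4) for s in cap.scores],
         captured=cap.captured)
    if not cap.usable:
        note("terminal", "train", Outcome.CAPTURE_INDETERMINATE,
             detail="last-3 S1 window or S2 not captured; "
                    "DeEP computation skipped")
        return PipelineResult(points=[], train=train, capture=cap, log=log,
                              disposition=Outcome.CAPTURE_INDETERMINATE)

    captured_s1 = cap.captured[:len(train.s1_times)]
    points: list[DeEPPoint] = []
    for channel in recording.bipolar_channels:
        s1_eps = detect_s1_eps(recording, train, channel,
                               captured_s1=captured_s1, config=config.ep)
        if isinstance(s1_eps, Outcome):
            note("s1-ep-detection", channel, s1_eps)
            continue
        stability = assess_stability(s1_eps, config.ep)
        if isinstance(stability, Outcome):
            note("stability", channel, stability)
            continue
        if not stability.stable:
            note("stability", channel, Outcome.UNSTABLE_S1,
                 latency_sd_ms=round(stability.latency_sd, 3),
                 morphology_correlation=round(
                     stability.mean_pairwise_morphology_correlation, 4))
            continue
        s2_ep = detect_s2_ep(recording, train, channel, s1_eps[-1], config.ep)
        if isinstance(s2_ep, Outcome):
            note("s2-ep-detection", channel, s2_ep)
            continue
        value = compute_deep(s1_eps[-1], s2_ep)
        note("deep", channel, Outcome.OK,
             s1_latency_ms=round(s1_eps[-1].latency, 3),
             s2_latency_ms=round(s2_ep.latency, 3),
             deep_ms=round(value, 3))
        pos = recording.electrode_positions.get(channel,
                                                np.full(3, np.nan))
        points.append(DeEPPoint(channel=channel,
                                position=np.asarray(pos, dtype=float),
                                deep_value=value))

    apply_display_threshold(points, config.deep.display_threshold_ms)
    note("terminal", "train", Outcome.OK,
         n_deep_points=len(points),
         n_displayed=sum(p.displayed for p in points))
    return PipelineResult(points=points, train=train, capture=cap, log=log,
                          disposition=Outcome.OK)


def write_results(result: PipelineResult, path: str | Path) -> Path:
    """DeEP results CSV: channel, x, y, z, deep_ms, displayed, flags."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("channel,x,y,z,deep_ms,displayed,flags\n")
        for p in result.points:
            x, y, z = (format(float(c), ".9g") for c in p.position)
            fh.write(f"{p.channel},{x},{y},{z},{p.deep_value:.9g},"
                     f"{int(p.displayed)},{';'.join(p.flags)}\n")
    return path


def read_results(path: str | Path) -> list[DeEPPoint]:
    import csv

    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points.append(DeEPPoint(
                channel=row["channel"],
                position=np.array([float(row["x"]), float(row["y"]),
                                   float(row["z"])]),
                deep_value=float(row["deep_ms"]),
                displayed=bool(int(row["displayed"])),
                flags=tuple(f for f in row["flags"].split(";") if f),
            ))
    return points


def write_log(log: list[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
    return path
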