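"""Capture confirmation from the surface ECG.

A stimulus that captures the myocardium produces a paced QRS of constant
morphology on the surface leads. Capture is therefore confirmed by
correlating each beat's post-stimulus surface segment against a template
built from the drive-train beats: the per-lead sample-wise **median** of
the S1 segments (robust to one non-captured beat contaminating the
template). Scores are zero-lag Pearson correlations — segments are
already stimulus-aligned — averaged over leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CaptureConfig, PipelineConfig
from .core import Outcome, PaceTrain, Recording

__all__ = ["BeatSegments", "CaptureResult", "extract_beat_segments",
           "confirm_capture", "pearson_at_zero_lag"]


@dataclass
class BeatSegments:
    """Post-stimulus surface-lead windows, one row set per beat.

    ``segments[beat][lead]`` is the sampled window, or None when the
    window would extend past the recording end (segment unavailable).
    ``labels`` carries "S1"/"S2" per beat so the template uses S1 only.
    """

    stimulus_times: list[float]
    labels: list[str]
    leads: list[str]
    segments: list[dict[str, np.ndarray | None]]


@dataclass
class CaptureResult:
    captured: list[bool]
    scores: list[float]
    outcome: Outcome  # OK or CAPTURE_INDETERMINATE
    usable: bool      # last 3 S1 beats and the S2 beat all captured


def extract_beat_segments(recording: Recording, train: PaceTrain,
                          config: CaptureConfig | None = None) -> BeatSegments:
    """Cut the configured post-stimulus window from each surface lead."""
    if config is None:
        config = PipelineConfig().capture
    if len(train.s1_times) < 2:
        raise ValueError("need at least 2 S1 stimuli to assess capture")
    leads = config.leads or list(recording.surface_channels)
    w0, w1 = config.window_ms
    n = recording.n_samples

    stim_times = list(train.s1_times)
    labels = ["S1"] * len(stim_times)
    if train.has_s2:
        stim_times.append(train.s2_time)
        labels.append("S2")

    segments: list[dict[str, np.ndarray | None]] = []
    for t in stim_times:
        i0 = recording.ms_to_index(t + w0)
        i1 = recording.ms_to_index(t + w1)
        row: dict[str, np.ndarray | None] = {}
        for lead in leads:
            if i0 < 0 or i1 > n:
                row[lead] = None  # clipped at recording end: unavailable
            else:
                row[lead] = recording.surface_channels[lead][i0:i1]
        segments.append(row)
    return BeatSegments(stimulus_times=stim_times, labels=labels,
                        leads=leads, segments=segments)


def pearson_at_zero_lag(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized zero-lag correlation; 0.0 when either input is constant
    (a flat segment carries no morphology to agree with)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((da * db).sum() / denom, -1.0, 1.0))


def confirm_capture(beats: BeatSegments,
                    config: CaptureConfig | None = None) -> CaptureResult:
    """Score each beat against the median S1 template and decide capture.

    A train is usable for DeEP computation only when the last 3 S1 beats
    and the S2 beat are all captured; otherwise the typed outcome is
    capture-indeterminate and DeEP computation must be skipped.
    """
    if config is None:
        config = PipelineConfig().capture

    s1_rows = [row for row, lab in zip(beats.segments, beats.labels)
               if lab == "S1"]
    templates: dict[str, np.ndarray] = {}
    for lead in beats.leads:
        stack = [row[lead] for row in s1_rows if row[lead] is not None]
        if len(stack) >= 2:
            templates[lead] = np.median(np.stack(stack), axis=0)
    if not templates:
        return CaptureResult(captured=[], scores=[],
                             outcome=Outcome.CAPTURE_INDETERMINATE,
                             usable=False)

    scores: list[float] = []
    captured: list[bool] = []
    for row in beats.segments:
        vals = [pearson_at_zero_lag(row[lead], tmpl)
                for lead, tmpl in templates.items() if row[lead] is not None]
        score = float(np.mean(vals)) if vals else float("nan")
        scores.append(score)
        captured.append(bool(score >= config.threshold))

    s1_idx = [i for i, lab in enumerate(beats.labels) if lab == "S1"]
    must_capture = s1_idx[-3:]
    if "S2" in beats.labels:
        must_capture = must_capture + [beats.labels.index("S2")]
    usable = all(captured[i] for i in must_capture)
    n_usable_s1 = sum(captured[i] for i in s1_idx)
    if n_usable_s1 < 2 or not usable:
        outcome = Outcome.CAPTURE_INDETERMINATE
        usable = False
    else:
        outcome = Outcome.OK
    return CaptureResult(captured=captured, scores=scores,
                         outcome=outcome, usable=usable)
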