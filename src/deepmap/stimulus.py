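"""Pacing-artifact detection and S1/S2 train classification.

The pacing artifact is a large broadband spike delivered through the
stimulator and visible simultaneously on (nearly) every channel. Detection
therefore requires supra-threshold peaks coincident across a configurable
fraction of channels; a refractory period suppresses double-detections of
one biphasic artifact.

Classification identifies the modal inter-stimulus interval as the S1
drive cycle length. The premature extra-stimulus announces itself by a
coupling interval at least 10% shorter than the drive interval; the first
such event is labelled S2 and ends the train. A train without a
qualifying interval carries no S2 — the pipeline then performs no DeEP
calculation for it.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig, StimulusConfig
from .core import PaceTrain, Recording, StimulusEvent, StimulusLabel

__all__ = ["detect_pacing_artifacts", "classify_train"]


def detect_pacing_artifacts(recording: Recording,
                            config: StimulusConfig | None = None,
                            ) -> list[StimulusEvent]:
    """Find impulse-like peaks present on most channels simultaneously.

    Returns events sorted by time and labelled ``unknown``; classification
    into S1/S2 is :func:`classify_train`'s job. An empty list is a valid
    result (no pacing in the recording).
    """
    if config is None:
        config = PipelineConfig().stimulus
    fs = recording.sampling_rate
    distance = max(1, int(round(config.refractory_ms * fs / 1000.0)))

    all_channels = {**recording.surface_channels, **recording.bipolar_channels}
    n_channels = len(all_channels)
    if n_channels == 0:
        return []

    per_channel_times: list[np.ndarray] = []
    for sig in all_channels.values():
        peaks, _ = find_peaks(np.abs(sig), height=config.threshold_mv,
                              distance=distance)
        per_channel_times.append(peaks * 1000.0 / fs)

    # cluster candidate times across channels within the coincidence window
    all_times = np.sort(np.concatenate(per_channel_times))
    if all_times.size == 0:
        return []
    clusters: list[list[float]] = [[all_times[0]]]
    for t in all_times[1:]:
        if t - clusters[-1][0] <= config.coincidence_window_ms:
            clusters[-1].append(t)
        else:
            clusters.append([t])

    min_support = config.coincidence_fraction * n_channels
    events: list[StimulusEvent] = []
    last_time = -np.inf
    for cluster in clusters:
        if len(cluster) < min_support:
            continue
        t = float(np.median(cluster))
        if t - last_time < config.refractory_ms:
            continue
        events.append(StimulusEvent(time=t, label=StimulusLabel.UNKNOWN))
        last_time = t
    return events


def _modal_interval(diffs: np.ndarray) -> float:
    """Robust drive-cycle estimate: median of diffs after discarding
    intervals shorter than 50% of the running median (drops the single
    short S2 coupling interval without biasing the S1 estimate)."""
    kept: list[float] = []
    for d in diffs:
        ref = float(np.median(kept)) if kept else float(np.median(diffs))
        if d >= 0.5 * ref:
            kept.append(float(d))
    return float(np.median(kept)) if kept else float(np.median(diffs))


def classify_train(events: list[StimulusEvent],
                   config: StimulusConfig | None = None) -> PaceTrain:
    """Label the S1 drive train and the extra-stimulus, if one exists.

    Events are sorted internally, so input order never affects the result.
    The returned :class:`PaceTrain` has ``s2_time is None`` when no interval
    qualifies as a premature coupling; callers must treat that as the
    typed no-S2 outcome and skip DeEP computation for the train.
    """
    if config is None:
        config = PipelineConfig().stimulus
    if len(events) < 3:
        raise ValueError("classify_train needs at least 3 stimulus events")
    times = sorted(e.time for e in events)
    diffs = np.diff(times)
    s1_interval = _modal_interval(diffs)

    jitter = config.jitter_fraction * s1_interval
    s2_cutoff = (1.0 - config.s2_shortening_fraction) * s1_interval

    s1_times = [times[0]]
    s2_time = None
    for t, d in zip(times[1:], diffs):
        if d <= s2_cutoff:
            # premature coupling identifies the extra-stimulus; train ends
            s2_time = t
            break
        if abs(d - s1_interval) <= jitter:
            s1_times.append(t)
        else:
            break  # long pause: train over, no S2 in this train
    return PaceTrain(s1_times=s1_times, s1_interval=s1_interval, s2_time=s2_time)
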