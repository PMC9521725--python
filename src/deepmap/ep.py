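"""Near-field evoked-potential detection and S1 stability assessment.

Near-field activity is isolated by band-limiting the bipolar electrogram
(default 30–300 Hz, zero-phase) after blanking the pacing artifact, whose
broadband energy would otherwise ring into the band. The EP fiducial is
the **peak** of the band-limited deflection magnitude inside the search
window — robust to noise-floor estimation, unlike an onset fiducial.

Stability of the drive-train response is assessed on the last 3 captured
S1 beats: the population standard deviation of their latencies and the
mean pairwise correlation of their morphology windows must both clear
their thresholds before the channel's S2 EP is trusted.

The S2 EP is found by template matching: the last stable S1 morphology is
slid over the band-limited post-S2 signal and the lag maximizing the
normalized cross-correlation gives the S2 fiducial, provided the match
clears a threshold — below it the response is considered absent (the
wavefront may have blocked at the premature coupling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .capture import pearson_at_zero_lag
from .config import EpConfig, PipelineConfig
from .core import EvokedPotential, Outcome, PaceTrain, Recording, StabilityResult

__all__ = ["band_limit", "detect_s1_eps", "assess_stability", "detect_s2_ep",
           "EpDetectionError"]


class EpDetectionError(Exception):
    """Raised for contract violations (not for typed pipeline outcomes)."""


def _blank_artifacts(sig: np.ndarray, fs: float, stim_times_ms: list[float],
                     blank_ms: float) -> np.ndarray:
    """Linearly interpolate across +/- blank_ms around each stimulus.

    Interpolation (rather than zeroing) avoids step discontinuities that
    would themselves ring through the band-pass filter.
    """
    out = sig.astype(float).copy()
    half = int(round(blank_ms * fs / 1000.0))
    n = len(out)
    for t in stim_times_ms:
        c = int(round(t * fs / 1000.0))
        i0, i1 = max(0, c - half), min(n - 1, c + half)
        if i1 <= i0:
            continue
        out[i0:i1 + 1] = np.linspace(out[i0], out[i1], i1 - i0 + 1)
    return out


def band_limit(sig: np.ndarray, fs: float, band_hz: tuple[float, float],
               stim_times_ms: list[float] | None = None,
               blank_ms: float = 0.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass, with optional artifact blanking."""
    if stim_times_ms and blank_ms > 0:
        sig = _blank_artifacts(sig, fs, stim_times_ms, blank_ms)
    lo, hi = band_hz
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, sig)


def _noise_floor(filtered: np.ndarray, fs: float, quiet_end_ms: float) -> float:
    """Robust sd (1.4826 * MAD) of the quiescent lead-in segment."""
    i1 = max(1, int(round(quiet_end_ms * fs / 1000.0)))
    seg = filtered[:i1]
    return 1.4826 * float(np.median(np.abs(seg - np.median(seg))))


def _all_stim_times(train: PaceTrain) -> list[float]:
    times = list(train.s1_times)
    if train.has_s2:
        times.append(train.s2_time)
    return times


def _peak_ep(filtered: np.ndarray, recording: Recording, channel: str,
             stim_time: float, w0_ms: float, w1_ms: float,
             floor: float, config: EpConfig) -> EvokedPotential | None:
    i0 = recording.ms_to_index(stim_time + w0_ms)
    i1 = min(recording.ms_to_index(stim_time + w1_ms), len(filtered))
    if i1 <= i0:
        return None
    window = np.abs(filtered[i0:i1])
    pk = int(np.argmax(window)) + i0
    amp = float(np.abs(filtered[pk]))
    if amp <= max(config.noise_floor_multiple * floor, config.min_amplitude_mv):
        return None
    half = int(round(config.morphology_half_width_ms
                     * recording.sampling_rate / 1000.0))
    m0, m1 = pk - half, pk + half + 1
    if m0 < 0 or m1 > len(filtered):
        return None  # morphology window must lie fully inside the recording
    return EvokedPotential(
        channel=channel,
        stimulus_time=stim_time,
        latency=recording.index_to_ms(pk) - stim_time,
        amplitude=amp,
        morphology=filtered[m0:m1].copy(),
    )


def detect_s1_eps(recording: Recording, train: PaceTrain, channel: str,
                  captured_s1: list[bool] | None = None,
                  config: EpConfig | None = None,
                  ) -> list[EvokedPotential] | Outcome:
    """EPs of the last 3 captured S1 beats on one bipole.

    Returns the typed ``insufficient-S1`` outcome when fewer than 3
    captured beats yield a supra-noise-floor deflection.
    """
    if config is None:
        config = PipelineConfig().ep
    sig = recording.bipolar_channels[channel]
    fs = recording.sampling_rate
    filtered = band_limit(sig, fs, config.band_hz,
                          stim_times_ms=_all_stim_times(train),
                          blank_ms=config.blank_ms)
    quiet_end = max(train.s1_times[0] - 2 * config.blank_ms, 10.0)
    floor = _noise_floor(filtered, fs, quiet_end)

    if captured_s1 is None:
        captured_s1 = [True] * len(train.s1_times)
    candidates = [t for t, cap in zip(train.s1_times, captured_s1) if cap]
    if len(candidates) < 3:
        return Outcome.INSUFFICIENT_S1

    w1 = config.search_end_fraction * train.s1_interval
    all_times = sorted(_all_stim_times(train))
    eps: list[EvokedPotential] = []
    for t in candidates[-3:]:
        # gate the window at the next stimulus: the response to this beat
        # must not be confused with the next beat's artifact or EP
        later = [s for s in all_times if s > t]
        w1_t = min(w1, later[0] - t - config.blank_ms) if later else w1
        ep = _peak_ep(filtered, recording, channel, t,
                      config.search_start_ms, w1_t, floor, config)
        if ep is not None:
            eps.append(ep)
    if len(eps) < 3:
        return Outcome.INSUFFICIENT_S1
    return eps


def assess_stability(eps: list[EvokedPotential],
                     config: EpConfig | None = None,
                     ) -> StabilityResult | Outcome:
    """Latency spread and morphology agreement of the last-3 S1 EPs.

    latency_sd is the population standard deviation of the 3 latencies;
    the correlation is the mean of the 3 pairwise zero-lag correlations of
    the morphology windows. The result is permutation-invariant.
    """
    if config is None:
        config = PipelineConfig().ep
    if len(eps) != 3:
        return Outcome.INSUFFICIENT_S1
    lat_sd = float(np.std([ep.latency for ep in eps]))  # population sd
    corrs = [
        pearson_at_zero_lag(eps[i].morphology, eps[j].morphology)
        for i in range(3) for j in range(i + 1, 3)
    ]
    mean_corr = float(np.mean(corrs))
    stable = (lat_sd <= config.stability_latency_sd_ms
              and mean_corr >= config.stability_correlation)
    return StabilityResult(latency_sd=lat_sd,
                           mean_pairwise_morphology_correlation=mean_corr,
                           stable=stable)


def detect_s2_ep(recording: Recording, train: PaceTrain, channel: str,
                 s1_template: EvokedPotential,
                 config: EpConfig | None = None,
                 ) -> EvokedPotential | Outcome:
    """Template-match the last S1 morphology over the post-S2 window.

    Returns the EP at the lag maximizing the normalized cross-correlation
    when the maximum clears the match threshold; the typed ``s2-ep-absent``
    outcome otherwise (decremental tissue may block at the premature
    coupling, leaving no response); ``no-S2`` when the train has no
    extra-stimulus.
    """
    if config is None:
        config = PipelineConfig().ep
    if not train.has_s2:
        return Outcome.NO_S2
    if s1_template.channel != channel:
        raise EpDetectionError(
            f"template from channel {s1_template.channel!r}, "
            f"searching {channel!r}")
    sig = recording.bipolar_channels[channel]
    fs = recording.sampling_rate
    filtered = band_limit(sig, fs, config.band_hz,
                          stim_times_ms=_all_stim_times(train),
                          blank_ms=config.blank_ms)

    i0 = recording.ms_to_index(train.s2_time + config.search_start_ms)
    i1 = len(filtered)
    tmpl = s1_template.morphology
    half = len(tmpl) // 2
    seg = filtered[max(0, i0 - half):i1]
    if len(seg) < len(tmpl):
        return Outcome.S2_EP_ABSENT

    # normalized cross-correlation of the template at every lag
    n = len(tmpl)
    tz = tmpl - tmpl.mean()
    t_norm = float(np.sqrt((tz ** 2).sum()))
    if t_norm == 0.0:
        return Outcome.S2_EP_ABSENT
    win = np.lib.stride_tricks.sliding_window_view(seg, n)
    wz = win - win.mean(axis=1, keepdims=True)
    w_norm = np.sqrt((wz ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = (wz @ tz) / (w_norm * t_norm)
    ncc = np.nan_to_num(ncc, nan=-1.0)
    best = int(np.argmax(ncc))
    if ncc[best] < config.s2_match_threshold:
        return Outcome.S2_EP_ABSENT

    pk = max(0, i0 - half) + best + half  # fiducial = template center
    latency = recording.index_to_ms(pk) - train.s2_time
    m0, m1 = pk - half, pk + half + 1
    morph = filtered[m0:m1].copy() if (m0 >= 0 and m1 <= len(filtered)) else tmpl
    return EvokedPotential(
        channel=channel,
        stimulus_time=train.s2_time,
        latency=latency,
        amplitude=float(np.abs(filtered[pk])),
        morphology=morph,
    )
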