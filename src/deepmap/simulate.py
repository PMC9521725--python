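"""Synthetic paced recordings with planted ground truth.

Emulates the structure of a decrement-protocol recording: an S1 drive
train (default 8 beats at 600 ms cycle length) followed by one premature
extra-stimulus (S2) near the effective refractory period. Each captured
beat carries a pacing artifact on every channel, a paced QRS on the
surface leads, and a near-field evoked potential (EP) on each bipole at a
planted latency; the S2 EP is delayed by a planted per-channel decrement.
Non-captured beats keep the pacing artifact but lose QRS and EP, matching
the clinical meaning of failure to capture.

The planted values are returned as :class:`GroundTruth` and serve as the
oracle for every downstream parameter-recovery test. All randomness
derives from one seed; identical seeds give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .core import Recording

__all__ = [
    "ChannelSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_recording",
    "place_electrodes",
    "generate_mesh",
]


@dataclass
class ChannelSpec:
    """Planted behaviour of one bipolar channel."""

    name: str
    base_ep_latency: float = 40.0   # ms after each captured stimulus
    planted_decrement: float = 0.0  # ms added to the S2 EP latency; 0 = no DeEP
    s2_blocked: bool = False        # omit the S2 EP entirely (conduction block)
    ep_amplitude_mv: float = 0.5


def _default_channels() -> list[ChannelSpec]:
    return [ChannelSpec(name=f"B{i + 1}") for i in range(5)]


@dataclass
class SimulationConfig:
    s1_interval: float = 600.0       # ms drive cycle length
    n_s1: int = 8
    s2_coupling: float = 300.0       # ms from last S1 to S2
    include_s2: bool = True
    channels: list[ChannelSpec] = field(default_factory=_default_channels)
    n_surface_leads: int = 12
    sampling_rate: float = 2000.0    # Hz
    pacing_artifact_amplitude: float = 10.0  # mV
    qrs_amplitude: float = 1.0       # mV
    far_field_amplitude: float = 0.2  # mV, ventricular far field on bipoles
    noise_sd: float = 0.02           # mV additive white noise
    capture_failure_beats: list[int] = field(default_factory=list)
    lead_in_ms: float = 200.0        # quiet segment before the first stimulus
    tail_ms: float = 300.0           # recording continues past the last stimulus
    rng_seed: int = 0

    # wavelet geometry (fixed shapes; amplitudes above scale them)
    ep_half_width_ms: float = 7.5    # near-field EP support is ~15 ms

    def validate(self) -> None:
        if not self.s2_coupling < self.s1_interval:
            raise ValueError("s2_coupling must be shorter than s1_interval")
        if self.n_s1 < 4:
            raise ValueError("n_s1 must be at least 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for ch in self.channels:
            s1_end = ch.base_ep_latency + self.ep_half_width_ms
            if s1_end >= self.s1_interval:
                raise ValueError(
                    f"channel {ch.name!r}: S1 EP window (ends {s1_end:.1f} ms "
                    f"post-stimulus) overlaps the next stimulus at "
                    f"{self.s1_interval:.1f} ms"
                )
            if self.include_s2 and s1_end >= self.s2_coupling:
                raise ValueError(
                    f"channel {ch.name!r}: last S1 EP window (ends "
                    f"{s1_end:.1f} ms) overlaps the extra-stimulus at "
                    f"{self.s2_coupling:.1f} ms"
                )
            s2_end = ch.base_ep_latency + ch.planted_decrement + self.ep_half_width_ms
            if self.include_s2 and s2_end >= self.tail_ms:
                raise ValueError(
                    f"channel {ch.name!r}: S2 EP window (ends {s2_end:.1f} ms "
                    f"post-S2) runs past the recording tail ({self.tail_ms:.1f} ms)"
                )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way the pipeline reports."""

    stimulus_times: list[tuple[float, str]]          # (ms, "S1"|"S2")
    ep_latencies: dict[str, dict[int, float]]        # channel -> beat idx -> ms
    true_deep: dict[str, Optional[float]]            # None = blocked / no S2
    capture: list[bool]                              # per beat, S2 last

    @property
    def s1_times(self) -> list[float]:
        return [t for t, lab in self.stimulus_times if lab == "S1"]

    @property
    def s2_time(self) -> Optional[float]:
        for t, lab in self.stimulus_times:
            if lab == "S2":
                return t
        return None


# ---------------------------------------------------------------------------
# waveform templates (time axes in ms, amplitudes normalized to 1)

def _pacing_artifact(t: np.ndarray) -> np.ndarray:
    """~2 ms biphasic spike with its unique |peak| at t = 0."""
    main = np.exp(-(t ** 2) / (2 * 0.3 ** 2))
    rebound = -0.4 * np.exp(-((t - 0.8) ** 2) / (2 * 0.4 ** 2))
    return main + rebound


def _qrs(t: np.ndarray) -> np.ndarray:
    """Smooth ~100 ms paced QRS starting at t = 0 (small Q, R, S waves)."""
    q = -0.2 * np.exp(-((t - 15.0) ** 2) / (2 * 6.0 ** 2))
    r = np.exp(-((t - 45.0) ** 2) / (2 * 12.0 ** 2))
    s = -0.35 * np.exp(-((t - 80.0) ** 2) / (2 * 9.0 ** 2))
    out = q + r + s
    out[(t < 0) | (t > 100.0)] = 0.0
    return out


def _ep_wavelet(t: np.ndarray) -> np.ndarray:
    """High-frequency ~15 ms near-field wavelet, even-symmetric.

    A cosine-carrier Gabor at 150 Hz: its magnitude has a unique maximum at
    t = 0, and zero-phase band-limiting preserves the peak location, so the
    planted latency is exactly the peak fiducial the detector reports.
    """
    return np.exp(-(t ** 2) / (2 * 3.0 ** 2)) * np.cos(2 * np.pi * 150.0 * t / 1000.0)


def _far_field(t: np.ndarray) -> np.ndarray:
    """Low-frequency ventricular far field as seen by a bipole."""
    return np.exp(-((t - 70.0) ** 2) / (2 * 20.0 ** 2))


def _add(signal: np.ndarray, fs: float, at_ms: float, shape, amplitude: float,
         support_ms: tuple[float, float]) -> None:
    """Add ``amplitude * shape(t - at_ms)`` to ``signal`` in place."""
    i0 = max(0, int(np.floor((at_ms + support_ms[0]) * fs / 1000.0)))
    i1 = min(len(signal), int(np.ceil((at_ms + support_ms[1]) * fs / 1000.0)) + 1)
    if i0 >= i1:
        return
    t = np.arange(i0, i1) * 1000.0 / fs - at_ms
    signal[i0:i1] += amplitude * shape(t)


# ---------------------------------------------------------------------------

def generate_recording(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize a paced recording and the ground truth planted into it."""
    config.validate()
    fs = config.sampling_rate

    s1_times = [config.lead_in_ms + k * config.s1_interval
                for k in range(config.n_s1)]
    stim: list[tuple[float, str]] = [(t, "S1") for t in s1_times]
    if config.include_s2:
        s2_time = s1_times[-1] + config.s2_coupling
        stim.append((s2_time, "S2"))
        end_ms = s2_time + config.tail_ms
    else:
        s2_time = None
        end_ms = s1_times[-1] + config.tail_ms
    n_samples = int(round(end_ms * fs / 1000.0))

    n_beats = len(stim)
    captured = [i not in config.capture_failure_beats for i in range(n_beats)]

    lead_names = [f"L{i + 1}" for i in range(config.n_surface_leads)]
    bip_names = [ch.name for ch in config.channels]
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            lead_names + bip_names,
            np.random.SeedSequence(config.rng_seed).spawn(
                len(lead_names) + len(bip_names)),
        )
    }

    surface: dict[str, np.ndarray] = {}
    for name in lead_names:
        sig = np.zeros(n_samples)
        for (t, _), cap in zip(stim, captured):
            _add(sig, fs, t, _pacing_artifact,
                 config.pacing_artifact_amplitude, (-2.0, 3.0))
            if cap:
                _add(sig, fs, t + 20.0, _qrs, config.qrs_amplitude, (0.0, 100.0))
        if config.noise_sd > 0:
            sig += streams[name].normal(0.0, config.noise_sd, n_samples)
        surface[name] = sig

    ep_latencies: dict[str, dict[int, float]] = {}
    true_deep: dict[str, Optional[float]] = {}
    bipolar: dict[str, np.ndarray] = {}
    for ch in config.channels:
        sig = np.zeros(n_samples)
        lats: dict[int, float] = {}
        for beat, ((t, label), cap) in enumerate(zip(stim, captured)):
            _add(sig, fs, t, _pacing_artifact,
                 config.pacing_artifact_amplitude, (-2.0, 3.0))
            if not cap:
                continue
            _add(sig, fs, t, _far_field, config.far_field_amplitude, (10.0, 130.0))
            if label == "S2":
                if ch.s2_blocked:
                    continue
                lat = ch.base_ep_latency + ch.planted_decrement
            else:
                lat = ch.base_ep_latency
            _add(sig, fs, t + lat, _ep_wavelet, ch.ep_amplitude_mv,
                 (-config.ep_half_width_ms, config.ep_half_width_ms))
            lats[beat] = lat
        if config.noise_sd > 0:
            sig += streams[ch.name].normal(0.0, config.noise_sd, n_samples)
        bipolar[ch.name] = sig
        ep_latencies[ch.name] = lats
        if s2_time is None or ch.s2_blocked:
            true_deep[ch.name] = None
        else:
            true_deep[ch.name] = ch.planted_decrement

    positions = place_electrodes(bip_names, seed=config.rng_seed)
    recording = Recording(
        sampling_rate=fs,
        surface_channels=surface,
        bipolar_channels=bipolar,
        electrode_positions=positions,
    )
    truth = GroundTruth(
        stimulus_times=stim,
        ep_latencies=ep_latencies,
        true_deep=true_deep,
        capture=captured,
    )
    return recording, truth


def place_electrodes(channel_names: list[str],
                     radii: tuple[float, float, float] = (30.0, 30.0, 30.0),
                     depth_mm: float = 1.0,
                     seed: int = 0) -> dict[str, np.ndarray]:
    """Spread electrodes over an ellipsoidal endocardium, slightly inside.

    Points follow a Fibonacci spiral on the unit sphere, scaled to sit
    ``depth_mm`` under the ellipsoid surface along the radial direction.
    """
    n = len(channel_names)
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + 5 ** 0.5) * idx
    unit = np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])
    rad = np.asarray(radii, dtype=float)
    pts = unit * (rad - depth_mm)
    return {name: pts[i] for i, name in enumerate(channel_names)}


def generate_mesh(electrode_positions: dict[str, np.ndarray],
                  radii: tuple[float, float, float] = (30.0, 30.0, 30.0),
                  subdivisions: int = 3,
                  ) -> tuple[trimesh.Trimesh, dict[str, int]]:
    """Closed triangulated ellipsoid plus the per-electrode nearest vertex.

    Returns the chamber surface mesh and a map from bipolar channel name to
    the index of its nearest mesh vertex (Euclidean distance).
    """
    rad = np.asarray(radii, dtype=float)
    if np.any(rad <= 0) or not np.all(np.isfinite(rad)):
        raise ValueError(f"degenerate ellipsoid radii {tuple(rad)}")
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale(rad)
    tree = cKDTree(mesh.vertices)
    nearest = {
        name: int(tree.query(np.asarray(pos, dtype=float))[1])
        for name, pos in electrode_positions.items()
    }
    return mesh, nearest
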