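"""Domain model for decrement-evoked-potential (DeEP) mapping.

Conventions shared by every stage of the pipeline:

* time is expressed in **milliseconds from recording start**, as floats;
* sample indices are 0-based; windows are half-open ``[start, end)``;
* voltages are in mV, geometry in mm (right-handed Cartesian, one frame
  shared by electrodes and the chamber mesh).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Recording",
    "StimulusLabel",
    "StimulusEvent",
    "PaceTrain",
    "EvokedPotential",
    "StabilityResult",
    "DeEPPoint",
    "PointStatus",
    "ConfusionCounts",
    "CorrectionBreakdown",
    "Outcome",
    "PipelineOutcome",
    "validate_recording",
]

MIN_SAMPLING_RATE_HZ = 1000.0


class StimulusLabel(str, Enum):
    S1 = "S1"
    S2 = "S2"
    UNKNOWN = "unknown"


class Outcome(str, Enum):
    """Typed early-termination reasons; these are results, not exceptions."""

    OK = "ok"
    NO_S2 = "no-S2"
    CAPTURE_INDETERMINATE = "capture-indeterminate"
    INSUFFICIENT_S1 = "insufficient-S1"
    UNSTABLE_S1 = "unstable-S1"
    S2_EP_ABSENT = "s2-ep-absent"
    UNDEFINED = "undefined"


class PointStatus(str, Enum):
    AUTO = "auto"
    EXPERT_CONFIRMED = "expert_confirmed"
    EXPERT_CHANGED = "expert_changed"
    EXPERT_DELETED = "expert_deleted"
    EXPERT_ADDED = "expert_added"


@dataclass
class Recording:
    """Multichannel paced recording: surface ECG leads + intracardiac bipoles.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz). Must be >= 1000 for sub-ms latency
        resolution of ms-scale DeEP values.
    surface_channels : dict[str, np.ndarray]
        Ordered mapping of lead name -> samples (mV).
    bipolar_channels : dict[str, np.ndarray]
        Ordered mapping of bipole name -> samples (mV).
    electrode_positions : dict[str, np.ndarray]
        Per-bipole 3D coordinate (mm), shape (3,).
    """

    sampling_rate: float
    surface_channels: dict[str, np.ndarray]
    bipolar_channels: dict[str, np.ndarray]
    electrode_positions: dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        for sig in self.surface_channels.values():
            return len(sig)
        for sig in self.bipolar_channels.values():
            return len(sig)
        return 0

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return list(self.surface_channels) + list(self.bipolar_channels)

    def ms_to_index(self, t_ms: float) -> int:
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def index_to_ms(self, idx: int) -> float:
        return idx * 1000.0 / self.sampling_rate

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate


def validate_recording(recording: Recording) -> list[str]:
    """Check Recording invariants; return one message per violation.

    An empty list means the recording is well formed. This is a diagnostic
    operation and never raises.
    """
    violations: list[str] = []
    if recording.sampling_rate < MIN_SAMPLING_RATE_HZ:
        violations.append(
            f"sampling_rate {recording.sampling_rate} Hz is below the "
            f"{MIN_SAMPLING_RATE_HZ:.0f} Hz floor"
        )
    lengths = {
        name: len(sig)
        for name, sig in {**recording.surface_channels,
                          **recording.bipolar_channels}.items()
    }
    if len(set(lengths.values())) > 1:
        violations.append(f"channel lengths differ: {lengths}")
    for name in recording.bipolar_channels:
        pos = recording.electrode_positions.get(name)
        if pos is None:
            violations.append(f"bipolar channel {name!r} has no 3D position")
        elif np.asarray(pos).shape != (3,):
            violations.append(
                f"bipolar channel {name!r} position has shape "
                f"{np.asarray(pos).shape}, expected (3,)"
            )
    extra = set(recording.electrode_positions) - set(recording.bipolar_channels)
    for name in sorted(extra):
        violations.append(f"position given for unknown channel {name!r}")
    return violations


@dataclass(frozen=True)
class StimulusEvent:
    """A detected pacing artifact. ``label`` is assigned only by the classifier."""

    time: float  # ms from recording start
    label: StimulusLabel = StimulusLabel.UNKNOWN


@dataclass
class PaceTrain:
    """S1 drive train plus the (optional) premature extra-stimulus S2."""

    s1_times: list[float]
    s1_interval: float
    s2_time: Optional[float] = None

    @property
    def s2_coupling_interval(self) -> Optional[float]:
        if self.s2_time is None:
            return None
        return self.s2_time - self.s1_times[-1]

    @property
    def has_s2(self) -> bool:
        return self.s2_time is not None


@dataclass
class EvokedPotential:
    """Near-field response on one bipole following one stimulus.

    ``latency`` is the fiducial time minus the stimulus time (ms); the
    fiducial is the peak of the band-limited near-field deflection.
    ``morphology`` is the sampled window around the fiducial used as a
    template for S2 matching and stability correlation.
    """

    channel: str
    stimulus_time: float
    latency: float
    amplitude: float
    morphology: np.ndarray

    @property
    def time(self) -> float:
        return self.stimulus_time + self.latency


@dataclass
class StabilityResult:
    latency_sd: float
    mean_pairwise_morphology_correlation: float
    stable: bool


@dataclass
class DeEPPoint:
    """Per-electrode decrement value bound to a 3D position."""

    channel: str
    position: np.ndarray
    deep_value: float  # ms; negative values are retained and flagged
    displayed: bool = False
    status: PointStatus = PointStatus.AUTO
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CorrectionBreakdown:
    """Expert-correction taxonomy over algorithm detections.

    unchanged -- algorithm marks the experts kept as-is;
    changed   -- algorithm marks the experts revised;
    deleted   -- algorithm marks the experts removed;
    added     -- expert marks the algorithm had missed.
    """

    unchanged: int
    changed: int
    deleted: int
    added: int

    @property
    def total(self) -> int:
        return self.unchanged + self.changed + self.deleted + self.added

    @property
    def percentages(self) -> dict[str, float]:
        """Percent of total per category, to one decimal."""
        tot = self.total
        if tot == 0:
            return {k: float("nan") for k in
                    ("unchanged", "changed", "deleted", "added")}
        return {
            "unchanged": round(100.0 * self.unchanged / tot, 1),
            "changed": round(100.0 * self.changed / tot, 1),
            "deleted": round(100.0 * self.deleted / tot, 1),
            "added": round(100.0 * self.added / tot, 1),
        }


@dataclass
class PipelineOutcome:
    """Terminal disposition of one train (or one channel within a train)."""

    outcome: Outcome
    scope: str = "train"  # "train" or a channel name
    detail: str = ""
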