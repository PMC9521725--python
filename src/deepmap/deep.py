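"""DeEP value extraction and display thresholding.

The decrement evoked potential (DeEP) of a bipole is the extra delay of
its near-field response to the premature extra-stimulus relative to the
drive train: ``DeEP = S2 EP latency − last S1 EP latency`` (ms). Values
above the display threshold (typically >10 ms, strict) mark decremental —
potentially arrhythmogenic — tissue. Negative values are physically
implausible and indicate an upstream detection fault; they are retained
and flagged rather than clipped so that QC surfaces them.
"""

from __future__ import annotations

from .core import DeEPPoint, EvokedPotential

__all__ = ["compute_deep", "apply_display_threshold"]


def compute_deep(s1_ep: EvokedPotential, s2_ep: EvokedPotential) -> float:
    """Decrement in ms: S2 latency minus the latest stable S1 latency."""
    if s1_ep.channel != s2_ep.channel:
        raise ValueError(
            f"channel mismatch: S1 EP on {s1_ep.channel!r}, "
            f"S2 EP on {s2_ep.channel!r}")
    return s2_ep.latency - s1_ep.latency


def apply_display_threshold(points: list[DeEPPoint],
                            threshold: float = 10.0) -> list[DeEPPoint]:
    """Set each point's displayed flag: displayed <=> deep_value > threshold.

    The comparison is strict — a decrement exactly at the threshold is
    hidden. Modifies the points in place and returns the same list.
    """
    if threshold < 0:
        raise ValueError("display threshold must be non-negative")
    for p in points:
        p.displayed = p.deep_value > threshold
        if p.deep_value < 0 and "negative-deep" not in p.flags:
            p.flags = p.flags + ("negative-deep",)
    return points
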