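"""Scoring algorithm output against expert gold-standard annotations.

The scored unit is one channel-train pair — one potential DeEP site. Two
annotation sets over the same units yield a 2x2 confusion (DeEP marked /
not marked), from which sensitivity, specificity and Cohen's kappa
follow. Expert manual correction of algorithm output is summarized by the
four-category taxonomy: unchanged / changed / deleted / added detections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .core import ConfusionCounts, CorrectionBreakdown, Outcome

__all__ = [
    "Annotation", "AnnotationSet", "MatchedPair", "UNDEFINED",
    "match_annotations", "sensitivity", "specificity",
    "cohen_kappa", "kappa_from_table", "categorize_corrections",
    "histogram_by_deep",
]

Unit = tuple[str, int]  # (channel, train index)

#: typed outcome for statistics whose denominator is empty — deliberately
#: neither 0 nor 100.
UNDEFINED = Outcome.UNDEFINED


@dataclass(frozen=True)
class Annotation:
    """One DeEP mark on one channel-train unit."""

    unit: Unit
    time_ms: Optional[float] = None
    deep_value_ms: Optional[float] = None


@dataclass
class AnnotationSet:
    """Marks plus the universe of units the annotator scored.

    ``units`` lists every unit looked at (so absence of a mark means an
    explicit "no DeEP here"); ``marks`` holds at most one mark per unit.
    """

    units: list[Unit] = field(default_factory=list)
    marks: dict[Unit, Annotation] = field(default_factory=dict)

    def add(self, annotation: Annotation) -> None:
        if annotation.unit in self.marks:
            raise ValueError(f"duplicate mark on unit {annotation.unit}")
        if annotation.unit not in self.units:
            self.units.append(annotation.unit)
        self.marks[annotation.unit] = annotation

    def add_unit(self, unit: Unit) -> None:
        if unit not in self.units:
            self.units.append(unit)

    def has_mark(self, unit: Unit) -> bool:
        return unit in self.marks


@dataclass(frozen=True)
class MatchedPair:
    unit: Unit
    time_diff_ms: Optional[float]
    deep_diff_ms: Optional[float]


def match_annotations(algorithm: AnnotationSet, expert: AnnotationSet,
                      tolerance_ms: float = 10.0,
                      ) -> tuple[ConfusionCounts, list[MatchedPair]]:
    """Confusion counts per channel-train unit, plus matched pairs.

    TP: both mark a DeEP on the unit; TN: neither; FP: only the
    algorithm; FN: only the expert. The pair list carries the latency and
    decrement differences of every TP for downstream category assignment.
    Units present in one universe only are scored from the side that has
    them, with a warning.
    """
    only_a = set(algorithm.units) - set(expert.units)
    only_e = set(expert.units) - set(algorithm.units)
    if only_a or only_e:
        warnings.warn(
            f"unit universes differ: {len(only_a)} only in algorithm set, "
            f"{len(only_e)} only in expert set")
    units = list(dict.fromkeys(list(algorithm.units) + list(expert.units)))

    tp = tn = fp = fn = 0
    pairs: list[MatchedPair] = []
    for u in units:
        a, e = algorithm.has_mark(u), expert.has_mark(u)
        if a and e:
            tp += 1
            ma, me = algorithm.marks[u], expert.marks[u]
            tdiff = (None if ma.time_ms is None or me.time_ms is None
                     else ma.time_ms - me.time_ms)
            ddiff = (None if ma.deep_value_ms is None
                     or me.deep_value_ms is None
                     else ma.deep_value_ms - me.deep_value_ms)
            pairs.append(MatchedPair(unit=u, time_diff_ms=tdiff,
                                     deep_diff_ms=ddiff))
        elif a:
            fp += 1
        elif e:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn), pairs


def sensitivity(counts: ConfusionCounts) -> Union[float, Outcome]:
    """100 * TP / (TP + FN), to one decimal; UNDEFINED when TP + FN = 0."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return UNDEFINED
    return round(100.0 * counts.tp / denom, 1)


def specificity(counts: ConfusionCounts) -> Union[float, Outcome]:
    """100 * TN / (TN + FP), to one decimal; UNDEFINED when TN + FP = 0."""
    denom = counts.tn + counts.fp
    if denom == 0:
        return UNDEFINED
    return round(100.0 * counts.tn / denom, 1)


def kappa_from_table(a: int, b: int, c: int, d: int) -> Union[float, Outcome]:
    """Cohen's kappa of a 2x2 cross-tabulation.

    ``a`` both positive, ``b`` rater-1-only positive, ``c`` rater-2-only
    positive, ``d`` both negative. kappa = (p_o - p_e) / (1 - p_e) with
    chance agreement p_e from the marginals; UNDEFINED when p_e = 1.
    """
    n = a + b + c + d
    if n == 0:
        return UNDEFINED
    p_o = (a + d) / n
    p1_pos, p2_pos = (a + b) / n, (a + c) / n
    p_e = p1_pos * p2_pos + (1 - p1_pos) * (1 - p2_pos)
    if p_e == 1.0:
        return UNDEFINED
    return (p_o - p_e) / (1.0 - p_e)


def cohen_kappa(rater_a: AnnotationSet, rater_b: AnnotationSet,
                ) -> Union[float, Outcome]:
    """Inter-rater agreement on binary DeEP/no-DeEP labels, same units."""
    if set(rater_a.units) != set(rater_b.units):
        raise ValueError("raters must annotate the same units")
    a = b = c = d = 0
    for u in rater_a.units:
        pa, pb = rater_a.has_mark(u), rater_b.has_mark(u)
        if pa and pb:
            a += 1
        elif pa:
            b += 1
        elif pb:
            c += 1
        else:
            d += 1
    return kappa_from_table(a, b, c, d)


def categorize_corrections(algorithm: AnnotationSet, corrected: AnnotationSet,
                           change_tolerance_ms: float = 5.0,
                           ) -> CorrectionBreakdown:
    """Four-category breakdown of expert edits to algorithm detections.

    Per algorithm mark: unchanged when the corrected set keeps a mark on
    the unit with |delta decrement| <= tolerance; changed when the kept
    mark differs by more; deleted when no corrected mark remains. Marks
    the experts added with no algorithm counterpart count as added.
    Percentages are taken over the union total of all four categories.
    """
    unchanged = changed = deleted = 0
    for u, mark in algorithm.marks.items():
        if not corrected.has_mark(u):
            deleted += 1
            continue
        corr = corrected.marks[u]
        if (mark.deep_value_ms is None or corr.deep_value_ms is None
                or abs(mark.deep_value_ms - corr.deep_value_ms)
                <= change_tolerance_ms):
            unchanged += 1
        else:
            changed += 1
    added = sum(1 for u in corrected.marks if not algorithm.has_mark(u))
    return CorrectionBreakdown(unchanged=unchanged, changed=changed,
                               deleted=deleted, added=added)


def histogram_by_deep(values: Iterable[float],
                      bin_edges: Iterable[float]) -> np.ndarray:
    """Counts of decrement values per half-open bin [e_i, e_{i+1}).

    Unlike a textbook histogram, the last bin is half-open too: a value
    equal to the final edge falls outside the range and is not counted.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = np.asarray(list(values), dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    if vals.size:
        idx = np.searchsorted(edges, vals, side="right") - 1
        ok = (idx >= 0) & (idx < len(counts)) & (vals < edges[-1])
        np.add.at(counts, idx[ok], 1)
    return counts
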