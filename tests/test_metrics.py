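import numpy as np
import pytest

from deepmap.core import ConfusionCounts
from deepmap.metrics import (UNDEFINED, Annotation, AnnotationSet,
                             categorize_corrections, cohen_kappa,
                             histogram_by_deep, kappa_from_table,
                             match_annotations, sensitivity, specificity)


def make_set(marked_units, all_units, deep_values=None):
    s = AnnotationSet()
    for u in all_units:
        s.add_unit(u)
    for u in marked_units:
        dv = (deep_values or {}).get(u, 20.0)
        s.add(Annotation(unit=u, time_ms=100.0, deep_value_ms=dv))
    return s


UNITS = [(f"B{i}", 0) for i in range(20)]


class TestMatch:
    def test_identical_sets(self):
        marked = UNITS[:10]
        a = make_set(marked, UNITS)
        e = make_set(marked, UNITS)
        counts, pairs = match_annotations(a, e)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (10, 10, 0, 0)
        assert len(pairs) == 10

    def test_disjoint_sets(self):
        a = make_set(UNITS, UNITS)
        e = make_set([], UNITS)
        counts, _ = match_annotations(a, e)
        assert counts.fp == 20 and counts.tp == 0

    def test_total_equals_units(self):
        a = make_set(UNITS[:7], UNITS)
        e = make_set(UNITS[4:12], UNITS)
        counts, _ = match_annotations(a, e)
        assert counts.total == len(UNITS)

    def test_universe_mismatch_warns(self):
        a = make_set(UNITS[:2], UNITS[:5])
        e = make_set(UNITS[:2], UNITS[:7])
        with pytest.warns(UserWarning, match="universes differ"):
            counts, _ = match_annotations(a, e)
        assert counts.total == 7


class TestRates:
    @pytest.mark.parametrize("tp,fn,expected", [
        (1451, 281, 83.8),   # first expert vs gold standard
        (1562, 77, 95.3),    # second expert vs gold standard
        (0, 5, 0.0),
    ])
    def test_sensitivity(self, tp, fn, expected):
        assert sensitivity(ConfusionCounts(tp=tp, tn=0, fp=0, fn=fn)) \
            == expected

    @pytest.mark.parametrize("tn,fp,expected", [
        (1812, 136, 93.0),
        (2016, 25, 98.8),
        (7, 0, 100.0),
    ])
    def test_specificity(self, tn, fp, expected):
        assert specificity(ConfusionCounts(tp=0, tn=tn, fp=fp, fn=0)) \
            == expected

    def test_undefined_is_typed(self):
        assert sensitivity(ConfusionCounts(0, 5, 5, 0)) is UNDEFINED
        assert specificity(ConfusionCounts(5, 0, 0, 5)) is UNDEFINED

    def test_scale_invariance(self):
        c1 = ConfusionCounts(tp=12, tn=34, fp=5, fn=7)
        c3 = ConfusionCounts(tp=36, tn=102, fp=15, fn=21)
        assert sensitivity(c1) == sensitivity(c3)
        assert specificity(c1) == specificity(c3)


class TestKappa:
    def test_perfect_agreement(self):
        a = make_set(UNITS[:8], UNITS)
        assert cohen_kappa(a, make_set(UNITS[:8], UNITS)) == pytest.approx(1.0)

    def test_hand_computed_cross_tab(self):
        # table a=45 b=15 c=25 d=15: p_o=0.60, p_e=0.60*0.70+0.40*0.30=0.54,
        # kappa = 0.06/0.46 (frozen from the formula evaluated by hand)
        assert kappa_from_table(45, 15, 25, 15) \
            == pytest.approx(0.06 / 0.46)

    def test_complete_disagreement_symmetric_marginals(self):
        units = UNITS[:10]
        a = make_set(units[:5], units)
        b = make_set(units[5:], units)
        assert cohen_kappa(a, b) == pytest.approx(-1.0)

    def test_degenerate_marginals_undefined(self):
        a = make_set(UNITS, UNITS)
        assert cohen_kappa(a, make_set(UNITS, UNITS)) is UNDEFINED

    def test_unit_mismatch_raises(self):
        with pytest.raises(ValueError):
            cohen_kappa(make_set([], UNITS[:5]), make_set([], UNITS[:6]))

    def test_matches_sklearn_on_random_tables(self, rng):
        """100 random 2x2 tables against the independent oracle."""
        from sklearn.metrics import cohen_kappa_score

        for _ in range(100):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b + c + d == 0:
                continue
            y1 = [1] * (a + b) + [0] * (c + d)
            y2 = [1] * a + [0] * b + [1] * c + [0] * d
            ours = kappa_from_table(int(a), int(b), int(c), int(d))
            theirs = cohen_kappa_score(y1, y2)
            if ours is UNDEFINED:
                assert np.isnan(theirs) or theirs == 0.0
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)


class TestCorrections:
    def test_identity_edit_all_unchanged(self):
        a = make_set(UNITS[:9], UNITS)
        b = categorize_corrections(a, make_set(UNITS[:9], UNITS))
        assert (b.unchanged, b.changed, b.deleted, b.added) == (9, 0, 0, 0)
        assert b.percentages["unchanged"] == 100.0

    def test_total_removal_all_deleted(self):
        a = make_set(UNITS[:9], UNITS)
        b = categorize_corrections(a, make_set([], UNITS))
        assert b.deleted == 9 and b.percentages["deleted"] == 100.0

    def test_change_tolerance_splits_categories(self):
        a = make_set(UNITS[:3], UNITS, deep_values={u: 20.0 for u in UNITS})
        corrected = make_set(
            UNITS[:2] + [UNITS[3]], UNITS,
            deep_values={UNITS[0]: 22.0, UNITS[1]: 40.0, UNITS[3]: 15.0})
        b = categorize_corrections(a, corrected, change_tolerance_ms=5.0)
        assert (b.unchanged, b.changed, b.deleted, b.added) == (1, 1, 1, 1)

    def test_printed_counts_reproduce_percentages(self):
        from deepmap.core import CorrectionBreakdown

        b = CorrectionBreakdown(unchanged=5390, changed=375, deleted=110,
                                added=10)
        assert b.percentages == {"unchanged": 91.6, "changed": 6.4,
                                 "deleted": 1.9, "added": 0.2}

    def test_percentages_sum_within_rounding(self, rng):
        for _ in range(50):
            from deepmap.core import CorrectionBreakdown

            counts = rng.integers(0, 1000, size=4)
            if counts.sum() == 0:
                continue
            b = CorrectionBreakdown(*[int(c) for c in counts])
            assert abs(sum(b.percentages.values()) - 100.0) <= 0.2


class TestHistogram:
    def test_direct_binning(self):
        counts = histogram_by_deep([5.0, 12.0, 160.0], [0, 50, 150, 300])
        assert counts.tolist() == [2, 0, 1]

    def test_empty_input(self):
        assert histogram_by_deep([], [0, 50, 100]).tolist() == [0, 0]

    def test_last_bin_is_half_open(self):
        assert histogram_by_deep([100.0], [0, 50, 100]).tolist() == [0, 0]

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            histogram_by_deep([1.0], [0, 50, 50, 100])

    def test_uniform_values_split_evenly(self, rng):
        vals = rng.uniform(0, 100, 1000)
        counts = histogram_by_deep(vals, [0, 50, 100])
        sd = np.sqrt(1000 * 0.25)
        assert abs(counts[0] - 500) <= 3 * sd
        assert abs(counts[1] - 500) <= 3 * sd
        assert counts.sum() == (vals < 100).sum()

    def test_duplicate_mark_rejected(self):
        s = AnnotationSet()
        s.add(Annotation(unit=("B1", 0)))
        with pytest.raises(ValueError, match="duplicate"):
            s.add(Annotation(unit=("B1", 0)))
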