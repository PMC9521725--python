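"""Score algorithm annotations against an expert gold standard.

Feeds the study's printed contingency counts through the same statistics
the validation module applies to any pair of annotation sets, then shows
the correction taxonomy on a small synthetic edit session.
"""

from deepmap.core import ConfusionCounts
from deepmap.metrics import (Annotation, AnnotationSet,
                             categorize_corrections, cohen_kappa,
                             kappa_from_table, sensitivity, specificity)

# contingency counts of the two experts vs the gold standard
for name, counts in (("expert 1", ConfusionCounts(tp=1451, tn=1812,
                                                  fp=136, fn=281)),
                     ("expert 2", ConfusionCounts(tp=1562, tn=2016,
                                                  fp=25, fn=77))):
    print(f"{name}: sensitivity {sensitivity(counts)}%, "
          f"specificity {specificity(counts)}%  (n={counts.total})")

# a small expert-correction session: 3 algorithm marks; the expert keeps
# one, revises one by 25 ms, deletes one, and adds one of their own
units = [(f"B{i}", 0) for i in range(6)]
algo, corrected = AnnotationSet(), AnnotationSet()
for u in units:
    algo.add_unit(u)
    corrected.add_unit(u)
for u, dv in zip(units[:3], (20.0, 20.0, 20.0)):
    algo.add(Annotation(u, deep_value_ms=dv))
corrected.add(Annotation(units[0], deep_value_ms=21.0))   # unchanged
corrected.add(Annotation(units[1], deep_value_ms=45.0))   # changed
corrected.add(Annotation(units[3], deep_value_ms=30.0))   # added
breakdown = categorize_corrections(algo, corrected, change_tolerance_ms=5.0)
print(f"corrections: {breakdown.percentages} of {breakdown.total} detections")

print(f"kappa for the cross-tab a=45 b=15 c=25 d=15: "
      f"{kappa_from_table(45, 15, 25, 15):.3f}")
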