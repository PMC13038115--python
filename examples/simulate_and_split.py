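"""Synthetic phantom suite: generation, tumor-fraction filtering, splitting.

Builds a small suite of nested-ellipsoid tumor phantoms, drops cases whose
tumor occupies less than 1% of the volume, and produces a seeded 75/25
case-level split plus four cross-validation folds.
"""

from vitunet3d.data import (PhantomSpec, generate_phantom_suite, kfold_splits,
                            split_cases, tumor_fraction,
                            tumor_fraction_filter)

suite = generate_phantom_suite(12, seed=3,
                               base=PhantomSpec(extents=(48, 48, 48),
                                                tumor_fraction=0.02))
kept = tumor_fraction_filter(suite, threshold=0.01)
print(f"generated {len(suite)} phantoms; {len(kept)} pass the 1% tumor filter")
for case in suite:
    mark = "kept" if case in kept else "dropped"
    print(f"  {case.case_id}: tumor fraction {tumor_fraction(case.labels):.4f} ({mark})")

train, val = split_cases(kept, ratio=0.75, seed=0)
print(f"\n75/25 split: {len(train)} training / {len(val)} validation cases")
folds = kfold_splits(kept, k=4, seed=0)
sizes = [len(v) for _, v in folds]
print(f"4-fold validation fold sizes: {sizes} (each case validates once)")
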