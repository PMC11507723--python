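"""Redundancy-reduce curated complexes and split them into train/test pairs.

Complexes sharing most members collapse to one; the survivors are randomly
assigned to train or test, any complex sharing a protein pair across the
divide is dropped (largest first), and each side is expanded into positive
(same complex) and negative (different complexes) protein pairs with no
pair on both sides.
"""

import complexkit as ck
from complexkit.goldstd import Complex, ComplexSet

complexes = ComplexSet(
    [
        Complex("exosome", frozenset({"EXO1", "EXO2", "EXO3", "EXO4"})),
        Complex("exosome_variant", frozenset({"EXO1", "EXO2", "EXO3", "EXO5"})),
        Complex("proteasome_lid", frozenset({"PSM1", "PSM2", "PSM3"})),
        Complex("condensin", frozenset({"SMC2", "SMC4", "CAPD2"})),
        Complex("cohesin", frozenset({"SMC1", "SMC3", "RAD21"})),
    ]
)

reduced = ck.merge_redundant(complexes, merge_threshold=0.6, size_threshold=30)
print(f"{len(complexes)} complexes -> {len(reduced)} after redundancy reduction")
# the two exosome variants overlap at Jaccard 3/5 = 0.6 -> larger-id one removed

train, test = ck.split_train_test(reduced, seed=1234)
train_labels, test_labels = ck.label_pairs(train, test)
print(f"train: {len(train)} complexes, {len(train_labels.positives())} positive / "
      f"{len(train_labels.negatives())} negative pairs")
print(f"test:  {len(test)} complexes, {len(test_labels.positives())} positive / "
      f"{len(test_labels.negatives())} negative pairs")
overlap = set(train_labels.labels) & set(test_labels.labels)
print(f"pairs shared between sides: {len(overlap)} (guaranteed 0)")
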