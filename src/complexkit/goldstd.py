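"""Gold-standard complex handling: redundancy reduction, train/test split
and pair labeling.

Curated complexes (one complex per line, tab-separated UniProt accessions)
are redundancy-reduced by Jaccard overlap, randomly split into disjoint
train and test complex sets, and expanded into labeled protein pairs:
positives are intra-complex pairs, negatives are cross-complex pairs, and
anything else is unknown. Pairs appearing on both sides of the split are
removed from both so the test set stays a genuine leave-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from .pairs import Pair, canonical_pair, iter_pairs, strip_isoform


@dataclass
class Complex:
    complex_id: str
    members: frozenset
    tier: Optional[int] = None  # 1 (Extremely High) .. 6 (Medium)

    @property
    def size(self) -> int:
        return len(self.members)

    def pairs(self) -> Set[Pair]:
        return set(iter_pairs(self.members))


@dataclass
class ComplexSet:
    complexes: List[Complex] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def member_sets(self) -> List[frozenset]:
        return [c.members for c in self.complexes]

    def proteins(self) -> Set[str]:
        out: Set[str] = set()
        for c in self.complexes:
            out |= c.members
        return out

    def all_pairs(self) -> Set[Pair]:
        out: Set[Pair] = set()
        for c in self.complexes:
            out |= c.pairs()
        return out

    def deduplicate(self) -> "ComplexSet":
        """Collapse exact duplicate member-sets, keeping the best tier."""
        best: Dict[frozenset, Complex] = {}
        for c in self.complexes:
            prev = best.get(c.members)
            if prev is None:
                best[c.members] = c
            else:
                tiers = [t for t in (prev.tier, c.tier) if t is not None]
                keep = prev if prev.complex_id <= c.complex_id else c
                keep = Complex(keep.complex_id, keep.members, min(tiers) if tiers else None)
                best[c.members] = keep
        return ComplexSet(sorted(best.values(), key=lambda c: c.complex_id))


def read_complexes(path, strip_isoforms: bool = True) -> ComplexSet:
    """Read complexes from a one-complex-per-line tab-separated file."""
    complexes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            accs = [a for a in line.strip().split("\t") if a]
            if strip_isoforms:
                accs = [strip_isoform(a) for a in accs]
            members = frozenset(accs)
            if len(members) >= 2:
                complexes.append(Complex(f"cpx{i:05d}", members))
    if not complexes:
        raise ValueError(f"no complexes with >= 2 members in {path}")
    return ComplexSet(complexes)


def write_complexes(cset: ComplexSet, path) -> None:
    with open(path, "w") as fh:
        for c in cset.complexes:
            fh.write("\t".join(sorted(c.members)) + "\n")


def jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def _removal_order_key(c: Complex) -> Tuple[int, str]:
    # larger complexes removed first; equal size -> lexicographically later id
    return (-c.size, c.complex_id)


def merge_redundant(
    cset: ComplexSet,
    merge_threshold: float = 0.6,
    size_threshold: int = 30,
    remove_largest: bool = True,
    remove_large_subcomplexes: bool = False,
) -> ComplexSet:
    """Redundancy-reduce a complex set.

    Complexes larger than ``size_threshold`` are removed first. Then, while
    any pair of complexes overlaps with Jaccard >= ``merge_threshold``, the
    larger of the two is removed (``remove_largest``) or the two are merged
    into their union. Iteration order is deterministic: complexes sorted by
    size descending, ties by id, and equal-size redundant pairs drop the
    lexicographically later id.

    ``remove_large_subcomplexes`` additionally removes any complex fully
    contained in a larger one (off by default).
    """
    if not 0 < merge_threshold <= 1:
        raise ValueError("merge_threshold must be in (0, 1]")
    if size_threshold < 2:
        raise ValueError("size_threshold must be >= 2")
    if len(cset) == 0:
        raise ValueError("empty complex set")

    alive = [c for c in cset if c.size <= size_threshold]
    alive = sorted(alive, key=lambda c: (-c.size, c.complex_id))

    changed = True
    while changed:
        changed = False
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                a, b = alive[i], alive[j]
                if jaccard(a.members, b.members) >= merge_threshold:
                    if remove_largest:
                        drop = max(a, b, key=_drop_key)
                        alive = [c for c in alive if c is not drop]
                    else:
                        union = Complex(min(a.complex_id, b.complex_id), a.members | b.members)
                        alive = [c for c in alive if c is not a and c is not b]
                        alive.append(union)
                        alive.sort(key=lambda c: (-c.size, c.complex_id))
                    changed = True
                    break
            if changed:
                break

    if remove_large_subcomplexes:
        alive = [
            c
            for c in alive
            if not any(o is not c and c.members < o.members for o in alive)
        ]
    if not alive:
        raise ValueError("no complexes survive redundancy reduction")
    return ComplexSet(sorted(alive, key=lambda c: c.complex_id)).deduplicate()


def _drop_key(c: Complex) -> Tuple[int, str]:
    # the larger complex is dropped; equal size -> lexicographically later id
    return (c.size, c.complex_id)


def split_train_test(
    cset: ComplexSet, seed: int = 1234
) -> Tuple[ComplexSet, ComplexSet]:
    """Randomly split complexes into train and test sets with no shared pair.

    Each complex lands on exactly one side. If a train and a test complex
    share any protein pair, the larger of the two is removed (ties drop the
    lexicographically later id), so that no pair is present in both sets.
    Deterministic given ``seed``.
    """
    if len(cset) < 2:
        raise ValueError("need at least 2 complexes to split")
    rng = np.random.default_rng(seed)
    ordered = sorted(cset.complexes, key=lambda c: c.complex_id)
    assign = rng.random(len(ordered)) < 0.5
    train = [c for c, t in zip(ordered, assign) if t]
    test = [c for c, t in zip(ordered, assign) if not t]
    if not train or not test:
        # degenerate draw on tiny inputs: force one complex to the empty side
        if not train:
            train, test = [test[0]], test[1:]
        else:
            train, test = train[1:], [train[0]]

    # resolve cross-side pair sharing
    changed = True
    while changed:
        changed = False
        for tr in list(train):
            tr_pairs = tr.pairs()
            for te in list(test):
                if tr_pairs & te.pairs():
                    drop = max(tr, te, key=_drop_key)
                    if drop is tr:
                        train = [c for c in train if c is not tr]
                    else:
                        test = [c for c in test if c is not te]
                    changed = True
                    break
            if changed:
                break
    return ComplexSet(train), ComplexSet(test)


@dataclass
class LabeledPairs:
    """Map from canonical pair to a boolean label (True = positive)."""

    labels: Dict[Pair, bool] = field(default_factory=dict)

    def positives(self) -> Set[Pair]:
        return {p for p, v in self.labels.items() if v}

    def negatives(self) -> Set[Pair]:
        return {p for p, v in self.labels.items() if not v}

    def __len__(self) -> int:
        return len(self.labels)


def _side_labels(side: ComplexSet) -> LabeledPairs:
    positives = side.all_pairs()
    labels: Dict[Pair, bool] = {p: True for p in positives}
    complexes = side.complexes
    for i in range(len(complexes)):
        for j in range(i + 1, len(complexes)):
            for a in complexes[i].members:
                for b in complexes[j].members:
                    if a == b:
                        continue
                    key = canonical_pair(a, b)
                    if key not in positives:
                        labels[key] = False
    return LabeledPairs(labels)


def label_pairs(train: ComplexSet, test: ComplexSet) -> Tuple[LabeledPairs, LabeledPairs]:
    """Expand both sides into labeled pairs and drop any pair seen on both.

    Within a side, a pair of proteins in the same complex is positive; a
    pair drawn from two different complexes (and never co-complexed on that
    side) is negative. Any pair carrying a label on both sides is removed
    from both, guaranteeing disjoint train and test label maps.
    """
    tr = _side_labels(train)
    te = _side_labels(test)
    shared = set(tr.labels) & set(te.labels)
    for p in shared:
        del tr.labels[p]
        del te.labels[p]
    return tr, te


def write_split_files(
    train: ComplexSet,
    test: ComplexSet,
    train_labels: LabeledPairs,
    test_labels: LabeledPairs,
    out_prefix,
) -> Dict[str, Path]:
    """Write the six split artifacts (pos/neg x train/test pairs, two complex lists)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "train_complexes": prefix.with_suffix(".train.txt"),
        "test_complexes": prefix.with_suffix(".test.txt"),
        "pos_train": prefix.with_suffix(".train_ppis.txt"),
        "pos_test": prefix.with_suffix(".test_ppis.txt"),
        "neg_train": prefix.with_suffix(".neg_train_ppis.txt"),
        "neg_test": prefix.with_suffix(".neg_test_ppis.txt"),
    }
    write_complexes(train, paths["train_complexes"])
    write_complexes(test, paths["test_complexes"])
    for key, pairs in (
        ("pos_train", train_labels.positives()),
        ("pos_test", test_labels.positives()),
        ("neg_train", train_labels.negatives()),
        ("neg_test", test_labels.negatives()),
    ):
        with open(paths[key], "w") as fh:
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")
    return paths


def read_labeled_pairs(pos_path, neg_path) -> LabeledPairs:
    labels: Dict[Pair, bool] = {}
    for path, value in ((pos_path, True), (neg_path, False)):
        with open(path) as fh:
            for line in fh:
                a, b = line.strip().split("\t")[:2]
                labels[canonical_pair(a, b)] = value
    return LabeledPairs(labels)
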