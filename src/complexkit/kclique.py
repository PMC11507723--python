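"""Weighted k-clique precision/recall for cluster-vs-benchmark comparison.

Predicted clusters and gold-standard complexes are compared through the
cliques (k-subsets) they contain, for every clique size k from pairs up
to the largest set. For each k, precision is the fraction of distinct
predicted k-subsets contained in some gold complex, and recall the
fraction of distinct gold k-subsets contained in some predicted cluster.
Per-size values are averaged with weights equal to the number of sets of
size >= k on the corresponding side, damping the combinatorial dominance
of large complexes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .goldstd import ComplexSet


@dataclass
class CliqueEvaluation:
    per_size: pd.DataFrame  # columns k, precision_k, recall_k, weight_p_k, weight_r_k
    precision_weighted: float
    recall_weighted: float
    f1: float
    empty_predicted: bool = False


def _containment_index(sets: Sequence[frozenset]) -> Dict[str, Set[int]]:
    index: Dict[str, Set[int]] = {}
    for i, s in enumerate(sets):
        for p in s:
            index.setdefault(p, set()).add(i)
    return index


def _contained_in_any(subset: Tuple, sets: Sequence[frozenset], index) -> bool:
    candidates: Set[int] | None = None
    for p in subset:
        hits = index.get(p)
        if not hits:
            return False
        candidates = hits.copy() if candidates is None else candidates & hits
        if not candidates:
            return False
    return bool(candidates)


def _k_subset_fraction(
    source: Sequence[frozenset],
    target: Sequence[frozenset],
    target_index,
    k: int,
    sample_limit: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of distinct k-subsets of ``source`` sets contained in some
    ``target`` set; exact when the combination budget allows, else sampled."""
    sized = [s for s in source if len(s) >= k]
    total = sum(comb(len(s), k) for s in sized)
    if total == 0:
        return float("nan")
    if total <= sample_limit:
        seen: Set[Tuple] = set()
        for s in sized:
            for sub in itertools.combinations(sorted(s), k):
                seen.add(sub)
        hits = sum(_contained_in_any(sub, target, target_index) for sub in seen)
        return hits / len(seen)
    # sample clusters proportional to their k-subset count, then a uniform
    # k-subset; deduplicate draws
    weights = np.array([comb(len(s), k) for s in sized], dtype=float)
    weights /= weights.sum()
    members = [sorted(s) for s in sized]
    seen = set()
    picks = rng.choice(len(sized), size=sample_limit, p=weights)
    for i in picks:
        mem = members[i]
        sub = tuple(sorted(rng.choice(len(mem), size=k, replace=False)))
        seen.add(tuple(mem[j] for j in sub))
    hits = sum(_contained_in_any(sub, target, target_index) for sub in seen)
    return hits / len(seen)


def clique_pr(
    predicted: ComplexSet,
    gold: ComplexSet,
    sample_limit: int = 10_000,
    seed: int = 0,
) -> CliqueEvaluation:
    """Weighted k-clique precision/recall of predicted clusters vs gold complexes.

    Duplicate member-sets on either side are collapsed before evaluation.
    Sizes k run from 2 to the largest set on either side; per-size values
    are weighted by the count of same-side sets of size >= k. The F1 is the
    harmonic mean of the weighted precision and recall.
    """
    pred_sets = sorted(set(predicted.member_sets()), key=lambda s: (len(s), sorted(s)))
    gold_sets = sorted(set(gold.member_sets()), key=lambda s: (len(s), sorted(s)))
    if not gold_sets:
        raise ValueError("empty gold set")
    empty_predicted = not pred_sets
    rng = np.random.default_rng(seed)
    pred_index = _containment_index(pred_sets)
    gold_index = _containment_index(gold_sets)

    max_k = max(
        [len(s) for s in gold_sets] + [len(s) for s in pred_sets] or [2]
    )
    rows = []
    for k in range(2, max_k + 1):
        w_p = sum(1 for s in pred_sets if len(s) >= k)
        w_r = sum(1 for s in gold_sets if len(s) >= k)
        prec = (
            _k_subset_fraction(pred_sets, gold_sets, gold_index, k, sample_limit, rng)
            if w_p
            else float("nan")
        )
        rec = (
            _k_subset_fraction(gold_sets, pred_sets, pred_index, k, sample_limit, rng)
            if w_r
            else float("nan")
        )
        rows.append(
            {"k": k, "precision_k": prec, "recall_k": rec, "weight_p_k": w_p, "weight_r_k": w_r}
        )
    table = pd.DataFrame(rows)

    def _weighted(col, wcol):
        sub = table[table[wcol] > 0].dropna(subset=[col])
        if sub.empty or sub[wcol].sum() == 0:
            return 0.0
        return float(np.average(sub[col], weights=sub[wcol]))

    p_w = 0.0 if empty_predicted else _weighted("precision_k", "weight_p_k")
    r_w = _weighted("recall_k", "weight_r_k")
    f1 = 0.0 if (p_w + r_w) == 0 else 2 * p_w * r_w / (p_w + r_w)
    return CliqueEvaluation(table, p_w, r_w, f1, empty_predicted)
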