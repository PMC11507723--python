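"""Complex-level annotation enrichment and guilt-by-association transfer.

Each predicted complex is tested for over-representation of annotation
terms (GO, KEGG, Reactome, CORUM, HP) against the full experimental
background with a one-sided hypergeometric test, Benjamini-Hochberg
corrected within the complex. A shuffled-complex baseline (protein ids
reassigned to complexes of identical sizes) calibrates how many enriched
complexes arise by chance. Enriched terms are then transferred to
uncharacterized member proteins under coverage, significance and
annotation-score rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .goldstd import ComplexSet
from .wmm import wmm_pvalue


@dataclass
class AnnotationTerm:
    term: str
    source: str  # GO, KEGG, Reactome, CORUM, HP, ...
    members: frozenset
    root: bool = False
    description: str = ""


@dataclass
class AnnotationSets:
    terms: Dict[str, AnnotationTerm] = field(default_factory=dict)

    def add(self, term: AnnotationTerm) -> None:
        if not term.members:
            raise ValueError(f"term {term.term!r} has no members")
        self.terms[term.term] = term

    def __iter__(self):
        return iter(self.terms.values())

    def __len__(self):
        return len(self.terms)


def read_gmt(path) -> AnnotationSets:
    """Read annotation sets from GMT (term, description, members...).

    The description field encodes ``source`` and an optional ``root`` flag
    as ``source=GO;root=1;free text`` — fields written by :func:`write_gmt`.
    A bare description is taken as the source name.
    """
    out = AnnotationSets()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, members = parts[0], parts[1], parts[2:]
            source, root, text = _parse_gmt_description(desc)
            out.add(
                AnnotationTerm(term, source, frozenset(m for m in members if m), root, text)
            )
    return out


def _parse_gmt_description(desc: str) -> Tuple[str, bool, str]:
    source, root, text = "NA", False, desc
    if "source=" in desc:
        fields = desc.split(";")
        text_parts = []
        for f in fields:
            if f.startswith("source="):
                source = f[len("source=") :]
            elif f.startswith("root="):
                root = f[len("root=") :] in ("1", "true", "True")
            else:
                text_parts.append(f)
        text = ";".join(text_parts)
    elif desc:
        source = desc
        text = ""
    return source, root, text


def write_gmt(annotations: AnnotationSets, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(annotations, key=lambda t: t.term):
            desc = f"source={t.source};root={int(t.root)}"
            if t.description:
                desc += f";{t.description}"
            fh.write("\t".join([t.term, desc] + sorted(t.members)) + "\n")


def enrich_complexes(
    complexes: ComplexSet,
    annotations: AnnotationSets,
    background: Set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per (complex, term).

    For a complex of size n whose members overlap a term in k proteins,
    with m term members inside the background of size N, the p-value is
    the tail P(overlap >= k | n, m, N) — the same kernel as the WMM
    co-occurrence test. BH correction is applied within each complex
    across its tested terms.
    """
    background = set(background)
    for c in complexes:
        stray = c.members - background
        if stray:
            raise ValueError(
                f"complex {c.complex_id} member(s) not in background: {sorted(stray)[:5]}"
            )
    N = len(background)
    rows = []
    for c in complexes:
        n = len(c.members)
        c_rows = []
        for t in annotations:
            m_set = t.members & background
            k = len(c.members & m_set)
            if k == 0:
                continue
            p = wmm_pvalue(k, n, len(m_set), N)
            c_rows.append(
                {
                    "complex_id": c.complex_id,
                    "term": t.term,
                    "source": t.source,
                    "overlap": k,
                    "p_value": p,
                }
            )
        if c_rows:
            pvals = [r["p_value"] for r in c_rows]
            adj = multipletests(pvals, method="fdr_bh")[1]
            for r, a in zip(c_rows, adj):
                r["p_adjusted"] = float(max(a, r["p_value"]))
            rows.extend(c_rows)
    return pd.DataFrame(
        rows, columns=["complex_id", "term", "source", "overlap", "p_value", "p_adjusted"]
    )


def shuffle_complexes(complexes: ComplexSet, seed: int = 0) -> ComplexSet:
    """Reassign protein ids to complexes, preserving every complex's size.

    Membership slots are permuted across complexes; duplicate proteins
    landing in one complex are repaired by greedy swapping with later
    slots, so the multiset of complex sizes is preserved exactly.
    """
    from .goldstd import Complex

    rng = np.random.default_rng(seed)
    sizes = [c.size for c in complexes]
    slots: List[str] = [p for c in complexes for p in sorted(c.members)]
    perm = rng.permutation(len(slots))
    slots = [slots[i] for i in perm]

    # partition back into the original sizes, repairing duplicates
    out: List[List[str]] = []
    pos = 0
    for size in sizes:
        out.append(slots[pos : pos + size])
        pos += size
    for ci, members in enumerate(out):
        seen = set()
        for mi, p in enumerate(members):
            if p not in seen:
                seen.add(p)
                continue
            swapped = False
            for cj in range(len(out)):
                if cj == ci:
                    continue
                for mj, q in enumerate(out[cj]):
                    if q not in seen and p not in set(out[cj]) - {q}:
                        out[cj][mj], members[mi] = p, q
                        seen.add(q)
                        swapped = True
                        break
                if swapped:
                    break
            if not swapped:
                raise RuntimeError("could not repair duplicate assignment")
    return ComplexSet(
        [
            Complex(f"shuf{i:05d}", frozenset(members))
            for i, members in enumerate(out)
        ]
    )


def shuffled_baseline(
    complexes: ComplexSet,
    annotations: AnnotationSets,
    background: Set[str],
    seed: int = 0,
    p_threshold: float = 0.01,
) -> int:
    """Number of shuffled complexes with at least one enriched term.

    The shuffle preserves the multiset of complex sizes; enrichment and
    the adjusted-p threshold mirror the real analysis.
    """
    shuffled = shuffle_complexes(complexes, seed=seed)
    enr = enrich_complexes(shuffled, annotations, background)
    if enr.empty:
        return 0
    hits = enr[enr["p_adjusted"] <= p_threshold]
    return int(hits["complex_id"].nunique())


def count_enriched(enrichments: pd.DataFrame, p_threshold: float = 0.01) -> int:
    if enrichments.empty:
        return 0
    return int(
        enrichments[enrichments["p_adjusted"] <= p_threshold]["complex_id"].nunique()
    )


def transfer_annotations(
    complexes: ComplexSet,
    enrichments: pd.DataFrame,
    annotation_scores: Mapping[str, int],
    annotations: AnnotationSets,
    p_threshold: float = 0.01,
    coverage: float = 0.5,
    max_score: int = 3,
    count_target_in_denominator: bool = True,
) -> pd.DataFrame:
    """Guilt-by-association transfer of enriched terms to uncharacterized members.

    A term transfers to protein U in complex C iff
      (1) at least ``coverage`` of C's members already carry the term,
      (2) the term's adjusted p in C is <= ``p_threshold``,
      (3) U's annotation score is <= ``max_score`` (1 = least characterized),
      (4) the term is not root-flagged, and
      (5) U does not already carry the term.

    ``count_target_in_denominator`` controls whether U itself counts in the
    coverage denominator (default yes).
    """
    by_complex: Dict[str, Dict[str, float]] = {}
    for _, row in enrichments.iterrows():
        by_complex.setdefault(row["complex_id"], {})[row["term"]] = row["p_adjusted"]
    rows = []
    for c in complexes:
        enriched = by_complex.get(c.complex_id, {})
        for term, adj_p in sorted(enriched.items()):
            t = annotations.terms.get(term)
            if t is None or t.root or adj_p > p_threshold:
                continue
            carriers = c.members & t.members
            for u in sorted(c.members - t.members):
                score = annotation_scores.get(u)
                if score is None or score > max_score:
                    continue
                denom = len(c.members) if count_target_in_denominator else len(c.members) - 1
                if denom <= 0 or len(carriers) / denom < coverage:
                    continue
                rows.append(
                    {
                        "protein": u,
                        "complex_id": c.complex_id,
                        "term": term,
                        "source": t.source,
                        "p_adjusted": adj_p,
                        "coverage": len(carriers) / denom,
                    }
                )
    return pd.DataFrame(
        rows, columns=["protein", "complex_id", "term", "source", "p_adjusted", "coverage"]
    )
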