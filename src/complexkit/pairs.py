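"""Canonical unordered protein-pair keys.

Every table in the toolkit that is keyed by a pair of proteins uses the
lexicographically ordered tuple as its key, so that (A, B) and (B, A)
always address the same row.
"""

from __future__ import annotations

from typing import Iterable, Tuple

Pair = Tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair as a lexicographically sorted tuple."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def iter_pairs(members: Iterable[str]) -> Iterable[Pair]:
    """All canonical pairs among a set of members."""
    ordered = sorted(set(members))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            yield (a, b)


def strip_isoform(accession: str) -> str:
    """Strip an isoform suffix (dash + digits) from a UniProt accession."""
    base, dash, suffix = accession.partition("-")
    if dash and suffix.isdigit():
        return base
    return accession
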