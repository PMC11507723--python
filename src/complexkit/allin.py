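"""ALL-IN (Average celL Lineage co-expressIoN) mutual-exclusivity scoring.

Mutually exclusive subunits of a complex tend to be expressed in an
anti-correlated, often lineage-specific fashion. From a protein x
cell-line matrix of z-scored log abundances with a lineage label per cell
line, four sub-scores are computed for each co-complex pair:

1. robust correlation (bicor) of the two abundance profiles across all
   cell lines;
2. bicor after averaging abundances per lineage, removing the bias from
   unequal lineage sizes;
3. a large-expression-difference score: with missing values imputed from
   N(-4, 0.3) (far below the observed z-range), the mean abundance of A
   in B's 50 highest- minus 50 lowest-expressing cell lines, and vice
   versa, averaged;
4. bicor across lineages of the two proteins' per-lineage average
   correlation with the rest of their complex.

Each sub-score is oriented so larger means more mutually exclusive,
z-scored across all scored pairs, and averaged into the ALL-IN score for
pairs carrying at least two sub-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .goldstd import ComplexSet
from .pairs import Pair, canonical_pair, iter_pairs

# sub-scores measure co-expression; exclusivity is their negation
SUBSCORE_ORIENTATION = {"s1": -1.0, "s2": -1.0, "s3": -1.0, "s4": -1.0}


def zscore_relative(log_abundance: pd.DataFrame, min_observed: int = 3) -> pd.DataFrame:
    """Per-protein z-scores of log abundance across observed cell lines.

    Missing entries stay missing; proteins observed in fewer than
    ``min_observed`` cell lines, or with zero variance, are dropped with a
    warning.
    """
    keep = []
    dropped = []
    for prot, row in log_abundance.iterrows():
        obs = row.dropna()
        if len(obs) < min_observed or obs.std(ddof=1) == 0:
            dropped.append(prot)
            continue
        keep.append((row - obs.mean()) / obs.std(ddof=1))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} protein(s) with <{min_observed} observations or zero variance"
        )
    if not keep:
        raise ValueError("no proteins left after z-scoring")
    return pd.DataFrame(keep)


def bicor(x, y, min_overlap: int = 10, c: float = 9.0) -> float:
    """Biweight midcorrelation of two vectors over pairwise-complete entries.

    Uses the standard 9-MAD tuning: deviations beyond c = 9 median absolute
    deviations get zero weight. Returns NaN when fewer than ``min_overlap``
    complete pairs are available or either vector's MAD is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < min_overlap:
        return float("nan")
    x, y = x[mask], y[mask]

    def _weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2
        w[np.abs(u) >= 1] = 0.0
        return (v - med) * w

    a = _weights(x)
    b = _weights(y)
    if a is None or b is None:
        return float("nan")
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return float("nan")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


@dataclass
class ExpressionMatrix:
    """Protein x cell-line z-score matrix with a lineage label per cell line."""

    values: pd.DataFrame
    lineages: pd.Series  # index = cell line, value = lineage label

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.lineages.index)
        if missing:
            raise ValueError(f"cell lines without lineage label: {sorted(missing)[:5]}")
        self.lineages = self.lineages.loc[self.values.columns]

    @property
    def lineage_names(self) -> List[str]:
        return sorted(self.lineages.unique())

    def lineage_means(self) -> pd.DataFrame:
        """Per-lineage mean z-score per protein (NaN where never observed)."""
        return self.values.T.groupby(self.lineages).mean().T

    def detected_counts(self) -> pd.Series:
        return self.values.notna().sum(axis=1)


def impute_missing(
    matrix: pd.DataFrame,
    seed: int = 0,
    center: float = -4.0,
    sd: float = 0.3,
    min_detected: int = 50,
) -> pd.DataFrame:
    """Detection-floor imputation for the expression-difference sub-score.

    Proteins detected in fewer than ``min_detected`` cell lines are
    dropped; remaining missing entries are drawn from N(center, sd),
    far below the observed z-score range, representing below-detection
    abundance. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    kept = matrix.loc[matrix.notna().sum(axis=1) >= min_detected].copy()
    vals = kept.to_numpy(dtype=float)
    miss = ~np.isfinite(vals)
    vals[miss] = rng.normal(center, sd, size=int(miss.sum()))
    return pd.DataFrame(vals, index=kept.index, columns=kept.columns)


def _top_bottom_difference(
    imputed: pd.DataFrame, a: str, b: str, top_n: int = 50
) -> float:
    """Mean of A in B's top-n minus bottom-n cell lines, and vice versa, averaged."""

    def one_direction(target: str, ranker: str) -> float:
        # ties broken by cell-line id for determinism
        vals = imputed.loc[ranker]
        order = np.lexsort((vals.index.to_numpy(), vals.to_numpy(dtype=float)))
        cells = vals.index[order]
        bottom, top = cells[:top_n], cells[-top_n:]
        tvals = imputed.loc[target]
        return float(tvals[top].mean() - tvals[bottom].mean())

    return 0.5 * (one_direction(a, b) + one_direction(b, a))


@dataclass
class SubScores:
    pair: Pair
    s1: float = float("nan")
    s2: float = float("nan")
    s3: float = float("nan")
    s4: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {"s1": self.s1, "s2": self.s2, "s3": self.s3, "s4": self.s4}

    @property
    def n_present(self) -> int:
        return int(sum(np.isfinite(v) for v in self.as_dict().values()))


def lineage_complex_profiles(
    matrix: ExpressionMatrix,
    imputed: pd.DataFrame,
    members: Set[str],
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Per-lineage average bicor of each member to the rest of its complex.

    Computed on the imputed matrix so that lineages where a subunit sits
    below detection contribute a near-zero correlation rather than a
    missing value — exactly the signal the lineage-profile sub-score needs.
    Returns a member x lineage table.
    """
    members = sorted(m for m in members if m in imputed.index)
    out = pd.DataFrame(index=members, columns=matrix.lineage_names, dtype=float)
    for lineage in matrix.lineage_names:
        cells = matrix.lineages.index[matrix.lineages == lineage]
        cells = [c for c in cells if c in imputed.columns]
        block = imputed.loc[members, cells]
        for m in members:
            others = [o for o in members if o != m]
            rs = [
                bicor(block.loc[m], block.loc[o], min_overlap=min_overlap)
                for o in others
            ]
            rs = [r for r in rs if np.isfinite(r)]
            out.loc[m, lineage] = float(np.mean(rs)) if rs else np.nan
    return out


def compute_subscores(
    matrix: ExpressionMatrix,
    complexes: ComplexSet,
    pair: Tuple[str, str],
    seed: int = 0,
    top_n: int = 50,
    min_overlap: int = 10,
    min_lineages: int = 3,
    imputed: Optional[pd.DataFrame] = None,
    profiles: Optional[pd.DataFrame] = None,
) -> SubScores:
    """The four expression sub-scores for one co-complex pair.

    ``imputed`` and ``profiles`` allow precomputed shared intermediates
    (see :func:`allin_scores`); otherwise they are derived here with the
    given seed. The pair must belong to some complex in ``complexes``.
    """
    a, b = canonical_pair(*pair)
    home = next((c for c in complexes if a in c.members and b in c.members), None)
    if home is None:
        raise ValueError(f"pair {a}/{b} is not co-complex in the supplied set")
    sub = SubScores(pair=(a, b))
    if a in matrix.values.index and b in matrix.values.index:
        sub.s1 = bicor(matrix.values.loc[a], matrix.values.loc[b], min_overlap=min_overlap)
        means = matrix.lineage_means()
        sub.s2 = bicor(means.loc[a], means.loc[b], min_overlap=min_lineages)
    if imputed is None:
        imputed = impute_missing(matrix.values, seed=seed, min_detected=top_n)
    if a in imputed.index and b in imputed.index:
        sub.s3 = _top_bottom_difference(imputed, a, b, top_n=top_n)
        if profiles is None:
            profiles = lineage_complex_profiles(
                matrix, imputed, home.members, min_overlap=min_overlap
            )
        if a in profiles.index and b in profiles.index:
            sub.s4 = bicor(profiles.loc[a], profiles.loc[b], min_overlap=min_lineages)
    return sub


def allin_scores(
    matrix: ExpressionMatrix,
    complexes: ComplexSet,
    seed: int = 0,
    top_n: int = 50,
    min_overlap: int = 10,
    min_lineages: int = 3,
    min_subscores: int = 2,
) -> pd.DataFrame:
    """ALL-IN scores for every co-complex pair in the matrix.

    Sub-scores are oriented (all negated: anti-correlation and negative
    expression differences indicate exclusivity), z-scored across all
    scored pairs, and averaged over the sub-scores present; pairs with
    fewer than ``min_subscores`` are omitted. Output is invariant to pair
    order.
    """
    imputed = impute_missing(matrix.values, seed=seed, min_detected=top_n)
    subrows: List[SubScores] = []
    seen: Set[Pair] = set()
    for cpx in complexes:
        profiles = lineage_complex_profiles(
            matrix, imputed, cpx.members, min_overlap=min_overlap
        )
        for a, b in iter_pairs(cpx.members):
            if (a, b) in seen:
                continue
            seen.add((a, b))
            subrows.append(
                compute_subscores(
                    matrix,
                    complexes,
                    (a, b),
                    seed=seed,
                    top_n=top_n,
                    min_overlap=min_overlap,
                    min_lineages=min_lineages,
                    imputed=imputed,
                    profiles=profiles,
                )
            )
    if len(subrows) < 2:
        raise ValueError("need at least 2 co-complex pairs to z-score sub-scores")
    table = pd.DataFrame(
        [
            {"protein_a": s.pair[0], "protein_b": s.pair[1], **s.as_dict()}
            for s in sorted(subrows, key=lambda s: s.pair)
        ]
    ).set_index(["protein_a", "protein_b"])
    return combine_subscores(table, min_subscores=min_subscores)


def combine_subscores(subscores: pd.DataFrame, min_subscores: int = 2) -> pd.DataFrame:
    """Orient, z-score and average a sub-score table into ALL-IN scores."""
    z = pd.DataFrame(index=subscores.index)
    for col, sign in SUBSCORE_ORIENTATION.items():
        if col not in subscores.columns:
            continue
        v = sign * subscores[col]
        obs = v.dropna()
        if len(obs) < 2 or obs.std(ddof=1) == 0:
            continue  # sub-score unusable globally
        z[f"z_{col}"] = (v - obs.mean()) / obs.std(ddof=1)
    n_present = z.notna().sum(axis=1)
    out = z.copy()
    out["n_subscores"] = n_present
    out["allin"] = z.mean(axis=1, skipna=True)
    out = out[n_present >= min_subscores]
    return out


def stratify_by_homomultimer(
    allin_table: pd.DataFrame,
    common_subunits: Mapping[Pair, str],
    homomultimer: Mapping[str, bool],
) -> pd.DataFrame:
    """Compare ALL-IN scores by whether the pair's common subunit homomultimerizes.

    ``common_subunits`` maps each pair to its shared third subunit.
    Returns per-group summaries plus a Mann-Whitney U comparison of the
    yes/no groups when both are populated.
    """
    from scipy.stats import mannwhitneyu

    groups: Dict[str, List[float]] = {"yes": [], "no": [], "unknown": []}
    for pair, row in allin_table.iterrows():
        common = common_subunits.get(tuple(pair))
        if common is None or common not in homomultimer:
            groups["unknown"].append(row["allin"])
        else:
            groups["yes" if homomultimer[common] else "no"].append(row["allin"])
    rows = []
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "group": name,
                "n": len(arr),
                "mean_allin": float(np.mean(arr)) if len(arr) else np.nan,
                "median_allin": float(np.median(arr)) if len(arr) else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    if groups["yes"] and groups["no"]:
        stat, p = mannwhitneyu(groups["no"], groups["yes"], alternative="two-sided")
        summary.attrs["mannwhitney_u"] = float(stat)
        summary.attrs["mannwhitney_p"] = float(p)
    return summary


def complex_covariation_median(
    complexes: ComplexSet,
    pair_covariation: Mapping[Pair, float],
    min_size: int = 4,
    min_coverage: float = 0.5,
    max_tier: Optional[int] = None,
) -> pd.DataFrame:
    """Median intra-complex covariation per eligible complex.

    Complexes smaller than ``min_size``, with less than ``min_coverage``
    of subunits covered by at least one scored pair, or (when tiers are
    present and ``max_tier`` given) with a worse tier, are excluded.
    """
    rows = []
    for c in complexes:
        if c.size < min_size:
            continue
        if max_tier is not None and c.tier is not None and c.tier > max_tier:
            continue
        scores = []
        covered: Set[str] = set()
        for p in iter_pairs(c.members):
            s = pair_covariation.get(p)
            if s is not None and np.isfinite(s):
                scores.append(float(s))
                covered |= set(p)
        if not scores or len(covered) / c.size < min_coverage:
            continue
        rows.append(
            {
                "complex_id": c.complex_id,
                "n_members": c.size,
                "n_scored_pairs": len(scores),
                "coverage": len(covered) / c.size,
                "median_covariation": float(np.median(scores)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["complex_id", "n_members", "n_scored_pairs", "coverage", "median_covariation"],
    )
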