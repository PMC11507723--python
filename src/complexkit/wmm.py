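"""Weighted matrix model (WMM) co-occurrence features.

Affinity-purification and co-fractionation compendia are reduced to one
detected-protein set per experiment. For every pair of proteins seen
together at least once, the WMM asks how surprising their co-detection
count is under a hypergeometric null: given that protein A appears in
``n`` of ``N`` experiments and protein B in ``m``, the probability of
sharing at least ``k`` experiments by chance is the upper tail

    p(#shared >= k | n, m, N) = sum_{i=k}^{min(n,m)} C(n,i) C(N-n, m-i) / C(N,m).

The negative natural log of this tail, together with the raw pair count
``k``, form one tagged feature group per compendium (e.g. per cell type
and per abundance threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .pairs import canonical_pair


@dataclass(frozen=True)
class Experiment:
    experiment_id: str
    dataset_tag: str
    proteins: frozenset

    def __post_init__(self):
        if not self.proteins:
            raise ValueError(f"experiment {self.experiment_id!r} has no proteins")


@dataclass
class ExperimentCompendium:
    """A list of experiments, each reduced to its set of detected proteins."""

    experiments: list

    def __post_init__(self):
        if not self.experiments:
            raise ValueError("empty compendium")
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValueError("experiment ids not unique")

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    def protein_universe(self) -> set:
        out: set = set()
        for e in self.experiments:
            out |= e.proteins
        return out


def filter_compendium(raw_observations: pd.DataFrame, threshold: float) -> ExperimentCompendium:
    """Reduce an observation table to per-experiment detected-protein sets.

    A protein counts as detected in an experiment iff its abundance score
    is strictly greater than ``threshold``. Experiments emptied by the
    filter are dropped and the experiment count recomputed.

    Parameters
    ----------
    raw_observations
        Table with columns ``experiment_id``, ``dataset_tag``, ``protein``,
        ``score``.
    threshold
        Strict lower bound on the abundance score.
    """
    if raw_observations is None or len(raw_observations) == 0:
        raise ValueError("no observations")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    required = {"experiment_id", "dataset_tag", "protein", "score"}
    missing = required - set(raw_observations.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")

    kept = raw_observations[raw_observations["score"].astype(float) > threshold]
    experiments = []
    for (eid, tag), grp in kept.groupby(["experiment_id", "dataset_tag"], sort=True):
        prots = frozenset(grp["protein"].astype(str))
        if prots:
            experiments.append(Experiment(str(eid), str(tag), prots))
    if not experiments:
        raise ValueError("empty compendium")
    return ExperimentCompendium(experiments)


def wmm_pvalue(k: int, n: int, m: int, N: int) -> float:
    """Hypergeometric upper-tail probability of sharing >= k experiments.

    Computed in log-space via log-gamma so that compendia of tens of
    thousands of experiments do not overflow. Returns a probability in
    (0, 1].
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if n > N or m > N:
        raise ValueError(f"n={n}, m={m} exceed N={N}")
    if n < 0 or m < 0 or k < 0:
        raise ValueError("counts must be non-negative")
    upper = min(n, m)
    if k > upper:
        raise ValueError(f"k={k} exceeds min(n, m)={upper}")
    if k == 0:
        return 1.0
    i = np.arange(k, upper + 1)
    log_terms = (
        _log_comb(n, i)
        + _log_comb(N - n, m - i)
        - _log_comb(N, m)
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    # C(n, k) = 0 outside 0 <= k <= n; callers stay in range by construction
    return np.where((k < 0) | (k > n), -np.inf, out)


def wmm_features(
    compendium: ExperimentCompendium,
    tag: str,
    existing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-pair WMM features for one tagged compendium.

    For every pair co-observed at least once the table carries
    ``neg_ln_pval_<tag>`` (the negative natural log of the hypergeometric
    tail) and ``pair_count_<tag>`` (the co-observation count). Pairs never
    co-observed are absent and treated as missing downstream.

    When ``existing`` is given, the new columns are merged onto it on the
    canonical pair index (outer join); re-using a tag raises.
    """
    col_p = f"neg_ln_pval_{tag}"
    col_k = f"pair_count_{tag}"
    if existing is not None and (col_p in existing.columns or col_k in existing.columns):
        raise ValueError(f"feature name collision: tag {tag!r} already present")

    N = compendium.n_experiments
    protein_experiments: dict = {}
    pair_counts: dict = {}
    for e in compendium.experiments:
        members = sorted(e.proteins)
        for p in members:
            protein_experiments[p] = protein_experiments.get(p, 0) + 1
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                key = (a, b)
                pair_counts[key] = pair_counts.get(key, 0) + 1

    rows = []
    for (a, b), k in sorted(pair_counts.items()):
        n = protein_experiments[a]
        m = protein_experiments[b]
        p = wmm_pvalue(k, n, m, N)
        rows.append((a, b, -np.log(p), k))
    table = pd.DataFrame(rows, columns=["protein_a", "protein_b", col_p, col_k])
    table = table.set_index(["protein_a", "protein_b"])
    if existing is None:
        return table
    return existing.join(table, how="outer")


def feature_table_from_pairs(pairs: Iterable, columns: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Assemble a pair-indexed feature table from parallel columns."""
    idx = pd.MultiIndex.from_tuples(
        [canonical_pair(a, b) for a, b in pairs], names=["protein_a", "protein_b"]
    )
    df = pd.DataFrame(dict(columns), index=idx)
    if df.index.has_duplicates:
        raise ValueError("duplicate pair rows")
    return df


def read_feature_table(path) -> pd.DataFrame:
    """Read a (possibly gzipped) TSV feature matrix keyed by pair."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["protein_a", "protein_b"])


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)
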