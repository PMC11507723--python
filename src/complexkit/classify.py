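"""Co-complex pair classification.

A gradient-boosted classifier is trained on labeled pair features
(positives kept in full, negatives subsampled to a fixed budget), then
applied to every pair in the feature matrix to produce a confidence score
in [0, 1] interpreted as the probability that the two proteins belong to
the same complex. Evaluation is by precision-recall on a leave-out test
set, plus a score-vs-precision calibration table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .goldstd import LabeledPairs
from .pairs import Pair


def balance_training(
    features: pd.DataFrame,
    labels: LabeledPairs,
    n_neg: int = 10_000,
    seed: int = 0,
    impute_value: float = 0.0,
) -> pd.DataFrame:
    """Assemble a balanced training table.

    All labeled positives are kept; negatives are subsampled without
    replacement down to ``n_neg`` (all kept when fewer are available).
    Labeled pairs absent from the feature table still enter the training
    set: their features, like any other missing value, are imputed with
    ``impute_value`` (default 0 = "no evidence") at assembly time. The
    returned table has a ``label`` column (1/0).
    """
    if n_neg < 1:
        raise ValueError("n_neg must be >= 1")
    pos = sorted(labels.positives())
    neg = sorted(labels.negatives())
    if not pos:
        raise ValueError("no labeled positive pairs")
    rng = np.random.default_rng(seed)
    if len(neg) > n_neg:
        chosen = rng.choice(len(neg), size=n_neg, replace=False)
        neg = [neg[i] for i in sorted(chosen)]
    idx = pd.MultiIndex.from_tuples(pos + neg, names=features.index.names)
    rows = features.reindex(idx).fillna(impute_value)
    rows["label"] = [1] * len(pos) + [0] * len(neg)
    return rows


@dataclass
class TrainedScorer:
    """A fitted pair scorer with a frozen feature schema."""

    model: object
    schema: List[str]
    metadata: Dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict_proba(X))[:, 1]


def train_scorer(
    training: pd.DataFrame,
    seed: int = 0,
    learner: str = "xgboost",
    params: Optional[Dict] = None,
) -> TrainedScorer:
    """Fit a gradient-boosted co-complex scorer on a balanced table.

    ``learner`` selects the backend: "xgboost" (default) or
    "sklearn" (scikit-learn's GradientBoostingClassifier). Refitting with
    the same seed and config reproduces identical scores.
    """
    if "label" not in training.columns:
        raise ValueError("training table must carry a 'label' column")
    y = training["label"].to_numpy()
    X = training.drop(columns=["label"])
    schema = list(X.columns)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to train")
    if all(X[c].nunique(dropna=False) <= 1 for c in schema):
        warnings.warn("all features constant; scorer will be uninformative")
    params = dict(params or {})
    if learner == "xgboost":
        from xgboost import XGBClassifier

        defaults = dict(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            tree_method="hist",
        )
        defaults.update(params)
        model = XGBClassifier(**defaults)
    elif learner == "sklearn":
        from sklearn.ensemble import GradientBoostingClassifier

        defaults = dict(n_estimators=200, max_depth=3, random_state=seed)
        defaults.update(params)
        model = GradientBoostingClassifier(**defaults)
    else:
        raise ValueError(f"unknown learner {learner!r}")
    model.fit(X.to_numpy(dtype=float), y)
    meta = {
        "seed": seed,
        "learner": learner,
        "n_pos": int((y == 1).sum()),
        "n_neg": int((y == 0).sum()),
    }
    return TrainedScorer(model, schema, meta)


def score_pairs(
    scorer: TrainedScorer,
    features: pd.DataFrame,
    impute_value: float = 0.0,
    extra_pairs: Optional[Iterable[Pair]] = None,
) -> Dict[Pair, float]:
    """Score every pair in the feature table; returns pair -> score in [0, 1].

    ``extra_pairs`` adds pairs absent from the feature table (e.g. labeled
    evaluation pairs with no experimental evidence); their features are
    imputed like any other missing value.
    """
    missing = [c for c in scorer.schema if c not in features.columns]
    extra = [c for c in features.columns if c not in scorer.schema]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing}, extra={extra}"
        )
    if extra_pairs is not None:
        wanted = pd.MultiIndex.from_tuples(
            sorted(set(map(tuple, features.index)) | set(extra_pairs)),
            names=features.index.names,
        )
        features = features.reindex(wanted)
    X = features[scorer.schema].fillna(impute_value).to_numpy(dtype=float)
    scores = np.clip(scorer.predict_proba(X), 0.0, 1.0)
    return {tuple(idx): float(s) for idx, s in zip(features.index, scores)}


@dataclass
class PRCurve:
    """Precision-recall curve over descending score thresholds."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auprc: float


def precision_recall(scored: Dict[Pair, float], test_labels: LabeledPairs) -> PRCurve:
    """Precision-recall over the labeled pairs present in the scored network.

    The curve walks descending unique score thresholds; the area under it
    is the step-wise (rectangular) integral over recall, which avoids the
    optimism of linear interpolation in PR space.
    """
    y, s = _labeled_scores(scored, test_labels)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("need at least one positive and one negative labeled pair")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    thresholds = np.unique(s)[::-1]
    precisions, recalls = [], []
    tp = np.cumsum(y)
    n_at = np.arange(1, len(y) + 1)
    for t in thresholds:
        cut = np.searchsorted(-s, -t, side="right")  # pairs with score >= t
        precisions.append(tp[cut - 1] / n_at[cut - 1])
        recalls.append(tp[cut - 1] / n_pos)
    precision = np.asarray(precisions, dtype=float)
    recall = np.asarray(recalls, dtype=float)
    auprc = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return PRCurve(precision, recall, thresholds, auprc)


def _labeled_scores(scored, labels: LabeledPairs) -> Tuple[np.ndarray, np.ndarray]:
    pairs = [p for p in labels.labels if p in scored]
    if not pairs:
        raise ValueError("no labeled pair appears in the scored network")
    y = np.array([1 if labels.labels[p] else 0 for p in pairs])
    s = np.array([scored[p] for p in pairs], dtype=float)
    return y, s


def score_precision_calibration(
    scored: Dict[Pair, float],
    test_labels: LabeledPairs,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Empirical precision among labeled pairs scoring at or above each threshold.

    Rows where no labeled pair reaches the threshold report NaN precision.
    """
    for t in thresholds:
        if not 0 <= t <= 1:
            raise ValueError(f"threshold {t} outside [0, 1]")
    y, s = _labeled_scores(scored, test_labels)
    rows = []
    for t in thresholds:
        mask = s >= t
        n = int(mask.sum())
        prec = float(y[mask].mean()) if n else float("nan")
        rows.append({"threshold": t, "precision": prec, "n_at_threshold": n})
    return pd.DataFrame(rows)


def write_scored_network(scored: Dict[Pair, float], path) -> None:
    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(scored.items())],
        columns=["protein_a", "protein_b", "score"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_scored_network(path) -> Dict[Pair, float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(a), str(b)): float(s)
        for a, b, s in zip(df["protein_a"], df["protein_b"], df["score"])
    }
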