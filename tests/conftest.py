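import numpy as np
import pandas as pd
import pytest

import complexkit as ck
from complexkit.simulate import (
    AnnotationSpec,
    CompendiumSpec,
    DimerSpec,
    ExpressionSpec,
    plant_complexes,
    simulate_annotations,
    simulate_compendium,
    simulate_dimer_models,
    simulate_expression,
)


@pytest.fixture(scope="session")
def compendium_fixture():
    """Planted pulldown compendium at the standard study conditions."""
    obs, planted = simulate_compendium(CompendiumSpec(seed=7))
    return obs, planted


@pytest.fixture(scope="session")
def scored_network(compendium_fixture):
    """WMM features -> trained scorer -> scored network, plus the split."""
    obs, planted = compendium_fixture
    comp = ck.filter_compendium(obs, 2.0)
    feats = ck.wmm_features(comp, "sim")
    train, test = ck.split_train_test(planted, seed=1234)
    train_labels, test_labels = ck.label_pairs(train, test)
    table = ck.balance_training(feats, train_labels, n_neg=10_000, seed=0)
    scorer = ck.train_scorer(table, seed=0)
    scored = ck.score_pairs(scorer, feats, extra_pairs=test_labels.labels.keys())
    return {
        "planted": planted,
        "features": feats,
        "train": train,
        "test": test,
        "train_labels": train_labels,
        "test_labels": test_labels,
        "scorer": scorer,
        "scored": scored,
    }


@pytest.fixture(scope="session")
def dimer_fixture():
    instances, truth = simulate_dimer_models(DimerSpec(seed=3))
    return instances, truth


@pytest.fixture(scope="session")
def expression_fixture():
    matrix, lineages, complexes, truth = simulate_expression(ExpressionSpec(seed=11))
    return matrix, lineages, complexes, truth


@pytest.fixture(scope="session")
def annotation_fixture():
    planted = plant_complexes(n_complexes=8, size_range=(4, 7), seed=5)
    annotations, scores, background, expected = simulate_annotations(
        planted, AnnotationSpec(seed=5)
    )
    return planted, annotations, scores, background, expected
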