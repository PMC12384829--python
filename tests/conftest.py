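"""Shared fixtures: one default synthetic cohort, its preprocessed feature
matrix, and the best cross-validated model, all session-scoped because
training and attribution reuse them across test modules."""

from __future__ import annotations

import pytest
from hypothesis import settings

import pdcognet as p
from pdcognet import network as net, preprocessing as prep

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

COHORT_SEED = 0
FOLD_SEED = 0


@pytest.fixture(scope="session")
def cohort() -> p.SyntheticCohort:
    """Default 618-subject cohort, fully observed, fixed seed."""
    return p.generate_cohort(p.default_cohort_spec(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def preprocessed(cohort):
    """(feature matrix, reduced group map, X ndarray, follow-up labels)."""
    Z = prep.standardize(cohort.X_raw)
    fm, gmap, _ = prep.groupwise_pca(Z, cohort.group_map)
    return fm, gmap, fm.values.to_numpy(), cohort.followup_labels


@pytest.fixture(scope="session")
def fold_results(preprocessed):
    fm, gmap, X, y = preprocessed
    plan = p.make_stratified_folds(y, k=5, seed=FOLD_SEED)
    return p.cross_validate(X, net.labels_to_onehot(y), plan)


@pytest.fixture(scope="session")
def best_model(fold_results) -> net.NetworkParams:
    _, params = p.select_best_model(fold_results)
    return params


@pytest.fixture(scope="session")
def toy_net_10() -> net.NetworkParams:
    """Small fixed random network on 10 inputs for attribution oracles."""
    return net.init_network(10, (5,), seed=7)
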