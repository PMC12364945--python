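import numpy as np
import pandas as pd
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def block_truth():
    """Sparse block-diagonal truth (3 clusters, 12 true edges of 45 pairs)."""
    return sn.make_cluster_precision(
        10, [3, 3, 4], within_strength=0.15, between_strength=0.10,
        density_between=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def block_table(block_truth):
    return sn.sample_likert(block_truth, 2000, seed=107)


@pytest.fixture(scope="session")
def strong_truth():
    """Strong block structure for stability checks."""
    return sn.make_cluster_precision(
        10, [3, 3, 4], within_strength=0.25, between_strength=0.10,
        density_between=0.0, seed=2,
    )


@pytest.fixture(scope="session")
def strong_table(strong_truth):
    return sn.sample_likert(strong_truth, 2000, seed=302)


@pytest.fixture(scope="session")
def noise_truth():
    """True empty network: independent items."""
    p = 10
    return sn.SyntheticTruth(
        precision=np.eye(p),
        true_partials=np.zeros((p, p)),
        thresholds=sn.skewed_thresholds(p),
        item_names=[f"item_{k + 1:02d}" for k in range(p)],
    )


@pytest.fixture(scope="session")
def fast_net_config():
    """Shortened penalty path for resampling-heavy checks."""
    return sn.NetworkConfig(n_lambdas=40)


@pytest.fixture
def tiny_table():
    """4 persons x 3 items, fully valid."""
    return sn.SymptomTable(
        person_ids=["a", "b", "c", "d"],
        items=["diarrhea", "fatigue", "anxiety"],
        ratings=np.array([[1, 2, 3], [2, 3, 4], [5, 1, 2], [3, 3, 3]]),
    )


def support_scores(truth, network):
    """(sensitivity, false-positive rate) of an estimated edge support."""
    p = truth.p
    iu = np.triu_indices(p, 1)
    true = truth.support()[iu]
    est = network.edge_mask()[iu]
    sens = (true & est).sum() / true.sum()
    fpr = (~true & est).sum() / (~true).sum()
    return float(sens), float(fpr)
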