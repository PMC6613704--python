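"""Shared fixtures: small synthetic problems and a desk-scale repertoire."""

import numpy as np
import pytest

import cellfrust as cf
from cellfrust.config import RunConfig, _replicated_split, prepare_fold


@pytest.fixture(scope="session")
def iris_like():
    """A 150-row, 3-class, 4-feature dataset with the classic class sizes."""
    rng = np.random.default_rng(7)
    blocks, labels = [], []
    for k, name in enumerate(["setosa", "versicolour", "virginica"]):
        blocks.append(rng.normal(loc=3.0 * k, scale=1.0, size=(50, 4)))
        labels += [name] * 50
    X = np.vstack(blocks)
    return cf.LabeledDataset(X, np.array(labels),
                             ("sl", "sw", "pl", "pw"))


@pytest.fixture(scope="session")
def small_split():
    """Synthetic split small enough for fast unit tests."""
    return cf.generate_synthetic(
        cf.SyntheticConfig(n_features=6, n_normal=120, n_anomalous=30,
                           anomaly_mechanism="outlier", seed=11))


@pytest.fixture(scope="session")
def small_cfg():
    return RunConfig(
        synthetic=cf.SyntheticConfig(n_features=6, n_normal=120,
                                     n_anomalous=30, seed=11),
        N_pop=2, C=12, W_tau=500, T_S=50, W_d=500, t_max=30,
        tau_target=150, folds=1, seed=5)


@pytest.fixture(scope="session")
def small_repertoire(small_split, small_cfg):
    """A desk-scale educated repertoire (36 presenters, 2 populations)."""
    return prepare_fold(small_split, small_cfg, seed=21)


@pytest.fixture(scope="session")
def small_rsplit(small_split):
    rsplit, _ = _replicated_split(small_split, 32)
    return rsplit


@pytest.fixture()
def small_population():
    """An untrained population over 8 constant-free features."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(50, 8))
    mapper = cf.fit_mapper(X)
    return cf.build_population(mapper, C=5, v_max=0.1, seed=13)
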