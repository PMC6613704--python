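"""Dataset loading, splits, replication and the synthetic generator."""

import numpy as np
import pytest
from scipy import stats

import cellfrust as cf
from cellfrust.datasets import replication_factor


# -- load_csv ----------------------------------------------------------------

def test_load_csv_roundtrip(tmp_path, iris_like):
    p = tmp_path / "iris.csv"
    iris_like.to_frame("species").to_csv(p, index=False)
    ds = cf.load_csv(p, "species")
    assert ds.n_features == 4
    assert ds.n_samples == 150
    np.testing.assert_allclose(ds.X, iris_like.X)
    assert set(ds.y) == {"setosa", "versicolour", "virginica"}


def test_load_csv_single_row(tmp_path):
    p = tmp_path / "one.csv"
    p.write_text("a,b,label\n1.5,2.5,ok\n")
    ds = cf.load_csv(p, "label")
    assert ds.n_samples == 1 and ds.n_features == 2


@pytest.mark.parametrize("content,err", [
    ("a,b,label\n1,x,ok\n", "non-numeric"),
    ("a,b\n1,2\n", "label column"),
    ("", "empty"),
])
def test_load_csv_errors(tmp_path, content, err):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(ValueError, match=err):
        cf.load_csv(p, "label")


# -- make_split --------------------------------------------------------------

def test_split_sizes_one_class_normal(iris_like):
    split = cf.make_split(iris_like, {"setosa"}, n_train=17, seed=1)
    assert split.sizes == (17, 33, 100)
    assert set(split.train_normal.y) == {"setosa"}
    assert set(split.test_normal.y) == {"setosa"}
    assert "setosa" not in set(split.test_anomalous.y)


def test_split_partitions_rows(iris_like):
    split = cf.make_split(iris_like, {"setosa", "virginica"}, 40, seed=2)
    assert sum(split.sizes) == iris_like.n_samples


def test_split_all_normals_in_training(iris_like):
    split = cf.make_split(iris_like, {"setosa"}, n_train=50, seed=0)
    assert split.test_normal is None
    assert split.sizes == (50, 0, 100)


def test_split_seed_contract(iris_like):
    a = cf.make_split(iris_like, {"setosa"}, 17, seed=1)
    b = cf.make_split(iris_like, {"setosa"}, 17, seed=2)
    assert a.sizes == b.sizes
    assert not np.array_equal(np.sort(a.train_normal.X[:, 0]),
                              np.sort(b.train_normal.X[:, 0]))


def test_split_errors(iris_like):
    with pytest.raises(ValueError):
        cf.make_split(iris_like, set(), 5, seed=0)
    with pytest.raises(ValueError):
        cf.make_split(iris_like, {"nope"}, 5, seed=0)
    with pytest.raises(ValueError):
        cf.make_split(iris_like, {"setosa"}, 51, seed=0)


# -- replicate_features ------------------------------------------------------

@pytest.mark.parametrize("nf,minp,expected_k", [
    (4, 32, 10),    # smallest even k with 4k > 32
    (60, 32, 1),    # already wide enough
    (32, 32, 2),    # 32 is not > 32, so replicate
])
def test_replication_factor(nf, minp, expected_k, iris_like):
    assert replication_factor(nf, minp) == expected_k


def test_replicate_features_copies_exactly(iris_like):
    wide = cf.replicate_features(iris_like, 32)
    assert wide.n_features == 40
    for m in range(10):
        np.testing.assert_array_equal(wide.X[:, 4 * m: 4 * (m + 1)],
                                      iris_like.X)


def test_replicate_features_noop_when_wide():
    rng = np.random.default_rng(0)
    ds = cf.LabeledDataset(rng.normal(size=(5, 40)), np.zeros(5),
                           tuple(f"f{i}" for i in range(40)))
    assert cf.replicate_features(ds, 32) is ds


# -- monte_carlo_folds -------------------------------------------------------

def test_monte_carlo_folds_resampled(iris_like):
    folds = cf.monte_carlo_folds(iris_like, {"setosa"}, 17, k=10, seed=3)
    assert len(folds) == 10
    assert all(f.sizes == (17, 33, 100) for f in folds)
    first_rows = {tuple(np.sort(f.train_normal.X[:, 0])) for f in folds}
    assert len(first_rows) > 1  # memberships differ between folds


def test_monte_carlo_folds_reproducible(iris_like):
    a = cf.monte_carlo_folds(iris_like, {"setosa"}, 17, k=3, seed=9)
    b = cf.monte_carlo_folds(iris_like, {"setosa"}, 17, k=3, seed=9)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.train_normal.X, fb.train_normal.X)


# -- synthetic generator -----------------------------------------------------

def test_synthetic_outlier_out_of_range():
    cfg = cf.SyntheticConfig(n_features=6, n_normal=100, n_anomalous=40,
                             anomaly_mechanism="outlier", seed=4)
    split = cf.generate_synthetic(cfg)
    Xn = np.vstack([split.train_normal.X, split.test_normal.X])
    lo, hi = Xn.min(axis=0), Xn.max(axis=0)
    outside = (split.test_anomalous.X < lo) | (split.test_anomalous.X > hi)
    assert outside.any(axis=1).all()


def test_synthetic_outlier_magnitude_zero_stays_in_range():
    # degenerate control: the manipulated feature lands exactly on the
    # normal min/max boundary, never outside it
    cfg = cf.SyntheticConfig(n_features=6, n_normal=100, n_anomalous=40,
                             anomaly_mechanism="outlier",
                             anomaly_magnitude=0.0, seed=4)
    split = cf.generate_synthetic(cfg)
    Xn = np.vstack([split.train_normal.X, split.test_normal.X])
    lo, hi = Xn.min(axis=0), Xn.max(axis=0)
    Xa = split.test_anomalous.X
    on_boundary = np.isclose(Xa, lo) | np.isclose(Xa, hi)
    assert on_boundary.any(axis=1).all()
    # out-of-range cells occur no more often than for fresh normal draws
    n_outside = ((Xa < lo) | (Xa > hi)).sum()
    null_rate = 2 / (Xn.shape[0] + 1)
    assert n_outside <= Xa.size * null_rate + 3 * np.sqrt(Xa.size * null_rate)


def test_synthetic_broken_combination_preserves_marginals():
    pairs = ((0, 1, 0.9), (2, 3, 0.9))
    cfg = cf.SyntheticConfig(n_features=4, n_normal=2000, n_anomalous=1000,
                             correlated_pairs=pairs,
                             anomaly_mechanism="broken_combination", seed=8)
    split = cf.generate_synthetic(cfg)
    Xn = np.vstack([split.train_normal.X, split.test_normal.X])
    Xa = split.test_anomalous.X
    for i in range(4):
        d = stats.ks_2samp(Xn[:, i], Xa[:, i]).statistic
        assert d < 0.08, f"marginal {i} shifted (KS={d:.3f})"
    for a, b, rho in pairs:
        r_norm = np.corrcoef(Xn[:, a], Xn[:, b])[0, 1]
        r_anom = np.corrcoef(Xa[:, a], Xa[:, b])[0, 1]
        assert r_norm > 0.8
        assert abs(r_anom) < 0.15


def test_synthetic_excess_absence_shifts_into_tails():
    cfg = cf.SyntheticConfig(n_features=8, n_normal=400, n_anomalous=50,
                             correlated_pairs=(),
                             anomaly_mechanism="excess_absence", seed=5)
    split = cf.generate_synthetic(cfg)
    # per sample, at least ceil(8/4)=2 features must sit in the 2% tails of
    # the standard-normal marginal
    z = stats.norm.ppf(0.02)
    in_tail = (split.test_anomalous.X <= z) | (split.test_anomalous.X >= -z)
    assert (in_tail.sum(axis=1) >= 2).all()


def test_synthetic_seed_determinism():
    cfg = cf.SyntheticConfig(n_features=5, n_normal=50, n_anomalous=20, seed=6)
    a, b = cf.generate_synthetic(cfg), cf.generate_synthetic(cfg)
    np.testing.assert_array_equal(a.train_normal.X, b.train_normal.X)
    np.testing.assert_array_equal(a.test_anomalous.X, b.test_anomalous.X)


def test_synthetic_config_validation():
    with pytest.raises(ValueError, match="mechanism"):
        cf.SyntheticConfig(anomaly_mechanism="nope")
    with pytest.raises(ValueError, match="correlation"):
        cf.SyntheticConfig(correlated_pairs=((0, 1, 1.5),))
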