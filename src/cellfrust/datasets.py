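"""Tabular datasets, semi-supervised splits and synthetic data generation.

The detection task is semi-supervised: only samples from a declared *normal*
class are available for training, and the test pool mixes held-out normal
samples with every sample from the other classes, which play the role of
anomalies.  This module loads labelled CSV tables, builds such splits
(optionally resampled into Monte-Carlo cross-validation folds), widens
narrow tables by feature replication so that the agent population is large
enough to stay dynamically frustrated, and generates synthetic datasets
exercising the three anomaly mechanisms a cellular frustration system can
detect: out-of-range outliers, an excess of simultaneously absent frequent
signals, and broken co-occurrence between correlated features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledDataset",
    "SemiSupervisedSplit",
    "SyntheticConfig",
    "load_csv",
    "make_split",
    "replicate_features",
    "monte_carlo_folds",
    "generate_synthetic",
]


@dataclass(frozen=True)
class LabeledDataset:
    """A numeric feature matrix with one categorical label per row."""

    X: np.ndarray  # (n_samples, n_features) float
    y: np.ndarray  # (n_samples,) labels
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("dataset must have at least one row and one feature")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length does not match X")
        if not np.all(np.isfinite(X)):
            raise ValueError("dataset contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.feature_names)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df[label_column] = self.y
        return df


@dataclass(frozen=True)
class SemiSupervisedSplit:
    """Train-normal / test-normal / test-anomalous partition of a dataset."""

    train_normal: LabeledDataset
    test_normal: Optional[LabeledDataset]
    test_anomalous: LabeledDataset
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        n_tn = self.test_normal.n_samples if self.test_normal is not None else 0
        return (self.train_normal.n_samples, n_tn, self.test_anomalous.n_samples)


def load_csv(path, label_column: str) -> LabeledDataset:
    """Read a header-rowed CSV into a :class:`LabeledDataset`.

    All columns other than ``label_column`` must be numeric.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty CSV") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty CSV")
    if label_column not in df.columns:
        raise ValueError(f"{path}: label column {label_column!r} not found")
    y = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    try:
        X = feats.astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric value in a feature column") from exc
    return LabeledDataset(X, y, tuple(str(c) for c in feats.columns))


def make_split(
    ds: LabeledDataset,
    normal_labels: Sequence,
    n_train: int,
    seed: int,
) -> SemiSupervisedSplit:
    """Draw ``n_train`` normal samples (uniformly, without replacement) for
    training; remaining normal samples become the normal test set and every
    sample with a non-normal label becomes the anomalous test set."""
    normal_labels = set(normal_labels)
    if not normal_labels:
        raise ValueError("normal_labels must be nonempty")
    is_normal = np.isin(ds.y, list(normal_labels))
    n_normal = int(is_normal.sum())
    if n_normal == 0:
        raise ValueError("no sample carries a normal label")
    if n_train > n_normal:
        raise ValueError(f"n_train={n_train} exceeds {n_normal} normal samples")
    rng = np.random.default_rng(seed)
    normal_idx = np.flatnonzero(is_normal)
    train_idx = rng.choice(normal_idx, size=n_train, replace=False)
    train_mask = np.zeros(ds.n_samples, dtype=bool)
    train_mask[train_idx] = True
    test_normal_idx = np.flatnonzero(is_normal & ~train_mask)
    anom_idx = np.flatnonzero(~is_normal)
    test_normal = ds.subset(test_normal_idx) if test_normal_idx.size else None
    return SemiSupervisedSplit(
        train_normal=ds.subset(np.sort(train_idx)),
        test_normal=test_normal,
        test_anomalous=ds.subset(anom_idx),
        seed=seed,
    )


def replicate_features(ds: LabeledDataset, min_presenters: int = 32) -> LabeledDataset:
    """Tile the feature columns until there are more than ``min_presenters``.

    Small feature counts can let the agent population lock into a stable
    matching; widening the table keeps the pairing dynamics frustrated.  The
    columns are tiled ``k`` times with the smallest even ``k`` such that
    ``k * n_features > min_presenters``; tables already wider than
    ``min_presenters`` are returned unchanged.
    """
    if min_presenters < 1:
        raise ValueError("min_presenters must be >= 1")
    nf = ds.n_features
    if nf > min_presenters:
        return ds
    k = 2
    while k * nf <= min_presenters:
        k += 2
    X = np.tile(ds.X, (1, k))
    names = tuple(
        f"{name}#rep{m}" for m in range(k) for name in ds.feature_names
    )
    return LabeledDataset(X, ds.y, names)


def replication_factor(n_features: int, min_presenters: int = 32) -> int:
    """The tiling factor ``replicate_features`` would apply (1 if none)."""
    if n_features > min_presenters:
        return 1
    k = 2
    while k * n_features <= min_presenters:
        k += 2
    return k


def monte_carlo_folds(
    ds: LabeledDataset,
    normal_labels: Sequence,
    n_train: int,
    k: int,
    seed: int,
) -> list[SemiSupervisedSplit]:
    """``k`` independently resampled splits (Monte-Carlo cross-validation).

    Each fold redraws the training subset from scratch; folds are not a
    partition of the normal class.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)
    return [make_split(ds, normal_labels, n_train, int(s)) for s in fold_seeds]


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

MECHANISMS = ("outlier", "excess_absence", "broken_combination")


def _default_distributions(n_features: int) -> tuple:
    return tuple(("gaussian", 0.0, 1.0) for _ in range(n_features))


def _default_pairs(n_features: int) -> tuple:
    n_pairs = min(5, n_features // 2)
    return tuple((2 * i, 2 * i + 1, 0.9) for i in range(n_pairs))


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a synthetic semi-supervised anomaly detection problem.

    Normal samples are drawn from per-feature marginals (``("gaussian", mu,
    sigma)`` or ``("uniform", lo, hi)``) coupled through a Gaussian copula
    carrying the requested pairwise correlations.  Anomalous samples are
    generated by one of three mechanisms:

    ``outlier``
        one randomly chosen feature per sample is pushed outside the normal
        empirical range by ``anomaly_magnitude`` times that range;
    ``excess_absence``
        ``ceil(n_features / 4)`` randomly chosen features per sample are
        simultaneously moved into their 2% marginal tails — each value is
        individually unremarkable, but so many near-absent frequent signals
        at once is atypical;
    ``broken_combination``
        samples are drawn from the normal joint distribution and then the
        second member of each correlated pair is independently permuted
        across samples, preserving every marginal while destroying the
        co-occurrence structure.
    """

    n_features: int = 4
    n_normal: int = 600
    n_anomalous: int = 100
    base_distributions: tuple = None  # type: ignore[assignment]
    correlated_pairs: tuple = None  # type: ignore[assignment]
    anomaly_mechanism: str = "outlier"
    anomaly_magnitude: float = 0.5
    n_train: Optional[int] = None  # default: 2/3 of n_normal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_distributions is None:
            object.__setattr__(
                self, "base_distributions", _default_distributions(self.n_features)
            )
        else:
            object.__setattr__(
                self, "base_distributions", tuple(map(tuple, self.base_distributions))
            )
        if self.correlated_pairs is None:
            object.__setattr__(self, "correlated_pairs", _default_pairs(self.n_features))
        else:
            object.__setattr__(
                self, "correlated_pairs", tuple(map(tuple, self.correlated_pairs))
            )
        if self.n_features < 1 or self.n_normal < 1 or self.n_anomalous < 1:
            raise ValueError("counts must be positive")
        if len(self.base_distributions) != self.n_features:
            raise ValueError("need one distribution spec per feature")
        if self.anomaly_mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.anomaly_mechanism!r}; choose from {MECHANISMS}"
            )
        for a, b, rho in self.correlated_pairs:
            if not (0 <= a < self.n_features and 0 <= b < self.n_features and a != b):
                raise ValueError(f"bad correlated pair ({a}, {b})")
            if not (-1.0 < rho < 1.0):
                raise ValueError("correlation strengths must lie in (-1, 1)")

    @property
    def train_size(self) -> int:
        if self.n_train is not None:
            return self.n_train
        return max(1, (2 * self.n_normal) // 3)


def _marginal_transform(spec, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws onto the requested marginal."""
    kind = spec[0]
    if kind == "gaussian":
        _, mu, sigma = spec
        return mu + sigma * z
    if kind == "uniform":
        _, lo, hi = spec
        return lo + (hi - lo) * stats.norm.cdf(z)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _marginal_quantile(spec, u: np.ndarray) -> np.ndarray:
    kind = spec[0]
    if kind == "gaussian":
        _, mu, sigma = spec
        return mu + sigma * stats.norm.ppf(u)
    if kind == "uniform":
        _, lo, hi = spec
        return lo + (hi - lo) * np.asarray(u)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _draw_joint(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    nf = cfg.n_features
    corr = np.eye(nf)
    for a, b, rho in cfg.correlated_pairs:
        corr[a, b] = corr[b, a] = rho
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlated_pairs yield a non-positive-definite matrix") from exc
    z = rng.standard_normal((n, nf)) @ L.T
    X = np.empty((n, nf))
    for i, spec in enumerate(cfg.base_distributions):
        X[:, i] = _marginal_transform(spec, z[:, i])
    return X


def generate_synthetic(cfg: SyntheticConfig) -> SemiSupervisedSplit:
    """Generate a seed-deterministic :class:`SemiSupervisedSplit`."""
    rng = np.random.default_rng(cfg.seed)
    nf = cfg.n_features
    X_norm = _draw_joint(cfg, cfg.n_normal, rng)

    mech = cfg.anomaly_mechanism
    n_a = cfg.n_anomalous
    if mech == "broken_combination":
        X_anom = _draw_joint(cfg, n_a, rng)
        for _, b, _rho in cfg.correlated_pairs:
            X_anom[:, b] = X_anom[rng.permutation(n_a), b]
    elif mech == "outlier":
        X_anom = _draw_joint(cfg, n_a, rng)
        lo = X_norm.min(axis=0)
        hi = X_norm.max(axis=0)
        span = hi - lo
        feat = rng.integers(0, nf, size=n_a)
        high_side = rng.random(n_a) < 0.5
        for s in range(n_a):
            i = feat[s]
            if high_side[s]:
                X_anom[s, i] = hi[i] + cfg.anomaly_magnitude * span[i]
            else:
                X_anom[s, i] = lo[i] - cfg.anomaly_magnitude * span[i]
    elif mech == "excess_absence":
        X_anom = _draw_joint(cfg, n_a, rng)
        n_shift = math.ceil(nf / 4)
        for s in range(n_a):
            feats = rng.choice(nf, size=n_shift, replace=False)
            for i in feats:
                u = rng.uniform(0.0, 0.02)
                if rng.random() < 0.5:
                    u = 1.0 - u
                X_anom[s, i] = _marginal_quantile(cfg.base_distributions[i], u)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown mechanism {mech!r}")

    names = tuple(f"x{i}" for i in range(nf))
    n_train = cfg.train_size
    train = LabeledDataset(X_norm[:n_train], np.array(["normal"] * n_train), names)
    n_test = cfg.n_normal - n_train
    test_normal = (
        LabeledDataset(X_norm[n_train:], np.array(["normal"] * n_test), names)
        if n_test
        else None
    )
    anom = LabeledDataset(X_anom, np.array(["anomalous"] * n_a), names)
    return SemiSupervisedSplit(train, test_normal, anom, seed=cfg.seed)
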