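"""Feature-to-signal mapping and detector perception of rare/frequent signals.

Each presenter agent ``i`` displays a signal derived from the ``i``-th
feature value of the current sample,

    s_i = i + (x_i - x_min_i) / (x_max_i - x_min_i + eps),

so that signal ranges of distinct presenters are disjoint (``floor(s_i) =
i``).  The training-set extremes and a per-feature empirical CDF ``F_i`` are
the only statistics a detector can use: a detector senses presenter ``i``'s
signal as *rare* when it falls into a one-sided tail of the training
distribution — ``F_i(s) < v`` for a left-sided perception or ``F_i(s) >
1 - v`` for a right-sided one — and as *frequent* otherwise.  The tail
probability ``v`` is drawn per (detector, presenter) edge from
``Uniform(0, v_max)`` and the side equiprobably, so an ensemble of
detectors covers tails of many sizes on both flanks.

Values never seen in training map to ``F = 0`` or ``F = 1`` and are
therefore perceived as rare by every detector with ``v > 0`` on the
matching side: outliers are exactly the signals that were never displayed
during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import LabeledDataset

__all__ = [
    "FeatureMapper",
    "PerceptionMap",
    "MappedSample",
    "fit_mapper",
    "map_sample",
    "draw_perceptions",
    "perceive",
]

LEFT, RIGHT = 0, 1
_EPS = 2.0**-52


@dataclass(frozen=True)
class MappedSample:
    """Per-presenter displayed signals; ``s[i]`` lies in ``[i, i+1)``."""

    s: np.ndarray


@dataclass(frozen=True)
class PerceptionMap:
    """One detector's rare-signal window for one presenter."""

    detector: int
    presenter: int
    side: int  # LEFT or RIGHT
    v: float

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError("side must be LEFT (0) or RIGHT (1)")
        if not 0.0 <= self.v < 1.0:
            raise ValueError("v must lie in [0, 1)")


class FeatureMapper:
    """Training-set extremes and empirical CDFs, fit once on normal data.

    The ECDF convention is right-continuous: ``F(x) = #(train <= x) / n``.
    Test values outside the training range clip into the presenter's signal
    interval and evaluate to ``F = 0`` or ``F = 1``.
    """

    def __init__(self, sorted_train: np.ndarray):
        sorted_train = np.asarray(sorted_train, dtype=float)
        if sorted_train.ndim != 2 or sorted_train.shape[0] < 1:
            raise ValueError("need a nonempty (n_train, n_features) matrix")
        self._sorted = sorted_train
        self.x_min = sorted_train[0]
        self.x_max = sorted_train[-1]
        self.n_train = sorted_train.shape[0]

    @property
    def n_features(self) -> int:
        return self._sorted.shape[1]

    def cdf(self, X: np.ndarray) -> np.ndarray:
        """Evaluate every feature's ECDF at the rows of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError("feature count mismatch")
        out = np.empty_like(X)
        for i in range(self.n_features):
            out[:, i] = np.searchsorted(self._sorted[:, i], X[:, i], side="right")
        return out / self.n_train

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"sorted_train": self._sorted.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMapper":
        return cls(np.asarray(d["sorted_train"], dtype=float))


def fit_mapper(train: LabeledDataset | np.ndarray) -> FeatureMapper:
    """Fit extremes and ECDFs on training rows only."""
    X = train.X if isinstance(train, LabeledDataset) else np.asarray(train, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("empty training set")
    return FeatureMapper(np.sort(X, axis=0))


def map_sample(m: FeatureMapper, x: np.ndarray) -> MappedSample:
    """Map one feature vector onto disjoint presenter signals."""
    x = np.asarray(x, dtype=float)
    if x.shape != (m.n_features,):
        raise ValueError(f"expected {m.n_features} features, got {x.shape}")
    idx = np.arange(m.n_features, dtype=float)
    span = m.x_max - m.x_min
    frac = np.zeros_like(x)
    nz = span > 0
    frac[nz] = (x[nz] - m.x_min[nz]) / (span[nz] * (1.0 + _EPS))
    # out-of-training-range values clip into the presenter's interval
    frac = np.clip(frac, 0.0, np.nextafter(1.0, 0.0))
    return MappedSample(idx + frac)


def draw_perceptions(
    m: FeatureMapper,
    detector: int,
    presenters: Sequence[int],
    v_max: float,
    rng: np.random.Generator,
) -> list[PerceptionMap]:
    """Draw one perception map per connected presenter."""
    if not 0.0 <= v_max < 1.0:
        raise ValueError("v_max must lie in [0, 1)")
    maps = []
    for i in presenters:
        if not 0 <= i < m.n_features:
            raise ValueError(f"presenter index {i} out of range")
        maps.append(
            PerceptionMap(
                detector=detector,
                presenter=int(i),
                side=RIGHT if rng.random() < 0.5 else LEFT,
                v=float(rng.uniform(0.0, v_max)),
            )
        )
    return maps


def perceive(p: PerceptionMap, m: FeatureMapper, s_i: float) -> str:
    """Classify a displayed signal as frequent (``'f'``) or rare (``'r'``).

    ``s_i`` must lie in presenter ``p.presenter``'s signal interval; it is
    converted back to the feature scale before evaluating the ECDF.
    """
    i = p.presenter
    if not i <= s_i < i + 1:
        raise ValueError(f"signal {s_i} outside presenter {i}'s range")
    frac = s_i - i
    span = m.x_max[i] - m.x_min[i]
    x = m.x_min[i] + frac * span * (1.0 + _EPS)
    # guard against 1-ulp round-off in the signal -> feature inversion
    x = np.nextafter(np.nextafter(x, np.inf), np.inf)
    col = m._sorted[:, i]
    F = np.searchsorted(col, x, side="right") / m.n_train
    if p.side == RIGHT:
        return "r" if F > 1.0 - p.v else "f"
    return "r" if F < p.v else "f"
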