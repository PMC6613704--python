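"""Calibration, monitoring with anergy, the response statistic and baselines.

Detection converts pairing lifetimes into scores by kinetic proofreading:
during monitoring any pairing that survives ``tau_A`` iterations is
terminated (anergy), both members' survival counters increment, and the
detector slot is refilled with a random repertoire member.  For presenter
``i`` and sample ``s`` the counters ``c_{i,s}(t)``, ``t = 0..tau_A``, count
contacts surviving at least ``t`` iterations, so the normalized count

    ctilde_{i,s} = c_{i,s}(tau_act) / c_{i,s}(0)

is the fraction of ``i``'s contacts that lasted long enough to activate.
Calibration runs the same dynamics on the normal training samples and sets
per-presenter activation thresholds ``ntilde_i`` at the ``x``-th largest
normalized count over the ``N_c`` calibration samples, ``x = ceil(N_c *
f)``.  A test sample's response is the summed positive excess

    R_s = sum_i max(0, ctilde_{i,s} - ntilde_i),

large when some presenters sustain unusually many long pairings.  Accuracy
is reported as the true-positive rate at a fixed false-positive rate: the
score threshold is the ``ceil(N * FPR)``-th largest normal response and
TPR is the fraction of anomalous responses strictly above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .datasets import SemiSupervisedSplit
from .signals import FeatureMapper
from .training import Repertoire

__all__ = ["DetectionParams", "ContactCounts", "ActivationThresholds",
           "monitor", "calibrate", "response", "score_samples",
           "tpr_at_fpr", "roc_curve",
           "baseline_rare_count", "baseline_ilists_rare_count"]


@dataclass(frozen=True)
class DetectionParams:
    """Monitoring/calibration knobs; defaults follow the standard table."""

    W_d: int = 10_000
    tau_A: int = 5
    tau_act: Optional[int] = None  # default: tau_A
    f: float = 0.1
    FPR: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_A < 2:
            raise ValueError("tau_A must be >= 2 (kinetic proofreading)")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must lie in (0, 1]")
        if not 0.0 < self.FPR < 1.0:
            raise ValueError("FPR must lie in (0, 1)")
        if self.W_d < 1:
            raise ValueError("W_d must be >= 1")

    @property
    def tau_act_(self) -> int:
        return self.tau_A if self.tau_act is None else self.tau_act


@dataclass(frozen=True)
class ContactCounts:
    """Survival counts for one monitored sample."""

    c_p: np.ndarray  # (N, tau_A + 1) presenter-side counts
    c_d: np.ndarray  # (N, tau_A + 1) detector-side counts (diagnostics)

    def normalized(self, tau_act: int) -> np.ndarray:
        """Per-presenter survival fractions ``c(tau_act)/c(0)`` (0 where
        the presenter never paired)."""
        c0 = self.c_p[:, 0].astype(float)
        out = np.zeros(self.c_p.shape[0])
        nz = c0 > 0
        out[nz] = self.c_p[nz, tau_act] / c0[nz]
        return out


@dataclass(frozen=True)
class ActivationThresholds:
    """Calibrated per-presenter thresholds on normalized counts."""

    n_tilde: np.ndarray
    n_cal: int


def monitor(rep: Repertoire, Fv: np.ndarray, params: DetectionParams,
            seed: int | None = None) -> ContactCounts:
    """Run the anergic monitoring dynamics for one sample."""
    pop = rep.pop
    Fv = np.ascontiguousarray(Fv, dtype=float)
    if Fv.shape != (pop.n_presenters,):
        raise ValueError("Fv length must equal the presenter count")
    kseed = params.seed if seed is None else seed
    c_p, c_d = _kernels.run_monitor(
        int(kseed) % (2**31 - 1),
        pop.pref, pop.digit, pop.conn, pop.adj_off, pop.adj_lst,
        pop.v, pop.sideR, rep.rank_f_all, rep.rank_r_all,
        Fv, params.W_d, params.tau_A)
    return ContactCounts(c_p=c_p, c_d=c_d)


def _descending_quantile(values: np.ndarray, fraction: float) -> np.ndarray:
    """The ``ceil(n * fraction)``-th largest entry along axis 0 (1-based)."""
    n = values.shape[0]
    x = max(1, math.ceil(n * fraction))
    return np.sort(values, axis=0)[::-1][x - 1]


def calibrate(rep: Repertoire, cal_X: np.ndarray,
              params: DetectionParams) -> ActivationThresholds:
    """Calibrate activation thresholds on normal (training) samples only."""
    cal_X = np.atleast_2d(np.asarray(cal_X, float))
    n_cal = cal_X.shape[0]
    if n_cal < 1:
        raise ValueError("empty calibration set")
    Fv = rep.pop.mapper.cdf(cal_X)
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(n_cal) % (2**31 - 1)
    ctilde = np.empty((n_cal, rep.pop.n_presenters))
    for s in range(n_cal):
        cc = monitor(rep, Fv[s], params, seed=int(seeds[s]))
        ctilde[s] = cc.normalized(params.tau_act_)
    n_tilde = _descending_quantile(ctilde, params.f)
    return ActivationThresholds(n_tilde=n_tilde, n_cal=n_cal)


def response(cc: ContactCounts, th: ActivationThresholds,
             tau_act: int) -> float:
    """Summed positive excess of normalized counts over the thresholds."""
    ctilde = cc.normalized(tau_act)
    if ctilde.shape != th.n_tilde.shape:
        raise ValueError("presenter sets of counts and thresholds differ")
    return float(np.maximum(ctilde - th.n_tilde, 0.0).sum())


def score_samples(rep: Repertoire, X: np.ndarray, th: ActivationThresholds,
                  params: DetectionParams, seed: int) -> np.ndarray:
    """Monitor every row of ``X`` (fresh repertoire draw per sample) and
    return the response vector."""
    X = np.atleast_2d(np.asarray(X, float))
    Fv = rep.pop.mapper.cdf(X)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(X.shape[0]) % (2**31 - 1)
    R = np.empty(X.shape[0])
    for s in range(X.shape[0]):
        cc = monitor(rep, Fv[s], params, seed=int(seeds[s]))
        R[s] = response(cc, th, params.tau_act_)
    return R


def tpr_at_fpr(normal_scores: Sequence[float], anomalous_scores: Sequence[float],
               fpr: float) -> float:
    """TPR at a fixed FPR: the threshold is the ``ceil(n * FPR)``-th
    largest normal score; anomalies count when strictly above it."""
    normal_scores = np.asarray(normal_scores, float)
    anomalous_scores = np.asarray(anomalous_scores, float)
    if normal_scores.size == 0 or anomalous_scores.size == 0:
        raise ValueError("score lists must be nonempty")
    thr = _descending_quantile(normal_scores, fpr)
    return float(np.mean(anomalous_scores > thr))


def roc_curve(normal_scores, anomalous_scores,
              fpr_grid: Sequence[float] | None = None) -> np.ndarray:
    """Evaluate ``tpr_at_fpr`` over a grid; returns (len(grid), 2) array of
    (FPR, TPR) rows, nondecreasing in FPR."""
    if fpr_grid is None:
        fpr_grid = np.linspace(0.02, 1.0, 50)
    out = np.empty((len(fpr_grid), 2))
    for k, g in enumerate(fpr_grid):
        g = min(max(float(g), 1e-9), 1.0 - 1e-9)
        out[k, 0] = g
        out[k, 1] = tpr_at_fpr(normal_scores, anomalous_scores, g)
    return out


# ---------------------------------------------------------------------------
# counting-rule baselines
# ---------------------------------------------------------------------------

def _rare_counts(mapper: FeatureMapper, X: np.ndarray, tail: float) -> np.ndarray:
    """Per-sample number of features in a two-sided training-tail of size
    ``tail`` (``tail = 0``: strictly outside the training range)."""
    F = mapper.cdf(np.atleast_2d(X))
    X = np.atleast_2d(np.asarray(X, float))
    if tail == 0.0:
        below = X < mapper.x_min
        above = X > mapper.x_max
        return (below | above).sum(axis=1)
    return ((F < tail) | (F > 1.0 - tail)).sum(axis=1)


def baseline_rare_count(mapper: FeatureMapper, split: SemiSupervisedSplit,
                        tail: float = 0.0, fpr: float = 0.1) -> float:
    """TPR of the rule that counts per-sample rare signals (features in the
    ``tail`` tails of the training distribution) and thresholds the count
    at the normal samples' top-``fpr`` quantile."""
    if split.test_normal is None:
        raise ValueError("split has no normal test samples")
    n_norm = _rare_counts(mapper, split.test_normal.X, tail)
    n_anom = _rare_counts(mapper, split.test_anomalous.X, tail)
    return tpr_at_fpr(n_norm, n_anom, fpr)


def _ilist_rare_counts(rep: Repertoire, X: np.ndarray) -> np.ndarray:
    """Per-sample number of (detector, presenter) perceptions mapped to
    rare, using the repertoire's own perception maps."""
    pop = rep.pop
    F = pop.mapper.cdf(np.atleast_2d(X))
    counts = np.zeros(F.shape[0], dtype=int)
    conn_mask = np.zeros_like(pop.v, dtype=bool)
    for j in range(pop.conn.shape[0]):
        conn_mask[j, pop.conn[j]] = True
    for s in range(F.shape[0]):
        Fv = F[s]
        right = conn_mask & pop.sideR & (Fv[None, :] > 1.0 - pop.v)
        left = conn_mask & ~pop.sideR & (Fv[None, :] < pop.v)
        counts[s] = int(right.sum() + left.sum())
    return counts


def baseline_ilists_rare_count(rep: Repertoire, split: SemiSupervisedSplit,
                               fpr: float = 0.1) -> float:
    """TPR of the rule that counts rare perceptions across detector ILists."""
    if split.test_normal is None:
        raise ValueError("split has no normal test samples")
    n_norm = _ilist_rare_counts(rep, split.test_normal.X)
    n_anom = _ilist_rare_counts(rep, split.test_anomalous.X)
    return tpr_at_fpr(n_norm, n_anom, fpr)
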