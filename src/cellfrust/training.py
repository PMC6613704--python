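"""Repertoire education: the IS and AIS training strategies.

Training drives the population toward maximal frustration: any detector
whose pairing lasts longer than an adaptive threshold ``tau_n`` has its
IList modified and is unpaired.  Two strategies are provided:

``IS`` (immunological strategy)
    the educable region of the IList is replaced by a fresh uniform
    permutation — the analogue of deleting a negatively selected T cell and
    drawing a new one;
``AIS`` (artificial-intelligence strategy)
    only the offending token (the one perceived from the long-lived
    partner) is swapped with a uniformly drawn token ranked strictly below
    it, so past corrections are preserved and the offender strictly loses
    rank on every call.

``tau_n`` starts at the window length ``W_tau`` and, at the end of any
window in which no detector was educated, tightens to the largest pairing
age observed in that window; it is therefore nonincreasing.  The displayed
training sample is redrawn uniformly every ``T_S`` iterations so that
corrections reflect many samples rather than one.

Educating the same connectivity ``N_pop`` times with independent RNG
streams yields a repertoire of IList sets that is pooled during detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .core import Population, _init_ilist
from .signals import FeatureMapper

__all__ = ["TrainingParams", "Repertoire", "educate_IS", "educate_AIS",
           "train_population", "build_repertoire", "iterations_to_threshold"]


@dataclass(frozen=True)
class TrainingParams:
    """Education schedule; defaults follow the standard parameter table."""

    strategy: str = "AIS"
    W_tau: int = 10_000
    T_S: int = 100
    t_max: int = 100
    tau_target: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("IS", "AIS"):
            raise ValueError("strategy must be 'IS' or 'AIS'")
        if not self.W_tau >= self.T_S >= 1:
            raise ValueError("require W_tau >= T_S >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


def educate_IS(pop: Population, j: int, seed: int | None = None) -> None:
    """Uniformly re-permute detector ``j``'s educable IList region."""
    if seed is not None:
        _kernels._seed(seed)
    _kernels._educate_is(j, pop.pref, pop.digit, pop.conn,
                         pop.rank_f, pop.rank_r, pop.emax)
    _kernels._update_dr_row(j, pop.conn, pop.rank_f, pop.rank_r,
                            pop.rare, pop.dr)


def educate_AIS(pop: Population, j: int, partner: int,
                seed: int | None = None) -> None:
    """Swap the token ``j`` perceives from ``partner`` strictly downward."""
    if not np.any(pop.conn[j] == partner):
        raise ValueError(f"presenter {partner} not connected to detector {j}")
    if seed is not None:
        _kernels._seed(seed)
    _kernels._educate_ais(j, partner, pop.pref, pop.digit, pop.conn,
                          pop.rank_f, pop.rank_r, pop.rare, pop.emax)
    _kernels._update_dr_row(j, pop.conn, pop.rank_f, pop.rank_r,
                            pop.rare, pop.dr)


def train_population(
    pop: Population,
    Fv_samples: np.ndarray,
    params: TrainingParams,
) -> dict:
    """Educate ``pop``'s ILists in place; returns the training trace.

    ``Fv_samples`` is the (n_samples, N) matrix of per-presenter ECDF
    values of the training samples.  The trace maps window index to the
    ``tau_n`` in force after the window, the number of educations in the
    window (``n_subs``) and the window's maximal pairing age (``tau_nW``).
    """
    Fv_samples = np.ascontiguousarray(Fv_samples, dtype=float)
    if Fv_samples.ndim != 2 or Fv_samples.shape[0] < 1:
        raise ValueError("need at least one training sample")
    if Fv_samples.shape[1] != pop.n_presenters:
        raise ValueError("sample width must equal the presenter count")
    tau_target = -1 if params.tau_target is None else int(params.tau_target)
    (windows, total_iters, iters_to_target,
     tau_n, n_subs, tau_nW) = _kernels.run_training(
        params.seed, params.strategy == "IS",
        pop.pref, pop.digit, pop.conn, pop.adj_off, pop.adj_lst,
        pop.v, pop.sideR, pop.rank_f, pop.rank_r, pop.emax,
        Fv_samples, params.W_tau, params.T_S, params.t_max, tau_target)
    return {
        "windows": int(windows),
        "total_iters": int(total_iters),
        "iters_to_target": None if iters_to_target < 0 else int(iters_to_target),
        "tau_n": np.asarray(tau_n),
        "n_subs": np.asarray(n_subs),
        "tau_nW": np.asarray(tau_nW),
        "W_tau": params.W_tau,
        "strategy": params.strategy,
    }


@dataclass
class Repertoire:
    """``n_pop`` independently educated IList sets over one connectivity."""

    pop: Population                  # template: connectivity + perceptions
    rank_f_all: np.ndarray           # (n_pop, N, N)
    rank_r_all: np.ndarray           # (n_pop, N, N)
    traces: list = field(default_factory=list)
    params: TrainingParams | None = None

    @property
    def n_pop(self) -> int:
        return self.rank_f_all.shape[0]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        p = self.pop
        return {
            "mapper": p.mapper.to_dict() if p.mapper is not None else None,
            "pref": p.pref.tolist(),
            "digit": p.digit.tolist(),
            "conn": p.conn.tolist(),
            "v": p.v.tolist(),
            "sideR": p.sideR.astype(int).tolist(),
            "emax": p.emax.tolist(),
            "seed": p.seed,
            "rank_f_all": self.rank_f_all.tolist(),
            "rank_r_all": self.rank_r_all.tolist(),
            "params": None if self.params is None else {
                "strategy": self.params.strategy,
                "W_tau": self.params.W_tau,
                "T_S": self.params.T_S,
                "t_max": self.params.t_max,
                "tau_target": self.params.tau_target,
                "seed": self.params.seed,
            },
            "traces": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in tr.items()}
                for tr in self.traces
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Repertoire":
        mapper = (FeatureMapper.from_dict(d["mapper"])
                  if d.get("mapper") is not None else None)
        conn = np.asarray(d["conn"], dtype=np.int64)
        N = conn.shape[0]
        cover = [[] for _ in range(N)]
        for j in range(N):
            for i in conn[j]:
                cover[i].append(j)
        adj_off = np.zeros(N + 1, dtype=np.int64)
        for i in range(N):
            adj_off[i + 1] = adj_off[i] + len(cover[i])
        adj_lst = (np.concatenate([np.asarray(c, np.int64) for c in cover])
                   if adj_off[-1] else np.zeros(0, np.int64))
        pop = Population(
            pref=np.asarray(d["pref"], np.int64),
            digit=np.asarray(d["digit"], np.int64),
            conn=conn, adj_off=adj_off, adj_lst=adj_lst,
            v=np.asarray(d["v"], float),
            sideR=np.asarray(d["sideR"], bool),
            rank_f=np.asarray(d["rank_f_all"], np.int64)[0].copy(),
            rank_r=np.asarray(d["rank_r_all"], np.int64)[0].copy(),
            emax=np.asarray(d["emax"], np.int64),
            mapper=mapper, seed=d.get("seed", 0),
        )
        params = None
        if d.get("params"):
            params = TrainingParams(**d["params"])
        rep = cls(pop=pop,
                  rank_f_all=np.asarray(d["rank_f_all"], np.int64),
                  rank_r_all=np.asarray(d["rank_r_all"], np.int64),
                  params=params)
        rep.traces = d.get("traces", [])
        return rep


def build_repertoire(
    pop: Population,
    Fv_samples: np.ndarray,
    params: TrainingParams,
    n_pop: int = 12,
) -> Repertoire:
    """Educate ``n_pop`` IList sets sharing ``pop``'s connectivity and
    perception maps, each from a fresh random initial IList and an
    independent RNG stream."""
    if n_pop < 1:
        raise ValueError("n_pop must be >= 1")
    N = pop.n_presenters
    rank_f_all = np.empty((n_pop, N, N), np.int64)
    rank_r_all = np.empty((n_pop, N, N), np.int64)
    traces = []
    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.generate_state(2 * n_pop) % (2**31 - 1)
    for p in range(n_pop):
        init_rng = np.random.default_rng(int(child_seeds[2 * p]))
        for j in range(N):
            _init_ilist(j, pop.pref, pop.digit, pop.conn,
                        pop.rank_f, pop.rank_r, pop.emax, init_rng)
        member_params = TrainingParams(
            strategy=params.strategy, W_tau=params.W_tau, T_S=params.T_S,
            t_max=params.t_max, tau_target=params.tau_target,
            seed=int(child_seeds[2 * p + 1]))
        traces.append(train_population(pop, Fv_samples, member_params))
        rank_f_all[p] = pop.rank_f
        rank_r_all[p] = pop.rank_r
    return Repertoire(pop=pop, rank_f_all=rank_f_all, rank_r_all=rank_r_all,
                      traces=traces, params=params)


def iterations_to_threshold(trace: dict, tau_target: int) -> Optional[int]:
    """First total-iteration count at which ``tau_n <= tau_target``.

    Returns 0 when the target is at or above the initial threshold
    (``W_tau``), and ``None`` when the trace never reaches it.
    """
    if len(trace["tau_n"]) == 0:
        raise ValueError("empty trace")
    W_tau = trace["W_tau"]
    if tau_target >= W_tau:
        return 0
    hits = np.flatnonzero(np.asarray(trace["tau_n"]) <= tau_target)
    if hits.size == 0:
        return None
    return int((hits[0] + 1) * W_tau)
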