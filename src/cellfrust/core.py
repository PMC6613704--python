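"""Agent population and the one-step frustrated pairing dynamics.

A population holds ``N`` presenter agents (one per feature column, subtypes
I/II balanced so each feature is voiced by both subtypes across replicas)
and ``N`` detector agents (half displaying digit 1, half digit 2).  Each
detector is wired to ``C`` randomly drawn presenters and holds an
interaction list (IList): a total order over the ``2C`` frequent/rare
tokens those presenters can deliver.  Rare tokens of opposite-subtype
presenters are pinned ("frozen") to the bottom ranks — were they educable,
an absent frequent signal could be compensated by the matching rare one and
detection would be blunted.

Presenters prefer detectors displaying their own digit; a presenter of
subtype I paired with a same-subtype detector (digit 1) that in turn ranks
the presenter's token highly is the stable attraction that training must
frustrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .signals import FeatureMapper

__all__ = ["Population", "build_population", "decide", "iterate",
           "survival_histogram", "frustrated_toy_population"]


@dataclass
class Population:
    """Mutable agent-population state (arrays shared with the kernels)."""

    pref: np.ndarray        # (N,) presenter preferred digit, 1 or 2
    digit: np.ndarray       # (N,) detector displayed digit
    conn: np.ndarray        # (N, C) presenters wired to each detector
    adj_off: np.ndarray     # CSR adjacency presenter -> detectors
    adj_lst: np.ndarray
    v: np.ndarray           # (N, N) tail probabilities (connected entries)
    sideR: np.ndarray       # (N, N) True = right tail
    rank_f: np.ndarray      # (N, N) IList rank of the frequent token
    rank_r: np.ndarray      # (N, N) IList rank of the rare token
    emax: np.ndarray        # (N,) last educable rank per detector
    mapper: FeatureMapper | None = None
    seed: int = 0

    # pairing state
    p_part: np.ndarray = field(default=None)  # type: ignore[assignment]
    d_part: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau_d: np.ndarray = field(default=None)  # type: ignore[assignment]
    rare: np.ndarray = field(default=None)  # type: ignore[assignment]
    dr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        N = self.pref.shape[0]
        if self.p_part is None:
            self.p_part = np.full(N, _kernels.ALONE, np.int64)
            self.d_part = np.full(N, _kernels.ALONE, np.int64)
            self.tau_p = np.zeros(N, np.int64)
            self.tau_d = np.zeros(N, np.int64)
            self.rare = np.zeros((N, N), np.bool_)
            self.dr = np.zeros((N, N), np.int64)
        self._order = np.arange(2 * N)

    @property
    def n_presenters(self) -> int:
        return self.pref.shape[0]

    @property
    def connectivity(self) -> int:
        return self.conn.shape[1]

    def set_sample(self, Fv: np.ndarray) -> None:
        """Display a sample, given per-presenter ECDF values."""
        Fv = np.asarray(Fv, dtype=float)
        if Fv.shape != (self.n_presenters,):
            raise ValueError("Fv length must equal the presenter count")
        _kernels._set_sample(Fv, self.conn, self.v, self.sideR,
                             self.rank_f, self.rank_r, self.rare, self.dr)

    def rank_of_presenter(self, j: int, i: int) -> int:
        """Detector ``j``'s rank for presenter ``i``'s current token."""
        if not np.any(self.conn[j] == i):
            raise ValueError(f"presenter {i} not in detector {j}'s connectivity")
        return int(self.dr[j, i])

    def rank_of_digit(self, i: int, d: int) -> int:
        """Presenter ``i``'s rank of a displayed digit (1 = preferred)."""
        if d not in (1, 2):
            raise ValueError("digit must be 1 or 2")
        return 1 if d == self.pref[i] else 2

    def check_matching(self) -> None:
        """Assert partner symmetry and age agreement (test/debug helper)."""
        for i in range(self.n_presenters):
            j = self.p_part[i]
            if j != _kernels.ALONE:
                assert self.d_part[j] == i, "partner pointers asymmetric"
                assert self.tau_p[i] == self.tau_d[j], "pair ages disagree"
        for j in range(self.n_presenters):
            i = self.d_part[j]
            if i != _kernels.ALONE:
                assert self.p_part[i] == j, "partner pointers asymmetric"


def build_population(
    mapper: FeatureMapper,
    C: int,
    v_max: float,
    seed: int,
    subtype: np.ndarray | None = None,
) -> Population:
    """Build a population over ``mapper``'s features with connectivity ``C``.

    ``subtype`` optionally fixes presenter subtypes (values 1/2, balanced);
    by default presenters alternate subtype by index, which balances
    subtypes across the replica blocks produced by feature replication.
    """
    N = mapper.n_features
    if N % 2 != 0:
        raise ValueError("presenter count must be even (balanced subtypes)")
    if not 1 <= C <= N:
        raise ValueError(f"connectivity C={C} must lie in 1..{N}")
    if not 0.0 <= v_max < 1.0:
        raise ValueError("v_max must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    if subtype is None:
        pref = np.where(np.arange(N) % 2 == 0, 1, 2).astype(np.int64)
    else:
        pref = np.asarray(subtype, dtype=np.int64)
        if pref.shape != (N,) or not np.all(np.isin(pref, (1, 2))):
            raise ValueError("subtype must be an (N,) array of 1/2")
        if int((pref == 1).sum()) != N // 2:
            raise ValueError("subtypes must be balanced")
    digit = np.where(np.arange(N) < N // 2, 1, 2).astype(np.int64)

    conn = np.empty((N, C), dtype=np.int64)
    for j in range(N):
        conn[j] = rng.choice(N, size=C, replace=False)

    # CSR adjacency: presenter -> detectors covering it
    cover = [[] for _ in range(N)]
    for j in range(N):
        for i in conn[j]:
            cover[i].append(j)
    adj_off = np.zeros(N + 1, dtype=np.int64)
    for i in range(N):
        adj_off[i + 1] = adj_off[i] + len(cover[i])
    adj_lst = np.concatenate([np.asarray(c, dtype=np.int64) for c in cover]) \
        if adj_off[-1] else np.zeros(0, dtype=np.int64)

    v = np.zeros((N, N))
    sideR = np.zeros((N, N), dtype=np.bool_)
    rank_f = np.zeros((N, N), dtype=np.int64)
    rank_r = np.zeros((N, N), dtype=np.int64)
    emax = np.zeros(N, dtype=np.int64)
    for j in range(N):
        v[j, conn[j]] = rng.uniform(0.0, v_max, size=C) if v_max > 0 else 0.0
        sideR[j, conn[j]] = rng.random(C) < 0.5
        _init_ilist(j, pref, digit, conn, rank_f, rank_r, emax, rng)

    return Population(pref=pref, digit=digit, conn=conn,
                      adj_off=adj_off, adj_lst=adj_lst,
                      v=v, sideR=sideR, rank_f=rank_f, rank_r=rank_r,
                      emax=emax, mapper=mapper, seed=seed)


def _init_ilist(j, pref, digit, conn, rank_f, rank_r, emax, rng) -> None:
    """Random initial IList with frozen rare-opposite tokens at the bottom."""
    C = conn.shape[1]
    same = pref[conn[j]] == digit[j]
    n_frozen = int((~same).sum())
    ne = 2 * C - n_frozen
    emax[j] = ne
    educable_ranks = rng.permutation(ne) + 1
    frozen_ranks = rng.permutation(n_frozen) + ne + 1
    e = f = 0
    for c in range(C):
        i = conn[j, c]
        rank_f[j, i] = educable_ranks[e]
        e += 1
        if same[c]:
            rank_r[j, i] = educable_ranks[e]
            e += 1
        else:
            rank_r[j, i] = frozen_ranks[f]
            f += 1


def decide(pop: Population, i: int, j: int) -> None:
    """Run one pairing decision between presenter ``i`` and detector ``j``."""
    if not np.any(pop.conn[j] == i):
        raise ValueError(f"presenter {i} not in detector {j}'s connectivity")
    _kernels._decide(i, j, pop.pref, pop.digit, pop.dr,
                     pop.p_part, pop.d_part, pop.tau_p, pop.tau_d)


def iterate(pop: Population, n_iter: int = 1, seed: int | None = None) -> None:
    """Run ``n_iter`` global iterations on the current sample."""
    if seed is not None:
        _kernels._seed(seed)
    for _ in range(n_iter):
        _kernels._sweep(pop._order, pop.pref, pop.digit, pop.conn,
                        pop.adj_off, pop.adj_lst, pop.dr,
                        pop.p_part, pop.d_part, pop.tau_p, pop.tau_d)
        _kernels._age_pairs(pop.d_part, pop.tau_p, pop.tau_d)


def survival_histogram(
    pop: Population,
    Fv: np.ndarray,
    n_iter: int,
    max_tau: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Contact-survival counts from a fresh all-alone run.

    Returns ``(counts, max_age)`` where ``counts[j, t]`` is the number of
    detector ``j``'s contacts that survived at least ``t`` iterations (the
    last bin aggregates everything at or beyond ``max_tau`` and is not part
    of the survival curve), and ``max_age`` the largest pairing age seen.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    Fv = np.asarray(Fv, dtype=float)
    c_d, max_age = _kernels.run_dynamics(
        seed, pop.pref, pop.digit, pop.conn, pop.adj_off, pop.adj_lst,
        pop.v, pop.sideR, pop.rank_f, pop.rank_r, Fv, n_iter, max_tau)
    return c_d, int(max_age)


def frustrated_toy_population(n_presenters: int = 32, seed: int = 0) -> Population:
    """The classic two-subtype cyclic-preference population, many copies.

    Detectors displaying digit ``d`` rank all frequent tokens of
    opposite-subtype presenters above every same-subtype token (the fully
    educated ordering), presenters prefer same-digit detectors, and
    ``v = 0`` everywhere, so perceptions are all 'frequent'.  Preferences
    then chase each other in a cycle and no stable matching exists.
    """
    N = n_presenters
    if N % 2 != 0:
        raise ValueError("need an even presenter count")
    rng = np.random.default_rng(seed)
    # full connectivity, v = 0: a mapper with N constant features suffices
    mapper = FeatureMapper(np.zeros((1, N)))
    pop = build_population(mapper, C=N, v_max=0.0, seed=seed)
    # overwrite ILists: opposite-subtype frequent tokens on top
    for j in range(N):
        same = pop.pref[pop.conn[j]] == pop.digit[j]
        opp_f = np.flatnonzero(~same)
        same_idx = np.flatnonzero(same)
        top = rng.permutation(opp_f)
        mid = rng.permutation(same_idx)
        rank = 1
        for c in top:
            pop.rank_f[j, pop.conn[j, c]] = rank
            rank += 1
        for c in mid:
            pop.rank_f[j, pop.conn[j, c]] = rank
            rank += 1
        # rare tokens below all frequent ones (never displayed anyway)
        for c in np.concatenate([same_idx, opp_f]):
            pop.rank_r[j, pop.conn[j, c]] = rank
            rank += 1
    pop.set_sample(np.full(N, 0.5))
    return pop
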