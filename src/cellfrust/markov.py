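"""Absorbing-Markov-chain theory of single-IList education.

The education of one IList is abstracted to a list of ``N`` items, ``N/2``
of each of two types, with absorption once the top ``n`` positions all
hold items of the correct type.  Each time step selects a uniform list
position; selecting an incorrectly ranked item in the top ``n`` sends the
list through a one-step *education* state:

IS (immunological strategy)
    the list is replaced by a fresh random one, so the education state
    ``E`` feeds every waiting state ``W_m`` (``m`` correct items on top)
    with binomial weight ``q_m = C(n, m) / 2^n`` and the absorbing state
    with ``1 / 2^n``;
AIS (artificial-intelligence strategy)
    the selected item is swapped with a uniform item from the ``N - n``
    positions below, so each education state ``E_m`` returns to ``W_m`` or
    advances to ``W_{m+1}``, both with probability 1/2 in the ``N >> n``
    regime (the chain implemented here is this printed approximation; the
    explicit simulator is the finite-``N`` reference).

Waiting states leave for education with ``q_educ = (n - m) / N``.  Expected
absorption times satisfy ``K_i = 1 + sum_j p_ij K_j`` and admit closed
forms:

    K_E^IS      = 2^n + N * sum_{j=0}^{n-1} C(n, j) / (n - j)
    K_{W_m}^IS  = K_E^IS + N / (n - m)
    K_{W_m}^AIS = 2 (n - m) + 2 N * sum_{j=m}^{n-1} 1 / (n - j)

The IS closed form carries an ``n > 1`` annotation in its derivation but
evaluates consistently at ``n = 1`` (``K_E = 2 + N``, confirmed by the
linear solve), so it is exposed for ``n >= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from numba import njit

__all__ = ["MarkovSpec", "transition_matrix", "absorption_times_solve",
           "K_E_IS", "K_W_IS", "K_W_AIS", "simulate_education"]


@dataclass(frozen=True)
class MarkovSpec:
    """(strategy, n, N): educate the top ``n`` ranks of an ``N``-item list."""

    strategy: str
    n: int
    N: int

    def __post_init__(self) -> None:
        if self.strategy not in ("IS", "AIS"):
            raise ValueError("strategy must be 'IS' or 'AIS'")
        if not 1 <= self.n <= self.N // 2:
            raise ValueError("require 1 <= n <= N/2 (two item types, N/2 each)")

    @property
    def states(self) -> tuple[str, ...]:
        n = self.n
        if self.strategy == "IS":
            return ("E",) + tuple(f"W{m}" for m in range(n)) + ("S",)
        out: list[str] = []
        for m in range(n):
            out += [f"W{m}", f"E{m}"]
        return tuple(out) + ("S",)


def transition_matrix(spec: MarkovSpec) -> np.ndarray:
    """Row-stochastic transition matrix over ``spec.states`` (absorbing
    state last)."""
    n, N = spec.n, spec.N
    if spec.strategy == "IS":
        # states: [E, W_0 .. W_{n-1}, S]
        size = n + 2
        P = np.zeros((size, size))
        for m in range(n):
            P[0, 1 + m] = comb(n, m) / 2**n
        P[0, size - 1] = 1 / 2**n
        for m in range(n):
            q = (n - m) / N
            P[1 + m, 0] = q
            P[1 + m, 1 + m] = 1 - q
        P[size - 1, size - 1] = 1.0
        return P
    # AIS states: [W_0, E_0, W_1, E_1, ..., W_{n-1}, E_{n-1}, S]
    size = 2 * n + 1
    P = np.zeros((size, size))
    for m in range(n):
        w, e = 2 * m, 2 * m + 1
        q = (n - m) / N
        P[w, e] = q
        P[w, w] = 1 - q
        P[e, w] = 0.5
        nxt = 2 * (m + 1) if m + 1 < n else size - 1
        P[e, nxt] = 0.5
    P[size - 1, size - 1] = 1.0
    return P


def absorption_times_solve(P: np.ndarray) -> np.ndarray:
    """Expected steps to absorption from each transient state.

    ``P`` must be row-stochastic with exactly one absorbing state (last
    row), reachable from every transient state; solves
    ``(I - Q) K = 1`` (fundamental-matrix method).
    """
    P = np.asarray(P, float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("P rows must sum to 1")
    absorbing = np.isclose(np.diag(P), 1.0)
    if absorbing.sum() != 1:
        raise ValueError("expected exactly one absorbing state")
    t = ~absorbing
    Q = P[np.ix_(t, t)]
    A = np.eye(Q.shape[0]) - Q
    try:
        K = np.linalg.solve(A, np.ones(Q.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError("absorbing state unreachable from some state") from exc
    if not np.all(np.isfinite(K)) or np.any(K < 0):
        raise ValueError("absorbing state unreachable from some state")
    return K


def K_E_IS(n: int, N: int) -> float:
    """Closed-form expected absorption time from the IS education state."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0**n + N * sum(comb(n, j) / (n - j) for j in range(n))


def K_W_IS(m: int, n: int, N: int) -> float:
    """Closed-form IS absorption time from waiting state ``W_m``."""
    if not 0 <= m < n:
        raise ValueError("require 0 <= m < n")
    return K_E_IS(n, N) + N / (n - m)


def K_W_AIS(m: int, n: int, N: int) -> float:
    """Closed-form AIS absorption time from waiting state ``W_m``."""
    if not 0 <= m <= n - 1 or n < 1:
        raise ValueError("require 0 <= m <= n-1, n >= 1")
    return 2.0 * (n - m) + 2.0 * N * sum(1.0 / (n - j) for j in range(m, n))


@njit(cache=True)
def _simulate_lists(strategy_is, n, N, reps, seed, finite_pool):
    """Explicit list-process simulator; returns per-rep absorption steps.

    Item type 1 is 'correct'.  Start state is ``W_0`` (top ``n`` all
    incorrect).  Each selection costs one step; a triggered education
    costs one further step (the chain's pass through an education state).
    IS education draws a fresh list: by default each position is filled
    from an unlimited pool (type 1 with probability 1/2), matching
    negative selection's replacement by a brand-new detector and making
    the IS chain exact; ``finite_pool`` instead permutes the existing
    ``N/2 + N/2`` items (hypergeometric top compositions, biased relative
    to the chain at small ``N``).  AIS always swaps within the finite
    list.
    """
    out = np.empty(reps, np.int64)
    np.random.seed(seed)
    arr = np.empty(N, np.int64)
    for r in range(reps):
        # W_0: top n incorrect; below: all N/2 correct, N/2 - n incorrect
        for q in range(n):
            arr[q] = 0
        for q in range(n, n + N // 2):
            arr[q] = 1
        for q in range(n + N // 2, N):
            arr[q] = 0
        # shuffle the below-top region
        for t in range(N - 1, n, -1):
            u = n + np.random.randint(0, t - n + 1)
            tmp = arr[t]
            arr[t] = arr[u]
            arr[u] = tmp
        m = 0
        steps = 0
        while m < n:
            steps += 1
            pos = np.random.randint(0, N)
            if pos < n and arr[pos] == 0:
                steps += 1  # the education state occupies one iteration
                if strategy_is:
                    if finite_pool:
                        for t in range(N - 1, 0, -1):
                            u = np.random.randint(0, t + 1)
                            tmp = arr[t]
                            arr[t] = arr[u]
                            arr[u] = tmp
                    else:
                        for q in range(N):
                            arr[q] = np.random.randint(0, 2)
                else:
                    q = n + np.random.randint(0, N - n)
                    tmp = arr[pos]
                    arr[pos] = arr[q]
                    arr[q] = tmp
                m = 0
                for q in range(n):
                    m += arr[q]
        out[r] = steps
    return out


def simulate_education(strategy: str, n: int, N: int, reps: int,
                       seed: int = 0, finite_pool: bool = False
                       ) -> tuple[float, float]:
    """Monte-Carlo mean and standard error of steps to full correction,
    starting from ``W_0``.  ``n = 0`` absorbs immediately."""
    if strategy not in ("IS", "AIS"):
        raise ValueError("strategy must be 'IS' or 'AIS'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n == 0:
        return 0.0, 0.0
    MarkovSpec(strategy, n, N)  # validate n, N
    steps = _simulate_lists(strategy == "IS", n, N, reps,
                            int(seed) % (2**31 - 1), finite_pool)
    mean = float(steps.mean())
    se = float(steps.std() / np.sqrt(reps))
    return mean, se
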