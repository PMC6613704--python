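"""Population construction and the frustrated pairing decision dynamics."""

import itertools

import numpy as np
import pytest

import cellfrust as cf
from cellfrust import _kernels


# ---------------------------------------------------------------------------
# brute-force oracle for the pairing decision rule
# ---------------------------------------------------------------------------

def oracle_decide(state, i, j, pref, digit, det_rank):
    """Independent reference implementation of the four-branch rule.

    ``state`` maps are (p_part, d_part, tau_p, tau_d) lists; returns the
    updated copies.  Presenters rank detectors by displayed digit only;
    ``det_rank[j][i]`` is detector ``j``'s rank of presenter ``i``'s
    current token.
    """
    p_part, d_part, tau_p, tau_d = (list(x) for x in state)
    pr = lambda jj: 1 if digit[jj] == pref[i] else 2

    def pair():
        p_part[i] = j
        d_part[j] = i
        tau_p[i] = tau_d[j] = 0

    if p_part[i] == j:
        pass
    elif p_part[i] is None and d_part[j] is None:
        pair()
    elif p_part[i] is not None and d_part[j] is None:
        k = p_part[i]
        if pr(j) < pr(k):
            tau_p[i] = tau_d[k] = 0
            d_part[k] = None
            pair()
    elif p_part[i] is None and d_part[j] is not None:
        k = d_part[j]
        if det_rank[j][i] < det_rank[j][k]:
            tau_d[j] = tau_p[k] = 0
            p_part[k] = None
            pair()
    else:
        k, p = p_part[i], d_part[j]
        if pr(j) < pr(k) and det_rank[j][i] < det_rank[j][p]:
            d_part[k] = None
            p_part[p] = None
            tau_p[i] = tau_d[j] = tau_d[k] = tau_p[p] = 0
            pair()
    return p_part, d_part, tau_p, tau_d


def _run_kernel_decide(n, matching, i, j, pref, digit, det_rank):
    p_part = np.full(n, -1, np.int64)
    d_part = np.full(n, -1, np.int64)
    tau_p = np.zeros(n, np.int64)
    tau_d = np.zeros(n, np.int64)
    for (pi, dj) in matching:
        p_part[pi] = dj
        d_part[dj] = pi
        tau_p[pi] = tau_d[dj] = 5
    dr = np.zeros((n, n), np.int64)
    for jj in range(n):
        for ii in range(n):
            dr[jj, ii] = det_rank[jj][ii]
    _kernels._decide(i, j, np.asarray(pref, np.int64),
                     np.asarray(digit, np.int64), dr,
                     p_part, d_part, tau_p, tau_d)
    return p_part, d_part, tau_p, tau_d


def _oracle_state(n, matching):
    p_part = [None] * n
    d_part = [None] * n
    tau_p = [0] * n
    tau_d = [0] * n
    for (pi, dj) in matching:
        p_part[pi] = dj
        d_part[dj] = pi
        tau_p[pi] = tau_d[dj] = 5
    return p_part, d_part, tau_p, tau_d


def _assert_states_equal(kernel_state, oracle_state):
    p_part, d_part, tau_p, tau_d = kernel_state
    op, od, otp, otd = oracle_state
    np.testing.assert_array_equal(
        p_part, [x if x is not None else -1 for x in op])
    np.testing.assert_array_equal(
        d_part, [x if x is not None else -1 for x in od])
    np.testing.assert_array_equal(tau_p, otp)
    np.testing.assert_array_equal(tau_d, otd)


MATCHINGS_2 = [(), ((0, 0),), ((0, 1),), ((1, 0),), ((1, 1),),
               ((0, 0), (1, 1)), ((0, 1), (1, 0))]


def test_decide_matches_oracle_exhaustive_two_per_side():
    """Exhaustive truth-table check over all 2x2 configurations."""
    for pref in itertools.product((1, 2), repeat=2):
        for digit in itertools.product((1, 2), repeat=2):
            for r0 in ([1, 2], [2, 1]):
                for r1 in ([1, 2], [2, 1]):
                    det_rank = (r0, r1)
                    for matching in MATCHINGS_2:
                        for i, j in itertools.product(range(2), range(2)):
                            got = _run_kernel_decide(
                                2, matching, i, j, pref, digit, det_rank)
                            want = oracle_decide(
                                _oracle_state(2, matching), i, j,
                                pref, digit, det_rank)
                            _assert_states_equal(got, want)


def test_decide_matches_oracle_random_four_per_side():
    """Randomized check on 4-agents-per-side configurations."""
    rng = np.random.default_rng(17)
    for _ in range(2000):
        pref = rng.integers(1, 3, size=4)
        digit = rng.integers(1, 3, size=4)
        det_rank = [list(rng.permutation(4) + 1) for _ in range(4)]
        pres = list(rng.permutation(4))
        dets = list(rng.permutation(4))
        matching = tuple((pres[k], dets[k])
                         for k in range(rng.integers(0, 5)))
        i, j = int(rng.integers(4)), int(rng.integers(4))
        got = _run_kernel_decide(4, matching, i, j, pref, digit, det_rank)
        want = oracle_decide(_oracle_state(4, matching), i, j,
                             pref, digit, det_rank)
        _assert_states_equal(got, want)


def test_equal_digit_never_causes_switch():
    # presenter paired with a digit-1 detector never leaves for another
    # digit-1 detector (presenters cannot distinguish equal digits)
    got = _run_kernel_decide(2, ((0, 0),), 0, 1,
                             pref=(1, 1), digit=(1, 1),
                             det_rank=([1, 2], [1, 2]))
    assert got[0][0] == 0  # still paired with detector 0
    assert got[3][0] == 5  # age untouched


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

def test_build_population_structure(small_population):
    pop = small_population
    N = pop.n_presenters
    assert N == 8
    assert (pop.pref == 1).sum() == N // 2
    assert (pop.digit == 1).sum() == N // 2
    C = pop.connectivity
    for j in range(N):
        assert len(set(pop.conn[j])) == C
        ranks = ([pop.rank_f[j, i] for i in pop.conn[j]]
                 + [pop.rank_r[j, i] for i in pop.conn[j]])
        assert sorted(ranks) == list(range(1, 2 * C + 1))
        # frozen bottom: rare tokens of opposite-subtype presenters
        for i in pop.conn[j]:
            if pop.pref[i] != pop.digit[j]:
                assert pop.rank_r[j, i] > pop.emax[j]


def test_build_population_seed_determinism():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 6))
    mapper = cf.fit_mapper(X)
    a = cf.build_population(mapper, C=4, v_max=0.05, seed=9)
    b = cf.build_population(mapper, C=4, v_max=0.05, seed=9)
    np.testing.assert_array_equal(a.conn, b.conn)
    np.testing.assert_array_equal(a.rank_f, b.rank_f)
    np.testing.assert_array_equal(a.v, b.v)


def test_build_population_validation():
    mapper = cf.fit_mapper(np.zeros((2, 4)))
    with pytest.raises(ValueError):
        cf.build_population(mapper, C=5, v_max=0.05, seed=0)  # C > N
    with pytest.raises(ValueError):
        cf.build_population(mapper, C=2, v_max=1.5, seed=0)


def test_rank_accessors(small_population):
    pop = small_population
    i = int(pop.conn[0][0])
    assert pop.rank_of_digit(i, int(pop.pref[i])) == 1
    assert pop.rank_of_digit(i, 3 - int(pop.pref[i])) == 2
    pop.set_sample(np.full(pop.n_presenters, 0.5))
    r = pop.rank_of_presenter(0, i)
    assert 1 <= r <= 2 * pop.connectivity
    with pytest.raises(ValueError):
        pop.rank_of_presenter(0, int(
            next(x for x in range(8) if x not in pop.conn[0])))


# ---------------------------------------------------------------------------
# iteration dynamics
# ---------------------------------------------------------------------------

def test_iterate_preserves_matching_invariant(small_population):
    pop = small_population
    pop.set_sample(np.full(pop.n_presenters, 0.5))
    for _ in range(20):
        cf.iterate(pop, 5)
        pop.check_matching()


def test_iterate_ages_start_at_one(small_population):
    pop = small_population
    pop.set_sample(np.full(pop.n_presenters, 0.5))
    cf.iterate(pop, 1, seed=3)
    paired = pop.d_part >= 0
    assert paired.any()
    assert np.all(pop.tau_d[paired] == 1)


def test_toy_population_is_frustrated():
    pop = cf.frustrated_toy_population(32, seed=0)
    _, max_age = cf.survival_histogram(
        pop, np.full(32, 0.5), n_iter=2000, seed=1)
    assert max_age < 200


def test_survival_histogram_nonincreasing(small_population):
    pop = small_population
    Fv = np.full(pop.n_presenters, 0.5)
    counts, max_age = cf.survival_histogram(pop, Fv, 2000, max_tau=50, seed=2)
    surv = counts[:, :-1]  # last bin aggregates ages >= max_tau
    assert (np.diff(surv, axis=1) <= 0).all()
    assert max_age >= 0


def test_survival_decay_educated_vs_untrained(small_repertoire, small_rsplit):
    # educated populations show near-exponential contact-survival decay;
    # untrained ones keep heavier tails (quasi-stable pairings)
    rep = small_repertoire
    mapper = rep.pop.mapper
    Fv = mapper.cdf(small_rsplit.train_normal.X[:1])[0]
    counts_tr, ma_tr = cf.survival_histogram(rep.pop, Fv, 5000,
                                             max_tau=100, seed=3)
    pop_un = cf.build_population(mapper, C=12, v_max=0.05, seed=99)
    _, ma_un = cf.survival_histogram(pop_un, Fv, 5000, max_tau=100, seed=3)
    assert ma_un > ma_tr
    tot = counts_tr.sum(axis=0).astype(float)
    taus = np.arange(1, 31)
    y = np.log(tot[1:31])
    A = np.vstack([taus, np.ones_like(taus)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    r2 = 1 - res[0] / ((y - y.mean()) ** 2).sum()
    assert coef[0] < 0          # decaying
    assert r2 > 0.9             # close to log-linear


def test_dynamics_seed_determinism(small_population):
    pop = small_population
    Fv = np.full(pop.n_presenters, 0.5)
    a, ma = cf.survival_histogram(pop, Fv, 500, seed=4)
    b, mb = cf.survival_histogram(pop, Fv, 500, seed=4)
    np.testing.assert_array_equal(a, b)
    assert ma == mb


def test_decide_requires_connectivity(small_population):
    pop = small_population
    free = next(x for x in range(8) if x not in pop.conn[0])
    with pytest.raises(ValueError):
        cf.decide(pop, free, 0)
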