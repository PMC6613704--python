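"""Numba kernels for the frustrated pairing dynamics.

State layout (all arrays indexed by presenter ``i`` in ``0..N-1`` and
detector ``j`` in ``0..N-1``):

``pref[i]``      presenter subtype as its preferred detector digit (1 or 2)
``digit[j]``     digit displayed by detector ``j`` (1 or 2)
``conn[j, c]``   the ``C`` presenters detector ``j`` may interact with
``adj_off/adj_lst``  CSR adjacency presenter -> detectors covering it
``v, sideR``     per (j, i) tail probability and side (True = right tail)
``rank_f/rank_r[j, i]``  current IList rank (1 = top) of the frequent /
                 rare token presenter ``i`` delivers to detector ``j``
``emax[j]``      last educable rank; ranks above are the frozen bottom
                 (rare tokens of opposite-subtype presenters)
``rare[j, i]``   whether ``j`` perceives ``i``'s current signal as rare
``dr[j, i]``     rank of the currently perceived token (the sample view)
``p_part/d_part``  partner indices (-1 = alone); ``tau_p/tau_d`` pair ages

A global iteration visits all ``2N`` agents in a fresh random order; each
visited agent draws one uniform counterpart from its interaction set and
the four-branch pairing decision runs.  Ages of all intact pairs then
increment by one.
"""

import numpy as np
from numba import njit

ALONE = -1


@njit(cache=True)
def _seed(seed):
    """Seed the kernels' RNG stream from Python."""
    np.random.seed(seed)


@njit(cache=True)
def _decide(i, j, pref, digit, dr, p_part, d_part, tau_p, tau_d):
    """One pairing decision between presenter ``i`` and detector ``j``.

    Branches: both alone -> pair; one paired -> switch on the paired
    agent's strict preference for the newcomer; both paired -> switch only
    if both strictly prefer each other.  Every broken pair has its ages
    reset to zero.
    """
    pi = p_part[i]
    dj = d_part[j]
    if pi == j:
        return  # already paired with each other; no strict preference fires
    if pi == ALONE and dj == ALONE:
        p_part[i] = j
        d_part[j] = i
        tau_p[i] = 0
        tau_d[j] = 0
    elif pi != ALONE and dj == ALONE:
        # presenter compares displayed digits; ties never cause a switch
        ri_new = 1 if digit[j] == pref[i] else 2
        ri_cur = 1 if digit[pi] == pref[i] else 2
        if ri_new < ri_cur:
            d_part[pi] = ALONE
            tau_d[pi] = 0
            p_part[i] = j
            d_part[j] = i
            tau_p[i] = 0
            tau_d[j] = 0
    elif pi == ALONE and dj != ALONE:
        if dr[j, i] < dr[j, dj]:
            p_part[dj] = ALONE
            tau_p[dj] = 0
            p_part[i] = j
            d_part[j] = i
            tau_p[i] = 0
            tau_d[j] = 0
    else:
        ri_new = 1 if digit[j] == pref[i] else 2
        ri_cur = 1 if digit[pi] == pref[i] else 2
        if ri_new < ri_cur and dr[j, i] < dr[j, dj]:
            d_part[pi] = ALONE
            tau_d[pi] = 0
            p_part[dj] = ALONE
            tau_p[dj] = 0
            p_part[i] = j
            d_part[j] = i
            tau_p[i] = 0
            tau_d[j] = 0


@njit(cache=True)
def _sweep(order, pref, digit, conn, adj_off, adj_lst, dr,
           p_part, d_part, tau_p, tau_d):
    """One global iteration: every agent, in fresh random order, draws one
    uniform counterpart and the decision function runs."""
    n_agents = order.shape[0]
    N = pref.shape[0]
    C = conn.shape[1]
    # Fisher-Yates refresh of the visiting order
    for t in range(n_agents - 1, 0, -1):
        u = np.random.randint(0, t + 1)
        tmp = order[t]
        order[t] = order[u]
        order[u] = tmp
    for a in range(n_agents):
        idx = order[a]
        if idx < N:
            i = idx
            deg = adj_off[i + 1] - adj_off[i]
            if deg == 0:
                continue  # presenter covered by no detector
            j = adj_lst[adj_off[i] + np.random.randint(0, deg)]
        else:
            j = idx - N
            i = conn[j, np.random.randint(0, C)]
        _decide(i, j, pref, digit, dr, p_part, d_part, tau_p, tau_d)


@njit(cache=True)
def _age_pairs(d_part, tau_p, tau_d):
    for j in range(d_part.shape[0]):
        i = d_part[j]
        if i != ALONE:
            tau_d[j] += 1
            tau_p[i] += 1


@njit(cache=True)
def _set_sample(Fv, conn, v, sideR, rank_f, rank_r, rare, dr):
    """Recompute perceived tokens and their ranks for a new sample."""
    Nd, C = conn.shape
    for j in range(Nd):
        for c in range(C):
            i = conn[j, c]
            F = Fv[i]
            if sideR[j, i]:
                r = F > 1.0 - v[j, i]
            else:
                r = F < v[j, i]
            rare[j, i] = r
            dr[j, i] = rank_r[j, i] if r else rank_f[j, i]


@njit(cache=True)
def _update_dr_row(j, conn, rank_f, rank_r, rare, dr):
    C = conn.shape[1]
    for c in range(C):
        i = conn[j, c]
        dr[j, i] = rank_r[j, i] if rare[j, i] else rank_f[j, i]


@njit(cache=True)
def _educate_is(j, pref, digit, conn, rank_f, rank_r, emax):
    """Immunological strategy: re-permute the educable region uniformly.

    The frozen bottom (rare tokens of opposite-subtype presenters) keeps
    its ranks; the remaining ``emax[j]`` tokens receive a fresh uniform
    permutation of ranks ``1..emax[j]``.
    """
    C = conn.shape[1]
    ne = emax[j]
    ranks = np.empty(ne, np.int64)
    # gather current educable ranks in a fixed slot order
    pos = 0
    for c in range(C):
        i = conn[j, c]
        ranks[pos] = rank_f[j, i]
        pos += 1
        if pref[i] == digit[j]:
            ranks[pos] = rank_r[j, i]
            pos += 1
    # Fisher-Yates on the rank values
    for t in range(ne - 1, 0, -1):
        u = np.random.randint(0, t + 1)
        tmp = ranks[t]
        ranks[t] = ranks[u]
        ranks[u] = tmp
    pos = 0
    for c in range(C):
        i = conn[j, c]
        rank_f[j, i] = ranks[pos]
        pos += 1
        if pref[i] == digit[j]:
            rank_r[j, i] = ranks[pos]
            pos += 1


@njit(cache=True)
def _educate_ais(j, k, pref, digit, conn, rank_f, rank_r, rare, emax):
    """AI strategy: swap the token perceived from long-lived partner ``k``
    with a uniformly drawn token ranked strictly below it (within the
    educable region).  Degenerate case (token already at the last educable
    rank): no swap; the unpairing alone removes the stable pair."""
    r0 = rank_r[j, k] if rare[j, k] else rank_f[j, k]
    ne = emax[j]
    if r0 >= ne:
        return
    p = np.random.randint(r0 + 1, ne + 1)
    C = conn.shape[1]
    # find the token currently holding rank p and give it rank r0
    for c in range(C):
        i = conn[j, c]
        if rank_f[j, i] == p:
            rank_f[j, i] = r0
            break
        if pref[i] == digit[j] and rank_r[j, i] == p:
            rank_r[j, i] = r0
            break
    if rare[j, k]:
        rank_r[j, k] = p
    else:
        rank_f[j, k] = p


@njit(cache=True)
def run_training(seed, strategy_is,
                 pref, digit, conn, adj_off, adj_lst,
                 v, sideR, rank_f, rank_r, emax,
                 Fv_samples, W_tau, T_S, t_max, tau_target):
    """Repertoire education: adaptive pairing-duration threshold tau_n.

    Runs up to ``t_max`` windows of ``W_tau`` iterations.  The displayed
    sample is redrawn uniformly every ``T_S`` iterations.  After each
    iteration every detector paired for ``tau >= tau_n`` is educated
    (strategy IS or AIS), unpaired and counted; at a window's end, if no
    detector was educated and the window's maximal pairing age fell below
    ``tau_n``, the threshold tightens to that maximum.  Training stops
    early once ``tau_n <= tau_target`` (pass a negative target to disable).

    Returns ``(windows_used, total_iters, iters_to_target, tau_n_trace,
    nsubs_trace, taunw_trace)``; ``iters_to_target`` is -1 if the target
    was never reached.  ``rank_f``/``rank_r`` are educated in place.
    """
    np.random.seed(seed)
    N = pref.shape[0]
    Nd = digit.shape[0]
    n_samples = Fv_samples.shape[0]

    p_part = np.full(N, ALONE, np.int64)
    d_part = np.full(Nd, ALONE, np.int64)
    tau_p = np.zeros(N, np.int64)
    tau_d = np.zeros(Nd, np.int64)
    rare = np.zeros((Nd, N), np.bool_)
    dr = np.zeros((Nd, N), np.int64)
    order = np.arange(2 * N)

    tau_n = W_tau
    tau_n_trace = np.zeros(t_max, np.int64)
    nsubs_trace = np.zeros(t_max, np.int64)
    taunw_trace = np.zeros(t_max, np.int64)
    total_iters = 0
    iters_to_target = -1

    s_idx = np.random.randint(0, n_samples)
    _set_sample(Fv_samples[s_idx], conn, v, sideR, rank_f, rank_r, rare, dr)

    windows = 0
    for t in range(t_max):
        N_subs = 0
        tau_nW = 0
        for tw in range(1, W_tau + 1):
            if tw % T_S == 0:
                s_idx = np.random.randint(0, n_samples)
                _set_sample(Fv_samples[s_idx], conn, v, sideR,
                            rank_f, rank_r, rare, dr)
            _sweep(order, pref, digit, conn, adj_off, adj_lst, dr,
                   p_part, d_part, tau_p, tau_d)
            for j in range(Nd):
                if d_part[j] != ALONE and tau_d[j] >= tau_n:
                    k = d_part[j]
                    if strategy_is:
                        _educate_is(j, pref, digit, conn, rank_f, rank_r, emax)
                    else:
                        _educate_ais(j, k, pref, digit, conn,
                                     rank_f, rank_r, rare, emax)
                    _update_dr_row(j, conn, rank_f, rank_r, rare, dr)
                    p_part[k] = ALONE
                    tau_p[k] = 0
                    d_part[j] = ALONE
                    tau_d[j] = 0
                    N_subs += 1
            for j in range(Nd):
                if tau_d[j] > tau_nW:
                    tau_nW = tau_d[j]
            _age_pairs(d_part, tau_p, tau_d)
        total_iters += W_tau
        if N_subs == 0 and tau_nW < tau_n:
            tau_n = tau_nW
        tau_n_trace[t] = tau_n
        nsubs_trace[t] = N_subs
        taunw_trace[t] = tau_nW
        windows = t + 1
        if tau_target >= 0 and tau_n <= tau_target:
            iters_to_target = total_iters
            break
    return (windows, total_iters, iters_to_target,
            tau_n_trace[:windows], nsubs_trace[:windows], taunw_trace[:windows])


@njit(cache=True)
def run_monitor(seed,
                pref, digit, conn, adj_off, adj_lst,
                v, sideR, rank_f_all, rank_r_all,
                Fv, W_d, tau_A):
    """Monitoring with anergy, one sample, ``W_d`` iterations.

    Each detector slot starts with a uniformly drawn repertoire member.
    Any pairing reaching age ``tau_A`` is terminated, both members'
    survival counters increment at ``tau_A``, and the slot is refilled by a
    fresh random member (same connectivity).  Each intact pair increments
    its members' counters at the pair's current age and then ages by one,
    so ``c[., 0]`` counts contact events and ``c[., t]`` contacts that
    survived at least ``t`` iterations.

    Returns ``(c_p, c_d)`` with shapes ``(N, tau_A + 1)`` and
    ``(Nd, tau_A + 1)``.
    """
    np.random.seed(seed)
    N = pref.shape[0]
    Nd = digit.shape[0]
    P = rank_f_all.shape[0]

    p_part = np.full(N, ALONE, np.int64)
    d_part = np.full(Nd, ALONE, np.int64)
    tau_p = np.zeros(N, np.int64)
    tau_d = np.zeros(Nd, np.int64)
    rare = np.zeros((Nd, N), np.bool_)
    dr = np.zeros((Nd, N), np.int64)
    order = np.arange(2 * N)
    member = np.empty(Nd, np.int64)
    for j in range(Nd):
        member[j] = np.random.randint(0, P)

    # rare depends only on the perception maps (shared by all members)
    C = conn.shape[1]
    for j in range(Nd):
        for c in range(C):
            i = conn[j, c]
            F = Fv[i]
            if sideR[j, i]:
                rare[j, i] = F > 1.0 - v[j, i]
            else:
                rare[j, i] = F < v[j, i]
        m = member[j]
        for c in range(C):
            i = conn[j, c]
            dr[j, i] = rank_r_all[m, j, i] if rare[j, i] else rank_f_all[m, j, i]

    c_p = np.zeros((N, tau_A + 1), np.int64)
    c_d = np.zeros((Nd, tau_A + 1), np.int64)

    for tw in range(W_d):
        _sweep(order, pref, digit, conn, adj_off, adj_lst, dr,
               p_part, d_part, tau_p, tau_d)
        for j in range(Nd):
            if d_part[j] != ALONE and tau_d[j] >= tau_A:
                i = d_part[j]
                c_p[i, tau_A] += 1
                c_d[j, tau_A] += 1
                p_part[i] = ALONE
                tau_p[i] = 0
                d_part[j] = ALONE
                tau_d[j] = 0
                m = np.random.randint(0, P)
                member[j] = m
                for c in range(C):
                    ii = conn[j, c]
                    dr[j, ii] = (rank_r_all[m, j, ii] if rare[j, ii]
                                 else rank_f_all[m, j, ii])
        for j in range(Nd):
            i = d_part[j]
            if i != ALONE:
                c_p[i, tau_d[j]] += 1
                c_d[j, tau_d[j]] += 1
        _age_pairs(d_part, tau_p, tau_d)
    return c_p, c_d


@njit(cache=True)
def run_dynamics(seed,
                 pref, digit, conn, adj_off, adj_lst,
                 v, sideR, rank_f, rank_r,
                 Fv, n_iter, max_tau):
    """Plain frustrated dynamics (no education, no anergy) for diagnostics.

    Returns ``(c_d, max_age)``: per-detector contact-survival counts capped
    at ``max_tau`` and the largest pairing age observed anywhere.
    """
    np.random.seed(seed)
    N = pref.shape[0]
    Nd = digit.shape[0]
    p_part = np.full(N, ALONE, np.int64)
    d_part = np.full(Nd, ALONE, np.int64)
    tau_p = np.zeros(N, np.int64)
    tau_d = np.zeros(Nd, np.int64)
    rare = np.zeros((Nd, N), np.bool_)
    dr = np.zeros((Nd, N), np.int64)
    order = np.arange(2 * N)
    _set_sample(Fv, conn, v, sideR, rank_f, rank_r, rare, dr)

    c_d = np.zeros((Nd, max_tau + 1), np.int64)
    max_age = 0
    for tw in range(n_iter):
        _sweep(order, pref, digit, conn, adj_off, adj_lst, dr,
               p_part, d_part, tau_p, tau_d)
        for j in range(Nd):
            i = d_part[j]
            if i != ALONE:
                a = tau_d[j]
                if a > max_age:
                    max_age = a
                c_d[j, min(a, max_tau)] += 1
        _age_pairs(d_part, tau_p, tau_d)
    return c_d, max_age
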