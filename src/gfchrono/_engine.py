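"""Numba core of the two-deme structured-coalescent simulator.

Time runs backwards in generations.  A demography is flattened into epochs
``[t0, t1)`` with, per epoch: a symmetric per-lineage migration rate ``m``,
deme sizes at the epoch start ``N_d`` (diploid) with backward exponential
rates ``b_d`` (``N_d(tau) = N_d * exp(b_d * (tau - t0))``), and a merged
flag (all lineages collapse into deme 0 of the ancestral size).  Within an
epoch, event times for the three competing processes (coalescence in each
deme, migration) are drawn independently from their own hazards — exact
for competing independent clocks — and capped at the epoch boundary.
Coalescence hazard for k lineages in a deme of diploid size N(tau) is
C(k,2) / (2 N(tau)); the time-varying integrated hazard is inverted in
closed form.

Randomness comes from an inlined xorshift128+ stream seeded per replicate
via splitmix64, so replicate r of a likelihood evaluation always consumes
the same random sequence for a given base seed (common random numbers)
without the cost of re-initialising a Mersenne state per genealogy.
"""

import numpy as np
from numba import njit

_INF = 1e300
_U64 = np.uint64
_DNORM = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = _U64(x) + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _unif(state):
    """Uniform (0, 1] draw from xorshift128+ state (length-2 uint64)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << _U64(23)
    state[1] = s1 ^ s0 ^ (s1 >> _U64(17)) ^ (s0 >> _U64(26))
    u = (state[1] + s0) >> _U64(11)
    return (np.float64(u) + 1.0) * _DNORM


@njit(cache=True, inline="always")
def _init_state(seed, rep):
    state = np.empty(2, dtype=np.uint64)
    base = _U64(seed) ^ (_U64(rep) * _U64(0x9E3779B97F4A7C15))
    state[0] = _splitmix64(base)
    state[1] = _splitmix64(base + _U64(1))
    if state[0] == _U64(0) and state[1] == _U64(0):
        state[0] = _U64(1)
    return state


@njit(cache=True, inline="always")
def _coal_wait(kd, n_start, b, t0, tau, state):
    """Waiting time to next coalescence among kd lineages, from time tau.

    Hazard lam(u) = a * exp(-b * u) with a = C(kd,2) / (2 N(tau)).
    Returns _INF when the (decaying) hazard never accumulates enough mass.
    """
    if kd < 2:
        return _INF
    n_tau = n_start * np.exp(b * (tau - t0))
    a = kd * (kd - 1) / 2.0 / (2.0 * n_tau)
    e = -np.log(_unif(state))
    if abs(b) < 1e-300:
        return e / a
    # integrated hazard A(s) = a*(1 - exp(-b s))/b ; solve A(s) = e
    arg = 1.0 - b * e / a
    if arg <= 0.0:
        return _INF
    return -np.log(arg) / b


@njit(cache=True)
def _simulate_one(k1, k2, ep_t0, ep_t1, ep_m, ep_n1, ep_b1, ep_n2, ep_b2,
                  ep_merged, tally, state):
    """One genealogy; adds branch lengths into ``tally`` (k1+1, k2+1).

    A lineage's descendant configuration is constant over its lifespan, so
    its branch length is credited once, at its death (coalescence); the
    final (MRCA) lineage subtends the whole sample and is not credited.
    Returns (total_tree_length, tmrca) in generations.
    """
    n_act = k1 + k2
    deme = np.empty(n_act, dtype=np.int64)
    di = np.empty(n_act, dtype=np.int64)
    dj = np.empty(n_act, dtype=np.int64)
    birth = np.zeros(n_act, dtype=np.float64)
    for i in range(k1):
        deme[i] = 0
        di[i] = 1
        dj[i] = 0
    for i in range(k2):
        deme[k1 + i] = 1
        di[k1 + i] = 0
        dj[k1 + i] = 1

    tau = 0.0
    e = 0
    total_len = 0.0
    if ep_merged[e] == 1:
        for i in range(n_act):
            deme[i] = 0

    while n_act > 1:
        while tau >= ep_t1[e]:
            e += 1
            if ep_merged[e] == 1:
                for i in range(n_act):
                    deme[i] = 0

        ka = 0
        for i in range(n_act):
            if deme[i] == 0:
                ka += 1
        kb = n_act - ka

        s0 = _coal_wait(ka, ep_n1[e], ep_b1[e], ep_t0[e], tau, state)
        s1 = _coal_wait(kb, ep_n2[e], ep_b2[e], ep_t0[e], tau, state)
        m = ep_m[e]
        if m > 0.0 and ep_merged[e] == 0:
            sm = -np.log(_unif(state)) / (n_act * m)
        else:
            sm = _INF

        cap = ep_t1[e] - tau
        s = s0
        ev = 0
        if s1 < s:
            s = s1
            ev = 1
        if sm < s:
            s = sm
            ev = 2
        if s >= cap:
            # no event before the epoch boundary
            total_len += n_act * cap
            tau = ep_t1[e]
            continue

        total_len += n_act * s
        tau += s

        if ev == 2:
            # migration: uniform over lineages, flip deme
            pick = int(_unif(state) * n_act)
            if pick >= n_act:
                pick = n_act - 1
            deme[pick] = 1 - deme[pick]
        else:
            # coalescence in deme ev: uniform pair
            kd = ka if ev == 0 else kb
            r1 = int(_unif(state) * kd)
            if r1 >= kd:
                r1 = kd - 1
            r2 = int(_unif(state) * (kd - 1))
            if r2 >= kd - 1:
                r2 = kd - 2
            if r2 >= r1:
                r2 += 1
            # map within-deme ranks to lineage indices
            ia = -1
            ib = -1
            rank = 0
            for i in range(n_act):
                if deme[i] == ev:
                    if rank == r1:
                        ia = i
                    if rank == r2:
                        ib = i
                    rank += 1
            # credit both children's branches; the parent reuses slot ia
            tally[di[ia], dj[ia]] += tau - birth[ia]
            tally[di[ib], dj[ib]] += tau - birth[ib]
            di[ia] += di[ib]
            dj[ia] += dj[ib]
            birth[ia] = tau
            last = n_act - 1
            deme[ib] = deme[last]
            di[ib] = di[last]
            dj[ib] = dj[last]
            birth[ib] = birth[last]
            n_act -= 1

    return total_len, tau


@njit(cache=True)
def _mean_tally(n_reps, seed, k1, k2, ep_t0, ep_t1, ep_m, ep_n1, ep_b1,
                ep_n2, ep_b2, ep_merged):
    """Mean branch-length tally over replicates.

    Replicate r draws from an independent stream derived from (seed, r), so
    the result is deterministic in (seed, n_reps) and replicate streams are
    shared across calls with the same seed (common random numbers).
    """
    acc = np.zeros((k1 + 1, k2 + 1))
    tot = 0.0
    for r in range(n_reps):
        state = _init_state(seed, r)
        tl, _ = _simulate_one(k1, k2, ep_t0, ep_t1, ep_m, ep_n1, ep_b1,
                              ep_n2, ep_b2, ep_merged, tally=acc,
                              state=state)
        tot += tl
    return acc / n_reps, tot / n_reps
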