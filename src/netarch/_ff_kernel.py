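"""Numba kernels for forest-fire likelihood estimation and reversal.

The FF likelihood of a candidate (node v, anchor u) is estimated by Monte
Carlo: on the graph with v absent, simulate fires from u and count the
fraction whose burned set equals N(v) \\ {u} exactly.  Simulations abort
the moment they burn a node outside the target set, so a simulation's
trace depends only on the adjacency of {u} plus the target set.  That
locality makes the incremental cache exact: after removing node r, only
candidates (v', u') with v' within distance 2 of r or u' adjacent to r
can change, so everything else is provably stale-free.

Each candidate owns an RNG substream derived from (run seed, v, u) with a
splitmix64 mix, so estimates are reproducible and independent of the
order in which candidates are (re)computed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _splitmix(state):
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    z = z ^ (z >> U64(31))
    return state, z


@njit(cache=True, inline="always")
def _u01(state):
    state, z = _splitmix(state)
    # 53-bit mantissa uniform in (0, 1]
    return state, (np.float64(z >> U64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _randint(state, n):
    state, z = _splitmix(state)
    return state, np.int64(z % U64(n))


@njit(cache=True, inline="always")
def _geometric(state, p):
    """x ~ Geometric with P(x=k) = p^k (1-p), support {0,1,...}, mean p/(1-p)."""
    if p <= 0.0:
        return state, np.int64(0)
    state, u = _u01(state)
    return state, np.int64(np.log(u) / np.log(p))


@njit(cache=True)
def candidate_seed(base_seed, v, u):
    """Deterministic per-candidate substream seed (kept below 2**63 so the
    value survives a round trip through Python integers)."""
    s = U64(base_seed)
    s, _ = _splitmix(s + U64(v + 1) * U64(0x9E3779B1))
    s, z = _splitmix(s + U64(u + 1) * U64(0x85EBCA77))
    return z & U64(0x7FFFFFFFFFFFFFFF)


@njit(cache=True)
def estimate_candidate(A, active, v, u, p, n_sims, stream_seed,
                       stamp, queue, scratch, elig0, picks, token0):
    """Fraction of ``n_sims`` fires from ``u`` (with ``v`` absent) whose
    burned set equals N(v) \\ {u} exactly.

    ``stamp``/``queue``/``scratch``/``elig0``/``picks`` are caller-provided
    work arrays of length n; ``token0`` is a fresh stamp token base (caller
    advances it by n_sims between calls).  The anchor's eligible-neighbor
    list is identical across simulations, so it is collected once; deeper
    fire levels (rare for the burn probabilities in use) rescan adjacency.
    A simulation aborts as soon as it burns a node outside the target set.
    """
    n = A.shape[0]
    # Target set: neighbors of v other than u.
    tsize = 0
    for j in range(n):
        if A[v, j] != 0 and active[j] and j != u and j != v:
            tsize += 1
    target = A[v]  # row of v; chosen nodes are always active and != u, v
    # Level-1 eligible neighbors of the anchor (v absent), fixed across sims.
    ne0 = 0
    for j in range(n):
        if A[u, j] != 0 and active[j] and j != v:
            elig0[ne0] = j
            ne0 += 1
    state = U64(stream_seed)
    successes = 0
    for s in range(n_sims):
        token = token0 + s
        stamp[u] = token
        stamp[v] = token  # v is absent
        burned = 0
        qhead = 0
        qtail = 0
        ok = True
        state, x = _geometric(state, p)
        if x > 0 and ne0 > 0:
            if x >= ne0:
                for t in range(ne0):
                    c = elig0[t]
                    if target[c] == 0:
                        ok = False
                        break
                    stamp[c] = token
                    burned += 1
                    queue[qtail] = c
                    qtail += 1
            else:
                for t in range(x):
                    # rejection sampling of distinct indices (x is small)
                    while True:
                        state, r = _randint(state, ne0)
                        dup = False
                        for q in range(t):
                            if picks[q] == r:
                                dup = True
                                break
                        if not dup:
                            break
                    picks[t] = r
                    c = elig0[r]
                    if target[c] == 0:
                        ok = False
                        break
                    stamp[c] = token
                    burned += 1
                    queue[qtail] = c
                    qtail += 1
        # deeper levels: breadth-first spread from the level-1 burns
        while qhead < qtail and ok:
            w = queue[qhead]
            qhead += 1
            state, x = _geometric(state, p)
            if x <= 0:
                continue
            ne = 0
            for j in range(n):
                if A[w, j] != 0 and active[j] and stamp[j] != token:
                    scratch[ne] = j
                    ne += 1
            if ne == 0:
                continue
            take = ne if x >= ne else np.int64(x)
            # partial Fisher-Yates over scratch[0:ne]
            for t in range(take):
                state, r = _randint(state, ne - t)
                idx = t + r
                c = scratch[idx]
                scratch[idx] = scratch[t]
                scratch[t] = c
                if target[c] == 0:
                    ok = False
                    break
                stamp[c] = token
                burned += 1
                queue[qtail] = c
                qtail += 1
        if ok and burned == tsize:
            successes += 1
    return successes / n_sims


@njit(cache=True)
def ff_reverse_kernel(A, p, n_sims, base_seed, tie_seed, use_cache):
    """Greedy FF reversal of the graph encoded by adjacency matrix ``A``.

    Returns (removed, anchors, estimates, fallback) index arrays of length
    n-1.  ``estimates`` holds the winning candidate's likelihood estimate
    (0.0 on fallback steps).  With ``use_cache`` the per-candidate
    estimates are maintained incrementally under the exact distance-2
    dirty rule; otherwise everything is recomputed each step.
    """
    n = A.shape[0]
    A = A.copy()
    active = np.ones(n, np.bool_)
    est = np.full((n, n), -1.0)
    removed = np.empty(n - 1, np.int64)
    anchors = np.empty(n - 1, np.int64)
    estimates = np.zeros(n - 1, np.float64)
    fallback = np.zeros(n - 1, np.bool_)

    stamp = np.full(n, -1, np.int64)
    queue = np.empty(n, np.int64)
    scratch = np.empty(n, np.int64)
    elig0 = np.empty(n, np.int64)
    picks = np.empty(n, np.int64)
    token = np.int64(1)
    tie_state = U64(tie_seed)

    b1 = np.zeros(n, np.bool_)
    b2 = np.zeros(n, np.bool_)

    for step in range(n - 1):
        # (re)compute estimates for dirty candidates
        for v in range(n):
            if not active[v]:
                continue
            for u in range(n):
                if A[v, u] == 0 or not active[u]:
                    continue
                if est[v, u] < 0.0 or not use_cache:
                    seed_vu = candidate_seed(base_seed, v, u)
                    est[v, u] = estimate_candidate(
                        A, active, v, u, p, n_sims, seed_vu,
                        stamp, queue, scratch, elig0, picks, token)
                    token += n_sims
        # pick the best candidate (ties uniform at random)
        best = 0.0
        ties = 0
        for v in range(n):
            if not active[v]:
                continue
            for u in range(n):
                if A[v, u] == 0 or not active[u]:
                    continue
                e = est[v, u]
                if e > best:
                    best = e
                    ties = 1
                elif e == best and e > 0.0:
                    ties += 1
        if best > 0.0:
            tie_state, pick = _randint(tie_state, ties)
            sel_v = -1
            sel_u = -1
            k = 0
            for v in range(n):
                if sel_v >= 0 or not active[v]:
                    continue
                for u in range(n):
                    if A[v, u] == 0 or not active[u]:
                        continue
                    if est[v, u] == best:
                        if k == pick:
                            sel_v = v
                            sel_u = u
                            break
                        k += 1
            removed[step] = sel_v
            anchors[step] = sel_u
            estimates[step] = best
        else:
            # no candidate has positive estimated likelihood: random removal
            n_active = 0
            for j in range(n):
                if active[j]:
                    n_active += 1
            tie_state, pick = _randint(tie_state, n_active)
            sel_v = -1
            k = 0
            for j in range(n):
                if active[j]:
                    if k == pick:
                        sel_v = j
                        break
                    k += 1
            # anchor: random neighbor if any, else random other active node
            degv = 0
            for j in range(n):
                if A[sel_v, j] != 0 and active[j]:
                    degv += 1
            if degv > 0:
                tie_state, pick = _randint(tie_state, degv)
                k = 0
                sel_u = -1
                for j in range(n):
                    if A[sel_v, j] != 0 and active[j]:
                        if k == pick:
                            sel_u = j
                            break
                        k += 1
            else:
                tie_state, pick = _randint(tie_state, n_active - 1)
                k = 0
                sel_u = -1
                for j in range(n):
                    if active[j] and j != sel_v:
                        if k == pick:
                            sel_u = j
                            break
                        k += 1
            removed[step] = sel_v
            anchors[step] = sel_u
            estimates[step] = 0.0
            fallback[step] = True

        # mark dirty candidates: v' within distance 2 of sel_v, u' adjacent
        if use_cache:
            for j in range(n):
                b1[j] = A[sel_v, j] != 0 and active[j]
            b1[sel_v] = True
            for j in range(n):
                if not active[j]:
                    b2[j] = False
                    continue
                if b1[j]:
                    b2[j] = True
                    continue
                hit = False
                for k2 in range(n):
                    if A[j, k2] != 0 and b1[k2]:
                        hit = True
                        break
                b2[j] = hit
            for vp in range(n):
                if not active[vp]:
                    continue
                if b2[vp]:
                    for up in range(n):
                        est[vp, up] = -1.0
                else:
                    for up in range(n):
                        if b1[up]:
                            est[vp, up] = -1.0

        # remove sel_v
        active[sel_v] = False
        for j in range(n):
            A[sel_v, j] = 0
            A[j, sel_v] = 0
    return removed, anchors, estimates, fallback
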