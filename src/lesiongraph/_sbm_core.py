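"""Numba kernels for layered weighted SBM description-length minimisation.

The description length (in nats) of a layered weighted graph under a flat
partition ``b`` with ``B`` non-empty blocks of sizes ``n_r`` is

    S = S_partition + sum_l sum_{r<=s} [ placement(l, r, s) + weights(l, r, s) ]

with

* ``S_partition = ln N + ln C(N-1, B-1) + ln N! - sum_r ln n_r!`` — the cost
  of encoding the number of blocks, their sizes (a composition of N) and the
  node-to-block assignment given the sizes;
* ``placement = ln(N_rs + 1) + ln C(N_rs + m - 1, m)`` — encoding the layer-l
  entry count ``m`` between blocks r and s and the placement of those
  entries over the ``N_rs`` available node pairs (multiset code, so the
  layer-randomised null's duplicated pairs stay well defined);
* ``weights`` — a conjugate normal-inverse-gamma code for the layer-l entry
  values in the group, quantised at resolution DELTA.  Every entry value is
  a min-max rescaled weight in [0, 1], so a common real-valued code keeps
  layered and null description lengths directly comparable.

All kernels treat exactly two layers.  State is kept as dense per-block-pair
sufficient statistics (entry count M, value sum S1, value sum of squares S2)
with canonical index [layer, min(r,s), max(r,s)].
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Conjugate prior for the per-group Gaussian weight code: values live in
# [0, 1], so centre 0.5 with prior scale 0.25; one pseudo-observation.
MU0 = 0.5
KAPPA0 = 1.0
ALPHA0 = 1.0
BETA0 = 0.0625  # ALPHA0 * 0.25**2
DELTA = 0.01  # weight quantisation resolution (1% of the rescaled range)

_LN2PI = math.log(2.0 * math.pi)
_LN_DINV = -math.log(DELTA)
_LGA0 = math.lgamma(ALPHA0)


@njit(cache=True)
def _gauss_code(m: float, s1: float, s2: float) -> float:
    """Code length of m quantised values with sum s1 and sum-of-squares s2."""
    if m <= 0:
        return 0.0
    kn = KAPPA0 + m
    an = ALPHA0 + 0.5 * m
    mean = s1 / m
    ssq = s2 - s1 * mean
    if ssq < 0.0:
        ssq = 0.0
    bn = BETA0 + 0.5 * ssq + KAPPA0 * m * (mean - MU0) ** 2 / (2.0 * kn)
    lnp = (
        math.lgamma(an)
        - _LGA0
        + ALPHA0 * math.log(BETA0)
        - an * math.log(bn)
        + 0.5 * (math.log(KAPPA0) - math.log(kn))
        - 0.5 * m * _LN2PI
    )
    return -lnp + m * _LN_DINV


@njit(cache=True)
def _pair_term(r, s, sizes, M, S1, S2):
    """Placement + weight code for block pair (r, s), summed over layers."""
    nr = sizes[r]
    ns = sizes[s]
    if r == s:
        npairs = nr * (nr - 1) // 2
    else:
        npairs = nr * ns
    lo, hi = (r, s) if r <= s else (s, r)
    total = 0.0
    for l in range(2):
        m = M[l, lo, hi]
        if m == 0:
            total += math.log(npairs + 1.0)
        else:
            total += math.log(npairs + 1.0)
            # multiset placement: ln C(npairs + m - 1, m)
            total += (
                math.lgamma(npairs + m) - math.lgamma(m + 1.0) - math.lgamma(npairs)
            )
            total += _gauss_code(m, S1[l, lo, hi], S2[l, lo, hi])
    return total


@njit(cache=True)
def _partition_code(n_nodes, sizes, b_hi):
    n_blocks = 0
    lg_sizes = 0.0
    for r in range(b_hi):
        if sizes[r] > 0:
            n_blocks += 1
            lg_sizes += math.lgamma(sizes[r] + 1.0)
    # ln N  +  ln C(N-1, B-1)  +  ln N! - sum ln n_r!
    comp = (
        math.lgamma(n_nodes + 0.0)
        - math.lgamma(n_blocks + 0.0)
        - math.lgamma(n_nodes - n_blocks + 1.0)
        if n_blocks > 1
        else 0.0
    )
    return math.log(n_nodes + 0.0) + comp + math.lgamma(n_nodes + 1.0) - lg_sizes


@njit(cache=True)
def _full_entropy(n_nodes, sizes, M, S1, S2, b_hi):
    total = _partition_code(n_nodes, sizes, b_hi)
    for r in range(b_hi):
        if sizes[r] == 0:
            continue
        for s in range(r, b_hi):
            if sizes[s] == 0:
                continue
            total += _pair_term(r, s, sizes, M, S1, S2)
    return total


@njit(cache=True)
def _build_stats(b, ent_u, ent_v, ent_l, ent_w, sizes, M, S1, S2):
    sizes[:] = 0
    M[:, :, :] = 0.0
    S1[:, :, :] = 0.0
    S2[:, :, :] = 0.0
    for i in range(b.shape[0]):
        sizes[b[i]] += 1
    for e in range(ent_u.shape[0]):
        r = b[ent_u[e]]
        s = b[ent_v[e]]
        lo, hi = (r, s) if r <= s else (s, r)
        l = ent_l[e]
        w = ent_w[e]
        M[l, lo, hi] += 1.0
        S1[l, lo, hi] += w
        S2[l, lo, hi] += w * w


@njit(cache=True)
def _shift_node_entries(i, frm, to, b, indptr, adj_other, adj_layer, adj_value, M, S1, S2):
    """Move every entry incident to node i from pairs (frm, .) to (to, .)."""
    for k in range(indptr[i], indptr[i + 1]):
        c = b[adj_other[k]]
        l = adj_layer[k]
        w = adj_value[k]
        lo, hi = (frm, c) if frm <= c else (c, frm)
        M[l, lo, hi] -= 1.0
        S1[l, lo, hi] -= w
        S2[l, lo, hi] -= w * w
        lo, hi = (to, c) if to <= c else (c, to)
        M[l, lo, hi] += 1.0
        S1[l, lo, hi] += w
        S2[l, lo, hi] += w * w


@njit(cache=True)
def _affected_sum(r, t, sizes, M, S1, S2, b_hi):
    """Sum of pair terms over all pairs touching block r or block t."""
    total = 0.0
    for s in range(b_hi):
        total += _pair_term(r, s, sizes, M, S1, S2)
        if s != r:
            total += _pair_term(t, s, sizes, M, S1, S2)
    return total


@njit(cache=True)
def _try_move(i, t, beta, n_nodes, b, sizes, M, S1, S2, b_hi,
              indptr, adj_other, adj_layer, adj_value):
    """Metropolis move of node i to block t; returns (accepted, dS)."""
    r = b[i]
    if t == r:
        return False, 0.0
    old_pairs = _affected_sum(r, t, sizes, M, S1, S2, b_hi)
    old_part = _partition_code(n_nodes, sizes, b_hi)

    _shift_node_entries(i, r, t, b, indptr, adj_other, adj_layer, adj_value, M, S1, S2)
    sizes[r] -= 1
    sizes[t] += 1
    b[i] = t

    new_pairs = _affected_sum(r, t, sizes, M, S1, S2, b_hi)
    new_part = _partition_code(n_nodes, sizes, b_hi)
    d_s = (new_pairs - old_pairs) + (new_part - old_part)

    if d_s <= 0.0 or np.random.random() < math.exp(-beta * d_s):
        return True, d_s
    # undo
    b[i] = r
    sizes[t] -= 1
    sizes[r] += 1
    _shift_node_entries(i, t, r, b, indptr, adj_other, adj_layer, adj_value, M, S1, S2)
    return False, 0.0


@njit(cache=True)
def _merged_pair_term(r, t, s, sizes, M, S1, S2):
    """Pair term for (t, s) after hypothetically merging r into t."""
    nt = sizes[r] + sizes[t]
    if s == t:
        npairs = nt * (nt - 1) // 2
    else:
        npairs = nt * sizes[s]
    total = 0.0
    for l in range(2):
        if s == t:
            lo1, hi1 = (r, r)
            lo2, hi2 = (t, t)
            lo3, hi3 = (r, t) if r <= t else (t, r)
            m = M[l, lo1, hi1] + M[l, lo2, hi2] + M[l, lo3, hi3]
            s1 = S1[l, lo1, hi1] + S1[l, lo2, hi2] + S1[l, lo3, hi3]
            s2 = S2[l, lo1, hi1] + S2[l, lo2, hi2] + S2[l, lo3, hi3]
        else:
            lo1, hi1 = (r, s) if r <= s else (s, r)
            lo2, hi2 = (t, s) if t <= s else (s, t)
            m = M[l, lo1, hi1] + M[l, lo2, hi2]
            s1 = S1[l, lo1, hi1] + S1[l, lo2, hi2]
            s2 = S2[l, lo1, hi1] + S2[l, lo2, hi2]
        total += math.log(npairs + 1.0)
        if m > 0:
            total += math.lgamma(npairs + m) - math.lgamma(m + 1.0) - math.lgamma(npairs)
            total += _gauss_code(m, s1, s2)
    return total


@njit(cache=True)
def _merge_delta(r, t, n_nodes, sizes, M, S1, S2, b_hi):
    """Description-length change of merging block r into block t."""
    old = _affected_sum(r, t, sizes, M, S1, S2, b_hi) + _partition_code(n_nodes, sizes, b_hi)
    new = 0.0
    for s in range(b_hi):
        if s == r:
            continue
        if sizes[s] == 0 and s != t:
            new += 0.0
        else:
            new += _merged_pair_term(r, t, s, sizes, M, S1, S2)
    nr = sizes[r]
    sizes[r] = 0
    sizes[t] += nr
    new += _partition_code(n_nodes, sizes, b_hi)
    sizes[t] -= nr
    sizes[r] = nr
    return new - old


@njit(cache=True)
def _apply_merge(r, t, b, sizes, M, S1, S2, b_hi):
    for s in range(b_hi):
        if s == r:
            continue
        for l in range(2):
            if s == t:
                lo3, hi3 = (r, t) if r <= t else (t, r)
                M[l, t, t] += M[l, r, r] + M[l, lo3, hi3]
                S1[l, t, t] += S1[l, r, r] + S1[l, lo3, hi3]
                S2[l, t, t] += S2[l, r, r] + S2[l, lo3, hi3]
                M[l, r, r] = 0.0
                S1[l, r, r] = 0.0
                S2[l, r, r] = 0.0
                M[l, lo3, hi3] = 0.0
                S1[l, lo3, hi3] = 0.0
                S2[l, lo3, hi3] = 0.0
            else:
                lo1, hi1 = (r, s) if r <= s else (s, r)
                lo2, hi2 = (t, s) if t <= s else (s, t)
                M[l, lo2, hi2] += M[l, lo1, hi1]
                S1[l, lo2, hi2] += S1[l, lo1, hi1]
                S2[l, lo2, hi2] += S2[l, lo1, hi1]
                M[l, lo1, hi1] = 0.0
                S1[l, lo1, hi1] = 0.0
                S2[l, lo1, hi1] = 0.0
    sizes[t] += sizes[r]
    sizes[r] = 0
    for i in range(b.shape[0]):
        if b[i] == r:
            b[i] = t


@njit(cache=True)
def _greedy_insert_init(n_nodes, b_max, indptr, adj_other, adj_layer, adj_value,
                        b, sizes, M, S1, S2):
    """Sequential agglomerative initialisation.

    Nodes are inserted in random order; each joins the candidate block
    (an already-assigned neighbour's block, or a fresh one) that minimises
    the description-length increase.  Each entry is added to the sufficient
    statistics exactly once — when its second endpoint is inserted.
    """
    order = np.random.permutation(n_nodes)
    assigned = np.zeros(n_nodes, dtype=np.uint8)
    b_hi = 0
    cand = np.empty(64, dtype=np.int64)
    for oi in range(n_nodes):
        i = order[oi]
        # candidate blocks: assigned neighbours' blocks + a fresh slot
        n_cand = 0
        for k in range(indptr[i], indptr[i + 1]):
            j = adj_other[k]
            if assigned[j] == 1:
                c = b[j]
                dup = False
                for q in range(n_cand):
                    if cand[q] == c:
                        dup = True
                        break
                if not dup and n_cand < 63:
                    cand[n_cand] = c
                    n_cand += 1
        fresh = -1
        if b_hi < b_max:
            fresh = b_hi
            cand[n_cand] = fresh
            n_cand += 1
        if n_cand == 0:
            cand[0] = 0
            n_cand = 1

        best_t = cand[0]
        best_ds = 1e300
        for q in range(n_cand):
            t = cand[q]
            hi_eval = b_hi + 1 if t == fresh else max(b_hi, t + 1)
            old = 0.0
            for s in range(hi_eval):
                old += _pair_term(t, s, sizes, M, S1, S2)
            old_part = _partition_code(n_nodes, sizes, hi_eval) if oi > 0 else 0.0
            # tentatively insert
            for k in range(indptr[i], indptr[i + 1]):
                j = adj_other[k]
                if assigned[j] == 1:
                    c = b[j]
                    l = adj_layer[k]
                    w = adj_value[k]
                    lo, hi = (t, c) if t <= c else (c, t)
                    M[l, lo, hi] += 1.0
                    S1[l, lo, hi] += w
                    S2[l, lo, hi] += w * w
            sizes[t] += 1
            new = 0.0
            for s in range(hi_eval):
                new += _pair_term(t, s, sizes, M, S1, S2)
            new_part = _partition_code(n_nodes, sizes, hi_eval)
            d_s = (new - old) + (new_part - old_part)
            # undo
            sizes[t] -= 1
            for k in range(indptr[i], indptr[i + 1]):
                j = adj_other[k]
                if assigned[j] == 1:
                    c = b[j]
                    l = adj_layer[k]
                    w = adj_value[k]
                    lo, hi = (t, c) if t <= c else (c, t)
                    M[l, lo, hi] -= 1.0
                    S1[l, lo, hi] -= w
                    S2[l, lo, hi] -= w * w
            if d_s < best_ds:
                best_ds = d_s
                best_t = t
        # commit
        t = best_t
        for k in range(indptr[i], indptr[i + 1]):
            j = adj_other[k]
            if assigned[j] == 1:
                c = b[j]
                l = adj_layer[k]
                w = adj_value[k]
                lo, hi = (t, c) if t <= c else (c, t)
                M[l, lo, hi] += 1.0
                S1[l, lo, hi] += w
                S2[l, lo, hi] += w * w
        sizes[t] += 1
        b[i] = t
        assigned[i] = 1
        if t == fresh:
            b_hi += 1
    return b_hi


@njit(cache=True)
def anneal(n_nodes, b_max, indptr, adj_other, adj_layer, adj_value,
           ent_u, ent_v, ent_l, ent_w,
           seed, beta_min, beta_max, anneal_sweeps, max_sweeps, wait,
           p_uniform, reheat, b_init, use_init):
    """Annealed single-node-move + merge MCMC over partitions.

    Returns the record-best partition, its description length and the
    sequence of record-breaking description lengths.
    """
    np.random.seed(seed)
    b = np.zeros(n_nodes, dtype=np.int64)
    sizes = np.zeros(b_max, dtype=np.int64)
    M = np.zeros((2, b_max, b_max))
    S1 = np.zeros((2, b_max, b_max))
    S2 = np.zeros((2, b_max, b_max))

    if use_init:
        for i in range(n_nodes):
            b[i] = b_init[i]
        _build_stats(b, ent_u, ent_v, ent_l, ent_w, sizes, M, S1, S2)
        b_hi = int(b.max()) + 1
    else:
        b_hi = _greedy_insert_init(
            n_nodes, b_max, indptr, adj_other, adj_layer, adj_value, b, sizes, M, S1, S2
        )

    s_cur = _full_entropy(n_nodes, sizes, M, S1, S2, b_hi)
    s_best = s_cur
    b_best = b.copy()
    records = np.empty(max_sweeps + 2)
    records[0] = s_cur
    n_rec = 1
    last_rec = 0

    for sweep in range(max_sweeps):
        if anneal_sweeps > 0:
            phase = sweep % anneal_sweeps if reheat else min(sweep, anneal_sweeps)
            beta = beta_min * (beta_max / beta_min) ** (phase / anneal_sweeps)
        else:
            beta = beta_max

        order = np.random.permutation(n_nodes)
        for oi in range(n_nodes):
            i = order[oi]
            deg = indptr[i + 1] - indptr[i]
            if deg > 0 and np.random.random() >= p_uniform:
                k = indptr[i] + np.random.randint(deg)
                t = b[adj_other[k]]
            else:
                t = np.random.randint(b_hi + 1)
                if t == b_hi:
                    if b_hi >= b_max:
                        t = np.random.randint(b_hi)
                    else:
                        b_hi += 1  # open a fresh block slot
            acc, d_s = _try_move(
                i, t, beta, n_nodes, b, sizes, M, S1, S2, b_hi,
                indptr, adj_other, adj_layer, adj_value,
            )
            if acc:
                s_cur += d_s
        # trim b_hi if trailing slots emptied
        while b_hi > 1 and sizes[b_hi - 1] == 0:
            b_hi -= 1

        # merge proposals
        n_active = 0
        for r in range(b_hi):
            if sizes[r] > 0:
                n_active += 1
        n_merge = 1 + n_active // 5
        for _ in range(n_merge):
            if n_active < 2:
                break
            r = np.random.randint(b_hi)
            t = np.random.randint(b_hi)
            if r == t or sizes[r] == 0 or sizes[t] == 0:
                continue
            d_s = _merge_delta(r, t, n_nodes, sizes, M, S1, S2, b_hi)
            if d_s <= 0.0 or np.random.random() < math.exp(-beta * d_s):
                _apply_merge(r, t, b, sizes, M, S1, S2, b_hi)
                s_cur += d_s
                n_active -= 1
        while b_hi > 1 and sizes[b_hi - 1] == 0:
            b_hi -= 1

        # resync against float drift before record bookkeeping
        if sweep % 25 == 24:
            s_cur = _full_entropy(n_nodes, sizes, M, S1, S2, b_hi)
        if s_cur < s_best - 1e-7:
            s_best = s_cur
            for i in range(n_nodes):
                b_best[i] = b[i]
            records[n_rec] = s_cur
            n_rec += 1
            last_rec = sweep
        if sweep - last_rec >= wait:
            break

    # deterministic polish from the record-best partition
    _build_stats(b_best, ent_u, ent_v, ent_l, ent_w, sizes, M, S1, S2)
    b_hi = int(b_best.max()) + 1
    s_polished = _greedy_polish(
        n_nodes, b_best, sizes, M, S1, S2, b_hi,
        indptr, adj_other, adj_layer, adj_value, 50,
    )
    if s_polished < s_best:
        s_best = s_polished
        records_out = np.empty(n_rec + 1)
        records_out[:n_rec] = records[:n_rec]
        records_out[n_rec] = s_polished
        return b_best, s_best, records_out
    return b_best, s_best, records[:n_rec]


@njit(cache=True)
def _eval_move(i, t, n_nodes, b, sizes, M, S1, S2, b_hi,
               indptr, adj_other, adj_layer, adj_value):
    """Description-length change of moving node i to block t (no acceptance)."""
    r = b[i]
    if t == r:
        return 0.0
    old = _affected_sum(r, t, sizes, M, S1, S2, b_hi) + _partition_code(n_nodes, sizes, b_hi)
    _shift_node_entries(i, r, t, b, indptr, adj_other, adj_layer, adj_value, M, S1, S2)
    sizes[r] -= 1
    sizes[t] += 1
    b[i] = t
    new = _affected_sum(r, t, sizes, M, S1, S2, b_hi) + _partition_code(n_nodes, sizes, b_hi)
    b[i] = r
    sizes[t] -= 1
    sizes[r] += 1
    _shift_node_entries(i, t, r, b, indptr, adj_other, adj_layer, adj_value, M, S1, S2)
    return new - old


@njit(cache=True)
def _greedy_polish(n_nodes, b, sizes, M, S1, S2, b_hi,
                   indptr, adj_other, adj_layer, adj_value, max_rounds):
    """Deterministic hill-climb: best single-node moves, then greedy merges.

    Runs until a full round yields no description-length improvement;
    collapses run-to-run variance left by the stochastic phase.
    """
    cand = np.empty(64, dtype=np.int64)
    for _ in range(max_rounds):
        improved = False
        for i in range(n_nodes):
            n_cand = 0
            for k in range(indptr[i], indptr[i + 1]):
                c = b[adj_other[k]]
                dup = False
                for q in range(n_cand):
                    if cand[q] == c:
                        dup = True
                        break
                if not dup and c != b[i] and n_cand < 64:
                    cand[n_cand] = c
                    n_cand += 1
            best_ds = -1e-9
            best_t = -1
            for q in range(n_cand):
                d_s = _eval_move(i, cand[q], n_nodes, b, sizes, M, S1, S2, b_hi,
                                 indptr, adj_other, adj_layer, adj_value)
                if d_s < best_ds:
                    best_ds = d_s
                    best_t = cand[q]
            if best_t >= 0:
                r = b[i]
                _shift_node_entries(i, r, best_t, b, indptr, adj_other, adj_layer,
                                    adj_value, M, S1, S2)
                sizes[r] -= 1
                sizes[best_t] += 1
                b[i] = best_t
                improved = True
        # greedy merges while they lower S
        while True:
            best_ds = -1e-9
            best_r = -1
            best_t = -1
            for r in range(b_hi):
                if sizes[r] == 0:
                    continue
                for t in range(b_hi):
                    if t == r or sizes[t] == 0:
                        continue
                    d_s = _merge_delta(r, t, n_nodes, sizes, M, S1, S2, b_hi)
                    if d_s < best_ds:
                        best_ds = d_s
                        best_r = r
                        best_t = t
            if best_r < 0:
                break
            _apply_merge(best_r, best_t, b, sizes, M, S1, S2, b_hi)
            improved = True
        if not improved:
            break
    return _full_entropy(n_nodes, sizes, M, S1, S2, b_hi)


@njit(cache=True)
def entropy_of_partition(n_nodes, b_max, ent_u, ent_v, ent_l, ent_w, b):
    """Description length of a given partition (kernel-side evaluation)."""
    sizes = np.zeros(b_max, dtype=np.int64)
    M = np.zeros((2, b_max, b_max))
    S1 = np.zeros((2, b_max, b_max))
    S2 = np.zeros((2, b_max, b_max))
    _build_stats(b, ent_u, ent_v, ent_l, ent_w, sizes, M, S1, S2)
    b_hi = int(b.max()) + 1
    return _full_entropy(n_nodes, sizes, M, S1, S2, b_hi)


@njit(cache=True)
def greedy_coarsen(n_nodes, b_max, ent_u, ent_v, ent_l, ent_w, b, n_target):
    """Greedily merge blocks of partition b down to n_target blocks.

    Each step applies the merge with the smallest description-length
    increase (or largest decrease); used to build coarser hierarchy levels.
    """
    sizes = np.zeros(b_max, dtype=np.int64)
    M = np.zeros((2, b_max, b_max))
    S1 = np.zeros((2, b_max, b_max))
    S2 = np.zeros((2, b_max, b_max))
    bb = b.copy()
    _build_stats(bb, ent_u, ent_v, ent_l, ent_w, sizes, M, S1, S2)
    b_hi = int(bb.max()) + 1
    n_active = 0
    for r in range(b_hi):
        if sizes[r] > 0:
            n_active += 1
    while n_active > n_target:
        best = 1e300
        best_r = -1
        best_t = -1
        for r in range(b_hi):
            if sizes[r] == 0:
                continue
            for t in range(b_hi):
                if t == r or sizes[t] == 0:
                    continue
                d_s = _merge_delta(r, t, n_nodes, sizes, M, S1, S2, b_hi)
                if d_s < best:
                    best = d_s
                    best_r = r
                    best_t = t
        if best_r < 0:
            break
        _apply_merge(best_r, best_t, bb, sizes, M, S1, S2, b_hi)
        n_active -= 1
    return bb
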