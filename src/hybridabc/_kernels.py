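"""Numba kernels for structured-coalescent tree and SNP simulation.

These are the hot loops behind :mod:`hybridabc.coalsim`.  All kernels draw
from numba's own legacy numpy random state, seeded explicitly per call via
``np.random.seed`` inside the jitted code, so results are deterministic for
a given seed and independent of the caller's numpy state.

Scenario encoding (prepared by ``coalsim.compile_scenario``): demes are
integer ids; ``N`` holds diploid sizes per deme; events are parallel arrays
sorted by time with ``kind`` 0 = merge (demes ``a`` and ``b`` pour into
``dest``) and 1 = admixture (each lineage of ``a`` moves to ``b`` with
probability ``frac``, else to ``dest``).
"""

import numpy as np
from numba import njit

__all__ = ["sim_tree_seeded", "sim_tree", "drop_mutation", "drop_mutation_seeded", "sim_dataset"]


@njit(cache=True)
def _sim_tree_core(leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac):
    n = leaf_deme.size
    nn = 2 * n - 1
    parent = np.full(nn, -1, np.int32)
    ntime = np.zeros(nn, np.float64)
    lch = np.full(nn, -1, np.int32)
    rch = np.full(nn, -1, np.int32)
    nd = N.size
    active = np.empty(n, np.int32)
    deme = np.empty(n, np.int32)
    for i in range(n):
        active[i] = i
        deme[i] = leaf_deme[i]
    k = n
    nxt = n
    t = 0.0
    ei = 0
    cnt = np.zeros(nd, np.int64)
    for i in range(n):
        cnt[leaf_deme[i]] += 1
    while k > 1:
        total = 0.0
        for d in range(nd):
            c = cnt[d]
            if c > 1:
                total += c * (c - 1) / (4.0 * N[d])
        if total > 0.0:
            w = np.random.exponential(1.0 / total)
        else:
            w = 1.0e300
        if ei < ev_time.size and t + w >= ev_time[ei]:
            t = ev_time[ei]
            if ev_kind[ei] == 0:  # merge: a, b -> dest
                a = ev_a[ei]
                b = ev_b[ei]
                dst = ev_dest[ei]
                for i in range(k):
                    if deme[i] == a or deme[i] == b:
                        deme[i] = dst
                cnt[dst] += cnt[a] + cnt[b]
                cnt[a] = 0
                cnt[b] = 0
            else:  # admixture: child a -> b (prob frac) else dest
                a = ev_a[ei]
                pa = ev_b[ei]
                pb = ev_dest[ei]
                fr = ev_frac[ei]
                for i in range(k):
                    if deme[i] == a:
                        if np.random.random() < fr:
                            deme[i] = pa
                            cnt[pa] += 1
                        else:
                            deme[i] = pb
                            cnt[pb] += 1
                        cnt[a] -= 1
            ei += 1
            continue
        t += w
        # choose the coalescing deme proportionally to its pair rate
        u = np.random.random() * total
        acc = 0.0
        chosen = -1
        for d in range(nd):
            c = cnt[d]
            if c > 1:
                acc += c * (c - 1) / (4.0 * N[d])
                if u <= acc:
                    chosen = d
                    break
        if chosen < 0:  # numerical edge: u == total
            for d in range(nd):
                if cnt[d] > 1:
                    chosen = d
        # choose two distinct lineages uniformly within the deme
        c = cnt[chosen]
        i1 = np.random.randint(0, c)
        i2 = np.random.randint(0, c - 1)
        if i2 >= i1:
            i2 += 1
        p1 = -1
        p2 = -1
        seen = 0
        for i in range(k):
            if deme[i] == chosen:
                if seen == i1:
                    p1 = i
                if seen == i2:
                    p2 = i
                seen += 1
        node = nxt
        nxt += 1
        ntime[node] = t
        lch[node] = active[p1]
        rch[node] = active[p2]
        parent[active[p1]] = node
        parent[active[p2]] = node
        active[p1] = node
        active[p2] = active[k - 1]
        deme[p2] = deme[k - 1]
        k -= 1
        cnt[chosen] -= 1
    return parent, ntime, lch, rch


@njit(cache=True)
def sim_tree_seeded(seed, leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac):
    np.random.seed(seed)
    return _sim_tree_core(leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac)


@njit(cache=True)
def sim_tree(leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac):
    return _sim_tree_core(leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac)


@njit(cache=True)
def _drop_mutation_core(parent, ntime, lch, rch, n_leaves):
    nn = parent.size
    tot = 0.0
    for v in range(nn - 1):  # every node except the root carries a branch
        tot += ntime[parent[v]] - ntime[v]
    u = np.random.random() * tot
    acc = 0.0
    pick = nn - 2
    for v in range(nn - 1):
        acc += ntime[parent[v]] - ntime[v]
        if u <= acc:
            pick = v
            break
    carrier = np.zeros(n_leaves, np.uint8)
    stack = np.empty(nn, np.int32)
    sp = 0
    stack[sp] = pick
    sp += 1
    while sp > 0:
        sp -= 1
        v = stack[sp]
        if v < n_leaves:
            carrier[v] = 1
        else:
            stack[sp] = lch[v]
            sp += 1
            stack[sp] = rch[v]
            sp += 1
    return carrier


@njit(cache=True)
def drop_mutation(parent, ntime, lch, rch, n_leaves):
    return _drop_mutation_core(parent, ntime, lch, rch, n_leaves)


@njit(cache=True)
def drop_mutation_seeded(seed, parent, ntime, lch, rch, n_leaves):
    np.random.seed(seed)
    return _drop_mutation_core(parent, ntime, lch, rch, n_leaves)


@njit(cache=True)
def sim_tree_ensemble(seed, n_reps, leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac):
    """TMRCA and total branch length over ``n_reps`` independent trees."""
    np.random.seed(seed)
    tmrca = np.empty(n_reps, np.float64)
    tbl = np.empty(n_reps, np.float64)
    for r in range(n_reps):
        parent, ntime, lch, rch = _sim_tree_core(
            leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac
        )
        nn = parent.size
        tmrca[r] = ntime[nn - 1]
        tot = 0.0
        for v in range(nn - 1):
            tot += ntime[parent[v]] - ntime[v]
        tbl[r] = tot
    return tmrca, tbl


@njit(cache=True)
def sim_dataset(seed, n_ind, n_loci, min_maf, cap, lcap, leaf_deme, N,
                ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac):
    """Simulate ``n_loci`` independent SNPs; returns (dosages, rejects, failed).

    Each locus is one tree plus one branch-proportional mutation, accepted
    when the pooled minor-allele frequency reaches ``min_maf``.  With
    ``lcap > 0`` the tree itself is first accepted with probability
    ``total length / lcap`` (length-biased sampling — the low-mutation-rate
    limit of infinite-sites conditioned on one segregating site); with
    ``lcap <= 0`` every tree is kept (fixed-one-mutation-per-tree scheme).
    ``failed`` is -1 on success, else the locus index whose attempt cap was
    exhausted.
    """
    np.random.seed(seed)
    dos = np.zeros((n_ind, n_loci), np.int8)
    rejects = 0
    tot_copies = 2 * n_ind
    for locus in range(n_loci):
        ok = False
        for _ in range(cap):
            parent, ntime, lch, rch = _sim_tree_core(
                leaf_deme, N, ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac
            )
            if lcap > 0.0:
                tot = 0.0
                for v in range(parent.size - 1):
                    tot += ntime[parent[v]] - ntime[v]
                if np.random.random() > tot / lcap:
                    rejects += 1
                    continue
            carrier = _drop_mutation_core(parent, ntime, lch, rch, leaf_deme.size)
            alt = 0
            for i in range(leaf_deme.size):
                alt += carrier[i]
            p = alt / tot_copies
            maf = p if p <= 0.5 else 1.0 - p
            if 0 < alt < tot_copies and maf >= min_maf - 1e-12:
                for i in range(n_ind):
                    dos[i, locus] = carrier[2 * i] + carrier[2 * i + 1]
                ok = True
                break
            rejects += 1
        if not ok:
            return dos, rejects, locus
    return dos, rejects, -1
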