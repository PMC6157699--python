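"""Numba kernels for the structured-coalescent SNP simulator.

One kernel call simulates a batch of unlinked loci under a piecewise-constant
multi-deme demography (optional symmetric island migration, backward-time
merge/resize events), places a single mutation uniformly on the genealogy,
and rejection-samples each locus until the pooled minor-allele frequency
clears the ascertainment threshold.

Randomness comes from an inline xorshift64* stream (seeded per batch): the
event loop is RNG-bound, and the inline generator roughly halves the cost of
a tree relative to numba's built-in distributions.
"""

import numpy as np
from numba import njit

# event kinds
EV_MERGE = 0   # move all lineages of deme `ev_deme` into deme 0; ev_size > 0 resizes deme 0
EV_RESIZE = 1  # set deme `ev_deme` size to ev_size

_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _u01(state):
    """xorshift64* step -> uniform double in [0, 1)."""
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return float((x * _MULT) >> np.uint64(11)) * _INV53


@njit(cache=True)
def _init_state(seed):
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    if state[0] == np.uint64(0):
        state[0] = np.uint64(0x9E3779B97F4A7C15)
    for _ in range(8):  # warm up
        _u01(state)
    return state


@njit(cache=True)
def _run_tree(samples, sizes0, mig, ev_time, ev_kind, ev_deme, ev_size,
              parent, time, ch1, ch2, members, k, crate_d, sizes, state):
    """Simulate one genealogy; fills parent/time/child arrays, returns root."""
    n_demes = samples.shape[0]
    ngenes = 0
    for d in range(n_demes):
        ngenes += samples[d]
    g0 = 0
    for d in range(n_demes):
        sizes[d] = sizes0[d]
        k[d] = samples[d]
        for i in range(samples[d]):
            members[d, i] = g0 + i
            time[g0 + i] = 0.0
        g0 += samples[d]
    inv = np.empty(n_demes)
    for d in range(n_demes):
        inv[d] = 0.25 / sizes[d]
    next_node = ngenes
    ktot = ngenes
    t = 0.0
    ei = 0
    nev = ev_time.shape[0]
    while ktot > 1:
        if ei >= nev and mig == 0.0 and k[0] == ktot:
            # tight finish: one active deme, no pending events or migration
            invN = inv[0]
            while ktot > 1:
                t += -np.log(1.0 - _u01(state)) / (ktot * (ktot - 1) * invN)
                i = int(_u01(state) * ktot)
                j = int(_u01(state) * (ktot - 1))
                if j >= i:
                    j += 1
                a = members[0, i]
                b = members[0, j]
                node = next_node
                next_node += 1
                time[node] = t
                ch1[node] = a
                ch2[node] = b
                parent[a] = node
                parent[b] = node
                members[0, i] = node
                members[0, j] = members[0, ktot - 1]
                ktot -= 1
            break
        crate = 0.0
        for d in range(n_demes):
            r = k[d] * (k[d] - 1) * inv[d]
            crate_d[d] = r
            crate += r
        mrate = mig * ktot if n_demes > 1 else 0.0
        total = crate + mrate
        t_ev = ev_time[ei] if ei < nev else np.inf
        if total <= 0.0:
            dt = np.inf
        else:
            dt = -np.log(1.0 - _u01(state)) / total
        if t + dt >= t_ev:
            t = t_ev
            while ei < nev and ev_time[ei] <= t_ev:
                if ev_kind[ei] == EV_MERGE:
                    d = ev_deme[ei]
                    for i in range(k[d]):
                        members[0, k[0] + i] = members[d, i]
                    k[0] += k[d]
                    k[d] = 0
                    if ev_size[ei] > 0.0:
                        sizes[0] = ev_size[ei]
                        inv[0] = 0.25 / sizes[0]
                else:
                    sizes[ev_deme[ei]] = ev_size[ei]
                    inv[ev_deme[ei]] = 0.25 / ev_size[ei]
                ei += 1
            continue
        t += dt
        u = _u01(state) * total
        if u < crate:
            acc = 0.0
            d = 0
            for dd in range(n_demes):
                acc += crate_d[dd]
                if u < acc:
                    d = dd
                    break
            i = int(_u01(state) * k[d])
            j = int(_u01(state) * (k[d] - 1))
            if j >= i:
                j += 1
            a = members[d, i]
            b = members[d, j]
            node = next_node
            next_node += 1
            time[node] = t
            ch1[node] = a
            ch2[node] = b
            parent[a] = node
            parent[b] = node
            members[d, i] = node
            members[d, j] = members[d, k[d] - 1]
            k[d] -= 1
            ktot -= 1
        else:
            r = int((u - crate) / mig)
            if r >= ktot:
                r = ktot - 1
            d = 0
            while r >= k[d]:
                r -= k[d]
                d += 1
            dest = int(_u01(state) * (n_demes - 1))
            if dest >= d:
                dest += 1
            members[dest, k[dest]] = members[d, r]
            k[dest] += 1
            members[d, r] = members[d, k[d] - 1]
            k[d] -= 1
    return next_node - 1


@njit(cache=True)
def _drop_mutation(root, ngenes, parent, time, ch1, ch2, stack, buf, state):
    """Place one mutation uniformly on total branch length; mark derived leaves."""
    L = 0.0
    for v in range(root):
        L += time[parent[v]] - time[v]
    u = _u01(state) * L
    acc = 0.0
    branch = root - 1
    for v in range(root):
        acc += time[parent[v]] - time[v]
        if u < acc:
            branch = v
            break
    for i in range(ngenes):
        buf[i] = 0
    sp = 0
    stack[sp] = branch
    sp = 1
    c = 0
    while sp > 0:
        sp -= 1
        v = stack[sp]
        if v < ngenes:
            buf[v] = 1
            c += 1
        else:
            stack[sp] = ch1[v]
            sp += 1
            stack[sp] = ch2[v]
            sp += 1
    return c


@njit(cache=True)
def simulate_batch(n_loci, samples, sizes0, mig, ev_time, ev_kind, ev_deme, ev_size,
                   min_maf, max_redraws, seed):
    """Simulate ``n_loci`` ascertained SNPs; returns (derived matrix, redraw count).

    ``derived`` is (total genes x n_loci) uint8; the second return value is
    -1 - locus index if the rejection cap was exceeded at that locus.
    """
    state = _init_state(seed)
    n_demes = samples.shape[0]
    ngenes = 0
    for d in range(n_demes):
        ngenes += samples[d]
    n_nodes = 2 * ngenes - 1
    derived = np.zeros((ngenes, n_loci), dtype=np.uint8)
    parent = np.zeros(n_nodes, dtype=np.int32)
    time = np.zeros(n_nodes)
    ch1 = np.zeros(n_nodes, dtype=np.int32)
    ch2 = np.zeros(n_nodes, dtype=np.int32)
    members = np.zeros((n_demes, ngenes), dtype=np.int32)
    k = np.zeros(n_demes, dtype=np.int64)
    crate_d = np.zeros(n_demes)
    sizes = np.zeros(n_demes)
    stack = np.zeros(n_nodes, dtype=np.int32)
    buf = np.zeros(ngenes, dtype=np.uint8)
    total_redraws = 0
    for locus in range(n_loci):
        redraws = 0
        while True:
            root = _run_tree(samples, sizes0, mig, ev_time, ev_kind, ev_deme, ev_size,
                             parent, time, ch1, ch2, members, k, crate_d, sizes, state)
            c = _drop_mutation(root, ngenes, parent, time, ch1, ch2, stack, buf, state)
            maf = c if c * 2 <= ngenes else ngenes - c
            if maf >= min_maf * ngenes - 1e-9:
                for i in range(ngenes):
                    derived[i, locus] = buf[i]
                break
            redraws += 1
            if redraws > max_redraws:
                return derived, -1 - locus
        total_redraws += redraws
    return derived, total_redraws


@njit(cache=True)
def simulate_tree(samples, sizes0, mig, ev_time, ev_kind, ev_deme, ev_size, seed):
    """Simulate one genealogy; returns (parent, node time) arrays (root last)."""
    state = _init_state(seed)
    n_demes = samples.shape[0]
    ngenes = 0
    for d in range(n_demes):
        ngenes += samples[d]
    n_nodes = 2 * ngenes - 1
    parent = np.zeros(n_nodes, dtype=np.int32)
    time = np.zeros(n_nodes)
    ch1 = np.zeros(n_nodes, dtype=np.int32)
    ch2 = np.zeros(n_nodes, dtype=np.int32)
    members = np.zeros((n_demes, ngenes), dtype=np.int32)
    k = np.zeros(n_demes, dtype=np.int64)
    crate_d = np.zeros(n_demes)
    sizes = np.zeros(n_demes)
    root = _run_tree(samples, sizes0, mig, ev_time, ev_kind, ev_deme, ev_size,
                     parent, time, ch1, ch2, members, k, crate_d, sizes, state)
    parent[root] = -1
    return parent, time
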