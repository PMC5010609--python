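"""Compiled inner loops: permutation decoding, wiring-length evaluation,
the memetic steady-state GA, and the junction hill-climber.

Everything here works on plain int64/float64 arrays indexed 0..n-1; the
object-level API in :mod:`neurowire.drcmst` and :mod:`neurowire.ssga`
translates between external node ids and these indices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "decode_into",
    "decode_eval",
    "ssga_loop",
    "junction_hill_climb",
]


@njit(cache=True)
def _find(uf, x):
    root = x
    while uf[root] != root:
        root = uf[root]
    # path compression
    while uf[x] != root:
        nxt = uf[x]
        uf[x] = root
        x = nxt
    return root


@njit(cache=True)
def decode_into(perm, slot_node, child_node, n_nodes, parents):
    """Decode ``perm`` into parent pointers, repairing in place.

    perm       : int64[m]   permutation of slot indices 0..m-1 (mutated by repair)
    slot_node  : int64[m]   node index owning each parent slot
    child_node : int64[c]   node index per child position, c <= m
    parents    : int64[n]   output, -1 for parentless nodes

    Position k connects child_node[k] under slot_node[perm[k]].  When the
    raw connection would close a cycle — or would leave the remaining
    sub-problem unsolvable — perm[k] is swapped with the nearest later
    position whose slot is acceptable.

    Feasibility bookkeeping: a partial state remains completable exactly
    when at least one remaining slot lies in a component containing a root
    (components headed by pending children can then be attached one at a
    time, capacity-rich ones first).  The repair therefore rejects any
    assignment that would drop that count to zero while children remain,
    which makes decoding deadlock-free whenever the instance itself is
    feasible.  Returns 0 on success, -1 for infeasible instances.
    """
    m = perm.shape[0]
    c = child_node.shape[0]
    uf = np.empty(n_nodes, np.int64)
    rooted = np.empty(n_nodes, np.bool_)
    slots_in = np.zeros(n_nodes, np.int64)
    for i in range(n_nodes):
        uf[i] = i
        parents[i] = -1
        rooted[i] = True
    for k in range(c):
        rooted[child_node[k]] = False
    for s in range(m):
        slots_in[slot_node[s]] += 1
    rooted_slots = 0
    for i in range(n_nodes):
        if rooted[i]:
            rooted_slots += slots_in[i]
    if c > 0 and rooted_slots == 0:
        return -1
    for k in range(c):
        ch = child_node[k]
        hc = _find(uf, ch)
        rem_after = c - k - 1
        j = -1
        for k2 in range(k, m):
            hp = _find(uf, slot_node[perm[k2]])
            if hp == hc:
                continue
            if rem_after > 0:
                delta = 0
                if rooted[hp]:
                    delta = slots_in[hc] - 1
                if rooted_slots + delta < 1:
                    continue
            j = k2
            break
        if j < 0:
            return -1
        if j != k:
            tmp = perm[k]
            perm[k] = perm[j]
            perm[j] = tmp
        pa = slot_node[perm[k]]
        hp = _find(uf, pa)
        # consume the slot, then merge the child's component into the parent's
        slots_in[hp] -= 1
        if rooted[hp]:
            rooted_slots -= 1
            rooted_slots += slots_in[hc]
        uf[hc] = hp
        slots_in[hp] += slots_in[hc]
        parents[ch] = pa
    return 0


@njit(cache=True)
def decode_eval(perm, slot_node, child_node, n_nodes, xyz, parents):
    """Decode and return total Euclidean wiring length (inf on failure)."""
    status = decode_into(perm, slot_node, child_node, n_nodes, parents)
    if status < 0:
        return np.inf
    total = 0.0
    for i in range(n_nodes):
        p = parents[i]
        if p >= 0:
            dx = xyz[p, 0] - xyz[i, 0]
            dy = xyz[p, 1] - xyz[i, 1]
            dz = xyz[p, 2] - xyz[i, 2]
            total += np.sqrt(dx * dx + dy * dy + dz * dz)
    return total


@njit(cache=True)
def _tournament(g, tsize):
    best = np.random.randint(0, g.shape[0])
    for _ in range(tsize - 1):
        cand = np.random.randint(0, g.shape[0])
        if g[cand] < g[best]:
            best = cand
    return best


@njit(cache=True)
def _pmx(p1, p2, child):
    """Partially mapped crossover: child keeps p1's random slice in place
    and p2's positions elsewhere, conflicts resolved by the slice mapping.
    Preserves absolute positions, which carry the child->parent-slot
    assignment semantics of this encoding."""
    m = p1.shape[0]
    a = np.random.randint(0, m)
    b = np.random.randint(0, m)
    if a > b:
        tmp = a
        a = b
        b = tmp
    b += 1
    pos = np.empty(m, np.int64)
    for i in range(m):
        pos[p2[i]] = i
        child[i] = p2[i]
    for i in range(a, b):
        v1 = p1[i]
        v2 = child[i]
        if v1 != v2:
            j = pos[v1]
            child[i] = v1
            child[j] = v2
            pos[v1] = i
            pos[v2] = j


@njit(cache=True)
def _local_refine(
    perm, slot_node, child_node, n_nodes, xyz, cand, sign, parents, budget
):
    """First-improvement local search on one genotype (in place).

    Moves, directed by ``cand`` (per child position, candidate parent
    *nodes* ranked best-first for the search direction):
    - 2-swap: give child k the slot of candidate parent pn, sending k's
      current slot to the position that held pn's slot;
    - 3-cycle: additionally forward the displaced child j to one of *its*
      candidate parents, closing the cycle at k's old slot.

    Accepts only strict improvements of sign*length; stops at a local
    optimum or when ``budget`` evaluations are spent.
    Returns (signed length, evaluations used).
    """
    m = perm.shape[0]
    c = child_node.shape[0]
    nk = cand.shape[1]
    pos_of = np.empty(m, np.int64)
    f = sign * decode_eval(perm, slot_node, child_node, n_nodes, xyz, parents)
    evals = 1
    improved = True
    while improved and evals < budget:
        improved = False
        for k in range(c):
            for i in range(m):
                pos_of[perm[i]] = i
            for q in range(nk):
                pn = cand[k, q]
                for s in range(m):
                    if slot_node[s] != pn:
                        continue
                    j = pos_of[s]
                    if j == k:
                        continue
                    work = perm.copy()
                    tmp = work[k]
                    work[k] = work[j]
                    work[j] = tmp
                    f2 = sign * decode_eval(
                        work, slot_node, child_node, n_nodes, xyz, parents
                    )
                    evals += 1
                    if f2 < f - 1e-12:
                        perm[:] = work
                        f = f2
                        improved = True
                        for i in range(m):
                            pos_of[perm[i]] = i
                        if evals >= budget:
                            return f, evals
                        continue
                    if evals >= budget:
                        return f, evals
                    if j < c:
                        for q2 in range(nk):
                            pn2 = cand[j, q2]
                            done = False
                            for s2 in range(m):
                                if slot_node[s2] != pn2:
                                    continue
                                l = pos_of[s2]
                                if l == k or l == j:
                                    continue
                                work2 = perm.copy()
                                tmp = work2[k]
                                work2[k] = work2[j]
                                work2[j] = work2[l]
                                work2[l] = tmp
                                f3 = sign * decode_eval(
                                    work2, slot_node, child_node, n_nodes,
                                    xyz, parents,
                                )
                                evals += 1
                                if f3 < f - 1e-12:
                                    perm[:] = work2
                                    f = f3
                                    improved = True
                                    for i in range(m):
                                        pos_of[perm[i]] = i
                                    done = True
                                break
                            if done or evals >= budget:
                                break
                    if evals >= budget:
                        return f, evals
    return f, evals


@njit(cache=True)
def ssga_loop(
    pop,
    slot_node,
    child_node,
    n_nodes,
    xyz,
    cand,
    max_evals,
    cx_rate,
    mut_rate,
    tsize,
    sign,
    refine,
    seed,
    history,
):
    """Memetic steady-state GA: one offspring per step (tournament parents,
    PMX crossover, swap mutation, optional local refinement) replaces the
    worst individual on strict improvement.  ``sign`` +1 minimizes, -1
    maximizes; every decode — including refinement decodes — counts
    against ``max_evals``.

    ``pop`` (P, m) holds the initial population and is evolved in place.
    ``history`` (max_evals+1, 2) receives (evaluation index, best length)
    rows at every improvement of the best-so-far.

    Returns (best_perm, best_length, evaluations_used, history_rows).
    """
    np.random.seed(seed)
    P = pop.shape[0]
    m = pop.shape[1]
    g = np.empty(P)
    parents = np.empty(n_nodes, np.int64)
    best_g = np.inf
    best_perm = np.empty(m, np.int64)
    hist_n = 0
    evals = 0
    for i in range(P):
        # reserve one evaluation for every not-yet-scored individual
        init_budget = max_evals - evals - (P - 1 - i)
        if refine and init_budget > 1:
            f, e = _local_refine(
                pop[i], slot_node, child_node, n_nodes, xyz, cand, sign,
                parents, init_budget,
            )
        else:
            f = sign * decode_eval(
                pop[i], slot_node, child_node, n_nodes, xyz, parents
            )
            e = 1
        evals += e
        g[i] = f
        if f < best_g:
            best_g = f
            best_perm[:] = pop[i]
            history[hist_n, 0] = evals
            history[hist_n, 1] = sign * f
            hist_n += 1
    child = np.empty(m, np.int64)
    while evals < max_evals:
        i1 = _tournament(g, tsize)
        i2 = _tournament(g, tsize)
        if np.random.random() < cx_rate:
            _pmx(pop[i1], pop[i2], child)
        else:
            child[:] = pop[i1]
        if np.random.random() < mut_rate:
            a = np.random.randint(0, m)
            b = np.random.randint(0, m)
            tmp = child[a]
            child[a] = child[b]
            child[b] = tmp
        if refine:
            f, e = _local_refine(
                child, slot_node, child_node, n_nodes, xyz, cand, sign,
                parents, max_evals - evals,
            )
        else:
            f = sign * decode_eval(
                child, slot_node, child_node, n_nodes, xyz, parents
            )
            e = 1
        evals += e
        w = 0
        for i in range(1, P):
            if g[i] > g[w]:
                w = i
        if f < g[w]:
            pop[w, :] = child
            g[w] = f
            if f < best_g:
                best_g = f
                best_perm[:] = child
                history[hist_n, 0] = evals
                history[hist_n, 1] = sign * f
                hist_n += 1
    return best_perm, sign * best_g, evals, hist_n


@njit(cache=True)
def junction_hill_climb(
    perm, slot_node, child_node, n_nodes, xyz, positions, sign, max_sweeps
):
    """First-improvement hill climb swapping permutation values between the
    given positions, accepting a swap only on strict improvement of the
    (signed) wiring length.  Sweeps until a full pass yields nothing.

    Returns (best_perm, best_length).
    """
    parents = np.empty(n_nodes, np.int64)
    work = perm.copy()
    best = sign * decode_eval(work, slot_node, child_node, n_nodes, xyz, parents)
    npos = positions.shape[0]
    sweeps = 0
    improved = True
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        for ii in range(npos):
            for jj in range(ii + 1, npos):
                i = positions[ii]
                j = positions[jj]
                cand = work.copy()
                tmp = cand[i]
                cand[i] = cand[j]
                cand[j] = tmp
                f = decode_eval(
                    cand, slot_node, child_node, n_nodes, xyz, parents
                )
                if sign * f < best - 1e-12:
                    best = sign * f
                    work = cand
                    improved = True
    return work, sign * best
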