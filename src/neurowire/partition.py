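"""Spatial partitioning of large axonal clouds.

Degree/role-constrained problems beyond ~200 nodes are too slow to solve
whole, so the cloud is split into sub-regions (k-means on coordinates, or
concentric soma-distance shells), each sub-region is solved as an
independent sub-problem, the block solutions are merged into one global
arborization, and a local search polishes the permutation positions near
the block junctions.  The whole merge procedure is repeated (default 20
times, keeping the same sub-regions) and the shortest global tree wins.

Block sub-problems keep every node's global out-degree as its capacity.
The block containing the real root keeps it; every other block is rooted
at a *pseudo-root*, the block node nearest the previously ordered block's
centroid.  A block whose total capacity cannot span it receives extra
pseudo-roots until it balances.  At merge time each pseudo-root is
attached to the nearest free parent slot in an earlier-ordered block
(falling back to any non-descendant free slot), which restores its
original non-root role in the global tree and consumes exactly the
capacity the block solves left unused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import _kernels
from .drcmst import (
    AuxiliaryArrays,
    PermutationGenotype,
    WiringForest,
    build_auxiliary_arrays,
    decode,
    encode,
)
from .morphology import ROLE_ROOT, PointCloud
from .ssga import GAConfig, GARunResult, ssga_optimize
from .validate import check_forest

__all__ = [
    "Partition",
    "MergedRunResult",
    "MergeError",
    "auto_k",
    "kmeans_partition",
    "soma_distance_partition",
    "optimize_partitioned",
    "junction_local_search",
    "choose_axon_method",
    "derive_seed",
]

logger = logging.getLogger(__name__)

#: soma-distance group sizes scanned by :func:`choose_axon_method`
DEFAULT_GROUP_SIZES = (100, 125, 150, 165, 200)


class MergeError(RuntimeError):
    """No feasible attachment slot for a pseudo-root during merging."""


def derive_seed(*parts: int) -> int:
    """Deterministic small-integer seed from a tuple of integers (< 2^31)."""
    h = 0
    for p in parts:
        h = (h * 1_000_003 + int(p) + 12_345) % (2**31 - 1)
    return h


@dataclass
class Partition:
    """Assignment of cloud nodes to blocks plus the block processing order.

    ``block_order`` puts the root-containing block first (k-means) or the
    soma-nearest shell first (soma_distance)."""

    method: str
    assignment: dict[int, int]
    block_order: list[int]
    parameters: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return len(self.block_order)

    def blocks_in_order(self, cloud: PointCloud) -> list[np.ndarray]:
        """Node-id arrays per block, following block_order; within a block,
        ids ascend."""
        members: dict[int, list[int]] = {b: [] for b in self.block_order}
        for nid in sorted(self.assignment):
            members[self.assignment[nid]].append(nid)
        return [np.array(members[b], dtype=np.int64) for b in self.block_order]

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["node_id", "block_index"])
            for nid in sorted(self.assignment):
                w.writerow([nid, self.assignment[nid]])


@dataclass
class MergedRunResult:
    best_forest: WiringForest
    per_block_lengths: list[float]
    repeats_used: int
    method_chosen: str

    @property
    def best_length(self) -> float:
        return self.best_forest.total_length


def auto_k(n: int) -> int:
    """k nearest to how many hundreds of nodes the cloud has (min 1)."""
    return max(1, int(np.floor(n / 100.0 + 0.5)))


def kmeans_partition(cloud: PointCloud, k="auto", seed: int = 0) -> Partition:
    """Cluster the 3D coordinates into k blocks (10 seeded restarts).

    Blocks are ordered root-block first, then by centroid distance to the
    root, so the pseudo-root chain grows outward from the soma."""
    n = cloud.n
    if k == "auto":
        k = auto_k(n)
    k = int(k)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(cloud.xyz)
    assignment = {int(cloud.node_ids[i]): int(labels[i]) for i in range(n)}
    roots = cloud.root_ids()
    root_pos = cloud.coords_of(roots[0]) if roots else cloud.xyz.mean(axis=0)
    root_block = assignment[roots[0]] if roots else 0
    centroid_dist = {}
    for b in range(k):
        mask = labels == b
        centroid_dist[b] = float(
            np.linalg.norm(cloud.xyz[mask].mean(axis=0) - root_pos)
        )
    order = sorted(range(k), key=lambda b: (b != root_block, centroid_dist[b], b))
    return Partition(
        method="kmeans",
        assignment=assignment,
        block_order=order,
        parameters={"k": k, "seed": seed},
    )


def soma_distance_partition(cloud: PointCloud, group_size: int) -> Partition:
    """Concentric shells: sort nodes by distance to the soma (the axon root
    position stands in for the soma) and slice consecutive groups of
    ``group_size``; the last shell keeps the remainder.  Distance ties are
    broken by ascending node id."""
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    roots = cloud.root_ids()
    origin = cloud.coords_of(roots[0]) if roots else cloud.xyz.mean(axis=0)
    dist = np.linalg.norm(cloud.xyz - origin, axis=1)
    order = sorted(range(cloud.n), key=lambda i: (dist[i], int(cloud.node_ids[i])))
    assignment = {}
    for rank, i in enumerate(order):
        assignment[int(cloud.node_ids[i])] = rank // group_size
    n_blocks = (cloud.n + group_size - 1) // group_size
    return Partition(
        method="soma_distance",
        assignment=assignment,
        block_order=list(range(n_blocks)),
        parameters={"group_size": group_size},
    )


# ---------------------------------------------------------------------------
# Block sub-problems
# ---------------------------------------------------------------------------

def _sub_cloud(cloud: PointCloud, members: np.ndarray, roots: set[int]) -> PointCloud:
    idx = [cloud.index_of(v) for v in members]
    roles = []
    for v, i in zip(members, idx):
        if int(v) in roots:
            roles.append(ROLE_ROOT)
        else:
            roles.append(cloud.roles[i])
    return PointCloud(
        node_ids=np.asarray(members, dtype=np.int64),
        xyz=cloud.xyz[idx],
        roles=roles,
        out_degree=cloud.out_degree[idx],
        compartment=cloud.compartment,
        real_edges=[],
        label=f"{cloud.label}:block",
    )


def _plan_blocks(cloud: PointCloud, partition: Partition):
    """Choose pseudo-roots per block and balance capacities.

    Returns (blocks, block_roots, pseudo_roots) where ``blocks`` is the
    node-id arrays in block order, ``block_roots[bi]`` the set of nodes
    acting as roots inside block bi (real roots + pseudo-roots), and
    ``pseudo_roots[bi]`` the ordered pseudo-root list (primary first).
    """
    blocks = partition.blocks_in_order(cloud)
    real_roots = set(cloud.root_ids())
    deg_of = {
        int(v): int(cloud.out_degree[i]) for i, v in enumerate(cloud.node_ids)
    }
    block_roots: list[set[int]] = []
    pseudo_roots: list[list[int]] = []
    prev_centroid = None
    for bi, members in enumerate(blocks):
        idx = [cloud.index_of(v) for v in members]
        centroid = cloud.xyz[idx].mean(axis=0)
        roots_here = {int(v) for v in members if int(v) in real_roots}
        pseudo: list[int] = []
        candidates = [int(v) for v in members if int(v) not in roots_here]
        if prev_centroid is not None:
            candidates.sort(
                key=lambda v: (
                    float(np.linalg.norm(cloud.coords_of(v) - prev_centroid)),
                    v,
                )
            )
        if not roots_here:
            if not candidates:
                raise MergeError(f"block {bi} is empty")
            # the block is only spannable if its roots hold parent capacity,
            # so prefer the nearest candidate that has any
            primary = next(
                (v for v in candidates if deg_of[v] > 0), candidates[0]
            )
            candidates.remove(primary)
            pseudo.append(primary)
        # balance: capacity must cover the block's children; the root block
        # additionally keeps one spare slot so the merge can start growing
        # from the real root's fragment
        min_surplus = 1 if bi == 0 and len(blocks) > 1 else 0
        while True:
            n_roots = len(roots_here) + len(pseudo)
            n_children = len(members) - n_roots
            capacity = sum(deg_of[int(v)] for v in members)
            if capacity >= n_children + min_surplus or n_children <= 0:
                break
            if not candidates:
                raise MergeError(f"block {bi} cannot be balanced")
            pseudo.append(candidates.pop(0))
        block_roots.append(roots_here | set(pseudo))
        pseudo_roots.append(pseudo)
        prev_centroid = centroid
    return blocks, block_roots, pseudo_roots


def _merge_blocks(
    cloud: PointCloud,
    blocks: list[np.ndarray],
    block_roots: list[set[int]],
    pseudo_roots: list[list[int]],
    block_forests: list[WiringForest],
) -> WiringForest:
    """Join block solutions into one global forest.

    The block solutions form tree *fragments*, one per real root or
    pseudo-root.  Starting from the fragments holding the real roots, the
    merged structure grows outward: at each step the pseudo-rooted
    fragment with the shortest junction edge to a free parent slot in the
    already-merged part is attached there.  Attaching only to the merged
    part makes cycles impossible, and a capacity-aware rule (when a single
    free slot remains but several fragments are pending, a fragment that
    brings capacity of its own must come first) guarantees completion
    whenever the degree bookkeeping balances.
    """
    deg_of = {
        int(v): int(cloud.out_degree[i]) for i, v in enumerate(cloud.node_ids)
    }
    parent: dict[int, int] = {}
    free: dict[int, int] = dict(deg_of)
    for bf in block_forests:
        for p, c in bf.edges:
            parent[c] = p
            free[p] -= 1

    # fragment membership: walk up to the parentless head
    head_cache: dict[int, int] = {}

    def head_of(v: int) -> int:
        path = []
        while v not in head_cache and v in parent:
            path.append(v)
            v = parent[v]
        h = head_cache.get(v, v)
        for u in path:
            head_cache[u] = h
        head_cache[v] = h
        return h

    all_pseudo = [pr for prs in pseudo_roots for pr in prs]
    real_roots = set(cloud.root_ids())
    members: dict[int, list[int]] = {}
    for v in (int(x) for x in cloud.node_ids):
        members.setdefault(head_of(v), []).append(v)

    merged_nodes: list[int] = []
    for r in real_roots:
        merged_nodes.extend(members.get(r, [r]))
    if not merged_nodes:  # no real root in the cloud: seed with first fragment
        first = head_of(int(blocks[0][0]))
        merged_nodes.extend(members[first])
        all_pseudo = [pr for pr in all_pseudo if pr != first]
    pending = [pr for pr in all_pseudo]

    if pending and not any(free[v] > 0 for v in merged_nodes):
        # rescue: the block solves left every free slot outside the merged
        # fragment.  Re-parent one child of a merged branching node onto a
        # free slot in a pending fragment, freeing a slot on the merged side
        # (acyclic: pseudo-roots never lie inside the moved subtree).
        movable = [
            (c, p) for c, p in parent.items()
            if p in set(merged_nodes) and c in set(merged_nodes)
        ]
        holders = [
            v for v in (int(x) for x in cloud.node_ids)
            if free[v] > 0 and v not in set(merged_nodes)
        ]
        if not movable or not holders:
            raise MergeError("insufficient parent capacity to start merging")
        c, x, y = min(
            (
                (c, p, y)
                for c, p in movable
                for y in holders
            ),
            key=lambda t: (cloud.edge_length(t[2], t[0]), t[0], t[2]),
        )
        parent[c] = y
        free[y] -= 1
        free[x] += 1
        head_cache.clear()
        members = {}
        for v in (int(x2) for x2 in cloud.node_ids):
            members.setdefault(head_of(v), []).append(v)
        merged_nodes = []
        for r in real_roots:
            merged_nodes.extend(members.get(r, [r]))

    while pending:
        frontier = [v for v in merged_nodes if free[v] > 0]
        if not frontier:
            raise MergeError("merged structure has no free parent slots left")
        frontier_cap = sum(free[v] for v in frontier)
        candidates = pending
        if frontier_cap == 1 and len(pending) > 1:
            with_cap = [
                pr for pr in pending
                if sum(free[u] for u in members[pr]) > 0
            ]
            if not with_cap:
                raise MergeError(
                    "insufficient parent capacity to join all sub-regions"
                )
            candidates = with_cap
        best = None
        for pr in candidates:
            pos = cloud.coords_of(pr)
            for x in frontier:
                d = float(np.linalg.norm(cloud.coords_of(x) - pos))
                key = (d, pr, x)
                if best is None or key < best:
                    best = key
        _d, pr, x = best
        parent[pr] = x
        free[x] -= 1
        merged_nodes.extend(members[pr])
        pending.remove(pr)

    edges = [(p, c) for c, p in parent.items()]
    total = sum(cloud.edge_length(p, c) for p, c in edges)
    return WiringForest(edges=edges, total_length=float(total),
                        cloud_ref=cloud.label)


def junction_local_search(
    global_perm: PermutationGenotype,
    aux: AuxiliaryArrays,
    cloud: PointCloud,
    window: int,
    direction: str = "minimize",
    max_sweeps: int = 50,
) -> PermutationGenotype:
    """Hill climb swapping permutation values near block boundaries.

    Accepts a swap only on strict improvement; terminates when a full sweep
    improves nothing.  ``window=0`` sweeps nothing and returns the input.
    """
    if aux.block_bounds is None:
        raise ValueError("aux.block_bounds required for junction search")
    if window <= 0 or len(aux.block_bounds) < 2:
        return global_perm
    m = aux.n_slots
    pos: set[int] = set()
    for start, _end in aux.block_bounds[1:]:
        lo = max(0, start - window)
        hi = min(m, start + window)
        pos.update(range(lo, hi))
    positions = np.array(sorted(pos), dtype=np.int64)
    slot_node, child_node = aux.index_arrays(cloud)
    sign = 1 if direction == "minimize" else -1
    best_perm, _best = _kernels.junction_hill_climb(
        global_perm.perm.copy(),
        slot_node,
        child_node,
        cloud.n,
        cloud.xyz,
        positions,
        sign,
        max_sweeps,
    )
    return PermutationGenotype(best_perm)


def optimize_partitioned(
    cloud: PointCloud,
    partition: Partition,
    config: GAConfig | None = None,
    repeats: int = 20,
    junction_window: int = 10,
) -> MergedRunResult:
    """Partitioned solve: per repeat, optimize every block independently,
    merge, polish the junctions, and keep the best global tree over all
    repeats (same sub-regions throughout)."""
    config = config or GAConfig()
    blocks, block_roots, pseudo_roots = _plan_blocks(cloud, partition)
    sub_clouds = [
        _sub_cloud(cloud, members, block_roots[bi])
        for bi, members in enumerate(blocks)
    ]
    sub_aux = [
        build_auxiliary_arrays(sc, allow_surplus=True) for sc in sub_clouds
    ]
    single = len(blocks) == 1
    global_aux = None
    if not single:
        global_aux = build_auxiliary_arrays(
            cloud,
            partition=partition,
            pseudo_roots={bi: pr for bi, pr in enumerate(pseudo_roots)},
            allow_surplus=False,
        )
    best: WiringForest | None = None
    best_block_lengths: list[float] = []
    sign = config.sign
    for r in range(repeats):
        block_forests: list[WiringForest] = []
        block_lengths: list[float] = []
        for bi, sc in enumerate(sub_clouds):
            if sc.n <= 1 or sub_aux[bi].n_children == 0:
                bf = WiringForest(edges=[], total_length=0.0, cloud_ref=sc.label)
            else:
                sub_cfg = config.with_(
                    seed=derive_seed(config.seed, r, bi)
                )
                bf = ssga_optimize(sc, sub_cfg, aux=sub_aux[bi]).best_forest
            block_forests.append(bf)
            block_lengths.append(bf.total_length)
        merged = _merge_blocks(
            cloud, blocks, block_roots, pseudo_roots, block_forests
        )
        if not single and junction_window > 0:
            perm = encode(merged, global_aux, cloud)
            perm = junction_local_search(
                perm, global_aux, cloud, junction_window,
                direction=config.direction,
            )
            merged = decode(perm, global_aux, cloud)
        check_forest(merged, cloud)
        if best is None or sign * merged.total_length < sign * best.total_length:
            best = merged
            best_block_lengths = block_lengths
        logger.debug(
            "partition repeat %d/%d: %.3f um (best %.3f)",
            r + 1, repeats, merged.total_length, best.total_length,
        )
    return MergedRunResult(
        best_forest=best,
        per_block_lengths=best_block_lengths,
        repeats_used=repeats,
        method_chosen=partition.method,
    )


def choose_axon_method(
    cloud: PointCloud,
    config: GAConfig | None = None,
    repeats: int = 20,
    junction_window: int = 10,
    group_sizes=DEFAULT_GROUP_SIZES,
    kmeans_k="auto",
) -> MergedRunResult:
    """Run the partitioned solve under both partitioning methods (k-means
    with the automatic k; soma-distance over a scan of group sizes) and
    return the winner for the configured direction."""
    config = config or GAConfig()
    sign = config.sign
    results: list[tuple[str, MergedRunResult]] = []
    km = kmeans_partition(cloud, k=kmeans_k, seed=config.seed)
    res = optimize_partitioned(
        cloud, km, config, repeats=repeats, junction_window=junction_window
    )
    results.append((f"kmeans(k={km.parameters['k']})", res))
    for gs in group_sizes:
        sd = soma_distance_partition(cloud, group_size=gs)
        res = optimize_partitioned(
            cloud, sd, config, repeats=repeats, junction_window=junction_window
        )
        results.append((f"soma_distance(group_size={gs})", res))
    name, winner = min(
        results, key=lambda item: sign * item[1].best_forest.total_length
    )
    winner.method_chosen = name
    logger.info(
        "axon method comparison on %s: %s",
        cloud.label or "cloud",
        "; ".join(f"{n}={r.best_forest.total_length:.1f}" for n, r in results),
    )
    return winner
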