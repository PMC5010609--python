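"""Permutation encoding of degree- and role-constrained spanning forests.

A candidate arborization over a critical-point cloud with ``n`` nodes and
``t`` roots is encoded as a permutation of length ``n - t``.  Two auxiliary
arrays decode it: array 1 lists *parent slots* (every node repeated
out_degree times), array 2 lists *child slots* (every non-root node once).
The value ``s`` at permutation position ``k`` connects the node at position
``s`` of array 1 as parent of the node at position ``k`` of array 2.  A
union-find repair applied during decoding guarantees that every permutation
decodes to a valid forest (acyclic, spanning, degree- and role-respecting),
so the genetic search never wastes evaluations on infeasible genotypes.

Sub-problems arising from spatial partitioning may have more parent slots
than children (surplus capacity absorbed later by junction edges); the
encoding generalises transparently: the permutation runs over all slots and
only the first ``c`` positions (c = number of children) are consumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .morphology import ROLE_ROOT, PointCloud

__all__ = [
    "ConstraintError",
    "DecodingError",
    "PermutationGenotype",
    "AuxiliaryArrays",
    "WiringForest",
    "build_auxiliary_arrays",
    "decode",
    "encode",
    "forest_length",
]


class ConstraintError(ValueError):
    """Degree/role bookkeeping violated (slot counts, forbidden parents...)."""


class DecodingError(RuntimeError):
    """No feasible repair existed while decoding (infeasible instance)."""


@dataclass(frozen=True)
class PermutationGenotype:
    """A permutation of slot indices, stored 0-based.

    The field notation indexes permutations from 1; use
    :meth:`from_one_based` / :meth:`to_one_based` at that boundary.
    """

    perm: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "perm", np.asarray(self.perm, dtype=np.int64)
        )
        p = np.sort(self.perm)
        if not np.array_equal(p, np.arange(len(self.perm))):
            raise ConstraintError("not a permutation of 0..m-1")

    def __len__(self) -> int:
        return len(self.perm)

    @classmethod
    def from_one_based(cls, seq) -> "PermutationGenotype":
        return cls(np.asarray(seq, dtype=np.int64) - 1)

    def to_one_based(self) -> np.ndarray:
        return self.perm + 1


@dataclass
class AuxiliaryArrays:
    """Decoding tables for one cloud (node ids, not indices).

    array1: parent slots, node v repeated out_degree(v) times.
    array2: child slots, every non-root node exactly once; |array2| = n - t.
    block_bounds: optional (start, end) child-position ranges marking
        partition blocks in block order.
    """

    array1: np.ndarray
    array2: np.ndarray
    block_bounds: list[tuple[int, int]] | None = None

    def __post_init__(self):
        self.array1 = np.asarray(self.array1, dtype=np.int64)
        self.array2 = np.asarray(self.array2, dtype=np.int64)

    @property
    def n_slots(self) -> int:
        return len(self.array1)

    @property
    def n_children(self) -> int:
        return len(self.array2)

    def index_arrays(self, cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
        """0-based node-index versions of the two arrays for the kernels."""
        slot_node = np.array(
            [cloud.index_of(v) for v in self.array1], dtype=np.int64
        )
        child_node = np.array(
            [cloud.index_of(v) for v in self.array2], dtype=np.int64
        )
        return slot_node, child_node


@dataclass
class WiringForest:
    """A decoded arborization: rooted trees over a cloud with total length."""

    edges: list[tuple[int, int]]
    total_length: float
    cloud_ref: str = ""

    def parent_map(self) -> dict[int, int]:
        return {c: p for p, c in self.edges}

    def child_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for p, _ in self.edges:
            counts[p] = counts.get(p, 0) + 1
        return counts

    def to_csv(self, path, cloud: PointCloud) -> None:
        import csv

        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["parent_id", "child_id", "length_um"])
            for p, c in self.edges:
                w.writerow([p, c, f"{cloud.edge_length(p, c):.6f}"])

    def summary_json(self, cloud: PointCloud) -> str:
        return json.dumps(
            {"n": cloud.n, "t": cloud.t, "total_length_um": self.total_length}
        )


def build_auxiliary_arrays(
    cloud: PointCloud,
    partition=None,
    pseudo_roots: dict[int, list[int]] | None = None,
    allow_surplus: bool = False,
) -> AuxiliaryArrays:
    """Deterministic auxiliary-array construction for a cloud.

    Unpartitioned: array2 lists non-root nodes ascending by id; array1 lists
    roots first, then branching nodes, each repeated out_degree times,
    ascending by id within class.

    With a partition (see :mod:`neurowire.partition`), both arrays are
    grouped by block in block order; within each block, nodes named in
    ``pseudo_roots[block]`` head the child segment so the junction edges
    sit adjacent to the block boundaries that the junction local search
    sweeps.
    """
    role_of = {int(v): cloud.roles[i] for i, v in enumerate(cloud.node_ids)}
    deg_of = {
        int(v): int(cloud.out_degree[i]) for i, v in enumerate(cloud.node_ids)
    }

    def group_arrays(node_ids, first_children=()):
        node_ids = list(node_ids)
        roots = sorted(v for v in node_ids if role_of[v] == ROLE_ROOT)
        nonroots = sorted(v for v in node_ids if role_of[v] != ROLE_ROOT)
        first = [v for v in first_children if v in set(nonroots)]
        rest = [v for v in nonroots if v not in set(first)]
        a2 = first + rest
        branchers = [v for v in nonroots if deg_of[v] > 0]
        a1: list[int] = []
        for v in roots + branchers:
            a1.extend([v] * deg_of[v])
        return a1, a2

    if partition is None:
        array1, array2 = group_arrays(int(v) for v in cloud.node_ids)
        bounds = None
    else:
        blocks = partition.blocks_in_order(cloud)
        array1, array2, bounds = [], [], []
        for bi, members in enumerate(blocks):
            firsts = (pseudo_roots or {}).get(bi, [])
            a1, a2 = group_arrays((int(v) for v in members), firsts)
            start = len(array2)
            array1.extend(a1)
            array2.extend(a2)
            bounds.append((start, len(array2)))
    if not allow_surplus and len(array1) != len(array2):
        raise ConstraintError(
            f"out_degree sum {len(array1)} != n - t = {len(array2)}"
        )
    if len(array1) < len(array2):
        raise ConstraintError(
            f"insufficient parent capacity: {len(array1)} slots for "
            f"{len(array2)} children"
        )
    return AuxiliaryArrays(
        np.array(array1, dtype=np.int64),
        np.array(array2, dtype=np.int64),
        bounds,
    )


def decode(
    perm: PermutationGenotype, aux: AuxiliaryArrays, cloud: PointCloud
) -> WiringForest:
    """Decode a genotype to a valid wiring forest (deterministic).

    The union-find repair rule fires only when the raw slot assignment
    would close a cycle; see the module docstring.
    """
    if len(perm) != aux.n_slots:
        raise ConstraintError(
            f"permutation length {len(perm)} != number of slots {aux.n_slots}"
        )
    slot_node, child_node = aux.index_arrays(cloud)
    parents = np.empty(cloud.n, dtype=np.int64)
    work = perm.perm.copy()
    status = _kernels.decode_into(work, slot_node, child_node, cloud.n, parents)
    if status < 0:
        raise DecodingError("no feasible parent slot during repair")
    edges = [
        (int(cloud.node_ids[parents[i]]), int(cloud.node_ids[i]))
        for i in range(cloud.n)
        if parents[i] >= 0
    ]
    total = sum(cloud.edge_length(p, c) for p, c in edges)
    return WiringForest(edges=edges, total_length=float(total),
                        cloud_ref=cloud.label)


def forest_length(forest: WiringForest, cloud: PointCloud) -> float:
    """Sum of Euclidean edge lengths of a forest over its cloud (µm)."""
    total = 0.0
    for p, c in forest.edges:
        if int(p) not in cloud._index or int(c) not in cloud._index:
            raise KeyError(f"edge ({p}, {c}) references a node not in the cloud")
        total += cloud.edge_length(p, c)
    return float(total)


def encode(
    forest: WiringForest, aux: AuxiliaryArrays, cloud: PointCloud
) -> PermutationGenotype:
    """Encode a valid forest as a genotype; decode(encode(f)) == f on edges.

    Each child position receives the lowest unused parent slot belonging to
    its parent node; surplus slots (partitioned sub-problems) fill the tail
    in ascending order.  Raises :class:`ConstraintError` if the forest
    violates the cloud's degree or role constraints.
    """
    from .validate import check_forest

    check_forest(forest, cloud)
    parent_of = forest.parent_map()
    slots_of: dict[int, list[int]] = {}
    for idx, v in enumerate(aux.array1):
        slots_of.setdefault(int(v), []).append(idx)
    used: set[int] = set()
    perm = np.empty(aux.n_slots, dtype=np.int64)
    for k, child in enumerate(aux.array2):
        child = int(child)
        if child not in parent_of:
            raise ConstraintError(f"non-root node {child} has no parent")
        p = parent_of[child]
        free = [s for s in slots_of.get(p, []) if s not in used]
        if not free:
            raise ConstraintError(
                f"node {p} exceeds its out_degree (no free slot for child {child})"
            )
        perm[k] = free[0]
        used.add(free[0])
    leftover = [s for s in range(aux.n_slots) if s not in used]
    perm[aux.n_children:] = leftover
    return PermutationGenotype(perm)
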