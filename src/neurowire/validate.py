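"""Independent forest validity checker.

Deliberately separate from the decoding machinery: uses its own union-find
and parent bookkeeping so it can serve as an oracle for decoded genotypes
and merged partition solutions.
"""

from __future__ import annotations

from .drcmst import WiringForest
from .morphology import PointCloud

__all__ = ["ForestInvalidError", "check_forest", "is_valid_forest"]


class ForestInvalidError(ValueError):
    pass


def check_forest(
    forest: WiringForest, cloud: PointCloud, exact_degrees: bool = False
) -> None:
    """Raise :class:`ForestInvalidError` unless the forest is a valid
    degree- and role-respecting spanning arborization of the cloud:

    - exactly n - t edges, endpoints all in the cloud;
    - every non-root has exactly one parent, roots have none;
    - each node's child count <= out_degree (== when ``exact_degrees``);
    - acyclic, i.e. the edges union into n - (n - t) = t components, each
      containing exactly one root.
    """
    ids = set(int(v) for v in cloud.node_ids)
    roots = set(cloud.root_ids())
    n, t = cloud.n, cloud.t
    if len(forest.edges) != n - t:
        raise ForestInvalidError(
            f"expected {n - t} edges, got {len(forest.edges)}"
        )
    parent_of: dict[int, int] = {}
    child_count: dict[int, int] = {}
    for p, c in forest.edges:
        if p not in ids or c not in ids:
            raise ForestInvalidError(f"edge ({p}, {c}) leaves the cloud")
        if c in roots:
            raise ForestInvalidError(f"root {c} has a parent")
        if c in parent_of:
            raise ForestInvalidError(f"node {c} has two parents")
        parent_of[c] = p
        child_count[p] = child_count.get(p, 0) + 1
    for v in ids - roots:
        if v not in parent_of:
            raise ForestInvalidError(f"non-root node {v} has no parent")
    for i, v in enumerate(cloud.node_ids):
        v = int(v)
        got = child_count.get(v, 0)
        cap = int(cloud.out_degree[i])
        if got > cap or (exact_degrees and got != cap):
            raise ForestInvalidError(
                f"node {v}: child count {got} vs out_degree {cap}"
            )

    # union-find acyclicity / reachability
    uf = {v: v for v in ids}

    def find(x: int) -> int:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for p, c in forest.edges:
        rp, rc = find(p), find(c)
        if rp == rc:
            raise ForestInvalidError(f"edge ({p}, {c}) closes a cycle")
        uf[rp] = rc
    comp_root: dict[int, int] = {}
    for r in roots:
        cr = find(r)
        if cr in comp_root:
            raise ForestInvalidError("two roots share one component")
        comp_root[cr] = r
    for v in ids:
        if find(v) not in comp_root:
            raise ForestInvalidError(f"node {v} unreachable from any root")


def is_valid_forest(
    forest: WiringForest, cloud: PointCloud, exact_degrees: bool = False
) -> bool:
    try:
        check_forest(forest, cloud, exact_degrees=exact_degrees)
    except ForestInvalidError:
        return False
    return True
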