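"""Self-contained validation of the wiring solver against a known optimum.

Random 3D point clouds are generated, their Euclidean minimum spanning
trees built, and per-node degree and role constraints derived *from the
MST itself*, which makes the MST the known optimum of the induced
degree/role-constrained problem.  The solver's excess over the MST length
(the *MST gap*, in percent) then measures pure algorithmic performance,
with no neuronal data required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .morphology import (
    ROLE_BIFURCATION,
    ROLE_ROOT,
    ROLE_TERMINAL,
    PointCloud,
)
from .partition import (
    derive_seed,
    kmeans_partition,
    optimize_partitioned,
    soma_distance_partition,
)
from .ssga import GAConfig, ssga_optimize

__all__ = [
    "BenchmarkSpec",
    "BenchmarkResult",
    "random_cloud",
    "prim_mst",
    "constraints_from_tree",
    "mst_gap_benchmark",
]

logger = logging.getLogger(__name__)

#: partitioned solves are only worthwhile above this cloud size
UNPARTITIONED_LIMIT = 100


@dataclass
class BenchmarkSpec:
    """One benchmark condition: cloud size, replicate count, distribution
    (uniform cube of given side, or uniform ball of given radius; the
    spatial scale cancels in the gap ratio) and partitioning method
    ('none', 'kmeans', 'soma_distance', or 'best' = shorter of the two)."""

    n: int
    replicates: int = 10
    distribution: str = "uniform_cube"
    size: float = 100.0
    partition_method: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.distribution not in ("uniform_cube", "uniform_ball"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.partition_method not in ("none", "kmeans", "soma_distance", "best"):
            raise ValueError(
                f"unknown partition_method {self.partition_method!r}"
            )


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    mean_gap: float
    sd_gap: float
    spec: BenchmarkSpec = None

    def summary(self) -> dict:
        return {
            "n": int(self.spec.n) if self.spec else None,
            "replicates": len(self.table["replicate"].unique()),
            "mean_gap_percent": self.mean_gap,
            "sd_gap_percent": self.sd_gap,
        }


def random_cloud(
    n: int, distribution: str = "uniform_cube", size: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """i.i.d. random 3D points: uniform in a cube of side ``size`` or in a
    ball of radius ``size`` (rejection sampling).  Deterministic per seed."""
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    if distribution == "uniform_cube":
        return rng.uniform(0.0, size, size=(n, 3))
    if distribution == "uniform_ball":
        pts = np.empty((n, 3))
        got = 0
        while got < n:
            cand = rng.uniform(-size, size, size=(2 * (n - got), 3))
            keep = cand[np.linalg.norm(cand, axis=1) <= size]
            take = min(len(keep), n - got)
            pts[got:got + take] = keep[:take]
            got += take
        return pts
    raise ValueError(f"unknown distribution {distribution!r}")


def prim_mst(points: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Euclidean minimum spanning tree of a point set.

    Returns (edges as index pairs, total length).  The Euclidean MST is
    unique for generic point sets, so any exact MST algorithm yields the
    tree Prim's would.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    dense = squareform(pdist(points))
    tree = minimum_spanning_tree(dense).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(tree.row, tree.col)]
    return edges, float(tree.data.sum())


def constraints_from_tree(
    points: np.ndarray,
    edges: list[tuple[int, int]],
    root: int,
    label: str = "benchmark",
) -> PointCloud:
    """Orient a spanning tree at ``root`` and freeze each node's child count
    as its out-degree constraint (roles follow: root / branching /
    terminal).  The source tree is then a feasible — and optimal, when it
    is the MST — solution of the induced problem; it becomes the cloud's
    ``real_edges``."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    if len(order) != n:
        raise ValueError("edges do not span the points")
    out_deg = np.zeros(n, dtype=np.int64)
    for v, p in parent.items():
        if p is not None:
            out_deg[p] += 1
    roles = []
    for i in range(n):
        if i == root:
            roles.append(ROLE_ROOT)
        elif out_deg[i] == 0:
            roles.append(ROLE_TERMINAL)
        else:
            roles.append(ROLE_BIFURCATION)
    directed = [
        (int(p) + 1, int(v) + 1) for v, p in parent.items() if p is not None
    ]
    cloud = PointCloud(
        node_ids=np.arange(1, n + 1),
        xyz=points,
        roles=roles,
        out_degree=out_deg,
        compartment="axon",
        real_edges=directed,
        label=label,
    )
    cloud.validate()
    return cloud


def _solve_one(
    cloud: PointCloud,
    spec: BenchmarkSpec,
    config: GAConfig,
    repeats: int,
    junction_window: int,
    group_size: int,
    kmeans_k,
) -> tuple[float, str]:
    method = spec.partition_method
    if method == "none" or cloud.n <= UNPARTITIONED_LIMIT:
        res = ssga_optimize(cloud, config)
        return res.best_length, "none"
    candidates = []
    if method in ("kmeans", "best"):
        part = kmeans_partition(cloud, k=kmeans_k, seed=config.seed)
        r = optimize_partitioned(
            cloud, part, config, repeats=repeats,
            junction_window=junction_window,
        )
        candidates.append((r.best_forest.total_length, f"kmeans(k={part.parameters['k']})"))
    if method in ("soma_distance", "best"):
        part = soma_distance_partition(cloud, group_size=group_size)
        r = optimize_partitioned(
            cloud, part, config, repeats=repeats,
            junction_window=junction_window,
        )
        candidates.append(
            (r.best_forest.total_length, f"soma_distance(group_size={group_size})")
        )
    return min(candidates)


def mst_gap_benchmark(
    spec: BenchmarkSpec,
    ga_config: GAConfig | None = None,
    repeats: int = 20,
    junction_window: int = 10,
    group_size: int = 100,
    kmeans_k="auto",
) -> BenchmarkResult:
    """Run the MST-gap experiment for one condition.

    Per replicate: random cloud -> Euclidean MST -> constraints from the
    MST rooted at the node nearest the centroid -> solve (unpartitioned up
    to 100 nodes, else with the requested partitioning) ->
    gap = 100 x (found - MST) / MST.  Returns per-replicate gaps and their
    mean/sd.
    """
    ga_config = ga_config or GAConfig()
    rows = []
    for rep in range(spec.replicates):
        pts = random_cloud(
            spec.n, spec.distribution, spec.size,
            seed=derive_seed(spec.seed, rep),
        )
        edges, mst_len = prim_mst(pts)
        centroid = pts.mean(axis=0)
        root = int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))
        cloud = constraints_from_tree(
            pts, edges, root, label=f"bench_n{spec.n}_r{rep}"
        )
        cfg = ga_config.with_(seed=derive_seed(spec.seed, rep, 7))
        found, method = _solve_one(
            cloud, spec, cfg, repeats, junction_window, group_size, kmeans_k
        )
        gap = 100.0 * (found - mst_len) / mst_len
        if -1e-6 < gap < 0.0:
            gap = 0.0  # MST optimality: tiny negatives are float noise
        rows.append(
            {
                "n": spec.n,
                "method": method,
                "replicate": rep,
                "mst_length": mst_len,
                "found_length": found,
                "gap_percent": gap,
            }
        )
        logger.info(
            "benchmark n=%d rep %d: MST %.2f, found %.2f (gap %.2f%%, %s)",
            spec.n, rep, mst_len, found, gap, method,
        )
    table = pd.DataFrame(rows)
    return BenchmarkResult(
        table=table,
        mean_gap=float(table["gap_percent"].mean()),
        sd_gap=float(table["gap_percent"].std(ddof=1))
        if len(table) > 1
        else 0.0,
        spec=spec,
    )
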