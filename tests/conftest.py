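"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from neurowire import PermutationGenotype, build_auxiliary_arrays
from neurowire._kernels import decode_eval
from neurowire.morphology import (
    ROLE_BIFURCATION,
    ROLE_ROOT,
    ROLE_TERMINAL,
    PointCloud,
)


def random_tree_cloud(
    n: int, t: int, seed: int, size: float = 100.0
) -> PointCloud:
    """A random forest over random 3D points: the first t nodes are roots,
    every later node attaches to a uniformly chosen earlier node; degree
    constraints are derived from the resulting child counts."""
    assert 1 <= t < n
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0, size, size=(n, 3))
    parent = {}
    for i in range(t, n):
        parent[i] = int(rng.integers(0, i))
    out_deg = np.zeros(n, dtype=np.int64)
    for i, p in parent.items():
        out_deg[p] += 1
    roles = []
    for i in range(n):
        if i < t:
            roles.append(ROLE_ROOT)
        elif out_deg[i] == 0:
            roles.append(ROLE_TERMINAL)
        else:
            roles.append(ROLE_BIFURCATION)
    return PointCloud(
        node_ids=np.arange(1, n + 1),
        xyz=xyz,
        roles=roles,
        out_degree=out_deg,
        compartment="dendrites",
        real_edges=[(p + 1, c + 1) for c, p in parent.items()],
        label=f"random_tree_{n}_{t}_{seed}",
    )


def enumerate_optimum(cloud: PointCloud) -> tuple[float, int]:
    """Brute force: decode every permutation, return (min length, count)."""
    aux = build_auxiliary_arrays(cloud)
    slot_node, child_node = aux.index_arrays(cloud)
    m = aux.n_slots
    parents = np.empty(cloud.n, dtype=np.int64)
    best = np.inf
    count = 0
    for p in itertools.permutations(range(m)):
        f = decode_eval(
            np.array(p, dtype=np.int64), slot_node, child_node, cloud.n,
            cloud.xyz, parents,
        )
        best = min(best, f)
        count += 1
    return float(best), count


@pytest.fixture
def worked_example_cloud() -> PointCloud:
    """The ten-point, two-tree worked example: roots 1-2 (out-degree 1),
    bifurcations 3-5 (out-degree 2), terminals 6-10."""
    rng = np.random.default_rng(42)
    return PointCloud(
        node_ids=np.arange(1, 11),
        xyz=rng.uniform(0, 100, size=(10, 3)),
        roles=[ROLE_ROOT] * 2 + [ROLE_BIFURCATION] * 3 + [ROLE_TERMINAL] * 5,
        out_degree=np.array([1, 1, 2, 2, 2, 0, 0, 0, 0, 0]),
        compartment="dendrites",
        real_edges=[],
        label="worked_example",
    )
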