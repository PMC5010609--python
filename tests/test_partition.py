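"""Spatial partitioning, block merging and junction polishing."""

import numpy as np
import pytest

from neurowire import (
    GAConfig,
    build_auxiliary_arrays,
    decode,
    encode,
    junction_local_search,
    kmeans_partition,
    optimize_partitioned,
    soma_distance_partition,
    ssga_optimize,
)
from neurowire.benchmark import constraints_from_tree, prim_mst, random_cloud
from neurowire.morphology import PointCloud
from neurowire.partition import Partition, auto_k, choose_axon_method, derive_seed
from neurowire.validate import check_forest

from conftest import enumerate_optimum


def mst_cloud(n, seed, size=100.0):
    pts = random_cloud(n, seed=seed, size=size)
    edges, length = prim_mst(pts)
    root = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    return constraints_from_tree(pts, edges, root), length


class TestPartitioning:
    @pytest.mark.parametrize("n,k", [(274, 3), (80, 1), (500, 5), (150, 2)])
    def test_auto_k_rounds_to_hundreds(self, n, k):
        assert auto_k(n) == k

    def test_kmeans_root_block_first_and_covers_cloud(self):
        cloud, _ = mst_cloud(220, seed=1)
        part = kmeans_partition(cloud, seed=0)
        assert part.parameters["k"] == 2
        assert set(part.assignment) == {int(v) for v in cloud.node_ids}
        root = cloud.root_ids()[0]
        assert part.block_order[0] == part.assignment[root]

    def test_kmeans_k_equals_n_degenerate(self):
        cloud, _ = mst_cloud(12, seed=2)
        part = kmeans_partition(cloud, k=12, seed=0)
        assert len(set(part.assignment.values())) == 12

    def test_kmeans_k_out_of_range(self):
        cloud, _ = mst_cloud(10, seed=3)
        with pytest.raises(ValueError):
            kmeans_partition(cloud, k=11)

    def test_soma_distance_block_sizes(self):
        cloud, _ = mst_cloud(800, seed=4)
        part = soma_distance_partition(cloud, group_size=125)
        sizes = [len(b) for b in part.blocks_in_order(cloud)]
        assert sizes == [125] * 6 + [50]

    def test_soma_distance_shells_ordered_by_distance(self):
        cloud, _ = mst_cloud(300, seed=5)
        part = soma_distance_partition(cloud, group_size=100)
        origin = cloud.coords_of(cloud.root_ids()[0])
        blocks = part.blocks_in_order(cloud)
        maxima = [
            max(np.linalg.norm(cloud.coords_of(v) - origin) for v in blk)
            for blk in blocks[:-1]
        ]
        minima = [
            min(np.linalg.norm(cloud.coords_of(v) - origin) for v in blk)
            for blk in blocks[1:]
        ]
        for hi, lo in zip(maxima, minima):
            assert hi <= lo + 1e-9

    def test_soma_distance_single_block_when_group_size_exceeds_n(self):
        cloud, _ = mst_cloud(40, seed=6)
        part = soma_distance_partition(cloud, group_size=100)
        assert part.n_blocks == 1

    def test_group_size_must_be_at_least_two(self):
        cloud, _ = mst_cloud(10, seed=7)
        with pytest.raises(ValueError):
            soma_distance_partition(cloud, group_size=1)


class TestOptimizePartitioned:
    def test_single_block_equals_unpartitioned_run(self):
        cloud, _ = mst_cloud(40, seed=8)
        part = kmeans_partition(cloud, k=1, seed=0)
        cfg = GAConfig(seed=9, max_evaluations=4000)
        merged = optimize_partitioned(cloud, part, cfg, repeats=1)
        direct = ssga_optimize(cloud, cfg.with_(seed=derive_seed(9, 0, 0)))
        assert merged.best_length == pytest.approx(direct.best_length)
        assert sorted(merged.best_forest.edges) == sorted(
            direct.best_forest.edges
        )

    def test_merged_forest_valid_both_methods(self):
        cloud, mst_len = mst_cloud(230, seed=10)
        cfg = GAConfig(seed=1, max_evaluations=5000)
        for part in (
            kmeans_partition(cloud, seed=1),
            soma_distance_partition(cloud, group_size=100),
        ):
            res = optimize_partitioned(cloud, part, cfg, repeats=2)
            check_forest(res.best_forest, cloud, exact_degrees=True)
            assert res.best_length >= mst_len - 1e-9
            assert res.repeats_used == 2

    def test_more_repeats_never_worse(self):
        cloud, _ = mst_cloud(150, seed=11)
        part = kmeans_partition(cloud, k=2, seed=0)
        cfg = GAConfig(seed=2, max_evaluations=3000)
        one = optimize_partitioned(cloud, part, cfg, repeats=1)
        five = optimize_partitioned(cloud, part, cfg, repeats=5)
        assert five.best_length <= one.best_length + 1e-9

    def test_terminal_rich_blocks_are_balanced_with_extra_pseudo_roots(self):
        """A hand-built partition isolating mostly terminals still merges
        into a valid global tree."""
        cloud, _ = mst_cloud(60, seed=12)
        terminals = [
            int(v)
            for i, v in enumerate(cloud.node_ids)
            if cloud.out_degree[i] == 0
        ]
        assignment = {
            int(v): (1 if int(v) in set(terminals[: len(terminals) // 2]) else 0)
            for v in cloud.node_ids
        }
        part = Partition(
            method="kmeans", assignment=assignment, block_order=[0, 1],
            parameters={"k": 2},
        )
        res = optimize_partitioned(
            cloud, part, GAConfig(seed=3, max_evaluations=3000), repeats=1
        )
        check_forest(res.best_forest, cloud, exact_degrees=True)


class TestJunctionLocalSearch:
    def _two_block_setup(self):
        """Collinear points whose optimum is the plain chain, with the
        junction between the two halves."""
        n = 8
        xyz = np.column_stack(
            [np.arange(n, dtype=float), np.zeros(n), np.zeros(n)]
        )
        edges = [(i, i + 1) for i in range(n - 1)]
        cloud = constraints_from_tree(xyz, edges, root=0, label="chain")
        part = Partition(
            method="kmeans",
            assignment={int(v): (0 if int(v) <= 4 else 1) for v in cloud.node_ids},
            block_order=[0, 1],
            parameters={"k": 2},
        )
        aux = build_auxiliary_arrays(
            cloud, partition=part, pseudo_roots={1: [5]}
        )
        return cloud, part, aux

    def test_window_zero_is_identity(self):
        cloud, _part, aux = self._two_block_setup()
        from neurowire.drcmst import PermutationGenotype

        perm = PermutationGenotype(np.random.default_rng(0).permutation(7))
        out = junction_local_search(perm, aux, cloud, window=0)
        assert np.array_equal(out.perm, perm.perm)

    def test_never_worsens(self):
        cloud, _part, aux = self._two_block_setup()
        from neurowire.drcmst import PermutationGenotype

        rng = np.random.default_rng(1)
        for _ in range(10):
            perm = PermutationGenotype(rng.permutation(7))
            before = decode(perm, aux, cloud).total_length
            out = junction_local_search(perm, aux, cloud, window=3)
            after = decode(out, aux, cloud).total_length
            assert after <= before + 1e-9

    def test_uncrosses_junction_to_brute_force_optimum(self):
        """Deliberately cross the chain at the block boundary; the polish
        step must recover the global optimum (the straight chain)."""
        cloud, _part, aux = self._two_block_setup()
        optimum, _ = enumerate_optimum(cloud)
        crossed_edges = [(1, 2), (2, 3), (3, 4), (4, 6), (6, 5), (5, 7), (7, 8)]
        from neurowire.drcmst import WiringForest

        crossed = WiringForest(edges=crossed_edges, total_length=0.0)
        perm = encode(crossed, aux, cloud)
        assert decode(perm, aux, cloud).total_length > optimum + 1.0
        polished = junction_local_search(perm, aux, cloud, window=4)
        assert decode(polished, aux, cloud).total_length == pytest.approx(
            optimum
        )


class TestChooseAxonMethod:
    def test_returns_min_of_both_methods_and_records_choice(self):
        cloud, mst_len = mst_cloud(210, seed=13)
        cfg = GAConfig(seed=4, max_evaluations=3000)
        res = choose_axon_method(
            cloud, cfg, repeats=1, group_sizes=(100, 150)
        )
        km = optimize_partitioned(
            cloud, kmeans_partition(cloud, seed=cfg.seed), cfg, repeats=1
        )
        sd = min(
            optimize_partitioned(
                cloud, soma_distance_partition(cloud, gs), cfg, repeats=1
            ).best_length
            for gs in (100, 150)
        )
        assert res.best_length == pytest.approx(min(km.best_length, sd))
        assert res.method_chosen.startswith(("kmeans", "soma_distance"))
        check_forest(res.best_forest, cloud, exact_degrees=True)
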