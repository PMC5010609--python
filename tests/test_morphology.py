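"""Parsing and critical-point extraction."""

import io

import numpy as np
import pytest

from neurowire.morphology import (
    FormatError,
    MultifurcationError,
    NeuronReconstruction,
    PointCloud,
    Sample,
    compartment_arc_length,
    extract_critical_cloud,
    parse_asc,
    parse_swc,
    real_wiring_length,
)
from neurowire.synthetic import SyntheticNeuronSpec, generate_synthetic_neuron

MINIMAL_SWC = """\
# soma, axon child, axon grandchild
1 1 0 0 0 5 -1
2 2 0 0 10 1 1
3 2 0 0 20 1 2
"""


class TestParseSwc:
    def test_minimal_chain(self):
        rec = parse_swc(io.StringIO(MINIMAL_SWC))
        assert rec.n_samples == 3
        assert len(rec.parentless()) == 1
        assert rec.sample(3).parent_id == 2
        assert rec.sample(2).type_code == 2

    def test_orphan_parent_rejected(self):
        bad = "1 1 0 0 0 5 -1\n2 2 0 0 1 1 9\n"
        with pytest.raises(FormatError, match="parent 9"):
            parse_swc(io.StringIO(bad))

    def test_forward_reference_rejected(self):
        # a parent declared later would permit cycles; the dialect forbids it
        bad = "1 1 0 0 0 5 2\n2 2 0 0 1 1 -1\n"
        with pytest.raises(FormatError, match="sample 1"):
            parse_swc(io.StringIO(bad))

    def test_duplicate_id_rejected(self):
        bad = "1 1 0 0 0 5 -1\n1 2 0 0 1 1 1\n"
        with pytest.raises(FormatError, match="duplicate"):
            parse_swc(io.StringIO(bad))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(FormatError, match="7 columns"):
            parse_swc(io.StringIO("1 1 0 0 0 5\n"))


def _chain_rec(samples):
    return NeuronReconstruction(samples, neuron_label="toy")


class TestExtraction:
    def test_chain_compresses_to_root_and_terminal(self):
        # root—a—b—tip: a, b are tracing points, not critical
        samples = [
            Sample(1, 1, 0, 0, 0, 5, None),
            Sample(2, 2, 0, 0, 1, 1, 1),
            Sample(3, 2, 0, 0, 2, 1, 2),
            Sample(4, 2, 0, 0, 3, 1, 3),
            Sample(5, 2, 0, 0, 4, 1, 4),
        ]
        cloud = extract_critical_cloud(_chain_rec(samples), "axon")
        assert cloud.n == 2
        assert sorted(cloud.roles) == ["root", "terminal"]
        assert len(cloud.real_edges) == 1
        assert real_wiring_length(cloud) == pytest.approx(3.0)

    def test_y_tree(self):
        samples = [
            Sample(1, 1, 0, 0, 0, 5, None),
            Sample(2, 3, 0, 0, 1, 1, 1),
            Sample(3, 3, 0, 0, 2, 1, 2),   # bifurcation
            Sample(4, 3, 1, 0, 2, 1, 3),
            Sample(5, 3, -1, 0, 2, 1, 3),
        ]
        cloud = extract_critical_cloud(_chain_rec(samples), "dendrites")
        assert cloud.n == 4
        assert cloud.t == 1
        assert sorted(cloud.roles) == ["bifurcation", "root", "terminal", "terminal"]
        assert len(cloud.real_edges) == 3
        assert int(cloud.out_degree.sum()) == cloud.n - cloud.t

    def test_multifurcation_raises_and_override(self):
        samples = [
            Sample(1, 1, 0, 0, 0, 5, None),
            Sample(2, 2, 0, 0, 1, 1, 1),
            Sample(3, 2, 0, 0, 2, 1, 2),
            Sample(4, 2, 1, 0, 3, 1, 3),
            Sample(5, 2, -1, 0, 3, 1, 3),
            Sample(6, 2, 0, 1, 3, 1, 3),
        ]
        rec = _chain_rec(samples)
        with pytest.raises(MultifurcationError, match="3"):
            extract_critical_cloud(rec, "axon")
        cloud = extract_critical_cloud(rec, "axon", allow_multifurcations=True)
        trifurcation = cloud.out_degree[
            [i for i, r in enumerate(cloud.roles) if r == "bifurcation"][0]
        ]
        assert trifurcation == 3

    def test_soma_never_in_cloud_and_root_is_first_traced_sample(self):
        samples = [
            Sample(1, 1, 0, 0, 0, 5, None),
            Sample(2, 1, 0, 0, 1, 5, 1),
            Sample(3, 2, 3, 4, 0, 1, 2),
            Sample(4, 2, 3, 4, 12, 1, 3),
        ]
        cloud = extract_critical_cloud(_chain_rec(samples), "axon")
        assert cloud.n == 2
        root_xyz = cloud.coords_of(cloud.root_ids()[0])
        assert np.allclose(root_xyz, [3, 4, 0])

    def test_basal_and_apical_merge_into_dendrites(self):
        spec = SyntheticNeuronSpec(
            n_dendritic_trees=3, bifurcations_per_tree=2,
            axon_bifurcations=2, include_apical=True, seed=1,
        )
        neuron = generate_synthetic_neuron(spec)
        rec = parse_swc(io.StringIO(neuron.swc_text))
        cloud = extract_critical_cloud(rec, "dendrites")
        assert cloud.t == 3  # the apical-coded tree counts with the rest

    def test_missing_compartment_errors(self):
        rec = parse_swc(io.StringIO(MINIMAL_SWC))
        with pytest.raises(ValueError, match="no dendrites samples"):
            extract_critical_cloud(rec, "dendrites")


class TestAgainstGenerator:
    """Round trips against the generator's recorded ground truth."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_swc_topology_and_length_match_truth(self, seed):
        spec = SyntheticNeuronSpec(
            n_dendritic_trees=4, bifurcations_per_tree=5,
            axon_bifurcations=12, seed=seed,
        )
        neuron = generate_synthetic_neuron(spec)
        rec = parse_swc(io.StringIO(neuron.swc_text))
        for comp in ("dendrites", "axon"):
            cloud = extract_critical_cloud(rec, comp)
            truth = neuron.truth[comp]
            assert cloud.n == truth["n"]
            assert cloud.t == truth["t"]
            got = real_wiring_length(cloud)
            assert got == pytest.approx(truth["critical_length"], rel=1e-9)

    def test_five_dendritic_trees_give_five_roots(self):
        spec = SyntheticNeuronSpec(
            n_dendritic_trees=5, bifurcations_per_tree=3,
            axon_bifurcations=3, seed=9,
        )
        neuron = generate_synthetic_neuron(spec)
        rec = parse_swc(io.StringIO(neuron.swc_text))
        assert extract_critical_cloud(rec, "dendrites").t == 5

    def test_asc_parser_agrees_with_swc(self):
        spec = SyntheticNeuronSpec(
            n_dendritic_trees=3, bifurcations_per_tree=4,
            axon_bifurcations=6, include_apical=True, seed=4,
        )
        neuron = generate_synthetic_neuron(spec)
        rec_swc = parse_swc(io.StringIO(neuron.swc_text))
        rec_asc = parse_asc(io.StringIO(neuron.asc_text))
        for comp in ("dendrites", "axon"):
            a = extract_critical_cloud(rec_swc, comp)
            b = extract_critical_cloud(rec_asc, comp)
            assert a.n == b.n and a.t == b.t
            assert real_wiring_length(a) == pytest.approx(
                real_wiring_length(b), rel=1e-6
            )

    def test_chord_never_exceeds_arc(self):
        spec = SyntheticNeuronSpec(seed=5)
        neuron = generate_synthetic_neuron(spec)
        rec = parse_swc(io.StringIO(neuron.swc_text))
        for comp in ("dendrites", "axon"):
            cloud = extract_critical_cloud(rec, comp)
            assert real_wiring_length(cloud) <= compartment_arc_length(rec, comp)

    def test_extraction_is_idempotent(self):
        """Re-extracting from a reconstruction built from the critical tree
        returns the same cloud."""
        spec = SyntheticNeuronSpec(
            n_dendritic_trees=3, bifurcations_per_tree=4,
            axon_bifurcations=5, seed=6,
        )
        neuron = generate_synthetic_neuron(spec)
        rec = parse_swc(io.StringIO(neuron.swc_text))
        cloud = extract_critical_cloud(rec, "dendrites")
        # rebuild: one sample per critical point, soma attached stems
        samples = [Sample(1, 1, 0, 0, 0, 5, None)]
        parent_of = {c: p for p, c in cloud.real_edges}
        for i, nid in enumerate(cloud.node_ids):
            nid = int(nid)
            pid = parent_of.get(nid)
            samples.append(
                Sample(
                    nid + 1, 3,
                    *cloud.xyz[i], 1.0,
                    1 if pid is None else pid + 1,
                )
            )
        samples[1:] = sorted(samples[1:], key=lambda s: (
            0 if s.parent_id == 1 else 1, s.id))
        # re-declare in topological order (parents before children)
        ordered, emitted = [], {1}
        pendings = samples[1:]
        while pendings:
            rest = []
            for s in pendings:
                if s.parent_id in emitted:
                    ordered.append(s)
                    emitted.add(s.id)
                else:
                    rest.append(s)
            pendings = rest
        rec2 = NeuronReconstruction([samples[0]] + ordered)
        cloud2 = extract_critical_cloud(rec2, "dendrites")
        assert cloud2.n == cloud.n and cloud2.t == cloud.t
        assert sorted(cloud2.roles) == sorted(cloud.roles)
        assert real_wiring_length(cloud2) == pytest.approx(
            real_wiring_length(cloud), rel=1e-9
        )

    def test_cloud_csv_round_trip(self, tmp_path):
        spec = SyntheticNeuronSpec(seed=7)
        neuron = generate_synthetic_neuron(spec)
        rec = parse_swc(io.StringIO(neuron.swc_text))
        cloud = extract_critical_cloud(rec, "axon")
        path = tmp_path / "cloud.csv"
        cloud.to_csv(path)
        back = PointCloud.from_csv(path)
        assert back.n == cloud.n
        assert np.allclose(back.xyz, cloud.xyz)
        assert back.roles == cloud.roles
        assert sorted(back.real_edges) == sorted(cloud.real_edges)
        assert real_wiring_length(back) == pytest.approx(
            real_wiring_length(cloud)
        )


class TestRealWiringLength:
    def test_three_four_five_edge(self):
        cloud = PointCloud(
            node_ids=np.array([1, 2]),
            xyz=np.array([[0.0, 0, 0], [3.0, 4, 0]]),
            roles=["root", "terminal"],
            out_degree=np.array([1, 0]),
            compartment="axon",
            real_edges=[(1, 2)],
        )
        assert real_wiring_length(cloud) == pytest.approx(5.0)

    def test_additivity_on_y_tree(self):
        cloud = PointCloud(
            node_ids=np.array([1, 2, 3, 4]),
            xyz=np.array(
                [[0.0, 0, 0], [0, 0, 1], [0, 2, 1], [2, 0, 1]]
            ),
            roles=["root", "bifurcation", "terminal", "terminal"],
            out_degree=np.array([1, 2, 0, 0]),
            compartment="dendrites",
            real_edges=[(1, 2), (2, 3), (2, 4)],
        )
        assert real_wiring_length(cloud) == pytest.approx(5.0)

    def test_zero_length_edges_allowed(self):
        cloud = PointCloud(
            node_ids=np.array([1, 2]),
            xyz=np.zeros((2, 3)),
            roles=["root", "terminal"],
            out_degree=np.array([1, 0]),
            compartment="axon",
            real_edges=[(1, 2)],
        )
        assert real_wiring_length(cloud) == 0.0

    def test_empty_edges_rejected(self):
        cloud = PointCloud(
            node_ids=np.array([1]),
            xyz=np.zeros((1, 3)),
            roles=["root"],
            out_degree=np.array([0]),
            compartment="axon",
            real_edges=[],
        )
        with pytest.raises(ValueError):
            real_wiring_length(cloud)
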