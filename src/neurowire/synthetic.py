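"""Synthetic bifurcation-only neuron morphologies with known ground truth.

Generates SWC (and Neurolucida ASCII) text for a neuron with a soma,
several dendritic stems and one axonal tree, where every branching point
is a bifurcation and every branch is traced as a degree-2 chain of
intermediate samples with mild lateral jitter (tortuosity).  The critical
points (roots, bifurcations, tips) and the exact chord length between
them are recorded alongside, so every upstream stage — parsing, critical
point extraction, wiring-length measurement, encoding — can be tested
end-to-end without downloading real reconstructions.

What this emulates: branch counts, tree multiplicity, branch-length
statistics and overall shape (spherical vs elongated axonal fields).
What it does not: realistic branch-angle correlations, diameter taper,
or tortuosity driven by obstacles — conclusions about those must come
from real data.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .morphology import (
    SWC_APICAL_DENDRITE,
    SWC_AXON,
    SWC_BASAL_DENDRITE,
    SWC_SOMA,
)

__all__ = ["SyntheticNeuronSpec", "SyntheticNeuron", "generate_synthetic_neuron"]


@dataclass
class SyntheticNeuronSpec:
    """Generation parameters (lengths in micrometres).

    ``shape='elongated'`` stretches the axonal field along z by
    ``aspect_ratio``; dendrites stay isotropic.  ``include_apical`` marks
    one dendritic tree with the apical SWC type code to exercise the
    basal/apical merge."""

    n_dendritic_trees: int = 5
    bifurcations_per_tree: int = 6
    axon_bifurcations: int = 30
    branch_length_mean: float = 40.0
    branch_length_sd: float = 10.0
    tortuosity_points_per_branch: int = 3
    shape: str = "spherical"
    aspect_ratio: float = 3.0
    include_apical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dendritic_trees < 1 or self.bifurcations_per_tree < 1:
            raise ValueError("tree and bifurcation counts must be positive")
        if self.axon_bifurcations < 1:
            raise ValueError("axon_bifurcations must be positive")
        if self.shape not in ("spherical", "elongated"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass
class SyntheticNeuron:
    """Generated morphology text plus ground truth.

    ``truth`` maps each compartment to its critical-point topology:
    node roles/out-degrees keyed by SWC sample id, directed critical
    edges, tree count and exact total chord length (computed from the
    coordinates as written to file)."""

    swc_text: str
    asc_text: str
    truth: dict
    label: str = "synthetic"

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "swc": os.path.join(out_dir, f"{self.label}.swc"),
            "asc": os.path.join(out_dir, f"{self.label}.asc"),
            "truth": os.path.join(out_dir, f"{self.label}.truth.json"),
        }
        with open(paths["swc"], "w") as f:
            f.write(self.swc_text)
        with open(paths["asc"], "w") as f:
            f.write(self.asc_text)
        with open(paths["truth"], "w") as f:
            json.dump(self.truth, f, indent=1)
        return paths


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perturbed_direction(rng, direction: np.ndarray, sd: float = 0.5) -> np.ndarray:
    return _unit(direction + rng.normal(0.0, sd, size=3))


class _Builder:
    def __init__(self):
        self.rows: list[tuple] = []  # (id, type, x, y, z, radius, parent)
        self.next_id = 1

    def add(self, tcode, xyz, radius, parent_id) -> int:
        sid = self.next_id
        self.next_id += 1
        # round to the precision written to file so recorded truth matches
        x, y, z = (round(float(v), 4) for v in xyz)
        self.rows.append((sid, tcode, x, y, z, radius, parent_id))
        return sid

    def coords(self, sid: int) -> np.ndarray:
        row = self.rows[sid - 1]
        return np.array(row[2:5])


def _grow_tree(
    builder: _Builder,
    rng: np.random.Generator,
    tcode: int,
    soma_id: int,
    stem_direction: np.ndarray,
    n_bifurcations: int,
    spec: SyntheticNeuronSpec,
    stretch_z: float = 1.0,
):
    """Grow one bifurcation-only tree; returns ground-truth bookkeeping.

    Critical-point positions are exact branch endpoints; intermediate
    tracing samples get lateral jitter, so the traced arc is never shorter
    than the critical chord."""

    def branch_length() -> float:
        return float(
            np.clip(
                rng.normal(spec.branch_length_mean, spec.branch_length_sd),
                5.0,
                None,
            )
        )

    def stretch(p: np.ndarray) -> np.ndarray:
        return p * np.array([1.0, 1.0, stretch_z])

    def add_branch(parent_sid: int, start: np.ndarray, direction: np.ndarray):
        """One branch from `start`: tortuous chain then a critical endpoint."""
        length = branch_length()
        end = start + direction * length
        prev = parent_sid
        for i in range(1, spec.tortuosity_points_per_branch + 1):
            frac = i / (spec.tortuosity_points_per_branch + 1)
            mid = start + direction * (length * frac)
            mid = mid + rng.normal(0.0, 0.02 * length, size=3)
            prev = builder.add(tcode, stretch(mid), 0.4, prev)
        sid = builder.add(tcode, stretch(end), 0.4, prev)
        return sid, end

    # stem root: first sample of the tree, just off the soma surface
    root_pos = stem_direction * 8.0
    root_sid = builder.add(tcode, stretch(root_pos), 0.6, soma_id)
    crit_parent = {}  # critical sample id -> parent critical sample id
    # the root's single initial branch
    first_sid, first_pos = add_branch(root_sid, root_pos, stem_direction)
    crit_parent[first_sid] = root_sid
    tips = [(first_sid, first_pos, stem_direction)]
    for _ in range(n_bifurcations):
        i = int(rng.integers(len(tips)))
        sid, pos, direction = tips.pop(i)
        for _child in range(2):
            d = _perturbed_direction(rng, direction)
            child_sid, child_pos = add_branch(sid, pos, d)
            crit_parent[child_sid] = sid
            tips.append((child_sid, child_pos, d))
    crit_ids = [root_sid] + sorted(crit_parent)
    children: dict[int, int] = {c: 0 for c in crit_ids}
    for c, p in crit_parent.items():
        children[p] += 1
    nodes = {}
    for sid in crit_ids:
        deg = children[sid]
        if sid == root_sid:
            role = "root"
        elif deg == 0:
            role = "terminal"
        else:
            role = "bifurcation"
        nodes[sid] = {"role": role, "out_degree": deg}
    length = sum(
        float(np.linalg.norm(builder.coords(c) - builder.coords(p)))
        for c, p in crit_parent.items()
    )
    return {
        "root": root_sid,
        "edges": sorted((p, c) for c, p in crit_parent.items()),
        "nodes": nodes,
        "critical_length": length,
    }


def _swc_text(builder: _Builder, label: str) -> str:
    lines = [f"# synthetic bifurcation-only morphology: {label}"]
    for sid, tcode, x, y, z, radius, parent in builder.rows:
        p = -1 if parent is None else parent
        lines.append(f"{sid} {tcode} {x:.4f} {y:.4f} {z:.4f} {radius:.4f} {p}")
    return "\n".join(lines) + "\n"


def _asc_text(builder: _Builder) -> str:
    """Minimal Neurolucida ASCII rendering of the same morphology."""
    children: dict[int | None, list] = {}
    for row in builder.rows:
        children.setdefault(row[6], []).append(row)

    def pt(row) -> str:
        return f"({row[2]:.4f} {row[3]:.4f} {row[4]:.4f} {2 * row[5]:.4f})"

    def chain(row, indent: str) -> list[str]:
        out = [indent + pt(row)]
        kids = children.get(row[0], [])
        while len(kids) == 1:
            row = kids[0]
            out.append(indent + pt(row))
            kids = children.get(row[0], [])
        if kids:
            out.append(indent + "(")
            for i, kid in enumerate(kids):
                out.extend(chain(kid, indent + "  "))
                if i < len(kids) - 1:
                    out.append(indent + "|")
            out.append(indent + ")")
        return out

    blocks = []
    soma_rows = [r for r in builder.rows if r[1] == SWC_SOMA]
    if soma_rows:
        body = ["(  (CellBody)"] + ["  " + pt(r) for r in soma_rows] + [")"]
        blocks.append("\n".join(body))
    soma_ids = {r[0] for r in soma_rows}
    stems = [
        r for r in builder.rows
        if r[1] != SWC_SOMA and (r[6] is None or r[6] in soma_ids)
    ]
    for stem in stems:
        tag = {
            SWC_AXON: "(Axon)",
            SWC_BASAL_DENDRITE: "(Dendrite)",
            SWC_APICAL_DENDRITE: "(Apical)",
        }[stem[1]]
        body = ["(  " + tag] + chain(stem, "  ") + [")"]
        blocks.append("\n".join(body))
    return "\n".join(blocks) + "\n"


def generate_synthetic_neuron(
    spec: SyntheticNeuronSpec, label: str = "synthetic"
) -> SyntheticNeuron:
    """Build one synthetic neuron per the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    builder = _Builder()
    soma_id = builder.add(SWC_SOMA, np.zeros(3), 6.0, None)

    dend_truth = []
    for tree_i in range(spec.n_dendritic_trees):
        tcode = (
            SWC_APICAL_DENDRITE
            if spec.include_apical and tree_i == 0 and spec.n_dendritic_trees > 1
            else SWC_BASAL_DENDRITE
        )
        direction = _unit(rng.normal(size=3))
        dend_truth.append(
            _grow_tree(
                builder, rng, tcode, soma_id, direction,
                spec.bifurcations_per_tree, spec,
            )
        )
    stretch_z = spec.aspect_ratio if spec.shape == "elongated" else 1.0
    axon_truth = _grow_tree(
        builder, rng, SWC_AXON, soma_id, _unit(rng.normal(size=3)),
        spec.axon_bifurcations, spec, stretch_z=stretch_z,
    )

    def compartment_record(trees: list[dict]) -> dict:
        nodes = {}
        edges = []
        for t in trees:
            nodes.update({str(k): v for k, v in t["nodes"].items()})
            edges.extend(t["edges"])
        return {
            "n": len(nodes),
            "t": len(trees),
            "roots": [t["root"] for t in trees],
            "edges_sample_ids": sorted(edges),
            "nodes": nodes,
            "critical_length": sum(t["critical_length"] for t in trees),
        }

    truth = {
        "label": label,
        "spec": asdict(spec),
        "dendrites": compartment_record(dend_truth),
        "axon": compartment_record([axon_truth]),
    }
    return SyntheticNeuron(
        swc_text=_swc_text(builder, label),
        asc_text=_asc_text(builder),
        truth=truth,
        label=label,
    )
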