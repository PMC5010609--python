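"""Reading neuronal reconstructions and collapsing them to critical-point clouds.

A traced morphology is a forest of sample points (SWC rows or Neurolucida
segments); for wiring analysis only the *critical points* matter: the stem
origins (roots), the branching points and the terminal tips of each
compartment.  Degree-2 tracing chains between critical points are path
artefacts of the digitisation and are compressed away, so the resulting
:class:`PointCloud` carries one node per critical point together with the
edges of the real arborization and each node's out-degree (child-branch
count).  Wiring length is always the straight-line (chord) length between
connected critical points; tracing tortuosity is deliberately ignored.
"""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SWC_SOMA",
    "SWC_AXON",
    "SWC_BASAL_DENDRITE",
    "SWC_APICAL_DENDRITE",
    "COMPARTMENTS",
    "ROLE_ROOT",
    "ROLE_BIFURCATION",
    "ROLE_TERMINAL",
    "FormatError",
    "MultifurcationError",
    "Sample",
    "NeuronReconstruction",
    "PointCloud",
    "parse_morphology",
    "parse_swc",
    "parse_asc",
    "extract_critical_cloud",
    "real_wiring_length",
    "compartment_arc_length",
]

SWC_SOMA = 1
SWC_AXON = 2
SWC_BASAL_DENDRITE = 3
SWC_APICAL_DENDRITE = 4

#: SWC type codes per analysis compartment.  Basal and apical dendrites are
#: merged: interneurons lack apical dendrites and all dendrites are analysed
#: as one receptive compartment.
COMPARTMENTS = {
    "axon": (SWC_AXON,),
    "dendrites": (SWC_BASAL_DENDRITE, SWC_APICAL_DENDRITE),
}

ROLE_ROOT = "root"
ROLE_BIFURCATION = "bifurcation"
ROLE_TERMINAL = "terminal"


class FormatError(ValueError):
    """Malformed reconstruction file (bad row, orphan or cyclic parent link)."""


class MultifurcationError(ValueError):
    """A critical point with more than two child branches.

    The analysed neurons are bifurcation-only, so a multifurcation normally
    indicates a tracing artefact; pass ``allow_multifurcations=True`` to
    accept the node with its data-driven out-degree instead.
    """


@dataclass(frozen=True)
class Sample:
    """One traced point: SWC row semantics (coordinates in micrometres)."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class NeuronReconstruction:
    """A full traced morphology: samples with parent links forming a forest."""

    samples: list[Sample]
    source_path: str = ""
    neuron_label: str = ""

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.samples}
        self._children: dict[int, list[Sample]] = {s.id: [] for s in self.samples}
        for s in self.samples:
            if s.parent_id is not None:
                self._children[s.parent_id].append(s)

    def sample(self, sample_id: int) -> Sample:
        return self._by_id[sample_id]

    def children_of(self, sample_id: int) -> list[Sample]:
        return self._children[sample_id]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def parentless(self) -> list[Sample]:
        return [s for s in self.samples if s.parent_id is None]

    def soma_samples(self) -> list[Sample]:
        return [s for s in self.samples if s.type_code == SWC_SOMA]


@dataclass
class PointCloud:
    """Critical points of one compartment.

    ``node_ids`` are stable external identifiers; ``real_edges`` are
    (parent_id, child_id) pairs of the reconstruction's own arborization,
    forming ``t`` rooted trees over the nodes (t = number of roots).
    ``out_degree[i]`` is node i's child-branch count in that arborization
    and doubles as its degree constraint when searching alternatives.
    """

    node_ids: np.ndarray
    xyz: np.ndarray
    roles: list[str]
    out_degree: np.ndarray
    compartment: str
    real_edges: list[tuple[int, int]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.out_degree = np.asarray(self.out_degree, dtype=np.int64)
        self._index = {int(v): i for i, v in enumerate(self.node_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def t(self) -> int:
        """Number of trees (= number of roots)."""
        return sum(1 for r in self.roles if r == ROLE_ROOT)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def coords_of(self, node_id: int) -> np.ndarray:
        return self.xyz[self.index_of(node_id)]

    def root_ids(self) -> list[int]:
        return [
            int(self.node_ids[i])
            for i, r in enumerate(self.roles)
            if r == ROLE_ROOT
        ]

    def edge_length(self, parent_id: int, child_id: int) -> float:
        return float(
            np.linalg.norm(self.coords_of(parent_id) - self.coords_of(child_id))
        )

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants of a cloud derived from a forest."""
        n, t = self.n, self.t
        if int(self.out_degree.sum()) != n - t:
            raise ValueError(
                f"out_degree sum {int(self.out_degree.sum())} != n - t = {n - t}"
            )
        for i, role in enumerate(self.roles):
            deg = int(self.out_degree[i])
            if (role == ROLE_TERMINAL) != (deg == 0):
                raise ValueError(
                    f"node {int(self.node_ids[i])}: role {role} inconsistent "
                    f"with out_degree {deg}"
                )
        if self.real_edges:
            parent_of: dict[int, int] = {}
            for p, c in self.real_edges:
                if c in parent_of:
                    raise ValueError(f"node {c} has two parents in real_edges")
                parent_of[c] = p
            roots = set(self.root_ids())
            for r in roots:
                if r in parent_of:
                    raise ValueError(f"root {r} has a parent in real_edges")
            if len(self.real_edges) != n - t:
                raise ValueError("real_edges do not span the cloud")

    # -- CSV round trip --------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        parent_of = {c: p for p, c in self.real_edges}
        own = isinstance(path_or_buf, (str, os.PathLike))
        f = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            w = csv.writer(f)
            w.writerow(
                ["node_id", "x", "y", "z", "role", "out_degree", "parent_id",
                 "compartment"]
            )
            for i, nid in enumerate(self.node_ids):
                pid = parent_of.get(int(nid), "")
                w.writerow(
                    [int(nid), repr(float(self.xyz[i, 0])),
                     repr(float(self.xyz[i, 1])), repr(float(self.xyz[i, 2])),
                     self.roles[i], int(self.out_degree[i]), pid,
                     self.compartment]
                )
        finally:
            if own:
                f.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "PointCloud":
        own = isinstance(path_or_buf, (str, os.PathLike))
        f = open(path_or_buf, newline="") if own else path_or_buf
        try:
            rows = list(csv.DictReader(f))
        finally:
            if own:
                f.close()
        ids, xyz, roles, degs, edges = [], [], [], [], []
        compartment = rows[0]["compartment"] if rows else "dendrites"
        for r in rows:
            nid = int(r["node_id"])
            ids.append(nid)
            xyz.append([float(r["x"]), float(r["y"]), float(r["z"])])
            roles.append(r["role"])
            degs.append(int(r["out_degree"]))
            if r["parent_id"] not in ("", None):
                edges.append((int(r["parent_id"]), nid))
        return cls(
            node_ids=np.array(ids),
            xyz=np.array(xyz),
            roles=roles,
            out_degree=np.array(degs),
            compartment=compartment,
            real_edges=edges,
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_morphology(path: str, format: str = "auto") -> NeuronReconstruction:
    """Read a reconstruction file in SWC or Neurolucida ASCII format.

    ``format='auto'`` dispatches on the file extension (.swc / .asc).
    """
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        if ext == ".swc":
            format = "swc"
        elif ext == ".asc":
            format = "asc"
        else:
            raise FormatError(f"cannot infer format from extension {ext!r}")
    if format == "swc":
        return parse_swc(path)
    if format == "asc":
        return parse_asc(path)
    raise FormatError(f"unknown format {format!r}")


def parse_swc(path_or_buf) -> NeuronReconstruction:
    """Parse the 7-column NeuroMorpho standardized SWC dialect.

    Whitespace-separated ``id type x y z radius parent`` rows, ``#``
    comments, parent ``-1`` for stems.  Every parent must be declared on an
    earlier row (which also rules out cycles).
    """
    own = isinstance(path_or_buf, (str, os.PathLike))
    source = str(path_or_buf) if own else ""
    f = open(path_or_buf) if own else path_or_buf
    try:
        text = f.read()
    finally:
        if own:
            f.close()
    samples: list[Sample] = []
    seen: set[int] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise FormatError(f"line {lineno}: expected 7 columns, got {len(fields)}")
        try:
            sid = int(fields[0])
            tcode = int(fields[1])
            x, y, z, radius = (float(v) for v in fields[2:6])
            pid = int(fields[6])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        if sid in seen:
            raise FormatError(f"sample {sid}: duplicate id")
        parent = None if pid < 0 else pid
        if parent is not None and parent not in seen:
            raise FormatError(
                f"sample {sid}: parent {parent} not declared earlier"
            )
        seen.add(sid)
        samples.append(Sample(sid, tcode, x, y, z, radius, parent))
    if not samples:
        raise FormatError("no samples in file")
    label = os.path.splitext(os.path.basename(source))[0] if source else ""
    return NeuronReconstruction(samples, source_path=source, neuron_label=label)


_ASC_TOKEN = re.compile(r'\(|\)|\||"[^"]*"|;[^\n]*|[^\s()|;]+')


def _asc_tokens(text: str):
    for match in _ASC_TOKEN.finditer(text):
        tok = match.group(0)
        if tok.startswith(";"):
            continue
        yield tok


def _asc_parse_block(tokens: list[str], pos: int):
    """Parse one parenthesised block into nested python lists (``|`` kept)."""
    out: list = []
    while pos < len(tokens):
        tok = tokens[pos]
        if tok == "(":
            sub, pos = _asc_parse_block(tokens, pos + 1)
            out.append(sub)
        elif tok == ")":
            return out, pos + 1
        else:
            out.append(tok)
            pos += 1
    return out, pos


def parse_asc(path_or_buf) -> NeuronReconstruction:
    """Parse a Neurolucida ASCII (.asc) reconstruction.

    Only coordinates, branch structure and the tree class (CellBody /
    Axon / Dendrite / Apical) are consumed; markers, spines and display
    attributes are ignored.
    """
    own = isinstance(path_or_buf, (str, os.PathLike))
    source = str(path_or_buf) if own else ""
    f = open(path_or_buf) if own else path_or_buf
    try:
        text = f.read()
    finally:
        if own:
            f.close()
    tokens = list(_asc_tokens(text))
    blocks: list = []
    pos = 0
    while pos < len(tokens):
        if tokens[pos] == "(":
            blk, pos = _asc_parse_block(tokens, pos + 1)
            blocks.append(blk)
        else:
            pos += 1

    samples: list[Sample] = []
    counter = [0]

    def new_sample(tcode, point, parent_id):
        counter[0] += 1
        x, y, z = point[0], point[1], point[2]
        radius = point[3] / 2.0 if len(point) > 3 else 0.5
        samples.append(Sample(counter[0], tcode, x, y, z, radius, parent_id))
        return counter[0]

    def is_point(item) -> bool:
        if not isinstance(item, list) or not (3 <= len(item) <= 4):
            return False
        try:
            [float(v) for v in item]
        except (TypeError, ValueError):
            return False
        return True

    def as_point(item) -> list[float]:
        return [float(v) for v in item]

    def walk(items: list, tcode: int, parent_id: int | None) -> None:
        """Consume a chain of points; a trailing sublist with '|' separators
        opens child branches."""
        last = parent_id
        for item in items:
            if is_point(item):
                last = new_sample(tcode, as_point(item), last)
            elif isinstance(item, list) and "|" in item:
                branch: list = []
                for sub in item:
                    if sub == "|":
                        walk(branch, tcode, last)
                        branch = []
                    else:
                        branch.append(sub)
                walk(branch, tcode, last)
            # bare words (Normal, Generated, colour specs ...) are ignored

    for blk in blocks:
        words = {w.strip('"') for w in blk if isinstance(w, str)}
        nested_words = {
            w.strip('"')
            for item in blk
            if isinstance(item, list)
            for w in item
            if isinstance(w, str)
        }
        words |= nested_words
        if "CellBody" in words:
            for item in blk:
                if is_point(item):
                    new_sample(SWC_SOMA, as_point(item), None)
        elif "Axon" in words:
            walk(blk, SWC_AXON, None)
        elif "Apical" in words:
            walk(blk, SWC_APICAL_DENDRITE, None)
        elif "Dendrite" in words:
            walk(blk, SWC_BASAL_DENDRITE, None)
    if not samples:
        raise FormatError("no recognisable CellBody/Axon/Dendrite blocks")
    label = os.path.splitext(os.path.basename(source))[0] if source else ""
    return NeuronReconstruction(samples, source_path=source, neuron_label=label)


# ---------------------------------------------------------------------------
# Critical-point extraction
# ---------------------------------------------------------------------------

def extract_critical_cloud(
    rec: NeuronReconstruction,
    compartment: str,
    allow_multifurcations: bool = False,
) -> PointCloud:
    """Collapse one compartment of a reconstruction to its critical points.

    Soma samples are never cloud nodes: each stem's root is the first
    sample of the compartment in its subtree (the point of origin of the
    dendrite or axon at the cell body).  Degree-2 tracing chains are
    path-compressed; the returned ``real_edges`` connect consecutive
    critical points and ``out_degree`` records each node's child-branch
    count (roots normally 1, bifurcations 2, terminals 0).
    """
    try:
        codes = COMPARTMENTS[compartment]
    except KeyError:
        raise ValueError(
            f"compartment must be one of {sorted(COMPARTMENTS)}, got {compartment!r}"
        ) from None
    comp_ids = {s.id for s in rec.samples if s.type_code in codes}
    if not comp_ids:
        raise ValueError(
            f"reconstruction {rec.neuron_label!r} has no {compartment} samples"
        )

    def comp_children(sid: int) -> list[Sample]:
        return [c for c in rec.children_of(sid) if c.id in comp_ids]

    stems = [
        s
        for s in rec.samples
        if s.id in comp_ids and (s.parent_id is None or s.parent_id not in comp_ids)
    ]

    crit_samples: list[Sample] = []  # discovery order within role class later
    roles: dict[int, str] = {}
    out_deg: dict[int, int] = {}
    edges: list[tuple[int, int]] = []  # (parent sample id, child sample id)

    def next_critical(sample: Sample) -> Sample:
        """Follow a degree-1 tracing chain to the next critical sample."""
        cur = sample
        kids = comp_children(cur.id)
        while len(kids) == 1:
            cur = kids[0]
            kids = comp_children(cur.id)
        return cur

    for stem in stems:
        stack = [(stem, None)]  # (critical sample, parent critical id)
        while stack:
            node, parent_crit = stack.pop()
            kids = comp_children(node.id)
            n_branches = len(kids)
            if parent_crit is None:
                role = ROLE_ROOT
            elif n_branches == 0:
                role = ROLE_TERMINAL
            else:
                role = ROLE_BIFURCATION
            if role != ROLE_ROOT and n_branches > 2 and not allow_multifurcations:
                raise MultifurcationError(
                    f"sample {node.id} has {n_branches} child branches"
                )
            if role == ROLE_ROOT and n_branches > 2 and not allow_multifurcations:
                raise MultifurcationError(
                    f"root sample {node.id} has {n_branches} child branches"
                )
            crit_samples.append(node)
            roles[node.id] = role
            out_deg[node.id] = n_branches
            if parent_crit is not None:
                edges.append((parent_crit, node.id))
            for kid in kids:
                stack.append((next_critical(kid), node.id))

    # Stable numbering: roots, then bifurcations, then terminals, by sample id.
    rank = {ROLE_ROOT: 0, ROLE_BIFURCATION: 1, ROLE_TERMINAL: 2}
    ordered = sorted(crit_samples, key=lambda s: (rank[roles[s.id]], s.id))
    id_map = {s.id: i + 1 for i, s in enumerate(ordered)}
    cloud = PointCloud(
        node_ids=np.arange(1, len(ordered) + 1),
        xyz=np.array([[s.x, s.y, s.z] for s in ordered]),
        roles=[roles[s.id] for s in ordered],
        out_degree=np.array([out_deg[s.id] for s in ordered]),
        compartment=compartment,
        real_edges=[(id_map[p], id_map[c]) for p, c in edges],
        label=rec.neuron_label,
    )
    cloud.validate()
    return cloud


def real_wiring_length(cloud: PointCloud) -> float:
    """Total chord length of the reconstruction's own arborization (µm).

    Sum over ``real_edges`` of the straight-line distance between the two
    critical points; tortuosity of intermediate tracing samples is ignored.
    """
    if not cloud.real_edges:
        raise ValueError("cloud has no real edges")
    return float(
        sum(cloud.edge_length(p, c) for p, c in cloud.real_edges)
    )


def compartment_arc_length(rec: NeuronReconstruction, compartment: str) -> float:
    """Arc length along all tracing samples of a compartment (µm).

    Sums sample-to-parent distances where both endpoints belong to the
    compartment; always >= the critical-point chord length.
    """
    codes = COMPARTMENTS[compartment]
    comp_ids = {s.id for s in rec.samples if s.type_code in codes}
    total = 0.0
    for s in rec.samples:
        if s.id in comp_ids and s.parent_id in comp_ids:
            p = rec.sample(s.parent_id)
            total += float(np.linalg.norm(s.xyz - p.xyz))
    return total
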