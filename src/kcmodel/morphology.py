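"""Labelled neuron morphologies and their electrical discretization.

Morphologies are SWC-style trees of nodes (id, label, x, y, z, radius,
parent).  Beyond the standard SWC region codes (soma = 1, axon = 2,
dendrites = 3) the mushroom-body labelling scheme used here adds
tether = 11, pre-SIZ = 12 and SIZ = 13 (spike initiation zone).  Unknown
labels are preserved but flagged.

Each inter-node edge is treated as a truncated cone (frustum): membrane
area pi*(r1+r2)*L and axial resistance Ra*L/(pi*r1*r2).  A point soma
(single label-1 root) is interpreted as a sphere and mapped to the
equivalent cylinder with L = d = 2r, which preserves the 4*pi*r^2
surface area.  Discretization subdivides every section into segments no
longer than a fixed fraction (default 0.1) of the section's length
constant lambda = sqrt(d * R_m / (4 * R_a)) evaluated at the section
midpoint diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Region codes used by the mushroom-body labelling scheme.
SOMA, AXON, DENDRITE, TETHER, PRE_SIZ, SIZ = 1, 2, 3, 11, 12, 13
KNOWN_LABELS = frozenset({SOMA, AXON, DENDRITE, TETHER, PRE_SIZ, SIZ})

REGION_NAMES = {
    SOMA: "soma",
    AXON: "axon",
    DENDRITE: "dendrite",
    TETHER: "tether",
    PRE_SIZ: "pre_siz",
    SIZ: "siz",
}


class MorphologyError(ValueError):
    """Structural or validation error in a morphology."""


@dataclass(frozen=True)
class MorphNode:
    """One SWC node: position and radius in micrometres."""

    id: int
    label: int
    x: float
    y: float
    z: float
    radius: float
    parent: int | None  # parent node id, None for the root

    def __post_init__(self):
        if self.radius <= 0:
            raise MorphologyError(f"node {self.id}: radius must be > 0, got {self.radius}")
        if self.id <= 0:
            raise MorphologyError(f"node id must be positive, got {self.id}")


@dataclass
class Morphology:
    """A validated tree of :class:`MorphNode`.

    ``unknown_labels`` lists labels outside the recognised scheme; they
    are kept verbatim so that downstream code can decide what to do.
    """

    nodes: list[MorphNode]
    metadata: str = ""
    unknown_labels: set[int] = field(default_factory=set)

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise MorphologyError("duplicate node ids")
        byid = {n.id: n for n in self.nodes}
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        # tree check: every node reaches the root without cycles
        root = roots[0]
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent is not None:
                if cur.id in seen:
                    raise MorphologyError(f"cycle involving node {cur.id}")
                seen.add(cur.id)
                if cur.parent not in byid:
                    raise MorphologyError(f"node {cur.id}: orphan parent {cur.parent}")
                cur = byid[cur.parent]
            if cur.id != root.id:
                raise MorphologyError(f"node {n.id} not connected to root")
        self.unknown_labels = {n.label for n in self.nodes if n.label not in KNOWN_LABELS}

    @property
    def root(self) -> MorphNode:
        return next(n for n in self.nodes if n.parent is None)

    def node(self, node_id: int) -> MorphNode:
        return next(n for n in self.nodes if n.id == node_id)

    def children(self, node_id: int) -> list[MorphNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def total_area_cm2(self) -> float:
        """Membrane area of the undiscretized morphology (cm^2).

        Sums frustum areas over edges plus the sphere-equivalent soma
        area if the root is a point soma.
        """
        byid = {n.id: n for n in self.nodes}
        area_um2 = 0.0
        root = self.root
        if _is_point_soma(self, root):
            area_um2 += 4.0 * math.pi * root.radius**2
        for n in self.nodes:
            if n.parent is None:
                continue
            p = byid[n.parent]
            L = _dist(p, n)
            r1 = n.radius if (p.id == root.id and _is_point_soma(self, root)) else p.radius
            area_um2 += math.pi * (r1 + n.radius) * L
        return area_um2 * 1e-8  # um^2 -> cm^2


@dataclass(frozen=True)
class Segment:
    """One electrical compartment produced by :func:`discretize`."""

    index: int
    section_id: int  # SWC id of the distal node of the parent section
    label: int
    length: float  # um
    diameter: float  # um, mean of the two end diameters
    r_prox: float  # um
    r_dist: float  # um
    area_cm2: float  # frustum lateral area pi*(r1+r2)*L
    parent: int | None  # index of parent segment, None for root

    def axial_resistance_mohm(self, Ra: float) -> float:
        """Frustum axial resistance (MOhm) for axial resistivity Ra (Ohm*cm)."""
        L_cm = self.length * 1e-4
        r1_cm = self.r_prox * 1e-4
        r2_cm = self.r_dist * 1e-4
        return Ra * L_cm / (math.pi * r1_cm * r2_cm) * 1e-6


@dataclass(frozen=True)
class PassiveParams:
    """Uniform passive membrane properties.

    Cm in uF/cm^2, g_leak in S/cm^2, Ra in Ohm*cm, E_rev in mV.
    """

    Cm: float = 2.0
    g_leak: float = 1.1e-4
    Ra: float = 110.0
    E_rev: float = -75.0

    def __post_init__(self):
        for name in ("Cm", "g_leak", "Ra"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not math.isfinite(self.E_rev):
            raise ValueError("E_rev must be finite")

    @property
    def Rm(self) -> float:
        """Specific membrane resistance 1/g_leak (Ohm*cm^2)."""
        return 1.0 / self.g_leak


def _dist(a: MorphNode, b: MorphNode) -> float:
    return math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)


def _is_point_soma(morph: Morphology, root: MorphNode) -> bool:
    """True when the root is a lone label-1 node (sphere convention)."""
    if root.label != SOMA:
        return False
    return not any(n.label == SOMA for n in morph.nodes if n.id != root.id)


def length_constant_um(diameter_um: float, passive: PassiveParams) -> float:
    """Cable length constant lambda = sqrt(d*R_m/(4*R_a)) in micrometres."""
    if diameter_um <= 0:
        raise MorphologyError("zero-diameter section")
    d_cm = diameter_um * 1e-4
    lam_cm = math.sqrt(d_cm * passive.Rm / (4.0 * passive.Ra))
    return lam_cm * 1e4


def read_swc(path: str | Path) -> Morphology:
    """Read a whitespace-delimited 7-column SWC file.

    Columns: id, label, x, y, z, radius, parent (parent -1 for root).
    Lines starting with ``#`` are collected into the metadata string.
    """
    path = Path(path)
    nodes: list[MorphNode] = []
    meta: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta.append(line.lstrip("# "))
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        nid, label = int(parts[0]), int(parts[1])
        x, y, z, radius = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if parent == nid:
            raise MorphologyError(f"{path}:{lineno}: node {nid} is its own parent")
        nodes.append(MorphNode(nid, label, x, y, z, radius, None if parent == -1 else parent))
    return Morphology(nodes=nodes, metadata="\n".join(meta))


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology back to 7-column SWC text."""
    path = Path(path)
    lines = [f"# {m}" for m in morph.metadata.splitlines()]
    for n in morph.nodes:
        parent = -1 if n.parent is None else n.parent
        lines.append(
            f"{n.id} {n.label} {n.x:.6g} {n.y:.6g} {n.z:.6g} {n.radius:.6g} {parent}"
        )
    path.write_text("\n".join(lines) + "\n")


def discretize(
    morph: Morphology,
    passive: PassiveParams,
    max_fraction: float = 0.1,
) -> list[Segment]:
    """Subdivide every section into segments no longer than ``max_fraction*lambda``.

    Each inter-node edge is one section; lambda is evaluated at the
    section's midpoint diameter.  Radii are interpolated linearly along
    the section so total frustum membrane area is conserved exactly.
    Returns segments in a topological order (parent index < child index).
    """
    if max_fraction <= 0:
        raise ValueError("max_fraction must be > 0")
    byid = {n.id: n for n in morph.nodes}
    root = morph.root
    point_soma = _is_point_soma(morph, root)

    segments: list[Segment] = []
    # segment index that children of a given node id must attach to
    attach: dict[int, int] = {}

    if point_soma:
        d = 2.0 * root.radius
        L = 2.0 * root.radius
        seg = Segment(
            index=0, section_id=root.id, label=SOMA, length=L, diameter=d,
            r_prox=root.radius, r_dist=root.radius,
            area_cm2=math.pi * d * L * 1e-8, parent=None,
        )
        segments.append(seg)
        attach[root.id] = 0
    else:
        attach[root.id] = -1  # filled by the first edge off the root

    # walk edges in BFS order from the root so parents come first
    order: list[MorphNode] = []
    stack = [root.id]
    children_of: dict[int, list[MorphNode]] = {}
    for n in morph.nodes:
        if n.parent is not None:
            children_of.setdefault(n.parent, []).append(n)
    while stack:
        nid = stack.pop(0)
        for ch in children_of.get(nid, []):
            order.append(ch)
            stack.append(ch.id)

    for child in order:
        parent_node = byid[child.parent]
        L = _dist(parent_node, child)
        if L <= 0:
            raise MorphologyError(
                f"zero-length section between nodes {parent_node.id} and {child.id}"
            )
        # neurites leaving a point soma start at the child's own radius
        if point_soma and parent_node.id == root.id:
            r1 = child.radius
        else:
            r1 = parent_node.radius
        r2 = child.radius
        d_mid = r1 + r2  # midpoint diameter of the linear taper
        if d_mid <= 0:
            raise MorphologyError("zero-diameter section")
        lam = length_constant_um(d_mid, passive)
        n_sub = max(1, math.ceil(L / (max_fraction * lam) - 1e-12))
        sub_L = L / n_sub
        parent_idx = attach.get(parent_node.id, -1)
        root_edge = parent_idx < 0
        first_idx = len(segments)
        for i in range(n_sub):
            ra = r1 + (r2 - r1) * (i / n_sub)
            rb = r1 + (r2 - r1) * ((i + 1) / n_sub)
            idx = len(segments)
            segments.append(
                Segment(
                    index=idx, section_id=child.id, label=child.label,
                    length=sub_L, diameter=ra + rb,
                    r_prox=ra, r_dist=rb,
                    area_cm2=math.pi * (ra + rb) * sub_L * 1e-8,
                    parent=None if parent_idx < 0 else parent_idx,
                )
            )
            parent_idx = idx
        attach[child.id] = parent_idx
        if root_edge:
            # later siblings off a multi-node root attach at this edge's
            # proximal segment so the segment graph stays a single tree
            attach[parent_node.id] = first_idx

    return segments


def segments_to_table(segments: Sequence[Segment]):
    """Segments as a pandas DataFrame (id, label, length_um, diam_um, area_cm2, parent)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [s.index for s in segments],
            "label": [s.label for s in segments],
            "length_um": [s.length for s in segments],
            "diam_um": [s.diameter for s in segments],
            "area_cm2": [s.area_cm2 for s in segments],
            "parent": [-1 if s.parent is None else s.parent for s in segments],
        }
    )


def total_segment_area_cm2(segments: Iterable[Segment]) -> float:
    return float(sum(s.area_cm2 for s in segments))
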