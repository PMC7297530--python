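"""Reading and writing webKnossos-style NML skeleton annotations.

NML is an XML dialect: a ``<things>`` root holding per-tree ``<thing>``
elements (``<nodes>``/``<edges>`` children) and a ``<comments>`` block
keyed by node id.  Both ``<thing>`` and ``<tree>`` element names are
accepted, and comments may appear either inline as a node attribute or in
the trailing block; both map onto :attr:`SkeletonNode.comment`.

Coordinates are voxel-indexed (0-based, corner-anchored) at parse time;
:func:`to_physical` is the single conversion boundary to nanometres, with
an optional anisotropic cutting-thickness correction and a per-dataset
pia offset for cortical-depth computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from lxml import etree

__all__ = [
    "DatasetMeta",
    "SkeletonNode",
    "SkeletonTree",
    "AnnotationSet",
    "NMLStructureError",
    "parse_nml",
    "write_nml",
    "to_physical",
    "node_depth_um",
]


class NMLStructureError(ValueError):
    """Raised for structurally invalid skeleton documents (dangling edges...)."""


@dataclass(frozen=True)
class DatasetMeta:
    """Per-dataset acquisition metadata.

    Parameters
    ----------
    name : str
        Dataset label (e.g. ``"S1"``, ``"PPC-2"``).
    voxel_size : tuple of float
        Nominal voxel size in nm along x/y/z.
    pia_offset : float
        Depth of the dataset's top face below the pial surface, in µm.
    depth_axis : int
        Axis index whose positive direction is increasing cortical depth.
    cutting_axis : int
        Axis along which sections were cut.
    thickness_correction : float
        Dimensionless factor applied along the cutting axis (default 1.0);
        compensates nominal-vs-actual section thickness mismatch.
    """

    name: str = "synthetic"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pia_offset: float = 0.0
    depth_axis: int = 1
    cutting_axis: int = 2
    thickness_correction: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.pia_offset < 0:
            raise ValueError("pia_offset must be >= 0")
        if self.thickness_correction <= 0:
            raise ValueError("thickness_correction must be > 0")


@dataclass
class SkeletonNode:
    id: int
    position: tuple[float, float, float]
    radius: float | None = None
    comment: str | None = None


@dataclass
class SkeletonTree:
    name: str
    nodes: dict[int, SkeletonNode] = field(default_factory=dict)
    edges: set[frozenset[int]] = field(default_factory=set)
    group_label: str | None = None

    def add_node(self, node: SkeletonNode) -> None:
        if node.id in self.nodes:
            raise NMLStructureError(f"duplicate node id {node.id} in tree {self.name!r}")
        self.nodes[node.id] = node

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise NMLStructureError(f"self-edge at node {a} in tree {self.name!r}")
        for nid in (a, b):
            if nid not in self.nodes:
                raise NMLStructureError(
                    f"edge ({a},{b}) references missing node {nid} in tree {self.name!r}"
                )
        self.edges.add(frozenset((a, b)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SkeletonTree):
            return NotImplemented
        return (
            self.name == other.name
            and self.group_label == other.group_label
            and self.edges == other.edges
            and {i: (n.position, n.radius, n.comment) for i, n in self.nodes.items()}
            == {i: (n.position, n.radius, n.comment) for i, n in other.nodes.items()}
        )


@dataclass
class AnnotationSet:
    meta: DatasetMeta = field(default_factory=DatasetMeta)
    trees: list[SkeletonTree] = field(default_factory=list)
    physical: bool = False  # True once positions are in nm

    def __post_init__(self) -> None:
        names = [t.name for t in self.trees]
        if len(names) != len(set(names)):
            raise NMLStructureError("tree names must be unique within an AnnotationSet")

    def tree(self, name: str) -> SkeletonTree:
        for t in self.trees:
            if t.name == name:
                return t
        raise KeyError(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.trees == other.trees


def _fmt(x: float) -> str:
    # repr round-trips floats exactly; integers render without trailing .0
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def parse_nml(text: str | bytes, meta: DatasetMeta | None = None) -> AnnotationSet:
    """Parse an NML document into an :class:`AnnotationSet`.

    Accepts both ``<thing>`` and ``<tree>`` tree elements; node comments may
    be inline ``comment`` attributes or entries of a ``<comments>`` block.
    Multi-component trees are allowed here and rejected only by operations
    that require connectivity.

    Raises
    ------
    NMLStructureError
        If an edge references a node id absent from its tree, on duplicate
        node ids, or on self-edges.
    lxml.etree.XMLSyntaxError
        On malformed XML (the error names the offending line).
    """
    if isinstance(text, str):
        text = text.encode()
    root = etree.fromstring(text)

    if meta is None:
        name = "synthetic"
        voxel = (1.0, 1.0, 1.0)
        exp = root.find("parameters/experiment")
        if exp is not None and exp.get("name"):
            name = exp.get("name")
        sc = root.find("parameters/scale")
        if sc is not None:
            voxel = tuple(float(sc.get(ax, 1)) for ax in "xyz")
        meta = DatasetMeta(name=name, voxel_size=voxel)

    trees: list[SkeletonTree] = []
    node_owner: dict[int, SkeletonNode] = {}
    for el in root.iter():
        if el.tag not in ("thing", "tree"):
            continue
        name = el.get("name") or f"tree_{el.get('id', len(trees) + 1)}"
        tree = SkeletonTree(name=name, group_label=el.get("groupId"))
        for nd in el.iter("node"):
            node = SkeletonNode(
                id=int(nd.get("id")),
                position=(float(nd.get("x")), float(nd.get("y")), float(nd.get("z"))),
                radius=float(nd.get("radius")) if nd.get("radius") is not None else None,
                comment=nd.get("comment"),
            )
            tree.add_node(node)
            node_owner[node.id] = node
        for ed in el.iter("edge"):
            tree.add_edge(int(ed.get("source")), int(ed.get("target")))
        trees.append(tree)

    for block in root.iter("comments"):
        for cm in block.iter("comment"):
            nid = int(cm.get("node"))
            if nid in node_owner:
                node_owner[nid].comment = cm.get("content")

    return AnnotationSet(meta=meta, trees=trees)


def write_nml(aset: AnnotationSet) -> str:
    """Serialize an :class:`AnnotationSet` to a canonical NML document.

    Output is deterministic (nodes/edges sorted by id) so equal annotation
    sets serialize byte-identically; comments are written inline as node
    attributes, which keeps them unambiguous when node ids repeat across
    trees. ``parse_nml(write_nml(a)) == a``.
    """
    root = etree.Element("things")
    params = etree.SubElement(root, "parameters")
    etree.SubElement(params, "experiment", name=aset.meta.name)
    vx, vy, vz = aset.meta.voxel_size
    etree.SubElement(params, "scale", x=_fmt(vx), y=_fmt(vy), z=_fmt(vz))
    for i, tree in enumerate(aset.trees, start=1):
        el = etree.SubElement(root, "thing", id=str(i), name=tree.name)
        if tree.group_label is not None:
            el.set("groupId", tree.group_label)
        nodes_el = etree.SubElement(el, "nodes")
        for nid in sorted(tree.nodes):
            node = tree.nodes[nid]
            x, y, z = node.position
            attrs = {"id": str(nid), "x": _fmt(x), "y": _fmt(y), "z": _fmt(z)}
            if node.radius is not None:
                attrs["radius"] = _fmt(node.radius)
            if node.comment is not None:
                attrs["comment"] = node.comment
            etree.SubElement(nodes_el, "node", **attrs)
        edges_el = etree.SubElement(el, "edges")
        for a, b in sorted(tuple(sorted(e)) for e in tree.edges):
            etree.SubElement(edges_el, "edge", source=str(a), target=str(b))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def to_physical(aset: AnnotationSet) -> AnnotationSet:
    """Convert voxel coordinates to physical nanometres.

    Each coordinate is multiplied by its axis voxel size; the cutting-axis
    coordinate is additionally multiplied by ``meta.thickness_correction``
    (e.g. the 1.49 factor compensating compressed sections). Idempotent
    input is not allowed: converting an already-physical set raises.
    """
    if aset.physical:
        raise ValueError("AnnotationSet is already in physical units")
    meta = aset.meta
    scale = np.asarray(meta.voxel_size, dtype=float)
    scale[meta.cutting_axis] *= meta.thickness_correction
    trees = []
    for tree in aset.trees:
        new = SkeletonTree(name=tree.name, group_label=tree.group_label)
        for nid, node in tree.nodes.items():
            pos = tuple(np.asarray(node.position, dtype=float) * scale)
            new.nodes[nid] = replace(node, position=pos)
        new.edges = set(tree.edges)
        trees.append(new)
    return AnnotationSet(meta=meta, trees=trees, physical=True)


def node_depth_um(node: SkeletonNode, meta: DatasetMeta) -> float:
    """Cortical depth below pia of a physical-unit node, in µm."""
    return meta.pia_offset + node.position[meta.depth_axis] / 1000.0
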