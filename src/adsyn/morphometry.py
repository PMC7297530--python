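"""Geometric measurements on dendrite and soma skeleton annotations.

All operations here work on :class:`DendriteAnnotation` objects whose tree
coordinates are in µm (one conversion from voxel/nm space happens when the
annotation is built, see :func:`adsyn.synapse_quant.dendrite_from_tree`).
Path lengths are Euclidean edge sums on the skeleton graph; shaft lengths
exclude spine necks, mirroring how complete synaptic input maps are
measured: spine necks are removed and the remaining edges summed.

Windows are closed intervals of arc distance (µm) from the reference node
(the soma if present, otherwise the annotated trunk origin); the default
analysis window is ±10 µm around the main bifurcation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from adsyn.skeleton_io import DatasetMeta, SkeletonTree

__all__ = [
    "DendriteAnnotation",
    "SomaMeasure",
    "DetectionFailedError",
    "MeasurementMissingError",
    "shaft_path_length",
    "average_diameter",
    "surface_area",
    "equivalent_sphere_diameter",
    "trunk_diameter_at",
    "synapse_interface_area",
    "detect_main_bifurcation",
    "soma_to_bifurcation_distance",
    "tuft_branches",
    "arc_distances",
    "mb_window",
    "landmark_depth_profiles",
    "DepthProfiles",
]

CELLTYPES = ("L2", "L2MN", "L3", "L5tt", "L5st", "DL", "unknown")


class DetectionFailedError(RuntimeError):
    """No skeleton node qualified as the requested landmark."""


class MeasurementMissingError(RuntimeError):
    """The annotation carries no data for the requested measurement."""


@dataclass
class DendriteAnnotation:
    """One apical dendrite: skeleton (µm), landmarks and synapse records.

    ``synapses`` holds :class:`adsyn.synapse_quant.SynapseRecord` objects;
    ``diameter_samples`` are (arc position µm, diameter µm) pairs;
    ``trunk_ellipse_samples`` are (arc position µm, major µm, minor µm)
    cross-section approximations of the trunk.
    """

    tree: SkeletonTree
    celltype: str = "unknown"
    soma_node: int | None = None
    root_node: int | None = None  # trunk origin for DL ADs without a soma
    main_bifurcation_node: int | None = None
    spine_neck_nodes: set[int] = field(default_factory=set)
    synapses: list = field(default_factory=list)
    diameter_samples: list[tuple[float, float]] = field(default_factory=list)
    trunk_ellipse_samples: list[tuple[float, float, float]] = field(default_factory=list)
    analysis_window: tuple[float, float] | None = None
    meta: DatasetMeta | None = None
    name: str = ""

    @property
    def reference_node(self) -> int:
        """Proximal reference: soma if annotated, else the trunk origin."""
        if self.soma_node is not None:
            return self.soma_node
        if self.root_node is not None:
            return self.root_node
        raise MeasurementMissingError(
            f"dendrite {self.name!r} has neither soma nor trunk-origin landmark"
        )


@dataclass(frozen=True)
class SomaMeasure:
    """Ellipsoid approximation of a soma: diameters along dataset axes, µm."""

    axis_diameters: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.axis_diameters):
            raise ValueError("axis diameters must be positive")

    @property
    def equivalent_diameter(self) -> float:
        return equivalent_sphere_diameter(self.axis_diameters)


# ---------------------------------------------------------------------------
# graph helpers

def skeleton_graph(tree: SkeletonTree, exclude: set[int] | None = None) -> nx.Graph:
    """Weighted graph of a skeleton tree; edge weight = Euclidean length (µm)."""
    g = nx.Graph()
    exclude = exclude or set()
    for nid, node in tree.nodes.items():
        if nid not in exclude:
            g.add_node(nid, pos=np.asarray(node.position, dtype=float))
    for e in tree.edges:
        a, b = tuple(e)
        if a in exclude or b in exclude:
            continue
        w = float(np.linalg.norm(g.nodes[a]["pos"] - g.nodes[b]["pos"]))
        g.add_edge(a, b, weight=w)
    return g


def pruned_graph(ad: DendriteAnnotation) -> nx.Graph:
    """Skeleton graph with spine-neck nodes removed (shaft only)."""
    necks = set(ad.spine_neck_nodes)
    for nid, node in ad.tree.nodes.items():
        if node.comment and any(
            t.strip() == "spine neck" for t in node.comment.split(";")
        ):
            necks.add(nid)
    return skeleton_graph(ad.tree, exclude=necks)


def arc_distances(ad: DendriteAnnotation, source: int | None = None) -> dict[int, float]:
    """Arc distance (µm) from the reference node to every shaft node."""
    g = pruned_graph(ad)
    src = ad.reference_node if source is None else source
    if src not in g:
        raise MeasurementMissingError(f"reference node {src} not on the shaft skeleton")
    return nx.single_source_dijkstra_path_length(g, src, weight="weight")


def mb_window(ad: DendriteAnnotation, half_width: float = 10.0) -> tuple[float, float]:
    """Closed arc-distance interval ±half_width µm around the main bifurcation."""
    if ad.main_bifurcation_node is None:
        raise MeasurementMissingError("main bifurcation not set")
    d_mb = arc_distances(ad)[ad.main_bifurcation_node]
    return (d_mb - half_width, d_mb + half_width)


# ---------------------------------------------------------------------------
# path lengths and diameters

def shaft_path_length(
    ad: DendriteAnnotation, window: tuple[float, float] | None = None
) -> float:
    """Shaft path length in µm: spine necks removed, remaining edges summed.

    With ``window = (lo, hi)`` (arc distance from the reference node) each
    edge contributes the part of its [d(u), d(v)] span overlapping the
    window — exact on a tree, where adjacent arc distances differ by the
    edge length.  Returns 0.0 (with a warning) if the window excludes the
    whole dendrite.
    """
    g = pruned_graph(ad)
    if window is None:
        return float(sum(w for _, _, w in g.edges(data="weight")))
    lo, hi = window
    dist = arc_distances(ad)
    total = 0.0
    for u, v, w in g.edges(data="weight"):
        a, b = sorted((dist[u], dist[v]))
        total += max(0.0, min(hi, b) - max(lo, a))
    if total == 0.0:
        warnings.warn("analysis window excludes the entire dendrite", stacklevel=2)
    return float(total)


def average_diameter(ad: DendriteAnnotation, spacing: float = 2.5) -> float:
    """Mean dendrite diameter (µm) sampled every ``spacing`` µm of arc length.

    Diameter source precedence: explicit ``diameter_samples``, then node
    radii; linear interpolation between samples.
    """
    if ad.diameter_samples:
        samples = sorted(ad.diameter_samples)
    else:
        dist = arc_distances(ad)
        samples = sorted(
            (dist[nid], 2.0 * node.radius)
            for nid, node in ad.tree.nodes.items()
            if node.radius is not None and nid in dist
        )
    if not samples:
        raise MeasurementMissingError("no diameter samples or node radii available")
    pos = np.array([s[0] for s in samples])
    dia = np.array([s[1] for s in samples])
    if np.any(dia <= 0):
        raise ValueError("diameter samples must be positive")
    grid = np.arange(pos.min(), pos.max() + spacing / 2, spacing)
    return float(np.interp(grid, pos, dia).mean())


def surface_area(path_length: float, avg_diameter: float) -> float:
    """Open-cylinder dendrite surface: π · L · d̄ (µm²)."""
    if path_length <= 0 or avg_diameter <= 0:
        raise ValueError("path length and diameter must be positive")
    return float(np.pi * path_length * avg_diameter)


def equivalent_sphere_diameter(axis_diameters) -> float:
    """Diameter of the sphere whose volume equals the axis-aligned ellipsoid's."""
    a = np.asarray(axis_diameters, dtype=float)
    if a.shape != (3,) or np.any(a <= 0):
        raise ValueError("need three positive axis diameters")
    return float(np.prod(a) ** (1.0 / 3.0))


def trunk_diameter_at(ad: DendriteAnnotation, distance_from_soma: float = 50.0) -> float:
    """Equal-area trunk diameter (µm) at an arc distance from the soma.

    The trunk cross-section is annotated as an ellipse; the returned value
    is the diameter of the circle with the same area, √(major·minor).  If
    the trunk annotation is shorter than the requested distance the most
    distal sample is used (with a warning).
    """
    if not ad.trunk_ellipse_samples:
        raise MeasurementMissingError("no trunk ellipse samples annotated")
    samples = sorted(ad.trunk_ellipse_samples)
    positions = np.array([s[0] for s in samples])
    if distance_from_soma > positions.max():
        warnings.warn(
            "trunk annotation shorter than requested distance; using most distal sample",
            stacklevel=2,
        )
        _, major, minor = samples[-1]
    else:
        idx = int(np.argmin(np.abs(positions - distance_from_soma)))
        _, major, minor = samples[idx]
    if major <= 0 or minor <= 0:
        raise ValueError("ellipse axes must be positive")
    return float(np.sqrt(major * minor))


def synapse_interface_area(major_axis: float, minor_axis: float) -> float:
    """Synaptic contact area from annotated full axes: π·(major/2)·(minor/2), µm²."""
    if major_axis <= 0 or minor_axis <= 0:
        raise ValueError("axes must be positive")
    return float(np.pi * major_axis * minor_axis / 4.0)


# ---------------------------------------------------------------------------
# landmarks

def _subtree_length(g: nx.Graph, removed: int, start: int) -> float:
    """Total edge length of the component of g−removed containing start."""
    h = g.copy()
    h.remove_node(removed)
    comp = nx.node_connected_component(h, start)
    return float(
        sum(w for u, v, w in h.edges(data="weight") if u in comp and v in comp)
    )


def detect_main_bifurcation(
    ad: DendriteAnnotation, similarity_tol: float = 0.5
) -> int:
    """Locate the Y-shaped main bifurcation of an apical dendrite.

    An annotated bifurcation (node comment containing ``"main bifurcation"``)
    is authoritative.  Otherwise the most proximal degree-≥3 shaft node whose
    two largest daughter subtrees have total path lengths within
    ``similarity_tol`` (relative to the larger) is returned — the "two
    daughter branches of similar thickness and branching angle" criterion
    reduced to a deterministic length-similarity rule.
    """
    for nid, node in ad.tree.nodes.items():
        if node.comment and "main bifurcation" in node.comment:
            return nid
    g = pruned_graph(ad)
    dist = arc_distances(ad)
    ref = ad.reference_node
    candidates = sorted(
        (n for n in g.nodes if g.degree(n) >= 3 and n != ref), key=dist.get
    )
    for cand in candidates:
        daughters = [nb for nb in g.neighbors(cand) if dist[nb] > dist[cand]]
        if len(daughters) < 2:
            continue
        lengths = sorted(
            (
                _subtree_length(g, cand, d)
                + float(g.edges[cand, d]["weight"])
                for d in daughters
            ),
            reverse=True,
        )
        l1, l2 = lengths[0], lengths[1]
        if l1 > 0 and (l1 - l2) / l1 <= similarity_tol:
            return cand
    raise DetectionFailedError("no bifurcation with similar daughter branches found")


def tuft_branches(ad: DendriteAnnotation) -> list[DendriteAnnotation]:
    """Split the tuft into per-daughter-branch sub-annotations.

    Each returned annotation is rooted at the main bifurcation and contains
    one daughter subtree (spine necks excluded from the split logic but
    retained on the sub-tree); synapse records are carried over for the
    nodes of that branch.  Arc distances on a branch are measured from the
    bifurcation, so a window ``(offset, inf)`` selects its distal part.
    """
    if ad.main_bifurcation_node is None:
        raise MeasurementMissingError("main bifurcation not set")
    g = pruned_graph(ad)
    dist = arc_distances(ad)
    mb = ad.main_bifurcation_node
    branches = []
    daughters = [nb for nb in g.neighbors(mb) if dist[nb] > dist[mb]]
    for i, daughter in enumerate(daughters):
        h = g.copy()
        h.remove_node(mb)
        comp = nx.node_connected_component(h, daughter)
        keep = comp | {mb}
        sub = SkeletonTree(name=f"{ad.name}/branch{i}")
        for nid in keep:
            sub.nodes[nid] = ad.tree.nodes[nid]
        sub.edges = {e for e in ad.tree.edges if set(e) <= keep}
        branch = DendriteAnnotation(
            tree=sub,
            celltype=ad.celltype,
            root_node=mb,
            meta=ad.meta,
            name=sub.name,
            synapses=[r for r in ad.synapses if r.node in comp],
        )
        branches.append(branch)
    return branches


def soma_to_bifurcation_distance(ad: DendriteAnnotation) -> float:
    """Arc length (µm) of the shaft path soma → main bifurcation (d_MB)."""
    if ad.soma_node is None or ad.main_bifurcation_node is None:
        raise MeasurementMissingError("soma and main bifurcation landmarks required")
    return float(arc_distances(ad, source=ad.soma_node)[ad.main_bifurcation_node])


# ---------------------------------------------------------------------------
# depth profiles

@dataclass
class DepthProfiles:
    """Bifurcation-depth histogram/KDE and axonal path fractions per slice."""

    bif_bin_edges: np.ndarray
    bif_density: np.ndarray
    bif_kde: object | None
    axon_slice_edges: np.ndarray
    axon_fractions: np.ndarray  # averaged across datasets
    axon_fractions_per_dataset: dict[str, np.ndarray]


def _edge_depth_lengths(
    tree: SkeletonTree, meta: DatasetMeta, edges_grid: np.ndarray
) -> np.ndarray:
    """Path length per depth slice, distributing each edge proportionally."""
    out = np.zeros(len(edges_grid) - 1)
    ax = meta.depth_axis
    for e in tree.edges:
        a, b = tuple(e)
        pa = np.asarray(tree.nodes[a].position, dtype=float)
        pb = np.asarray(tree.nodes[b].position, dtype=float)
        length = float(np.linalg.norm(pa - pb))
        da = meta.pia_offset + pa[ax]
        db = meta.pia_offset + pb[ax]
        lo, hi = sorted((da, db))
        if hi == lo:
            idx = np.clip(np.searchsorted(edges_grid, lo, side="right") - 1, 0, len(out) - 1)
            out[idx] += length
            continue
        for i in range(len(out)):
            ov = max(0.0, min(hi, edges_grid[i + 1]) - max(lo, edges_grid[i]))
            if ov > 0:
                out[i] += length * ov / (hi - lo)
    return out


def landmark_depth_profiles(
    ads,
    axon_trees,
    bin: float = 20.0,
    kde_bandwidth: float = 25.0,
) -> DepthProfiles:
    """Depth distributions of main bifurcations and axonal paths.

    Parameters
    ----------
    ads : sequence of DendriteAnnotation
        Must carry ``meta`` (for the pia offset) and a main bifurcation.
    axon_trees : sequence of (SkeletonTree, DatasetMeta)
        Axonal skeletons in µm; synapse-marker nodes already removed.
    bin : float
        Histogram bin / tangential slice thickness, µm.
    kde_bandwidth : float
        Gaussian KDE bandwidth in µm for the bifurcation-depth density.
    """
    from scipy.stats import gaussian_kde

    depths = []
    for ad in ads:
        if ad.main_bifurcation_node is None or ad.meta is None:
            continue
        pos = ad.tree.nodes[ad.main_bifurcation_node].position
        depths.append(ad.meta.pia_offset + pos[ad.meta.depth_axis])
    depths = np.asarray(depths, dtype=float)

    if depths.size:
        lo = bin * np.floor(depths.min() / bin)
        hi = bin * np.ceil(depths.max() / bin)
        if hi == lo:
            hi = lo + bin
        bif_edges = np.arange(lo, hi + bin / 2, bin)
        bif_density, _ = np.histogram(depths, bins=bif_edges, density=True)
        kde = None
        if depths.size > 1 and np.std(depths) > 0:
            kde = gaussian_kde(depths, bw_method=kde_bandwidth / np.std(depths, ddof=1))
    else:
        bif_edges = np.array([0.0, bin])
        bif_density = np.zeros(1)
        kde = None

    per_ds_lengths: dict[str, np.ndarray] = {}
    max_depth = 0.0
    for tree, meta in axon_trees:
        for e in tree.edges:
            for nid in e:
                max_depth = max(
                    max_depth, meta.pia_offset + tree.nodes[nid].position[meta.depth_axis]
                )
    slice_edges = np.arange(0.0, bin * np.ceil(max_depth / bin) + bin / 2, bin)
    if len(slice_edges) < 2:
        slice_edges = np.array([0.0, bin])
    for tree, meta in axon_trees:
        lengths = _edge_depth_lengths(tree, meta, slice_edges)
        key = meta.name
        per_ds_lengths[key] = per_ds_lengths.get(key, np.zeros(len(slice_edges) - 1)) + lengths

    per_ds_fracs = {
        k: (v / v.sum() if v.sum() > 0 else v) for k, v in per_ds_lengths.items()
    }
    if per_ds_fracs:
        avg = np.mean(list(per_ds_fracs.values()), axis=0)
    else:
        avg = np.zeros(len(slice_edges) - 1)

    return DepthProfiles(
        bif_bin_edges=bif_edges,
        bif_density=bif_density,
        bif_kde=kde,
        axon_slice_edges=slice_edges,
        axon_fractions=avg,
        axon_fractions_per_dataset=per_ds_fracs,
    )
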