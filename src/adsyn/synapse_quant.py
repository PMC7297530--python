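"""Synapse classification, densities and inhibitory-fraction profiles.

The identity rule: synapses onto the dendritic shaft, onto spine necks and
secondary innervations of a spine head count as putative inhibitory;
primary spine innervations count as excitatory.  Densities are per µm of
spine-neck-free shaft path length (and per µm² of shaft surface when
diameter information is available).

Two averaging conventions coexist and are both exposed: per-dendrite
statistics are means over dendrites; pooled/slab statistics sum counts and
lengths first and divide once (ratio of means).  They differ in general
and downstream code must pick the labelled one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from adsyn.morphometry import (
    DendriteAnnotation,
    arc_distances,
    pruned_graph,
    shaft_path_length,
    surface_area,
    average_diameter,
    MeasurementMissingError,
    _edge_depth_lengths,
)
from adsyn.skeleton_io import DatasetMeta, SkeletonTree

__all__ = [
    "SynapseRecord",
    "DensityResult",
    "DistanceProfile",
    "SlabProfile",
    "UndefinedDensityError",
    "classify_synapse",
    "density_result",
    "distance_profile",
    "cortical_depth_profile",
    "dendrite_from_tree",
    "INHIBITORY_ONTO",
    "ONTO_CATEGORIES",
]

ONTO_CATEGORIES = ("shaft", "spine_primary", "spine_secondary", "spine_neck")
INHIBITORY_ONTO = frozenset({"shaft", "spine_neck", "spine_secondary"})


class UndefinedDensityError(ZeroDivisionError):
    """Shaft path length is zero; densities are undefined."""


@dataclass
class SynapseRecord:
    """One input synapse on a dendrite.

    ``node`` is the shaft attachment node (spine synapses are referenced at
    the shaft node their spine branches from, so arc positions are defined
    on the pruned skeleton). ``spine_id`` groups multiple innervations of
    the same spine; it defaults to the attachment node id for spine
    synapses.
    """

    id: int
    node: int
    onto: str
    size_axes: tuple[float, float] | None = None
    presyn_axon: int | None = None
    spine_id: int | None = None

    def __post_init__(self) -> None:
        if self.onto not in ONTO_CATEGORIES:
            raise ValueError(f"unknown synapse category {self.onto!r}")
        if self.spine_id is None and self.onto in ("spine_primary", "spine_secondary"):
            self.spine_id = self.node


def classify_synapse(rec: SynapseRecord) -> str:
    """Map a synapse to ``"excitatory"`` or ``"putative_inhibitory"``.

    Shaft, spine-neck and secondary-spine synapses are putative inhibitory;
    primary spine innervations are excitatory.
    """
    if rec.onto in INHIBITORY_ONTO:
        return "putative_inhibitory"
    if rec.onto == "spine_primary":
        return "excitatory"
    raise ValueError(f"unknown synapse category {rec.onto!r}")


@dataclass
class DensityResult:
    """Per-dendrite (or per-window) synapse counts, densities and fractions.

    ``n_shaft`` / ``dens_shaft_len`` single out shaft-onto synapses — the
    quantity printed as "density of shaft synapses" — from the full
    putative-inhibitory tally ``n_inh`` which also counts neck and
    secondary-spine synapses.
    """

    n_exc: int
    n_inh: int
    n_shaft: int
    shaft_length: float
    surface_area: float | None
    dens_exc_len: float
    dens_inh_len: float
    dens_shaft_len: float
    dens_exc_area: float | None
    dens_inh_area: float | None
    inh_fraction: float
    spine_density: float
    multi_spine_fraction: float
    corrected: bool = False
    celltype: str = "unknown"
    name: str = ""

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


def _synapses_in_window(ad: DendriteAnnotation, window):
    if window is None:
        return list(ad.synapses)
    lo, hi = window
    dist = arc_distances(ad)
    out = []
    for rec in ad.synapses:
        d = dist.get(rec.node)
        if d is not None and lo <= d <= hi:
            out.append(rec)
    return out


def density_result(
    ad: DendriteAnnotation,
    window: tuple[float, float] | None = None,
    with_area: bool = False,
) -> DensityResult:
    """Count and normalize the synaptic input of one dendrite.

    ``window`` is a closed arc-distance interval from the reference node
    (use :func:`adsyn.morphometry.mb_window` for the ±10 µm
    main-bifurcation window); synapses are assigned by the arc position of
    their attachment node.  Surface-area densities are computed only when
    ``with_area`` and diameter information is present.
    """
    length = shaft_path_length(ad, window)
    if length <= 0:
        raise UndefinedDensityError(f"zero shaft path length for dendrite {ad.name!r}")
    recs = _synapses_in_window(ad, window)
    n_exc = sum(1 for r in recs if classify_synapse(r) == "excitatory")
    n_inh = sum(1 for r in recs if classify_synapse(r) == "putative_inhibitory")
    n_shaft = sum(1 for r in recs if r.onto == "shaft")

    spine_ids = [r.spine_id for r in recs if r.onto in ("spine_primary", "spine_secondary")]
    innervated = set(spine_ids)
    multi = {s for s in innervated if spine_ids.count(s) >= 2}
    multi_frac = len(multi) / len(innervated) if innervated else 0.0

    area = None
    dens_exc_area = dens_inh_area = None
    if with_area:
        try:
            area = surface_area(length, average_diameter(ad))
            dens_exc_area = n_exc / area
            dens_inh_area = n_inh / area
        except MeasurementMissingError:
            area = None

    total = n_exc + n_inh
    return DensityResult(
        n_exc=n_exc,
        n_inh=n_inh,
        n_shaft=n_shaft,
        shaft_length=length,
        surface_area=area,
        dens_exc_len=n_exc / length,
        dens_inh_len=n_inh / length,
        dens_shaft_len=n_shaft / length,
        dens_exc_area=dens_exc_area,
        dens_inh_area=dens_inh_area,
        inh_fraction=n_inh / total if total else float("nan"),
        spine_density=sum(1 for r in recs if r.onto == "spine_primary") / length,
        multi_spine_fraction=multi_frac,
        celltype=ad.celltype,
        name=ad.name,
    )


# ---------------------------------------------------------------------------
# distance profile with low-count bin merging

@dataclass
class DistanceProfile:
    """Inhibitory fraction vs path distance to soma, low-count bins merged."""

    bin_edges: list[tuple[float, float]]
    n_exc: np.ndarray
    n_inh: np.ndarray
    inh_fraction: np.ndarray
    merged_from: list[list[int]]  # original bin indices per reported bin
    min_count: int


def merge_low_count_bins(
    counts: np.ndarray, min_count: int = 4
) -> list[list[int]]:
    """Group consecutive bin indices so every group reaches ``min_count``.

    Scan proximal→distal: a deficient bin merges into its proximal
    neighbour group if one exists, otherwise it is held and merged into the
    next group that forms.  A deficient trailing remainder merges into the
    last group; if no group ever reaches the threshold a single group of
    all bins is returned.
    """
    groups: list[list[int]] = []
    totals: list[float] = []
    pend_idx: list[int] = []
    pend_tot = 0.0
    for i, c in enumerate(np.asarray(counts, dtype=float)):
        if pend_idx or not groups:
            if c + pend_tot >= min_count:
                groups.append(pend_idx + [i])
                totals.append(pend_tot + c)
                pend_idx, pend_tot = [], 0.0
            elif groups:
                groups[-1].append(i)
                totals[-1] += c
            else:
                pend_idx.append(i)
                pend_tot += c
        elif c >= min_count:
            groups.append([i])
            totals.append(c)
        else:
            groups[-1].append(i)
            totals[-1] += c
    if pend_idx:
        if groups:
            groups[-1].extend(pend_idx)
        else:
            groups.append(pend_idx)
    return groups


def distance_profile(
    ads: DendriteAnnotation | list[DendriteAnnotation],
    bin: float = 10.0,
    min_count: int = 4,
) -> DistanceProfile:
    """Bin synapses by path distance to soma; report i/(i+e) per merged bin.

    Bins are [k·bin, (k+1)·bin) half-open; bins totalling fewer than
    ``min_count`` synapses are merged (proximal-first) so low counts never
    produce extreme fraction values.
    """
    if isinstance(ads, DendriteAnnotation):
        ads = [ads]
    dists, classes = [], []
    for ad in ads:
        arc = arc_distances(ad)
        for rec in ad.synapses:
            if rec.node in arc:
                dists.append(arc[rec.node])
                classes.append(classify_synapse(rec))
    if not dists:
        return DistanceProfile([], np.array([]), np.array([]), np.array([]), [], min_count)
    dists = np.asarray(dists)
    is_inh = np.array([c == "putative_inhibitory" for c in classes])
    n_bins = int(np.floor(dists.max() / bin)) + 1
    idx = np.minimum((dists // bin).astype(int), n_bins - 1)
    exc_counts = np.bincount(idx[~is_inh], minlength=n_bins).astype(float)
    inh_counts = np.bincount(idx[is_inh], minlength=n_bins).astype(float)
    groups = merge_low_count_bins(exc_counts + inh_counts, min_count)
    edges, ne, ni = [], [], []
    for g in groups:
        edges.append((g[0] * bin, (g[-1] + 1) * bin))
        ne.append(exc_counts[g].sum())
        ni.append(inh_counts[g].sum())
    ne, ni = np.asarray(ne), np.asarray(ni)
    with np.errstate(invalid="ignore"):
        frac = ni / (ne + ni)
    return DistanceProfile(edges, ne, ni, frac, groups, min_count)


# ---------------------------------------------------------------------------
# cortical-depth (100 µm slab) profile with bootstrap CI

@dataclass
class SlabProfile:
    slab_edges: np.ndarray
    n_exc: np.ndarray
    n_inh: np.ndarray
    length: np.ndarray
    inh_fraction: np.ndarray
    dens_exc: np.ndarray
    dens_inh: np.ndarray
    frac_ci: np.ndarray  # (n_slabs, 2) percentile bootstrap CI of the fraction


def _per_slab_arrays(ad: DendriteAnnotation, slab_edges: np.ndarray):
    meta = ad.meta or DatasetMeta()
    g = pruned_graph(ad)
    shaft = SkeletonTree(name=ad.tree.name)
    shaft.nodes = {n: ad.tree.nodes[n] for n in g.nodes}
    shaft.edges = {frozenset((u, v)) for u, v in g.edges}
    lengths = _edge_depth_lengths(shaft, meta, slab_edges)
    n = len(slab_edges) - 1
    exc = np.zeros(n)
    inh = np.zeros(n)
    for rec in ad.synapses:
        if rec.node not in ad.tree.nodes:
            continue
        depth = meta.pia_offset + ad.tree.nodes[rec.node].position[meta.depth_axis]
        i = int(np.clip(np.searchsorted(slab_edges, depth, side="right") - 1, 0, n - 1))
        if classify_synapse(rec) == "putative_inhibitory":
            inh[i] += 1
        else:
            exc[i] += 1
    return exc, inh, lengths


def cortical_depth_profile(
    ads: list[DendriteAnnotation],
    slab: float = 100.0,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> SlabProfile:
    """Pooled inhibitory fraction and densities per 100 µm cortical slab.

    Reconstructions (with their pia offsets applied) are partitioned into
    virtual tangential sections; counts and shaft path lengths are pooled
    across all dendritic segments per section.  The percentile bootstrap CI
    resamples whole dendrites (the resampling unit) ``n_boot`` times.
    Slabs with zero pooled path length are omitted.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    max_depth = 0.0
    for ad in ads:
        meta = ad.meta or DatasetMeta()
        for node in ad.tree.nodes.values():
            max_depth = max(max_depth, meta.pia_offset + node.position[meta.depth_axis])
    edges = np.arange(0.0, slab * np.ceil(max_depth / slab) + slab / 2, slab)
    if len(edges) < 2:
        edges = np.array([0.0, slab])
    per = [_per_slab_arrays(ad, edges) for ad in ads]
    exc = np.array([p[0] for p in per])  # (n_dend, n_slabs)
    inh = np.array([p[1] for p in per])
    lng = np.array([p[2] for p in per])

    keep = lng.sum(axis=0) > 0
    exc, inh, lng = exc[:, keep], inh[:, keep], lng[:, keep]
    edges_kept = edges[:-1][keep]

    tot_exc, tot_inh, tot_len = exc.sum(0), inh.sum(0), lng.sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = tot_inh / (tot_inh + tot_exc)

    n = len(ads)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_inh = inh[idx].sum(axis=1)  # (n_boot, n_slabs)
    boot_tot = (exc + inh)[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_frac = boot_inh / boot_tot
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    frac_ci = np.stack(
        [np.nanpercentile(boot_frac, lo_q, axis=0), np.nanpercentile(boot_frac, hi_q, axis=0)],
        axis=1,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dens_exc = tot_exc / tot_len
        dens_inh = tot_inh / tot_len
    return SlabProfile(
        slab_edges=edges_kept,
        n_exc=tot_exc,
        n_inh=tot_inh,
        length=tot_len,
        inh_fraction=frac,
        dens_exc=dens_exc,
        dens_inh=dens_inh,
        frac_ci=frac_ci,
    )


# ---------------------------------------------------------------------------
# comment-convention bridge: SkeletonTree -> DendriteAnnotation

_SYNAPSE_TOKENS = (
    ("secondary spine synapse", "spine_secondary"),
    ("spine neck synapse", "spine_neck"),
    ("spine synapse", "spine_primary"),
    ("shaft synapse", "shaft"),
)


def dendrite_from_tree(
    tree: SkeletonTree,
    meta: DatasetMeta | None = None,
    celltype: str = "unknown",
    scale: float = 1e-3,
) -> DendriteAnnotation:
    """Build a :class:`DendriteAnnotation` from an annotated skeleton tree.

    Node comments carry the annotation vocabulary: ``soma``,
    ``trunk origin``, ``main bifurcation``, ``spine neck`` (neck-branch
    nodes) and per-synapse tokens (``shaft synapse``, ``spine synapse``,
    ``secondary spine synapse``, ``spine neck synapse``), ``;``-separated
    when a node carries several.  ``scale`` converts coordinates into µm
    (default from nm).
    """
    scaled = SkeletonTree(name=tree.name, group_label=tree.group_label)
    for nid, node in tree.nodes.items():
        pos = tuple(c * scale for c in node.position)
        radius = node.radius * scale if node.radius is not None else None
        scaled.nodes[nid] = type(node)(
            id=nid, position=pos, radius=radius, comment=node.comment
        )
    scaled.edges = set(tree.edges)

    ad = DendriteAnnotation(tree=scaled, celltype=celltype, meta=meta, name=tree.name)
    sid = 0
    for nid, node in scaled.nodes.items():
        if not node.comment:
            continue
        for token in (t.strip() for t in node.comment.split(";")):
            if token == "soma":
                ad.soma_node = nid
            elif token == "trunk origin":
                ad.root_node = nid
            elif token == "main bifurcation":
                ad.main_bifurcation_node = nid
            elif token == "spine neck":
                ad.spine_neck_nodes.add(nid)
            else:
                for prefix, onto in _SYNAPSE_TOKENS:
                    if token.startswith(prefix):
                        sid += 1
                        spine_id = None
                        if "#" in token:
                            spine_id = int(token.split("#", 1)[1])
                        ad.synapses.append(
                            SynapseRecord(id=sid, node=nid, onto=onto, spine_id=spine_id)
                        )
                        break
    return ad
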