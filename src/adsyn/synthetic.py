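"""Synthetic annotation generator with ground-truth labels.

Emulates the statistical structure of apical-dendrite (AD) input maps and
AD-seeded axon reconstructions so that every analysis operation can be
exercised against a known generating process:

* per-cell-type Poisson synapse placement along the skeleton arc length,
  with compartment-specific rates at the main-bifurcation (MB) window and
  the distal tuft, and a distance-dependent inhibitory fraction
  f(d) = a·e^(b·d) + c along the trunk;
* axon populations with a per-synapse AD-targeting probability, tunable
  same-type selectivity s ((1+s)/2 probability that an AD connection hits
  the seed's AD type), per-target multiplicity, and a category mix for
  non-AD targets;
* two-cluster 4-D Gaussian L5 morphology features, plus density models
  linking thick-tuftedness (PC 1) to excitatory density and inhibitory
  fraction.

Default rates encode the reference population values the analysis is
expected to recover (shaft densities 0.42 and 0.22 /µm for L2 and DL,
spine density 2.16 /µm for DL, AD-targeting 20.3%, AD-restricted
same-type fraction 77.4%, distal-tuft inhibitory fractions).  Skeleton node spacing is 1 µm; spine necks are
short labelled side branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from adsyn.skeleton_io import AnnotationSet, DatasetMeta, SkeletonNode, SkeletonTree
from adsyn.morphometry import DendriteAnnotation
from adsyn.synapse_quant import SynapseRecord
from adsyn.axon_analysis import AxonAnnotation, OutputSynapse, TARGET_CATEGORIES
from adsyn.celltype_models import L5Features, ThickTuftednessPCA

__all__ = [
    "GeneratorConfig",
    "generate_dendrite_annotations",
    "generate_dendrites",
    "generate_axons",
    "generate_identity_axons",
    "generate_l5_features",
    "generate_l5_population",
    "generate_distance_fraction_data",
]


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic study, with their defaults.

    Rates are synapses per µm of shaft path length.  ``mb_rates`` and
    ``tuft_rates`` map cell type → (inhibitory shaft rate, excitatory
    primary-spine rate); the trunk outside the MB window uses the total MB
    rate with the inhibitory share taken from the exponential distance
    model, which makes rates continuous at the window boundary.
    """

    rng_seed: int = 0

    # geometry (µm); trunk lengths are rounded to whole 1 µm segments
    node_spacing: float = 1.0
    mb_depth_mean: float = 15.0  # below dataset top face
    mb_depth_sd: float = 5.0
    trunk_length: dict = field(
        default_factory=lambda: {
            "L2": (41.0, 8.0),  # (mean, sd); chosen so f(d_MB) ~ the L2 MB fraction
            "L2MN": (41.0, 8.0),
            "L3": (120.0, 20.0),
            "L5tt": (300.0, 40.0),
            "L5st": (260.0, 40.0),
            "DL": (30.0, 0.0),  # visible trunk stub below the MB; no soma in volume
        }
    )
    tuft_branch_length: dict = field(
        default_factory=lambda: {
            "L2": 30.0,
            "L2MN": 30.0,
            "L3": 40.0,
            "L5tt": 60.0,
            "L5st": 50.0,
            "DL": 30.0,
        }
    )

    # synapse rates per µm at the MB window: (inhibitory shaft, excitatory spine)
    mb_rates: dict = field(
        default_factory=lambda: {
            "L2": (0.42, 0.84),
            "L2MN": (0.42, 0.84),
            "L3": (0.11, 1.30),
            "L5tt": (0.133, 1.40),
            "L5st": (0.107, 0.59),
            "DL": (0.22, 2.16),
        }
    )
    # distal tuft rates beyond `distal_offset` past the MB; the shaft rate is
    # calibrated so the TOTAL putative-inhibitory rate (shaft + neck +
    # secondary-spine) divided by the total rate gives the target distal
    # inhibitory fraction for each type (22.5% for L5tt, 31.3% L5st,
    # 11.4% L2, 10.2% L3)
    tuft_rates: dict = field(
        default_factory=lambda: {
            "L2": (0.106, 1.79),
            "L2MN": (0.106, 1.79),
            "L3": (0.073, 1.30),
            "L5tt": (0.102, 0.465),
            "L5st": (0.112, 0.30),
            "DL": (0.106, 1.79),
        }
    )
    window_half: float = 10.0
    distal_offset: float = 30.0  # start of the distal tuft compartment past the MB

    # exponential distance model of the inhibitory fraction f(d) = a e^(b d) + c
    distance_model: tuple = (1.57, -0.047, 0.10)
    distance_noise_sd: float = 0.12

    # spine extras
    double_spine_rate: dict = field(
        default_factory=lambda: {"L2": 0.064, "L2MN": 0.064, "DL": 0.035}
    )
    double_spine_rate_default: float = 0.05
    spine_neck_syn_rate: float = 0.01  # per µm, everywhere

    # axon model
    n_axons: dict = field(default_factory=lambda: {"L2": 92, "DL": 91})
    p_ad: float = 0.203
    selectivity: float = 0.548  # (1+s)/2 = 0.774 same-type AD connection probability
    syn_per_axon_mean: float = 15.0
    syn_per_axon_min: int = 6
    multiplicity_probs: tuple = (0.77, 0.17, 0.04, 0.02)  # synapses per AD target 1..4
    nonad_mix: dict = field(
        default_factory=lambda: {
            "other_shaft": 0.315,
            "single_spine": 0.345,
            "double_spine": 0.030,
            "soma": 0.105,
            "AIS": 0.008,
            "glia": 0.0005,
        }
    )
    ad_pool_size: int = 60
    regions: tuple = ("S1", "V2", "PPC", "ACC")

    # axon identity model (spine-fraction bimodality and shaft-identity mixing)
    exc_single_spine_frac: float = 0.9
    inh_single_spine_frac: float = 0.1
    shaft_exc_mixing: dict = field(
        default_factory=lambda: {("L5st", "L1"): 0.44, ("L5st", "L2"): 0.60}
    )
    shaft_exc_mixing_default: float = 0.05
    spine_exc_mixing: float = 0.95

    # L5 morphology model: two 4-D Gaussians
    l5_mean: dict = field(
        default_factory=lambda: {
            "L5tt": (14.0, 55.0, 6.0, 2.5),
            "L5st": (10.0, 95.0, 2.5, 1.5),
        }
    )
    l5_sd: dict = field(
        default_factory=lambda: {
            "L5tt": (1.0, 10.0, 1.2, 0.3),
            "L5st": (1.0, 10.0, 1.2, 0.3),
        }
    )
    l5_tt_fraction: float = 7.0 / 18.0
    # density models vs thick-tuftedness (PC 1)
    e_density_model: tuple = (0.44, 1.40)  # slope, intercept
    e_density_noise_sd: float = 0.25
    i_fraction_model: tuple = (0.043, 0.13, 0.58, 1.40)  # (a, b, c, d)
    i_fraction_noise_sd: float = 0.02

    meta: DatasetMeta = field(
        default_factory=lambda: DatasetMeta(
            name="synthetic", voxel_size=(11.24, 11.24, 28.0), pia_offset=110.0
        )
    )

    def validate(self) -> None:
        bad = []
        if not 0 <= self.selectivity <= 1:
            bad.append("selectivity")
        if not 0 <= self.p_ad <= 1:
            bad.append("p_ad")
        for ct, (ri, re) in self.mb_rates.items():
            if ri < 0 or re < 0:
                bad.append(f"mb_rates[{ct}]")
        if abs(sum(self.multiplicity_probs) - 1) > 1e-9:
            bad.append("multiplicity_probs")
        if bad:
            raise ValueError(f"invalid generator config fields: {bad}")

    def f_inh(self, d: float) -> float:
        a, b, c = self.distance_model
        return float(np.clip(a * np.exp(b * d) + c, 0.0, 1.0))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# dendrites

def _build_dendrite(
    cfg: GeneratorConfig, celltype: str, name: str, rng: np.random.Generator
) -> tuple[DendriteAnnotation, dict]:
    """One cell: trunk + Y bifurcation + two tuft branches, synapses placed.

    Synapses are drawn from inhomogeneous Poisson processes along the
    continuous arc length (rates piecewise constant per 1 µm subinterval)
    and inserted as dedicated skeleton nodes at their exact arc positions,
    so realized densities are unbiased estimates of the configured rates
    regardless of node spacing or window boundaries.
    """
    sp = cfg.node_spacing
    mu, sd = cfg.trunk_length[celltype]
    trunk_len = max(3, int(round(rng.normal(mu, sd) if sd > 0 else mu)))
    branch_len = int(round(cfg.tuft_branch_length[celltype]))
    mb_depth = float(rng.normal(cfg.mb_depth_mean, cfg.mb_depth_sd))
    d_mb = float(trunk_len)

    horizontal = celltype == "L2MN"  # oblique trunk parallel to pia
    if horizontal:
        start = np.array([0.0, mb_depth, 0.0])
        trunk_dir = np.array([1.0, 0.0, 0.0])
    else:
        start = np.array([0.0, mb_depth + trunk_len, 0.0])
        trunk_dir = np.array([0.0, -1.0, 0.0])
    mb_pos = start + d_mb * trunk_dir
    diag = 1.0 / np.sqrt(2.0)
    branch_dirs = [
        np.array([+diag, -diag, 0.0]),
        np.array([-diag, -diag, 0.0]),
    ]

    r_inh_mb, r_exc_mb = cfg.mb_rates[celltype]
    r_inh_tuft, r_exc_tuft = cfg.tuft_rates[celltype]
    ds_rate = cfg.double_spine_rate.get(celltype, cfg.double_spine_rate_default)

    def rates_at(mid: float, on_tuft: bool) -> tuple[float, float]:
        """(inhibitory shaft, excitatory spine) rate for a subinterval midpoint."""
        if abs(mid - d_mb) < cfg.window_half:
            return r_inh_mb, r_exc_mb
        if on_tuft and (mid - d_mb) > cfg.distal_offset:
            return r_inh_tuft, r_exc_tuft
        if on_tuft or celltype == "DL":
            return r_inh_mb, r_exc_mb
        tot = r_inh_mb + r_exc_mb
        f = cfg.f_inh(mid)
        return tot * f, tot * (1 - f)

    def draw_branch_events(arc_lo: float, arc_hi: float, on_tuft: bool):
        """Poisson events (arc position, class) on [arc_lo, arc_hi)."""
        events = []
        for i in range(int(round(arc_lo)), int(round(arc_hi))):
            mid = i + 0.5 * sp
            r_inh, r_exc = rates_at(mid, on_tuft)
            for rate, onto in (
                (r_inh, "shaft"),
                (r_exc, "spine_primary"),
                (cfg.spine_neck_syn_rate, "spine_neck"),
            ):
                for _ in range(rng.poisson(rate * sp)):
                    events.append((i + float(rng.uniform(0, sp)), onto))
        events.sort(key=lambda t: t[0])
        return events

    tree = SkeletonTree(name=name, group_label=celltype)
    ad = DendriteAnnotation(
        tree=tree, celltype=celltype, meta=cfg.meta, name=name
    )
    nid = 0
    sid = 0
    spine_counter = 0

    def add_node(pos, comment=None):
        nonlocal nid
        nid += 1
        tree.nodes[nid] = SkeletonNode(id=nid, position=tuple(pos), comment=comment)
        return nid

    def emit(node, onto, spine_id=None):
        nonlocal sid
        sid += 1
        ad.synapses.append(SynapseRecord(id=sid, node=node, onto=onto, spine_id=spine_id))
        token = {
            "shaft": "shaft synapse",
            "spine_primary": f"spine synapse #{spine_id}",
            "spine_secondary": f"secondary spine synapse #{spine_id}",
            "spine_neck": "spine neck synapse",
        }[onto]
        node_obj = tree.nodes[node]
        node_obj.comment = f"{node_obj.comment}; {token}" if node_obj.comment else token

    def lay_out(origin, direction, arc0, arc1, prev_node, events, end_comment=None):
        """Chain structural (integer-arc) and synapse nodes along a segment."""
        nonlocal spine_counter
        pts = [(float(a), None) for a in np.arange(arc0 + sp, arc1 + sp / 2, sp)]
        pts += [(a, onto) for a, onto in events]
        pts.sort(key=lambda t: (t[0], t[1] is None))
        last_node = prev_node
        for arc, onto in pts:
            pos = origin + (arc - arc0) * direction
            is_end = onto is None and abs(arc - arc1) < 1e-9
            node = add_node(pos, comment=end_comment if is_end else None)
            tree.edges.add(frozenset((last_node, node)))
            last_node = node
            if onto == "spine_primary":
                spine_counter += 1
                emit(node, "spine_primary", spine_id=spine_counter)
                if rng.random() < ds_rate:
                    emit(node, "spine_secondary", spine_id=spine_counter)
                neck = add_node(pos + np.array([0.0, 0.0, 0.7]), comment="spine neck")
                tree.edges.add(frozenset((node, neck)))
            elif onto is not None:
                emit(node, onto)
        return last_node

    root_comment = "soma" if celltype != "DL" else "trunk origin"
    root = add_node(start, comment=root_comment)
    mb_node = lay_out(
        start,
        trunk_dir,
        0.0,
        d_mb,
        root,
        draw_branch_events(0.0, d_mb, on_tuft=False),
        end_comment="main bifurcation",
    )
    ad.soma_node = None if celltype == "DL" else root
    ad.root_node = root if celltype == "DL" else None
    ad.main_bifurcation_node = mb_node
    for bdir in branch_dirs:
        events = [
            (a, o)
            for a, o in draw_branch_events(d_mb, d_mb + branch_len, on_tuft=True)
        ]
        lay_out(mb_pos, bdir, d_mb, d_mb + branch_len, mb_node, events)

    truth = {
        "name": name,
        "celltype": celltype,
        "d_mb": d_mb,
        "mb_depth": mb_depth,
        "rate_inh_mb": r_inh_mb,
        "rate_exc_mb": r_exc_mb,
        "rate_inh_tuft": r_inh_tuft,
        "rate_exc_tuft": r_exc_tuft,
        "double_spine_rate": ds_rate,
        "n_synapses": len(ad.synapses),
    }
    return ad, truth


def generate_dendrite_annotations(
    config: GeneratorConfig | None = None,
    n_per_celltype: dict[str, int] | None = None,
    seed=None,
) -> tuple[list[DendriteAnnotation], pd.DataFrame]:
    """Generate labelled dendrite annotations (µm units) plus a truth table."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = _rng(cfg.rng_seed if seed is None else seed)
    n_per_celltype = n_per_celltype or {"L2": 41, "DL": 41}
    ads, rows = [], []
    for celltype, n in n_per_celltype.items():
        for k in range(n):
            ad, truth = _build_dendrite(cfg, celltype, f"{celltype}_{k:03d}", rng)
            ads.append(ad)
            rows.append(truth)
    return ads, pd.DataFrame(rows)


def generate_dendrites(
    config: GeneratorConfig | None = None,
    n_per_celltype: dict[str, int] | None = None,
    seed=None,
) -> tuple[AnnotationSet, pd.DataFrame]:
    """Generate an NML-ready :class:`AnnotationSet` (voxel units) + truth.

    Positions are converted from µm to voxel indices using the configured
    dataset metadata, so ``to_physical`` + ``dendrite_from_tree`` recovers
    the generated geometry.
    """
    cfg = config or GeneratorConfig()
    ads, truth = generate_dendrite_annotations(cfg, n_per_celltype, seed)
    scale = np.asarray(cfg.meta.voxel_size, dtype=float) / 1000.0  # µm per voxel
    scale[cfg.meta.cutting_axis] *= cfg.meta.thickness_correction
    trees = []
    for ad in ads:
        t = SkeletonTree(name=ad.tree.name, group_label=ad.tree.group_label)
        for nid, node in ad.tree.nodes.items():
            pos = tuple(np.asarray(node.position) / scale)
            t.nodes[nid] = SkeletonNode(id=nid, position=pos, comment=node.comment)
        t.edges = set(ad.tree.edges)
        trees.append(t)
    return AnnotationSet(meta=cfg.meta, trees=trees), truth


# ---------------------------------------------------------------------------
# axons

def _draw_n_syn(cfg: GeneratorConfig, rng) -> int:
    return max(cfg.syn_per_axon_min, int(rng.poisson(cfg.syn_per_axon_mean)))


def generate_axons(
    config: GeneratorConfig | None = None,
    seed_groups: dict[str, int] | None = None,
    seed=None,
) -> tuple[list[AxonAnnotation], dict]:
    """Generate AD-seeded (putative inhibitory) axon populations.

    Per axon: the number of AD-targeted output synapses is
    Binomial(n_syn, p_ad); AD synapses are grouped into connections with
    the configured multiplicity distribution, each connection hitting the
    seed's own AD type with probability (1+s)/2 (s = 0 indiscriminate,
    s = 1 fully selective) and a distinct AD id per connection.  Non-AD
    synapses draw a category from the configured mix.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = _rng(cfg.rng_seed if seed is None else seed)
    seed_groups = seed_groups or dict(cfg.n_axons)
    mix_cats = list(cfg.nonad_mix)
    mix_p = np.array([cfg.nonad_mix[c] for c in mix_cats], dtype=float)
    mix_p = mix_p / mix_p.sum()
    mult_k = np.arange(1, len(cfg.multiplicity_probs) + 1)
    p_same = (1.0 + cfg.selectivity) / 2.0

    axons = []
    aid = 0
    for seed_type, n_axons in seed_groups.items():
        seed_class = "L2" if seed_type in ("L2", "L2MN") else "DL"
        for _ in range(n_axons):
            aid += 1
            region = cfg.regions[int(rng.integers(len(cfg.regions)))]
            n_syn = _draw_n_syn(cfg, rng)
            n_ad = int(rng.binomial(n_syn, cfg.p_ad))
            outputs = []
            remaining = n_ad
            used_ids: set[int] = set()
            while remaining > 0:
                k = int(rng.choice(mult_k, p=cfg.multiplicity_probs))
                k = min(k, remaining)
                same = rng.random() < p_same
                ttype = seed_class if same else ("DL" if seed_class == "L2" else "L2")
                pool_base = 0 if ttype == "L2" else cfg.ad_pool_size
                while True:
                    tid = pool_base + int(rng.integers(cfg.ad_pool_size))
                    if tid not in used_ids:
                        used_ids.add(tid)
                        break
                cat = "L2_AD" if ttype == "L2" else "DL_AD"
                outputs.extend(OutputSynapse(category=cat, target_ad=tid) for _ in range(k))
                remaining -= k
            for _ in range(n_syn - n_ad):
                cat = mix_cats[int(rng.choice(len(mix_cats), p=mix_p))]
                outputs.append(
                    OutputSynapse(category=cat, single_spine=(cat == "single_spine"))
                )
            axons.append(
                AxonAnnotation(
                    id=aid,
                    seed_type=seed_type,
                    seed_location="shaft",
                    outputs=outputs,
                    region=region,
                )
            )
    ad_types = {
        i: ("L2" if i < cfg.ad_pool_size else "DL") for i in range(2 * cfg.ad_pool_size)
    }
    truth = {
        "p_ad": cfg.p_ad,
        "selectivity": cfg.selectivity,
        "p_same_type": p_same,
        "multiplicity_mean": float(np.dot(mult_k, cfg.multiplicity_probs)),
        "ad_types": ad_types,
    }
    return axons, truth


def generate_identity_axons(
    config: GeneratorConfig | None = None,
    groups: dict[tuple[str, str, str], int] | None = None,
    seed=None,
) -> tuple[list[AxonAnnotation], dict]:
    """Generate the axon calibration population for identity estimation.

    ``groups`` maps (seed AD type, seed location, layer context) to axon
    counts.  Each axon is excitatory with the configured mixing rate for
    its seed structure (shaft-seeded axons from excitatory axons are the
    confound the correction removes); output synapses land on
    single-innervated spines with a high rate for excitatory axons and a
    low rate for inhibitory ones, producing the bimodal spine-fraction
    histogram the 50% threshold exploits.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = _rng(cfg.rng_seed if seed is None else seed)
    groups = groups or {
        ("L2", "shaft", "L2"): 40,
        ("L2", "spine", "L2"): 40,
        ("L5st", "shaft", "L1"): 40,
        ("L5st", "shaft", "L2"): 40,
    }
    axons = []
    truth_rows = []
    aid = 0
    for (seed_type, seed_loc, layer), n in groups.items():
        if seed_loc == "shaft":
            p_exc = cfg.shaft_exc_mixing.get((seed_type, layer), cfg.shaft_exc_mixing_default)
        else:
            p_exc = cfg.spine_exc_mixing
        for _ in range(n):
            aid += 1
            is_exc = rng.random() < p_exc
            p_ss = cfg.exc_single_spine_frac if is_exc else cfg.inh_single_spine_frac
            n_syn = _draw_n_syn(cfg, rng)
            outputs = []
            for _ in range(n_syn):
                ss = rng.random() < p_ss
                outputs.append(
                    OutputSynapse(
                        category="single_spine" if ss else "other_shaft", single_spine=ss
                    )
                )
            axons.append(
                AxonAnnotation(
                    id=aid,
                    seed_type=seed_type,
                    seed_location=seed_loc,
                    layer_context=layer,
                    outputs=outputs,
                )
            )
            truth_rows.append(
                {
                    "axon_id": aid,
                    "seed_type": seed_type,
                    "seed_location": seed_loc,
                    "layer_context": layer,
                    "p_exc": p_exc,
                    "excitatory": is_exc,
                }
            )
    return axons, {"table": pd.DataFrame(truth_rows)}


# ---------------------------------------------------------------------------
# L5 features and density models

def generate_l5_features(
    config: GeneratorConfig | None = None, n: int = 18, seed=None
) -> tuple[list[L5Features], np.ndarray]:
    """Sample L5 morphology feature vectors from the two-Gaussian model."""
    cfg = config or GeneratorConfig()
    rng = _rng(cfg.rng_seed if seed is None else seed)
    n_tt = int(round(n * cfg.l5_tt_fraction))
    labels = np.array(["L5tt"] * n_tt + ["L5st"] * (n - n_tt))
    feats = []
    for lab in labels:
        mean = np.asarray(cfg.l5_mean[lab])
        sd = np.asarray(cfg.l5_sd[lab])
        v = rng.normal(mean, sd)
        v[0] = max(v[0], 1.0)
        v[2] = max(round(v[2]), 0)
        v[3] = max(v[3], 0.2)
        feats.append(L5Features(*v))
    return feats, labels


def generate_l5_population(
    config: GeneratorConfig | None = None, n: int = 18, seed=None
) -> pd.DataFrame:
    """L5 cells with features, thick-tuftedness and model-linked densities.

    The excitatory density follows the linear PC1 model and the inhibitory
    fraction the linear-fraction model, both with additive Gaussian noise;
    the inhibitory density is implied by I = E·f/(1−f).
    """
    cfg = config or GeneratorConfig()
    rng = _rng(cfg.rng_seed if seed is None else seed)
    feats, labels = generate_l5_features(cfg, n=n, seed=rng)
    pc1 = ThickTuftednessPCA().fit(feats).scores_
    slope, intercept = cfg.e_density_model
    e_dens = slope * pc1 + intercept + rng.normal(0, cfg.e_density_noise_sd, size=n)
    e_dens = np.clip(e_dens, 0.05, None)
    a, b, c, d = cfg.i_fraction_model
    frac = (a * pc1 + b) / (c * pc1 + d) + rng.normal(0, cfg.i_fraction_noise_sd, size=n)
    frac = np.clip(frac, 0.01, 0.95)
    i_dens = e_dens * frac / (1 - frac)
    return pd.DataFrame(
        {
            "label": labels,
            "soma_equiv_diameter": [f.soma_equiv_diameter for f in feats],
            "bifurcation_depth": [f.bifurcation_depth for f in feats],
            "n_oblique": [f.n_oblique for f in feats],
            "trunk_diameter": [f.trunk_diameter for f in feats],
            "pc1": pc1,
            "e_density": e_dens,
            "i_density": i_dens,
            "i_fraction": frac,
        }
    )


def generate_distance_fraction_data(
    config: GeneratorConfig | None = None, n: int = 81, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """(d_MB, inhibitory fraction) samples from the distance model + noise."""
    cfg = config or GeneratorConfig()
    rng = _rng(cfg.rng_seed if seed is None else seed)
    a, b, c = cfg.distance_model
    x = rng.uniform(10.0, 330.0, size=n)
    y = a * np.exp(b * x) + c + rng.normal(0, cfg.distance_noise_sd, size=n)
    return x, y
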