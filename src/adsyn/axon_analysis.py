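"""Axon-level identity calibration and target-preference statistics.

Each reconstructed axon starts from a seed synapse on an apical dendrite
(AD) and carries a list of output synapses, each categorized into one of
eight mutually exclusive subcellular targets.  The seed synapse is always
excluded from the output statistics.

The identity rule for axons: an axon with a strict majority (> 50%) of its
output synapses onto single-innervated spines is excitatory; otherwise it
is putative inhibitory.  This calibration feeds the per-structure density
correction for shaft synapses that actually originate from excitatory
(spine-preferring) axons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TARGET_CATEGORIES",
    "SEED_TYPES",
    "AxonAnnotation",
    "InnervationProfile",
    "SpecificityResult",
    "RegionConsistencyResult",
    "spine_fraction",
    "classify_axon",
    "excitatory_fraction_per_structure",
    "correct_density",
    "prediction_accuracy",
    "innervation_profile",
    "conditional_matrix",
    "multiplicity_stats",
    "binarized_preference",
    "bootstrap_specificity_test",
    "region_consistency",
    "axons_to_table",
    "axons_from_table",
]

TARGET_CATEGORIES = (
    "L2_AD",
    "DL_AD",
    "other_shaft",
    "single_spine",
    "double_spine",
    "soma",
    "AIS",
    "glia",
)
AD_CATEGORIES = ("L2_AD", "DL_AD")
SEED_TYPES = ("L2", "DL", "L3", "L5tt", "L5st")


@dataclass(frozen=True)
class OutputSynapse:
    category: str
    target_ad: int | None = None  # identity of the targeted AD, if an AD target
    single_spine: bool = False  # synapse onto a single-innervated spine

    def __post_init__(self) -> None:
        if self.category not in TARGET_CATEGORIES:
            raise ValueError(f"unknown target category {self.category!r}")


@dataclass
class AxonAnnotation:
    """One reconstructed axon: seed synapse context plus output synapses."""

    id: int
    seed_type: str  # AD type the seed synapse was on
    seed_location: str  # "shaft" or "spine"
    outputs: list[OutputSynapse] = field(default_factory=list)
    region: str = ""
    layer_context: str = "L2"

    def __post_init__(self) -> None:
        if self.seed_type not in SEED_TYPES:
            raise ValueError(f"unknown seed AD type {self.seed_type!r}")
        if self.seed_location not in ("shaft", "spine"):
            raise ValueError(f"seed location must be shaft or spine")


@dataclass
class InnervationProfile:
    axon_id: int
    fractions: dict[str, float]
    n_synapses: int
    seed_type: str = ""
    region: str = ""


def spine_fraction(axon: AxonAnnotation) -> float:
    """Fraction of output synapses made onto single-innervated spines."""
    if not axon.outputs:
        raise ValueError(f"axon {axon.id} has no output synapses")
    return sum(1 for o in axon.outputs if o.single_spine) / len(axon.outputs)


def classify_axon(f: float, threshold: float = 0.5) -> str:
    """Excitatory iff a strict majority of synapses is on single spines.

    Exactly at the threshold the axon is putative inhibitory (majority is
    strict).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("spine fraction must lie in [0, 1]")
    return "excitatory" if f > threshold else "putative_inhibitory"


def excitatory_fraction_per_structure(
    axons: list[AxonAnnotation], threshold: float = 0.5
) -> pd.DataFrame:
    """Fraction of seed synapses per structure whose axon is excitatory.

    Grouped by (seed AD type, seed location, layer context); empty cells
    are absent from the table (missing, not zero).  This is the
    calibration table behind the shaft-synapse identity correction.
    """
    rows = []
    for ax in axons:
        rows.append(
            {
                "seed_type": ax.seed_type,
                "seed_location": ax.seed_location,
                "layer_context": ax.layer_context,
                "excitatory": classify_axon(spine_fraction(ax), threshold) == "excitatory",
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["seed_type", "seed_location", "layer_context"])["excitatory"]
        .agg(f_exc="mean", n="size")
        .reset_index()
    )
    return out


def correct_density(raw, f_exc_shaft: float):
    """Reassign the excitatory share of shaft synapses and recompute.

    A fraction ``f_exc_shaft`` of shaft-onto synapses actually comes from
    excitatory (spine-preferring) axons: that mass moves from the putative
    inhibitory to the excitatory tally.  Double-spine contributions are
    left untouched.  Returns a corrected :class:`DensityResult` copy.
    """
    if not 0.0 <= f_exc_shaft <= 1.0:
        raise ValueError("f_exc_shaft must lie in [0, 1]")
    if raw.corrected:
        raise ValueError("density result already corrected")
    moved = raw.n_shaft * f_exc_shaft
    n_inh = raw.n_inh - moved
    n_exc = raw.n_exc + moved
    total = n_inh + n_exc
    length = raw.shaft_length
    out = replace(
        raw,
        n_exc=n_exc,
        n_inh=n_inh,
        dens_exc_len=n_exc / length,
        dens_inh_len=n_inh / length,
        dens_exc_area=(n_exc / raw.surface_area) if raw.surface_area else None,
        dens_inh_area=(n_inh / raw.surface_area) if raw.surface_area else None,
        inh_fraction=n_inh / total if total else float("nan"),
        corrected=True,
    )
    return out


def prediction_accuracy(
    axons: list[AxonAnnotation], threshold: float = 0.5
) -> pd.DataFrame:
    """Accuracy of predicting axon identity from the seed-synapse location.

    The location-implied class (shaft seed → inhibitory, spine seed →
    excitatory) is compared with the spine-fraction classification; the
    table reports the match fraction per (seed AD type, seed location).
    """
    rows = []
    for ax in axons:
        implied = "putative_inhibitory" if ax.seed_location == "shaft" else "excitatory"
        actual = classify_axon(spine_fraction(ax), threshold)
        rows.append(
            {
                "seed_type": ax.seed_type,
                "seed_location": ax.seed_location,
                "match": implied == actual,
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["seed_type", "seed_location"])["match"]
        .agg(accuracy="mean", n="size")
        .reset_index()
    )


def innervation_profile(axon: AxonAnnotation) -> InnervationProfile:
    """8-category output fraction vector of one axon (seed excluded)."""
    if not axon.outputs:
        raise ValueError(f"axon {axon.id} has no output synapses")
    n = len(axon.outputs)
    fractions = {
        cat: sum(1 for o in axon.outputs if o.category == cat) / n
        for cat in TARGET_CATEGORIES
    }
    return InnervationProfile(
        axon_id=axon.id,
        fractions=fractions,
        n_synapses=n,
        seed_type=axon.seed_type,
        region=axon.region,
    )


def _ad_restricted(fr: dict[str, float]) -> dict[str, float] | None:
    tot = fr["L2_AD"] + fr["DL_AD"]
    if tot == 0:
        return None
    return {"L2_AD": fr["L2_AD"] / tot, "DL_AD": fr["DL_AD"] / tot}


def conditional_matrix(profiles: list[InnervationProfile]) -> pd.DataFrame:
    """Conditional AD-innervation p(B|A) per seed group.

    Rows are seed AD types; columns are the mean per-axon fraction of
    output synapses onto L2 and DL ADs, the mean overall AD-targeting
    fraction, and the AD-restricted renormalization (mean of per-axon
    fractions among AD synapses only, axons without AD synapses excluded).
    """
    rows = []
    for seed in sorted({p.seed_type for p in profiles}):
        group = [p for p in profiles if p.seed_type == seed]
        l2 = np.mean([p.fractions["L2_AD"] for p in group])
        dl = np.mean([p.fractions["DL_AD"] for p in group])
        restricted = [_ad_restricted(p.fractions) for p in group]
        restricted = [r for r in restricted if r is not None]
        rows.append(
            {
                "seed_type": seed,
                "p_L2_AD": l2,
                "p_DL_AD": dl,
                "p_AD_total": l2 + dl,
                "p_L2_AD_restricted": np.mean([r["L2_AD"] for r in restricted])
                if restricted
                else np.nan,
                "p_DL_AD_restricted": np.mean([r["DL_AD"] for r in restricted])
                if restricted
                else np.nan,
                "n_axons": len(group),
                "n_axons_with_AD": len(restricted),
            }
        )
    return pd.DataFrame(rows).set_index("seed_type")


def multiplicity_stats(axons: list[AxonAnnotation]) -> pd.DataFrame:
    """Multiple innervation of individual AD targets.

    Per axon: the mean number of synapses on each distinct AD target (axons
    with no identified AD target are excluded — averages are undefined on
    empty sets).  The table reports, per seed group, the population mean of
    those per-axon means, its SEM, and the connection-level fraction of
    monosynaptic (single-synapse) connections.
    """
    rows = []
    for seed in sorted({a.seed_type for a in axons}):
        group = [a for a in axons if a.seed_type == seed]
        per_axon_means = []
        n_conn = 0
        n_mono = 0
        for ax in group:
            targets = [o.target_ad for o in ax.outputs if o.target_ad is not None]
            if not targets:
                continue
            counts = pd.Series(targets).value_counts()
            per_axon_means.append(float(counts.mean()))
            n_conn += len(counts)
            n_mono += int((counts == 1).sum())
        if not per_axon_means:
            continue
        arr = np.asarray(per_axon_means)
        rows.append(
            {
                "seed_type": seed,
                "mean_syn_per_target": arr.mean(),
                "sem_syn_per_target": arr.std(ddof=1) / np.sqrt(len(arr))
                if len(arr) > 1
                else np.nan,
                "frac_monosynaptic": n_mono / n_conn,
                "n_axons": len(arr),
                "n_connections": n_conn,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["seed_type"]).set_index("seed_type")
    return pd.DataFrame(rows).set_index("seed_type")


def binarized_preference(
    axons: list[AxonAnnotation], ad_types: dict[int, str]
) -> pd.DataFrame:
    """AD-type preference counting each distinct AD target once.

    ``ad_types`` maps AD ids to their type (``"L2"`` or ``"DL"``).  Per
    axon, multiple innervations of the same AD collapse to one; fractions
    over distinct-AD targets are averaged per seed group.  Axons with no
    distinct AD target are excluded.
    """
    rows = []
    for seed in sorted({a.seed_type for a in axons}):
        group = [a for a in axons if a.seed_type == seed]
        fracs_l2, fracs_dl = [], []
        for ax in group:
            distinct = {o.target_ad for o in ax.outputs if o.target_ad is not None}
            if not distinct:
                continue
            types = [ad_types[t] for t in distinct]
            fracs_l2.append(types.count("L2") / len(types))
            fracs_dl.append(types.count("DL") / len(types))
        if not fracs_l2:
            continue
        rows.append(
            {
                "seed_type": seed,
                "p_L2_target": float(np.mean(fracs_l2)),
                "p_DL_target": float(np.mean(fracs_dl)),
                "n_axons": len(fracs_l2),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["seed_type"]).set_index("seed_type")
    return pd.DataFrame(rows).set_index("seed_type")


# ---------------------------------------------------------------------------
# bootstrap specificity test

@dataclass
class SpecificityResult:
    categories: tuple[str, ...]
    observed_diff: np.ndarray
    p_values: np.ndarray
    p_values_plus_one: np.ndarray  # (1 + extreme)/(1 + n_boot) convention
    significant: np.ndarray
    alpha: float
    n_comparisons: int
    n_boot: int


def bootstrap_specificity_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 10000,
    alpha: float = 0.05,
    n_comparisons: int = 8,
    seed: int | np.random.Generator = 0,
    categories: tuple[str, ...] = TARGET_CATEGORIES,
    plus_one: bool = False,
) -> SpecificityResult:
    """Pooled-resampling bootstrap test of per-category mean differences.

    The per-axon fraction vectors of the two groups are concatenated;
    ``n_boot`` resamples are drawn matching the original group sizes, and
    the per-category p-value is the fraction of resampled mean differences
    at least as extreme (two-sided, in absolute value) as the observed one.
    Significance uses Bonferroni correction: p < alpha / n_comparisons.

    ``plus_one`` switches to the (1+extreme)/(1+n_boot) convention; both
    p-value sets are always reported.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the category dimension")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    observed = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.vstack([a, b])
    n = n_a + n_b
    idx_a = rng.integers(0, n, size=(n_boot, n_a))
    idx_b = rng.integers(0, n, size=(n_boot, n_b))
    diffs = pooled[idx_a].mean(axis=1) - pooled[idx_b].mean(axis=1)
    extreme = (np.abs(diffs) >= np.abs(observed)[None, :]).sum(axis=0)
    p = extreme / n_boot
    p1 = (extreme + 1) / (n_boot + 1)
    used = p1 if plus_one else p
    return SpecificityResult(
        categories=tuple(categories[: a.shape[1]]),
        observed_diff=observed,
        p_values=p,
        p_values_plus_one=p1,
        significant=used < alpha / n_comparisons,
        alpha=alpha,
        n_comparisons=n_comparisons,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# cross-region consistency

@dataclass
class RegionConsistencyResult:
    cv_table: pd.DataFrame  # CV (%) per (seed_type, category)
    omnibus: pd.DataFrame | None  # per-seed MANOVA-type result
    followups: pd.DataFrame | None  # per-category one-way ANOVA (on rejection)
    retained_categories: tuple[str, ...]


def region_consistency(
    profiles: list[InnervationProfile],
    alpha: float = 0.05,
    retained: tuple[str, ...] = TARGET_CATEGORIES[:6],
) -> RegionConsistencyResult:
    """Consistency of target preference across cortical regions.

    CV per (seed, target) = std of the region means / mean of the region
    means × 100.  An omnibus multivariate location test (Wilks' lambda) is
    run per seed group over the retained categories (AIS and glia excluded
    by default: too few synapses, singular covariance); per-category
    one-way ANOVAs at Bonferroni-corrected alpha follow only on rejection.
    """
    from statsmodels.multivariate.manova import MANOVA

    regions = sorted({p.region for p in profiles})
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    cv_rows = []
    omnibus_rows = []
    followup_rows = []
    for seed in sorted({p.seed_type for p in profiles}):
        group = [p for p in profiles if p.seed_type == seed]
        for cat in TARGET_CATEGORIES:
            means = [
                np.mean([p.fractions[cat] for p in group if p.region == r])
                for r in regions
                if any(p.region == r for p in group)
            ]
            m = np.mean(means)
            cv = (np.std(means, ddof=1) / m * 100) if (len(means) > 1 and m > 0) else np.nan
            cv_rows.append({"seed_type": seed, "category": cat, "cv_percent": cv})

        x = np.array([[p.fractions[c] for c in retained] for p in group])
        labels = [p.region for p in group]
        try:
            df = pd.DataFrame(x, columns=[f"c{i}" for i in range(x.shape[1])])
            df["region"] = labels
            mv = MANOVA.from_formula(
                " + ".join(df.columns[:-1]) + " ~ region", data=df
            )
            tab = mv.mv_test().results["region"]["stat"]
            p_omni = float(tab.loc["Wilks' lambda", "Pr > F"])
            omnibus_rows.append({"seed_type": seed, "p_value": p_omni, "applicable": True})
        except Exception:
            omnibus_rows.append({"seed_type": seed, "p_value": np.nan, "applicable": False})
            continue
        if p_omni < alpha:
            m = len(retained)
            for cat in retained:
                samples = [
                    [p.fractions[cat] for p in group if p.region == r] for r in regions
                ]
                samples = [s for s in samples if len(s) > 0]
                stat, p_cat = stats.f_oneway(*samples)
                followup_rows.append(
                    {
                        "seed_type": seed,
                        "category": cat,
                        "F": stat,
                        "p_value": p_cat,
                        "significant": p_cat < alpha / m,
                    }
                )
    return RegionConsistencyResult(
        cv_table=pd.DataFrame(cv_rows),
        omnibus=pd.DataFrame(omnibus_rows) if omnibus_rows else None,
        followups=pd.DataFrame(followup_rows) if followup_rows else None,
        retained_categories=retained,
    )


# ---------------------------------------------------------------------------
# tabular I/O (one row per output synapse)

_TABLE_COLS = [
    "axon_id",
    "seed_type",
    "seed_location",
    "layer_context",
    "region",
    "category",
    "target_ad",
    "single_spine",
]


def axons_to_table(axons: list[AxonAnnotation]) -> pd.DataFrame:
    rows = []
    for ax in axons:
        for o in ax.outputs:
            rows.append(
                {
                    "axon_id": ax.id,
                    "seed_type": ax.seed_type,
                    "seed_location": ax.seed_location,
                    "layer_context": ax.layer_context,
                    "region": ax.region,
                    "category": o.category,
                    "target_ad": o.target_ad if o.target_ad is not None else -1,
                    "single_spine": int(o.single_spine),
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def axons_from_table(df: pd.DataFrame) -> list[AxonAnnotation]:
    axons = []
    for (aid,), sub in df.groupby(["axon_id"]):
        first = sub.iloc[0]
        outputs = [
            OutputSynapse(
                category=r.category,
                target_ad=None if r.target_ad < 0 else int(r.target_ad),
                single_spine=bool(r.single_spine),
            )
            for r in sub.itertuples()
        ]
        axons.append(
            AxonAnnotation(
                id=int(aid),
                seed_type=first["seed_type"],
                seed_location=first["seed_location"],
                layer_context=first["layer_context"],
                region=first["region"],
                outputs=outputs,
            )
        )
    return axons
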