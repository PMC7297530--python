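"""Cell-type assignment, L5 subtype models and regression fits.

Pyramidal-cell types are assigned by soma depth below pia (L2/L3/L5; ADs
without a soma in the volume are "deep layer", DL).  L5 cells split into
thick-tufted (L5tt) and slender-tufted (L5st) subtypes by agglomerative
average-linkage clustering of four morphological features — soma
equivalent diameter, main-bifurcation depth, number of oblique dendrites,
trunk diameter — with the distance metric selected by cophenetic
correlation.  The first principal component of the same feature space is
the "thick-tuftedness" score.

Model fits: y = c + a·e^(b·x) (exponential with offset, for the
inhibitory-fraction vs soma→bifurcation-distance relation), ordinary least
squares, and the linear-fraction model y = (a·x+b)/(c·x+d) (only defined
up to a common scale of the four parameters).

The model classes follow the sklearn estimator contract (``fit``,
``predict``/``transform``, ``get_params``); module-level ``fit_*``
functions are thin wrappers returning a :class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.decomposition import PCA

from adsyn.morphometry import DendriteAnnotation, MeasurementMissingError

__all__ = [
    "L5Features",
    "FitResult",
    "FitError",
    "assign_layer",
    "flag_l2mn",
    "ExponentialDecayRegressor",
    "LinearFractionRegressor",
    "L5SubtypeClusterer",
    "ThickTuftednessPCA",
    "cluster_l5",
    "thick_tuftedness",
    "fit_exponential",
    "fit_linear",
    "fit_linear_fraction",
    "predict_fraction_from_densities",
    "compare_groups",
    "features_to_matrix",
]

L5_FEATURE_NAMES = (
    "soma_equiv_diameter",
    "bifurcation_depth",
    "n_oblique",
    "trunk_diameter",
)


class FitError(RuntimeError):
    """A regression failed to converge or violated a model constraint."""


@dataclass(frozen=True)
class L5Features:
    """Morphological feature vector of one L5 pyramidal cell."""

    soma_equiv_diameter: float  # µm
    bifurcation_depth: float  # µm below pia
    n_oblique: int
    trunk_diameter: float  # µm

    def __post_init__(self) -> None:
        if self.soma_equiv_diameter <= 0 or self.trunk_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.n_oblique < 0:
            raise ValueError("oblique count must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.soma_equiv_diameter,
                self.bifurcation_depth,
                self.n_oblique,
                self.trunk_diameter,
            ],
            dtype=float,
        )


def features_to_matrix(features) -> np.ndarray:
    if len(features) and isinstance(features[0], L5Features):
        return np.vstack([f.as_array() for f in features])
    return np.asarray(features, dtype=float)


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    r_squared: float
    n: int


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# layer assignment and L2MN flag

def assign_layer(soma_depth: float | None, thresholds=(150.0, 350.0, 700.0)) -> str:
    """Layer of a pyramidal cell from its soma depth below pia (µm).

    ``thresholds = (b1, b2, b3)`` strictly increasing: depth in [0, b1) →
    L2, [b1, b2) → L3, [b2, b3) → L5; boundary values belong to the deeper
    layer (half-open intervals).  ``soma_depth=None`` (no soma in the image
    volume) → "DL"; depth beyond b3 → "unknown".
    """
    if soma_depth is None:
        return "DL"
    b1, b2, b3 = thresholds
    if not (0 < b1 < b2 < b3):
        raise ValueError("thresholds must be strictly increasing and positive")
    if soma_depth < 0:
        raise ValueError("soma depth must be >= 0")
    if soma_depth < b1:
        return "L2"
    if soma_depth < b2:
        return "L3"
    if soma_depth < b3:
        return "L5"
    return "unknown"


def flag_l2mn(ad: DendriteAnnotation, angle_threshold: float = 60.0) -> bool:
    """Layer-2 marginal neuron flag: an AD trunk running parallel to pia.

    The trunk direction is the soma→main-bifurcation chord; the flag is
    true iff its angle to the pia normal (the depth axis) exceeds
    ``angle_threshold`` degrees.  Chords shorter than 5 µm cannot be
    evaluated.
    """
    if ad.soma_node is None or ad.main_bifurcation_node is None:
        raise MeasurementMissingError("soma and main bifurcation required")
    p0 = np.asarray(ad.tree.nodes[ad.soma_node].position, dtype=float)
    p1 = np.asarray(ad.tree.nodes[ad.main_bifurcation_node].position, dtype=float)
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm < 5.0:
        raise MeasurementMissingError("soma-bifurcation chord shorter than 5 µm")
    axis = (ad.meta.depth_axis if ad.meta is not None else 1)
    cos = abs(chord[axis]) / norm
    angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return bool(angle > angle_threshold)


# ---------------------------------------------------------------------------
# regression estimators

class ExponentialDecayRegressor(BaseEstimator, RegressorMixin):
    """Single-term exponential with offset: y = c + a·e^(b·x).

    Nonlinear least squares; initialization c₀ = min(y),
    a₀ = max(y) − c₀, b₀ from a log-linear regression of (y − c₀).
    ``offset_bounds`` constrains c (use (0, 1) when y is a fraction).
    """

    def __init__(self, offset_bounds: tuple[float, float] | None = None, maxfev: int = 10000):
        self.offset_bounds = offset_bounds
        self.maxfev = maxfev

    @staticmethod
    def _model(x, a, b, c):
        return c + a * np.exp(b * x)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 4:
            raise FitError("exponential fit needs at least 4 points")
        if np.ptp(y) == 0:
            self.a_, self.b_, self.c_ = 0.0, 0.0, float(y.mean())
            self.r_squared_, self.n_ = 0.0, x.size
            return self
        c0 = float(y.min())
        a0 = float(y.max() - c0)
        resid = np.clip(y - c0, 1e-9, None)
        b0 = float(stats.linregress(x, np.log(resid)).slope)
        if not np.isfinite(b0) or b0 == 0:
            b0 = -1.0 / max(np.ptp(x), 1.0)
        lo = [-np.inf, -np.inf, -np.inf]
        hi = [np.inf, np.inf, np.inf]
        if self.offset_bounds is not None:
            lo[2], hi[2] = self.offset_bounds
            c0 = float(np.clip(c0, lo[2], hi[2]))
        try:
            popt, _ = optimize.curve_fit(
                self._model, x, y, p0=(a0, b0, c0), bounds=(lo, hi), maxfev=self.maxfev
            )
        except RuntimeError as err:
            raise FitError(f"exponential fit did not converge: {err}") from err
        self.a_, self.b_, self.c_ = (float(v) for v in popt)
        self.r_squared_ = _r_squared(y, self._model(x, *popt))
        self.n_ = x.size
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return self._model(x, self.a_, self.b_, self.c_)


class LinearFractionRegressor(BaseEstimator, RegressorMixin):
    """Ratio of two linear expressions: y = (a·x + b) / (c·x + d).

    The model is invariant under common scaling of (a, b, c, d); the raw
    optimizer solution is reported in ``params_`` and a d-normalized copy
    (scaled so d = 1) in ``params_dnorm_``.  Fits whose denominator
    changes sign over the data range are rejected.
    """

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    @staticmethod
    def _model(x, a, b, c, d):
        return (a * x + b) / (c * x + d)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 5:
            raise FitError("linear-fraction fit needs at least 5 points")
        lin = stats.linregress(x, y)
        inits = [(float(lin.slope), float(lin.intercept), 0.0, 1.0)]
        if np.all(y != 0):  # hyperbolic start from the reciprocal regression
            rec = stats.linregress(x, 1.0 / y)
            inits.append((0.0, 1.0, float(rec.slope), float(rec.intercept)))
        best = None
        for p0 in inits:
            try:
                popt, _ = optimize.curve_fit(
                    self._model, x, y, p0=p0, maxfev=self.maxfev
                )
            except RuntimeError:
                continue
            sse = float(np.sum((y - self._model(x, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            raise FitError("linear-fraction fit did not converge")
        a, b, c, d = (float(v) for v in best[1])
        den = c * np.array([x.min(), x.max()]) + d
        if den[0] * den[1] <= 0:
            raise FitError("denominator changes sign over the data range")
        if den[0] < 0:  # use the positive-denominator representative
            a, b, c, d = -a, -b, -c, -d
        self.params_ = {"a": a, "b": b, "c": c, "d": d}
        self.params_dnorm_ = {k: v / d for k, v in self.params_.items()}
        self.r_squared_ = _r_squared(y, self._model(x, a, b, c, d))
        self.n_ = x.size
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        p = self.params_
        return self._model(x, p["a"], p["b"], p["c"], p["d"])


# ---------------------------------------------------------------------------
# L5 subtype clustering and thick-tuftedness

class L5SubtypeClusterer(BaseEstimator):
    """Two-cluster L5tt/L5st partition of the 4-D morphology space.

    Agglomerative average-linkage clustering; the metric is chosen among
    candidates by highest cophenetic correlation (the paper's criterion:
    agreement between pairwise distances and dendrogram link heights).
    Features are z-scored first by default — cosine distance mixes units
    otherwise.  The cluster with larger mean soma equivalent diameter is
    labelled L5tt.
    """

    def __init__(
        self,
        metrics: tuple[str, ...] = ("cosine", "euclidean", "correlation", "cityblock"),
        standardize: bool = True,
        soma_col: int = 0,
    ):
        self.metrics = metrics
        self.standardize = standardize
        self.soma_col = soma_col

    def fit(self, X, y=None):
        x = features_to_matrix(X)
        if x.shape[0] < 4:
            raise ValueError("need at least 4 cells to cluster")
        if np.allclose(x, x[0]):
            raise ValueError("identical feature vectors: clustering is degenerate")
        z = x.copy()
        if self.standardize:
            sd = z.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            z = (z - z.mean(axis=0)) / sd
        self.cophenetic_correlations_ = {}
        best = None
        for metric in self.metrics:
            d = pdist(z, metric=metric)
            lk = linkage(d, method="average")
            coph = float(cophenet(lk, d)[0])
            self.cophenetic_correlations_[metric] = coph
            if best is None or coph > best[0]:
                best = (coph, metric, lk)
        _, self.metric_, self.linkage_ = best
        if self.metric_ != "cosine":
            warnings.warn(
                f"cophenetic selection picked {self.metric_!r}, not cosine", stacklevel=2
            )
        raw = fcluster(self.linkage_, t=2, criterion="maxclust")
        soma = x[:, self.soma_col]
        mean1 = soma[raw == 1].mean() if np.any(raw == 1) else -np.inf
        mean2 = soma[raw == 2].mean() if np.any(raw == 2) else -np.inf
        tt = 1 if mean1 >= mean2 else 2
        self.labels_ = np.where(raw == tt, "L5tt", "L5st")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ThickTuftednessPCA(BaseEstimator, TransformerMixin):
    """First principal component of the L5 feature space ("thick-tuftedness").

    The PC1 sign is oriented so scores correlate positively with the soma
    equivalent diameter, making the score deterministic.
    """

    def __init__(self, standardize: bool = True, soma_col: int = 0):
        self.standardize = standardize
        self.soma_col = soma_col

    def fit(self, X, y=None):
        x = features_to_matrix(X)
        if x.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        sd = x.std(axis=0, ddof=1)
        if np.all(sd == 0):
            raise ValueError("zero-variance features")
        self.mean_ = x.mean(axis=0)
        self.scale_ = np.where(sd == 0, 1.0, sd) if self.standardize else np.ones_like(sd)
        z = (x - self.mean_) / self.scale_
        self._pca = PCA(n_components=min(x.shape)).fit(z)
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        scores = self._pca.transform(z)[:, 0]
        corr = np.corrcoef(scores, x[:, self.soma_col])[0, 1]
        self.sign_ = -1.0 if corr < 0 else 1.0
        self.scores_ = self.sign_ * scores
        return self

    def transform(self, X):
        x = features_to_matrix(X)
        z = (x - self.mean_) / self.scale_
        return self.sign_ * self._pca.transform(z)[:, 0]


def cluster_l5(features, **kwargs):
    """Two-cluster L5tt/L5st partition; returns (labels, fitted clusterer)."""
    est = L5SubtypeClusterer(**kwargs).fit(features)
    return est.labels_, est


def thick_tuftedness(features, **kwargs) -> np.ndarray:
    """PC1 score per cell, oriented positive with soma diameter."""
    return ThickTuftednessPCA(**kwargs).fit(features).scores_


# ---------------------------------------------------------------------------
# fit wrappers

def fit_exponential(x, y, offset_bounds=None) -> FitResult:
    est = ExponentialDecayRegressor(offset_bounds=offset_bounds).fit(x, y)
    return FitResult(
        model="exponential_offset",
        params={"a": est.a_, "b": est.b_, "c": est.c_},
        r_squared=est.r_squared_,
        n=est.n_,
    )


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares y = a·x + b with R²."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3:
        raise FitError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise FitError("zero variance in x")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    return FitResult(
        model="linear",
        params={"a": float(res.slope), "b": float(res.intercept)},
        r_squared=_r_squared(y, yhat),
        n=x.size,
    )


def fit_linear_fraction(x, y) -> FitResult:
    est = LinearFractionRegressor().fit(x, y)
    params = dict(est.params_)
    params.update({f"{k}_dnorm": v for k, v in est.params_dnorm_.items()})
    return FitResult(
        model="linear_fraction", params=params, r_squared=est.r_squared_, n=est.n_
    )


def predict_fraction_from_densities(
    x,
    observed_fraction,
    e_fit: FitResult | None = None,
    i_fit: FitResult | None = None,
    e_mean: float | None = None,
    i_mean: float | None = None,
    mode: str = "combined",
):
    """Predict the inhibitory fraction Î/(Î+Ê) from density models.

    ``mode`` selects which density carries the linear model: ``"E_only"``
    (I held at its mean), ``"I_only"`` (E held at its mean) or
    ``"combined"`` (both linear).  Returns (predicted fraction array,
    explained variance of the prediction vs the observed fractions).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(observed_fraction, dtype=float).ravel()

    def _lin(fit):
        return fit.params["a"] * x + fit.params["b"]

    if mode == "E_only":
        if e_fit is None or i_mean is None:
            raise ValueError("E_only mode needs e_fit and i_mean")
        e, i = _lin(e_fit), np.full_like(x, i_mean)
    elif mode == "I_only":
        if i_fit is None or e_mean is None:
            raise ValueError("I_only mode needs i_fit and e_mean")
        e, i = np.full_like(x, e_mean), _lin(i_fit)
    elif mode == "combined":
        if e_fit is None or i_fit is None:
            raise ValueError("combined mode needs both fits")
        e, i = _lin(e_fit), _lin(i_fit)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    den = e + i
    if np.any(den <= 0):
        raise FitError("predicted total density is non-positive")
    pred = i / den
    return pred, _r_squared(y, pred)


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    posthoc: object | None = None


def compare_groups(samples: list[np.ndarray]) -> GroupComparison:
    """Nonparametric group comparison.

    Two groups: Wilcoxon rank-sum.  Three or more: Kruskal-Wallis followed
    by Tukey's honestly-significant-difference post-hoc test.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if len(samples) == 2:
        stat, p = stats.ranksums(samples[0], samples[1])
        return GroupComparison(test="wilcoxon_rank_sum", statistic=float(stat), p_value=float(p))
    stat, p = stats.kruskal(*samples)
    posthoc = stats.tukey_hsd(*samples)
    return GroupComparison(
        test="kruskal_wallis", statistic=float(stat), p_value=float(p), posthoc=posthoc
    )
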