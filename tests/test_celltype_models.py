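"""Layer assignment, L5 subtype models and regression fits."""

import numpy as np
import pytest

from adsyn.celltype_models import (
    ExponentialDecayRegressor,
    FitError,
    L5SubtypeClusterer,
    ThickTuftednessPCA,
    assign_layer,
    cluster_l5,
    compare_groups,
    fit_exponential,
    fit_linear,
    fit_linear_fraction,
    flag_l2mn,
    predict_fraction_from_densities,
    thick_tuftedness,
)
from adsyn.morphometry import MeasurementMissingError
from adsyn.skeleton_io import DatasetMeta
from adsyn.synthetic import GeneratorConfig, generate_l5_features, generate_l5_population

from conftest import chain_annotation, make_chain
from adsyn.morphometry import DendriteAnnotation


class TestAssignLayer:
    def test_interval_lookup(self):
        assert assign_layer(50.0) == "L2"
        assert assign_layer(200.0) == "L3"
        assert assign_layer(500.0) == "L5"

    def test_no_soma_is_deep_layer(self):
        assert assign_layer(None) == "DL"

    def test_boundary_belongs_to_deeper_layer(self):
        assert assign_layer(150.0, (150, 350, 700)) == "L3"
        assert assign_layer(350.0, (150, 350, 700)) == "L5"

    def test_beyond_range_unknown(self):
        assert assign_layer(800.0) == "unknown"

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            assign_layer(10.0, (300, 200, 700))


class TestL2MNFlag:
    def _trunk(self, dx, dy):
        tree = make_chain([(0, 0, 0), (dx, dy, 0)])
        return DendriteAnnotation(
            tree=tree, soma_node=1, main_bifurcation_node=2,
            meta=DatasetMeta(depth_axis=1),
        )

    def test_vertical_trunk_not_marginal(self):
        assert not flag_l2mn(self._trunk(0, -30))

    def test_horizontal_trunk_marginal(self):
        assert flag_l2mn(self._trunk(30, 0))

    def test_45_degrees_below_60_threshold(self):
        assert not flag_l2mn(self._trunk(20, -20), angle_threshold=60)

    def test_degenerate_chord(self):
        with pytest.raises(MeasurementMissingError):
            flag_l2mn(self._trunk(1, -1))


class TestClustering:
    def test_generator_blobs_recovered(self, default_config):
        agreements = []
        for seed in range(20):
            feats, labels = generate_l5_features(default_config, n=18, seed=seed)
            pred, est = cluster_l5(feats)
            agreements.append(np.mean(pred == labels))
        assert np.mean(agreements) >= 0.95

    def test_degenerate_identical_vectors(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1))
        with pytest.raises(ValueError, match="degenerate"):
            L5SubtypeClusterer().fit(x)

    def test_partition_invariant_to_feature_order(self, default_config):
        feats, _ = generate_l5_features(default_config, n=18, seed=3)
        x = np.vstack([f.as_array() for f in feats])
        l1 = L5SubtypeClusterer().fit(x).labels_
        perm = [2, 0, 3, 1]
        l2 = L5SubtypeClusterer(soma_col=perm.index(0)).fit(x[:, perm]).labels_
        assert np.array_equal(l1, l2)

    def test_cosine_selected_on_default_data(self, default_config):
        feats, _ = generate_l5_features(default_config, n=18, seed=0)
        _, est = cluster_l5(feats)
        assert est.metric_ in est.cophenetic_correlations_
        assert max(est.cophenetic_correlations_.values()) == pytest.approx(
            est.cophenetic_correlations_[est.metric_]
        )

    def test_larger_soma_cluster_is_l5tt(self, default_config):
        feats, labels = generate_l5_features(default_config, n=18, seed=1)
        pred, _ = cluster_l5(feats)
        soma = np.array([f.soma_equiv_diameter for f in feats])
        assert soma[pred == "L5tt"].mean() > soma[pred == "L5st"].mean()


class TestThickTuftedness:
    def test_rank_one_recovery(self, rng):
        t = rng.normal(size=30)
        x = np.outer(t, [1.0, -2.0, 0.5, 3.0]) + 5.0
        scores = thick_tuftedness(x, standardize=False)
        assert abs(np.corrcoef(scores, t)[0, 1]) == pytest.approx(1.0)

    def test_orientation_positive_with_soma_diameter(self, rng):
        x = rng.normal(size=(40, 4))
        x[:, 0] = x[:, 0] * 3 + 10
        s1 = thick_tuftedness(x)
        s2 = thick_tuftedness(-x + 20)  # flipped data
        assert np.corrcoef(s1, x[:, 0])[0, 1] > 0
        assert np.corrcoef(s2, (-x + 20)[:, 0])[0, 1] > 0

    def test_explained_variance_matches_eigen_oracle(self, rng):
        x = rng.normal(size=(200, 4)) @ np.diag([3.0, 1.0, 0.5, 0.2])
        est = ThickTuftednessPCA(standardize=False).fit(x)
        z = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(z.T)))[::-1]
        np.testing.assert_allclose(est.explained_variance_, eig, rtol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ThickTuftednessPCA().fit(np.ones((5, 4)))


class TestExponentialFit:
    def test_noiseless_recovery(self):
        x = np.arange(10, 331, 4, dtype=float)
        y = 1.57 * np.exp(-0.047 * x) + 0.1
        res = fit_exponential(x, y)
        assert res.params["a"] == pytest.approx(1.57, rel=1e-4)
        assert res.params["b"] == pytest.approx(-0.047, rel=1e-4)
        assert res.params["c"] == pytest.approx(0.1, rel=1e-4)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        res = fit_exponential([1, 2, 3, 4], [2.0, 2.0, 2.0, 2.0])
        assert res.params["a"] == pytest.approx(0.0)
        assert res.params["c"] == pytest.approx(2.0)
        assert res.r_squared == 0.0

    def test_shuffle_invariance(self, rng):
        x = np.linspace(0, 50, 40)
        y = 0.8 * np.exp(-0.05 * x) + 0.2 + rng.normal(0, 0.02, size=40)
        r1 = fit_exponential(x, y)
        perm = rng.permutation(40)
        r2 = fit_exponential(x[perm], y[perm])
        for k in ("a", "b", "c"):
            assert r1.params[k] == pytest.approx(r2.params[k], rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_exponential([1, 2, 3], [1, 2, 3])


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(-3, 3, 18)
        res = fit_linear(x, 0.44 * x + 1.4)
        assert res.params["a"] == pytest.approx(0.44)
        assert res.params["b"] == pytest.approx(1.4)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_y(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0])
        assert fit_linear(x, y).params["a"] == pytest.approx(0.0)

    def test_normal_equation_oracle(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        res = fit_linear(x, y)
        X = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.params["a"] == pytest.approx(beta[0])
        assert res.params["b"] == pytest.approx(beta[1])

    def test_zero_x_variance(self):
        with pytest.raises(FitError):
            fit_linear([1, 1, 1, 1], [1, 2, 3, 4])


class TestLinearFractionFit:
    def test_noiseless_curve_recovery(self):
        x = np.linspace(-2, 4, 25)
        y = (0.043 * x + 0.13) / (0.58 * x + 1.40)
        res = fit_linear_fraction(x, y)
        p = res.params
        yhat = (p["a"] * x + p["b"]) / (p["c"] * x + p["d"])
        np.testing.assert_allclose(yhat, y, atol=1e-6)
        assert res.r_squared == pytest.approx(1.0)
        # d-normalized parameters are the common-scale representative
        assert p["d_dnorm"] == pytest.approx(1.0)
        assert p["a_dnorm"] == pytest.approx(0.043 / 1.40, rel=1e-3)

    def test_reduces_to_linear_when_denominator_constant(self):
        x = np.linspace(0, 5, 20)
        y = 0.3 * x + 0.7
        res = fit_linear_fraction(x, y)
        lin = fit_linear(x, y)
        yhat = (res.params["a"] * x + res.params["b"]) / (
            res.params["c"] * x + res.params["d"]
        )
        np.testing.assert_allclose(yhat, lin.params["a"] * x + lin.params["b"], atol=1e-6)

    def test_r_squared_scale_invariant(self, rng):
        x = np.linspace(0.5, 4, 20)
        y = (0.1 * x + 0.2) / (0.3 * x + 1.0) + rng.normal(0, 0.01, 20)
        res = fit_linear_fraction(x, y)
        p = res.params
        scaled = (5 * p["a"] * x + 5 * p["b"]) / (5 * p["c"] * x + 5 * p["d"])
        base = (p["a"] * x + p["b"]) / (p["c"] * x + p["d"])
        np.testing.assert_allclose(scaled, base)

    def test_denominator_sign_change_rejected(self):
        # data from a hyperbola with its pole inside the data range: the
        # best fit needs a denominator root there and must be rejected
        x = np.concatenate([np.linspace(0.5, 1.5, 8), np.linspace(2.5, 5, 10)])
        y = 1.0 / (x - 2.0)
        with pytest.raises(FitError):
            fit_linear_fraction(x, y)


class TestFractionPrediction:
    def test_self_consistent_model_explains_everything(self):
        x = np.linspace(-2, 2, 30)
        e = 0.44 * x + 1.4
        i = np.full_like(x, 0.2)
        frac = i / (i + e)
        e_fit = fit_linear(x, e)
        pred, ev = predict_fraction_from_densities(
            x, frac, e_fit=e_fit, i_mean=0.2, mode="E_only"
        )
        np.testing.assert_allclose(pred, frac, atol=1e-10)
        assert ev == pytest.approx(1.0)

    def test_i_only_equals_combined_when_e_constant(self):
        x = np.linspace(-2, 2, 30)
        e = np.full_like(x, 1.4)
        i = 0.05 * x + 0.2
        frac = i / (i + e)
        i_fit, e_fit = fit_linear(x, i), fit_linear(x, e)
        p1, _ = predict_fraction_from_densities(
            x, frac, i_fit=i_fit, e_mean=1.4, mode="I_only"
        )
        p2, _ = predict_fraction_from_densities(
            x, frac, e_fit=e_fit, i_fit=i_fit, mode="combined"
        )
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_mode_ordering_on_generator_population(self, default_config):
        evs = {}
        for mode in ("E_only", "I_only", "combined"):
            vals = []
            for seed in range(10):
                pop = generate_l5_population(default_config, n=18, seed=seed)
                x, frac = pop["pc1"].values, pop["i_fraction"].values
                e_fit = fit_linear(x, pop["e_density"])
                i_fit = fit_linear(x, pop["i_density"])
                _, ev = predict_fraction_from_densities(
                    x, frac, e_fit=e_fit, i_fit=i_fit,
                    e_mean=pop["e_density"].mean(), i_mean=pop["i_density"].mean(),
                    mode=mode,
                )
                vals.append(ev)
            evs[mode] = np.mean(vals)
        assert evs["combined"] >= evs["E_only"] - 0.02
        assert evs["E_only"] > evs["I_only"]


class TestCompareGroups:
    def test_identical_groups(self, rng):
        g = rng.normal(size=30)
        res = compare_groups([g, g.copy()])
        assert res.p_value > 0.9

    def test_fully_separated_groups(self):
        res = compare_groups([np.arange(20.0), np.arange(100.0, 120.0)])
        assert res.p_value < 1e-4

    def test_three_groups_kruskal_with_posthoc(self, rng):
        gs = [rng.normal(loc=m, size=15) for m in (0, 0, 3)]
        res = compare_groups(gs)
        assert res.test == "kruskal_wallis"
        assert res.p_value < 0.01
        assert res.posthoc is not None

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a, b = rng.normal(size=20), rng.normal(size=20)
            if compare_groups([a, b]).p_value < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.035

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([np.array([]), np.array([1.0])])
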