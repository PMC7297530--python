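"""Axon identity, target preference, multiplicity and bootstrap testing."""

import numpy as np
import pandas as pd
import pytest

from adsyn.axon_analysis import (
    AxonAnnotation,
    OutputSynapse,
    TARGET_CATEGORIES,
    axons_from_table,
    axons_to_table,
    binarized_preference,
    bootstrap_specificity_test,
    classify_axon,
    conditional_matrix,
    correct_density,
    excitatory_fraction_per_structure,
    innervation_profile,
    multiplicity_stats,
    prediction_accuracy,
    region_consistency,
    spine_fraction,
)
from adsyn.synapse_quant import density_result
from adsyn.synthetic import GeneratorConfig, generate_identity_axons

from conftest import add_synapses, chain_annotation


def axon(outputs, seed_type="L2", seed_location="shaft", aid=1, region="S1"):
    return AxonAnnotation(id=aid, seed_type=seed_type, seed_location=seed_location,
                          outputs=outputs, region=region)


def out(cat, target=None, ss=False):
    return OutputSynapse(category=cat, target_ad=target, single_spine=ss)


class TestIdentity:
    def test_spine_fraction_examples(self):
        a = axon([out("single_spine", ss=True)] * 9 + [out("other_shaft")])
        assert spine_fraction(a) == pytest.approx(0.9)
        b = axon([out("other_shaft")] * 7)
        assert spine_fraction(b) == 0.0

    def test_spine_fraction_brute_force(self, rng):
        flags = rng.random(25) < 0.4
        a = axon([out("single_spine", ss=bool(f)) if f else out("soma") for f in flags])
        assert spine_fraction(a) == pytest.approx(flags.mean())

    def test_classification_thresholds(self):
        assert classify_axon(0.9) == "excitatory"
        assert classify_axon(0.1) == "putative_inhibitory"
        # strict majority required: exactly 50% stays putative inhibitory
        assert classify_axon(0.5) == "putative_inhibitory"

    def test_excitatory_fraction_table(self):
        axons = []
        for i in range(5):
            ss = i < 3  # 3 of 5 shaft-seeded axons excitatory
            axons.append(
                axon([out("single_spine", ss=ss)] * 10, aid=i)
            )
        tab = excitatory_fraction_per_structure(axons)
        assert tab.loc[0, "f_exc"] == pytest.approx(0.6)

    def test_mixing_rate_recovery(self):
        cfg = GeneratorConfig()
        axons, truth = generate_identity_axons(
            cfg, {("L5st", "shaft", "L1"): 200}, seed=11
        )
        tab = excitatory_fraction_per_structure(axons)
        f = tab.loc[0, "f_exc"]
        p = cfg.shaft_exc_mixing[("L5st", "L1")]
        se = np.sqrt(p * (1 - p) / 200)
        assert abs(f - p) < 3 * se

    def test_prediction_accuracy_perfect_and_planted(self):
        inh = [axon([out("other_shaft")] * 8, aid=i) for i in range(6)]
        assert prediction_accuracy(inh)["accuracy"].iloc[0] == 1.0
        mixed = inh + [axon([out("single_spine", ss=True)] * 8, aid=10 + i)
                       for i in range(6)]
        assert prediction_accuracy(mixed)["accuracy"].iloc[0] == pytest.approx(0.5)


class TestCorrection:
    def _raw(self):
        ad = chain_annotation(21)
        add_synapses(ad, [(i, "shaft") for i in range(2, 12)])
        return density_result(ad)

    def test_zero_fraction_is_identity(self):
        raw = self._raw()
        cor = correct_density(raw, 0.0)
        assert cor.n_inh == raw.n_inh and cor.n_exc == raw.n_exc
        assert cor.corrected

    def test_sixty_percent_reassignment(self):
        cor = correct_density(self._raw(), 0.6)
        assert cor.n_inh == pytest.approx(4.0)
        assert cor.n_exc == pytest.approx(6.0)
        assert cor.inh_fraction == pytest.approx(0.4)

    def test_matches_per_synapse_reclassification_in_expectation(self, rng):
        f = 0.44
        raws = self._raw()
        sims = []
        for _ in range(3000):
            reassigned = rng.binomial(raws.n_shaft, f)
            sims.append((raws.n_inh - reassigned) / raws.n_total)
        cor = correct_density(raws, f)
        assert cor.inh_fraction == pytest.approx(np.mean(sims), abs=0.01)

    def test_double_correction_rejected(self):
        cor = correct_density(self._raw(), 0.2)
        with pytest.raises(ValueError):
            correct_density(cor, 0.2)


class TestProfiles:
    def test_profile_fractions(self):
        a = axon([out("L2_AD", 1)] * 2 + [out("soma")] * 8)
        prof = innervation_profile(a)
        assert prof.fractions["L2_AD"] == pytest.approx(0.2)
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_all_glia(self):
        prof = innervation_profile(axon([out("glia")] * 4))
        assert prof.fractions["glia"] == 1.0

    def test_fractions_sum_to_one_random(self, rng):
        cats = list(TARGET_CATEGORIES)
        a = axon([out(cats[i]) for i in rng.integers(0, 8, size=37)])
        assert sum(innervation_profile(a).fractions.values()) == pytest.approx(1.0)

    def test_conditional_matrix_single_axon(self):
        outs = [out("L2_AD", 1)] * 1 + [out("DL_AD", 70)] * 3 + [out("soma")] * 6
        cm = conditional_matrix([innervation_profile(axon(outs))])
        row = cm.loc["L2"]
        assert row["p_L2_AD"] == pytest.approx(0.1)
        assert row["p_DL_AD"] == pytest.approx(0.3)
        assert row["p_L2_AD_restricted"] == pytest.approx(0.25)
        assert row["p_DL_AD_restricted"] == pytest.approx(0.75)

    def test_identical_axons_mean_equals_individual(self):
        outs = [out("L2_AD", 1)] * 2 + [out("soma")] * 8
        profs = [innervation_profile(axon(outs, aid=i)) for i in range(5)]
        cm = conditional_matrix(profs)
        assert cm.loc["L2", "p_L2_AD"] == pytest.approx(0.2)


class TestMultiplicity:
    def test_example_counts(self):
        a = axon([out("L2_AD", 1), out("L2_AD", 1), out("L2_AD", 2)])
        tab = multiplicity_stats([a])
        assert tab.loc["L2", "mean_syn_per_target"] == pytest.approx(1.5)
        assert tab.loc["L2", "frac_monosynaptic"] == pytest.approx(0.5)

    def test_all_single_hits(self):
        a = axon([out("DL_AD", i) for i in range(5)])
        tab = multiplicity_stats([a])
        assert tab.loc["L2", "mean_syn_per_target"] == 1.0
        assert tab.loc["L2", "frac_monosynaptic"] == 1.0

    def test_axons_without_ad_targets_excluded(self):
        a = axon([out("soma")] * 5)
        assert multiplicity_stats([a]).empty

    def test_matches_groupby_oracle(self, rng):
        axons = []
        for i in range(20):
            targets = rng.integers(0, 6, size=rng.integers(1, 10))
            axons.append(axon([out("L2_AD", int(t)) for t in targets], aid=i))
        tab = multiplicity_stats(axons)
        means, n_conn, n_mono = [], 0, 0
        for a in axons:
            s = pd.Series([o.target_ad for o in a.outputs]).value_counts()
            means.append(s.mean())
            n_conn += len(s)
            n_mono += (s == 1).sum()
        assert tab.loc["L2", "mean_syn_per_target"] == pytest.approx(np.mean(means))
        assert tab.loc["L2", "frac_monosynaptic"] == pytest.approx(n_mono / n_conn)

    def test_binarized_preference(self):
        ad_types = {1: "L2", 2: "DL"}
        a = axon([out("L2_AD", 1), out("L2_AD", 1), out("DL_AD", 2)])
        tab = binarized_preference([a], ad_types)
        assert tab.loc["L2", "p_L2_target"] == pytest.approx(0.5)
        b = axon([out("L2_AD", 1)] * 4)
        tab = binarized_preference([b], ad_types)
        assert tab.loc["L2", "p_L2_target"] == 1.0

    def test_binarized_equals_conditional_when_monosynaptic(self, rng):
        ad_types = {i: ("L2" if i < 50 else "DL") for i in range(100)}
        axons = []
        for i in range(10):
            ids = rng.choice(100, size=6, replace=False)
            axons.append(axon([out("L2_AD" if t < 50 else "DL_AD", int(t))
                               for t in ids], aid=i))
        cm = conditional_matrix([innervation_profile(a) for a in axons])
        bp = binarized_preference(axons, ad_types)
        assert bp.loc["L2", "p_L2_target"] == pytest.approx(
            cm.loc["L2", "p_L2_AD_restricted"]
        )


class TestBootstrapSpecificity:
    def test_identical_groups_not_significant(self, rng):
        g = rng.random((15, 8))
        res = bootstrap_specificity_test(g, g.copy(), n_boot=2000, seed=0)
        assert np.all(res.p_values > 0.9)
        assert not res.significant.any()

    def test_disjoint_supports_extreme(self, rng):
        a = rng.uniform(0.8, 1.0, size=(20, 1))
        b = rng.uniform(0.0, 0.2, size=(20, 1))
        res = bootstrap_specificity_test(a, b, n_boot=5000, seed=0)
        assert res.p_values[0] <= 1 / 5000
        assert res.significant[0]

    def test_relabeling_invariance(self, rng):
        a, b = rng.random((12, 8)), rng.random((10, 8))
        perm = rng.permutation(8)
        r1 = bootstrap_specificity_test(a, b, n_boot=1000, seed=5)
        r2 = bootstrap_specificity_test(a[:, perm], b[:, perm], n_boot=1000, seed=5)
        np.testing.assert_allclose(r1.p_values[perm], r2.p_values)

    def test_common_scaling_invariance(self, rng):
        a, b = rng.random((12, 4)), rng.random((10, 4))
        r1 = bootstrap_specificity_test(a, b, n_boot=1000, seed=5)
        r2 = bootstrap_specificity_test(3 * a, 3 * b, n_boot=1000, seed=5)
        np.testing.assert_allclose(r1.p_values, r2.p_values)

    def test_plus_one_convention_exposed(self, rng):
        a, b = rng.random((8, 2)), rng.random((8, 2))
        res = bootstrap_specificity_test(a, b, n_boot=1000, seed=3)
        np.testing.assert_allclose(
            res.p_values_plus_one, (res.p_values * 1000 + 1) / 1001
        )


class TestRegionConsistency:
    def _profiles(self, region_means, n_per_region=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        profs = []
        aid = 0
        for region, mean in region_means.items():
            for _ in range(n_per_region):
                aid += 1
                f = np.clip(mean + rng.normal(0, noise, size=8), 1e-6, None)
                f = f / f.sum()
                a = axon([out("soma")], aid=aid, region=region)
                p = innervation_profile(a)
                p.fractions = dict(zip(TARGET_CATEGORIES, f))
                p.region = region
                profs.append(p)
        return profs

    def test_identical_region_means_zero_cv(self):
        mean = np.full(8, 1 / 8)
        profs = self._profiles({r: mean for r in ["S1", "V2", "PPC", "ACC"]})
        res = region_consistency(profs)
        cvs = res.cv_table["cv_percent"].dropna()
        np.testing.assert_allclose(cvs, 0.0, atol=1e-10)

    def test_cv_formula_oracle(self):
        # region means of one category: {1,1,1,3} scaled into fractions
        means = {r: np.full(8, 1 / 8) for r in ["S1", "V2", "PPC", "ACC"]}
        vals = {"S1": 0.05, "V2": 0.05, "PPC": 0.05, "ACC": 0.15}
        for r, v in vals.items():
            m = means[r].copy()
            m[0] = v
            m[1] = 0.25 - v
            means[r] = m
        res = region_consistency(self._profiles(means))
        row = res.cv_table.query("seed_type == 'L2' and category == 'L2_AD'")
        arr = np.array([0.05, 0.05, 0.05, 0.15])
        expected = arr.std(ddof=1) / arr.mean() * 100
        assert row["cv_percent"].iloc[0] == pytest.approx(expected)

    def test_omnibus_null_rejection_rate(self):
        """Type-I error of the omnibus multivariate test near nominal."""
        mean = np.full(8, 1 / 8)
        rejections = 0
        reps = 100
        for rep in range(reps):
            profs = self._profiles(
                {r: mean for r in ["S1", "V2", "PPC", "ACC"]},
                n_per_region=10, noise=0.02, seed=rep,
            )
            res = region_consistency(profs)
            p = res.omnibus.query("seed_type == 'L2'")["p_value"].iloc[0]
            rejections += p < 0.05
        assert rejections / reps < 0.15

    def test_fewer_than_two_regions_rejected(self):
        profs = self._profiles({"S1": np.full(8, 1 / 8)})
        with pytest.raises(ValueError):
            region_consistency(profs)


class TestTableIO:
    def test_round_trip(self, rng):
        axons = [
            axon([out("L2_AD", 3), out("soma"), out("single_spine", ss=True)],
                 aid=1, region="S1"),
            axon([out("DL_AD", 70)] * 2, seed_type="DL", aid=2, region="V2"),
        ]
        df = axons_to_table(axons)
        back = axons_from_table(df)
        assert len(back) == 2
        a0 = back[0]
        assert a0.seed_type == "L2" and a0.region == "S1"
        assert [o.category for o in a0.outputs] == ["L2_AD", "soma", "single_spine"]
        assert a0.outputs[0].target_ad == 3
        assert a0.outputs[2].single_spine
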