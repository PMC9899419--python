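import numpy as np
import pandas as pd
import pytest

from grainfill import trends
from grainfill.design import DEFAULT_IONOME_DESIGN, StudyDesign
from grainfill.exceptions import ValidationError
from grainfill.kinetics import fit_logistic, logistic
from grainfill.simulate import (
    DEFAULT_PANEL,
    ElementArchetype,
    ProfilePlant,
    random_archetype,
    simulate_expression,
    simulate_grain_series,
    simulate_panel,
    simulate_tissue_budget,
)


class TestGrainSeries:
    def test_noise_free_values_on_the_curve(self, mid_archetype):
        s = simulate_grain_series(mid_archetype, seed=0)
        expected = logistic(s.daf.astype(float), 25.0, 0.25, 13.0)
        np.testing.assert_allclose(s.value, expected, rtol=1e-12)
        # half the asymptote exactly at the inflection
        at_xc = s.value[s.daf == 13]
        np.testing.assert_allclose(at_xc, 12.5, rtol=1e-12)

    def test_early_archetype_concave_past_inflection(self):
        arch = ElementArchetype("K", "early", a=10.0, k=0.4, x_c=2.0,
                                noise_cv=0.0)
        s = simulate_grain_series(arch, seed=0)
        means = s.replicate_means().to_numpy()
        assert np.all(np.diff(means) >= 0)
        rates = np.diff(means) / np.diff(s.times.astype(float))
        assert np.all(np.diff(rates) < 0)  # concave: slowing growth

    def test_negative_cv_rejected(self):
        with pytest.raises(ValidationError):
            ElementArchetype("X", "mid", a=1.0, k=0.1, x_c=13.0,
                             noise_cv=-0.1)

    def test_label_window_consistency_enforced(self):
        arch = ElementArchetype("X", "early", a=1.0, k=0.1, x_c=13.0)
        with pytest.raises(ValidationError):
            simulate_grain_series(arch, DEFAULT_IONOME_DESIGN, seed=0)

    def test_monte_carlo_noise_cv(self):
        """Sample CV of the lognormal replicate noise approximates the target."""
        design = StudyDesign(time_points=(5, 9, 13, 17), replicates=1000)
        arch = ElementArchetype("X", "mid", a=25.0, k=0.25, x_c=13.0,
                                noise_cv=0.05)
        s = simulate_grain_series(arch, design, seed=123)
        vals = s.value[s.daf == 13]
        cv = vals.std(ddof=1) / vals.mean()
        assert cv == pytest.approx(0.05, rel=0.10)

    def test_seed_determinism(self):
        a = simulate_panel(seed=17)
        b = simulate_panel(seed=17)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.value, s2.value)

    def test_default_panel_composition(self):
        labels = [a.label for a in DEFAULT_PANEL]
        assert labels.count("early") == 4
        assert labels.count("mid") == 9
        assert labels.count("sustained") == 1

    def test_random_archetype_respects_window(self):
        rng = np.random.default_rng(0)
        for label in ("early", "mid", "sustained"):
            arch = random_archetype(label, rng)
            arch.validate_against(DEFAULT_IONOME_DESIGN)


class TestBudgetSimulation:
    def test_sink_tissue_content_increases(self):
        tissues = simulate_tissue_budget("Mn", -0.15, 0.02, noise_cv=0.0)
        leaf = tissues["flag_leaf"].replicate_means()
        assert leaf.iloc[-1] > leaf.iloc[0]

    def test_noise_free_fit_recovers_truth(self):
        tissues = simulate_tissue_budget("K", 0.185, 0.05, noise_cv=0.0)
        res = fit_logistic(tissues["grain"])
        meta = tissues["grain"].metadata
        np.testing.assert_allclose(
            res.params,
            [meta["truth_a"], meta["truth_k"], meta["truth_x_c"]],
            rtol=1e-6,
        )


class TestExpressionSimulation:
    def test_noise_off_ratios_match_planted_shapes(self):
        plant = ProfilePlant(genes_per_shape=3, n_null=2, noise_cv=0.0,
                             baseline_fpkm=(100.0, 100.0))
        m, truth = simulate_expression(plant, seed=0)
        ratios = m.log2_ratios(eps=1e-9)
        for gene, row in truth.iterrows():
            if row["shape"] == "null":
                np.testing.assert_allclose(ratios.loc[gene], 0.0, atol=1e-9)
            else:
                shape = np.array([int(v) for v in row["shape"].split()])
                np.testing.assert_allclose(ratios.loc[gene], shape, atol=1e-6)

    def test_filter_matches_planted_magnitudes(self):
        """Noise off: exactly the genes whose planted shape moves at least
        the threshold amount pass the log2-ratio filter; flat genes do not.
        (A pseudo-count keeps noise-free ratios strictly below the planted
        magnitude, so the threshold sits clear of the shape values.)"""
        plant = ProfilePlant(
            shapes=((0, -1, -2, -3, -4), (0, 0, 1, 0, 0), (0, 0, 0, 0, 0)),
            genes_per_shape=10, n_null=0, noise_cv=0.0,
            baseline_fpkm=(100.0, 100.0),
        )
        m, truth = simulate_expression(plant, seed=0)
        kept, _ = trends.log2_ratio_filter(m, threshold=0.5, eps=1e-9)
        expected = truth.index[truth["shape_index"].isin([0, 1])]
        assert set(kept) == set(expected)

    def test_planted_membership_recovery_at_default_noise(self):
        """>= 95% of planted genes are assigned to the selected profile that
        best matches their planted shape."""
        plant = ProfilePlant()  # default noise
        m, truth = simulate_expression(plant, seed=20)
        kept, ratios = trends.log2_ratio_filter(m)
        profiles = trends.select_model_profiles(
            trends.generate_candidate_profiles(5, 2), 20
        )
        asg = trends.assign_genes(ratios.loc[kept], profiles)
        # ground truth: noise-free assignment of each planted shape
        shape_map = {}
        for si, shape in enumerate(plant.shapes):
            ideal = pd.DataFrame([np.array(shape, dtype=float)], index=["s"])
            shape_map[si] = trends.assign_genes(ideal, profiles).assignments[
                "profile"
            ].iloc[0]
        planted = truth[truth["shape_index"] >= 0]
        scored = planted.index.intersection(asg.assignments.index)
        correct = sum(
            asg.assignments.loc[g, "profile"]
            == shape_map[planted.loc[g, "shape_index"]]
            for g in scored
        )
        assert len(scored) >= 0.95 * len(planted)
        assert correct >= 0.95 * len(planted)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValidationError):
            ProfilePlant(genes_per_shape=0, n_null=0)

    def test_shape_length_must_match_design(self):
        plant = ProfilePlant(shapes=((0, 1, 2),))
        with pytest.raises(ValidationError):
            simulate_expression(plant, seed=0)

    def test_seed_determinism(self):
        m1, t1 = simulate_expression(ProfilePlant(genes_per_shape=5, n_null=2),
                                     seed=3)
        m2, t2 = simulate_expression(ProfilePlant(genes_per_shape=5, n_null=2),
                                     seed=3)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)
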