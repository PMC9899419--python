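import itertools

import numpy as np
import pandas as pd
import pytest

from grainfill import trends
from grainfill.exceptions import ValidationError
from grainfill.simulate import ProfilePlant, simulate_expression


def matrix_from(values, dafs, reps):
    cols = [f"{d}DAF_r{r}" for d in dafs for r in range(1, reps + 1)]
    samples = pd.DataFrame(
        {"daf": [d for d in dafs for _ in range(reps)],
         "replicate": list(range(1, reps + 1)) * len(dafs)},
        index=pd.Index(cols, name="sample"),
    )
    df = pd.DataFrame(values, columns=cols)
    df.index = [f"g{i}" for i in range(len(df))]
    return trends.ExpressionMatrix(df, samples)


class TestFpkm:
    def test_plug_in_value(self):
        counts = pd.DataFrame({"5DAF_r1": [100], "9DAF_r1": [0]},
                              index=["g1"])
        em = trends.fpkm_normalize(
            counts,
            lengths=pd.Series({"g1": 1000}),
            library_sizes=pd.Series({"5DAF_r1": 1e7, "9DAF_r1": 1e7}),
        )
        assert em.values.loc["g1", "5DAF_r1"] == pytest.approx(10.0)
        assert em.values.loc["g1", "9DAF_r1"] == 0.0

    def test_depth_scale_invariance(self):
        counts = pd.DataFrame({"5DAF_r1": [100, 7], "9DAF_r1": [3, 50]},
                              index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2500})
        lib = pd.Series({"5DAF_r1": 1e7, "9DAF_r1": 2e7})
        a = trends.fpkm_normalize(counts, lengths, lib)
        b = trends.fpkm_normalize(counts * 2, lengths, lib * 2)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"5DAF_r1": [1]}, index=["g1"])
        with pytest.raises(ValidationError):
            trends.fpkm_normalize(counts, pd.Series({"g1": 100}),
                                  pd.Series({"5DAF_r1": 0}))


class TestRatios:
    def test_first_stage_column_is_zero(self):
        m, _ = simulate_expression(ProfilePlant(genes_per_shape=10, n_null=5),
                                   seed=0)
        ratios = m.log2_ratios()
        assert (ratios.iloc[:, 0] == 0).all()

    def test_flat_gene_filtered_and_boundary_gene_kept(self):
        # g0 flat; g1 exactly doubles (with eps=1): (19+1)/(9+1) = 2
        em = matrix_from([[5.0, 5.0], [9.0, 19.0]], dafs=[5, 9], reps=1)
        kept, ratios = trends.log2_ratio_filter(em, threshold=1.0)
        assert list(kept) == ["g1"]
        assert ratios.loc["g1"].iloc[1] == pytest.approx(1.0)
        assert (ratios.loc["g0"] == 0).all()

    def test_filter_monotone_in_threshold(self):
        m, _ = simulate_expression(ProfilePlant(), seed=2)
        sizes = [
            len(trends.log2_ratio_filter(m, threshold=t)[0])
            for t in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCandidateProfiles:
    @pytest.mark.parametrize("T,c,expected", [(3, 1, 8), (5, 1, 80),
                                              (2, 1, 2), (5, 2, 624)])
    def test_counts_match_enumeration(self, T, c, expected):
        cand = trends.generate_candidate_profiles(T, c)
        assert len(cand) == expected == (2 * c + 1) ** (T - 1) - 1

    def test_structure(self):
        cand = trends.generate_candidate_profiles(5, 2)
        assert (cand[:, 0] == 0).all()
        steps = np.diff(cand, axis=1)
        assert np.abs(steps).max() <= 2
        assert not np.any((cand == 0).all(axis=1))  # flat profile excluded

    def test_T2_candidates(self):
        cand = trends.generate_candidate_profiles(2, 1)
        assert cand.tolist() == [[0, -1], [0, 1]]


class TestSelection:
    def test_select_all_when_m_equals_count(self):
        cand = trends.generate_candidate_profiles(3, 1)
        sel = trends.select_model_profiles(cand, len(cand))
        assert sel.tolist() == sorted(cand.tolist())

    def test_seed_pair_is_max_distance_brute_force(self):
        cand = trends.generate_candidate_profiles(3, 1)
        sel = trends.select_model_profiles(cand, 2)
        # brute force best pair distance
        d = trends._profile_distance_matrix(cand)
        best = max(
            d[i, j] for i, j in itertools.combinations(range(len(cand)), 2)
        )
        i = cand.tolist().index(sel[0].tolist())
        j = cand.tolist().index(sel[1].tolist())
        assert d[i, j] == pytest.approx(best)
        # the maximally anticorrelated pair is a decreasing + increasing profile
        shapes = {tuple(s) for s in sel.tolist()}
        assert any(all(np.diff(s) < 0) for s in shapes)
        assert any(all(np.diff(s) > 0) for s in shapes)

    def test_greedy_beats_random_subsets(self):
        cand = trends.generate_candidate_profiles(5, 2)
        sel = trends.select_model_profiles(cand, 20)
        d_sel = trends._profile_distance_matrix(sel)
        np.fill_diagonal(d_sel, np.inf)
        greedy_mindist = d_sel.min()
        rng = np.random.default_rng(0)
        for _ in range(1000):
            idx = rng.choice(len(cand), size=20, replace=False)
            d = trends._profile_distance_matrix(cand[idx])
            np.fill_diagonal(d, np.inf)
            assert d.min() <= greedy_mindist + 1e-12

    def test_m_too_large(self):
        cand = trends.generate_candidate_profiles(2, 1)
        with pytest.raises(ValidationError):
            trends.select_model_profiles(cand, 3)


@pytest.fixture(scope="module")
def selected_profiles():
    return trends.select_model_profiles(
        trends.generate_candidate_profiles(5, 2), 20
    )


class TestAssignment:
    def test_exact_profile_match_has_zero_distance(self, selected_profiles):
        ratios = pd.DataFrame([selected_profiles[4].astype(float)],
                              index=["g0"])
        asg = trends.assign_genes(ratios, selected_profiles)
        assert asg.assignments.loc["g0", "profile"] == 4
        assert asg.assignments.loc["g0", "distance"] == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_sign_flip_moves_to_anticorrelated_profile(self, selected_profiles):
        """A gene that is -1 x a profile lands on a perfectly anticorrelated
        counterpart (correlation -1 with the original profile)."""
        p = selected_profiles[0]
        ratios = pd.DataFrame([-p.astype(float)], index=["g0"])
        asg = trends.assign_genes(ratios, selected_profiles)
        got = selected_profiles[asg.assignments.loc["g0", "profile"]]
        assert np.corrcoef(got, p)[0, 1] == pytest.approx(-1.0)
        assert asg.assignments.loc["g0", "distance"] == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_matches_brute_force_oracle(self, selected_profiles):
        """Vectorized assignment equals per-gene argmax of np.corrcoef."""
        rng = np.random.default_rng(42)
        ratios = pd.DataFrame(rng.normal(size=(200, 5)),
                              index=[f"g{i}" for i in range(200)])
        ratios.iloc[:, 0] = 0.0
        asg = trends.assign_genes(ratios, selected_profiles)
        for gene, row in asg.assignments.iterrows():
            cors = [
                np.corrcoef(ratios.loc[gene], p)[0, 1]
                for p in selected_profiles
            ]
            assert int(np.argmax(cors)) == row["profile"]

    def test_constant_gene_excluded_with_warning(self, selected_profiles):
        ratios = pd.DataFrame(
            [[0.0, 1.0, 2.0, 1.0, 0.0], [0.0, 0.0, 0.0, 0.0, 0.0]],
            index=["g0", "gflat"],
        )
        with pytest.warns(UserWarning, match="constant"):
            asg = trends.assign_genes(ratios, selected_profiles)
        assert asg.n_excluded == 1
        assert "gflat" not in asg.assignments.index

    def test_empty_input_rejected(self, selected_profiles):
        with pytest.raises(ValidationError):
            trends.assign_genes(pd.DataFrame(columns=range(5)),
                                selected_profiles)


class TestSignificance:
    def test_balanced_two_point_data_has_large_p(self):
        """With T=2, up and down genes in equal numbers, every permutation
        reproduces the observed sizes, so observed == expected and p >= 0.5."""
        profiles = trends.generate_candidate_profiles(2, 1)
        vals = [[0.0, 2.0]] * 10 + [[0.0, -2.0]] * 10
        ratios = pd.DataFrame(vals, index=[f"g{i}" for i in range(20)])
        asg = trends.assign_genes(ratios, profiles)
        sig = trends.profile_significance(asg, ratios, mode="exact")
        np.testing.assert_allclose(sig["expected"], sig["size"])
        assert (sig["pvalue"] >= 0.5).all()

    def test_planted_profile_detected(self, selected_profiles):
        """300 genes planted noise-free on one profile: p below 1e-6."""
        p = selected_profiles[7].astype(float)
        ratios = pd.DataFrame([p] * 300, index=[f"g{i}" for i in range(300)])
        asg = trends.assign_genes(ratios, selected_profiles)
        sig = trends.profile_significance(asg, ratios, mode="exact")
        assert sig.loc[7, "pvalue"] < 1e-6
        assert sig.loc[7, "significant"]

    def test_exact_mode_guard(self, selected_profiles):
        ratios = pd.DataFrame(np.arange(16, dtype=float).reshape(2, 8))
        profiles = trends.generate_candidate_profiles(8, 1)[:4]
        asg = trends.assign_genes(ratios, profiles)
        with pytest.raises(ValidationError, match="sampled"):
            trends.profile_significance(asg, ratios, mode="exact")

    def test_sampled_mode_is_seeded(self, selected_profiles):
        rng = np.random.default_rng(3)
        ratios = pd.DataFrame(rng.normal(size=(50, 5)))
        ratios.iloc[:, 0] = 0.0
        asg = trends.assign_genes(ratios, selected_profiles)
        s1 = trends.profile_significance(asg, ratios, mode="sampled",
                                         n_perm=50, seed=9)
        s2 = trends.profile_significance(asg, ratios, mode="sampled",
                                         n_perm=50, seed=9)
        pd.testing.assert_frame_equal(s1, s2)


class TestPca:
    def test_single_direction_gives_pc1_everything(self):
        base = np.ones(30)
        vals = np.column_stack([base * s for s in (1.0, 2.0, 4.0, 8.0)])
        em = matrix_from(vals, dafs=[5, 9], reps=2)
        _, evr = trends.pca_samples(em)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_fractions_non_increasing(self):
        m, _ = simulate_expression(ProfilePlant(genes_per_shape=20, n_null=10),
                                   seed=5)
        _, evr = trends.pca_samples(m)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_single_sample_rejected(self):
        em = matrix_from(np.ones((3, 1)), dafs=[5], reps=1)
        with pytest.raises(ValidationError):
            trends.pca_samples(em)


class TestClustering:
    def test_zero_variance_rows_dropped(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                          index=["g0", "gflat"])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = trends.zscore_rows(df)
        assert list(z.index) == ["g0"]
        np.testing.assert_allclose(z.to_numpy().mean(axis=1), 0, atol=1e-12)

    def test_identical_rows_merge_first_at_zero_height(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 0.0]],
                          index=["a", "b", "c"])
        Z, _ = trends.hierarchical_cluster(df)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_points_on_line_merge_nearest_first(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        Z, leaves = trends.hierarchical_cluster(df)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_linkage_heights_monotone(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(12, 5)))
        Z, _ = trends.hierarchical_cluster(df)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_rendering_balanced(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        Z, _ = trends.hierarchical_cluster(df)
        nwk = trends.linkage_to_newick(Z, list(df.index))
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 2
        for label in "abc":
            assert label in nwk
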