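"""Correlation, clustering, MDS, UMAP and episignature classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanoepisig as ne
from conftest import make_beta_matrix
from nanoepisig.analysis import (
    balanced_accuracy,
    centroid_classify,
    classical_mds,
    group_silhouette,
    hierarchical_clustering,
    pairwise_platform_correlations,
    pearson_correlation,
    specificity_check,
    svm_loo_validate,
    umap_embed,
)

finite_floats = st.floats(min_value=-10, max_value=10, allow_nan=False)


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_correlation([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == pytest.approx(1.0)

    def test_negated_input_gives_minus_one(self):
        x = np.array([0.1, 0.4, 0.7, 0.2])
        assert pearson_correlation(x, -x + 1.0) == pytest.approx(-1.0)

    def test_frozen_hand_computed_value(self):
        # independent closed-form evaluation: cov=0.27, var_x=0.38, var_y=0.2275
        r = pearson_correlation([0.1, 0.4, 0.9, 0.2], [0.2, 0.5, 0.7, 0.1])
        assert r == pytest.approx(0.9182929821994384, abs=1e-12)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            pearson_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    def test_too_short_input_is_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([0.1, 0.2], [0.3, 0.4])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        x=st.lists(finite_floats, min_size=3, max_size=20),
        a=st.floats(min_value=0.1, max_value=5),
        b=finite_floats,
    )
    def test_affine_invariance_property(self, x, a, b):
        """r is invariant under positive affine maps and flips sign under
        negative slope."""
        x = np.asarray(x)
        # guard against float absorption making a*x+b numerically constant
        if np.ptp(x) < 1e-6 * max(1.0, np.abs(x).max(), abs(b)):
            return
        y = np.linspace(0, 1, len(x)) + np.sin(np.arange(len(x)))
        r = pearson_correlation(x, y)
        assert pearson_correlation(a * x + b, y) == pytest.approx(r, abs=1e-8)
        assert pearson_correlation(-a * x + b, y) == pytest.approx(-r, abs=1e-8)


class TestPairwiseCorrelations:
    def test_identical_columns_give_r_one(self):
        m = make_beta_matrix({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9]})
        (res,) = pairwise_platform_correlations(m, [("a", "b")])
        assert res.r == pytest.approx(1.0)
        assert res.n_probes == 3

    def test_three_pairs_ordered(self):
        rng = np.random.default_rng(0)
        m = make_beta_matrix({s: rng.random(10) for s in "abcd"})
        pairs = [("a", "b"), ("c", "d"), ("a", "d")]
        results = pairwise_platform_correlations(m, pairs)
        assert [(r.sample_a, r.sample_b) for r in results] == pairs

    def test_unknown_sample_is_error(self):
        m = make_beta_matrix({"a": [0.1, 0.5, 0.9], "b": [0.2, 0.4, 0.8]})
        with pytest.raises(KeyError, match="ghost"):
            pairwise_platform_correlations(m, [("a", "ghost")])


def brute_force_complete_linkage(X):
    """Exhaustive complete-linkage reference: O(n^3), greedy minimum of the
    max pairwise distance between clusters."""
    n = X.shape[0]
    dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = max(dist[i, j] for i in a for j in b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a | b, d))
    return merges


class TestHierarchicalClustering:
    def test_two_tight_pairs_merge_first(self):
        m = make_beta_matrix({
            "a1": [0.10, 0.10], "a2": [0.11, 0.10],
            "b1": [0.90, 0.90], "b2": [0.90, 0.91],
        })
        dendro = hierarchical_clustering(m)
        first_two = [frozenset(a | b) for a, b, _ in dendro.merges()[:2]]
        assert {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})} == set(first_two)

    def test_two_samples_single_merge_at_their_distance(self):
        m = make_beta_matrix({"a": [0.1, 0.2], "b": [0.4, 0.6]})
        dendro = hierarchical_clustering(m)
        (merge,) = dendro.merges()
        assert merge[2] == pytest.approx(0.5)

    def test_duplicate_columns_merge_at_zero(self):
        m = make_beta_matrix({"a": [0.3, 0.7], "b": [0.3, 0.7], "c": [0.9, 0.1]})
        dendro = hierarchical_clustering(m)
        a, b, h = dendro.merges()[0]
        assert h == 0.0 and a | b == frozenset({"a", "b"})

    def test_heights_monotone_and_match_brute_force_oracle(self):
        """Merge structure equals the exhaustive reference on random inputs
        with n <= 6."""
        rng = np.random.default_rng(5)
        for trial in range(25):
            n = int(rng.integers(2, 7))
            cols = {f"s{i}": rng.random(4) for i in range(n)}
            m = make_beta_matrix(cols)
            dendro = hierarchical_clustering(m)
            heights = dendro.heights
            assert np.all(np.diff(heights) >= -1e-12)
            X = m.values.to_numpy().T
            expected = brute_force_complete_linkage(X)
            got = [(frozenset(a | b), h) for a, b, h in dendro.merges()]
            name = {f"s{i}": i for i in range(n)}
            got_idx = [(frozenset(name[s] for s in members), h) for members, h in got]
            for (mem_g, h_g), (mem_e, h_e) in zip(got_idx, expected):
                assert mem_g == mem_e
                assert h_g == pytest.approx(h_e, abs=1e-10)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(2)
        m = make_beta_matrix({f"s{i}": rng.random(3) for i in range(5)})
        nwk = hierarchical_clustering(m).to_newick()
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(5))

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            hierarchical_clustering(make_beta_matrix({"a": [0.1, 0.5]}))


class TestClassicalMDS:
    def test_two_points_k1_isometry(self):
        m = make_beta_matrix({"a": [0.1, 0.1], "b": [0.4, 0.5]})
        emb = classical_mds(m, k=1)
        d = abs(emb.coordinates.iloc[0, 0] - emb.coordinates.iloc[1, 0])
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_identical_samples_embed_at_origin(self):
        m = make_beta_matrix({s: [0.3, 0.6, 0.2] for s in "abc"})
        emb = classical_mds(m, k=2)
        assert np.allclose(emb.coordinates.to_numpy(), 0.0, atol=1e-9)

    def test_3_4_5_triangle_distances_recovered(self):
        # points (0.1,0.1), (0.4,0.1), (0.1,0.5): pairwise 0.3, 0.4, 0.5
        m = make_beta_matrix({"a": [0.1, 0.1], "b": [0.4, 0.1], "c": [0.1, 0.5]})
        emb = classical_mds(m, k=2)
        C = emb.coordinates.to_numpy()
        got = {
            ("a", "b"): np.linalg.norm(C[0] - C[1]),
            ("a", "c"): np.linalg.norm(C[0] - C[2]),
            ("b", "c"): np.linalg.norm(C[1] - C[2]),
        }
        want = {("a", "b"): 0.3, ("a", "c"): 0.4, ("b", "c"): 0.5}
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-8)

    def test_planar_point_sets_reproduce_all_distances(self):
        """Points genuinely lying in 2-D are embedded isometrically (1e-8)."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            P = rng.random((n, 2))
            # lift the plane into a higher-dimensional beta space
            lift = np.zeros((n, 5))
            lift[:, :2] = P * 0.5
            m = make_beta_matrix({f"s{i}": lift[i] for i in range(n)})
            emb = classical_mds(m, k=2)
            C = emb.coordinates.to_numpy()
            D_in = np.linalg.norm(lift[:, None] - lift[None, :], axis=2)
            D_out = np.linalg.norm(C[:, None] - C[None, :], axis=2)
            assert np.allclose(D_in, D_out, atol=1e-8)

    def test_axis_sign_convention(self):
        rng = np.random.default_rng(4)
        m = make_beta_matrix({f"s{i}": rng.random(6) for i in range(5)})
        C = classical_mds(m, k=2).coordinates.to_numpy()
        for j in range(2):
            assert C[np.argmax(np.abs(C[:, j])), j] >= 0

    def test_k_beyond_span_is_error(self):
        m = make_beta_matrix({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ValueError):
            classical_mds(m, k=2)


class TestUmap:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        m = make_beta_matrix({f"s{i}": rng.random(30) for i in range(8)})
        a = umap_embed(m, seed=15).coordinates.to_numpy()
        b = umap_embed(m, seed=15).coordinates.to_numpy()
        assert np.array_equal(a, b)

    def test_too_few_samples_points_to_mds(self):
        m = make_beta_matrix({"a": [0.1], "b": [0.2], "c": [0.3]}, probes=["p"])
        with pytest.raises(ValueError, match="classical_mds"):
            umap_embed(m)

    def test_separated_groups_have_positive_silhouette(self, small_cohort):
        ref = small_cohort.reference.subset_probes(list(small_cohort.signature_v2.probe_ids))
        emb = umap_embed(ref, seed=15)
        assert group_silhouette(emb, ref) > 0


class TestCentroidClassify:
    def symmetric_reference(self):
        probes = ["p1", "p2", "p3", "p4"]
        e = np.array([0.01, -0.01, 0.02, -0.02])
        case_c = np.array([0.80, 0.70, 0.75, 0.85])
        ctrl_c = np.array([0.20, 0.10, 0.15, 0.25])
        m = make_beta_matrix(
            {"c1": case_c + e, "c2": case_c - e, "n1": ctrl_c + e, "n2": ctrl_c - e},
            groups={"c1": "case", "c2": "case", "n1": "control", "n2": "control"},
            probes=probes,
        )
        return m, probes, case_c, ctrl_c

    def profile(self, probes, values):
        return ne.BetaProfile("q", "nanopore", "unknown", dict(zip(probes, values)))

    def test_profile_at_case_centroid_scores_one(self):
        ref, probes, case_c, _ = self.symmetric_reference()
        res = centroid_classify(self.profile(probes, case_c), ref, ne.ProbeSet("s", tuple(probes), "v2"))
        assert res.centroid_score == pytest.approx(1.0)
        assert res.label == "positive"

    def test_profile_at_control_centroid_scores_minus_one(self):
        ref, probes, _, ctrl_c = self.symmetric_reference()
        res = centroid_classify(self.profile(probes, ctrl_c), ref, ne.ProbeSet("s", tuple(probes), "v2"))
        assert res.centroid_score == pytest.approx(-1.0)
        assert res.label == "negative"

    def test_midpoint_ties_to_negative(self):
        ref, probes, case_c, ctrl_c = self.symmetric_reference()
        res = centroid_classify(self.profile(probes, (case_c + ctrl_c) / 2), ref,
                                ne.ProbeSet("s", tuple(probes), "v2"))
        assert res.centroid_score == pytest.approx(0.0, abs=1e-12)
        assert res.label == "negative"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=4, max_size=4))
    def test_antisymmetry_under_label_swap(self, values):
        """Swapping the case/control reference labels negates the score."""
        ref, probes, _, _ = self.symmetric_reference()
        swapped = ne.BetaMatrix(
            ref.values, ref.samples.assign(group=ref.samples["group"].map(
                {"case": "control", "control": "case"}))
        )
        pset = ne.ProbeSet("s", tuple(probes), "v2")
        prof = self.profile(probes, values)
        s1 = centroid_classify(prof, ref, pset).centroid_score
        s2 = centroid_classify(prof, swapped, pset).centroid_score
        assert s1 == pytest.approx(-s2, abs=1e-12)

    def test_low_coverage_is_error_listing_missing(self):
        ref, probes, case_c, _ = self.symmetric_reference()
        prof = ne.BetaProfile("q", "nanopore", "unknown", {"p1": 0.5})
        with pytest.raises(ValueError, match="p2"):
            centroid_classify(prof, ref, ne.ProbeSet("s", tuple(probes), "v2"))

    def test_single_label_reference_is_error(self):
        ref, probes, case_c, _ = self.symmetric_reference()
        only_cases = ref.subset_samples(["c1", "c2"])
        with pytest.raises(ValueError, match="case and control"):
            centroid_classify(self.profile(probes, case_c), only_cases,
                              ne.ProbeSet("s", tuple(probes), "v2"))


class TestSvm:
    def separable_matrix(self, n_per_class=10, delta=0.2, seed=0):
        rng = np.random.default_rng(seed)
        probes = [f"p{i}" for i in range(50)]
        mu = rng.uniform(0.2, 0.6, size=50)
        cols, groups = {}, {}
        for i in range(n_per_class):
            cols[f"case{i}"] = np.clip(mu + delta + rng.normal(0, 0.02, 50), 0, 1)
            groups[f"case{i}"] = "case"
            cols[f"ctrl{i}"] = np.clip(mu + rng.normal(0, 0.02, 50), 0, 1)
            groups[f"ctrl{i}"] = "control"
        return make_beta_matrix(cols, groups=groups, probes=probes), ne.ProbeSet("s", tuple(probes), "v2")

    def test_separable_classes_loo_accuracy_one(self):
        matrix, pset = self.separable_matrix()
        table, accuracy = svm_loo_validate(matrix, pset)
        assert accuracy == 1.0
        assert balanced_accuracy(table) == 1.0
        margins = table["svm_margin"]
        assert (margins[table["group"] == "case"] > 0).all()
        assert (margins[table["group"] == "control"] < 0).all()

    def test_deterministic(self):
        matrix, pset = self.separable_matrix()
        t1, _ = svm_loo_validate(matrix, pset)
        t2, _ = svm_loo_validate(matrix, pset)
        pd.testing.assert_frame_equal(t1, t2)

    def test_minimum_class_size_enforced(self):
        rng = np.random.default_rng(1)
        cols = {f"c{i}": rng.random(10) for i in range(2)}
        cols |= {f"n{i}": rng.random(10) for i in range(10)}
        groups = {k: ("case" if k.startswith("c") and not k.startswith("n") else "control")
                  for k in cols}
        m = make_beta_matrix(cols, groups=groups)
        with pytest.raises(ValueError, match=">= 3 samples per class"):
            svm_loo_validate(m, ne.ProbeSet("s", tuple(m.probe_ids), "v2"))


class TestSpecificity:
    def test_target_separates_but_decoy_does_not(self, small_cohort):
        cohort = small_cohort
        ref = cohort.reference
        sig_ids = set(cohort.signature_v2.probe_ids)
        nonsig = [p for p in ref.probe_ids if p not in sig_ids]
        decoy = ne.ProbeSet("decoy", tuple(nonsig[:50]), "v2")
        table = specificity_check(ref, cohort.signature_v2, [decoy])
        assert table.loc[cohort.signature_v2.name, "silhouette"] > 0
        assert table.loc["decoy", "silhouette"] < table.loc[cohort.signature_v2.name, "silhouette"]

    def test_decoy_identical_to_target_warns_but_computes(self, small_cohort):
        cohort = small_cohort
        clone = ne.ProbeSet("clone", cohort.signature_v2.probe_ids, "v2")
        with pytest.warns(UserWarning, match="overlaps target"):
            table = specificity_check(cohort.reference, cohort.signature_v2, [clone])
        assert len(table) == 2
        assert np.isfinite(table["silhouette"]).all()
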