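"""Clustering: endpoint matrices, distance cubes, agglomeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stressplate.cluster import (
    ClusterError,
    DistanceCube,
    cubic_cluster,
    curve_distance_cube,
    endpoint_cluster,
    pairwise_distances,
)


class TestEndpointCluster:
    def test_identical_rows_merge_at_zero(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = endpoint_cluster(m, labels=["a", "b", "c"])
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_three_points_on_a_line(self):
        # 0, 1, 10 with euclidean/complete: first merge {0,1} at 1, then at 10
        m = np.array([[0.0], [1.0], [10.0]])
        res = endpoint_cluster(m, labels=["x0", "x1", "x10"])
        assert res.linkage[0, 2] == pytest.approx(1.0)
        assert res.linkage[1, 2] == pytest.approx(10.0)

    def test_pearson_metric_is_affine_invariant(self):
        r = np.array([1.0, 2.0, 4.0, 8.0])
        d = pairwise_distances(np.vstack([r, 2 * r + 5]), "pearson")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_values_imputed_by_zero(self):
        m = np.array([[np.nan, 1.0], [0.0, 1.0], [9.0, 9.0]])
        res = endpoint_cluster(m, labels=["a", "b", "c"])
        assert res.linkage[0, 2] == pytest.approx(0.0)  # a == b after imputation

    def test_fewer_than_two_entities_rejected(self):
        with pytest.raises(ClusterError):
            endpoint_cluster(np.array([[1.0, 2.0]]), labels=["only"])

    def test_preset_fig6_selects_maximum_complete(self):
        m = np.random.default_rng(0).normal(size=(4, 6))
        res = endpoint_cluster(m, preset="fig6")
        assert res.metric == "maximum" and res.method == "complete"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(6, 4))
        labels = [f"e{i}" for i in range(6)]
        res1 = endpoint_cluster(m, labels=labels)
        perm = rng.permutation(6)
        res2 = endpoint_cluster(m[perm], labels=[labels[i] for i in perm])
        np.testing.assert_allclose(
            np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2]), atol=1e-12
        )
        assert res1.leaf_order == res2.leaf_order


class TestDistanceCube:
    def _curves(self):
        rows = []
        for tr, level in (("a", 0.0), ("b", 1.0)):
            for feat in ("f1", "f2"):
                for tp in range(24):
                    rows.append(
                        {
                            "reporter": "Nrf2",
                            "feature": feat,
                            "treatment": tr,
                            "replicate": 1,
                            "time_h": float(tp),
                            "value": level if feat == "f1" else level * 2,
                        }
                    )
        return pd.DataFrame(rows)

    def test_self_distance_zero_everywhere(self):
        cube = curve_distance_cube(self._curves())
        assert np.all(np.diagonal(cube.stack, axis1=1, axis2=2) == 0.0)
        assert np.all(np.diag(cube.mean_matrix) == 0.0)

    def test_constant_curves_have_closed_form_distance(self):
        # constant curves at 0 and 1 over 24 points: euclidean sqrt(24)
        cube = curve_distance_cube(self._curves())
        i, j = cube.entities.index("a"), cube.entities.index("b")
        f1 = cube.slice_names.index("Nrf2/f1")
        assert cube.stack[f1, i, j] == pytest.approx(np.sqrt(24.0))

    def test_mean_over_slices(self):
        cube = curve_distance_cube(self._curves())
        i, j = cube.entities.index("a"), cube.entities.index("b")
        expected = (np.sqrt(24.0) + 2 * np.sqrt(24.0)) / 2.0
        assert cube.mean_matrix[i, j] == pytest.approx(expected)

    def test_missing_slice_entity_averaged_over_available(self):
        curves = self._curves()
        curves = curves[~((curves["treatment"] == "b") & (curves["feature"] == "f2"))]
        extra = curves[curves["treatment"] == "a"].copy()
        extra["treatment"] = "c"
        extra["value"] += 3.0
        cube = curve_distance_cube(pd.concat([curves, extra]))
        i, j = cube.entities.index("a"), cube.entities.index("b")
        f1 = cube.slice_names.index("Nrf2/f1")
        assert cube.mean_matrix[i, j] == pytest.approx(cube.stack[f1, i, j])

    def test_symmetry_and_nonnegativity_invariants(self):
        rng = np.random.default_rng(0)
        rows = []
        for tr in "abcd":
            for feat in ("f1", "f2", "f3"):
                vals = rng.normal(size=24)
                for tp, v in enumerate(vals):
                    rows.append(
                        {"reporter": "R", "feature": feat, "treatment": tr,
                         "replicate": 1, "time_h": float(tp), "value": v}
                    )
        cube = curve_distance_cube(pd.DataFrame(rows))
        for sl in cube.stack:
            np.testing.assert_allclose(sl, sl.T, atol=1e-12)
            assert np.all(sl >= 0)
        m = cube.mean_matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        # euclidean slices obey the triangle inequality; so does their mean
        n = len(cube.entities)
        for a, b, c in itertools.permutations(range(n), 3):
            assert m[a, c] <= m[a, b] + m[b, c] + 1e-9


class TestCubicCluster:
    def test_two_entities_single_merge_at_distance(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        res, _ = cubic_cluster(d, labels=["a", "b"])
        assert res.linkage.shape == (1, 4)
        assert res.linkage[0, 2] == pytest.approx(3.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ClusterError, match="symmetric"):
            cubic_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_merge_sequence_equals_exhaustive_oracle(self):
        """Complete-linkage merges match brute-force agglomeration on <=6
        entities: at every step the pair of clusters with the smallest
        maximum inter-point distance merges at exactly that height."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.normal(size=(6, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            res, _ = cubic_cluster(d, labels=[str(i) for i in range(6)])
            # brute-force oracle
            clusters = {i: {i} for i in range(6)}
            heights = []
            next_id = 6
            while len(clusters) > 1:
                best = None
                for a, b in itertools.combinations(sorted(clusters), 2):
                    h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                    if best is None or h < best[0]:
                        best = (h, a, b)
                h, a, b = best
                heights.append(h)
                clusters[next_id] = clusters.pop(a) | clusters.pop(b)
                next_id += 1
            np.testing.assert_allclose(res.linkage[:, 2], heights, atol=1e-10)

    def test_heights_nondecreasing_for_complete_linkage(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res, _ = cubic_cluster(d)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_flat_clusters_by_count(self):
        d = np.array(
            [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]], dtype=float
        )
        _, flat = cubic_cluster(d, labels=list("abcd"), n_clusters=2)
        assert flat["a"] == flat["b"] and flat["c"] == flat["d"]
        assert flat["a"] != flat["c"]

    def test_newick_export_contains_all_labels(self):
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        res, _ = cubic_cluster(d, labels=["x", "y", "z"])
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for lab in "xyz":
            assert lab in nwk


class TestPlantedClassRecovery:
    def test_three_dynamic_classes_recovered(self):
        """Planted transient / sustained / null classes, 6 entities each at
        noise_cv 0.1, are recovered by a 3-cluster cut (ARI >= 0.9)."""
        from sklearn.metrics import adjusted_rand_score

        from stressplate.layout import make_layout
        from stressplate.normalize import normalize_curves
        from stressplate.synthetic import (
            DynamicClassSpec,
            PlateEffect,
            generate_feature_curves,
        )

        classes = {
            "transient": DynamicClassSpec("transient_nuclear", 2, 8, 15, 4.0, 0.1),
            "sustained": DynamicClassSpec("sustained_cytosolic", 3, 12, 24, 4.0, 0.1),
            "flat": DynamicClassSpec("null", amplitude=1.0, noise_cv=0.1),
        }
        treatments = {f"{c}_{i}": s for c, s in classes.items() for i in range(6)}
        layout = make_layout("P1", ["Nrf2"], list(treatments), n_replicates=3)
        specs = {**treatments, "DMSO": DynamicClassSpec("null", amplitude=1.0, noise_cv=0.1)}
        curves, _ = generate_feature_curves(layout, specs, {"P1": PlateEffect()}, seed=17)
        norm, _ = normalize_curves(curves)
        cube = curve_distance_cube(norm[norm["treatment"] != "DMSO"])
        _, flat = cubic_cluster(cube, n_clusters=3)
        truth = [t.rsplit("_", 1)[0] for t in flat.index]
        assert adjusted_rand_score(truth, flat.to_numpy()) >= 0.9
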