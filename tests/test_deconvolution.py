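"""Reference preparation, cluster merging, and NNLS recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from maturekit.containers import CellMatrix
from maturekit.deconvolution import (
    ClassModel,
    build_class_model,
    cluster_profiles,
    downsample_clusters,
    merge_clusters,
    nnls_fit,
    two_stage_deconvolve,
)
from maturekit.errors import InvalidArgumentError
from maturekit.synthetic import (
    MixtureTruth,
    generate_bulk_mixture,
    generate_single_cell_reference,
)


def brute_force_nnls(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Active-set oracle: enumerate all support sets, keep the feasible
    least-squares solution with the smallest residual."""
    n = a.shape[1]
    best, best_res = np.zeros(n), float(np.linalg.norm(b))
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sol, *_ = np.linalg.lstsq(a[:, support], b, rcond=None)
            if (sol < -1e-10).any():
                continue
            w = np.zeros(n)
            w[list(support)] = np.clip(sol, 0, None)
            res = float(np.linalg.norm(a @ w - b))
            if res < best_res - 1e-12:
                best, best_res = w, res
    return best


def _cells(sizes: dict[str, int], n_genes: int = 40, seed: int = 0) -> CellMatrix:
    rng = np.random.default_rng(seed)
    ids, labels, rows = [], [], []
    for cluster, n in sizes.items():
        for i in range(n):
            ids.append(f"{cluster}_c{i}")
            labels.append(cluster)
            rows.append(rng.integers(0, 50, size=n_genes))
    counts = pd.DataFrame(rows, index=ids, columns=[f"g{i}" for i in range(n_genes)])
    return CellMatrix(counts, pd.Series(labels, index=ids))


class TestDownsample:
    def test_equal_sizes_pass_through(self):
        cells = _cells({"c1": 5, "c2": 5})
        out = downsample_clusters(cells, seed=1)
        pd.testing.assert_frame_equal(out.counts, cells.counts)

    def test_all_reduced_to_smallest(self):
        out = downsample_clusters(_cells({"c1": 10, "c2": 4, "c3": 7}), seed=1)
        assert set(out.cluster_sizes()) == {4}

    def test_seeded_determinism(self):
        cells = _cells({"c1": 10, "c2": 4})
        a = downsample_clusters(cells, seed=9)
        b = downsample_clusters(cells, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestClusterProfiles:
    def test_single_cell_cluster_equals_cell_log_values(self):
        cells = _cells({"c1": 1, "c2": 1})
        prof = cluster_profiles(cells)
        depths = cells.counts.sum(axis=1)
        expected = np.log1p(
            cells.counts.iloc[0].to_numpy() * depths.median() / depths.iloc[0]
        )
        np.testing.assert_allclose(prof.profiles.iloc[0].to_numpy(), expected)

    def test_matches_brute_force_mean(self):
        cells = downsample_clusters(_cells({"c1": 3, "c2": 3}, seed=5), seed=0)
        prof = cluster_profiles(cells)
        depths = cells.counts.sum(axis=1)
        logs = np.log1p(
            cells.counts.to_numpy(dtype=float)
            * (depths.median() / depths.to_numpy())[:, None]
        )
        mask = (cells.clusters == "c1").to_numpy()
        np.testing.assert_allclose(
            prof.profiles.loc["c1"].to_numpy(), logs[mask].mean(axis=0)
        )

    def test_unbalanced_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cluster_profiles(_cells({"c1": 3, "c2": 5}))


class TestMergeClusters:
    def test_identical_profiles_one_class(self):
        from maturekit.deconvolution import ClusterProfiles

        base = np.random.default_rng(1).uniform(0, 5, size=30)
        prof = ClusterProfiles(
            pd.DataFrame([base, base], index=["c1", "c2"],
                         columns=[f"g{i}" for i in range(30)]),
            cells_used=3,
        )
        model = merge_clusters(prof, corr_threshold=0.8)
        assert model.assignment.nunique() == 1

    def test_threshold_above_max_correlation_keeps_singletons(self):
        from maturekit.deconvolution import ClusterProfiles

        rng = np.random.default_rng(2)
        prof = ClusterProfiles(
            pd.DataFrame(rng.normal(size=(4, 200)),
                         index=[f"c{i}" for i in range(4)],
                         columns=[f"g{i}" for i in range(200)]),
            cells_used=3,
        )
        model = merge_clusters(prof, corr_threshold=0.999)
        assert model.assignment.nunique() == 4

    def test_recovers_generative_classes(self):
        cells, class_truth, _ = generate_single_cell_reference(
            3, 2, [30] * 6, 1500, within_class_corr=0.95, seed=21
        )
        model = build_class_model(cells, seed=3, corr_threshold=0.8)
        # same partition as the generative truth
        got = model.assignment
        for cls in class_truth.unique():
            members = class_truth.index[class_truth == cls]
            assert got[members].nunique() == 1
        assert got.nunique() == 3

    def test_invalid_threshold_rejected(self):
        from maturekit.deconvolution import ClusterProfiles

        prof = ClusterProfiles(
            pd.DataFrame(np.ones((2, 5)), index=["a", "b"]), cells_used=1
        )
        with pytest.raises(InvalidArgumentError):
            merge_clusters(prof, corr_threshold=1.5)


def _model(profiles: np.ndarray) -> ClassModel:
    classes = [f"class{i + 1}" for i in range(profiles.shape[0])]
    frame = pd.DataFrame(profiles, index=classes,
                         columns=[f"g{i}" for i in range(profiles.shape[1])])
    assignment = pd.Series(classes, index=classes)
    return ClassModel(assignment, frame, frame.columns, 0.8)


class TestNnlsFit:
    def test_pure_profile_recovers_unit_proportion(self, rng):
        profiles = rng.uniform(0, 5, size=(4, 50))
        model = _model(profiles)
        res = nnls_fit(pd.Series(profiles[2], index=model.class_profiles.columns), model)
        assert res.proportions["class3"] == pytest.approx(100.0, abs=1e-6)

    def test_zero_bulk_flagged_degenerate(self, rng):
        model = _model(rng.uniform(0, 5, size=(3, 20)))
        res = nnls_fit(pd.Series(0.0, index=model.class_profiles.columns), model)
        assert res.degenerate and (res.proportions == 0).all()

    def test_matches_active_set_oracle_on_many_instances(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            profiles = rng.uniform(0, 5, size=(4, 25))
            w_true = rng.uniform(0, 1, size=4) * rng.integers(0, 2, size=4)
            bulk = w_true @ profiles + rng.normal(0, 0.1, size=25)
            model = _model(profiles)
            res = nnls_fit(pd.Series(bulk, index=model.class_profiles.columns), model)
            oracle = brute_force_nnls(profiles.T, bulk)
            np.testing.assert_allclose(res.weights.to_numpy(), oracle, atol=1e-6)

    def test_scale_equivariance(self, rng):
        profiles = rng.uniform(0, 5, size=(3, 40))
        model = _model(profiles)
        bulk = pd.Series(rng.uniform(0, 5, size=40), index=model.class_profiles.columns)
        r1 = nnls_fit(bulk, model)
        r2 = nnls_fit(bulk * 2.5, model)
        np.testing.assert_allclose(r2.weights, r1.weights * 2.5, rtol=1e-8)
        np.testing.assert_allclose(r2.proportions, r1.proportions, rtol=1e-8)

    def test_permutation_invariance(self, rng):
        profiles = rng.uniform(0, 5, size=(4, 30))
        model = _model(profiles)
        bulk = pd.Series(rng.uniform(0, 5, size=30), index=model.class_profiles.columns)
        perm = [2, 0, 3, 1]
        model_p = _model(profiles[perm])
        r = nnls_fit(bulk, model)
        rp = nnls_fit(bulk, model_p)
        np.testing.assert_allclose(
            rp.weights.to_numpy(), r.weights.to_numpy()[perm], atol=1e-8
        )

    def test_kkt_conditions_hold(self, rng):
        for _ in range(20):
            profiles = rng.uniform(0, 5, size=(4, 30))
            model = _model(profiles)
            bulk = pd.Series(rng.uniform(0, 5, size=30), index=model.class_profiles.columns)
            res = nnls_fit(bulk, model)
            a = profiles.T
            grad = a.T @ (a @ res.weights.to_numpy() - bulk.to_numpy())
            w = res.weights.to_numpy()
            assert (grad[w == 0] >= -1e-6).all()
            np.testing.assert_allclose(grad[w > 0], 0.0, atol=1e-6)

    def test_no_shared_genes_rejected(self, rng):
        model = _model(rng.uniform(0, 5, size=(2, 10)))
        with pytest.raises(InvalidArgumentError):
            nnls_fit(pd.Series([1.0], index=["other"]), model)


@pytest.fixture(scope="module")
def reference():
    return generate_single_cell_reference(
        4, 2, [30] * 8, 1500, within_class_corr=0.95, seed=11,
        cholinergic_classes=[0, 1, 2],
    )


class TestTwoStage:
    def test_all_cholinergic_makes_stages_identical(self):
        cells, _, _ = generate_single_cell_reference(
            2, 2, [20] * 4, 500, within_class_corr=0.95, seed=4,
            cholinergic_classes=[0, 1],
        )
        model = build_class_model(cells, seed=1)
        bulk = generate_bulk_mixture(model.class_profiles, MixtureTruth((0.6, 0.4), 0.0, 5))
        s1, s2, *_ = two_stage_deconvolve(bulk, cells, seed=1)
        pd.testing.assert_series_equal(s1.proportions, s2.proportions)

    def test_purely_cholinergic_bulk_zeroes_other_classes(self, reference):
        cells, class_truth, _ = reference
        model = build_class_model(cells, seed=2)
        # mixture over the classes containing cholinergic clusters only
        chol_classes = sorted(
            model.assignment[cells.cholinergic_clusters()].unique()
        )
        weights = tuple(
            0.5 if c in chol_classes[:1] else (0.5 if c in chol_classes[1:2] else 0.0)
            for c in model.classes
        )
        bulk = generate_bulk_mixture(model.class_profiles, MixtureTruth(weights, 0.01, 6))
        s1, _, model1, _ = two_stage_deconvolve(bulk, cells, seed=2)
        non_chol = [c for c in model1.classes if c not in chol_classes]
        assert s1.proportions[non_chol].max() < 1.0  # < 1% weight

    def test_recovers_cholinergic_proportions(self, reference):
        cells, _, _ = reference
        chol = cells.subset_clusters(cells.cholinergic_clusters())
        model2 = build_class_model(chol, seed=2)
        assert len(model2.classes) == 3
        truth = MixtureTruth((0.76, 0.22, 0.02), 0.01, 8)
        bulk = generate_bulk_mixture(model2.class_profiles, truth)
        _, s2, _, _ = two_stage_deconvolve(bulk, cells, seed=2)
        got = s2.proportions.to_numpy()
        np.testing.assert_allclose(got, [76.0, 22.0, 2.0], atol=3.0)

    def test_no_cholinergic_clusters_raises(self):
        cells, _, _ = generate_single_cell_reference(
            2, 1, [10, 10], 200, seed=3, cholinergic_classes=[],
        )
        model = build_class_model(cells, seed=1)
        bulk = generate_bulk_mixture(model.class_profiles, MixtureTruth((1.0, 0.0), 0.0, 1))
        with pytest.raises(InvalidArgumentError):
            two_stage_deconvolve(bulk, cells, seed=1)
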