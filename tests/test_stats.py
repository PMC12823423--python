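"""Shape PCA, projection, permutation tests, QDA, size descriptors."""

import numpy as np
import pytest

from paleoshape.landmarks import LandmarkSet, gpa
from paleoshape.stats import (nearest_neighbours, pca_shape,
                              permutation_test, project, qda_loocv,
                              select_pcs, size_series,
                              standardize_by_geomean, warp_along_pc)
from paleoshape.synthetic import (SyntheticShapeSpec, gen_landmark_sample,
                                  make_template)


@pytest.fixture
def small_space(rng):
    coords = rng.standard_normal((12, 7, 2)) * 0.05 \
        + rng.standard_normal((7, 2))
    return pca_shape(coords), coords


class TestPCA:
    def test_eigenvalue_sum_is_total_variance(self, small_space):
        space, coords = small_space
        n = len(coords)
        flat = coords.reshape(n, -1)
        total = ((flat - flat.mean(0)) ** 2).sum() / (n - 1)
        assert space.eigenvalues.sum() == pytest.approx(total, abs=1e-9)

    def test_orthonormal_eigenvectors(self, small_space):
        space, _ = small_space
        g = space.eigenvectors.T @ space.eigenvectors
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-9)

    def test_training_shape_roundtrip(self, small_space):
        space, coords = small_space
        rec = space.reconstruct(space.training_scores[3])
        assert np.allclose(rec, coords[3], atol=1e-8)

    def test_scores_match_eigendecomposition_oracle(self, small_space):
        """Oracle route: eigendecomposition of the explicit covariance
        matrix rather than the SVD of the data matrix."""
        space, coords = small_space
        n = len(coords)
        flat = coords.reshape(n, -1)
        x = flat - flat.mean(0)
        cov = x.T @ x / (n - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:space.training_scores.shape[1]]
        w, v = w[order], v[:, order]
        assert np.allclose(w, space.eigenvalues, atol=1e-8)
        s_oracle = x @ v
        for j in range(s_oracle.shape[1]):
            col = s_oracle[:, j]
            got = space.training_scores[:, j]
            assert np.allclose(col, got, atol=1e-8) or \
                np.allclose(col, -got, atol=1e-8)

    def test_single_specimen_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_shape(rng.standard_normal((1, 5, 2)))


class TestProject:
    def test_mean_projects_to_zero(self, small_space):
        space, _ = small_space
        assert np.abs(project(space, space.mean_shape,
                              fit=False)).max() < 1e-10

    def test_basis_case(self, small_space):
        space, _ = small_space
        shape = space.reconstruct(
            np.eye(len(space.eigenvalues))[0] * 2.0)
        s = project(space, shape, fit=False)
        expect = np.zeros(len(space.eigenvalues))
        expect[0] = 2.0
        assert np.allclose(s, expect, atol=1e-9)

    def test_matches_inner_product_oracle(self, small_space, rng):
        space, _ = small_space
        probe = space.mean_shape + 0.03 * rng.standard_normal(
            space.mean_shape.shape)
        got = project(space, probe, fit=False)
        dev = probe.ravel() - space.mean_shape.ravel()
        oracle = np.array([np.dot(dev, space.eigenvectors[:, j])
                           for j in range(space.eigenvectors.shape[1])])
        assert np.allclose(got, oracle, atol=1e-10)

    def test_projection_leaves_space_untouched(self, small_space, rng):
        space, _ = small_space
        before = space.training_scores.copy()
        project(space, space.mean_shape + 0.1 * rng.standard_normal(
            space.mean_shape.shape))
        assert np.array_equal(before, space.training_scores)

    def test_template_mismatch(self, small_space, rng):
        space, _ = small_space
        with pytest.raises(ValueError, match="template"):
            project(space, rng.standard_normal((9, 2)))


class TestNearestNeighbours:
    def test_self_is_rank_one(self, rng):
        specs = [LandmarkSet(f"s{i}", rng.standard_normal((6, 2)))
                 for i in range(8)]
        al = gpa(specs)
        got = nearest_neighbours(al, al.specimens[3], k=3)
        assert got[0][0] == "s3"
        assert got[0][1] == pytest.approx(0.0, abs=1e-10)

    def test_two_cluster_separation(self):
        tpl, mean = make_template("nn", 10, 2)
        spec = SyntheticShapeSpec(
            template=tpl, mean_points=mean, n_per_group=10,
            group_effects={"A": np.zeros_like(mean),
                           "B": np.ones_like(mean)},
            effect_size=0.6, noise_sd=0.02, seed=11)
        sample, truth = gen_landmark_sample(spec)
        al = gpa(sample)
        probe = al.specimens[0]   # an A specimen
        top = nearest_neighbours(al, probe, k=10)
        assert all(name.startswith("A") for name, _d in top)

    def test_k_clamped_with_warning(self, rng):
        specs = [LandmarkSet(f"s{i}", rng.standard_normal((5, 2)))
                 for i in range(4)]
        al = gpa(specs)
        with pytest.warns(UserWarning, match="clamped"):
            got = nearest_neighbours(al, al.specimens[0], k=10)
        assert len(got) == 4


class TestWarp:
    def test_zero_multiple_is_mean(self, small_space):
        space, _ = small_space
        plus, minus = warp_along_pc(space, 0, 0.0)
        assert np.allclose(plus, space.mean_shape, atol=1e-12)
        assert np.allclose(minus, space.mean_shape, atol=1e-12)

    def test_plus_minus_reflect_about_mean(self, small_space):
        space, _ = small_space
        plus, minus = warp_along_pc(space, 1, 2.0)
        assert np.allclose(0.5 * (plus + minus), space.mean_shape,
                           atol=1e-12)

    def test_warp_score_roundtrip(self, small_space):
        space, _ = small_space
        plus, _ = warp_along_pc(space, 0, 2.0)
        s = project(space, plus, fit=False)
        assert s[0] == pytest.approx(2 * np.sqrt(space.eigenvalues[0]),
                                     abs=1e-9)
        assert np.abs(s[1:]).max() < 1e-9

    def test_out_of_range(self, small_space):
        space, _ = small_space
        with pytest.raises(ValueError):
            warp_along_pc(space, 99)


class TestPermutationTest:
    def test_zero_between_variance_gives_p_one(self):
        scores = np.tile(np.array([[1.0, 2.0, 3.0]]), (10, 1))
        labels = ["A"] * 5 + ["B"] * 5
        r = permutation_test(scores, labels, "A", "B", n_perm=200, seed=0)
        assert r.p_value == 1.0

    def test_huge_separation_gives_minimal_p(self, rng):
        scores = rng.standard_normal((20, 3)) * 0.01
        scores[10:] += 20.0
        labels = ["A"] * 10 + ["B"] * 10
        r = permutation_test(scores, labels, "A", "B", n_perm=999, seed=1)
        assert r.p_value == pytest.approx(1 / 1000)

    def test_reproducible_for_seed(self, rng):
        scores = rng.standard_normal((16, 3))
        labels = ["A"] * 8 + ["B"] * 8
        r1 = permutation_test(scores, labels, "A", "B", n_perm=499, seed=7)
        r2 = permutation_test(scores, labels, "A", "B", n_perm=499, seed=7)
        assert r1.p_value == r2.p_value

    def test_small_group_rejected(self, rng):
        scores = rng.standard_normal((4, 3))
        with pytest.raises(ValueError):
            permutation_test(scores, ["A", "A", "A", "B"], "A", "B",
                             n_perm=99, seed=0)


class TestSelectPCs:
    @pytest.mark.parametrize("eigvals,expected_k,expected_cum", [
        ((0.5, 0.25, 0.15, 0.10), 2, 0.75),
        ((0.71, 0.2, 0.09), 1, 0.71),
        (tuple([0.1] * 10), 7, 0.7),
    ])
    def test_examples(self, eigvals, expected_k, expected_cum):
        k, cum, _ = select_pcs(np.array(eigvals))
        assert k == expected_k
        assert cum == pytest.approx(expected_cum, abs=1e-12)

    def test_overshoot_flagged(self):
        k, cum, flagged = select_pcs(np.array([0.95, 0.05]))
        assert k == 1 and flagged

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            select_pcs(np.array([1.0]), lo=0.9, hi=0.7)


def gaussian_posterior_oracle(train, labels, probe, classes):
    """Independent posterior computation from explicit Gaussian densities."""
    dens = []
    for c in classes:
        x = train[labels == c]
        mu = x.mean(axis=0)
        cov = np.cov(x.T, ddof=1)
        cov = np.atleast_2d(cov)
        k = cov.shape[0]
        diff = probe - mu
        quad = diff @ np.linalg.solve(cov, diff)
        dens.append(np.exp(-0.5 * quad)
                    / np.sqrt((2 * np.pi) ** k * np.linalg.det(cov)))
    dens = np.array(dens)
    return dens / dens.sum()


class TestQDA:
    def test_symmetric_midpoint_posteriors(self, rng):
        x = rng.standard_normal((20, 2)) * 0.5
        x = x - x.mean(axis=0)      # exactly symmetric class means
        a = x - [3.0, 0]
        b = x + [3.0, 0]
        scores = np.vstack([a, b])
        labels = ["A"] * 20 + ["B"] * 20
        res = qda_loocv(scores, labels, unknowns=np.array([[0.0, 0.0]]))
        assert np.allclose(res.unknown_posteriors[0], [0.5, 0.5],
                           atol=1e-9)

    def test_posteriors_match_density_oracle(self, rng):
        train = rng.standard_normal((24, 2))
        train[12:] += 1.5
        labels = np.array(["A"] * 12 + ["B"] * 12)
        probe = np.array([0.7, 0.2])
        res = qda_loocv(train, list(labels), unknowns=probe[None])
        oracle = gaussian_posterior_oracle(train, labels, probe,
                                           ["A", "B"])
        assert np.allclose(res.unknown_posteriors[0], oracle, atol=1e-10)

    def test_loocv_never_sees_left_out_case(self, rng):
        """An extreme outlier relabelled into the wrong class must be
        misclassified under LOOCV (a model trained on it would not)."""
        a = rng.standard_normal((15, 2)) * 0.1
        b = rng.standard_normal((15, 2)) * 0.1 + [5.0, 0]
        scores = np.vstack([a, b])
        labels = ["A"] * 15 + ["B"] * 15
        labels[0] = "B"   # an A-cluster point labelled B
        res = qda_loocv(scores, labels)
        assert res.loocv_predictions[0] == "A"

    def test_separated_clusters_high_accuracy(self, rng):
        a = rng.standard_normal((30, 3))
        b = rng.standard_normal((30, 3)) + 6.0
        res = qda_loocv(np.vstack([a, b]), ["A"] * 30 + ["B"] * 30)
        assert res.loocv_accuracy_overall >= 0.95

    def test_posteriors_normalized(self, rng):
        scores = rng.standard_normal((30, 2))
        scores[15:] += 2
        res = qda_loocv(scores, ["A"] * 15 + ["B"] * 15)
        assert np.allclose(res.loocv_posteriors.sum(axis=1), 1.0,
                           atol=1e-12)

    def test_too_small_class_rejected(self, rng):
        scores = rng.standard_normal((8, 3))
        with pytest.raises(ValueError, match="members"):
            qda_loocv(scores, ["A"] * 4 + ["B"] * 4)


class TestSizeDescriptors:
    def test_molar_pattern(self):
        pattern, logs = size_series([("M1", 10.0), ("M2", 12.0),
                                     ("M3", 11.0)])
        assert pattern == "M1<M2>M3"
        assert logs["M1"] == pytest.approx(np.log(10.0))

    def test_equal_within_tolerance(self):
        pattern, _ = size_series([("M1", 10.0), ("M2", 10.0),
                                  ("M3", 10.0)])
        assert pattern == "M1=M2=M3"

    def test_ln_of_e(self):
        _, logs = size_series([("M1", np.e), ("M2", 1.0), ("M3", 1.0)])
        assert logs["M1"] == pytest.approx(1.0, abs=1e-12)

    def test_missing_position_indeterminate(self):
        pattern, _ = size_series([("M1", 10.0), ("M3", 11.0)])
        assert pattern == "indeterminate"

    def test_geomean_standardization(self):
        assert standardize_by_geomean(8.0, [2, 2, 2]) == pytest.approx(2.0)
        # dims (1, 4): geometric mean 2, so area 6 standardizes to 6/4
        assert standardize_by_geomean(6.0, [1, 4]) == pytest.approx(1.5)
        base = standardize_by_geomean(6.0, [1, 4])
        scaled = standardize_by_geomean(6.0 * 2.5 ** 2, [2.5, 10.0])
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_nonpositive_dim_rejected(self):
        with pytest.raises(ValueError):
            standardize_by_geomean(1.0, [2.0, 0.0])


class TestParameterRecovery:
    def test_pc1_aligns_with_injected_group_axis(self):
        """With between-group variance >= 4x within, PC1 recovers the
        injected deformation axis to within 10 degrees."""
        tpl, mean = make_template("recov", 20, 2)
        angles = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            effect = rng.standard_normal(mean.shape)
            spec = SyntheticShapeSpec(
                template=tpl, mean_points=mean, n_per_group=30,
                group_effects={"A": np.zeros_like(mean), "B": effect},
                effect_size=0.4, noise_sd=0.02, seed=seed)
            sample, truth = gen_landmark_sample(spec)
            al = gpa(sample)
            space = pca_shape(al)
            # express the injected axis in the aligned (gauge) frame:
            # rotate by the fit of the raw mean onto the GPA mean
            from paleoshape.landmarks import center, optimal_rotation
            m = center(mean)
            m = m / np.sqrt((m ** 2).sum())
            gm = center(al.mean_shape.points)
            gm = gm / np.sqrt((gm ** 2).sum())
            r = optimal_rotation(m, gm)
            v = (truth["effects"]["B"] @ r).ravel()
            v = v / np.linalg.norm(v)
            pc1 = space.eigenvectors[:, 0]
            cos = abs(np.dot(v, pc1))
            angles.append(np.degrees(np.arccos(min(cos, 1.0))))
        assert np.max(angles) < 10.0
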