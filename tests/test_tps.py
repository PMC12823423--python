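"""Thin-plate splines, bending energy, and sliding."""

import numpy as np
import pytest

from paleoshape.landmarks import LandmarkSet
from paleoshape.tps import (CurveGeometry, SurfaceGeometry, TPSModel,
                            bending_energy, bending_energy_matrix, slide)
from paleoshape.synthetic import random_rotation


def tps_oracle_2d(source, target, query):
    """Independent TPS solve: explicit dense system via lstsq on the
    stacked equations, evaluated at query points.  Returns (values,
    bending_energy)."""
    k = len(source)
    d = np.linalg.norm(source[:, None] - source[None, :], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        km = np.where(d > 0, d ** 2 * np.log(np.where(d > 0, d, 1.0)), 0.0)
    p = np.hstack([np.ones((k, 1)), source])
    top = np.hstack([km, p])
    bottom = np.hstack([p.T, np.zeros((3, 3))])
    lhs = np.vstack([top, bottom])
    rhs = np.vstack([target, np.zeros((3, 2))])
    sol, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    w, a = sol[:k], sol[k:]
    dq = np.linalg.norm(query[:, None] - source[None, :], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.where(dq > 0, dq ** 2 * np.log(np.where(dq > 0, dq, 1.0)),
                      0.0)
    vals = a[0] + query @ a[1:] + uq @ w
    be = np.einsum("id,ij,jd->", w, km, w)
    return vals, max(be, 0.0)


class TestTPSModel:
    def test_identity_map_zero_weights(self, rng):
        src = rng.standard_normal((7, 2))
        m = TPSModel.fit(src, src)
        assert np.abs(m.weights).max() < 1e-10
        assert m.bending_energy < 1e-12
        q = rng.standard_normal((5, 2))
        assert np.allclose(m(q), q, atol=1e-10)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_affine_exact_zero_energy(self, rng, dim):
        src = rng.standard_normal((9, dim))
        a = rng.standard_normal((dim, dim)) + 2 * np.eye(dim)
        t = rng.standard_normal(dim)
        tgt = src @ a.T + t
        m = TPSModel.fit(src, tgt)
        assert m.bending_energy < 1e-10
        q = rng.standard_normal((6, dim))
        assert np.allclose(m(q), q @ a.T + t, atol=1e-8)

    def test_interpolates_and_matches_dense_oracle(self, rng):
        src = rng.standard_normal((6, 2))
        tgt = src + 0.3 * rng.standard_normal((6, 2))
        m = TPSModel.fit(src, tgt)
        assert np.abs(m(src) - tgt).max() < 1e-8
        q = rng.standard_normal((8, 2))
        vals, be = tps_oracle_2d(src, tgt, q)
        assert np.allclose(m(q), vals, atol=1e-8)
        assert m.bending_energy == pytest.approx(be, abs=1e-9)

    def test_side_conditions(self, rng):
        src = rng.standard_normal((8, 3))
        tgt = src + 0.2 * rng.standard_normal((8, 3))
        m = TPSModel.fit(src, tgt)
        assert np.abs(m.weights.sum(axis=0)).max() < 1e-8
        assert np.abs(src.T @ m.weights).max() < 1e-8

    def test_duplicate_points_rejected(self, rng):
        src = rng.standard_normal((5, 2))
        src[3] = src[1]
        with pytest.raises(ValueError, match="duplicate"):
            TPSModel.fit(src, src + 0.1)

    def test_collinear_rejected(self):
        src = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            TPSModel.fit(src, src + np.random.default_rng(0).normal(
                size=(5, 2)))


class TestBendingEnergy:
    def test_quadratic_scaling_in_bump_size(self, rng):
        """BE of source + eps*bump grows like eps^2."""
        src = rng.standard_normal((10, 2))
        bump = np.zeros((10, 2))
        bump[4] = [0.3, -0.2]
        eps = np.array([1e-3, 1e-2, 1e-1])
        be = np.array([bending_energy(src, src + e * bump) for e in eps])
        slope = np.polyfit(np.log(eps), np.log(be), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_matrix_identity(self, rng, dim):
        """BE equals the quadratic form with the explicit BE matrix."""
        src = rng.standard_normal((9, dim))
        tgt = src + 0.25 * rng.standard_normal((9, dim))
        b = bending_energy_matrix(src)
        quad = sum(tgt[:, d] @ b @ tgt[:, d] for d in range(dim))
        assert bending_energy(src, tgt) == pytest.approx(quad, abs=1e-9)
        # PSD with affine null space
        eig = np.linalg.eigvalsh(b)
        assert eig[0] > -1e-9
        affine = np.hstack([np.ones((len(src), 1)), src])
        assert np.abs(b @ affine).max() < 1e-8

    def test_rotation_invariance(self, rng):
        src = rng.standard_normal((8, 3))
        tgt = src + 0.2 * rng.standard_normal((8, 3))
        r = random_rotation(rng, 3)
        assert bending_energy(src @ r.T, tgt @ r.T) == pytest.approx(
            bending_energy(src, tgt), rel=1e-8)


def _line_instance(rng, n_slide=5, jitter=0.15):
    """Sliding instance: semilandmarks on a straight segment, one specimen
    with perturbed spacing vs a mean with uniform spacing; two fixed
    anchors off the line make the TPS non-degenerate."""
    xs_mean = np.linspace(0.0, 1.0, n_slide + 2)
    anchors = np.array([[0.0, 0.6], [1.0, 0.6], [0.5, -0.6]])

    def config(xs):
        line = np.column_stack([xs, np.zeros_like(xs)])
        return np.vstack([anchors, line])

    mean = config(xs_mean)
    u = rng.uniform(-jitter, jitter, n_slide)
    xs_spec = xs_mean.copy()
    xs_spec[1:-1] = np.clip(xs_mean[1:-1] + u / (n_slide + 1), 0.02, 0.98)
    spec = config(xs_spec)
    slide_idx = list(range(len(anchors) + 1, len(anchors) + 1 + n_slide))
    return mean, spec, slide_idx


def coordinate_descent_oracle(mean, spec, slide_idx, n_rounds=300):
    """1-dof-per-landmark brute-force descent of the bending energy for
    semilandmarks confined to the y=0 line, with grid refinement."""
    b = bending_energy_matrix(mean)

    def be(pts):
        return sum(pts[:, d] @ b @ pts[:, d] for d in range(2))

    pts = spec.copy()
    for half_width in (0.02, 1e-3, 5e-5):
        for _ in range(n_rounds):
            moved = 0.0
            for i in slide_idx:
                grid = pts[i, 0] + np.linspace(-half_width, half_width, 81)
                best, best_be = pts[i, 0], be(pts)
                for g in grid:
                    trial = pts.copy()
                    trial[i, 0] = g
                    e = be(trial)
                    if e < best_be:
                        best, best_be = g, e
                moved = max(moved, abs(best - pts[i, 0]))
                pts[i, 0] = best
            if moved < half_width / 50:
                break
    return pts, be(pts)


class _LineGeometry:
    """The y=0 line as a sliding geometry (analytic, for tests)."""

    def tangents_at(self, p):
        return np.array([[1.0, 0.0]])

    def project(self, p):
        return np.array([p[0], 0.0]), p[0]


class TestSlide:
    def test_specimen_equal_to_mean_does_not_move(self, rng):
        mean, _spec, slide_idx = _line_instance(rng)
        geo = {i: _LineGeometry() for i in slide_idx}
        sample = [LandmarkSet("a", mean.copy()),
                  LandmarkSet("b", mean.copy())]
        res = slide(sample, None, {"a": geo, "b": geo}, n_passes=1)
        for out, inp in zip(res.slid_specimens, sample):
            assert np.allclose(out.points, mean, atol=1e-8)

    def test_line_instance_matches_coordinate_descent(self, rng):
        """One sliding pass solves the same quadratic program a brute
        force coordinate descent finds on a tiny line instance."""
        from paleoshape.landmarks import gpa
        from paleoshape.tps import _specimen_frame_mean

        mean, spec, slide_idx = _line_instance(rng)
        geo = {i: _LineGeometry() for i in slide_idx}
        sample = [LandmarkSet("m1", mean.copy()),
                  LandmarkSet("m2", mean.copy()),
                  LandmarkSet("s", spec.copy())]
        res = slide(sample, None, {s.specimen_id: geo for s in sample},
                    n_passes=1)
        slid = res.slid_specimens[2].points

        # the pass's objective: BE against the GPA mean of the input
        # sample, mapped into the specimen frame
        pass_mean = gpa(sample).mean_shape.points
        ref = _specimen_frame_mean(pass_mean, spec)
        oracle_pts, oracle_be = coordinate_descent_oracle(ref, spec,
                                                          slide_idx)
        b = bending_energy_matrix(ref)
        be_slid = sum(slid[:, d] @ b @ slid[:, d] for d in range(2))
        assert be_slid <= oracle_be + 1e-9
        assert np.allclose(slid[slide_idx], oracle_pts[slide_idx],
                           atol=1e-4)

    def test_energy_nonincreasing_and_anchors_fixed(self, rng):
        mean, spec, slide_idx = _line_instance(rng)
        geo = {i: _LineGeometry() for i in slide_idx}
        specs = []
        for j in range(4):
            _m, s, _i = _line_instance(np.random.default_rng(j))
            specs.append(LandmarkSet(f"s{j}", s))
        res = slide(specs, None, {s.specimen_id: geo for s in specs},
                    n_passes=2)
        assert np.all(res.bending_energy_after
                      <= res.bending_energy_before + 1e-12)
        for out, inp in zip(res.slid_specimens, specs):
            assert np.array_equal(out.points[:4], inp.points[:4])

    def test_tangential_local_optimality(self, rng):
        """Perturbing any slid semilandmark tangentially by +-delta never
        lowers the bending energy appreciably."""
        mean, spec, slide_idx = _line_instance(rng)
        geo = {i: _LineGeometry() for i in slide_idx}
        sample = [LandmarkSet("m1", mean.copy()),
                  LandmarkSet("m2", mean.copy()),
                  LandmarkSet("s", spec.copy())]
        res = slide(sample, None, {s.specimen_id: geo for s in sample},
                    n_passes=2)
        slid = res.slid_specimens[2].points
        from paleoshape.tps import _specimen_frame_mean
        ref = _specimen_frame_mean(res.aligned.mean_shape.points, slid)
        b = bending_energy_matrix(ref)

        def be(pts):
            return sum(pts[:, d] @ b @ pts[:, d] for d in range(2))

        base = be(slid)
        for i in slide_idx:
            for delta in (1e-4, -1e-4):
                trial = slid.copy()
                trial[i, 0] += delta
                assert be(trial) >= base - 1e-9

    def test_missing_geometry_rejected(self, rng):
        mean, spec, slide_idx = _line_instance(rng)
        geo = {i: _LineGeometry() for i in slide_idx}
        sample = [LandmarkSet("a", mean), LandmarkSet("b", spec)]
        with pytest.raises(ValueError, match="geometry"):
            slide(sample, None, {"a": geo}, n_passes=1)


class TestGeometries:
    def test_curve_projection_on_circle(self, rng):
        ang = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        geo = CurveGeometry(pts, closed=True)
        p = np.array([1.7, 0.4])
        proj, _t = geo.project(p)
        assert np.linalg.norm(proj) == pytest.approx(1.0, abs=1e-4)
        assert np.allclose(proj, p / np.linalg.norm(p), atol=1e-3)
        tan = geo.tangents_at(proj)[0]
        assert abs(np.dot(tan, proj)) < 1e-3  # tangent orthogonal to radius

    def test_surface_projection_on_plane(self, rng):
        xs, ys = np.meshgrid(np.linspace(-1, 1, 12), np.linspace(-1, 1, 12))
        cloud = np.column_stack([xs.ravel(), ys.ravel(),
                                 np.zeros(xs.size)])
        geo = SurfaceGeometry(cloud, k_neighbors=8)
        p = np.array([0.21, -0.33, 0.4])
        proj, _ = geo.project(p)
        assert abs(proj[2]) < 1e-8
        tans = geo.tangents_at(p)
        assert tans.shape == (2, 3)
        assert np.abs(tans[:, 2]).max() < 1e-8
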