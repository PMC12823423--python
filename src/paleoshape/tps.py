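"""Thin-plate splines, bending energy, and sliding semilandmarks.

A thin-plate spline (TPS) is the unique minimum-bending interpolant
between two landmark configurations.  Its non-affine cost — the bending
energy — is the criterion minimized when curve and surface
semilandmarks are slid along their tangent directions against the
sample Procrustes mean, the standard way of establishing geometric
homology for points that have no one-to-one anatomical identity.

Kernels: ``U(r) = r^2 log r`` in 2D and ``U(r) = r`` in 3D (the
biharmonic kernels of the respective dimensions).  The bending-energy
quadratic form is sign-normalized so that it is nonnegative in both
dimensions and zero exactly for affine maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .landmarks import LandmarkSet, TemplateDef, gpa, optimal_rotation, center

__all__ = [
    "TPSModel",
    "bending_energy",
    "bending_energy_matrix",
    "CurveGeometry",
    "SurfaceGeometry",
    "SlideResult",
    "slide",
]


def _kernel(r: np.ndarray, dim: int) -> np.ndarray:
    if dim == 2:
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out
    return r


# sign making w^T K w nonnegative on the side-condition subspace
_BE_SIGN = {2: 1.0, 3: -1.0}


def _kernel_matrix(points: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    return _kernel(d, points.shape[1])


@dataclass
class TPSModel:
    """Exact thin-plate-spline interpolant between two point sets."""

    source: np.ndarray
    affine: np.ndarray        # (dim+1, dim): row 0 translation, rest linear
    weights: np.ndarray       # (K, dim) kernel weights
    dim: int

    @classmethod
    def fit(cls, source: np.ndarray, target: np.ndarray) -> "TPSModel":
        source = np.asarray(source, float)
        target = np.asarray(target, float)
        if source.shape != target.shape:
            raise ValueError("source/target shape mismatch")
        k, dim = source.shape
        if dim not in (2, 3):
            raise ValueError("TPS supports 2D and 3D only")
        dists = np.linalg.norm(
            source[:, None, :] - source[None, :, :], axis=-1)
        scale = max(dists.max(), np.finfo(float).tiny)
        if np.min(dists + np.eye(k) * scale) < 1e-9 * scale:
            raise ValueError("duplicate source points make the TPS kernel "
                             "system singular")
        if np.linalg.matrix_rank(source - source.mean(0), tol=1e-9 * scale) < dim:
            raise ValueError("source points are collinear/coplanar; the TPS "
                             "side conditions are rank-deficient")
        kmat = _kernel(dists, dim)
        p = np.hstack([np.ones((k, 1)), source])
        lmat = np.zeros((k + dim + 1, k + dim + 1))
        lmat[:k, :k] = kmat
        lmat[:k, k:] = p
        lmat[k:, :k] = p.T
        rhs = np.zeros((k + dim + 1, dim))
        rhs[:k] = target
        # pivoted solve; the bordered system is symmetric indefinite
        sol = np.linalg.solve(lmat, rhs)
        return cls(source=source, affine=sol[k:], weights=sol[:k], dim=dim)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        d = np.linalg.norm(
            points[:, None, :] - self.source[None, :, :], axis=-1)
        u = _kernel(d, self.dim)
        return (self.affine[0][None, :]
                + points @ self.affine[1:]
                + u @ self.weights)

    @property
    def bending_energy(self) -> float:
        kmat = _kernel_matrix(self.source)
        be = _BE_SIGN[self.dim] * np.einsum(
            "id,ij,jd->", self.weights, kmat, self.weights)
        return float(max(be, 0.0))


def bending_energy(source: np.ndarray | LandmarkSet,
                   target: np.ndarray | LandmarkSet) -> float:
    """Bending energy of the TPS mapping ``source`` onto ``target``.

    Zero iff the deformation is affine; invariant to a common rotation
    of both configurations.
    """
    if isinstance(source, LandmarkSet):
        source = source.points
    if isinstance(target, LandmarkSet):
        target = target.points
    return TPSModel.fit(source, target).bending_energy


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """Bending-energy matrix ``B`` of a source configuration.

    For any target ``Y`` (K × dim), the TPS bending energy equals
    ``sum_d  Y[:, d]^T B Y[:, d]``.  ``B`` is the upper-left K × K block
    of the inverse bordered kernel system, sign-normalized to be
    positive semidefinite; its null space is spanned by the affine
    functions of the source coordinates.
    """
    source = np.asarray(source, float)
    k, dim = source.shape
    kmat = _kernel_matrix(source)
    p = np.hstack([np.ones((k, 1)), source])
    lmat = np.zeros((k + dim + 1, k + dim + 1))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    linv = np.linalg.inv(lmat)
    b = _BE_SIGN[dim] * linv[:k, :k]
    return 0.5 * (b + b.T)


# ---------------------------------------------------------------------------
# geometry evaluators

class CurveGeometry:
    """A curve sampled as an ordered polyline, usable for sliding.

    Fits an interpolating cubic spline through the samples
    (chord-length parameterized) and supports nearest-point projection
    and tangent queries.
    """

    def __init__(self, samples: np.ndarray, closed: bool = False):
        samples = np.asarray(samples, float)
        keep = np.ones(len(samples), bool)
        keep[1:] = np.linalg.norm(np.diff(samples, axis=0), axis=1) > 1e-12
        samples = samples[keep]
        if closed and np.linalg.norm(samples[0] - samples[-1]) > 1e-9:
            samples = np.vstack([samples, samples[0]])
        if len(samples) < 4:
            raise ValueError("need at least 4 distinct samples for a cubic "
                             "spline curve")
        t = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(samples, axis=0), axis=1))])
        self.closed = closed
        self._t = t
        self._tmax = t[-1]
        bc = "periodic" if closed else None
        if closed:
            self._spl = make_interp_spline(t, samples, k=3,
                                           bc_type="periodic")
        else:
            self._spl = make_interp_spline(t, samples, k=3)
        self._dspl = self._spl.derivative()
        # dense samples for the coarse projection stage
        td = np.linspace(0.0, self._tmax, max(8 * len(samples), 256))
        self._dense_t = td
        self._dense = self._spl(td)
        self._tree = cKDTree(self._dense)

    def point(self, t: float) -> np.ndarray:
        return np.asarray(self._spl(t), float)

    def tangent(self, t: float) -> np.ndarray:
        v = np.asarray(self._dspl(t), float)
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def project(self, p: np.ndarray) -> tuple[np.ndarray, float]:
        """Nearest point on the curve; returns (point, parameter)."""
        _, idx = self._tree.query(p)
        t0 = self._dense_t[idx]
        h = self._tmax / (len(self._dense_t) - 1)
        lo = t0 - 2 * h
        hi = t0 + 2 * h
        if not self.closed:
            lo, hi = max(0.0, lo), min(self._tmax, hi)

        def f(t):
            tt = t % self._tmax if self.closed else t
            return float(np.sum((np.asarray(self._spl(tt)) - p) ** 2))

        res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        t = res.x % self._tmax if self.closed else float(res.x)
        return self.point(t), float(t)

    def tangents_at(self, p: np.ndarray) -> np.ndarray:
        _, t = self.project(p)
        return self.tangent(t)[None, :]


class SurfaceGeometry:
    """A surface sampled as a point cloud, usable for sliding.

    The tangent plane at a query point is estimated by local PCA over
    the k nearest cloud samples; projection snaps to the nearest cloud
    point and refines within that local plane.
    """

    def __init__(self, samples: np.ndarray, k_neighbors: int = 8):
        self.samples = np.asarray(samples, float)
        if len(self.samples) < k_neighbors:
            raise ValueError("surface cloud smaller than the neighborhood")
        self.k = k_neighbors
        self._tree = cKDTree(self.samples)

    def _local_frame(self, p: np.ndarray):
        _, idx = self._tree.query(p, k=self.k)
        nbrs = self.samples[idx]
        c = nbrs.mean(axis=0)
        _u, _s, vt = np.linalg.svd(nbrs - c)
        return c, vt  # rows: principal directions, last = normal

    def project(self, p: np.ndarray) -> tuple[np.ndarray, None]:
        c, vt = self._local_frame(p)
        rel = p - c
        proj = c + rel @ vt[:-1].T @ vt[:-1]
        return proj, None

    def tangents_at(self, p: np.ndarray) -> np.ndarray:
        _c, vt = self._local_frame(p)
        return vt[:-1]


# ---------------------------------------------------------------------------
# sliding

@dataclass
class SlideResult:
    """Outcome of bending-energy sliding."""

    slid_specimens: list[LandmarkSet]
    bending_energy_before: np.ndarray   # (n_passes, n_specimens)
    bending_energy_after: np.ndarray
    n_passes: int
    mean_shape: LandmarkSet | None = None
    aligned: object = None              # final AlignedSample

    @property
    def initial_energy(self) -> np.ndarray:
        return self.bending_energy_before[0]

    @property
    def final_energy(self) -> np.ndarray:
        return self.bending_energy_after[-1]


def _specimen_frame_mean(mean_unit: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Ordinary-Procrustes fit of the unit mean into a specimen's raw frame."""
    x = center(pts)
    m = mean_unit - mean_unit.mean(axis=0)
    r = optimal_rotation(m, x)
    mr = m @ r
    beta = np.sum(x * mr) / np.sum(m ** 2)
    return mr * beta + pts.mean(axis=0)


def slide(sample: list[LandmarkSet], tpl: TemplateDef,
          geometries: dict[str, dict[int, object]],
          n_passes: int = 2) -> SlideResult:
    """Slide semilandmarks to minimize TPS bending energy against the mean.

    Per pass: the Procrustes mean is recomputed; for each specimen the
    generalized-least-squares tangential displacement minimizing the
    bending energy of the mean-to-specimen TPS is solved in closed
    form; displaced semilandmarks are projected back onto their curve
    or surface.  Anatomical anchors never move.  Exactly ``n_passes``
    passes are run, the mean being refreshed between them.

    Parameters
    ----------
    geometries : mapping specimen_id -> {landmark_index: evaluator}
        Evaluator objects expose ``tangents_at(point) -> (dof, dim)``
        and ``project(point) -> (point, param)``.  Curve evaluators
        give one tangent direction, surface evaluators two.
    """
    specs = [s.copy_with() for s in sample]
    for s in specs:
        if s.specimen_id not in geometries:
            raise ValueError(f"no geometry evaluators for specimen "
                             f"{s.specimen_id!r}")
    slide_idx = sorted({i for s in specs
                        for i in geometries[s.specimen_id].keys()})
    for s in specs:
        missing = set(slide_idx) - set(geometries[s.specimen_id].keys())
        if missing:
            raise ValueError(
                f"specimen {s.specimen_id!r} lacks geometry evaluators for "
                f"semilandmarks {sorted(missing)}")

    n = len(specs)
    be_before = np.zeros((n_passes, n))
    be_after = np.zeros((n_passes, n))

    for p in range(n_passes):
        aligned = gpa(specs)
        mean_unit = aligned.mean_shape.points
        for si, s in enumerate(specs):
            ref = _specimen_frame_mean(mean_unit, s.points)
            bmat = bending_energy_matrix(ref)

            def be_of(pts, _b=bmat):
                return float(max(np.einsum("id,ij,jd->", pts, _b, pts), 0.0))

            be0 = be_of(s.points)
            be_before[p, si] = be0

            geo = geometries[s.specimen_id]
            tangents = {}
            dof_index = []
            for i in slide_idx:
                t = np.atleast_2d(geo[i].tangents_at(s.points[i]))
                tangents[i] = t
                dof_index.extend((i, r) for r in range(t.shape[0]))
            ndof = len(dof_index)
            dim = s.dim
            # assemble U_d (K x ndof) per coordinate and the GLS system
            u = np.zeros((dim, s.n_landmarks, ndof))
            for j, (i, r) in enumerate(dof_index):
                u[:, i, j] = tangents[i][r]
            a = np.zeros((ndof, ndof))
            rhs = np.zeros(ndof)
            for d in range(dim):
                bu = bmat @ u[d]
                a += u[d].T @ bu
                rhs -= u[d].T @ (bmat @ s.points[:, d])
            lam, *_ = np.linalg.lstsq(a, rhs, rcond=None)

            disp = np.zeros_like(s.points)
            for j, (i, r) in enumerate(dof_index):
                disp[i] += lam[j] * tangents[i][r]

            # damped step: projection back onto the geometry may eat part
            # of the gain, so halve the tangential step until the energy
            # does not increase
            step = 1.0
            new_pts = s.points
            for _try in range(30):
                cand = s.points + step * disp
                for i in slide_idx:
                    proj, _param = geo[i].project(cand[i])
                    cand[i] = proj
                if be_of(cand) <= be0 + 1e-12:
                    new_pts = cand
                    break
                step *= 0.5
            s.points = new_pts
            be_after[p, si] = be_of(new_pts)

    final = gpa(specs)
    return SlideResult(
        slid_specimens=specs,
        bending_energy_before=be_before,
        bending_energy_after=be_after,
        n_passes=n_passes,
        mean_shape=final.mean_shape,
        aligned=final,
    )
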