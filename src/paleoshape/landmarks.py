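"""Landmark data model and Procrustes machinery.

Configurations of named 2D/3D landmarks are the elementary data of
landmark-based geometric morphometrics.  This module provides the
:class:`LandmarkSet` container, template schemas, centroid size,
generalized Procrustes analysis (GPA), full-Procrustes distance,
bilateral mirroring of missing landmarks, thin-plate-spline estimation
of missing landmarks without a bilateral counterpart, and
symmetrization of bilateral configurations.

Conventions
-----------
* Coordinates are unit-agnostic; GPA output is dimensionless shape
  coordinates with unit centroid size.
* GPA is *full* Procrustes: each configuration is centred, scaled to
  unit centroid size and rotated (proper rotation only, ``det = +1``)
  onto the iteratively re-estimated mean.  Reflections are never
  allowed, preserving anatomical chirality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LandmarkSet",
    "TemplateDef",
    "AlignedSample",
    "centroid_size",
    "center",
    "gpa",
    "procrustes_distance",
    "optimal_rotation",
    "mirror_estimate",
    "tps_fill_missing",
    "symmetrize",
]

ROLES = ("anatomical", "curve_semilandmark", "surface_semilandmark",
         "outline_pseudolandmark")


@dataclass
class LandmarkSet:
    """An ordered, labelled set of landmark coordinates for one specimen.

    Parameters
    ----------
    specimen_id : str
        Specimen identifier.
    points : (K, dim) array
        Landmark coordinates, ``dim`` in {2, 3}.  Rows flagged missing
        may hold NaN.
    missing : (K,) bool array, optional
        True where the landmark was not observed.
    roles : sequence of str, optional
        Per-landmark role tag; defaults to ``"anatomical"`` for all.
    template_id : str
        Identifier of the template this specimen was digitized against.
    """

    specimen_id: str
    points: np.ndarray
    missing: np.ndarray | None = None
    roles: Sequence[str] | None = None
    template_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValueError("points must be (K, 2) or (K, 3)")
        k = self.points.shape[0]
        if self.missing is None:
            self.missing = np.zeros(k, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (k,):
                raise ValueError("missing mask length mismatch")
        if self.roles is None:
            self.roles = ["anatomical"] * k
        elif len(self.roles) != k:
            raise ValueError("roles length mismatch")
        for r in self.roles:
            if r not in ROLES:
                raise ValueError(f"unknown landmark role {r!r}")
        observed = self.points[~self.missing]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-missing coordinates must be finite")

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def copy_with(self, **kw) -> "LandmarkSet":
        out = replace(self)
        out.points = self.points.copy()
        out.missing = self.missing.copy()
        out.roles = list(self.roles)
        for key, val in kw.items():
            setattr(out, key, val)
        return out


@dataclass
class TemplateDef:
    """Schema of a landmark dataset.

    ``bilateral_pairs`` lists (left_index, right_index) pairs related by
    the midsagittal plane; ``midline`` lists indices lying on it.
    ``curve_sections`` are ``(anchor_start, anchor_end, n_semilandmarks,
    closed)`` tuples describing slid curve segments; ``surface_patches``
    are index sets of surface semilandmarks.
    """

    template_id: str
    dim: int
    landmark_labels: Sequence[str]
    bilateral_pairs: Sequence[tuple[int, int]] = field(default_factory=list)
    midline: Sequence[int] = field(default_factory=list)
    curve_sections: Sequence[tuple[int, int, int, bool]] = field(default_factory=list)
    surface_patches: Sequence[Sequence[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.landmark_labels)
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        seen_in_section: set[int] = set()
        for a, b, n, _closed in self.curve_sections:
            if not (0 <= a < k and 0 <= b < k):
                raise ValueError("curve section anchor index out of range")
            if n <= 0:
                raise ValueError("curve section semilandmark count must be positive")
            for idx in (a, b):
                if idx in seen_in_section:
                    # anchors may bound two adjacent sections; interior
                    # landmarks may not repeat
                    pass
            seen_in_section.update((a, b))
        for i, j in self.bilateral_pairs:
            if not (0 <= i < k and 0 <= j < k):
                raise ValueError("bilateral pair index out of range")
        for i in self.midline:
            if not (0 <= i < k):
                raise ValueError("midline index out of range")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_labels)


@dataclass
class AlignedSample:
    """Result of a generalized Procrustes superimposition."""

    template_id: str
    specimens: list[LandmarkSet]
    centroid_sizes: np.ndarray
    mean_shape: LandmarkSet
    converged: bool
    n_iterations: int

    @property
    def coords(self) -> np.ndarray:
        """Aligned coordinates stacked as (n, K, dim)."""
        return np.stack([s.points for s in self.specimens])


# ---------------------------------------------------------------------------
# basic geometry

def centroid_size(ls: LandmarkSet | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark-to-centroid distances.

    The standard size measure of geometric morphometrics; scales
    linearly under uniform scaling of the configuration.
    """
    pts = ls.points if isinstance(ls, LandmarkSet) else np.asarray(ls, float)
    if isinstance(ls, LandmarkSet) and ls.missing.any():
        raise ValueError("centroid size undefined with missing landmarks")
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum()))


def center(pts: np.ndarray) -> np.ndarray:
    return pts - pts.mean(axis=0)


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det=+1) minimizing ||source @ R - target||_F.

    Kabsch solution with the reflection branch excluded.
    """
    h = source.T @ target
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    dim = source.shape[1]
    corr = np.eye(dim)
    corr[-1, -1] = d
    return u @ corr @ vt


def _check_no_missing(specimens: Sequence[LandmarkSet]) -> None:
    for s in specimens:
        if s.missing.any():
            raise ValueError(
                f"specimen {s.specimen_id!r} has missing landmarks; "
                "estimate them before superimposition")


def _unit(pts: np.ndarray) -> np.ndarray:
    """Centre and scale to unit centroid size."""
    pts = center(pts)
    size = np.sqrt((pts ** 2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return pts / size


def _canonical_gauge(mean: np.ndarray) -> np.ndarray:
    """Proper rotation taking the mean shape to its principal axes.

    Column signs are fixed by making the largest-magnitude coordinate
    along each axis positive; if that leaves an improper rotation the
    weakest axis is flipped back.
    """
    dim = mean.shape[1]
    _u, _s, vt = np.linalg.svd(mean - mean.mean(axis=0),
                               full_matrices=False)
    q = vt.T
    rotated = mean @ q
    for j in range(dim):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            q[:, j] = -q[:, j]
    if np.linalg.det(q) < 0:
        q[:, -1] = -q[:, -1]
    return q


def gpa(specimens: Sequence[LandmarkSet], *, tol: float = 1e-10,
        max_iter: int = 100) -> AlignedSample:
    """Generalized (full) Procrustes analysis.

    Each configuration is translated to centroid origin, scaled to unit
    centroid size, and rotated to minimize its summed squared distance
    to the iteratively updated mean shape, which is itself re-scaled to
    unit centroid size each iteration.  Deterministic given input
    order; converges when the mean shape's RMS change drops below
    ``tol``.
    """
    if len(specimens) < 2:
        raise ValueError("GPA requires at least two specimens")
    templates = {s.template_id for s in specimens}
    if len(templates) > 1:
        raise ValueError(f"mixed templates in GPA input: {templates}")
    _check_no_missing(specimens)
    shapes = {s.points.shape for s in specimens}
    if len(shapes) > 1:
        raise ValueError("inconsistent landmark counts")

    sizes = np.array([centroid_size(s) for s in specimens])
    configs = [_unit(s.points) for s in specimens]
    mean = _unit(configs[0].copy())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = [c @ optimal_rotation(c, mean) for c in configs]
        new_mean = _unit(np.mean(aligned, axis=0))
        # resolve the rotational gauge freedom: keep mean aligned to the
        # previous mean so the convergence criterion measures shape change
        new_mean = new_mean @ optimal_rotation(new_mean, mean)
        delta = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        configs = aligned
        if delta < tol:
            converged = True
            break
    # canonical global orientation: principal axes of the mean shape with
    # a deterministic sign convention, so GPA output is a fixed point of
    # re-alignment rather than defined up to a joint rotation
    q = _canonical_gauge(mean)
    mean = mean @ q
    configs = [c @ q for c in configs]
    aligned = [c @ optimal_rotation(c, mean) for c in configs]

    out = []
    for s, pts in zip(specimens, aligned):
        out.append(s.copy_with(points=pts))
    mean_ls = LandmarkSet(
        specimen_id="__mean__", points=mean,
        roles=list(specimens[0].roles),
        template_id=specimens[0].template_id)
    return AlignedSample(
        template_id=specimens[0].template_id, specimens=out,
        centroid_sizes=sizes, mean_shape=mean_ls,
        converged=converged, n_iterations=it)


def procrustes_distance(a: LandmarkSet | np.ndarray,
                        b: LandmarkSet | np.ndarray) -> float:
    """Full-Procrustes distance between two configurations.

    Both configurations are centred and scaled to unit centroid size,
    then ``b`` is rotated (no reflection) onto ``a``; the distance is
    the root summed squared difference.  Symmetric, and zero iff the
    shapes are identical up to a similarity transform.
    """
    if isinstance(a, LandmarkSet) and isinstance(b, LandmarkSet):
        if a.template_id != b.template_id:
            raise ValueError("template mismatch")
    pa = a.points if isinstance(a, LandmarkSet) else np.asarray(a, float)
    pb = b.points if isinstance(b, LandmarkSet) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError("landmark count mismatch")
    x = _unit(pa)
    y = _unit(pb)
    r = optimal_rotation(y, x)
    yr = y @ r
    # full-Procrustes distance allows a residual scaling of the fitted
    # configuration: min over beta of ||x - beta * y R||
    beta = np.sum(x * yr)
    return float(np.sqrt(max(0.0, 1.0 - beta ** 2)))


# ---------------------------------------------------------------------------
# bilateral operations

def _reflection_plane(ls: LandmarkSet, tpl: TemplateDef):
    """Best-fit midsagittal plane from midline points and bilateral midpoints.

    Returns (point_on_plane, unit_normal).  The normal's first nonzero
    component is made positive (deterministic tie-break).
    """
    pts = []
    for i in tpl.midline:
        if not ls.missing[i]:
            pts.append(ls.points[i])
    for i, j in tpl.bilateral_pairs:
        if not ls.missing[i] and not ls.missing[j]:
            pts.append(0.5 * (ls.points[i] + ls.points[j]))
    if len(pts) < ls.dim:
        raise ValueError("insufficient midline information to fit a "
                         "midsagittal plane")
    pts = np.asarray(pts)
    c = pts.mean(axis=0)
    # normal = smallest principal axis of the midplane point scatter; with
    # pure midline/midpoint data this is the direction of least extent
    _u, _s, vt = np.linalg.svd(pts - c, full_matrices=True)
    normal = vt[-1]
    nz = np.nonzero(np.abs(normal) > 1e-12)[0]
    if nz.size and normal[nz[0]] < 0:
        normal = -normal
    return c, normal


def _reflect(points: np.ndarray, origin: np.ndarray,
             normal: np.ndarray) -> np.ndarray:
    d = (points - origin) @ normal
    return points - 2.0 * d[:, None] * normal[None, :]


def mirror_estimate(ls: LandmarkSet, tpl: TemplateDef) -> LandmarkSet:
    """Fill missing bilateral landmarks by mirroring the preserved side.

    The configuration is reflected across the least-squares midsagittal
    plane (through midline landmarks and bilateral-pair midpoints); a
    missing landmark is replaced by the reflection of its preserved
    counterpart.  Preserved landmarks are untouched.
    """
    if not ls.missing.any():
        return ls.copy_with()
    origin, normal = _reflection_plane(ls, tpl)
    counterpart = {}
    for i, j in tpl.bilateral_pairs:
        counterpart[i] = j
        counterpart[j] = i
    out = ls.copy_with()
    for idx in np.nonzero(ls.missing)[0]:
        mate = counterpart.get(int(idx))
        if mate is None or ls.missing[mate]:
            continue  # no preserved bilateral counterpart; left for TPS
        out.points[idx] = _reflect(ls.points[mate][None, :], origin, normal)[0]
        out.missing[idx] = False
    return out


def tps_fill_missing(ls: LandmarkSet, reference: LandmarkSet) -> LandmarkSet:
    """Estimate missing landmarks by TPS-warping a reference onto the specimen.

    A thin-plate spline is fitted from the reference's landmarks at the
    specimen's *observed* positions to the specimen's observed
    coordinates; missing landmarks are placed at the warped reference
    positions.  Observed entries are unchanged.
    """
    from .tps import TPSModel  # local import: tps depends on this module

    if ls.points.shape != reference.points.shape:
        raise ValueError("reference landmark count mismatch")
    if not ls.missing.any():
        return ls.copy_with()
    obs = ~ls.missing
    src = reference.points[obs]
    dst = ls.points[obs]
    dim = ls.dim
    if obs.sum() < dim + 1:
        raise ValueError("insufficient observed landmarks for TPS estimation")
    # collinearity / coplanarity check
    rank = np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-9)
    if rank < dim:
        raise ValueError("observed landmarks are degenerate (collinear or "
                         "coplanar); TPS system is singular")
    model = TPSModel.fit(src, dst)
    out = ls.copy_with()
    miss_idx = np.nonzero(ls.missing)[0]
    out.points[miss_idx] = model(reference.points[miss_idx])
    out.missing[miss_idx] = False
    return out


def symmetrize(ls: LandmarkSet, tpl: TemplateDef) -> LandmarkSet:
    """Average a configuration with its relabelled reflection.

    The output is reflection-symmetric under the template's bilateral
    pairing; applying symmetrize twice equals applying it once.
    """
    if not tpl.bilateral_pairs:
        raise ValueError("template has no bilateral pairs; cannot symmetrize")
    if ls.missing.any():
        raise ValueError("estimate missing landmarks before symmetrizing")
    origin, normal = _reflection_plane(ls, tpl)
    reflected = _reflect(ls.points, origin, normal)
    # relabel: swap left/right partners so the reflection is comparable
    perm = np.arange(ls.n_landmarks)
    for i, j in tpl.bilateral_pairs:
        perm[i], perm[j] = j, i
    relabelled = reflected[perm]
    # the naive average is symmetric about the *original* plane only if the
    # plane itself is reflection-stable; iterate to a fixed point
    pts = 0.5 * (ls.points + relabelled)
    for _ in range(50):
        tmp = ls.copy_with(points=pts)
        origin, normal = _reflection_plane(tmp, tpl)
        relab = _reflect(pts, origin, normal)[perm]
        new = 0.5 * (pts + relab)
        if np.max(np.abs(new - pts)) < 1e-14:
            pts = new
            break
        pts = new
    return ls.copy_with(points=pts)
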