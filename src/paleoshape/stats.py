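"""Shape-space statistics.

Principal component analysis of Procrustes shape coordinates, post-hoc
projection of fossils into a reference shape space, nearest neighbours
by Procrustes distance, mean-shape warps along principal components,
permutation tests on PC scores, leave-one-out cross-validated
quadratic discriminant classification with posterior probabilities,
and simple size descriptors (molar size pattern, geometric-mean
standardization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from .landmarks import (AlignedSample, LandmarkSet, centroid_size,
                        procrustes_distance, optimal_rotation, center)

__all__ = [
    "ShapeSpace",
    "PermutationResult",
    "ClassificationResult",
    "pca_shape",
    "project",
    "nearest_neighbours",
    "warp_along_pc",
    "permutation_test",
    "select_pcs",
    "qda_loocv",
    "size_series",
    "standardize_by_geomean",
]


@dataclass
class ShapeSpace:
    """A fitted shape-space PCA.

    ``eigenvectors`` has orthonormal columns over the flattened
    (K·dim) coordinate space; ``eigenvalues`` are the non-increasing
    variances along them; ``training_scores`` are the training
    specimens' coordinates in the eigenbasis.
    """

    mean_shape: np.ndarray          # (K, dim)
    eigenvectors: np.ndarray        # (K*dim, p)
    eigenvalues: np.ndarray         # (p,)
    training_scores: np.ndarray     # (n, p)
    training_ids: list[str]
    training_labels: list[str] | None = None
    total_variance: float = 0.0

    @property
    def landmark_shape(self) -> tuple[int, int]:
        return self.mean_shape.shape

    def variance_ratios(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Shape at the given PC scores, in landmark layout."""
        flat = self.mean_shape.ravel() + self.eigenvectors @ np.asarray(scores)
        return flat.reshape(self.mean_shape.shape)


@dataclass
class PermutationResult:
    observed_stat: float
    n_permutations: int
    p_value: float
    seed: int | None
    groups: tuple[str, str]


@dataclass
class ClassificationResult:
    pcs_used: int
    loocv_predictions: list[str]
    loocv_accuracy_overall: float
    loocv_accuracy_by_group: dict[str, float]
    unknown_predictions: list[str] = field(default_factory=list)
    unknown_posteriors: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)
    loocv_posteriors: np.ndarray | None = None


# ---------------------------------------------------------------------------
# PCA

def pca_shape(aligned: AlignedSample | np.ndarray,
              ids: list[str] | None = None,
              labels: list[str] | None = None) -> ShapeSpace:
    """PCA of flattened Procrustes coordinates about the sample mean.

    Eigenvectors follow a deterministic sign convention: the largest-
    magnitude loading of each component is positive.
    """
    if isinstance(aligned, AlignedSample):
        coords = aligned.coords
        ids = [s.specimen_id for s in aligned.specimens]
    else:
        coords = np.asarray(aligned, float)
        if ids is None:
            ids = [f"spec_{i}" for i in range(len(coords))]
    n = coords.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two specimens")
    k, dim = coords.shape[1], coords.shape[2]
    flat = coords.reshape(n, k * dim)
    mean = flat.mean(axis=0)
    x = flat - mean
    # economical SVD; eigenvalues of the covariance with 1/(n-1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    vecs = vt.T
    # sign convention
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = x @ vecs
    return ShapeSpace(
        mean_shape=mean.reshape(k, dim),
        eigenvectors=vecs,
        eigenvalues=eigvals,
        training_scores=scores,
        training_ids=list(ids),
        training_labels=list(labels) if labels is not None else None,
        total_variance=float(eigvals.sum()),
    )


def _ops_fit_to_mean(specimen: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Ordinary-Procrustes fit of a configuration onto the mean shape."""
    x = center(np.asarray(specimen, float))
    size = np.sqrt((x ** 2).sum())
    if size == 0:
        raise ValueError("degenerate specimen")
    x = x / size
    m = center(mean)
    r = optimal_rotation(x, m)
    xr = x @ r
    beta = np.sum(m * xr)
    return beta * xr + mean.mean(axis=0)


def project(space: ShapeSpace, specimen: LandmarkSet | np.ndarray,
            fit: bool = True) -> np.ndarray:
    """Project a specimen into an existing shape space.

    The specimen is first ordinary-Procrustes fitted onto the space's
    mean shape (translation, unit scaling, rotation, residual scale),
    then its deviation from the mean is expressed in the eigenbasis.
    The training space is not altered.
    """
    pts = specimen.points if isinstance(specimen, LandmarkSet) else \
        np.asarray(specimen, float)
    if pts.shape != space.landmark_shape:
        raise ValueError("specimen does not match the shape space template")
    if fit:
        pts = _ops_fit_to_mean(pts, space.mean_shape)
    dev = pts.ravel() - space.mean_shape.ravel()
    return dev @ space.eigenvectors


def nearest_neighbours(aligned: AlignedSample, specimen: LandmarkSet,
                       k: int = 5) -> list[tuple[str, float]]:
    """k nearest training specimens by full-Procrustes distance.

    Ties are broken by specimen-id order (stable sort on id after
    distance).  ``k`` larger than the sample is clamped with a warning.
    """
    n = len(aligned.specimens)
    if k > n:
        warnings.warn(f"k={k} exceeds sample size {n}; clamped",
                      stacklevel=2)
        k = n
    dists = [(s.specimen_id, procrustes_distance(specimen, s))
             for s in aligned.specimens]
    dists.sort(key=lambda t: (t[1], t[0]))
    return dists[:k]


def warp_along_pc(space: ShapeSpace, pc_index: int,
                  sd_multiple: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean shape warped ±m standard deviations along one PC.

    Returns the (+m, −m) pair in landmark layout; the standard
    deviation is the square root of that PC's eigenvalue.
    """
    if not (0 <= pc_index < len(space.eigenvalues)):
        raise ValueError("pc_index out of range")
    sd = np.sqrt(space.eigenvalues[pc_index])
    k = np.zeros(len(space.eigenvalues))
    k[pc_index] = sd_multiple * sd
    plus = space.reconstruct(k)
    minus = space.reconstruct(-k)
    return plus, minus


# ---------------------------------------------------------------------------
# permutation tests

def _pairwise_stat(scores: np.ndarray, mask_a: np.ndarray,
                   mask_b: np.ndarray) -> float:
    ca = scores[mask_a].mean(axis=0)
    cb = scores[mask_b].mean(axis=0)
    return float(np.sum((ca - cb) ** 2))


def permutation_test(scores: np.ndarray, labels: list[str],
                     group_a: str, group_b: str,
                     n_perm: int = 10_000,
                     seed: int | None = None) -> PermutationResult:
    """Permutation test for a group difference on PC scores.

    Statistic: squared Euclidean distance between group centroids in
    the score subspace (conventionally the first three PCs).  Labels
    are permuted without replacement; the p-value includes the observed
    statistic, ``p = (1 + #{perm ≥ obs}) / (n_perm + 1)``, so the
    smallest attainable value is ``1/(n_perm+1)``.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(labels)
    sel = np.isin(labels, [group_a, group_b])
    x = scores[sel]
    lab = labels[sel]
    na = int((lab == group_a).sum())
    nb = int((lab == group_b).sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two members")
    mask_a = lab == group_a
    obs = _pairwise_stat(x, mask_a, ~mask_a)
    rng = np.random.default_rng(seed)
    n = len(lab)
    total = x.sum(axis=0)
    count = 0
    # vectorized in chunks: each permutation assigns na rows to group A
    chunk = max(1, min(n_perm, 2_000_000 // max(1, na * x.shape[1])))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :na]
        ca = x[order].mean(axis=1)
        cb = (total - na * ca) / nb
        stat = np.sum((ca - cb) ** 2, axis=1)
        count += int(np.count_nonzero(stat >= obs))
        done += m
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(observed_stat=obs, n_permutations=n_perm,
                             p_value=p, seed=seed,
                             groups=(group_a, group_b))


def pairwise_permutation_tests(scores: np.ndarray, labels: list[str],
                               n_perm: int = 10_000,
                               seed: int | None = None
                               ) -> list[PermutationResult]:
    """All pairwise group contrasts, each with its own stream drawn
    from a single seed."""
    groups = sorted(set(labels))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * (len(groups) - 1) // 2)
    out = []
    ci = 0
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            sub_seed = int(children[ci].generate_state(1)[0] % (2 ** 31))
            out.append(permutation_test(scores, labels, a, b,
                                        n_perm=n_perm, seed=sub_seed))
            ci += 1
    return out


def select_pcs(space_or_eigvals, lo: float = 0.70,
               hi: float = 0.90) -> tuple[int, float, bool]:
    """Minimum number of PCs whose cumulative variance ratio reaches ``lo``.

    Returns ``(k, cumulative_ratio, exceeded_hi)``; ``exceeded_hi``
    flags the case where even the minimal k overshoots ``hi``.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    eig = space_or_eigvals.eigenvalues if isinstance(
        space_or_eigvals, ShapeSpace) else np.asarray(space_or_eigvals, float)
    ratios = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(ratios, lo - 1e-12) + 1)
    cum = float(ratios[k - 1])
    return k, cum, cum > hi


# ---------------------------------------------------------------------------
# QDA

def qda_loocv(scores: np.ndarray, labels: list[str],
              unknowns: np.ndarray | None = None,
              priors: np.ndarray | None = None) -> ClassificationResult:
    """Leave-one-out cross-validated quadratic discriminant analysis.

    Class-conditional Gaussian densities with class-specific covariance
    matrices (unbiased, n−1 denominator) and equal priors unless given.
    LOOCV refits means and covariances for every left-out case; unknown
    specimens are scored against the full-sample model, returning
    normalized posterior probabilities.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    k = scores.shape[1]
    for c in classes:
        nc = int((labels == c).sum())
        if nc < k + 2:
            raise ValueError(
                f"class {c!r} has {nc} members; needs at least {k + 2} for "
                f"an invertible covariance on {k} PCs")
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    # explicit invertibility check: shape scores are dimensionless and can
    # have legitimately tiny variances, so the test is on conditioning,
    # not on an absolute variance floor
    for c in classes:
        xc = scores[labels == c]
        cov = np.cov(xc.T, ddof=1).reshape(k, k)
        eig = np.linalg.eigvalsh(cov)
        if eig[0] <= 0 or eig[-1] / max(eig[0], 1e-300) > 1e12:
            raise ValueError(f"singular covariance matrix for class {c!r}")

    def fit(x, y):
        m = QuadraticDiscriminantAnalysis(priors=priors,
                                          store_covariance=True,
                                          tol=1e-30)
        m.fit(x, y)
        return m

    n = len(labels)
    preds = []
    loo_post = np.zeros((n, len(classes)))
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = fit(scores[mask], labels[mask])
        post = model.predict_proba(scores[i:i + 1])[0]
        # align to global class order (a left-out case cannot remove a
        # class entirely given the minimum-size precondition)
        row = dict(zip(model.classes_, post))
        loo_post[i] = [row.get(c, 0.0) for c in classes]
        preds.append(classes[int(np.argmax(loo_post[i]))])

    correct = np.asarray(preds) == labels
    by_group = {c: float(correct[labels == c].mean()) for c in classes}
    result = ClassificationResult(
        pcs_used=k,
        loocv_predictions=preds,
        loocv_accuracy_overall=float(correct.mean()),
        loocv_accuracy_by_group=by_group,
        classes=classes,
        loocv_posteriors=loo_post,
    )
    if unknowns is not None and len(unknowns):
        unknowns = np.atleast_2d(np.asarray(unknowns, float))
        full = fit(scores, labels)
        post = full.predict_proba(unknowns)
        order = [list(full.classes_).index(c) for c in classes]
        post = post[:, order]
        result.unknown_posteriors = post
        result.unknown_predictions = [classes[int(np.argmax(r))]
                                      for r in post]
    return result


# ---------------------------------------------------------------------------
# size descriptors

def size_series(teeth: list[tuple[str, float]],
                positions: tuple[str, ...] = ("M1", "M2", "M3"),
                rtol: float = 1e-9) -> tuple[str, dict[str, float]]:
    """Molar (or other) size pattern and log centroid sizes.

    Returns the inequality pattern string over the requested positions
    (e.g. ``"M1<M2>M3"``) and the natural log of centroid size per
    tooth.  Missing positions make the pattern indeterminate.
    """
    sizes = dict(teeth)
    log_sizes = {pos: float(np.log(cs)) for pos, cs in sizes.items()
                 if cs > 0}
    vals = []
    for pos in positions:
        if pos not in sizes:
            return "indeterminate", log_sizes
        vals.append(sizes[pos])
    parts = [positions[0]]
    for i in range(1, len(positions)):
        a, b = vals[i - 1], vals[i]
        if np.isclose(a, b, rtol=rtol, atol=0.0):
            op = "="
        elif a < b:
            op = "<"
        else:
            op = ">"
        parts.append(op)
        parts.append(positions[i])
    return "".join(parts), log_sizes


def standardize_by_geomean(area: float, linear_dims: list[float]) -> float:
    """Standardize an area by the squared geometric mean of linear dims.

    Dimensionless: invariant under uniform scaling of the specimen
    (area scales with k², the geometric mean with k).
    """
    dims = np.asarray(linear_dims, float)
    if np.any(dims <= 0):
        raise ValueError("linear dimensions must be positive")
    gm = float(np.exp(np.mean(np.log(dims))))
    return float(area / gm ** 2)
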