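"""Seeded synthetic-data generators with known ground truth.

Micro-CT-derived landmark data of fossil specimens cannot be shipped
with a software package, so every input class the analysis pipeline
consumes is emulated here with generators whose ground truth (group
effects, curve anchors, harmonic coefficients, ChRM directions,
polarity boundaries) is recorded alongside the output.  All
randomness flows through a single integer seed; fixed seed means
bit-reproducible output.

What is emulated: multi-group landmark samples as a template mean plus
group-specific deformations plus isotropic Gaussian landmark noise,
wrapped in nuisance similarity transforms; EDJ marginal-ridge loops
with Gaussian cusp bumps at dentine-horn positions and an elliptical
cervix; crown outlines as radial harmonic perturbations of a circle;
demagnetization series as a soft overprint plus a ChRM with Fisher-
distributed directional noise across a stratigraphic polarity
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkSet, TemplateDef
from .magstrat import DemagSpecimen, direction_to_vector
from .outline import OutlinePolygon
from .ridge import RidgeCurveRaw, N_ANCHORS

__all__ = [
    "SyntheticShapeSpec",
    "SyntheticDemagSpec",
    "gen_landmark_sample",
    "gen_ridge_and_cervix",
    "gen_outlines",
    "gen_demag_series",
    "random_rotation",
    "sample_fisher",
    "make_template",
]


# ---------------------------------------------------------------------------
# shared samplers

def random_rotation(rng: np.random.Generator, dim: int) -> np.ndarray:
    """Uniform (Haar) random proper rotation in 2 or 3 dimensions."""
    a = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sample_fisher(rng: np.random.Generator, mean_dir: np.ndarray,
                  kappa: float, n: int = 1) -> np.ndarray:
    """Draw unit vectors from a Fisher distribution on the sphere.

    Inverse-CDF sampling of the colatitude about the mean direction:
    for concentration κ, cos θ = 1 + log(u + (1-u)e^{-2κ}) / κ with
    u ~ U(0,1); azimuth uniform.
    """
    mean_dir = np.asarray(mean_dir, float)
    mean_dir = mean_dir / np.linalg.norm(mean_dir)
    u = rng.random(n)
    if kappa <= 0:
        cos_t = 1 - 2 * u
    else:
        cos_t = 1.0 + np.log(u + (1 - u) * np.exp(-2.0 * kappa)) / kappa
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = rng.random(n) * 2 * np.pi
    local = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t],
                     axis=1)
    # rotate local +z to the mean direction
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, mean_dir)
    c = float(np.dot(z, mean_dir))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                       [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return local @ rot.T


# ---------------------------------------------------------------------------
# landmark samples

@dataclass
class SyntheticShapeSpec:
    """Recipe for a multi-group landmark sample with known truth."""

    template: TemplateDef
    mean_points: np.ndarray
    n_per_group: int = 20
    group_effects: dict[str, np.ndarray] = field(default_factory=dict)
    effect_size: float = 1.0
    noise_sd: float = 0.02
    rotation_nuisance: bool = True
    translation_range: float = 5.0
    log_scale_range: float = 0.5
    seed: int = 0


def _project_off_similarity(effect: np.ndarray,
                            mean: np.ndarray) -> np.ndarray:
    """Remove translation / rotation / scaling modes from an effect field.

    The tangent directions of the similarity group at the mean shape
    are spanned by the uniform translations, the infinitesimal
    rotations, and the radial scaling of the centred mean; projecting
    the effect off that span makes "effect size" pure shape change.
    """
    k, dim = mean.shape
    c = mean - mean.mean(axis=0)
    basis = []
    for d in range(dim):
        t = np.zeros((k, dim))
        t[:, d] = 1.0
        basis.append(t.ravel())
    basis.append(c.ravel())  # scaling mode
    if dim == 2:
        rot = np.stack([-c[:, 1], c[:, 0]], axis=1)
        basis.append(rot.ravel())
    else:
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            basis.append(np.cross(np.broadcast_to(e, c.shape), c).ravel())
    b = np.stack(basis, axis=1)
    q, _ = np.linalg.qr(b)
    flat = effect.ravel()
    flat = flat - q @ (q.T @ flat)
    return flat.reshape(k, dim)


def gen_landmark_sample(spec: SyntheticShapeSpec
                        ) -> tuple[list[LandmarkSet], dict]:
    """Generate a grouped landmark sample with recorded ground truth.

    Each specimen is mean + its group's effect (orthogonalized against
    similarity modes and scaled by ``effect_size``) + isotropic
    Gaussian noise, then hit with a random similarity nuisance
    transform (rotation, translation, log-uniform scale).
    """
    rng = np.random.default_rng(spec.seed)
    mean = np.asarray(spec.mean_points, float)
    k, dim = mean.shape
    groups = list(spec.group_effects) or ["all"]
    effects = {}
    for g in groups:
        raw = spec.group_effects.get(g, np.zeros_like(mean))
        eff = _project_off_similarity(np.asarray(raw, float), mean)
        norm = np.linalg.norm(eff)
        if norm > 0:
            eff = eff / norm * spec.effect_size
        effects[g] = eff
    specimens = []
    labels = []
    for g in groups:
        for i in range(spec.n_per_group):
            pts = mean + effects[g] + rng.standard_normal((k, dim)) * spec.noise_sd
            if spec.rotation_nuisance:
                pts = pts @ random_rotation(rng, dim).T
            scale = np.exp(rng.uniform(-spec.log_scale_range,
                                       spec.log_scale_range))
            shift = rng.uniform(-spec.translation_range,
                                spec.translation_range, dim)
            pts = pts * scale + shift
            specimens.append(LandmarkSet(
                specimen_id=f"{g}_{i:03d}", points=pts,
                template_id=spec.template.template_id))
            labels.append(g)
    truth = {"labels": labels, "effects": effects, "mean": mean,
             "seed": spec.seed}
    return specimens, truth


def make_template(template_id: str, n_landmarks: int, dim: int,
                  bilateral: bool = False) -> tuple[TemplateDef, np.ndarray]:
    """Convenience template + mean configuration for simulations.

    Without ``bilateral`` the mean is a deterministic quasi-random blob;
    with it, landmarks come in mirror pairs about the x=0 plane plus a
    midline chain, mimicking a mandibular dataset.
    """
    rng = np.random.default_rng(abs(hash(template_id)) % (2 ** 31))
    if not bilateral:
        pts = rng.standard_normal((n_landmarks, dim))
        tpl = TemplateDef(template_id=template_id, dim=dim,
                          landmark_labels=[f"lm{i}" for i in range(n_landmarks)])
        return tpl, pts
    n_pairs = n_landmarks // 3
    n_mid = n_landmarks - 2 * n_pairs
    right = rng.standard_normal((n_pairs, dim))
    right[:, 0] = np.abs(right[:, 0]) + 0.2
    left = right.copy()
    left[:, 0] = -left[:, 0]
    midline = rng.standard_normal((n_mid, dim))
    midline[:, 0] = 0.0
    pts = np.vstack([left, right, midline])
    labels = ([f"L{i}" for i in range(n_pairs)]
              + [f"R{i}" for i in range(n_pairs)]
              + [f"M{i}" for i in range(n_mid)])
    tpl = TemplateDef(
        template_id=template_id, dim=dim, landmark_labels=labels,
        bilateral_pairs=[(i, n_pairs + i) for i in range(n_pairs)],
        midline=list(range(2 * n_pairs, n_landmarks)))
    return tpl, pts


# ---------------------------------------------------------------------------
# EDJ curves

def gen_ridge_and_cervix(tooth_class: str,
                         horn_heights: np.ndarray | None = None,
                         noise: float = 0.0,
                         seed: int = 0,
                         n_ridge_points: int = 120,
                         n_cervix_points: int = 80,
                         specimen_id: str = "synthetic"
                         ) -> RidgeCurveRaw:
    """Synthetic EDJ marginal ridge and cervix for one tooth.

    The marginal ridge is a closed 3D loop: an ellipse in plan view
    whose height profile carries Gaussian bumps (dentine horns) at
    fixed parameter positions; bump maxima are exported as the anchor
    landmarks.  The cervix is a planar-ish ellipse below the ridge
    whose first point is the start anchor.  ``noise`` perturbs the
    digitized points (simulating digitization error) but never the
    anchors' presence.
    """
    n_anchors = N_ANCHORS.get(tooth_class)
    if n_anchors is None:
        raise ValueError(f"unknown tooth class {tooth_class!r}")
    if horn_heights is None:
        horn_heights = 1.0 + 0.25 * np.arange(n_anchors) % 2
    horn_heights = np.asarray(horn_heights, float)
    if len(horn_heights) != n_anchors:
        raise ValueError(f"{tooth_class} needs {n_anchors} horn heights")
    rng = np.random.default_rng(seed)
    # horn parameter positions, spread around the loop
    horn_params = np.linspace(0.0, 2 * np.pi, n_anchors, endpoint=False) + 0.4
    if np.any(np.diff(horn_params) <= 0):
        raise ValueError("horn positions must be increasing")

    def ridge(theta):
        theta = np.atleast_1d(theta)
        x = 5.0 * np.cos(theta)
        y = 3.5 * np.sin(theta)
        z = np.full_like(theta, 2.0)
        for hp, hh in zip(horn_params, horn_heights):
            d = np.angle(np.exp(1j * (theta - hp)))
            z = z + hh * np.exp(-0.5 * (d / 0.35) ** 2)
        return np.stack([x, y, z], axis=1)

    theta = np.linspace(0.0, 2 * np.pi, n_ridge_points, endpoint=False)
    # make sure the horn apices are sampled exactly so anchors lie on the
    # digitized polyline
    theta = np.sort(np.concatenate([theta, horn_params]))
    ridge_pts = ridge(theta)
    ridge_pts = np.vstack([ridge_pts, ridge_pts[:1]])  # close the loop
    anchors = ridge(horn_params)
    if noise > 0:
        jitter = rng.standard_normal(ridge_pts.shape) * noise
        jitter[-1] = jitter[0]
        anchor_idx = np.searchsorted(theta, horn_params)
        jitter[anchor_idx] = 0.0   # anchors stay on the curve
        ridge_pts = ridge_pts + jitter

    phi = np.linspace(0.0, 2 * np.pi, n_cervix_points, endpoint=False)
    cervix = np.stack([5.5 * np.cos(phi), 4.0 * np.sin(phi),
                       0.2 * np.sin(2 * phi)], axis=1)
    if noise > 0:
        cervix = cervix + rng.standard_normal(cervix.shape) * noise
    cervix = np.vstack([cervix, cervix[:1]])
    return RidgeCurveRaw(specimen_id=specimen_id, tooth_class=tooth_class,
                         dentine_horn_anchors=anchors,
                         ridge_points=ridge_pts, cervix_points=cervix)


# ---------------------------------------------------------------------------
# crown outlines

def gen_outlines(group_harmonics: dict[str, dict[int, float]],
                 n_per_group: int = 20, noise: float = 0.01,
                 seed: int = 0, n_vertices: int = 360,
                 base_radius: float = 1.0
                 ) -> tuple[list[OutlinePolygon], dict]:
    """Synthetic crown outlines as harmonic perturbations of a circle.

    r(θ) = base·(1 + Σ_k a_k cos(kθ + φ_k)); each group carries fixed
    harmonic amplitude offsets (``group_harmonics[group][k] = a_k``),
    specimens add Gaussian amplitude noise on harmonics 2..5.  Phases
    are fixed at zero so the group effect is purely in amplitude.
    Parameters implying non-positive radius are rejected.
    """
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    out = []
    labels = []
    for g, harm in group_harmonics.items():
        for i in range(n_per_group):
            r = np.full_like(theta, base_radius)
            for k, a in harm.items():
                r = r + base_radius * a * np.cos(k * theta)
            for k in range(2, 6):
                r = r + base_radius * noise * rng.standard_normal() * \
                    np.cos(k * theta + rng.random() * 2 * np.pi)
            if np.any(r <= 0):
                raise ValueError("harmonic amplitudes yield non-positive "
                                 "radius; reduce them")
            verts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
            out.append(OutlinePolygon(specimen_id=f"{g}_{i:03d}",
                                      vertices=verts, side="left",
                                      group_label=g))
            labels.append(g)
    truth = {"labels": labels, "harmonics": group_harmonics, "seed": seed}
    return out, truth


# ---------------------------------------------------------------------------
# demagnetization series

@dataclass
class SyntheticDemagSpec:
    """Recipe for a stratigraphic series of demagnetization records."""

    true_declination: float = 5.0
    true_inclination: float = 45.0
    overprint_declination: float = 350.0
    overprint_inclination: float = 60.0
    overprint_removal_level: float = 300.0
    overprint_fraction: float = 0.6    # of NRM intensity
    step_levels: np.ndarray = field(
        default_factory=lambda: np.array(
            [20, 100, 150, 200, 250, 300, 350, 400, 450, 500, 550, 600,
             650, 690], float))
    fisher_kappa: float = 100.0
    step_noise_kappa: float = np.inf   # per-step measurement noise
    site_latitude: float = 33.6
    site_longitude: float = 352.4
    seed: int = 0


def gen_demag_series(spec: SyntheticDemagSpec, heights: np.ndarray,
                     boundary_height: float
                     ) -> tuple[list[DemagSpecimen], dict]:
    """Generate demagnetization records across a polarity boundary.

    Specimens below ``boundary_height`` carry the antipode of the true
    ChRM direction (reverse polarity), those above the true direction
    (normal).  Each record is the sum of a soft overprint, fully
    removed above ``overprint_removal_level``, and a ChRM component
    decaying linearly to zero at the final step; the per-specimen ChRM
    direction is Fisher-distributed about its polarity's mean with
    concentration ``fisher_kappa``.
    """
    heights = np.asarray(heights, float)
    if heights.size == 0:
        raise ValueError("heights must be non-empty")
    rng = np.random.default_rng(spec.seed)
    levels = np.asarray(spec.step_levels, float)
    lmax = levels[-1]
    d_n = direction_to_vector(spec.true_declination, spec.true_inclination)
    d_over = direction_to_vector(spec.overprint_declination,
                                 spec.overprint_inclination)
    out = []
    truth_dirs = []
    for j, h in enumerate(heights):
        normal = h >= boundary_height
        mean_dir = d_n if normal else -d_n
        if np.isinf(spec.fisher_kappa):
            chrm_dir = mean_dir
        else:
            chrm_dir = sample_fisher(rng, mean_dir, spec.fisher_kappa, 1)[0]
        truth_dirs.append(chrm_dir)
        # component intensity profiles along the treatment axis
        chrm_amp = np.clip(1.0 - levels / lmax, 0.0, None)
        over_amp = spec.overprint_fraction * np.clip(
            1.0 - levels / spec.overprint_removal_level, 0.0, None)
        vecs = (chrm_amp[:, None] * chrm_dir[None, :]
                + over_amp[:, None] * d_over[None, :])
        if np.isfinite(spec.step_noise_kappa):
            # per-step directional measurement noise at fixed intensity
            for si in range(len(vecs)):
                norm = np.linalg.norm(vecs[si])
                if norm > 0:
                    vecs[si] = norm * sample_fisher(
                        rng, vecs[si] / norm, spec.step_noise_kappa, 1)[0]
        out.append(DemagSpecimen(
            specimen_id=f"pm{j:03d}",
            site_latitude=spec.site_latitude,
            site_longitude=spec.site_longitude,
            stratigraphic_height=float(h),
            treatment_levels=levels,
            vectors=vecs))
    truth = {"boundary_height": float(boundary_height),
             "chrm_directions": np.asarray(truth_dirs),
             "normal_direction": d_n, "seed": spec.seed}
    return out, truth
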