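"""Paleomagnetic directional analysis and magnetostratigraphy.

Stepwise (thermal or AF) demagnetization of an oriented sample traces
a path of vector endpoints; the characteristic remanent magnetization
(ChRM) is the straight-line trend of the stable segment, fitted by
principal-component (least-squares) analysis of the endpoints, with
the maximum angular deviation (MAD) quantifying scatter about the
line.  Where no stable endpoint is reached, a great circle through the
step *directions* constrains the ChRM orientation.  Under a
geocentric axial dipole (GAD), a site direction (D, I) maps to a
virtual geomagnetic pole (VGP); the sign of the VGP latitude encodes
polarity, and a stratigraphic series of VGP latitudes yields a
polarity column with reversal boundaries.

Conventions: declination in degrees clockwise from geographic north,
inclination positive downward; magnetization vectors are (north, east,
down) components in geographic coordinates, arbitrary intensity units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemagSpecimen",
    "ChRMFit",
    "VGPResult",
    "PolarityZone",
    "direction_to_vector",
    "vector_to_direction",
    "fit_chrm",
    "fit_great_circle",
    "vgp_from_direction",
    "expected_gad_direction",
    "polarity_column",
    "best_mad_range",
]

DEFAULT_POLARITY_THRESHOLD = 45.0


@dataclass
class DemagSpecimen:
    """Stepwise demagnetization record for one oriented sample."""

    specimen_id: str
    site_latitude: float
    site_longitude: float
    stratigraphic_height: float
    treatment_levels: np.ndarray      # strictly increasing (°C or mT)
    vectors: np.ndarray               # (n_steps, 3): north, east, down

    def __post_init__(self) -> None:
        self.treatment_levels = np.asarray(self.treatment_levels, float)
        self.vectors = np.asarray(self.vectors, float)
        if len(self.treatment_levels) < 3:
            raise ValueError("need at least 3 demagnetization steps")
        if np.any(np.diff(self.treatment_levels) <= 0):
            raise ValueError("treatment levels must be strictly increasing")
        if self.vectors.shape != (len(self.treatment_levels), 3):
            raise ValueError("vectors must be (n_steps, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("magnetization vectors must be finite")


@dataclass
class ChRMFit:
    specimen_id: str
    declination: float        # degrees [0, 360)
    inclination: float        # degrees [-90, 90]
    mad: float                # degrees
    anchored: bool
    step_range: tuple[int, int]
    n_steps_used: int
    stable: bool = True

    @property
    def direction_vector(self) -> np.ndarray:
        return direction_to_vector(self.declination, self.inclination)


@dataclass
class VGPResult:
    vgp_latitude: float
    vgp_longitude: float
    polarity: str             # normal | reverse | intermediate


@dataclass
class PolarityZone:
    polarity: str
    height_bottom: float
    height_top: float
    n_specimens: int
    excursional: bool = False


def direction_to_vector(dec: float, inc: float) -> np.ndarray:
    """Unit (north, east, down) vector from declination/inclination."""
    d, i = np.deg2rad(dec), np.deg2rad(inc)
    return np.array([np.cos(i) * np.cos(d),
                     np.cos(i) * np.sin(d),
                     np.sin(i)])


def vector_to_direction(v: np.ndarray) -> tuple[float, float]:
    """(declination, inclination) in degrees from an (N, E, D) vector."""
    n, e, d = np.asarray(v, float)
    h = np.hypot(n, e)
    dec = float(np.degrees(np.arctan2(e, n)) % 360.0)
    inc = float(np.degrees(np.arctan2(d, h)))
    return dec, inc


# ---------------------------------------------------------------------------
# line and plane fits

def fit_chrm(spec: DemagSpecimen, step_range: tuple[int, int] | None = None,
             anchored: bool = False) -> ChRMFit:
    """Least-squares ChRM direction from vector endpoints.

    Principal-component fit: the direction is the leading eigenvector of
    the endpoint second-moment matrix about the endpoint centroid (or
    about the origin if ``anchored``).  The sign is chosen so the
    direction points along the magnetization being removed, i.e. from
    the high-treatment end of the segment toward the low-treatment end.
    MAD = arctan sqrt((λ2 + λ3) / λ1), in degrees.
    """
    lo, hi = (0, len(spec.treatment_levels) - 1) if step_range is None \
        else step_range
    pts = spec.vectors[lo:hi + 1]
    if len(pts) < 3:
        raise ValueError("need at least 3 steps in the fit range")
    if anchored:
        x = pts
    else:
        x = pts - pts.mean(axis=0)
    moment = x.T @ x
    eigvals, eigvecs = np.linalg.eigh(moment)     # ascending
    lam = eigvals[::-1]
    v = eigvecs[:, -1]
    stable = True
    if lam[0] <= 0 or (lam[1] / lam[0]) > 0.99:
        stable = False   # isotropic scatter: line orientation unreliable
    # orient along demagnetization decay: low-treatment endpoint minus
    # high-treatment endpoint
    trend = pts[0] - pts[-1]
    if np.dot(v, trend) < 0:
        v = -v
    dec, inc = vector_to_direction(v)
    with np.errstate(invalid="ignore"):
        mad = float(np.degrees(np.arctan(
            np.sqrt(max(lam[1] + lam[2], 0.0) / lam[0]))))
    return ChRMFit(specimen_id=spec.specimen_id, declination=dec,
                   inclination=inc, mad=mad, anchored=anchored,
                   step_range=(lo, hi), n_steps_used=len(pts),
                   stable=stable)


def fit_great_circle(spec: DemagSpecimen,
                     step_range: tuple[int, int] | None = None) -> np.ndarray:
    """Best-fit great circle through the step *directions*.

    Returns the unit normal of the plane (the circle's pole): the minor
    eigenvector of the second-moment matrix of the unit direction
    vectors.  Used to constrain the ChRM qualitatively when no stable
    endpoint is reached.
    """
    lo, hi = (0, len(spec.treatment_levels) - 1) if step_range is None \
        else step_range
    pts = spec.vectors[lo:hi + 1]
    if len(pts) < 3:
        raise ValueError("need at least 3 steps in the fit range")
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-intensity step in range")
    units = pts / norms[:, None]
    moment = units.T @ units
    _eigvals, eigvecs = np.linalg.eigh(moment)
    normal = eigvecs[:, 0]
    nz = np.nonzero(np.abs(normal) > 1e-12)[0]
    if nz.size and normal[nz[0]] < 0:
        normal = -normal
    return normal


def best_mad_range(spec: DemagSpecimen, min_steps: int = 4,
                   anchored: bool = False) -> ChRMFit:
    """Exhaustive helper: the step range (≥ min_steps) minimizing MAD."""
    n = len(spec.treatment_levels)
    best = None
    for lo in range(0, n - min_steps + 1):
        for hi in range(lo + min_steps - 1, n):
            fit = fit_chrm(spec, (lo, hi), anchored=anchored)
            if best is None or fit.mad < best.mad:
                best = fit
    return best


# ---------------------------------------------------------------------------
# VGP and polarity

def vgp_from_direction(dec: float, inc: float, site_lat: float,
                       site_lon: float,
                       threshold: float = DEFAULT_POLARITY_THRESHOLD
                       ) -> VGPResult:
    """Virtual geomagnetic pole from a site direction under a GAD field.

    The magnetic colatitude p follows from the dipole equation
    tan I = 2 cot p; the pole is found by moving p along azimuth D
    from the site on the unit sphere (standard spherical-triangle
    construction).  Positive VGP latitudes beyond the threshold are
    normal polarity, negative ones reverse, the rest intermediate.
    """
    if not -90.0 <= inc <= 90.0:
        raise ValueError("inclination must be within [-90, 90] degrees")
    lam_s = np.deg2rad(site_lat)
    phi_s = np.deg2rad(site_lon)
    d = np.deg2rad(dec)
    i = np.deg2rad(inc)
    p = np.arctan2(2.0, np.tan(i))          # magnetic colatitude in (0, pi)
    sin_lat_p = np.clip(np.sin(lam_s) * np.cos(p)
                        + np.cos(lam_s) * np.sin(p) * np.cos(d), -1.0, 1.0)
    lam_p = np.arcsin(sin_lat_p)
    sin_beta = np.clip(np.sin(p) * np.sin(d) / max(np.cos(lam_p), 1e-300),
                       -1.0, 1.0)
    beta = np.arcsin(sin_beta)
    if np.cos(p) >= np.sin(lam_s) * sin_lat_p:
        phi_p = phi_s + beta
    else:
        phi_p = phi_s + np.pi - beta
    vlat = float(np.degrees(lam_p))
    vlon = float(np.degrees(phi_p) % 360.0)
    if vlat >= threshold:
        pol = "normal"
    elif vlat <= -threshold:
        pol = "reverse"
    else:
        pol = "intermediate"
    return VGPResult(vgp_latitude=vlat, vgp_longitude=vlon, polarity=pol)


def expected_gad_direction(pole_lat: float, pole_lon: float,
                           site_lat: float, site_lon: float
                           ) -> tuple[float, float]:
    """Inverse mapping: (D, I) expected at a site for a given pole.

    Used for round-trip checks of the VGP construction.
    """
    lam_s, phi_s = np.deg2rad(site_lat), np.deg2rad(site_lon)
    lam_p, phi_p = np.deg2rad(pole_lat), np.deg2rad(pole_lon)
    cos_p = (np.sin(lam_s) * np.sin(lam_p)
             + np.cos(lam_s) * np.cos(lam_p) * np.cos(phi_p - phi_s))
    p = np.arccos(np.clip(cos_p, -1.0, 1.0))
    inc = np.degrees(np.arctan2(2.0 * np.cos(p), np.sin(p)))
    sin_d = np.cos(lam_p) * np.sin(phi_p - phi_s) / max(np.sin(p), 1e-300)
    cos_d = (np.sin(lam_p) - np.sin(lam_s) * np.cos(p)) / max(
        np.cos(lam_s) * np.sin(p), 1e-300)
    dec = np.degrees(np.arctan2(sin_d, cos_d)) % 360.0
    return float(dec), float(inc)


def polarity_column(heights: np.ndarray, vgp_latitudes: np.ndarray,
                    specimen_ids: list[str] | None = None,
                    threshold: float = DEFAULT_POLARITY_THRESHOLD,
                    min_zone_specimens: int = 2) -> list[PolarityZone]:
    """Stratigraphic polarity zonation from VGP latitudes.

    Specimens are ordered by height (sorted with a warning if not);
    contiguous runs of equal polarity merge into zones whose boundaries
    sit at the midpoint between the bracketing opposite-polarity
    specimens.  Intermediate samples are reported as their own
    (excursional) intervals; zones thinner than ``min_zone_specimens``
    are flagged excursional.
    """
    heights = np.asarray(heights, float)
    vgp_latitudes = np.asarray(vgp_latitudes, float)
    if specimen_ids is None:
        specimen_ids = [f"s{i}" for i in range(len(heights))]
    if np.any(np.diff(heights) < 0):
        warnings.warn("heights not sorted; sorting by height",
                      stacklevel=2)
    order = np.lexsort((np.asarray(specimen_ids), heights))
    h = heights[order]
    v = vgp_latitudes[order]

    def pol(lat: float) -> str:
        if lat >= threshold:
            return "normal"
        if lat <= -threshold:
            return "reverse"
        return "intermediate"

    pols = [pol(x) for x in v]
    zones: list[PolarityZone] = []
    start = 0
    for i in range(1, len(pols) + 1):
        if i == len(pols) or pols[i] != pols[start]:
            n_in = i - start
            bottom = h[start] if start == 0 else 0.5 * (h[start - 1] + h[start])
            top = h[i - 1] if i == len(pols) else 0.5 * (h[i - 1] + h[i])
            zones.append(PolarityZone(
                polarity=pols[start], height_bottom=float(bottom),
                height_top=float(top), n_specimens=n_in,
                excursional=(n_in < min_zone_specimens
                             or pols[start] == "intermediate")))
            start = i
    return zones
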