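"""Enamel-dentine junction (EDJ) ridge and cervix semilandmarks.

The EDJ marginal ridge is digitized as an ordered sequence of 3D points
starting at the protoconid dentine horn and running lingually; the
cervix (cemento-enamel junction) is digitized as a closed loop.  To
make these curves comparable across teeth, a cubic spline is fitted
through the digitized points, split into sections at the dentine-horn
anchors (two sections for premolars, four for molars), and each
section is resampled with a fixed number of equidistant (arc-length)
semilandmarks: 20 and 25 for premolars; 18, 15, 22 and 12 for molars.
The printed counts are interior points — the bounding dentine horns
are kept as separate anatomical landmarks.

The cervix loop is resampled as ``n`` equidistant points starting at
its start anchor (mid-face of the protocone/protoconid base for
premolars, mesiobuccal corner below the protoconid for molars).  No
count is fixed for the cervix; the default here is 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import make_interp_spline
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "SECTION_COUNTS",
    "RidgeCurveRaw",
    "SmoothCurve",
    "fit_smooth_curve",
    "split_at_anchors",
    "resample_sections",
    "resample_cervix",
    "build_edj_semilandmarks",
]

# interior semilandmarks per inter-horn section, by tooth class
SECTION_COUNTS: dict[str, tuple[int, ...]] = {
    "premolar": (20, 25),
    "molar": (18, 15, 22, 12),
    "dm1": (18, 15, 22, 12),
    "dm2": (18, 15, 22, 12),
}

# dentine-horn anchors bounding the sections, in digitization order
N_ANCHORS = {"premolar": 2, "molar": 4, "dm1": 4, "dm2": 4}

DEFAULT_CERVIX_COUNT = 30


@dataclass
class RidgeCurveRaw:
    """Raw digitized EDJ curves for one tooth.

    ``ridge_points`` is the ordered marginal-ridge polyline beginning at
    the protoconid and moving lingually; ``dentine_horn_anchors`` are
    the horn tips in traversal order (they must lie on the ridge
    polyline); ``cervix_points`` is a closed loop whose first point is
    the start anchor.
    """

    specimen_id: str
    tooth_class: str
    dentine_horn_anchors: np.ndarray
    ridge_points: np.ndarray
    cervix_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tooth_class not in SECTION_COUNTS:
            raise ValueError(f"unknown tooth class {self.tooth_class!r}")
        self.dentine_horn_anchors = np.asarray(self.dentine_horn_anchors, float)
        self.ridge_points = np.asarray(self.ridge_points, float)
        if self.cervix_points is not None:
            self.cervix_points = np.asarray(self.cervix_points, float)
        n_exp = N_ANCHORS[self.tooth_class]
        if len(self.dentine_horn_anchors) != n_exp:
            raise ValueError(
                f"{self.tooth_class} needs {n_exp} dentine-horn anchors, "
                f"got {len(self.dentine_horn_anchors)}")


class SmoothCurve:
    """Interpolating cubic spline with accurate arc-length queries."""

    def __init__(self, points: np.ndarray, closed: bool = False):
        points = np.asarray(points, float)
        keep = np.ones(len(points), bool)
        keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12
        points = points[keep]
        if closed:
            if np.linalg.norm(points[0] - points[-1]) > 1e-9 * max(
                    1.0, np.abs(points).max()):
                raise ValueError("closed curve: first and last points must "
                                 "coincide")
            if np.linalg.norm(points[0] - points[-1]) > 0:
                points = np.vstack([points[:-1], points[0]])
        if len(points) < 4:
            raise ValueError("need at least 4 distinct points for a cubic "
                             "spline")
        t = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(points, axis=0), axis=1))])
        self.closed = closed
        self.knots = t
        if closed:
            self._spl = make_interp_spline(t, points, k=3, bc_type="periodic")
        else:
            self._spl = make_interp_spline(t, points, k=3)
        self._dspl = self._spl.derivative()
        self.tmax = float(t[-1])
        # cumulative arc length at a fine parameter grid (monotone; used
        # to bracket roots of s(t) = target)
        ng = max(20 * len(points), 400)
        self._tg = np.linspace(0.0, self.tmax, ng)
        speeds = np.linalg.norm(np.atleast_2d(self._dspl(self._tg)), axis=1)
        self._sg = np.concatenate([[0.0], np.cumsum(
            0.5 * (speeds[1:] + speeds[:-1]) * np.diff(self._tg))])

    def point(self, t):
        return np.asarray(self._spl(np.asarray(t) % self.tmax
                                    if self.closed else t), float)

    def _speed(self, t: float) -> float:
        return float(np.linalg.norm(self._dspl(t)))

    def arc_length(self, t0: float = 0.0, t1: float | None = None) -> float:
        """Arc length between parameters, by adaptive Gauss quadrature."""
        if t1 is None:
            t1 = self.tmax
        brk = self.knots[(self.knots > t0) & (self.knots < t1)] \
            if t1 > t0 else np.empty(0)
        val, _err = quad(self._speed, t0, t1,
                         limit=max(200, 4 * len(brk) + 50),
                         epsabs=1e-12, epsrel=1e-10,
                         points=list(brk) if len(brk) else None)
        return float(val)

    @property
    def length(self) -> float:
        return self.arc_length(0.0, self.tmax)

    def param_at_arclength(self, s: float, t0: float = 0.0) -> float:
        """Parameter t with arc_length(t0, t) == s, by monotone root-finding."""
        if s <= 0:
            return t0
        s0 = float(np.interp(t0, self._tg, self._sg))
        target = s0 + s
        if target >= self._sg[-1] - 1e-12:
            return self.tmax
        t_guess = float(np.interp(target, self._sg, self._tg))

        def f(t):
            return self.arc_length(t0, t) - s

        lo, hi = t0, self.tmax
        span = max(self.tmax * 1e-3, 1e-9)
        a, b = max(lo, t_guess - span), min(hi, t_guess + span)
        fa, fb = f(a), f(b)
        while fa > 0 and a > lo:
            a = max(lo, a - span); fa = f(a); span *= 2
        while fb < 0 and b < hi:
            b = min(hi, b + span); fb = f(b); span *= 2
        if fa == 0:
            return a
        if fb == 0:
            return b
        return float(brentq(f, a, b, xtol=1e-12))

    def project(self, p: np.ndarray) -> float:
        """Parameter of the nearest curve point to ``p``."""
        d = np.linalg.norm(np.atleast_2d(self._spl(self._tg)) - p, axis=1)
        i = int(np.argmin(d))
        h = self._tg[1] - self._tg[0]
        lo, hi = self._tg[i] - 2 * h, self._tg[i] + 2 * h
        if not self.closed:
            lo, hi = max(0.0, lo), min(self.tmax, hi)

        def fdist(t):
            tt = t % self.tmax if self.closed else t
            return float(np.sum((np.asarray(self._spl(tt)) - p) ** 2))

        res = minimize_scalar(fdist, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-13})
        return float(res.x % self.tmax if self.closed else res.x)


def fit_smooth_curve(points: np.ndarray, closed: bool = False) -> SmoothCurve:
    """Fit an interpolating cubic spline through ordered digitized points."""
    return SmoothCurve(points, closed=closed)


def split_at_anchors(curve: SmoothCurve, anchors: np.ndarray,
                     tol: float = 1e-6) -> list[tuple[float, float]]:
    """Split a curve at anchor landmarks; returns parameter intervals.

    Anchors must lie on the curve (within ``tol`` of the configuration
    scale) and be ordered along it.  The returned intervals partition
    [0, tmax] for an open curve; for a closed curve the first anchor
    also closes the last section.
    """
    anchors = np.asarray(anchors, float)
    scale = max(curve.length, 1e-30)
    params = []
    for a in anchors:
        t = curve.project(a)
        if np.linalg.norm(curve.point(t) - a) > tol * scale:
            raise ValueError(f"anchor {a} is not on the curve "
                             f"(distance exceeds {tol} of curve length)")
        params.append(t)
    params = sorted(params)
    if curve.closed:
        sections = [(params[i], params[(i + 1) % len(params)])
                    for i in range(len(params))]
    else:
        bounds = params
        if bounds[0] > 1e-9 * scale:
            bounds = [0.0] + bounds
        if bounds[-1] < curve.tmax - 1e-9 * scale:
            bounds = bounds + [curve.tmax]
        sections = list(zip(bounds[:-1], bounds[1:]))
    return sections


def _equidistant_interior(curve: SmoothCurve, t0: float, t1: float,
                          n: int) -> np.ndarray:
    """n interior points at equal arc spacing on [t0, t1] (endpoints excluded)."""
    if curve.closed and t1 <= t0:
        t1 = t1 + curve.tmax

    def par(t):
        return t % curve.tmax if curve.closed else t

    total = curve.arc_length(par(t0), curve.tmax) + curve.arc_length(0, par(t1)) \
        if (curve.closed and par(t1) < par(t0)) else curve.arc_length(par(t0), par(t1))
    step = total / (n + 1)
    pts = np.empty((n, curve.point(0.0).shape[-1]))
    t = par(t0)
    for i in range(n):
        remaining = step
        # walk across the closure point if needed
        t_new = curve.param_at_arclength(remaining, t0=t)
        if curve.closed and t_new >= curve.tmax - 1e-12:
            done = curve.arc_length(t, curve.tmax)
            t_new = curve.param_at_arclength(remaining - done, t0=0.0)
        t = t_new
        pts[i] = curve.point(t)
    return pts


def resample_sections(curve: SmoothCurve,
                      sections: list[tuple[float, float]],
                      tooth_class: str) -> list[np.ndarray]:
    """Equidistant semilandmarks per ridge section for a tooth class.

    Premolars carry (20, 25) interior semilandmarks on their two
    sections; molars (18, 15, 22, 12) on four.  Section endpoints (the
    dentine horns) are excluded — they remain anatomical landmarks.
    """
    if tooth_class not in SECTION_COUNTS:
        raise ValueError(f"unknown tooth class {tooth_class!r}")
    counts = SECTION_COUNTS[tooth_class]
    if len(sections) != len(counts):
        raise ValueError(
            f"{tooth_class} expects {len(counts)} sections, got "
            f"{len(sections)}")
    return [_equidistant_interior(curve, t0, t1, n)
            for (t0, t1), n in zip(sections, counts)]


def resample_cervix(cervix_points: np.ndarray, tooth_class: str,
                    n: int = DEFAULT_CERVIX_COUNT) -> np.ndarray:
    """Resample the closed cervix loop as n equidistant semilandmarks.

    The loop must be closed (first == last point within tolerance); the
    first output point is the start anchor (the loop's first vertex)
    and traversal preserves the input orientation.
    """
    cervix_points = np.asarray(cervix_points, float)
    scale = max(np.abs(cervix_points).max(), 1e-30)
    if np.linalg.norm(cervix_points[0] - cervix_points[-1]) > 1e-6 * scale:
        raise ValueError("cervix loop is not closed")
    curve = SmoothCurve(cervix_points, closed=True)
    total = curve.length
    step = total / n
    pts = np.empty((n, cervix_points.shape[1]))
    t = 0.0
    pts[0] = curve.point(0.0)
    for i in range(1, n):
        t = curve.param_at_arclength(step, t0=t)
        pts[i] = curve.point(t)
    return pts


def build_edj_semilandmarks(raw: RidgeCurveRaw,
                            cervix_n: int = DEFAULT_CERVIX_COUNT,
                            anchor_tol: float = 1e-6) -> dict:
    """Full resampling of one tooth: ridge sections plus cervix.

    Returns a dict with keys ``anchors``, ``ridge_sections`` (list of
    arrays), ``cervix`` (array or None), and ``all_points`` — anchors
    followed by ridge semilandmarks section by section, then cervix
    semilandmarks, matching the template ordering used downstream.
    """
    curve = fit_smooth_curve(raw.ridge_points, closed=True)
    sections = split_at_anchors(curve, raw.dentine_horn_anchors,
                                tol=anchor_tol)
    ridge = resample_sections(curve, sections, raw.tooth_class)
    cervix = None
    if raw.cervix_points is not None:
        cervix = resample_cervix(raw.cervix_points, raw.tooth_class,
                                 n=cervix_n)
    blocks = [raw.dentine_horn_anchors] + list(ridge)
    if cervix is not None:
        blocks.append(cervix)
    return {
        "anchors": raw.dentine_horn_anchors,
        "ridge_sections": ridge,
        "cervix": cervix,
        "all_points": np.vstack(blocks),
    }
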