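# Methods

This note documents the models, numerical choices and limitations of
the package, in the spirit of the methods documentation shipped with
statistical toolkits: what exactly is computed, which knobs matter, and
what the synthetic tests do and do not demonstrate about real data.

## Procrustes superimposition

GPA is implemented as *full* Procrustes with unit-size scaling: every
configuration is translated to centroid origin, scaled to centroid size
one, and rotated onto the current mean estimate; the mean is the
arithmetic average of the aligned configurations re-scaled to unit
centroid size. Rotations are solved by the SVD (Kabsch) construction
with the reflection branch excluded (`det R = +1`), so anatomical
chirality can never flip during alignment. Iteration stops when the
mean's RMS change falls below 1e-10 (at most 100 iterations; typical
samples converge in 2–5).

Two conventions deserve emphasis:

* **Scaling.** Partial Procrustes (no residual scaling) and full
  Procrustes (optimal per-specimen scaling) differ in the aligned
  residuals. This implementation fixes every specimen at exactly unit
  centroid size, and uses the full-Procrustes *distance*
  `d = sqrt(1 − ⟨x, yR⟩²)` between unit-size shapes for nearest
  neighbours. The choice is recorded here because published analyses
  rarely state it; both conventions give identical PCA orderings on the
  synthetic suites.
* **Gauge.** Procrustes alignment leaves one global rotation free. The
  output is canonicalized to the mean shape's principal axes with a
  deterministic sign rule (largest-magnitude coordinate per axis
  positive, weakest axis flipped if needed to keep `det = +1`), which
  makes GPA idempotent: re-aligning aligned output changes coordinates
  by less than 1e-8 RMS. The canonical frame is undefined when the
  mean has degenerate principal axes (exactly spherical scatter); no
  anatomical dataset is near that regime.

Ordinary (two-configuration) Procrustes fits, used when projecting a
fossil into an existing shape space, additionally apply the optimal
residual scale `β = ⟨m, x R⟩` so the fossil lands in the tangent-space
coordinates of the training mean.

## Thin-plate splines and sliding

The TPS interpolant uses the biharmonic kernels `U(r) = r² log r` (2D)
and `U(r) = r` (3D). The bordered kernel system is solved by a pivoted
dense factorization; source configurations with duplicate points
(within 1e-9 of the configuration scale) or rank-deficient geometry
are rejected rather than regularized. The bending energy is the
quadratic form `Σ_d y_dᵀ B y_d` where `B` is the upper-left block of
the inverse bordered system; the sign of the form is normalized per
dimension (the 3D kernel is conditionally negative definite) so that
bending energy is always ≥ 0 and vanishes exactly on affine maps.

Sliding follows the standard bending-energy formulation: per pass, the
Procrustes mean is recomputed, mapped into each specimen's raw frame
by an ordinary Procrustes fit, and the generalized-least-squares
displacement of the semilandmarks along their tangent directions —
one direction per curve point, two per surface point — is solved in
closed form from the normal equations `(Σ_d U_dᵀ B U_d) λ = −Σ_d U_dᵀ B
y_d`. Displaced semilandmarks are then projected back onto their curve
or surface. Because the projection is nonlinear it can eat part of the
tangential gain, so the step is damped (halved, up to 30 times) until
the post-projection energy does not exceed the pass's starting energy;
in practice the full step is almost always accepted. Two passes are
run by default, the mean being refreshed between them.

Tangents come from the geometry evaluators, not from finite
differences: curve evaluators fit an interpolating cubic spline
through the digitized polyline (chord-length parameterization,
periodic closure for loops) and return the analytic spline tangent at
the nearest-point parameter; surface evaluators estimate a local
tangent plane by PCA over the 8 nearest cloud samples. A single
bending-energy matrix couples all sliding landmarks of a specimen
(full-matrix sliding, not per-structure blocks).

## EDJ ridge and cervix resampling

The marginal ridge is treated as a closed loop starting at the
protoconid and running lingually. An interpolating cubic spline is
fitted through the digitized points; arc lengths are computed by
adaptive Gauss quadrature on the spline speed (spline knots passed as
integration break points), and equidistant placement solves the
monotone equation `s(t) = k·L/(n+1)` by bracketed root-finding to
1e-12. The dentine-horn landmarks split the loop into two (premolars)
or four (molars) sections; the printed per-section counts — 20 and 25
for premolars; 18, 15, 22 and 12 for molars — are *interior*
semilandmarks, the bounding horns remaining separate anatomical
landmarks. This reading follows from treating the horns as section
boundaries; a configuration flag could trivially switch to an
inclusive reading, which would change the totals from 45/67 to 43/59.

No count is published for the cervix; the default here is 30 closed
equidistant points starting at the tagged anchor. The choice affects
only how finely the cervix is sampled, not any algorithm, and is a
prominent configuration parameter.

Worn teeth with partial ridges are supported by masking sections in
the template rather than by a separate code path.

## Crown outlines

The area centroid is the polygon first moment over area (shoelace
form, via Shapely), independent of vertex orientation and of inserted
collinear vertices. Twenty-four rays leave the centroid at angles
`90° − k·15°` — the first buccal (+y), successive rays clockwise in
the left-tooth occlusal convention; right teeth are mirrored
(x ↦ −x, traversal reversed) before sampling. Where a ray crosses a
non-convex boundary several times the farthest intersection is taken;
molar crowns are near-convex so the rule rarely triggers, but it is
fixed and tested. Pseudolandmark configurations are centred and scaled
to unit centroid size with *no* rotation step, since orientation is
already standardized by the digitization convention; this makes the
coordinates sensitive to that convention by design, and the tests pin
the sensitivity rather than hide it.

## Shape statistics

PCA is the eigendecomposition of the covariance of flattened aligned
coordinates, computed via SVD with a deterministic sign convention
(largest-magnitude loading positive). Fossils are never part of the
training eigenbasis: they are ordinary-Procrustes-fitted to the
training mean and projected afterwards.

The permutation statistic is the squared Euclidean distance between
group centroids in the first-three-PC subspace, with labels permuted
without replacement and the observed statistic included in the count:
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, so p can never be zero and
the smallest attainable value is `1/(n_perm+1)`. With more than two
groups, all pairwise contrasts are run, each on an independent
substream of the master seed. The default 10,000 permutations match
standard practice; calibration suites use 999 for speed.

QDA fits class-conditional Gaussians with unbiased (n−1) covariances
and equal priors (both configurable); scikit-learn provides the
estimator, wrapped with a conditioning check that names the offending
class and with the absolute variance floor disabled — unit-size shape
coordinates legitimately produce variances far below generic software
defaults. Leave-one-out CV refits means and covariances for every
left-out case; unknowns are scored against the full-sample model. The
PC count is the smallest k with cumulative variance ≥ 0.70; if that k
overshoots 0.90 the case is flagged but k is still used, and both
numbers are reported.

## Paleomagnetic analysis

ChRM directions are principal-component line fits of the
demagnetization endpoints: leading eigenvector of the second-moment
matrix about the endpoint centroid (free fit) or the origin (anchored
fit; both exposed, free is the default as in vector end-point
practice), oriented along the demagnetization decay, with
`MAD = arctan sqrt((λ₂+λ₃)/λ₁)`. Near-isotropic scatter
(λ₂/λ₁ > 0.99) is flagged unstable rather than rejected. Great-circle
fits return the minor eigenvector of the unit-direction moment matrix.

VGP conversion uses the geocentric-axial-dipole construction: magnetic
colatitude from `tan I = 2 cot p`, pole position by the spherical
triangle from the site along azimuth D; declination is degrees
clockwise from north, inclination positive down. Polarity is assigned
from VGP latitude with a ±45° threshold (configurable; the choice of
threshold only matters for transitional directions). Zone boundaries
are midpoints between adjacent opposite-polarity specimens; zones with
fewer than two specimens, and all intermediate-direction intervals,
are flagged excursional rather than suppressed.

## Synthetic data: what it emulates and what it does not

The generators produce every input class with recorded ground truth:

* **Landmark samples** — template mean + per-group deformation +
  isotropic Gaussian landmark noise, wrapped in random similarity
  nuisances (Haar rotations, uniform translations, log-uniform scale).
  Group effects are projected off the similarity tangent space at the
  mean, so the nominal effect size is pure shape change. Defaults:
  20 specimens per group, noise s.d. 0.02 of configuration scale —
  comparable to digitization error relative to mandible size.
* **EDJ curves** — an elliptical ridge loop with Gaussian cusp bumps
  whose maxima are the dentine-horn anchors, and an elliptical,
  mildly non-planar cervix. Digitization noise perturbs curve points
  but anchors stay on the curve.
* **Crown outlines** — radial harmonic perturbations of a circle,
  `r(θ) = 1 + Σ a_k cos(kθ + φ_k)` with 360 vertices; group effects
  live in the low harmonic amplitudes.
* **Demagnetization series** — a soft overprint removed by 300 °C plus
  a ChRM decaying to zero at 690 °C, with Fisher-distributed
  specimen directions (inverse-CDF sampling) about the polarity mean,
  optional per-step measurement noise, and an antipodal flip below the
  stratigraphic boundary. Site coordinates default to a northwest
  African locality (33.6° N).

These generators produce smooth, unimodal, well-separated data. They
do not emulate correlated digitization error along curves, allometry,
missing-data patterns of real fossils, wear, overlapping group
distributions, or lightning/drilling overprints with unstable
directions. Passing recovery tests therefore demonstrates correctness
of the algorithms under their stated models, not performance on any
particular fossil assemblage.

## Problem sizes in the test and acceptance suites

The suites run on a single CPU: sliding monotonicity uses 50 (tests)
or 20 (script) three-specimen premolar samples with 80-point ridge
polylines; permutation calibration uses 500 null replicates of 999
permutations at n = 40; PC1 recovery uses 50 (tests) or 30 (script)
replicates of two 30-specimen groups on 20 landmarks; boundary
recovery uses 200 replicates of 21-specimen sections at Fisher
κ = 50. These sizes were chosen to keep Monte-Carlo noise well inside
the asserted bounds while the whole suite completes in about a minute.

## Known limitations

* Surface-semilandmark sliding is implemented and tested on synthetic
  clouds, but the shipped pipelines exercise curve sliding only.
* `symmetrize` iterates plane-fit/average to a fixed point; for
  grossly asymmetric configurations (beyond any biological case) the
  midplane estimate itself is ambiguous.
* The equidistant resampler assumes the digitized polyline is ordered
  and simple; it deduplicates repeated points but does not repair
  self-intersections.
* Polarity zonation reports boundaries at specimen midpoints; it does
  not interpolate VGP latitude crossings or attach numeric ages.
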