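# Methods

## Geometry and the least-squares vergence point

Coordinates are fixed package-wide: x horizontal, y up, z depth (away from
the observer); lengths in centimetres.  Eye centres sit at `(±a, 0, 0)`
with `2a` the interocular distance (default 6 cm) and are always derived
from it, never stored.  A gaze ray is an origin plus a unit direction; the
squared distance of a point to a ray is evaluated with the projector
`I − vvᵀ` of the ray direction.  The vergence point minimises the sum of
the two squared ray distances, i.e. solves `(E_l + E_r)x = E_l p_l + E_r p_r`.
The solve is a direct dense 3×3 `numpy.linalg.solve`; uniqueness holds
whenever the directions are not parallel, so no pseudo-inverse is used on
the non-degenerate path.  Directions with `|1 − |e_l·e_r|| < 1e−12` are
declared degenerate (the system's condition number explodes there);
degenerate draws return a flagged estimate rather than raising, so Monte
Carlo callers can count them.  Estimates behind the observer (z < 0) are
returned as-is and *included* in summary statistics: they are a real
feature of triangulation with diverging noisy rays and are the reason the
horizontal-dominant noise conditions are heavy-tailed.

## Noise model

Variable error is modelled per eye as `ε = (η, ν, 0)` with independent
zero-mean Gaussian horizontal and vertical components; systematic error as
a constant angular offset added to the same components.  User-facing units
are degrees; internally angles are converted to radians and added directly
to the unit gaze direction, followed by renormalisation.  For the angles
involved (≤ a few degrees) `sin φ ≈ φ`, so this is equivalent to rotating
the ray.  The error vector lies in the x–y plane rather than the plane
orthogonal to the ray; with targets near the z axis the difference is
O(a²/z²).  Offsets are added to the sampled components *before*
renormalisation (one combined ε per eye per draw).

Summary statistics over a Monte Carlo batch: mean point (arithmetic mean of
non-degenerate estimates), mean Euclidean error to the true target,
per-axis mean absolute deviations, and the sample standard deviations of
the same quantities.

Expected depth bias cannot be integrated in closed form for Gaussian noise
(the horizontal case even has a non-integrable pole where the rays turn
parallel), so expectations are always reported as Monte Carlo estimates.
Two regimes matter for interpretation:

* **vertical-dominant noise** — each sample's depth is bounded in (0, z],
  so the sample mean is stable; at σ_v = 1.5°, 6 cm interocular the
  simulated mean depth is ≈ 0.92·z (e.g. ≈ 46.2 cm for a 50 cm target).
* **horizontal-dominant noise** — the admissible-sample bias is away from
  the observer, but draws beyond the vergence angle produce estimates near
  ±∞ in depth; the expectation is formally divergent and the empirical mean
  is seed-sensitive.  Quantities from these conditions should be read as
  descriptive of one run, not as converged expectations.

## Closed-form paired bias ratios and their conventions

The closed forms in `bias_analytic` hold for the symmetric configuration
(target `(0,0,1)`, eyes `(±a,0,0)`) with the error applied as a lateral
displacement on the unit-depth plane, i.e. ray direction `(±a+η, ν, 1)`
before normalisation.  Under this *tangent-plane* convention the horizontal
(reversed-pair) and vertical (negated-pair) identities agree with the
solver to machine precision, and this is what the 1e−8 equivalence tests
assert.  Adding the same numbers to the *normalised* direction instead (the
simulation convention) agrees only to O(a²·error) — about 1e−3 relative at
a = 0.06 — which is negligible for simulated biases but not for exact
identities.  The two conventions are therefore kept deliberately distinct:
simulation uses unit-vector perturbation, the closed forms and their oracle
use tangent displacements.  Scaling the viewing distance is equivalent to
rescaling `a`, so the closed forms never need a general geometry.

## Fixation pipeline choices

* **Duration filter**: fixations shorter than 100 ms are removed; the
  boundary is strict, an exactly-100 ms fixation is kept (short fixations
  are predominantly undershoots followed by corrective saccades).
* **Outlier rule**: single pass per (observer, distance, condition, eye,
  target) cluster; a point is an outlier if its Euclidean distance from the
  cluster mean exceeds 2 pooled SDs, with the pooled SD defined as the
  square root of the summed per-axis variances (the RMS radial spread).
  The norm, the pooling and the single-shot character are recorded in the
  preprocessing metadata; clusters with fewer than two points skip the rule.
  The trim removes ≈ 2% of bivariate-Gaussian mass and therefore shaves a
  few percent off recovered variances — visible in the recovery tests.
* **Error ellipses**: 95% coverage ellipses with semi-axes `√(5.991·λᵢ)`
  (chi-square, 2 dof) and the orientation of the principal eigenvector.
* **Covariance distance**: the affine-invariant Riemannian metric
  `‖log(Σ₁^{−1/2} Σ₂ Σ₁^{−1/2})‖_F`, computed via eigendecomposition with a
  symmetrisation guard; inputs must be SPD (smallest eigenvalue > 1e−12,
  regularisation is the caller's concern).  Sets of covariances are
  aggregated by the element-wise arithmetic mean.
* **KS comparisons**: `scipy.stats.ks_2samp`; both the statistic and the
  p-value are reported, the significance flag uses the p-value at α = 0.05.
* **Pixel→degree conversion**: opposite ring targets subtend 14° of visual
  angle; the scale factor is 14° over the mean raw distance between
  opposite cluster centres.  The factor is uniform within a viewing
  distance but estimated *per distance*, because the pixel extent of a
  fixed visual angle grows with distance.
* **Covariance resampling**: a measured 2×2 covariance (possibly
  correlated) is rescaled so that the mean of its two marginal SDs equals a
  requested visual angle (1° or 2° typically), then used as the angular
  error covariance of both eyes.  This normalisation convention is a choice
  — "variance corresponding to 1°" is otherwise ambiguous — and is
  configurable at the call site.  With a diagonal covariance the sampler
  reproduces the independent-component path draw-for-draw.

## Synthetic experiment generator

The generator emulates a ring-target fixation study: 12 targets at 7°
eccentricity plus a centre target on a 0.52 m × 0.32 m, 1920 × 1200 px
display at 70 and 110 cm; four viewing conditions (ML, MR, BL, BR — the
analysis conditions of monocular/binocular viewing per eye); five
repetitions; each repetition presents every ring target once, preceded by a
centre fixation (24 visits).  Fixation counts per visit are
2 + Bernoulli(0.3), giving the target mean of 2.3 fixations per visit;
durations are log-normal with mean 821 ms and SD 494 ms (truncation floor
configurable, default none — at these parameters < 0.05% of draws fall
under 100 ms anyway).  Ring phase starts at 12 o'clock (the phase is not
identified by any statistic the pipeline computes).  Fixation positions are
the target pixel position plus Gaussian noise with the condition's 2×2
covariance in degrees², converted to pixels through the per-axis pixel
pitch and viewing distance.  Default covariances have marginal SDs of order
1° with vertical noise slightly dominant and the binocular conditions
tighter than the monocular ones; they are configuration, not constants.

What the generator does *not* emulate: saccade dynamics, drift,
undershoot/correction sequences, blinks, pupil-size-dependent errors,
spatially varying noise, or inter-observer heterogeneity beyond independent
noise draws.  Passing recovery tests therefore demonstrates that the
pipeline is self-consistent (generate → filter → convert → estimate
recovers the designed covariances within Wishart sampling error), not that
real eye-camera data obey the model.

## Averaging recipe

Both strategies draw k error pairs per trial: *average-then-estimate*
averages each eye's perturbed unit directions, renormalises and
triangulates once; *estimate-then-average* triangulates each pair and
averages the k points.  "Averaging raw samples" is implemented in direction
space — the analogue of averaging raw pupil−CR positions, equivalent under
the small-angle model.  Offsets are the mean over trials of the Euclidean
distance between the trial's (single or averaged) estimate and the target,
in cm.  Both strategies share the same error draws per k (paired seeds) so
their ordering is not masked by Monte Carlo noise.  Defaults: 2,000 trials;
the averaged-directions offset decays ≈ k^(−1/2) while the point-averaging
offset converges to the magnitude of the distribution's mean bias.

## Problem sizes and reproducibility

Monte Carlo batches default to n = 10,000 draws per condition (the
acceptance script uses exactly that); equivalence checks use 10,000 random
error pairs per closed form; metric-axiom checks use 1,000 random SPD
pairs; the pipeline-recovery test uses 8 observers × 5 repetitions
(≈ 90 fixations per target).  Every entry point takes an explicit seed and
derives independent substreams via `numpy.random.SeedSequence`, so all
outputs are reproducible bit-for-bit given the seed.

## Known limitations

* The depth-bias expectation under horizontal-dominant noise is divergent;
  reported means for those conditions are draw-dependent by construction.
* The closed forms cover only the two single-axis symmetric cases; mixed
  noise goes through the solver.
* The pixel grid and eye-camera quantisation are not modelled; raw units
  are treated as continuous.
* Binocular fixation disparity (a systematic per-eye gaze-direction
  difference) is outside the noise model; only zero-mean noise and constant
  offsets are represented.
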