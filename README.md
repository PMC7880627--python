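# vergence

Estimating a 3D point of regard from binocular eye-tracking data usually
means triangulating the two gaze rays: the rays rarely intersect, so the
point of regard is taken as the point with the smallest summed squared
distance to both lines of sight.  This package implements that estimator
and, more importantly, quantifies a property of it that matters for anyone
doing vergence or depth-from-gaze research: **under angular noise the mean
triangulated point is systematically biased in depth**, and the direction of
the bias depends on whether the noise is predominantly horizontal (bias away
from the observer) or vertical (bias toward the observer).

It is written for eye-tracking researchers who want to (a) propagate
realistic tracker noise through the triangulation, (b) analyse measured
fixation scatter with covariance statistics, and (c) design calibration
procedures that minimise the bias.

## The estimator and the bias

With eye centres `p_l = (-a, 0, 0)`, `p_r = (a, 0, 0)` and unit gaze
directions `e_l, e_r`, the squared distance of a point `x` to a gaze line is
`(x - p)^T E (x - p)` with the projector `E = I - e e^T`.  The vergence
point minimises the sum of the two squared distances and solves

    (E_l + E_r) x = E_l p_l + E_r p_r ,

a single 3×3 linear system (unique whenever the rays are not parallel).

Perturbing the gaze directions with per-eye angular errors
`ε = (η, ν, 0)` (horizontal η, vertical ν, small-angle radians) and pairing
each error instance with its symmetric counterpart gives closed forms for
the mean depth of the pair (target at unit depth):

    horizontal only:  z'/z = 4a² / (4a² − (η_l − η_r)²)  ≥ 1
    vertical only:    z'/z = (4a² + a²(ν_l + ν_r)²)
                             / ((ν_l − ν_r)² + 4a² + a²(ν_l + ν_r)²)  ≤ 1

so any centrally symmetric horizontal noise pushes the mean away from the
observer and any vertical noise pulls it toward the observer.  The package
verifies both forms against the solver to 1e−8 and propagates full noise
distributions by Monte Carlo.

The practical consequence: averaging *triangulated points* across fixations
cannot remove this bias, but averaging the *raw gaze samples* first and
triangulating once can.  The `recipe` module quantifies both strategies.

## Worked example

Closed-form bias ratios with the solver cross-check (`a` is the
half-interocular distance in units of the target depth; errors in radians):

```
$ vergence bias --a 0.06 --eta 0.02,-0.02
horizontal paired depth ratio z'/z = 1.125000000
solver cross-check          = 1.125000000  (|diff| = 1.48e-13)

$ vergence bias --a 0.06 --nu 0.02,-0.02
vertical paired depth ratio z'/z = 0.900000000
solver cross-check          = 0.900000000  (|diff| = 5.13e-14)
```

A horizontal error pair of ±0.02 rad at `a = 0.06` biases the paired mean
depth 12.5% *away* from the observer; the same pair applied vertically
biases it 10% *toward* the observer.

Monte Carlo propagation of vertical-dominant tracker noise (0.16°
horizontal, 1.5° vertical SD per eye; 6 cm interocular; target 50 cm away):

```
$ vergence simulate --sigma-h 0.16 --sigma-v 1.5 --target-z 50 \
    --n 10000 --seed 1 --out summary.json
mean point (cm): [-0.0, -0.02, 46.25]  mean error: 4.37 cm
```

The mean of 10,000 triangulated points sits at 46.25 cm depth — 3.75 cm in
front of the true 50 cm target even though the per-eye noise is zero-mean;
the transverse coordinates stay unbiased.

The averaging recipe under horizontal-dominant noise (1.5°/0.16°, 50 cm),
mean offset of the estimate from the target as a function of the number of
fixations k averaged per target:

```
$ vergence recipe --k 2,5,10 --trials 2000 --seed 1 --out curve.csv
k   average_then_estimate   estimate_then_average
2         10.42 cm                15.41 cm
5          5.75 cm                10.53 cm
10         3.88 cm                 8.83 cm
```

Averaging raw directions before triangulating (left column) decays toward
zero as k grows; averaging triangulated points (right column) flattens out
at the persistent bias.

Other subcommands: `vergence table1` (nine canonical distance × noise
conditions in one CSV), `vergence synth` (synthetic ring-target fixation
tables), `vergence analyze` (fixation covariances, 95% error ellipses,
affine-invariant covariance distances, KS comparisons).

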