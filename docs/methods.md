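# Methods

`memdiff` quantifies how impermeable membrane microdomains obstruct the
lateral diffusion of lipid probes in a supported lipid bilayer (SLB), and
how the same microdomains appear as shallow depressions in AFM topography.
Because raw single-particle-tracking (SPT) movies and AFM images of such
bilayers are rarely shared, every analysis stage is paired with a synthetic
generator that reproduces the statistical structure the analysis assumes;
the test suite then checks that each stage recovers what the generator put
in.

## Obstructed-diffusion model

Probes perform a two-dimensional Gaussian random walk in a square periodic
box (default 5 µm) containing non-overlapping circular obstacles. Each
coordinate receives an independent increment of standard deviation
√(2·D·Δt_sub) per substep, with D = `d_free` outside the obstacles. Two
obstacle interactions are supported:

* **impermeable** (`d_inside = 0`, the default): a proposed substep ending
  inside any disk is redrawn, up to 10 times, after which the particle
  holds its position for that substep. At small step lengths this
  rejection scheme approximates reflecting boundaries while remaining
  simple and unconditionally stable. The substep count is chosen
  automatically so the RMS substep is at most one fifth of the smallest
  obstacle radius, keeping the rejection probability per substep low.
* **slowed** (`d_inside > 0`): the local diffusion coefficient switches to
  `d_inside` inside disks, with no interface correction. This mode exists
  because it is not observable from the data whether the domains exclude
  the probes entirely or merely slow them; the impermeable mode is the
  default since the domains act as diffusion obstacles.

Obstacle fields are built by random sequential adsorption (RSA) to a target
area fraction (jamming for disks is near 0.55, so targets ≥ 0.5 are
rejected), with diameters from a normal distribution truncated at 20 nm, or
deterministically on a square lattice. The default geometry — area fraction
0.24, diameter 101 ± 7.8 nm — is the domain geometry measured by AFM in the
mirrored study. Recorded per-frame positions are kept *unwrapped*; obstacle
membership is evaluated in the wrapped box. MSD estimates on wrapped
coordinates would be corrupted by box-size jumps.

Observed positions add independent Gaussian localization noise per
coordinate (default σ = 44 nm, the study's stated position accuracy).
Trajectory lengths default to a geometric distribution above a configurable
minimum — the natural length law when trajectories end by single-step
photobleaching — with a fixed-length option for controlled experiments.

One integer seed drives everything; sub-streams (placement, initial
positions, steps, localization noise, camera noise) are split with
`numpy.random.SeedSequence` spawn keys, so identical configurations are
bit-reproducible regardless of how much randomness other stages consume.

## Movie rendering and tracking

Emitters are rendered at their true positions as pixel-integrated symmetric
2D Gaussians (default σ = 275.86 nm ≈ 1 pixel at the study's 275.86 nm
effective pixel), scaled to an expected photon count on a uniform
background; per-pixel Poisson shot noise and Gaussian read noise emulate an
EM-CCD. Localization error in the tracked output therefore arises from
photon statistics, as in a real acquisition.

Tracking is a functional equivalent of the ImageJ-style particle trackers
used in such studies: difference-of-Gaussians band-pass, local maxima above
an intensity percentile, and iterative intensity-weighted centroid
refinement on the positive part of the band-passed image (which removes the
uniform background without a separate estimate; a Gaussian fit was
considered and rejected as unnecessary at the SNR of interest — centroid
bias on noiseless spots is < 0.05 px). Linking is deterministic greedy
nearest-neighbour assignment in order of increasing distance, with an
optional gap memory; at the probe dilutions of single-molecule SPT,
global-optimization linking would change nothing. Trajectories shorter than
50 frames (500 fps) or 30 frames (30 fps) are discarded, implementing the
study's length filters with inclusive thresholds (the source alternates
between "longer than 50 frames" and "≥ 100 ms (50 frames)"; ≥ is used and
configurable). Gap-bridged trajectories are dropped at the filter stage
because the MSD estimator requires contiguous sampling.

## MSD and D(τ)

Per trajectory, the MSD at lag τ = nΔt is the overlapping-window average
with N − n displacement pairs. The ensemble curve pools all trajectories
with pair-count weights (total squared displacement over total pair count),
which is the frame-number-weighted average of per-trajectory curves and
reduces exactly to the single-trajectory estimator for one trajectory.
Both implementations are tested to machine precision against a brute-force
double-loop oracle.

D(τ = nΔt) is the unweighted through-origin least-squares slope of
MSD = 4Dτ over lags 1..n. No intercept is fitted: the model the curve is
read against has none, and the localization-noise offset (≈ 4σ²) is
acknowledged but deliberately not modelled, matching the analysis being
reproduced. For free diffusion D(τ) is flat; with obstacles it decreases
with τ as probes increasingly feel domain boundaries.

## Inflection points and diffusion lengths

On a log-τ axis, an obstructed D(τ) curve descends and turns flat where the
probes have explored a characteristic free-region size. Straight lines on a
log-τ plot are lines in (log₁₀τ, D) space, so all segment fitting happens
there (linear-τ fitting is available behind a flag). Two modes:

* **manual**: three user-supplied τ-ranges (first descent, intermediate,
  final plateau). The first inflection intersects the first descending line
  with the horizontal continuation of the intermediate line at its left
  edge; the second intersects the intermediate line with the plateau line.
* **automatic**: per transition, a continuous two-segment piecewise-linear
  least-squares fit whose breakpoint minimises the residual sum over a
  candidate grid; the default applies this in two τ-windows split at the
  curve's logarithmic midpoint. Because lag grids are linear in τ, points
  crowd the large-τ end of a log axis; the curve is first decimated to a
  roughly log-uniform grid (default 12 points per decade) so the tail
  cannot dominate the fit.

Each inflection (τ, D) converts to a mean diffusion distance L = √(4Dτ)
(µm; reported in nm rounded to the nearest integer). At the reference
coordinates of the study's lipid-probe curve, (0.022 s, 0.62 µm²/s) and
(0.10 s, 0.51 µm²/s), this gives 234 nm and 452 nm.

A note on what the simulation shows: the cumulative D(τ) of an RSA obstacle
field at fraction 0.24 relaxes over two scales — the typical inter-domain
gap and the larger open corridors that random (non-lattice) packings
contain. A single full-range breakpoint fit conflates the two and is
unstable; the two-window automatic mode separates them, and the first
inflection's L₁ then agrees with the field's geometric free-region scale
(equivalent-free-circle convention, 180 nm for the default geometry) to
well within 30% at the problem sizes used below.

## AFM topographies and morphometry

The generator produces a flat background plus a tilt plane (default ≈0.9 nm
edge-to-edge over a 3 µm image) and per-scanline offsets (0.1 nm SD, the
classic AFM line artifact), subtracts non-overlapping circular depressions
(RSA placement wholly inside the field of view; truncated-normal diameters
101 ± 7.8 nm and depths 1.4 ± 0.3 nm; area fraction 0.24), and adds 0.15 nm
RMS pixel noise. A ground-truth label map is returned alongside.

Flattening subtracts per-scanline medians, removes a least-squares plane
fitted to all pixels (so the height histogram is no longer smeared by
tilt), identifies background by thresholding at the histogram mode minus
half the expected depth, refits the plane on background only, and finally
re-centres per-scanline background medians and the background mode at 0 nm.
The all-pixel pre-fit matters: without it, a tilt range exceeding the
domain depth misclassifies background and biases the plane.

Segmentation thresholds at −0.7 nm (half the expected 1.4 nm step —
symmetric misclassification of noise at the step edge), labels 8-connected
components, and discards components smaller than a 20 nm disk. Per-domain
depth is the background median minus the in-domain mean (positive
magnitudes); equivalent diameter is 2√(area/π); area fraction and number
density refer to the whole image.

The domain-free region size is estimated under two explicit, labelled
conventions, since the periodic-allocation formula behind the published
261 nm figure is not stated and cannot be reverse-engineered unambiguously
from the printed statistics (plausible conventions span ≈160–260 nm):

* `equivalent_free_circle`: each domain owns a cell of area 1/ρ; the free
  area per cell is (1 − φ)/ρ; the estimate is the diameter of the circle
  with that area. At the published density (1589 domains over nine
  3×3 µm² images) and φ = 0.24 this gives 222 nm.
* `lattice_gap`: twice the edge-to-edge gap of the square lattice of
  mean-diameter disks reproducing φ: l = 2d(√(π/(4φ)) − 1); 163 nm at the
  same inputs.

## Problem sizes and what the tests show

The default verification runs use: 500 obstacle-free trajectories × 200
frames at 500 fps for free-diffusion recovery (D within 5%, flat within
10%); 400 trajectories × 400 frames in a 24%/101 nm field for the
obstructed analysis (monotone D(τ), L₁ within 30% of the geometric
free-region scale); nine 3×3 µm² synthetic topographies for AFM parameter
recovery (fraction within ±3 points, diameter within 10%, depth within
±0.2 nm); ten rendered sparse movies for tracking recall (≥95% of points in
the correct trajectory). These sizes give comfortably converged statistics
while keeping a full run in tens of seconds per study.

Passing these tests shows the estimators are unbiased and the pipeline is
self-consistent on data with the assumed statistical structure. It does not
certify behaviour on real data with features the generators omit: probe
blinking and intensity heterogeneity, drift, non-circular or mobile
domains, partially penetrable domains, tip convolution and feedback
artifacts in AFM, or dense fields where greedy linking breaks down. The
44 nm localization noise is modelled as additive Gaussian, not derived from
the optical system.

## Numerical choices and degenerate inputs

Tie-breaks in linking are by distance then lowest trajectory id, with
detections canonically ordered by (x, y) within a frame, making linking
invariant to input row order. MSD curves truncate with a warning when a
trajectory is shorter than the requested lag range; non-contiguous
trajectories are an error, not a silent gap. Descending-segment fits
require a strictly negative slope (tolerance 1e-9) and fail loudly on flat
curves; a constant D(τ) curve legitimately has no inflection. RSA failure
to reach a target fraction reports the achieved fraction. Merged D(τ)
curves keep both points at duplicated τ values, faster acquisition rate
first, and warn when the two rates' τ-ranges are disjoint by more than a
decade. Displays round lengths to the nearest nm and diffusion
coefficients to two decimals, matching the precision such results are
reported at; all stored values are full precision.
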