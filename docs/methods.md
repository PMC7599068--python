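# Methods

This note records the models implemented in `neurotopo`, the
assumptions behind them, the defaults that matter, and the places where
a genuinely open design choice was resolved.

## Coordinate conventions

Cell coordinates are in micrometres with the midline at x = 0 and x
increasing laterally (|x| is used as lateral distance, so both sides
share one ML axis), ventral at z = 0 with z increasing dorsally, and y
along the rostrocaudal axis. Eye angles are degrees, 0° along the body
axis, positive counter-clockwise in the top view; under this convention
the left eye moves nasally when its angle decreases and the right eye
when its angle increases.

## Clustering metrics

**Convex hull volume** (μm³) is computed by Qhull on ≥ 4 non-coplanar
points. It is invariant under rigid motion and scales as s³ under
dilation by s; near-coplanar inputs (rank < 3 after centring, tolerance
1e-9) raise a degenerate-geometry error rather than returning a
meaningless ~0 volume.

**Delaunay local density.** The density of cell *i* is the reciprocal
of the mean length of the Delaunay edges incident to *i* (units 1/μm,
reported as arbitrary units), and a nucleus is summarised by the mean
over its cells. This formula is a design choice — edge lengths rather
than simplex volumes or dual-cell areas — made for scale covariance
(dilation by s divides every density by exactly s), robustness to
varying neighbour counts, and simplicity; alternatives would order
clustered vs scattered groups the same way but differ in absolute
value, so densities should only be compared within one formula.
Exactly degenerate configurations (lattices, cospherical points) are
perturbed by a deterministic 1e-6 μm Gaussian jitter keyed to a seed
before tessellation.

**Aggregation.** Metrics are computed per side of the midline and
averaged within each larva, giving one value per specimen for group
comparisons. Sides with fewer than 5 cells are excluded from the
average with a warning rather than failing the larva; the dorsal half
of a nucleus is selected as z ≥ midpoint of that larva's [z_min,
z_max]. Group comparisons use the two-sided Mann–Whitney U test, exact
for combined n ≤ 20 without ties (the regime of the intended group
sizes, n = 6–16 larvae) and tie-corrected normal approximation
otherwise.

## Occupancy model

**Binning.** Each larva's cells are assigned to a 15 (DV) × 4 (ML) grid
with equally spaced bins anchored per specimen: the DV extent spans the
first to the last cell along z, the ML extent spans the midline to the
lateral-most cell. Bins are half-open [edge_i, edge_{i+1}) with the top
edge closed, so extreme cells land in bins 0 and n−1. Normalisation is
per-specimen *before* pooling, which makes grids comparable across
larvae of different physical size. When the true anatomical extent is
known (synthetic data), explicit extents can be supplied instead —
data-derived extents cannot reproduce generated bins exactly when an
extreme bin happens to be unoccupied, and a degenerate dataset
occupying a single bin would otherwise be stretched over the whole
grid.

**Posterior.** Counts pooled over larvae and sides are modelled as
multinomial with a symmetric Dirichlet(α) prior over the K = 60 bins,
giving the conjugate posterior Dirichlet(α + counts). The default
sampler draws directly from this closed form; 20,000 samples by
default. An MCMC route (random-scan pairwise Gibbs: each move resamples
a pair (p_i, p_j) from its exact Beta full conditional, 80 sweeps from
the posterior-mean start) is retained only to validate the conjugate
path — the two must agree within Monte-Carlo error, and a test enforces
this.

**Prior concentration.** α defaults to 1/K (total prior mass of one
pseudo-cell). A symmetric prior shrinks the occupancy-weighted mean bin
position toward the grid centre by N/(N + Kα); with α = 1 and a few
hundred cells that shrinkage is ~15% and visibly biases axis shifts,
while at 1/K it is negligible and every posterior sample remains
strictly positive (required for KL). α = 1 (uniform Dirichlet) is
available via configuration for sensitivity checks.

**Divergence and shifts.** For each paired posterior sample s,
KL(p_a^s ‖ p_b^s) = Σ_k p_a^s[k]·log(p_a^s[k]/p_b^s[k]) in nats;
the summary is the mean and central 95% interval (2.5–97.5 percentile)
over pairs. Because KL is asymmetric and the natural direction is a
convention, the reverse direction and the symmetrised Jeffreys value
are always reported alongside. Axis shifts are paired differences of
the occupancy-weighted mean bin index on the DV or ML marginal, in bin
units (bounded by ±14 DV, ±3 ML). A convergence check computes the KL
mean at increasing sample counts and declares convergence when
successive means differ by under 1% relative, an absolute floor of
1e-4, or twice their combined Monte-Carlo standard error — successive
estimates cannot be expected to agree more tightly than their own
sampling noise.

**Multivariate KS.** The model-free comparison is the two-sample 2D
Kolmogorov–Smirnov statistic in the Fasano–Franceschini sense: for
every data point of both samples, |F_a − F_b| is maximised over the
four axis-aligned quadrant orientations (closed inequalities, so ties
on the integer grid are handled symmetrically); the maxima conditioned
on each sample's own points are averaged, giving k ∈ [0, 1]. Because
grid data are tie-heavy, the p-value comes from label permutations
(default 999), which is exact under exchangeability; type-I error at
nominal 0.05 is verified to lie in [0.03, 0.07] by simulation.

## OKR analysis

**Eye segmentation.** Frames are thresholded, the two largest connected
components are taken as the eyes (smaller specks are ignored by
construction), and each orientation is θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂)
from central second moments, reported in (−90°, 90°] with the image
y-axis flipped to keep angles counter-clockwise-positive. Rotationally
symmetric components (μ₂₀ ≈ μ₀₂, μ₁₁ ≈ 0) are flagged as undefined
rather than returning an arbitrary angle.

**Slow phases.** Samples whose smoothed absolute eye velocity (5-sample
moving average with edge-replicated padding, then central difference at
100 Hz) exceeds a threshold — default 3× the peak stimulus speed — are
marked fast phase and removed together with a 50 ms guard window on
each side; remaining runs are cut at stimulus reversals and must last
≥ 100 ms. The velocity criterion cannot see saccades whose jump is
below roughly (threshold × smoothing window) ≈ 1.5° at the defaults;
such micro-resets contribute negligibly to gain.

**Gain.** Per slow-phase interval the eye velocity is the least-squares
slope of angle against time; the interval is classified nasal or
temporal from the slope's sign relative to that eye's nasal direction,
and gain = duration-weighted mean of |slope| / |grating velocity| over
qualifying intervals. The slope estimator was chosen over the mean of
per-sample |velocity| because with realistic angle noise (0.5° at
100 Hz) per-sample speeds are dominated by noise magnitude and the
mean-absolute-velocity estimator is badly biased upward, whereas the
regression slope is unbiased. A numerically stationary interval
(|slope| ≤ 1e-9·|stimulus|) has no direction and contributes its ~0
gain to both directions. **Eye range** is max − min angle per eye over
the session; the strong eye is the one with the greater range, ties
going to the left eye with a logged note.

## Intensity quantification

Five equally spaced slices are selected from the interior [1, depth−2]
of each sub-stack (nearest-integer rounding of a linear spacing; depth
must be ≥ 7). The mean grey value of each side's ROI in each selected
slice is corrected by subtracting the background estimate — the average
of three background-ROI means — and the specimen value is the mean of
the corrected values (slice-level values are also reported, selectable
as the aggregation level). Negative corrected values are reported, not
clipped. Expression categories use fixed left-closed bands in a.u.:
(−∞, 500) omitted, [500, 1500) small, [1500, 2500) regular,
[2500, 3500) large, [3500, ∞) large_bold; the printed band endpoints
overlap, and the left-closed convention is the documented resolution.
Midline area is the count of supra-threshold pixels in the sagittal
plane at the stated index times pixel_size², with a connected-component
report since contiguity of the signal is itself informative.

## Synthetic data

Generators are pure functions of their seed (a master seed expands into
independent per-generator streams via `SeedSequence` plus a tag CRC)
and record their parameters as ground truth.

- **Occupancy datasets**: per larva, a cell count uniform in a stated
  range (default 20–60, spanning the per-larva range implied by pooled
  totals of ~278 cells/19 larvae to ~399/22; the true per-larva
  distribution is not published, so this is a configurable choice, not
  a calibration), bins multinomial from the truth grid, coordinates
  uniform within the bin, anchored to nominal extents (DV 0–60 μm, ML
  0–40 μm) recorded in the truth sidecar.
- **Clustered nuclei**: Gaussian mixtures whose per-axis sd is dilated
  by a scatter factor ≥ 1; factor 3 reproduces the direction of the
  scattered phenotype (larger hulls, lower densities).
- **OKR sessions**: constant-speed grating reversing every 6 s, sampled
  at 100 Hz; eye angle integrates gain × stimulus velocity during slow
  phases (nasal/temporal gains selected by movement direction, per-eye
  scaling available), Poisson saccades reset the eye to rest within one
  sample, and Gaussian angle noise is added. Saccades as instantaneous
  resets are a simplification — only slow phases are analysed — and
  because the generator imposes no orbital limits, eye range in long
  noisy sessions is driven by reset timing; dominance recovery is
  therefore only meaningful for clearly asymmetric per-eye scaling.
- **Eye frames**: filled rotated ellipses rendered from the implicit
  equation in the same y-up angle convention the analysis reports, plus
  optional salt specks strictly smaller than the eyes.
- **Intensity stacks**: Gaussian noise around stated ROI and background
  means inside disjoint masks.

A green recovery test therefore establishes correctness of the
estimators under the generative model's assumptions (multinomial
placement, Gaussian noise, instantaneous saccades) — not robustness to
optical artefacts, segmentation errors, anatomical deformation, or
non-uniform within-bin densities, none of which the generators emulate.

## Known limitations

- The occupancy model pools cells across larvae; per-larva random
  effects are out of scope, so credible intervals reflect multinomial
  sampling, not between-animal variation.
- KL values between distributions with near-disjoint support are
  dominated by low-count edge bins and can be large; they are reported
  as computed, with the Jeffreys value as a symmetric companion.
- The Delaunay density is comparable only within the edge-length
  formula documented above.
- Binning with data-derived extents is sensitive to single extreme
  cells (they define the anchors); this mirrors the anchoring
  definition rather than a robust quantile choice.
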