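# neurotopo

Spatial statistics and behavioural analysis of neuronal nucleus
topography, built for studies of how cranial motor neurons cluster into
subnuclei — e.g. the oculomotor (nIII) and trochlear (nIV) nuclei of
larval zebrafish — and what happens to that organisation, and to the
eye movements it drives, when cell–cell adhesion is perturbed.

`neurotopo` takes per-cell 3D coordinates (μm, with specimen, genotype
and side annotations), eye-position traces or raw video frames, and
fluorescence stacks with ROI masks, and provides:

- **Clustering metrics** — convex-hull volume of a nucleus's cell
  coordinates and per-cell local density from the Delaunay tessellation
  (`density_i = 1 / mean incident-edge length`), summarised per larva
  (sides averaged) and compared across groups with the Mann–Whitney U
  test.
- **Bayesian occupancy model** — cells binned onto a 15×4
  dorsoventral × mediolateral grid (z0 ventral → z14 dorsal, x0 medial →
  x3 lateral, extents anchored per larva). With counts *n* and a
  symmetric Dirichlet(α) prior, the posterior over the K = 60 occupancy
  probabilities is Dirichlet(α + n); group differences are summarised
  across paired posterior samples by the Kullback–Leibler divergence
  KL(p_a‖p_b) = Σ_k p_a[k]·log(p_a[k]/p_b[k]) with a central 95%
  interval, by axis shifts of the occupancy-weighted mean bin position
  (e.g. z_shift = z̄_a − z̄_b, in bin units), and by differential
  probability maps. A pairwise-Gibbs MCMC sampler is included purely as
  a validation route against the conjugate closed form.
- **Multivariate KS test** — a quadrant-based two-sample 2D
  Kolmogorov–Smirnov statistic (Fasano–Franceschini) with a permutation
  p-value, for comparing binned distributions without the model.
- **Optokinetic reflex (OKR) analysis** — moment-based eye orientation
  from thresholded video frames, slow-phase segmentation, per-direction
  gain (slow-phase eye velocity / grating velocity, nasal vs temporal),
  total eye range, and strong/weak-eye assignment.
- **Fluorescence quantification** — background-corrected mean ROI
  intensities over five equally spaced interior slices, categorical
  expression bands, and thresholded midline-section areas.
- **Synthetic data generators** — every input above can be generated
  with known ground truth (occupancy grids with controllable DV/ML
  shifts, clustered vs scattered Gaussian nuclei, triangular-wave OKR
  sessions with resetting saccades, rendered eye frames, noisy
  intensity stacks), so each estimator is testable by parameter
  recovery.

## Worked example

Detecting a known one-bin dorsoventral shift between two synthetic
groups (`python examples/occupancy_shift.py`):

```
wildtype: 692 cells, 19 larvae
perturbed: 890 cells, 22 larvae
KL_mean = 4.3447, 95% CI [1.1985, 10.6459]
z-shift = 1.0636, 95% CI [0.8212, 1.3023]
x-shift = 0.0146, 95% CI [-0.0723, 0.1027]
multivariate KS: k = 0.1547, p = 0.0010
KL stability over sample sizes: [4.2689 4.2684 4.3131] converged at 5000
```

The z-shift posterior recovers the simulated shift (truth 1.0 bin, CI
[0.82, 1.30]); the ML axis, where nothing was shifted, straddles zero.
The KL divergence is large here because the shifted grids have
near-disjoint edge bins — with overlapping distributions it shrinks
toward zero. The multivariate KS test rejects equality of the binned
distributions independently of the model.

Other capabilities, one script each, under `examples/`:
`clustering_metrics.py` (hull/density contrast between tight and
scattered nuclei), `okr_gain.py` (gain and dominance recovery from a
synthetic session), `expression_quant.py` (corrected intensity and
midline area), `full_pipeline.py` (all stages end-to-end with a
manifest).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates all synthetic inputs from the given seed, runs the full
pipeline (clustering metrics, occupancy model with 20,000 posterior
samples, multivariate KS with 999 permutations, OKR analysis, intensity
quantification) into `results/pipeline/`, and writes the target summary
JSON to `--out`.

## Layout

- `src/neurotopo/synthetic.py` — generators with ground truth
- `src/neurotopo/spatial.py` — hull, Delaunay density, rank comparison
- `src/neurotopo/occupancy.py` — binning, Dirichlet posterior, KL,
  shifts, multivariate KS
- `src/neurotopo/okr.py` — eye tracking and gain analysis
- `src/neurotopo/imaging.py` — intensity quantification
- `src/neurotopo/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — models, assumptions, numerical choices
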