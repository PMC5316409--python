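# Methods

This note records the models, conventions and design choices behind
`stressplate`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not demonstrate about real screening data.

## Synthetic plates

The generator emulates 384-well live-imaging plates of HepG2 GFP reporter
lines.  Its defaults define the study conditions used throughout the test
suite and the acceptance script.

**Dynamics templates.** Each treatment is assigned one of four classes —
`transient_nuclear`, `sustained_cytosolic`, `foci_forming`, `null` — with
a piecewise log-linear fold-change template anchored at onset, peak and
decay times.  The transient template (onset 2 h, peak 8 h, decay 15 h,
amplitude 4 by default) mirrors a fast adaptive response that rises from
about 2 h and returns to baseline by ~15 h; sustained classes plateau at
their amplitude; the null class is identically 1.  Log-linear segments
were chosen as the simplest shape family that is positive, monotone per
segment and matches the qualitative rise/decay of reporter time courses
without asserting any kinetic model.

**Noise and batch effects.** A well's value at time t is
`shift + scale · profile(t) · ε`, with ε lognormal, unit mean, and
coefficient of variation `noise_cv` (default 0.2 — a typical well-level
spread for reporter intensities).  `scale`/`shift` are plate-level batch
effects; acquisition grids are irregular (13 points by default) and may
differ in total duration between plates.  Per-well noise streams are
seeded by hashing (root seed, plate id, well id), so generation is
reproducible, order-independent and — because the hash excludes the plate
effect — exactly linear in `scale`.

**Image rendering.** Nuclei are Gaussian-blurred discs (radius 8 px,
blur σ 1.5, 16-bit range, small Gaussian read noise) placed by rejection
sampling with a minimum spacing; impossible densities raise an error
naming the well.  The GFP channel renders *uniform* compartment fills —
the nuclear fill extends 2 px beyond the nucleus disc, cytosolic classes
fill the whole cell disc — so the planted compartment mean intensity is
realized exactly and the quantification round-trip has a well-defined
truth.  Foci are 3×3 puncta (+4000 counts) placed on a ring inside the
cytosol; the planted count per cell follows the class template scaled to
`max_foci`.  Planted-dead cells receive a PI disc covering their nucleus
in the final frame only, matching the endpoint death call.  The renderer
deliberately omits photobleaching, stage drift, optical PSF structure,
cell motion and division; passing the round-trip criteria therefore
validates the measurement logic, not robustness to those effects.

## Quantification

**Segmentation contract.** Stage 1 partitions the smoothed image by
watershed seeded at local maxima above the global Otsu level (minimum
peak distance 6 px); stage 2 classifies pixels within each region by a
per-region Otsu threshold (parameter-free, and well defined on the
bimodal region histograms the watershed produces).  Objects under
`min_area_px` (30) are removed and labels renumbered in scan order.
Blank or constant images yield an empty label map rather than an error.

**Cell propagation.** The GFP foreground comes from tile-based Li
(minimum cross-entropy) thresholding on ~20-px windows; tiles with less
than 5 % of the image contrast fall back to the global Li threshold so
large uniform areas classify consistently.  Foreground pixels join the
Euclidean-nearest nuclear seed, with equidistant pixels assigned to the
lower label for determinism.  The propagation is distance-based rather
than intensity-weighted: it is exactly reproducible by a brute-force
nearest-seed computation, which the tests exploit; every cell is a
superset of its nucleus by construction.

**Foci.** Local background is the grey-scale opening with an 11-px
square; foci are connected regions of residual ≥ prominence/2 whose peak
residual reaches `min_prominence` (default 2000 counts, i.e. half the
rendered focus amplitude and far above rim artefacts of the opening) and
whose area reaches `min_focus_px`.  A focus belongs to the parent region
under its peak pixel; peaks in background are kept in the output with
parent 0 but excluded from per-cell counts, so the per-parent counts plus
discarded foci always sum to the total detected.

**Tracking and death.** Greedy maximum-overlap matching links labels
between consecutive frames (ties to the larger, then lower-labelled
previous object).  The death call thresholds the PI channel by Otsu,
masks it with each nucleus dilated by 2 px, and flags a cell dead when
the PI-to-dilated-area ratio is at least 0.10 — boundary inclusive, since
the rule is "at least 10 %".  The ratio denominator is the dilated
nucleus; a whole-cell denominator is available via
`flag_death(denominator="cell")` since the prose definition admits either
reading.  A frame with no cells reports a missing fraction, not zero.

## Normalization

Order of operations: scaling → spline resampling → quantile
normalization.

- Min–max scaling operates per plate × reporter × feature; a constant
  group maps to all zeros.  GFP-positive fractions (cells ≥ 2× the
  matched DMSO background, boundary inclusive; background = mean per-cell
  DMSO value of the same plate, reporter and time point) are never
  scaled.
- The 6-df natural cubic spline puts its five interior knots at quantiles
  of the observed times and boundary knots at the observed extremes; the
  basis is the truncated-power natural construction, built in-house
  because predictions must be *analytically* linear beyond the boundary
  knots for stable extrapolation to the common duration.  Fits need at
  least df+1 points.  A consequence of the natural constraint worth
  stating: a generic cubic polynomial is *not* representable (its second
  derivative cannot vanish at both boundary knots), so exact recovery
  holds for linear inputs and for curves in the spline space — cubic
  within the knot span — but a free cubic is only approximated
  (interior error ~1–2 % at these knot counts).
- Quantile normalization pools each plate's resampled values within
  reporter × feature and maps ranks onto the mean quantile function
  across plates (linear interpolation reconciles unequal counts; ties
  share the mean reference value).  It is idempotent, and a per-well
  grouping is available behind `qn_grouping="plate_well"`.

The residual sum of squares and observation count of every spline fit are
carried forward, because the statistics stage needs regression residual
standard errors.

## Statistics

The standardized difference divides `x − x̄_DMSO` by the root sum of four
variance terms: SD over DMSO replicates and over treatment replicates at
that time point, plus two regression residual SEs computed as
`√(rss / (df_tp − 1))` with df_tp fixed at the 24 resampled points
(denominator 23) regardless of the raw grid length — the formula's df
refers to the sampled grid.  The DMSO residual term is the root mean
residual variance across DMSO replicates; the treatment term is the
replicate's own, keeping the statistic defined per treatment replicate.
Zero denominators yield missing values (logged), which meanDiff drops
with an adjusted count.  meanDiff averages x_diff over time; averaging
the raw normalized values instead is available via `meandiff_on="raw"`.
The pooled-variance Student t is the default (Welch behind a flag), the
alternative is one-sided "treatment > DMSO", and the reported p is
`min(1, 2·p_one-sided)`.

**Calibration.** The doubled one-sided test rejects reported p < 0.05
exactly when the one-sided p < 0.025, and on exchangeable replicate
summaries it operates at that level (measured 2.4–2.5 % over 1000
simulations).  Pushed through the full pipeline under the lognormal
noise_cv = 0.2 null, the realized rate is higher, about 4 %: the
lognormal right-skew feeds a positive-tail test, and the shared
within-group SD term couples replicate summaries.  This is a property of
the method itself, not of the implementation — an independent-control
variant shows the same rate, and Gaussian noise shrinks it to ~3 % — and
the acceptance checks therefore pin the test-level rate near 2.5 % and
the pipeline-level rate near 5 %.  Planted amplitude-2 transients at
noise_cv 0.2 with 3 replicates are detected in ~83 % of runs.

**Plate-effect removal.** The acceptance measure is the between-plate
mean absolute difference of matched DMSO mean curves, before (raw scale,
interpolated to a common grid) versus after normalization: planted
1.6–2× scale and additive shift effects are reduced by ~95 %.  Note the
measure spans the min–max unit change, and the residual gap after
normalization is dominated by replicate sampling noise at cv 0.2 rather
than surviving batch structure (it is comparable to the gap when no
plate effect is planted at all).

## Clustering

Distance metrics are euclidean (default), maximum (Chebyshev) and
Pearson (1 − r); linkages complete (default), ward and average.  Because
published figures used different combinations, presets name them:
`fig4` (pearson/ward endpoint), `fig6` (maximum/complete time-course),
`fig8` (euclidean/ward on the mean distance matrix).  The distance cube
stacks per-feature (or per-reporter) pairwise curve distance matrices;
"reducing the dimensions to 2" is implemented as averaging over the
stack — the mean of metrics is itself a metric — with pairs missing from
some slices averaged over the available ones (logged).  Entities are
sorted by label before agglomeration, making results invariant to input
order; dendrograms export to Newick, flat clusters by height or count.
Missing endpoint values are imputed by zero after normalization, where
absence means no measured response.

## Persistence and reproducibility

Per-cell records go to an HDF5 store with an explicit `schema_version`
root attribute and `/plates/<id>/wells/<id>/cells` datasets in fixed
column order; a store written by a newer schema is refused outright.
Frames are per-channel single-frame TIFFs named
`plate_well_tNN_channel.tif` (acquisition times in a TSV sidecar), label
masks 16-bit PNGs, and all tabular outputs tab-delimited text with a
fixed float format, so reruns with the same config and seed are
byte-identical; each run writes a manifest with the config hash, seed and
package version.  The `is_dead` flag is stored tri-state (−1 missing
before the final frame).

## Problem sizes

The validation suite uses deliberately small instances chosen to exercise
every code path with tight tolerances: 20 segmentation images of 10–50
nuclei at 256², wells of 10–25 cells over 3–13 frames, 1000 null and 200
power simulations of 3+3 replicate wells on a 13-point grid, and 18
entities for clustering recovery.  These sizes make the planted effects
estimable to the stated tolerances; scaling to full 384-well plates is a
matter of runtime, not of algorithmic change.

## Known limitations

- No 3D stacks, flat-field correction, machine-learned segmentation, or
  motion/division-aware tracking; tracks rely on frame-to-frame overlap.
- The foci detector is 2D prominence-based; its parameters are
  conventions, as the original plugin's tolerance semantics are not
  published.
- No multiple-testing correction across treatments (by design, matching
  the screening readout), and the pipeline-level test is mildly
  anti-conservative under skewed noise, as quantified above.
- The synthetic data carry no transcriptomic component; nothing here
  validates cross-platform concordance analyses.
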