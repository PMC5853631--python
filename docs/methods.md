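# Methods

`catring` re-implements, as a tested pipeline on synthetic data, the analysis
chain used to study how learned visuospatial categories are represented in
multivoxel fMRI patterns and in directed interactions between posterior
parietal cortex (IPS1/2) and primary visual cortex (V1).  This note documents
the models, the generator, the numerical choices, and what passing tests do
and do not show.

## Task geometry

Eight circular stimuli sit equally spaced on an invisible ring of radius
7 degrees of visual angle (dva), at polar angles 22.5° + 45k (k = 0..7,
counter-clockwise from the rightward horizontal).  A category boundary is a
diameter through fixation; the four candidate axes (0°, 45°, 90°, 135°) are
offset 22.5° from every stimulus, so each boundary splits the ring into two
contiguous arcs of four and no stimulus ever lies on a boundary.  Closed
forms used throughout:

* chord distance at s ring steps: 2·7·sin(sπ/8) → 5.36, 9.90, 12.93, 14.0 dva
  (printed as 5.4 / 9.9 / 12.9 / 14);
* perpendicular boundary distance: 7·sin(22.5°) = 2.68 dva for the four
  nearest positions, 7·sin(67.5°) = 6.47 dva for the four farthest.

WCS/BCS pair sets (within- vs between-category similarity) per separation:
at 1 step, the 2 boundary-straddling pairs (BCS) are matched by the 2 pairs
straddling the perpendicular axis (WCS), so both sets share chord length and
count.  At 3 steps the 2 within-category pairs are matched, by default, by
the 2 between pairs that are mirror-symmetric about the boundary axis; using
all 6 between pairs is available as `bcs_rule="all"` (which of the two the
original analysis used is not stated; the symmetric subset mirrors the
balanced 1-step construction).  At 2 steps no boundary-symmetric subset
exists, so all 4 within and all 4 between pairs are used.  The 4 diametric
(14 dva) pairs are all between-category and are annotated *near* (both
members 2.7 dva from the boundary) or *far* (both 6.5 dva).

## Synthetic experiments

The generator emulates the delayed match-to-category design: 15 runs of
16 task + 16 fixation trials, back-to-back 14-s trials sampled at TR = 2 s
(7 timepoints per trial, 448-s runs), 240 task trials with positions exactly
balanced (30 per position; 2 per position per run).  Default 12 subjects.

Per-ROI voxel responses at trial–timepoint resolution:

    r_v(k, t) = A · exp(κ (cos(θ_k − φ_v) − 1)) + λ_roi(t) · P_cat(k),v + ε,
    ε ~ N(0, σ²)

* **Position code** — von Mises tuning with voxel-preferred angles φ_v drawn
  uniformly; concentration κ is the spatial-scale knob: κ = 8 emulates a fine
  code (V1), κ = 1.5 a coarse one (IPS1/2).  A = 1, σ = 1 (per-voxel SNR ≈ 1
  at the tuning peak).
* **Category component** — two fixed prototype voxel patterns (one per
  category), unit per-voxel RMS, orthogonal to each other and to the mean
  tuning map so that position and category information are separable by
  construction.  The amplitude λ_roi(t) is time varying: the IPS-like ROI
  peaks early (6 s), the V1-like ROI late (10 s), matching the temporal
  dissociation the analyses probe.  Default peaks are 0.25 (IPS) and 0.20
  (V1) in units of the noise SD — the documented default effect size, chosen
  once (sweep over {0.15, 0.2, 0.25, 0.3}, 40 seeds) so that the boundary
  scan recovers an injected boundary in ≥ 90% of single-subject experiments
  at the ROI's preferred timepoint.
* No HRF convolution by default: the analyses operate on raw timepoints, so
  the generator produces the analysis surface directly.  An optional
  double-gamma mode exists (`hrf=True`) for shape experiments.
* The continuous-series view (for the preprocessing steps) embeds the trial
  blocks at their onsets on top of a positive baseline (100 response units)
  and a run-wise linear drift (slope SD 0.02 per timepoint), with fresh noise
  in fixation trials.

**Reaction times** (task trials): rt = 0.9 s + 0.12 s·1[near boundary] +
g·δ_run + N(0, 0.15 s), truncated to (0, 2] (the response window); near
stimuli are slower.  δ_run is the run-level deviation of the top-down
coupling (below) and g = −0.5 s per coupling unit ties faster runs to
stronger top-down influence — the relation the brain–behavior analysis is
asked to recover.

**Coupled ROI series** — a regime-switching bivariate VAR(1) at the TR grid:
self-lags 0.3, bottom-up (V1→IPS) coefficient 0, top-down (IPS→V1)
coefficient 0.35 + δ_run during categorization trials (δ_run ~ N(0, 0.08))
and 0.05 during fixation trials; unit-variance Gaussian innovations, 50
burn-in steps, stability (spectral radius < 1) enforced per regime at
construction.

All randomness flows from one integer seed via `SeedSequence([seed, subject,
stream, run/experiment])`; subject tuning maps are keyed by subject only, so
a retraining experiment (boundary rotated 90°) regenerates trials and noise
but keeps each subject's maps.

### What the generator does *not* emulate

No haemodynamic blurring or autocorrelated noise, no physiological/motion
artifacts, no voxel-to-voxel noise correlations, no eye movements, no
volumetric geometry.  Passing recovery tests therefore show that the
analysis chain is correct and well calibrated *for data satisfying its own
assumptions* — they say nothing about whether real BOLD data satisfy them.

## Preprocessing

Two conditioning steps are in scope (the volumetric steps of the original
stream act on data that are not simulated): run-wise linear detrending
(per-run, per-voxel least-squares line removal) and global scaling
(divide each timepoint by its spatial mean, then subtract the voxelwise
mean; a regression-based variant is available as `mode="regress"`).  The
pipeline applies **scaling before detrending**: ratio-style scaling needs the
positive raw baseline, since detrending zeroes the run means and would make
the spatial-mean divisor degenerate.  The order is configurable and recorded
in the serialized config.  Epoching cuts the series back to trials on the TR
grid; dropping the first 2 timepoints (4 s) of a trial leaves 5 of 7 samples.

## Decoding

Eight-way position decoding with a linear SVM (one-vs-one multiclass, the
convention of the classification toolkit the original analysis wrapped),
leave-one-run-out (LORO) cross-validation.  The SVM cost is data-scaled by
default, C = 1/⟨‖x‖²⟩ over training samples (the "C = −1 automatic scaling"
convention), overridable with a fixed value.  Recursive feature elimination
runs inside each training fold only: per iteration, rank voxels by the mean
absolute weight across the 28 binary classifiers and remove the lowest 20%
(at least 1; never below `min_features`, default 8); stop when a *nested*
LORO accuracy within the training runs has not exceeded the best so far for
10 consecutive iterations; keep the voxel set at the best recorded accuracy.
The nested inner loop is a design choice the original description leaves
open; it prevents the stopping rule from ever seeing the held-out run.
Tie-breaks in the elimination ranking are by voxel index (stable).

The permutation null shuffles training labels once per fold per permutation
(test labels intact) and reruns the decoding path;
p = (1 + #null ≥ observed)/(1 + n_perm).  Group-level significance is the
exact binomial upper tail on the number of subjects individually beating
their threshold.  The per-timepoint Bonferroni constant .05/8 = .00625 used
for decoding time courses is exposed in `stats`.

## Pattern similarity and the category index

Position patterns are per-position means over correct task trials at one
timepoint, restricted by default to the union of RFE-surviving voxels across
LORO splits at that timepoint (all-voxel mode available).  All 28 pairs are
scored with Spearman's rho; the category index at a separation is
CI = WCS − BCS.  The boundary-optimality scan recomputes CI under each of
the four candidate boundaries; group-level counts of subjects for which the
trained boundary wins are tested against chance 1/4 with the exact binomial
tail (9/8/7/6 of 12 → 3.92×10⁻⁴ / 2.78×10⁻³ / .014 / .054).  Controls:

* *near/far diametric contrast* — mean rho of the 2 near vs the 2 far
  14-dva pairs, paired t across subjects (df = n−1);
* *attention contrast* — between-category pairs with mixed boundary
  distances vs both-far pairs;
* *retinotopy interaction* — two-way ANOVA (position group × experiment) on
  subject-level mean similarity of adjacent pairs, where group 1 = pairs
  (0,1), (4,5) and group 2 = (2,3), (6,7) (0-based; groups share a category
  under exactly one of the two boundaries), fit by OLS with the interaction
  F from standard sums of squares.

## Granger causality

GC is Geweke's log variance ratio, GC(x→y) = ln(σ²_restricted/σ²_full), from
least-squares fits of the full bivariate model and the own-lags-only model
of the same order on the same observations.  Model order defaults to 1: with
5 usable timepoints per trial after transient removal, higher orders are
barely identifiable (order-2 fits are available).  Lagged designs are built
within trial segments only — lags never bridge trial edges, so concatenated
trials act as independent realizations.  Per condition and run, the first 2
timepoints of each trial are dropped (transients), leaving 16 × 5 = 80
timepoints per run per condition.  GC is estimated per run and averaged
downstream.  Finite-sample GC estimates can be marginally negative; they are
clamped to 0 before the standardized contrast
(GCc − GCf)/(GCc + GCf), which is undefined (error) when both terms are 0.

## Brain–behavior correlation

Runs are ranked by mean RT and binned into sliding windows of 5 neighbors
(15 runs → 11 groups).  RT is z-scored within subject before group
averaging (removing between-subject offsets); standardized GC is averaged
within groups and then across subjects; the 11 group points are summarized
by Spearman's rho.  **Caveat**: adjacent groups share 4 of 5 runs, so the 11
points are strongly dependent — under a null with no GC–RT link the
dispersion of the group-level rho is far wider than an independent-sample
n = 11 null (|rho| ≥ 0.57 occurs in roughly 40% of null simulations, not
~6%).  The implementation reports the descriptive rho exactly as defined;
its p-value should not be read as if the groups were independent.

## Statistics

Exact binomial tails by direct summation; t-test p-values through the
regularized incomplete beta function (matches `scipy.stats.t` to 1e-12);
Spearman's rho with average ranks, exact permutation p for n ≤ 10 and the
t approximation with n−2 df above; balanced two-way ANOVA interaction via
statsmodels OLS/anova_lm, verified in tests against hand-computed sums of
squares.  Reported p-values are displayed to three significant figures.

## Problem sizes used in tests and acceptance runs

Unit tests use reduced designs (1–4 subjects, 4–5 runs, 24–40 voxels) chosen
as the smallest instances that still exercise nested cross-validation and
balanced trial counts; recovery and calibration checks use the full 15-run
single-subject design over 100 seeds, and the brain–behavior recovery the
full 12-subject design.  The GC oracle check uses 5,000-timepoint series.

## Known limitations

* The RFE inner loop is O(splits² · iterations) SVM fits; full-scale ROIs
  (10³–10⁴ voxels) are feasible but slow on one core.
* The exact Spearman permutation p enumerates up to 10! orderings; above
  n = 10 the t approximation is used.
* The per-voxel noise is white; GC estimates on real, HRF-filtered BOLD have
  well-known interpretational caveats that no synthetic check removes.
* `category_index` at the diametric separation reuses the near/far
  annotation in the WCS/BCS roles, as no within-category diametric pairs
  exist.
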