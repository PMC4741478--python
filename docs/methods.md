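# Methods

This note documents the statistical model, the defaults, the synthetic
data generator, and the numerical and design choices behind
`sirnascreen`.

## Screen design assumptions

The pipeline targets arrayed screens on 96-well plates (rows A–H,
columns 1–12). One plate column (default 12) is reserved for controls,
alternating non-targeting (siNT, negative) and lethal positive controls
down the rows starting with NT at row A — 4 NT + 4 positive wells on a
full plate. Both the column index and the role pattern are
configurable, and `nt_wells_used` can restrict the NT average to the
first k NT wells for designs that carry fewer usable NT controls.
Each plate is measured per cell line and technical replicate; the raw
readout is a whole-well fluorescence intensity (FI), proportional to
total cell mass (colony number × size in a colony-formation assay).

## Normalization

%NT is computed strictly within (plate, cell line, replicate):
`%NT = 100 · FI / mean(FI over that plate's NT wells)`. Consequences:

- the mean %NT of a plate's NT wells is exactly 100 (asserted to 1e−9
  in tests), which is the inter-plate normalization anchor;
- any multiplicative factor applied to a whole plate (exposure time,
  staining efficiency, cell-line transfection/raw-signal scale) cancels
  exactly — %NT is scale-equivariant;
- values above 100 are preserved (growth-promoting silencing is
  information, not an artifact).

Replicate aggregation is the arithmetic mean of per-replicate %NT, not
%NT of summed FI; the SD over replicates uses the n−1 denominator and
is undefined (NaN) for a single replicate. A plate whose NT controls
are missing or average to a non-positive FI is a *normalization
failure*: its oligos keep their records but are flagged (`nt_failed`),
excluded from downstream distribution statistics, and carry no z*.
Missing replicates are likewise flagged (`missing_replicate`) rather
than dropped.

z* is the robust z-score (x − median)/(1.4826 · MAD), computed per cell
line over the replicate-mean %NT of all unflagged library oligos of a
run. The robust (median/MAD) variant is the conventional choice for
high-throughput screens, where a minority of strong phenotypes would
otherwise inflate a plain SD; it is provided as an auxiliary
per-cell-line activity score and plays no role in d thresholding.

## The d statistic and hit calling

Each library oligo is summarized by the point
p = (%NT_normal, %NT_tumor), built from replicate means. The statistic

    d = || p − (100, 0) ||₂ = sqrt((100 − %NT_normal)² + %NT_tumor²)

is its Euclidean distance from the point of maximal tumor-selective
lethality: the tumor line fully killed (0) with the normal line fully
spared (100). d is nonnegative, zero only at (100, 0), strictly
increasing in %NT_tumor and strictly decreasing in %NT_normal on
[0, 100). The asymmetry is the point: oligos lethal to both lines, or
preferentially lethal to the normal line, sit far from (100, 0) and are
excluded by construction.

Screen statistics μ (mean) and σ (SD, n−1) are plain moments of the
library d values — controls never enter — and hit thresholds are
μ − kσ. Phenotypes are called with a fixed precedence:

1. `lethal_both` if %NT ≤ cutoff (default 20, inclusive) in **both**
   lines;
2. `differential` if d is **strictly** below μ − kσ (k = 3 for primary
   screens);
3. `normal_selective` if %NT_normal ≤ cutoff only;
4. `inactive` otherwise.

With cutoff 20 and any threshold below 80 the first two classes cannot
overlap even without precedence, because %NT_normal ≤ 20 already forces
d ≥ 80; a test asserts this at the default parameters. Sigma binning
(`floor((d − μ)/σ)`) is provided for plotting the hit tail. Per-gene
summaries count the oligos with the queried phenotype among the gene's
tested oligos and report `n_active/n_total` strings; per-screen
summaries report counts and percentages of the library size, rounded
half-even to 2 decimals.

The thresholds are recomputed per run and never hard-coded. For
orientation: a Normal d distribution with μ = 55.0 and σ = 2.6 puts the
−3σ threshold at 47.2 and the −2σ threshold at 49.8; the acceptance
script refits exactly these thresholds from 10⁶ draws and checks the
fraction below μ̂ − 3σ̂ against Φ(−3) ≈ 0.00135.

## Confirmation

Confirmation runs (typically ~100 oligos, 3 manual replicates) are
re-normalized and re-scored like a screen, then re-called at
k_confirm = 2 — looser than the screen's 3, reflecting that the tested
set is pre-enriched for hits. An oligo is *confirmed* iff its
confirmation phenotype equals its screening phenotype, as exact
category equality: reproduced inactive and lethal-both calls count as
confirmed, while a screen-differential oligo returning lethal-both does
not. When the confirmation set has at least `min_confirm_stats_n`
(default 50) oligos its own d distribution anchors the threshold;
smaller sets reuse the screening-run statistics, since μ and σ from a
handful of pre-selected oligos would be meaningless. Confirming a run
against its own scores confirms 100 % of oligos whenever the refit
statistics reproduce the thresholds (always true for a noiseless run).

## Dose-response (4PL / IC50)

The four-parameter logistic `r(x) = bottom + (top − bottom)/(1 + (x/c)^h)`
is fit by unweighted least squares (scipy's Levenberg–Marquardt) to
per-dose replicate means. Initialization is deterministic: bottom/top
from the response extremes, inflection at the geometric mean dose
(optimized on the log scale to stay positive), |h| = 1 with the sign
taken from the empirical response-vs-log-dose trend so that the fitted
Hill sign matches the data's direction. The parameter symmetry
(bottom, top, h) ↔ (top, bottom, −h) is resolved by normalizing to
top > bottom. Fewer than 4 distinct doses, non-finite or constant
responses, and optimizer non-convergence raise errors rather than
returning garbage.

The reported IC50 is the **absolute** IC50 — the dose where the fitted
curve crosses 50 % of untreated control — not the relative EC50 (the
inflection c); the two coincide only for the symmetric curve
bottom = 0, top = 100. Crossings outside the tested dose range, and
curves whose asymptotes never straddle 50, are censored and reported as
`<min_dose` or `>max_dose` in the curve's direction. Fits are exact
fixed points on noiseless data (recovery to ~1e−8 relative) and IC50 is
equivariant under dose-unit changes.

## Synthetic screen generator

The generator is the stand-in for a real screen's raw data and defines
the study conditions for all end-to-end tests. Defaults: 309 plates,
25139 oligos, 9031 genes (2–3 oligos/gene, allocated to total exactly
the library size), two cell lines ("normal", "tumor") × two technical
replicates, baseline FI 10 000, log-normal multiplicative noise with
CV 0.15, positive controls at 5 %NT.

Gene classes are planted with fractions 2 % tumor-selective, 1 %
lethal, 0.5 % normal-selective, remainder inactive. Each oligo of a
non-inactive gene is independently effective with probability 0.5 —
mirroring the empirical pattern that differential genes are supported
by 1–2 of 3 oligos rather than all three. Expected %NT per line is
built from two components, both attenuated by the line's transfection
efficiency e (normal 1.0, tumor 0.9):

- a generic off-target growth inhibition g ~ U(0, 25) carried by every
  library oligo in both lines; because e differs between lines this
  shared component is what skews the bulk point cloud off the diagonal
  (the better-transfected normal line loses more growth), reproducing
  the asymmetric scatter seen when two lines transfect unequally;
- a class-specific kill for effective oligos: tumor-selective
  U(65, 95) %NT points in the tumor line only, lethal U(92, 100) in
  both, normal-selective U(85, 100) in the normal line only. The
  lethal range is deep enough that, after the tumor line's 0.9
  efficiency attenuation, both lines still land at or below the 20 %NT
  cutoff.

Expected %NT = clip(100 − e·(g + kill), 0, 150), stored per oligo in
the truth table; FI = baseline · e · (expected %NT/100) · noise, with
NT wells pinned at 100 and empty wells at 0. With the noise off, the
pipeline's normalized %NT equals the stored effects exactly and every
effective oligo is called as its class. Under the default noise the
planted effects sit well clear of the μ − 3σ threshold, so recovery of
tumor-selective oligos is essentially perfect (sensitivity ≥ 0.90,
specificity ≥ 0.99 are the acceptance floors; the measured values at
the default conditions are 1.0); raising the CV first blurs the
boundary cases and then collapses sensitivity, which the noise-sweep
tests exercise.

What the generator does **not** emulate — and therefore what passing
tests cannot certify about real screens: spatial artifacts (edge
effects, gradients, dispensing errors), sequence-driven off-target
structure (seed-sequence correlated phenotypes), plate-to-plate
biological drift, saturating or quantized detector response, and any
correlation between replicates beyond the shared expected value. On
real data the d distribution is wider and the hit boundary genuinely
ambiguous; the confirmation machinery exists precisely because real
borderline hits do not all reproduce.

Confirmation runs are simulated by re-arraying a subset of oligos on
fresh plates with the same planted effects and new noise draws
(3 replicates by default). All generation is deterministic under a
seed; changing only the seed changes noise and assignments but not the
marginal class counts.

## Problem sizes in tests and acceptance

Unit and property tests run on 1–6-plate screens (≤ 480 oligos). The
end-to-end recovery check runs the full 309-plate, 25139-oligo screen
(≈ 119 k measurements; a few seconds). The confirmation-consistency
check reruns a 30-plate, 2440-oligo screen plus a 100-oligo
confirmation across 10–12 seeds per noise level; the confirmed
*fraction* is scale-free, so the smaller screen changes nothing but
runtime. The tail-calibration check uses 10⁶ draws.

## Known limitations

- One oligo is assumed to occupy one well per run; re-arrayed
  duplicates of the same oligo within a run are not aggregated.
- No spatial (B-score / median-polish) correction and no
  multiple-testing adjustment — the σ-threshold rule is the method
  being provided, not an FDR procedure.
- 384-well formats and instrument-native raw files are out of scope;
  inputs are plain CSV/TSV tables.
- The z* reference distribution pools the whole run; per-plate z*
  variants are not offered.
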