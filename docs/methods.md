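# Methods

## Overview

`funconn` analyzes resting-state functional brain networks built from
regional BOLD time series. One subject's pipeline is:

1. **Motion screening.** A subject is excluded if any translation axis
   exceeds 1.5 mm or any rotation axis exceeds 1.5° in absolute value
   (strict inequality: values exactly at the limit pass). Screening uses
   per-axis maxima of the six rigid-body parameters, not a composite
   framewise displacement.
2. **Band-pass filtering** of every regional series to 0.01–0.08 Hz.
3. **Nuisance regression** of the six motion parameters plus white-matter
   and ventricle mean signals (with an intercept) from the *filtered*
   series. Filtering and regression do not commute; the pipeline fixes
   this order.
4. **Connectivity.** The N×N Pearson correlation matrix of the cleaned
   regional series (N = 90 regions of the AAL parcellation by default;
   the diagonal is set, not computed).
5. **Binarization at fixed wiring cost.** At sparsity *S*, the
   `round(S·N(N−1)/2)` most strongly correlated pairs become edges, so all
   subjects' graphs share one edge count. The reference density is
   S = 15% (601 edges at N = 90) with a sweep over 15–25% in 0.01 steps.
6. **Graph metrics.** Clustering coefficient C, characteristic path
   length L, per-node betweenness centrality, and the small-world ratios
   γ = C/C_rand, λ = L/L_rand, σ = γ/λ against an ensemble of
   degree-preserving rewired null graphs.
7. **Robustness.** Targeted attack: nodes removed in decreasing order of
   group-mean betweenness while tracking the largest connected component.
8. **Group statistics.** Per metric, a 2×2 (sex × disease) ANOVA;
   Benjamini–Hochberg FDR over each test family; Tukey HSD follow-ups for
   significant interactions; age-controlled partial correlations between
   disease duration and small-worldness.

`ConnectomeStudy` packages steps 1–8 behind a single `fit()`;
the functional modules expose each step individually.

## Definitions and numerical choices

**Clustering.** `C_i = 2E_i / (k_i(k_i−1))` with `E_i` the number of edges
among node *i*'s neighbors; nodes with degree < 2 contribute `C_i = 0`
(they are *not* dropped from the average). This convention keeps C defined
at sparse densities but lowers C relative to an exclusion convention —
comparisons across packages must account for it.

**Path length.** Mean shortest-path (edge-count) distance over unordered
pairs, computed from a BFS distance matrix. A disconnected graph is an
error, never an infinity or a harmonic mean: the analysis sparsity is
expected to be chosen (see `min_connected_sparsity`) so that every
subject's graph is one connected component.

**Betweenness.** Brandes' accumulation; reported unnormalized (raw counts
of pair-fractions), so on a 90-node graph hub values run into the
hundreds. Degree-1 nodes have betweenness 0.

**Thresholding.** Pairs are ranked by *signed* correlation by default (an
`absolute` mode exists behind a flag); ties at the cut rank break by
lexicographic (row, col) order so results are platform-reproducible. Edge
counts round half away from zero.

**Degree-preserving nulls.** Double-edge swaps: pick two edges (a,b),
(c,d), rewire to (a,d),(c,b) unless a self-loop or duplicate would result.
The effort is ≥10 *attempted* swaps per edge. Connectivity is enforced
with a windowed audit: swaps are applied in windows, the graph checked
after each window, and a disconnecting window rolled back and retried
swap-by-swap with per-swap checks. Degree sequence and edge count are
asserted on every call. γ and λ use the ensemble means of C and L
(default 100 realizations; seeded).

**σ.** Reported as γ/λ, the standard small-world scalar; γ and λ are also
emitted separately since some studies plot γ alone as "small-worldness".

**Two-way ANOVA.** The 18-male/20-female cells make the design unbalanced,
so Type II sums of squares are the default (invariant to factor order;
appropriate when no terms beyond the interaction are considered); Type III
is available by flag. Each term has 1 numerator df. The implementation is
a vectorized projection (nested-model SSE differences), which lets the
same code test one metric or all 4005 edges at once; it is cross-checked
against `statsmodels` `anova_lm` in the tests. Responses fitted perfectly
(zero residual variance) get F = 0, p = 1 when constant, and F = ∞, p = 0
when a term genuinely explains them.

**FDR.** Benjamini–Hochberg step-up at q = 0.05 by default;
Benjamini–Yekutieli behind a flag. Edge-level tests correct over all
tested pairs.

**Partial correlation.** Both variables are residualized on the covariates
(with intercept) and the residuals correlated; p from a t reference with
n − 2 − (#covariates) df. With no covariates this is exactly Pearson.

**Filter realization.** Order-4 Butterworth band-pass applied
forward-backward (`sosfiltfilt`) for zero phase — phase distortion would
corrupt the correlations. Even-reflection padding is used: with the
default odd extension, the 0.01 Hz high-pass pole's long transient leaves
~1.4% stopband leakage on a 205-sample series; even padding reduces it
below 0.2% while passband tones stay within 1%.

## The synthetic cohort

No imaging data ships with the package; `generate_cohort` realizes the
study design synthetically.

* **Design.** 20 female and 18 male subjects per group (patients and
  controls), 90 regions × 205 volumes at TR = 2 s by default. Clinical
  covariates (age; for patients disease duration, attack frequency and
  duration, pain intensity) are truncated normals matching the cell means
  and SDs of the study population (e.g. female patients: duration
  10.9 ± 7.4 y).
* **Signal model.** Regions are partitioned into `n_modules` contiguous
  communities; the target correlation is `within_module_r` (0.5) inside
  and `between_module_r` (0.1) between communities. Time series are drawn
  from a multivariate normal with that correlation and passed through a
  common AR(1) filter (`noise_ar1` = 0.3), which adds temporal
  autocorrelation without changing the contemporaneous correlations — the
  simplest model consistent with a Pearson-correlation analysis.
* **Effects.** Patients' within-module couplings on a configurable
  affected-region set (default: the first module) are reduced by
  `disease_effect`; female patients receive an extra reduction
  `sex_disease_interaction` (the interaction cell); each patient's
  coupling additionally shifts by `duration_slope` × (duration − cohort
  mean). Perturbed matrices are clipped and eigenvalue-floored back to a
  valid correlation matrix.
* **Nuisance.** Six slow random-walk motion traces (small enough that
  subjects ordinarily pass screening), plus AR(1) white-matter and
  ventricle signals, mixed into the regional signals with recorded
  weights (`nuisance_amplitude` total SD ≈ 0.3 of the neural signal). The
  recorded weights let tests verify that regression removes essentially
  all nuisance variance (< 10⁻⁶ of total).
* **Determinism.** One seed drives record sampling and per-subject
  sub-streams; identical config + seed reproduce the cohort bit for bit.

What the generator does *not* emulate: voxel-level structure, hemodynamic
response shapes, scanner drift spectra, physiological (cardiac/
respiratory) aliasing, heavy-tailed motion, or spatially heterogeneous
module sizes. Passing tests therefore demonstrate the *pipeline's*
correctness and the inference's calibration under the assumed model, not
robustness to every artifact of real fMRI.

## Simulation experiments (`funconn.experiments`)

Replicate experiments run at reduced problem sizes so hundreds of cohorts
complete in minutes; the sizes are part of the experiment definitions:

* **Null calibration.** 200 cohorts of 6 subjects per cell, 40 regions,
  120 volumes, all effects zero; the clustering-coefficient interaction
  term rejects at 4.5–7% across base seeds, within two binomial SEs of
  the nominal 5%.
* **Interaction power.** A coupling reduction of 0.35 on two of five
  modules (16/40 regions) in female patients, 12 subjects per cell,
  produces a ≈2-SD clustering shift and is detected (FDR q = 0.05) in
  essentially every replicate.
* **Duration sign recovery.** The 40-region/5-module layout is unsuitable
  here: at 15% sparsity its graphs often disconnect, and past that
  modularity level extra coupling *lengthens* paths faster than it raises
  clustering, inverting the coupling→σ link. The experiment instead uses
  45 regions in 9 five-region modules — small modules leave between-module
  edges inside the edge budget, keeping graphs connected and σ monotone
  increasing in coupling. With `duration_slope` = 0.025/yr on five
  modules and 22 patients, the age-controlled duration–σ partial
  correlation is positive in ≥95% of replicates (typical r ≈ 0.5–0.65).
* **Canonical graphs.** Watts–Strogatz graphs (N = 90, k = 12, p = 0.1)
  give σ ≈ 2.5–4 (> 1 for every seed); a density-matched random graph is
  statistically its own null, and its σ falls inside the ensemble's
  mean ± 2 SD interval around 1.

## Known limitations

* The block-covariance generator produces more regular modular structure
  than real connectomes; hub/rich-club organization is not modelled.
* At low sparsity and strong modularity, subject graphs can disconnect;
  `fit()` raises a stage-named error and `min_connected_sparsity`
  identifies the smallest usable threshold, but no automatic fallback is
  applied.
* The per-step robustness test (Welch t) treats removal steps
  independently; no correction across steps is applied (a permutation
  variant is available).
* Edge-level ANOVA over all 4005 pairs is implemented but disabled by
  default (`edge_stats` flag) to keep default runs light.
* Weighted or directed graph variants, efficiency metrics, and
  partial-correlation/wavelet connectivity estimators are out of scope.
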