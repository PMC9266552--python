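# Methods

## The model

Per-axon calibers within a tract are modeled as lognormal:
`ln d ~ N(μ, σ²)`, summarized by the geometric mean `GM = e^μ` (median
diameter) and geometric standard deviation `GSD = e^σ`. All other shape
features are closed forms in (μ, σ): `ω = e^{σ²}`, skewness
`(ω + 2)√(ω − 1)`, mode `e^{μ − σ²}`, percentile `e^{μ + σ z_p}`. The model
is an approximation — real tracts have a resolution-limited left edge and
possibly multimodal large-fiber populations — but on binned relative
frequencies it typically explains R² ≥ 0.94 of corticospinal ADDs.

Two fitting routes are deliberately kept distinct:

* `fit_lognormal_mle` — μ and σ are the mean and (1/n-normalized) SD of
  `ln d`. The 1/n vs 1/(n−1) choice changes σ by < 0.1% at n ≥ 500 axons and
  is irrelevant at morphometric sample sizes.
* `fit_lognormal_histogram` — nonlinear least squares of exact bin
  probabilities `CDF(hi) − CDF(lo)` against 0.1 μm-binned relative
  frequencies (not the density at bin centers, which biases σ upward in
  coarse bins). Initialized from log-moments of the bin centers; bounded
  iterations with an explicit `FitError` on non-convergence.

R² is always evaluated on the 0.1 μm binned frequencies, whichever route
produced (μ, σ), so both fits are judged on a common scale. Histograms are
half-open `[lo, hi)` starting at 0; a value exactly on an edge belongs to
the upper bin, and bin indices are computed with an edge-tolerant floor so
that binary-float artifacts (e.g. `0.3/0.1 < 3`) cannot misplace values. No
left-truncation correction is applied for unresolvable thin axons.

## Uncertainty and testing

Cohorts are small (6–7 animals per group), and axons are nested in animals,
so axon-level parametric errors would be badly anticonservative. Instead:

* **Jackknife** — leave-one-animal-out variance for any pooled-fit feature,
  `var = ((n−1)/n) Σ (θ_(i) − θ̄)²`, CI `θ̂ ± 1.96 se`. For multiplicative
  features (GM, GSD, percentiles) the interval is built on the log scale and
  exponentiated. For the sample mean this reduces exactly to `s/√n` (tested
  as an identity).
* **Permutation tests** — one-way F, pooled-variance t (pooled, not Welch,
  to match the classical post-hoc t after ANOVA) and the 2×2 two-way
  decomposition. Exact enumeration of distinct label arrangements whenever
  there are ≤ 20,000; otherwise 10,000 Monte-Carlo permutations with the
  add-one convention `(1 + exceedances)/(1 + n_perms)` (finite-sample valid,
  never 0). Exact p-values include the identity arrangement, so `p ≥ 1/N`.
  The two-way test permutes reduced-model residuals (Freedman–Lane) with
  effect-coded type-III sums of squares, valid for the unbalanced 2×2
  (time × apnea) layouts these studies produce; raw-label permutation is
  available via `method="labels"`.
* **Spearman ρ** with a Fisher-z interval, `SE = 1.03/√(n−3)`.

A caution surfaced by enumeration: for *unequal* group sizes the
pooled-variance t has no mirror arrangement, so a fully separated 7-vs-6
comparison has exact two-sided p `1/C(13,7)`, not `2/C(13,7)`; the factor-2
rule holds for equal sizes and for rank statistics such as the AUC.

## Survival adjustment and rank curves

Group survival is the mean per-animal axon count divided by the sham mean
count; sham is its own reference at survival 1.0. Adjusted frequencies are
the across-animal mean relative frequency per bin times mean survival, so
the curve area equals total survival exactly. Per-bin SEMs are computed from
the unadjusted relative-frequency spread; variance in survival itself is
deliberately not propagated. Per-bin surviving fractions (injured/sham)
are only reported where the sham curve has mass ≥ 1e-4 — tail bins below
that floor produce unstable ratios and are flagged instead.

Rank curves evaluate, for each percentile rank q, the fitted quantile `d_q`
and the adjusted frequency of the 0.1 μm bin containing it. The analytic
peak rank is the mode's percentile `100·Φ(−σ)` (≈ 23–25 for GSDs of
1.97–2.10); the discrete bin-mode curve plateaus over the modal bin's rank
span, which starts just above that value — plotted peaks therefore land a
couple of percentiles high, a pure binning artifact. A `density` mode
(frequency = density × bin width) gives the smooth imputed version.

## Discrimination and the effective radius

ROC analysis treats a per-animal feature as a diagnostic score. AUC is the
Mann–Whitney statistic with ties counted ½; orientation is auto-flipped so
reported AUC ≥ 0.5 and the flip is recorded. The CI is DeLong's
structural-components variance (Wald, clipped to [0, 1]); the p-value
permutes labels with the orientation-free statistic |AUC − 0.5|.

The effective axon radius is defined as the spherical-mean-MRI estimand
`r_eff = (⟨r⁶⟩/⟨r²⟩)^{1/4}`; for a lognormal radius distribution
(`μ_r = μ − ln 2`, same σ) this is `exp(μ_r + 4σ²)` exactly (cross-checked
against numeric moment quadrature to 1e-6). The `4σ²` term makes r_eff
strongly tail-weighted — it exceeds the median radius whenever σ > 0 and is
monotone in σ at fixed GM — which is why the late loss/atrophy of
large-caliber axons projects to a ~49% r_eff drop even though the median
caliber falls only ~26%.

## Synthetic cohorts

The generator emulates the hierarchical structure the analysis assumes:

* Group level — lognormal ADD at the group (GM, GSD); defaults are the
  observed values (sham 0.69/2.10 n=7; day 7 0.65/2.03 n=7; day 21
  0.51/1.97 n=6) with injured-group survival 0.70.
* Animal level — each animal's log-GM is offset by `N(0, τ²)` with
  `τ = 0.147` by default, calibrated so a 7-animal group GM has a 95% CI
  halfwidth of ≈ 0.075 μm at GM 0.69 (the observed sham precision). The
  per-group σ is shared — observed GSD intervals are narrow.
* Axon level — per-animal axon counts are Binomial(2000, survival), so
  count-based survival estimation works downstream. 2000 axons/animal is a
  package choice; per-animal counts are not published.

The mechanistic injury route thins a sham baseline with
`s(d) = clamp(s0 − slope·(d − 0.7)₊, 0, 1)` (s0 solved so expected survival
hits the target; unattainable targets raise a calibration error) and then
shrinks survivors by the monotone, rank-preserving map
`d → d·(1 − a·Φ((ln d − ln 0.7)/w))`, floored at the 0.1 μm imaging
resolution. Presets are calibrated by quadrature against the sham ADD:
`day7` is thinning only (slope ≈ 0.110 μm⁻¹ reproduces GM 0.65 at 70%
survival — and lands GSD at ≈ 2.01 with no extra freedom, close to the
observed 2.03); `day21` adds atrophy with (a ≈ 0.44, w ≈ 7.7) solved to hit
GM 0.51 / GSD 1.97. The wide w means the calibrated late remodeling is a
near-uniform ~30% shrink with only mild extra narrowing — consistent with
loss and atrophy being unidentifiable from cross-sectional histograms,
which is also why the package never attempts that decomposition on data.

What the generator does **not** emulate: measurement noise and segmentation
errors, within-animal spatial correlation, left-censoring of sub-resolution
axons, axon counts varying with tract area, or any biophysics of Wallerian
degeneration. Passing tests therefore demonstrate correctness of the
estimators and analysis chain under the stated hierarchical lognormal
conditions, not robustness to every property of real micrographs.

## Morphometry conventions

Feret diameter is the *maximum* caliper width, measured over the pixel
outline corners (each pixel contributes the 4 corners of its unit square) —
the common morphometry-software dialect in which a single pixel has feret
√2 px rather than 0. The maximum pairwise corner distance is found by convex
hull + rotating calipers and equals the O(n²) brute force exactly (tested on
random blobs). The corner convention inflates diagonal extents by up to
~√2 px; the fixture generator compensates by drawing ellipse semi-axes
0.375 px short of the requested diameter, which makes measured ferets
unbiased to < 1% down to ~4 px profiles. Component labels are interpreted
with 8-connectivity; fixture ellipses are near-circular (axis ratio
1.0–1.3), non-overlapping with a 1-px margin, and placed by rejection
sampling (largest first) with an explicit packing error when the canvas is
too full.

## Sizes, seeds and numerical choices

Analysis defaults: 0.1 μm bins, 10,000 Monte-Carlo permutations (seed
20220702), exact enumeration below 20,000 arrangements, per-animal fits
require ≥ 30 axons, sham-frequency ratio floor 1e-4. Simulation-based test
checks use 1,000 replicate null datasets (type-I error), 1,000 replicate
7-vs-6 cohorts (AUC) and 100 random blobs (calipers oracle); estimator
recovery is checked at 7 × 2,000 axons with animal heterogeneity zeroed,
since with the calibrated τ a single cohort's group GM carries ~5.6%
sampling spread that is a property of the design, not the estimator. All
generators and tests are seeded; reports are byte-identical given
config + seed (sorted-key JSON, no timestamps).

## Known limitations

* Normal-theory (point ± 1.96 se) jackknife intervals; percentile-jackknife
  or BCa intervals are not implemented.
* DeLong CIs are Wald-type and can touch 1.0 for perfect separation at
  small n.
* The histogram fit assumes independent bin residuals (as curve-fitting
  software does); its σ therefore has no honest standard error — use the
  jackknife for uncertainty.
* Rank-curve frequencies in bin mode are step functions of rank; compare
  groups in density mode.
* The Feret fixture generator is 2-D; it does not emulate z-projection
  effects of thick-section imaging.
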