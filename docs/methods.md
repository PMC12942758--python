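# Methods

`mirselect` implements a complete chemometric workflow for predicting total
polyphenol content (TPC, g gallic acid equivalents per 100 g dry weight) from
mid-infrared absorbance spectra in the p ≫ n regime: thousands of correlated
wavenumbers, under two hundred samples. This note documents the models, the
defaults and why they were chosen, the synthetic-data generator, and the
numerical decisions that were genuinely open.

## Problem setting

An ATR-FTIR spectrum of freeze-dried berry powder is a vector of absorbances
on a descending wavenumber grid (4000 → 400 cm⁻¹, p ≈ 7468 points). The
reference value for each sample is a Folin–Ciocalteu assay readout converted
through a gallic acid standard curve A = slope·C + intercept and

TPC = (A − intercept) · V · D / (slope · m · 10),

with extraction volume V (mL), dilution D and mass m (g). Absorbances below
the intercept imply negative concentration and are clamped to zero with a
warning. The ×10 divisor carries the conventional unit conversion from
mg/L·mL/g to g/100 g; we reproduce the formula as conventionally printed
rather than re-deriving the units.

## Preprocessing catalogue and screen

Ten chains are screened: raw; Savitzky–Golay (SG) smoothing; SG first
derivative; SNV; SNV+smoothing; SNV+derivative; MSC; MSC+smoothing;
MSC+derivative; polynomial detrending. Conventions:

* SG window 11 points, polynomial order 2 throughout; boundary windows are
  handled by evaluating the boundary polynomial fits (scipy `mode="interp"`),
  so output length equals input length and wavelength indices stay stable.
* SG derivatives are scaled by the physical grid spacing (per cm⁻¹) and
  sign-corrected for the descending storage order, so derivative bands are
  physically interpretable.
* SNV uses the sample (n−1) standard deviation, making the `[1,2,3] →
  [−1,0,1]` identity exact.
* MSC always regresses against the *calibration* mean spectrum; prediction
  spectra are corrected against that same reference (leakage control).
* Chains apply scatter correction before the derivative, as their names read.
* Detrending defaults to a quadratic baseline.

The screen fits a PLS model per chain, with the latent-variable count chosen
by 5-fold cross-validated RMSECV over 1..15 components, and ranks chains by
test-set R² (ties broken by catalogue order). Ranking on the prediction set
mirrors the original protocol; the per-chain CV report is also returned so a
leak-free CV-only ranking is available to users who prefer it.

## Sample partitioning

SPXY and Kennard–Stone are deterministic maximin selectors. Distances are
Euclidean in preprocessed X and absolute differences in scalar y; SPXY sums
the two after normalizing each by its maximum over the pool, so d ∈ [0, 2].
Both seed with the most-distant pair and accrete by the max–min rule; all
argmax ties break to the lowest sample index, so splits are bit-reproducible.
Calibration size is ⌊f·n⌋ (191 × 0.8 → 152). Partitioning operates on
preprocessed spectra. The comparison harness reports the RPD standard
deviation over repeats; with the default fixed fold plan it is exactly zero
(everything downstream is deterministic), and an optional fold-reseeding mode
isolates model-side variation.

## Importance engines and the strategy pool

**PLS-VIP.** VIP_j = √( p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a ), where SS_a
is the y sum-of-squares explained by latent variable a and w_a its X-weight
vector. The identity Σ_j VIP_j² = p holds algebraically and is enforced in
tests at 1e-6. The component count is chosen by 5-fold RMSECV over 1..15;
threshold comparisons are inclusive (VIP ≥ τ).

**Random-forest Gini importance.** Mean decrease in impurity across a
500-tree forest, normalized to sum to one. The forest uses
`max_features=0.3`: with heavily collinear spectra, restricting the candidate
features per split spreads importance across correlated neighbourhoods
instead of concentrating it on one representative wavelength, which is what a
coverage-style top-fraction rule needs. Top-fraction selection keeps
⌊q·p⌋ variables (⌊0.30·7468⌋ = 2240, ⌊0.10·7468⌋ = 746), ties at the cut
breaking to the lower wavelength index.

**The pool.** Six labeled strategies share the two profiles: the balanced
hybrid VIP1.0∩RFR30%, RFR-top10%, the strict hybrid VIP-1.2∩RFR-20%,
PLS-VIP-1.2, PLS-VIP-0.8, and CARS. Intersections are plain mask ANDs; empty
selections are legal, flagged results so a comparison never crashes.

**CARS.** Each of N iterations (default 50) draws 10 Monte-Carlo row
subsamples (80% of calibration rows), fits PLS on the surviving variables,
and averages |regression coefficients| into weights; the enforced-elimination
ratio follows r_i = a·e^(−k·i) with a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1),
so r_1 = 1 and r_N = 2/p; adaptive reweighted sampling then draws survivors
with probability proportional to weight (distinct draws survive); each
survivor set is scored by 5-fold RMSECV of a CV-tuned PLS model (component
cap 10), and the best-scoring iteration's subset is returned. Everything is
driven by one seed; retained counts are non-increasing by construction and
the run stops early if fewer than two variables survive.

## Models and the three-stage tuning protocol

Four families cover the main regression paradigms: PLS (linear latent
variables), random-forest regression (bagging), RBF-kernel SVR
(kernel methods, inputs standardized inside the model pipeline so scaling is
always fitted on training rows only), and gradient-boosted trees (XGBoost).

* **Stage 1** compares the six selection strategies with one frozen booster
  (max_depth 3, learning rate 0.1, 300 trees, shared seed), so ranking
  reflects the subsets and not the tuning.
* **Stage 2** gives each family an equal, light budget on the stage-1
  winner: PLS components 5–15 (11 candidates), forest depth {4,6,8,10} ×
  leaf {2,3,5}, SVR C {1,10,100} × γ {1e−3,1e−2,1e−1}, booster depth
  {3,4,5} × learning rate {0.05,0.1} — a space small enough that we
  enumerate it outright. All families share one fold plan.
* **Stage 3** fine-tunes the booster by seeded uniform random search (default
  60 draws) over trees 50–500, depth 2–6, learning rate 0.01–0.3, subsample
  and column-subsample 0.6–1.0, L1 0–1, L2 0–2, with 20-round early stopping
  against the held-out fold inside each CV fit. The final refit uses the mean
  early-stopped round count. The prediction set is evaluated exactly once,
  after the search; the result object records the touch count and the full
  search trace.

CV statistics (R²_cv, RMSECV, RPD_cv) are computed on pooled out-of-fold
predictions rather than averaged per-fold scores: at n ≈ 150 a pooled
statistic is a single well-defined quantity and is invariant to fold
ordering.

## Evaluation

R² = 1 − SSE/SST, RMSE = √(SSE/n), and RPD = SD_ref/RMSE where SD_ref is the
(n−1)-denominator standard deviation of the evaluated set's reference values,
so RPD × RMSE ≡ SD_ref. Williams bands are half-open exactly as
conventionally stated: < 1.5 unreliable, [1.5, 2.0) rough screening,
[2.0, 2.5) approximate quantification, [2.5, 3.0) good prediction, ≥ 3.0
excellent prediction. Derived percentage statistics (dimensionality
reduction, relative improvement) round to one decimal; the
calibration-minus-prediction R² gap rounds to four.

## Synthetic data generator

The measurement campaign the package targets is not publicly deposited, so a
seeded generator emulates its regime and plants ground truth. Each clean
spectrum is a Beer–Lambert mixture: tpc_i · P(ν) + matrix_i · M(ν) +
water_i · W(ν), with Gaussian bands (closed-form derivatives make the SG
tests exact):

* polyphenol bands at 1030, 1260, 1515, 1600 and 1720 cm⁻¹ (glycosidic C-O,
  phenolic C-O, aromatic C=C ×2, ester C=O), widths 15–20 cm⁻¹, amplitudes
  0.05–0.10 AU per unit TPC;
* matrix C-H bands at 2850/2920 cm⁻¹ (amplitudes 1.0/1.2) and water bands at
  1640 and 3300 cm⁻¹ (0.5 and 0.8, the latter 120 cm⁻¹ wide).

Concentrations are truncated-positive normals: TPC mean 2.0, sd 0.339 (the
sd implied by the published RPD × RMSEP product; the mean is an arbitrary,
documented choice since no summary statistics for the reference values are
published); matrix 1.0 ± 0.03 and water 0.5 ± 0.03. The tight matrix/water
spread encodes freeze-dried, sieved powder: a near-constant carbohydrate
matrix and little residual moisture. Observed spectra add per-sample
multiplicative scatter (slope sd 0.3 — ATR contact pressure is the dominant
nuisance for powders — offset sd 0.05), a random quadratic baseline (scale
0.05) and iid Gaussian noise (sd 0.01 AU). This nuisance budget is what makes
scatter-corrected derivative chains win the preprocessing screen, as they do
on real powder spectra; a generator whose composition variance dominates its
scatter would instead punish row-normalizing corrections and invert that
ordering. An optional knob correlates matrix/water with TPC to stress-test
false-positive filtering; it is off by default.

The planted "informative" mask is every wavelength within ±2 band widths of
a polyphenol band centre — an explicit, testable definition. Note its limits:
Gaussian tails beyond ±2σ still carry a little signal, so on noise-free data
a selection outside the mask is not strictly uninformative.

What passing recovery tests shows — and does not. The generator reproduces
the dimensional regime (p ≫ n), the nuisance structure (scatter, baseline,
noise, overlapping interferents) and a realistic signal-to-noise level; it
does not model ATR penetration-depth dispersion, instrument line shape,
Lorentzian/Voigt band shapes, chemically correlated constituents (by
default), or between-region heterogeneity. Recovery of planted wavelengths
and high held-out RPD on these simulations demonstrates that the pipeline's
machinery works as specified, not that the published accuracy transfers to
any particular real matrix. One deliberate divergence from the emulated
study: on exactly-linear synthetic mixtures, boosted trees have no
nonlinearity to exploit, so PLS-family models are usually at least as good —
the cross-model claim is therefore checked as "all families reach good
prediction", not "boosting wins".

## Problem sizes used by the test and acceptance suites

Routine tests run on small simulations (n ≈ 40–60, p ≈ 120–300). The
recovery study runs the core pipeline (chain 9 → SPXY → hybrid selection →
stage-2/stage-3 tuning) at n = 191, p = 2000 over ten seeds, with the
stage-3 random-search budget set to 20 draws and stage-2 medians taken over
the first five seeds — problem sizes chosen to keep the whole study around
ten minutes on one core while leaving the tested claims unchanged.

## Known limitations

* The preprocessing screen's headline ranking uses the prediction set, as in
  the emulated protocol; the CV-only ranking is reported alongside for
  leak-free selection.
* CARS with aggressive schedules on small pools can terminate early; the
  trace is flagged `truncated` and the best recorded iteration is still
  returned.
* The generator's truncated-normal TPC is effectively symmetric at the
  default mean/sd ratio (~6); strongly skewed reference distributions are out
  of scope.
* Stage-2/stage-3 comparability: stage 3 searches a different (larger) space
  than stage 2 with a stochastic budget, so per-seed CV improvements are
  typical but not guaranteed; the median improvement is what the tests
  assert.
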