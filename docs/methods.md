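# Methods

This note records the statistical model the package implements, the
numerical choices behind it, what the synthetic cohorts do and do not
emulate, and the design decisions taken where the procedure left room.

## Model and procedure

The outcome is a binary group label D_i for n subjects (default emulated
cohort: 28 cases, 14 controls). Features are organized in five modality
blocks (VBM, fALFF, FC, FA, SC); adjustment covariates are age (years),
sex (indicator) and head coil (indicator).

**Feature construction.** Voxel maps are averaged over parcellation
regions (no resampling: map and label volume must share a grid). fALFF is
the ratio of summed spectral *amplitude* (square root of the single-taper
periodogram of the linearly detrended series, the amplitude convention of
the fALFF literature) over 0.01–0.10 Hz to the total over all positive
frequencies up to Nyquist; band edges are inclusive and membership is by
bin center, the zero-frequency term is excluded, so the measure is
invariant to additive constants. FC is the Pearson correlation of each
unordered pair of regional time courses; SC matrices are symmetrized as
(M + Mᵀ)/2 and vectorized with the same strictly lexicographic (i < j)
pair ordering, which fixes column identity across runs. Note that fALFF
computed on series already band-passed to the analysis band is ≈ 1
everywhere and carries no contrast; the function computes the ratio on
whatever series it receives, and supplying unfiltered series is the
caller's decision.

**Screening.** B = 100 stratified bootstrap resamples (class sizes
preserved — unstratified resamples of 42 subjects can lose a class; an
unstratified mode redraws up to 100 times). The per-resample test is a
likelihood-ratio test by default: Wald statistics degenerate under the
separation that small resamples produce, while the LRT remains computable
from the deviance difference under a capped iteration budget. A separated
feature gets the smallest representable positive p-value and a flag; a
constant feature gets p = 1 with a warning. Covariate adjustment inside the
screening models is off by default (each feature is tested independently)
and available as a switch. The retention rule p* ≥ r with r = 0.75 and
modality thresholds p₀ (VBM/fALFF/FA/SC 0.2, FC 0.05) is monotone in both
r and p₀ by construction. Because resamples of one cohort are strongly
dependent, p* measures within-sample robustness, not an error rate: a pure
noise feature is retained at p₀ = 0.05 in roughly 2% of cases (measured),
namely when its full-sample association is strong by chance.

**Elastic net.** The objective uses the 1/n-averaged log-likelihood
exactly, so λ is sample-size invariant. The intercept and covariates are
unpenalized by default; `penalize_intercept` exists for literal
reproduction of an intercept-in-penalty formulation, which we consider a
typographical artifact since a penalized intercept breaks label-recoding
symmetry. Standardization (zero sum, unit mean square, divisor n) is
computed on the training fold and applied to held-out data with the
*fit's* centers and scales — no leakage; a `global` mode standardizes once
on the full sample. Solver: for α = 0 the objective is smooth and is
minimized by L-BFGS-B; otherwise FISTA (proximal gradient with Nesterov
momentum and adaptive restart) with the L1 part handled by
soft-thresholding of the feature block, one design matvec per iterate, and
periodic exact damped-Newton solves of the unpenalized block. The Newton
block matters: when the covariates alone separate a small training half —
frequent at n = 21 with a strongly group-shifted age — the unpenalized MLE
component diverges and first-order methods crawl logarithmically; Newton
saturates those directions in a few steps. Convergence is declared when
the relative objective change stays below `solver_tol` (default 1e-8) for
two consecutive iterates, or when a restart from the current iterate
cannot descend; hitting `max_iter` (default 1000; 300 in the desk-scale
sweeps) flags the fit as non-converged but still returns it, since the
degenerate near-separable points of the grid have no finite optimum to
converge to. Correctness is defined by objective equivalence with a
generic convex optimizer (split-variable L-BFGS-B) and holds to ~1e-11 on
random instances with p ≤ 20. λ = 0 is allowed only on non-separable data
(checked by linear programming); otherwise an error advises λ > 0.

**Cross-validation.** Fold assignment is stratified by class by default
(per-fold class counts within one; unstratified folds of 42 subjects can
produce one-control validation sets). Each iteration derives its random
state from the master seed and iteration index only, so results are
identical under any parallel schedule. Per iteration the two folds' held
out probabilities are pooled into one ROC/AUC (per-fold averaging is an
option); AUC uses the rank/Mann–Whitney formulation with ties counted ½.
Mean ROC curves are vertical (TPR) averages at 101 evenly spaced FPR
points with step-function interpolation. Individual fit failures are
recorded per (α, λ, iteration) and excluded from aggregates rather than
aborting the sweep.

**Selection.** The strength threshold ξ at a grid point is the value of
the ⌊τ_S·p⌋-th largest mean |β|; features ≥ ξ form the strong set, so
with distinct values exactly ⌊τ_S·p⌋ features pass and ties at ξ are all
included (the rule uses ≥; with all values equal — e.g. all-zero
coefficients at strong shrinkage — every feature ties in, the documented
degenerate case). The same top-τ_S construction applied to the selection
proportion gives the report's selection-rate column. Direction is the sign
of the region-averaged mean coefficient; an exact zero is reported as 0
with a warning. Perfect separation is decided by linear feasibility with
margin 1e-6 on column-normalized data and coefficients bounded in sup
norm, because maximum-likelihood logistic fits diverge under separation;
every reported subset is re-checked strictly in raw coordinates, and the
enumeration is guarded at 1e6 combinations.

**Validation.** The null experiment permutes labels once per repeat
(group sizes preserved) and reruns the full iterated CV on a configurable
reduced grid; the verdict checks whether the across-repeat confidence
interval covers 0.5. The sensitivity analysis reuses the primary run's
stored fold assignments (a seed mismatch is an error), computes plain —
not bootstrap — univariate p-values inside each training sample, and
applies the 75% pass rule over the 200 samples.

## Synthetic cohorts

`generate_cohort` draws each block from a correlated Gaussian
(exchangeable within-block correlation ρ, default 0.2, via a shared
factor), plants standardized mean shifts (default: 5 features at 2.0) in
the cases, and emulates the cohort's demographics: ages N(61.9, 8.7²) for
cases and N(71.4, 5.8²) for controls, exactly 13 female cases and 8 female
controls, and a 36/6 head-coil split (5 cases, 1 control on the second
coil). The default dimension is 500 features (100/50/250/50/50 across the
five blocks) so that full sweeps finish in minutes; the full 46,580-feature
combinatorics are exercised in the feature-construction layer alone.
`generate_timecourses` imposes a target correlation through a symmetric
matrix square root and concentrates spectra in a configurable band.

What the cohorts do *not* emulate: spatial structure, hemodynamics,
disease topography, heavy tails, or site/motion artifacts. Passing tests
on these cohorts demonstrates that the machinery behaves as specified
under its own assumptions (Gaussian blocks, additive effects); it does not
certify performance on real imaging data.

Two consequences of the emulated demographics are worth stating plainly.
First, age genuinely predicts group (standardized difference ≈ 1.1), so a
"zero-effect" cohort is not information-free once covariates are adjusted
for: the chance-line calibration therefore runs the feature channel
without covariate adjustment, exactly as a label permutation would break
the covariate–label association. Second, CV on signal-free data is not
unbiased at 0.5 point-by-point: mid-shrinkage grid points show a real
anti-learning bias (training noise anti-correlates with held-out folds at
n = 42), and the CV mean conditional on one dataset has dataset-level
variance well above the naive per-iteration standard error. Chance-level
checks therefore either average the grid (whose heavy-shrinkage points sit
exactly at 0.5) or average several independent permutations.

## Desk-scale suite configuration

The test and acceptance runs use a reduced grid that subsamples the
reference 51 × 151 layout: α ∈ {0, 0.5, 1} and one λ per decade over
[10⁻⁵, 10¹] (21 points). The null-calibration run uses the full 100
iterations; the parameter-recovery suite uses 25 iterations and 20
generator seeds, with the per-fit iteration budget set to 300 (the capped
points are the degenerate near-separable ones, where the exact optimum is
at infinity anyway; statistics remain deterministic).

The recovery suite applies the CV sweep and consistency selection to all
500 features rather than the screened subset, because recovery of five
planted effects requires a strong-set budget ⌊τ_S·p⌋ ≥ 5, and the screen
retains ~15–30 features (budget ≤ 3). This is a real property of the
top-τ_S construction, visible in the README example: the selectivity of C
scales with the dimension it is applied to. Conversely, specificity comes
from screening — on zero-effect cohorts the full screened pipeline admits
at most a couple of features into C — while C applied to 500 raw features
keeps the ~50 strongest in-sample associations, most of them noise at
n = 42. The recovery suite's accuracy floor is relative
(q₁ = 0.95 × the grid's best mean AUC, with p₁ = 75 unchanged) because the
attainable AUC of a synthetic condition is set by the planted effect
sizes; an absolute 0.90 floor presumes data whose best model approaches
0.99.

## Known limitations

- Binary outcomes only; no multinomial or survival extensions.
- No image preprocessing, registration, or parcellation construction;
  all spatial inputs must already live on a common grid.
- The bootstrap pass-proportion is not a multiple-testing-corrected error
  rate and is reported as such.
- The separating-subset search is exhaustive and intended for consistency
  sets of a few dozen features; the combinatorial guard refuses larger
  enumerations rather than sampling them.
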