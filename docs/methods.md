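# Methods

## Model

The response is critical swimming speed (Ucrit) in body lengths per second
(BL s⁻¹), standardized before mixed-model analysis to units of standard
deviation from the grand mean (sample SD, n − 1 denominator) over all
retained observations. Standardizing an already standardized response is a
no-op up to numerical tolerance.

The mean structure is a quadratic thermal reaction norm on the centered
test-temperature axis TT = test °C − 28:

    ucrit_z = β0 + β1·sex + β2·TT + β3·TT² + β4·AT + β5·TT·AT + β6·TT²·AT
              + u(fish) + ε

Sex is coded 0 = female, 1 = male; the acclimation treatment AT is 0 for
20 °C and 1 for 28 °C, so β4–β6 are the warm-acclimation changes in height,
slope and curvature of the curve, and the cool treatment is the reference.
Centering at 28 °C places the linear slope β2 and curvature β3 near the
middle of the measured range.

Eight per-fish random-effect structures are compared (the "ladder"):
1 intercept; 2 +TT; 3 +TT²; 4 +TT+TT²; 5 +AT; 6 +AT+AT:TT; 7 +AT+AT:TT²;
8 +AT+AT:TT+AT:TT². Structures are compared by REML likelihood-ratio tests
(identical fixed part throughout) along the comparisons 2/3/4/5 vs 1,
6/7 vs 5 and 8 vs 1/5/6/7, and by AIC. Fixed effects are tested by ML
within model 1. The AT interactions enter the random design as single
numeric product columns (AT:TT = AT·TT), so model 8 has 4 random terms,
10 free covariance elements plus the residual variance.

### Parameter counting and tests

AIC = 2k − 2·loglik with k = 7 fixed effects + free covariance elements
(q(q+1)/2 for q random terms) + 1 residual variance, for both ML and REML
fits; since every ladder model shares the fixed part, the constant fixed
count never affects rankings. LRT degrees of freedom are differences in
variance-parameter counts only. Null variance components lie on the boundary
of the parameter space; the naive chi-square reference used here is then
conservative, and such comparisons are flagged (`boundary`).

Degrees of freedom for the fixed-effect t-tests default to the residual
count n_obs − 7 (the `df_method` hook accepts a callable for other
choices); estimates and standard errors do not depend on this choice.

### Fitting and numerical choices

Fitting is delegated to statsmodels `MixedLM` (profiled (restricted)
likelihood over variance parameters, gradient optimization). The profiled
surface for the richer covariances has flat ridges where a single gradient
run can stall far from the optimum, so `fit_lmm` multi-starts: a cold
start, a warm start embedded from a nested fit (the ladder feeds each model
its best nested predecessor; otherwise a cheap random-intercept prefit),
and a derivative-free Powell rescue whenever the best candidate falls below
the nested fit's log-likelihood — a logical impossibility at the true
optimum — or nothing converged. The highest-likelihood candidate wins; its
`converged` flag is reported, never swallowed. `dense_mvn_loglik`
cross-checks the engine by assembling each fish's marginal covariance
Z G Zᵀ + σ²I explicitly and evaluating the Gaussian (restricted)
log-density directly; the two agree to well below 1e-6 on small instances.

## Per-fish curves

Quadratics perf = a·T² + b·T + c are fitted per fish × acclimation by least
squares on the raw BL s⁻¹ scale and the uncentered temperature axis (three
points interpolate exactly; conditioning is a non-issue at this size). The
raw scale is deliberate: a standardized maximum can be ≤ 0, which makes "80%
of maximum" meaningless. The optimum is Topt = −b/(2a) with maximum
Pmax = c − b²/(4a); the breadth at fraction f (default 0.8) comprises the
roots of a·T² + b·T + (c − f·Pmax), which algebraically equals a symmetric
interval of width 2·√((1−f)·Pmax/(−a)) around Topt — both derivations are
computed and compared in the tests. Fish are excluded when the curve is
convex or flat (a ≥ 0), the maximum is nonpositive, or Topt ≥ 32 °C
(strict), since an optimum at or beyond the top test temperature cannot be
located reliably from the grid; exclusion reasons are reported per
treatment.

## Capacity and trade-offs

Acclimation capacity = 1 − (P28 − P20)/((P28 + P20)/2), where P20 and P28
are the measured Ucrit values at the matched acclimation/test conditions
(20/20 and 28/28 °C) — measured values, not fitted maxima, though the
capacity table accepts any positive performance pair. The index is 1 under
perfect compensation, scale-invariant, and satisfies
capacity(a,b) + capacity(b,a) = 2. Six OLS regressions (per treatment:
Pmax ~ capacity, B80 ~ capacity, B80 ~ Pmax) are computed on the
curve-included fish intersected with the capacity table, sexes pooled, no
multiplicity correction. F = R²·(n−2)/(1−R²) with df (1, n−2); cells with
fewer than 3 usable fish are flagged, not fatal.

## Synthetic data generator

The generator emulates the study design: 48 fish (20 male, 28 female), two
consecutive acclimation treatments, three test temperatures, one trial per
cell (288 observations). Standardized values are drawn from the model-8
structure — fixed coefficients (default: β = 0.49, −0.33, −0.076, −0.024,
0.27, 0.15, 0.011, the published estimates for the design it emulates) plus
a per-fish random vector (intercept, AT, AT:TT, AT:TT²) and Gaussian
residual noise — then mapped to BL s⁻¹ by raw_mean + raw_sd·z (defaults 7
and 2 BL s⁻¹, plausible for small poeciliids, floored at 0.1 BL s⁻¹).

Random-effect magnitudes are generator choices, not published quantities
(the source reports only model comparisons): SDs 0.5 (intercept), 0.4 (AT),
0.12 (AT:TT), 0.025 (AT:TT²), identity correlation, residual SD 0.5. They
are sized so that acclimation-response variation dominates individual
differences — the acclimation-shift model then outranks the acute-slope
models and the full model 8 wins the ladder on typical replicates,
mirroring the qualitative conclusion of the study design the generator
emulates. At these values the AT:TT and AT:TT² contributions at the extreme
test temperatures (|TT| up to 8, TT² up to 64) are comparable to the
residual SD, so they are detectable but not overwhelming. All four SDs and
the correlation matrix remain configurable.

Randomness derives from a single integer seed through per-fish child
streams (`numpy.random.SeedSequence.spawn`), so per-fish draws are stable
under reordering. Sexes are assigned deterministically (first
round(prop_male·n_fish) fish male). Optional dropout removes whole
fish × acclimation blocks, emulating pump failures (default off).

The flume-protocol simulator decomposes a "true" speed into the highest
fully-completed step U_f and failure time T_f and applies
Ucrit = U_f + T_f/T_i·U_i; the composition is the identity, which the
property tests exploit.

What the generator does **not** emulate: order effects of the consecutive
acclimation treatments (assumed reversible), tank effects or other crossed
grouping, measurement error in body length, non-Gaussian residuals, and any
dependence of dropout on performance. Passing tests therefore demonstrate
correctness of the estimators and algebra under the stated generative
model, not robustness to those real-data features.

## Problem sizes in the checks

The dense-likelihood oracle runs on 5-fish (30-row) instances. The
parameter-recovery experiment uses 100 replicate datasets at the default
48-fish design, fit by REML with the generating (model 8) structure on the
generator's standardized scale, asserting mean recovery of each nonzero
coefficient within 10% and per-coefficient 95% Wald coverage within
[85%, 99%]. The model-selection experiment uses 50 replicates with the full
eight-model REML ladder. The acceptance script analyses one freshly
simulated 48-fish study per invocation.

## Known limitations

- Satterthwaite or Kenward–Roger degrees of freedom are not implemented;
  p-values for fixed effects use residual df by default and will differ
  slightly from mixed-model software that uses Satterthwaite.
- The naive chi-square LRT reference is anti-conservative nowhere but
  conservative at boundary nulls; no 50:50 mixture correction is applied.
- With three test temperatures the per-fish quadratic is exactly identified;
  measurement noise propagates directly into Topt and breadth, which is why
  population-level inference runs through the mixed model instead.
- Optimizer multi-start makes ladder fits deterministic for fixed data, but
  REML surfaces with near-singular covariances can still converge to
  boundary solutions; these are flagged rather than repaired.
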