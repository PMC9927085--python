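# Methods

This note documents the models, estimators and numerical choices behind
`phageburst`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## The burst-size/lysis-time model

Mean burst size as a function of lysis time LT (minutes after induction) is
modelled phenomenologically as

    BS(LT) = k_max (e^{r(LT−D)} − 1) / (e^{r(LT50−D)} + e^{r(LT−D)} − 2),
    BS(LT) = 0 for LT ≤ D.

Parameters, units and defaults used for study-scale simulations:

| parameter | meaning | unit | study-scale value |
|---|---|---|---|
| k_max | cellular capacity: saturating burst size | PFU/cell | 1430 |
| LT50  | lysis time at half-maximal burst | min | 119 |
| r     | exponential accumulation rate | min⁻¹ | 0.027 |
| D     | delay before progeny appear | min | 25 |

The form is algebraically anchored: BS(D) = 0, BS(LT50) = k_max/2 exactly,
BS is monotone in LT and approaches k_max from below. The model is
deliberately phenomenological — it encodes an exponential rise that
saturates, not any mechanistic account of holin thresholds or assembly
kinetics. Validity requires k_max > 0, r > 0, D ≥ 0 and LT50 > D (otherwise
the denominator can vanish on LT ≥ D); these are enforced as constructor
invariants.

Numerics: the denominator is evaluated as expm1(a) + expm1(b) with
a = r(LT−D), b = r(LT50−D), which is exact near a → 0⁺; for max(a, b) > 700
(where exp overflows doubles) everything is rescaled by e^{−max(a,b)}. The
result is clipped at k_max to remove a possible 1-ulp division overshoot.
In double precision BS equals k_max exactly once a − b ≳ 36 e-foldings.

## Noise propagation

Writing BS = f(LT, k_max, LT50, r) and expanding to first order in small
cell-to-cell parameter deviations around their means, squaring and taking
expectations gives

    CV²_BS = S²_kmax CV²_kmax + S²_LT50 CV²_LT50 + S²_r CV²_r,

with dimensionless log-sensitivities (elasticities) S_x = (x̂/f) ∂f/∂x.
Parameters are assumed independent across cells, so no covariance terms
appear, and D is held at its mean. The sensitivities are implemented
analytically —

    S_kmax = 1 (identically, at every lysis time)
    S_LT50 = −r·LT50 e^{b} / (e^{a} + e^{b} − 2)
    S_r    = a/(1 − e^{−a}) − (a e^{a} + b e^{b}) / (e^{a} + e^{b} − 2)

— and cross-checked against central finite differences of log f in log x in
the test suite (agreement to 1e-6 relative). The identity S_kmax = 1 then
holds exactly rather than to finite-difference error. Both timing
sensitivities vanish as LT → ∞. Scientific consequence: a flat CV² profile
across lysis times indicates heterogeneity in cellular capacity k_max,
whereas CV² decaying toward zero indicates heterogeneity in timing
parameters. The pipeline's `decompose` stage tabulates the observed per-time
CV² next to the three pure-hypothesis predictions, each scaled by a single
least-squares factor, and reports the OLS slope of CV² against mean burst
size with t-based and pairs-bootstrap 95% CIs (descriptive, not a formal
test).

## Limiting-dilution design

Well occupancy is Poisson(λ). The package reports exact probabilities plus
the presentation forms used in plate design: nearest-integer percent of
k-cell wells, and the floor of the expected empty-well count (floor, not
round, reproduces the conventional design integers 74 at λ = 0.25 and 52 at
λ = 0.61 on 96 wells). The inverse, zero-class estimator is
λ̂ = −ln(n_empty/n_wells); it is undefined when no well is empty. The forward
design value (0.25) and the zero-class inversion of its own floored
expectation (0.260) differ slightly; both directions are exposed rather than
reconciled.

## Sample statistics

Per-lysis-time summaries use the n−1 standard deviation, CV = SD/mean, and
the biased moment skewness g1 = m₃/m₂^{3/2} with 1/n central moments (the R
`moments` convention); constant samples get skewness 0 by convention.
Wells with zero plaques are treated as empty, not as occupied wells with
burst 0 — a real assay cannot tell them apart. Outlier trimming removes
values strictly greater than twice the untrimmed mean, once (no iteration);
ties at exactly twice the mean are kept. Bootstrap CIs are seeded percentile
intervals over resampled wells (1000 replicates, 95% by default); BCa was
not implemented because the percentile interval is the minimal-assumption
choice and its endpoints are directly checkable as order statistics.
A multiplicative `correction` factor (e.g. 1/0.81 for the ~19% virion loss
from chloroform handling) can be applied to reported means; it is off by
default since the uncorrected scale is what the assay observes, and CV, CV²
and skewness are scale-free either way.

## Model fitting

The fit minimizes (optionally weighted) squared residuals of observed
per-time means against BS(LT). The domain is enforced by optimizing over
(ln k_max, ln(LT50 − D), ln r, D ≥ 0), so LT50 > D by construction. Because
the LT ≤ D clause makes the objective non-smooth in D, each start runs
Nelder-Mead first and then a derivative-based least-squares polish; the
default 10 seeded multi-starts jitter the automatic initializer (k_max from
the max mean; LT50 from the half-maximum crossing; D from the first positive
time minus one sampling interval; r from the log-linear rising-phase slope).
Non-convergence returns the best iterate flagged `converged=False`; fewer
than five distinct lysis times raises an identifiability error.

Identifiability deserves emphasis. With noiseless data the fit recovers the
generating parameters to ~1e-6 relative when the rise spans a few
e-foldings (r(LT50−D) ≈ 1–3.5, as in study-scale parameters where it is
≈ 2.5). When the rise spans many e-foldings the early points are
exponentially small and carry no weight in an unweighted loss, leaving D
effectively free. Under multiplicative measurement noise the same mechanism
makes unweighted fits of r and D fragile (linearized SDs of 9–35% at
study-scale designs); inverse-variance weighting (weights 1/SE, the correct
loss for multiplicative noise) restores them (r ≈ 4%, D ≈ 1–4% at a 10-min
design). The default remains unweighted — the convention for fitting plotted
means — with `weighting: inverse_variance` available in the pipeline config.
Parameter CIs by resampling wells within lysis times and refitting are
available as an add-on diagnostic (`bootstrap_param_cis`); they are this
package's addition, not part of the standard mean-curve fit.

## CV-equality tests

`cv_test_asymptotic` is the Feltz–Miller test: with v_i = s_i/x̄_i and
m_i = n_i − 1, D′AD = Σ m_i (v_i − v̄)² / (v̄²(0.5 + v̄²)) is compared to
chi-square(k−1). `cv_test_mslr` is a likelihood-ratio test of a common
normal CV: for fixed τ the restricted mean solves
τ²μ² + x̄μ − (s̃² + x̄²) = 0 in closed form, the profile over τ is a bounded
1-D optimization, and W = 2(l₁ − l₀) is compared to chi-square(k−1); with
`n_boot > 0` the p-value instead comes from a parametric bootstrap at the
restricted MLEs (the small-sample route; the second-order analytic
correction of the signed root is not implemented). Both tests hold their 5%
level to within about ±1 point at n = 100/group (verified by 2000-replicate
null simulation in the acceptance suite) and are scale-invariant. Burst-size
data are right-skewed rather than normal; the tests are applied to such data
as-is, which is the standard field usage, and their calibration on the
generator's occupied-well samples is what the pipeline relies on.

## Synthetic assays

`simulate_experiment` draws, per well, N ~ Poisson(λ); each cell gets
independent parameters with k_max, LT50, r lognormal (moment-matched to the
configured means and CV²s; gamma available) and D fixed; each cell's burst
is BS(LT_cell) rounded to whole virions; the well's total is thinned
Binomial(total, viability). Chemical mode lyses every cell exactly at the
plate's nominal time; natural mode draws per-cell lysis times from a normal
distribution truncated at D.

Generator defaults are the study conditions: λ = 0.25, 96 wells, viability
0.81, capacity-only heterogeneity CV²_kmax = 0.16 (CV 0.4 — the capacity
heterogeneity the flat noise profile points to, consistent with single-size
sorted-cell noise of ≈ 0.42), natural lysis mean 40.89 min with CV 0.05
(burst noise is an order of magnitude larger than lysis-time noise:
CV²_LT ≈ 2.5e-3 against CV²_BS ≈ 0.2). Scenario simulations that contrast
timing-driven noise use CV²_LT50 = 0.04, which keeps first-order propagation
valid at short lysis times where |S_LT50| ≈ 3.

What the generator reproduces, and what it omits: multi-cell wells create
the observed right skew (g1 mostly 0.5–2 at λ = 0.25–0.61) and inflate
occupied-well means by E[N | N≥1] = λ/(1−e^{−λ}); trimming at twice the mean
removes most of them (<10% of wells, mean reductions ≲ 15%). Not emulated:
pipetting/clumping departures from Poisson occupancy, plaque-counting error
beyond binomial thinning, adsorption losses, cell-volume covariates (a hook
exists but is off by default), and any parameter covariance across cells.
Passing tests on synthetic data therefore validate the estimators under the
model's own assumptions — Poisson occupancy, independent lognormal
parameters, binomial thinning — not the biology of a real lysate.

## Degenerate inputs and tie-breaks

Samples with n < 2 or zero mean raise; constant samples give CV 0,
skewness 0, and degenerate (point) bootstrap intervals. Sensitivities are
undefined at LT ≤ D and raise. Trimming keeps ties. Zero-CV² heterogeneity
components return the population mean exactly. A simulated plate with λ = 0
contains only empty wells and the summary stage reports an error rather
than a table.

## Problem sizes

Simulation-based checks use plate counts that give ≈ 100 occupied wells per
time point (the assay's own scale), 50-replicate recovery experiments, and
2000-replicate null calibrations; these sizes make every property check
sharp enough to discriminate the alternatives it targets while keeping the
full suite and the acceptance script fast on a single CPU.
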