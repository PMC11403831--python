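# Methods

## The model

`woundcurve` analyses longitudinal wound-area measurements from two-arm
intervention studies. The observed area of patient *i*'s wound at day *t*
is modelled multiplicatively,

    y_i(t) = y*_i(0) · f(t; ρ) · u_i(t),

where `y*_i(0)` is the true (error-free) baseline area, `f(t; ρ)` is a
*healing-rate function* giving the mean proportionate area at day *t*, and
`u_i(t)` is lognormal multiplicative noise. The multiplicative form encodes
three assumptions: measurement error is proportional to wound size (tracing
a larger boundary accumulates more error), biological variation in healing
is likewise proportionate, and all wounds share a common mean trajectory on
the proportionate scale with no lag phase. On the log scale the model is
linear:

    log y_i(t) = β₀ + α_i + log f(t; ρ_arm(i)) + e_it,
    α_i ~ N(0, τ²),   e_it ~ N(0, ω²).

The log-baselines are `w_i(0) ~ N(μ, τ²)` and the noise is centred so that
`E[u] = 1`, i.e. `log u ~ N(−ω²/2, ω²)`: measurements are unbiased on the
area scale. Collecting constants gives the identity used everywhere in this
package,

    β₀ = μ − ω²/2.

This reconciliation matters: with it, the mean-area multiplier
`exp(β₀ + (τ² + ω²)/2)` appearing in the treatment-effect formulas equals
`exp(μ + τ²/2)` — the population mean *true* baseline area — rather than
being inflated by `exp(ω²/2)`. β₀ is therefore a derived quantity, never a
free parameter.

Both arms share (μ, τ, ω); randomisation justifies a common baseline
distribution. Only the healing-rate parameters are arm-specific: `f₁(t; ρ₁)`
for treatment, `f₀(t; ρ₀)` for control.

## Healing-rate function families

Eleven families are implemented (`woundcurve.functions.registry()` lists
them), with analytic time derivatives throughout:

| family | f(t; ρ) | ρ dim |
|---|---|---|
| exponential | exp(−ρt) | 1 |
| gompertz | exp(1 − exp(pt)) | 1 |
| linear | 1 + pt | 1 |
| quadratic | 1 + p₁t + p₂t² | 2 |
| square_root | 1 + p₁t + p₂√t | 2 |
| wendland0 | (1 − s)₊^p, s = t/t_max | 1 |
| wendland1 | (1 + (p+1)s)(1 − s)₊^{p+1} | 1 |
| semiparametric | 1 − Σₘ pₘ hₘ(t) | M |
| log_linear | exp(1 + pt) | 1 |
| log_quadratic | exp(1 + p₁t + p₂t²) | 2 |
| log_square_root | exp(1 + p₁t + p₂√t) | 2 |

Notes on the less obvious choices:

* **Wendland families.** These are compactly supported: after rescaling
  time by `t_max` (default 100 days — beyond the trial horizon, so that
  area need not reach zero within the study) they are *exactly* zero at
  `t = t_max` and beyond, letting a mean trajectory reach complete healing
  at finite time. For Wendland 1 the form `(1+(p+1)s)(1+s)^{p+1}` is
  sometimes printed, but it cannot vanish at `s = 1`; the standard
  compactly supported form with `(1−s)₊^{p+1}` is used here. The
  non-vanishing variant remains available behind the
  `wendland_as_printed` audit flag.
* **Log families.** The constant `1` inside the exponential is retained,
  so `f(0) = e` rather than 1. It is absorbed by β₀ (a pure shift), but
  keeping it makes fitted β₀ values directly comparable with the usual
  presentation of these curves; posterior β₀ for log families should be
  interpreted with this offset in mind. The other eight families satisfy
  `f(0) = 1` exactly.
* **Semiparametric family.** A clamped cubic B-spline basis with five
  evenly spaced knots over the observed time range (giving M = 7 basis
  columns). Each raw column is shifted by its value at `t = 0`, so every
  `hₘ(0) = 0` and `f(0) = 1` holds structurally; this anchoring also keeps
  the coefficients identifiable against β₀, which a free spline would not
  be.
* **Square-root derivative at the origin.** `df/dt` contains `1/(2√t)`;
  at `t = 0` the implementation raises a domain error rather than
  returning ±∞. Rate estimands therefore evaluate derivatives only at
  `t > 0`.

## Priors

Weakly informative, chosen to bracket the plausible clinical range
(baseline areas restricted to 2–20 cm² by typical inclusion criteria,
noise up to ±100%):

| parameter | prior | default |
|---|---|---|
| μ (mean log baseline area) | N(1, 2²) | — |
| τ (between-patient sd) | N(0, 2²) truncated to [0, ∞) | — |
| ω (measurement-error sd) | N(0, 0.5²) truncated to [0, ∞) | — |
| each ρ component | N(0, sd²), sd configurable | sd = 1 |

Time stays in days (no internal rescaling), so the per-day rates in the
families have small magnitude and an sd-1 prior on ρ is very diffuse;
`PriorSpec(rho_sd=...)` adjusts it.

## Posterior computation

The patient intercepts α_i enter the Gaussian log-scale likelihood
linearly, so they are integrated out analytically: for patient *i* with
n_i observations and residuals `r = log y − β₀ − log f(t)`, the marginal
covariance is compound-symmetric, `ω²I + τ²J`, with

    log|Σ| = (n_i − 1) log ω² + log(ω² + n_i τ²),
    r'Σ⁻¹r = [Σr² − τ²(Σr)²/(ω² + n_i τ²)]/ω².

This leaves a 3 + 2k–dimensional marginal posterior (k = ρ arity), which
is sampled with the affine-invariant ensemble sampler (`emcee`): gradient
free, well suited to the correlated low-dimensional ridges these targets
exhibit (notably between p₁ and p₂ in the square-root families).
`FitConfig.chains` independent ensembles are run from seeds derived from
one master seed; identical seed and configuration reproduce draws exactly.
Defaults are 4 chains, 16 walkers, 1000 adaptation steps, and 1000
retained draws per chain after thinning ensemble steps (thin = 5).

After sampling, each retained draw's α vector is drawn *exactly* from its
conjugate Normal conditional,

    α_i | θ, y ~ N(v_i Σr/ω², v_i),   v_i = (1/τ² + n_i/ω²)⁻¹,

and the pointwise log-likelihood matrix (draws × observations,
conditional on α) is assembled for model comparison. Because the
marginalisation is exact, no non-centred reparameterisation is needed —
the sampler never sees the α dimensions at all.

Other numerical choices:

* **Positivity of f.** For linear-scale families, ρ regions where
  `f(t) ≤ 0` at an observed time get log-posterior −∞ (soft rejection)
  rather than hard constraints, because the admissible region depends on
  the observed time range.
* **Initialisation.** μ starts at the log mean baseline area, τ and ω at
  half their prior sd, ρ at small family-appropriate values (decay
  presumed); walkers are jittered, each retrying up to 100 times for a
  start with `f > 0` everywhere, after which initialisation fails loudly.
  With an empty dataset walkers start from prior draws, so the sampler
  reproduces the prior (verified by a calibration test).
* **Diagnostics.** Split R-hat and ESS (via ArviZ) over the ensemble
  chains; R-hat > 1.01 warns but never fails (ensemble walkers are
  correlated within a chain, so R-hat on modest runs reads high even when
  quantiles are accurate). The divergence count is reported as 0: the
  ensemble sampler has no divergence concept; acceptance fractions are
  recorded instead.
* **Likelihood scale.** The pointwise log-likelihood is for `log(area)`
  without the lognormal Jacobian −log y. The Jacobian is parameter-free
  and identical across all families, so LOO/WAIC *differences* — the only
  quantities compared — are unaffected; absolute elpd values are on the
  log-area scale.
* **Zero areas.** A recorded area of 0 cannot enter a lognormal
  likelihood. Default policy: drop with a logged count. Alternative:
  treat as left-censored below a detection limit, contributing
  `Φ((log ε − mean)/ω)`; censored rows are supported by the explicit
  pointwise likelihood but not by the marginal sampler (they would break
  the closed-form integral), so fitting requires the drop policy.

## Model comparison

WAIC and PSIS-LOO are computed from the pointwise log-likelihood matrix
and reported on the **elpd scale (larger = better)** in all outputs.
WAIC is `Σᵢ [log meanₛ exp(llₛᵢ) − varₛ(llₛᵢ)]` with log-sum-exp guarding;
a single draw gives a zero penalty by convention. PSIS-LOO smooths the
importance ratios `exp(−ll)` per observation — generalised-Pareto fit to
the largest 20% of ratios, replacement by expected order statistics,
truncation at the raw maximum (the ArviZ implementation of this standard
procedure is used for the smoothing step) — and flags, never drops,
observations with shape diagnostic k > 0.7. LOO is observation-level;
patient-level (grouped) LOO is a possible extension, not implemented.

Posterior predictive checks replicate the full dataset at the observed
design points for each of K (default 50) evenly spaced draws and overlay
the replicated area densities (blue) on the observed density (red). The
check is primarily graphical; a pointwise density-envelope coverage number
(fraction of grid points where the observed density lies inside the
replicate min–max envelope) is also returned so tests can assert on it.

## Treatment-effect estimands

Per posterior draw, then summarised by mean and central 95% interval:

* **δ₁(t)** = `exp(β₀ + (τ²+ω²)/2)(f₁(t) − f₀(t))` in cm² — equivalently
  `exp(μ + τ²/2)(f₁ − f₀)` under the β₀ identity.
* **δ₂(t)** = `f₁(t) − f₀(t)`, dimensionless. By default the printed form
  is reported verbatim; `normalize=True` divides each arm by its own
  `f(0)`, forcing the curve through 0 at baseline — the honest
  "proportionate" reading for the log families, whose raw `f(0) = e`.
* **Rate difference** (reconstruction from the model's first principles;
  both modes are exposed and labelled): instantaneous
  `exp(μ + τ²/2)(f₁′(t) − f₀′(t))`, or average-to-T
  `exp(μ + τ²/2)[(f₁(T) − f₁(0)) − (f₀(T) − f₀(0))]/T`, in cm²/day.
* **Proportion healed** (likewise a model-based reconstruction): the true
  area at *t* is lognormal, `log y*(t) ~ N(μ + log f(t), τ²)`, so
  `P(y* ≤ c) = Φ((log c − μ − log f(t))/τ)` per arm, plus the arm
  difference. The default threshold c = 0.25 cm² is an arbitrary
  near-complete-re-epithelialisation proxy; it is user-set and carries no
  external authority. Draws with τ = 0 degenerate to a step function
  (value ½ exactly at the boundary).
* **Non-parametric comparator.** Welch difference in means of each
  patient's measurement nearest to a landmark day (default 42) within
  ±3.5 days, with a t interval — the estimator a trial would use without
  a model, kept for precision comparisons.

Draws where a linear-scale f goes non-positive on the requested grid are
dropped from estimand summaries with a logged count.

## The synthetic-trial generator

`generate_trial` emulates a two-arm ulcer-healing RCT: 130 patients,
1:1 randomisation, visits at alternating 3/4-day gaps from day 0 to 70,
baseline areas from `N(μ, τ²)` on the log scale truncated so that
`exp(w) ∈ [2, 20]` cm² (the inclusion criterion), up to three measurement
methods per visit with independent lognormal errors (per-method sd
configurable, defaulting to the model ω), optional per-visit dropout and
optional stopping once the true area crosses a healing threshold.

The baseline truncation is deliberate, mild model misspecification — the
fitted model assumes an untruncated Gaussian — and can be switched off
(`truncate_baseline=False`) for exact-recovery experiments. What the
generator does *not* emulate: assessor disagreement about healing,
image-level artefacts, correlated errors between methods at the same
visit (methods are conditionally independent given the true area), or
wound-specific departures from the common trajectory shape. Passing
recovery tests therefore demonstrates internal consistency of
model + sampler + estimands, not robustness to the messiness of real
trial data.

Experiment defaults (`woundcurve.experiments`): baseline `μ = log 4.2`,
`τ = 0.5` (mean enrolment area ≈ 4.5 cm², consistent with a 2–20 cm²
inclusion window), `ω = 0.3` (≈30% measurement noise, inside the
plausible 0.2–0.5 band for image-based area tracing), square-root truth
`ρ₀ = (0.005, −0.12)`, `ρ₁ = (0.004, −0.10)` (area ≈ one third of
baseline by day 70, small treatment benefit), exponential truth
`ρ₀ = 0.030`, `ρ₁ = 0.025`.

## Problem sizes in the experiment suite

The operating-characteristics experiments use 20 replicate trials of 130
patients (21 visits, one measurement method) with 2 ensembles × 24
walkers, 500 adaptation steps and 1000 retained draws per fit; the
PSIS-vs-exact-LOO comparison uses a 20-patient, 4-visit instance with 10
single-observation refits; Monte-Carlo oracles (mean-one error, δ₁) use
10⁶ draws. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the whole suite runnable on a single
CPU in minutes.

## Known limitations

* Additive-error (linear-scale) specifications are out of scope by
  design; the package commits to the multiplicative-error structure.
* One wound per patient; no multi-wound nesting.
* Methods are fitted separately; no joint multi-method measurement-error
  model.
* No autoregressive trajectory model and no lag-phase/delay term.
* Gompertz with p < 0 is increasing; it is accepted (the prior is
  symmetric) but scientifically intended for p > 0.
* The marginal sampler requires ω > 0; exact zero-noise data cannot be
  fitted (and would not need to be).
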