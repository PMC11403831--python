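# woundcurve

Model-based analysis of longitudinal wound-area measurements in
intervention studies.

Trials of wound- and ulcer-healing interventions usually compare mean
area, or the proportion healed, at a single landmark day — throwing away
the many measurements made at every dressing change in between. For
statisticians and trialists analysing such studies, `woundcurve` instead
fits a Bayesian hierarchical model to *all* measurements, compares a menu
of plausible healing trajectories by out-of-sample fit, and derives
treatment-effect curves over the whole trial timeline, typically with far
narrower intervals than the landmark comparison.

## The model

Observed area of patient *i*'s wound at day *t*:

    y_i(t) = y*_i(0) · f(t; ρ) · u_i(t)

— true baseline area, times a *healing-rate function* (mean proportionate
area at day *t*), times lognormal multiplicative error with mean one.
On the log scale this is a linear mixed model:

    log y_i(t) = β₀ + α_i + log f(t; ρ_arm) + e_it,
    α_i ~ N(0, τ²),  e_it ~ N(0, ω²),  β₀ = μ − ω²/2,

with `w_i(0) = log y*_i(0) ~ N(μ, τ²)`. Both arms share (μ, τ, ω); the
trajectory parameters ρ are arm-specific. Eleven trajectory families are
available — exponential, Gompertz, linear, quadratic, square-root, two
compactly supported Wendland functions (exactly zero area at a finite
horizon), a B-spline semiparametric form, and log-scale variants of the
polynomial/square-root families. Models are compared by PSIS-LOO and
WAIC (reported on the elpd scale, larger = better) plus graphical
posterior predictive checks. From the posterior the package derives:

* **δ₁(t)** = `exp(β₀ + (τ²+ω²)/2)(f₁(t) − f₀(t))` — mean area
  difference (cm²);
* **δ₂(t)** = `f₁(t) − f₀(t)` — proportionate area difference;
* healing-**rate** differences (instantaneous or averaged to *T*);
* **proportion healed** below a threshold, per arm and difference;
* a non-parametric Welch landmark comparator for precision benchmarking.

Sampling uses an affine-invariant ensemble MCMC on the *marginal*
posterior (patient intercepts are integrated out analytically and then
recovered exactly from their conjugate conditional). See
`docs/methods.md` for the full account.

## Worked example

Simulate a 130-patient trial with a square-root healing trajectory and a
small treatment benefit, fit the generating family, and derive effects:

```python
import numpy as np
from woundcurve import *

truth = ModelSpec(family=Family.SQUARE_ROOT, mu=np.log(4.2), tau=0.5,
                  omega=0.3, arm_rho={0: [0.005, -0.12], 1: [0.004, -0.10]})
table, record = generate_trial(
    TrialDesign(methods={"ARANZ Automatic": None}), truth, seed=1)

tmpl = ModelTemplate(family=Family.SQUARE_ROOT)
samples = fit(tmpl, table, FitConfig(chains=2, walkers=24, warmup=500,
                                     draws=500, thin=5, seed=1))
sc = score(samples.loglik_matrix, label="square_root")
curve = delta1(samples, tmpl, np.array([14.0, 42.0, 70.0]))
welch = nonparametric_difference(table, day=42.0)
```

Output:

```
rows: 2730 patients: 130
elpd_loo = -634.6, elpd_waic = -633.8, p_loo = 130.3
delta1(14 d) = +0.214 cm^2 (95% CrI +0.007, +0.466)
delta1(42 d) = +0.416 cm^2 (95% CrI +0.224, +0.640)
delta1(70 d) = +0.578 cm^2 (95% CrI +0.428, +0.730)
Welch at 42 d = +0.659 cm^2 (95% CI +0.162, +1.156)
```

The generating model puts the treated arm's proportionate area above the
control arm's (a *harmful* dummy intervention: ρ₁ decays more slowly), and
the fitted δ₁ curve tracks that: the mean area difference grows over the
trial and its 95% credible interval excludes zero from about two weeks.
`p_loo ≈ 130` reflects the 130 patient intercepts. The model-based
interval at day 42 (width 0.42 cm²) is less than half the width of the
Welch landmark interval (0.99 cm²) computed from the same trial — the
precision gain from using every visit rather than one.

The same pipeline is scriptable from the shell:

```sh
woundcurve simulate --n 130 --seed 1 --out trial.csv
woundcurve run --data trial.csv --families square_root,exponential,gompertz
woundcurve fit --data trial.csv --family square_root --seed 1 --out posterior
woundcurve effects --data trial.csv --posterior posterior --estimand delta2
```

`woundcurve run` writes a model-comparison CSV, PPC figures, effect-curve
CSVs/figures, and a manifest embedding the seed and config hash.

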