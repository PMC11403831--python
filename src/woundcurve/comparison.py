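"""Model comparison: WAIC, PSIS-LOO, and posterior predictive checks.

Both criteria are reported on the *elpd scale* — expected log pointwise
predictive density, larger is better — matching the convention in which
the best-fitting model has the largest LOO-CV/WAIC value.  They consume
the pointwise log-likelihood matrix (draws x observations) produced by
:func:`woundcurve.inference.fit`.

The Pareto-smoothed importance sampling step inside ``psis_loo`` uses the
reference smoothing implementation from ArviZ (generalised-Pareto fit to
the largest importance ratios, replacement by expected order statistics,
truncation at the raw maximum); elpd assembly and diagnostics are local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .inference import ModelTemplate, PosteriorSamples
from .model import MeasurementTable
from .functions import evaluate as f_eval

#: Pareto-k thresholds from the PSIS methodology: k < 0.5 good,
#: 0.5-0.7 usable, > 0.7 unreliable.
PARETO_K_GOOD = 0.5
PARETO_K_BAD = 0.7


@dataclass
class FitScore:
    """Goodness-of-fit summary for one fitted model."""

    label: str
    elpd_loo: float
    elpd_waic: float
    p_loo: float
    p_waic: float
    lppd: float
    pareto_k: np.ndarray = field(repr=False)
    n_bad_k: int = 0

    def as_row(self) -> dict:
        return {
            "model": self.label,
            "elpd_loo": self.elpd_loo,
            "elpd_waic": self.elpd_waic,
            "p_loo": self.p_loo,
            "p_waic": self.p_waic,
            "n_bad_pareto_k": self.n_bad_k,
        }


def _validate(loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik matrix must be 2-D (draws x observations)")
    if ll.shape[0] < 1 or ll.shape[1] < 1:
        raise ValueError("need at least one draw and one observation")
    if np.any(np.all(np.isneginf(ll), axis=0)):
        raise ValueError("an observation has -inf log-likelihood in every draw")
    return ll


def waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """(elpd_waic, p_waic, lppd) from a (draws, observations) matrix.

    elpd_waic_i = log mean_s exp(ll_si) - var_s(ll_si); the log-mean is
    computed with log-sum-exp.  With a single draw the variance penalty is
    zero by convention and elpd_waic equals the summed log-likelihood.
    """
    ll = _validate(loglik)
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    if S > 1:
        p_i = np.var(ll, axis=0, ddof=1)
    else:
        p_i = np.zeros(ll.shape[1])
    return float(np.sum(lppd_i - p_i)), float(np.sum(p_i)), float(np.sum(lppd_i))


def psis_loo(loglik: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(elpd_loo, p_loo, pareto_k) via Pareto-smoothed importance sampling.

    Importance ratios r_si = exp(-ll_si) are tail-smoothed per observation;
    elpd_loo_i = log(sum_s w_si exp(ll_si) / sum_s w_si).  Observations
    with shape diagnostic k > 0.7 are flagged (never dropped).  Columns
    with (numerically) constant log-likelihood are exact: the weights are
    uniform and elpd_loo_i reduces to the common value, with k = -inf.
    """
    import arviz as az

    ll = _validate(loglik)
    S = ll.shape[0]
    if S < 100:
        warnings.warn(
            f"only {S} draws: PSIS-LOO is unreliable below ~100 draws",
            stacklevel=2,
        )
    spread = ll.max(axis=0) - ll.min(axis=0)
    const = spread < 1e-12
    elpd_i = np.empty(ll.shape[1])
    k = np.full(ll.shape[1], -np.inf)
    if (~const).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lw, k_hat = az.psislw(-ll[:, ~const].T)  # (n_obs, n_samples)
        lw = np.asarray(lw)
        elpd_i[~const] = logsumexp(lw + ll[:, ~const].T, axis=1)
        k[~const] = np.asarray(k_hat)
    if const.any():
        elpd_i[const] = ll[0, const]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    elpd = float(np.sum(elpd_i))
    return elpd, float(np.sum(lppd_i) - elpd), k


def score(loglik: np.ndarray, label: str = "model") -> FitScore:
    """Full FitScore (both criteria) from one log-likelihood matrix."""
    elpd_waic, p_waic, lppd = waic(loglik)
    elpd_loo, p_loo, k = psis_loo(loglik)
    return FitScore(
        label=label, elpd_loo=elpd_loo, elpd_waic=elpd_waic,
        p_loo=p_loo, p_waic=p_waic, lppd=lppd, pareto_k=k,
        n_bad_k=int(np.sum(k > PARETO_K_BAD)),
    )


def comparison_table(scores: list[FitScore]):
    """Model-by-criteria table, best (largest elpd_loo) first."""
    import pandas as pd

    rows = sorted((s.as_row() for s in scores),
                  key=lambda r: -r["elpd_loo"])
    return pd.DataFrame(rows)


@dataclass
class PPCResult:
    """Replicated datasets and density overlays for a graphical check."""

    replicates: np.ndarray      # (K, N) replicated areas at observed design
    observed: np.ndarray        # (N,) observed areas
    grid: np.ndarray            # density evaluation grid (cm^2)
    rep_density: np.ndarray     # (K, len(grid))
    obs_density: np.ndarray     # (len(grid),)
    envelope_coverage: float    # fraction of grid pts inside the rep envelope

    def plot(self, path=None, title: str = "Posterior predictive check"):
        """Observed density (red) under replicate densities (blue)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for dens in self.rep_density:
            ax.plot(self.grid, dens, color="steelblue", alpha=0.25, lw=0.8)
        ax.plot(self.grid, self.obs_density, color="crimson", lw=2,
                label="observed")
        ax.set_xlabel("wound area (cm$^2$)")
        ax.set_ylabel("density")
        ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def posterior_predictive_check(
    samples: PosteriorSamples,
    template: ModelTemplate,
    data: MeasurementTable,
    n_rep: int = 50,
    seed: int = 0,
) -> PPCResult:
    """Simulate replicated datasets at the observed design points.

    For each of ``n_rep`` evenly spaced posterior draws, a full replicated
    dataset is generated (same patients, arms, and visit days, with the
    draw's alpha_i and a fresh measurement error), and its area density is
    overlaid on the observed density.
    """
    total = samples.n_chains * samples.n_draws
    if total < 20:
        raise ValueError("need at least 20 retained draws for a PPC")
    n_rep = min(n_rep, total)
    rng = np.random.default_rng(seed)
    df = data.df
    day = df["day"].to_numpy()
    arm = df["arm"].to_numpy()
    codes, uniques = data.patient_codes()
    pid_index = {p: i for i, p in enumerate(samples.patient_ids)}
    cols = np.array([pid_index[p] for p in uniques])[codes]
    observed = df["area_cm2"].to_numpy()

    idx = np.linspace(0, total - 1, n_rep).astype(int)
    mu = samples.flat("mu")[idx]
    omega = samples.flat("omega")[idx]
    rho0 = samples.flat("rho0")[idx]
    rho1 = samples.flat("rho1")[idx]
    alpha = samples.flat("alpha")[idx]

    reps = np.empty((n_rep, len(df)))
    for r in range(n_rep):
        logf = np.empty(len(df))
        for a, rho in ((0, rho0[r]), (1, rho1[r])):
            m = arm == a
            if m.any():
                f = np.atleast_1d(f_eval(template.function_spec(rho), day[m]))
                logf[m] = np.log(np.clip(f, 1e-300, None))
        mean = (mu[r] - omega[r] ** 2 / 2.0) + alpha[r, cols] + logf
        reps[r] = np.exp(mean + omega[r] * rng.standard_normal(len(df)))

    hi = max(observed.max(), np.percentile(reps, 99.5))
    grid = np.linspace(0.0, hi, 128)
    obs_density = gaussian_kde(observed)(grid)
    rep_density = np.vstack([gaussian_kde(reps[r])(grid)
                             for r in range(n_rep)])
    lo_env = rep_density.min(axis=0)
    hi_env = rep_density.max(axis=0)
    cover = float(np.mean((obs_density >= lo_env) & (obs_density <= hi_env)))
    return PPCResult(replicates=reps, observed=observed, grid=grid,
                     rep_density=rep_density, obs_density=obs_density,
                     envelope_coverage=cover)
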