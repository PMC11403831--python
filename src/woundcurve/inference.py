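"""Posterior sampling for the hierarchical wound-area model.

The sampler targets the *marginal* posterior of (mu, tau, omega, rho_0,
rho_1): the patient random intercepts alpha_i enter the Gaussian likelihood
linearly, so they are integrated out in closed form.  For patient i with
n_i observations and residual vector r_i = log y - beta0 - log f(t), the
marginal covariance is the compound-symmetry matrix omega^2 I + tau^2 J,
whose determinant and quadratic form reduce to per-patient sums:

    log|Sigma_i|    = (n_i - 1) log omega^2 + log(omega^2 + n_i tau^2)
    r' Sigma^-1 r   = [S2_i - tau^2 S1_i^2 / (omega^2 + n_i tau^2)] / omega^2

with S1_i = sum(r), S2_i = sum(r^2).  This leaves a 3 + 2k dimensional
target (k = rho arity), which an affine-invariant ensemble sampler (emcee)
explores efficiently without gradients.  After sampling, alpha_i is drawn
*exactly* from its conjugate Normal conditional for every retained draw,
and the pointwise log-likelihood matrix is assembled for LOO/WAIC.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import emcee
import numpy as np
import pandas as pd

from .functions import Family, FAMILY_ARITY, HealingFunctionSpec, SplineBasis
from .functions import evaluate as f_eval
from .model import MeasurementTable, ModelSpec, PriorSpec

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelTemplate:
    """A model with the family and priors fixed but parameters free."""

    family: Family
    priors: PriorSpec = field(default_factory=PriorSpec)
    t_max: float = 100.0
    basis: SplineBasis | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.family is Family.SEMIPARAMETRIC and self.basis is None:
            raise ValueError("semiparametric template requires a SplineBasis")

    @property
    def rho_dim(self) -> int:
        arity = FAMILY_ARITY[self.family]
        return self.basis.basis_count if arity is None else arity

    def function_spec(self, rho: np.ndarray) -> HealingFunctionSpec:
        return HealingFunctionSpec(family=self.family, rho=rho,
                                   t_max=self.t_max, basis=self.basis)

    def model_spec(self, mu, tau, omega, rho0, rho1) -> ModelSpec:
        return ModelSpec(family=self.family, mu=mu, tau=tau, omega=omega,
                         arm_rho={0: rho0, 1: rho1}, priors=self.priors,
                         t_max=self.t_max, basis=self.basis)


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings: independent ensembles ("chains") of walkers."""

    chains: int = 4
    walkers: int = 16
    warmup: int = 1000
    draws: int = 1000  # retained draws per chain (after thinning/flattening)
    thin: int = 5      # post-warmup thinning of ensemble steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")
        if self.walkers < 8 or self.walkers % 2:
            raise ValueError("walkers must be an even number >= 8")


@dataclass
class PosteriorSamples:
    """Posterior draws indexed (chain, draw), plus pointwise log-likelihood.

    ``loglik`` holds the per-observation log density (columns follow the
    row order of the fitted table) conditional on the sampled alpha_i,
    which is what observation-level LOO/WAIC consume.
    """

    mu: np.ndarray            # (C, D)
    tau: np.ndarray           # (C, D)
    omega: np.ndarray         # (C, D)
    rho0: np.ndarray          # (C, D, k)
    rho1: np.ndarray          # (C, D, k)
    alpha: np.ndarray         # (C, D, P)
    loglik: np.ndarray        # (C, D, N)
    patient_ids: np.ndarray   # (P,)
    meta: dict

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def loglik_matrix(self) -> np.ndarray:
        """Flattened (total draws, n_obs) pointwise log-likelihood."""
        C, D, N = self.loglik.shape
        return self.loglik.reshape(C * D, N)

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def to_inference_data(self):
        """ArviZ InferenceData with posterior and log_likelihood groups."""
        import arviz as az

        posterior = {
            "mu": self.mu, "tau": self.tau, "omega": self.omega,
            "rho0": self.rho0, "rho1": self.rho1,
        }
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"obs": self.loglik},
        )

    # -- persistence: CSV per chain + npz for the loglik matrix ----------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        k = self.rho0.shape[2]
        for c in range(self.n_chains):
            cols = {"mu": self.mu[c], "tau": self.tau[c], "omega": self.omega[c]}
            for j in range(k):
                cols[f"rho0_{j}"] = self.rho0[c, :, j]
                cols[f"rho1_{j}"] = self.rho1[c, :, j]
            for p, pid in enumerate(self.patient_ids):
                cols[f"alpha_{pid}"] = self.alpha[c, :, p]
            pd.DataFrame(cols).to_csv(d / f"chain_{c}.csv", index=False)
        np.savez_compressed(d / "loglik.npz", loglik=self.loglik)
        (d / "meta.json").write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSamples":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        chains = sorted(d.glob("chain_*.csv"),
                        key=lambda p: int(p.stem.split("_")[1]))
        frames = [pd.read_csv(p) for p in chains]
        k = sum(c.startswith("rho0_") for c in frames[0].columns)
        pids = [c[len("alpha_"):] for c in frames[0].columns
                if c.startswith("alpha_")]
        mu = np.stack([f["mu"].to_numpy() for f in frames])
        tau = np.stack([f["tau"].to_numpy() for f in frames])
        omega = np.stack([f["omega"].to_numpy() for f in frames])
        rho0 = np.stack([f[[f"rho0_{j}" for j in range(k)]].to_numpy()
                         for f in frames])
        rho1 = np.stack([f[[f"rho1_{j}" for j in range(k)]].to_numpy()
                         for f in frames])
        alpha = np.stack([f[[f"alpha_{p}" for p in pids]].to_numpy()
                          for f in frames])
        loglik = np.load(d / "loglik.npz")["loglik"]
        return cls(mu=mu, tau=tau, omega=omega, rho0=rho0, rho1=rho1,
                   alpha=alpha, loglik=loglik,
                   patient_ids=np.array(pids), meta=meta)


class _Problem:
    """Pre-digested data arrays for fast repeated likelihood evaluation."""

    def __init__(self, template: ModelTemplate, data: MeasurementTable):
        self.template = template
        df = data.df
        if df["censored"].any():
            raise ValueError(
                "censored rows cannot enter the marginal sampler; drop them "
                "or use the explicit-alpha likelihood"
            )
        self.logy = np.log(df["area_cm2"].to_numpy())
        self.day = df["day"].to_numpy()
        self.arm = df["arm"].to_numpy()
        self.codes, self.patient_ids = data.patient_codes()
        self.n_obs = len(df)
        self.n_patients = len(self.patient_ids)
        # unique days per arm -> evaluate f once per unique time
        self.arm_masks, self.u_days, self.inv = {}, {}, {}
        for a in (0, 1):
            m = self.arm == a
            self.arm_masks[a] = m
            u, inv = np.unique(self.day[m], return_inverse=True)
            self.u_days[a], self.inv[a] = u, inv
        # per-patient segment boundaries for reduceat
        self.order = np.argsort(self.codes, kind="stable")
        sorted_codes = self.codes[self.order]
        self.seg_starts = np.searchsorted(
            sorted_codes, np.arange(self.n_patients))
        self.n_per_patient = np.bincount(self.codes,
                                         minlength=self.n_patients).astype(float)

    def logf_per_obs(self, rho0: np.ndarray, rho1: np.ndarray) -> np.ndarray | None:
        """log f(t) per observation row; None if f <= 0 anywhere."""
        out = np.empty(self.n_obs)
        for a, rho in ((0, rho0), (1, rho1)):
            if not self.arm_masks[a].any():
                continue
            f = np.atleast_1d(f_eval(self.template.function_spec(rho),
                                     self.u_days[a]))
            if np.any(f <= 0) or not np.all(np.isfinite(f)):
                return None
            out[self.arm_masks[a]] = np.log(f)[self.inv[a]]
        return out

    def patient_sums(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rs = r[self.order]
        s1 = np.add.reduceat(rs, self.seg_starts)
        s2 = np.add.reduceat(rs * rs, self.seg_starts)
        return s1, s2

    def marginal_loglik(self, mu, tau, omega, rho0, rho1) -> float:
        if self.n_obs == 0:
            return 0.0
        logf = self.logf_per_obs(rho0, rho1)
        if logf is None:
            return -np.inf
        beta0 = mu - omega**2 / 2.0
        r = self.logy - beta0 - logf
        s1, s2 = self.patient_sums(r)
        n = self.n_per_patient
        w2, t2 = omega**2, tau**2
        denom = w2 + n * t2
        logdet = (n - 1.0) * math.log(w2) + np.log(denom)
        quad = (s2 - t2 * s1**2 / denom) / w2
        return float(-0.5 * np.sum(n * _LOG2PI + logdet + quad))

    def log_posterior(self, theta: np.ndarray) -> float:
        k = self.template.rho_dim
        mu, tau, omega = theta[0], theta[1], theta[2]
        if tau < 0 or omega <= 0:
            return -np.inf
        rho0, rho1 = theta[3:3 + k], theta[3 + k:3 + 2 * k]
        lp = self.template.priors.log_density(mu, tau, omega,
                                              np.r_[rho0, rho1])
        if not np.isfinite(lp):
            return -np.inf
        ll = self.marginal_loglik(mu, tau, omega, rho0, rho1)
        return lp + ll

    def log_posterior_vec(self, coords: np.ndarray) -> np.ndarray:
        return np.array([self.log_posterior(th) for th in coords])


_INIT_RHO = {
    Family.EXPONENTIAL: [0.02],
    Family.GOMPERTZ: [0.01],
    Family.LINEAR: [-0.005],
    Family.QUADRATIC: [-0.005, 1e-5],
    Family.SQUARE_ROOT: [0.005, -0.08],
    Family.WENDLAND0: [2.0],
    Family.WENDLAND1: [2.0],
    Family.LOG_LINEAR: [-0.005],
    Family.LOG_QUADRATIC: [-0.005, 1e-5],
    Family.LOG_SQUARE_ROOT: [0.005, -0.08],
}


def _initial_theta(problem: _Problem) -> np.ndarray:
    tmpl = problem.template
    pri = tmpl.priors
    if problem.n_obs:
        df_day = problem.day
        first = df_day <= df_day.min() + 1e-9
        mu0 = float(np.log(np.exp(problem.logy[first]).mean()))
    else:
        mu0 = pri.mu_mean
    tau0 = 0.5 * pri.tau_sd
    omega0 = 0.5 * pri.omega_sd
    if tmpl.family is Family.SEMIPARAMETRIC:
        rho_c = np.full(tmpl.rho_dim, 0.01)
    else:
        rho_c = np.array(_INIT_RHO[tmpl.family], dtype=float)
    return np.r_[mu0, tau0, omega0, rho_c, rho_c]


def _init_walkers(problem: _Problem, rng: np.random.Generator,
                  n_walkers: int) -> np.ndarray:
    center = _initial_theta(problem)
    k = problem.template.rho_dim
    pri = problem.template.priors
    scale = np.r_[0.1, 0.1, 0.05, np.full(2 * k, 0.002)]
    walkers = np.empty((n_walkers, center.size))
    for w in range(n_walkers):
        for attempt in range(100):
            if problem.n_obs == 0:
                # no data: the posterior is the prior, start from it
                draw = pri.sample(rng, 2 * k)
                cand = np.r_[draw["mu"], draw["tau"],
                             max(draw["omega"], 1e-3), draw["rho"]]
            else:
                cand = center + scale * rng.standard_normal(center.size)
                cand[1] = abs(cand[1])
                cand[2] = max(abs(cand[2]), 1e-3)
            if np.isfinite(problem.log_posterior(cand)):
                walkers[w] = cand
                break
        else:
            raise RuntimeError(
                "could not find a valid starting point (f > 0 at all "
                "observed times) in 100 attempts"
            )
    return walkers


def _conditional_alpha_and_loglik(
    problem: _Problem,
    theta_chain: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conjugate alpha draw + pointwise loglik for each theta draw."""
    k = problem.template.rho_dim
    D = theta_chain.shape[0]
    P, N = problem.n_patients, problem.n_obs
    alpha = np.empty((D, P))
    loglik = np.empty((D, N))
    n = problem.n_per_patient
    for d in range(D):
        mu, tau, omega = theta_chain[d, :3]
        rho0 = theta_chain[d, 3:3 + k]
        rho1 = theta_chain[d, 3 + k:]
        if N:
            logf = problem.logf_per_obs(rho0, rho1)
            beta0 = mu - omega**2 / 2.0
            r = problem.logy - beta0 - logf
            s1, _ = problem.patient_sums(r)
        else:
            s1 = np.zeros(P)
        t2 = max(tau, 1e-12) ** 2
        v = 1.0 / (1.0 / t2 + n / omega**2)
        m = v * s1 / omega**2
        a = m + np.sqrt(v) * rng.standard_normal(P)
        alpha[d] = a
        if N:
            resid = r - a[problem.codes]
            loglik[d] = (-0.5 * _LOG2PI - math.log(omega)
                         - 0.5 * (resid / omega) ** 2)
    return alpha, loglik


def fit(template: ModelTemplate, data: MeasurementTable,
        config: FitConfig) -> PosteriorSamples:
    """Sample the posterior; returns draws, alpha, and the loglik matrix.

    Runs ``config.chains`` independent walker ensembles with seeds derived
    from ``config.seed`` (identical seed + config => identical draws).
    Warns — never fails — on R-hat > 1.01.
    """
    problem = _Problem(template, data)
    k = template.rho_dim
    ndim = 3 + 2 * k
    n_walkers = max(config.walkers, 2 * ndim + 2)
    if n_walkers % 2:
        n_walkers += 1
    keep_steps = math.ceil(config.draws / n_walkers)
    total_steps = config.warmup + keep_steps * config.thin
    seeds = np.random.SeedSequence(config.seed).spawn(2 * config.chains)

    chains_theta = []
    accept = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        p0 = _init_walkers(problem, rng, n_walkers)
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, problem.log_posterior_vec, vectorize=True)
        sampler.random_state = np.random.RandomState(
            int(seeds[c].generate_state(1)[0])).get_state()
        sampler.run_mcmc(p0, total_steps, progress=False)
        chain = sampler.get_chain(discard=config.warmup, thin=config.thin)
        flat = chain.reshape(-1, ndim)[:config.draws]
        chains_theta.append(flat)
        accept.append(float(np.mean(sampler.acceptance_fraction)))

    theta = np.stack(chains_theta)  # (C, D, ndim)
    C, D = theta.shape[:2]
    alpha = np.empty((C, D, problem.n_patients))
    loglik = np.empty((C, D, problem.n_obs))
    for c in range(C):
        rng = np.random.default_rng(seeds[config.chains + c])
        alpha[c], loglik[c] = _conditional_alpha_and_loglik(
            problem, theta[c], rng)

    samples = PosteriorSamples(
        mu=theta[:, :, 0], tau=theta[:, :, 1], omega=theta[:, :, 2],
        rho0=theta[:, :, 3:3 + k], rho1=theta[:, :, 3 + k:],
        alpha=alpha, loglik=loglik, patient_ids=problem.patient_ids,
        meta={
            "family": template.family.value,
            "seed": config.seed, "chains": config.chains,
            "walkers": n_walkers, "warmup": config.warmup,
            "draws": D, "thin": config.thin,
            "mean_acceptance_fraction": float(np.mean(accept)),
            "divergences": 0,
            "n_obs": problem.n_obs, "n_patients": problem.n_patients,
        },
    )
    samples.meta.update(_diagnostics(samples))
    max_rhat = samples.meta.get("max_rhat")
    if max_rhat is not None and max_rhat > 1.01:
        warnings.warn(
            f"max R-hat {max_rhat:.3f} > 1.01: chains may not have mixed",
            stacklevel=2,
        )
    return samples


def _diagnostics(samples: PosteriorSamples) -> dict:
    import arviz as az

    post = {"mu": samples.mu, "tau": samples.tau, "omega": samples.omega,
            "rho0": samples.rho0, "rho1": samples.rho1}
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(max(np.nanmax(np.atleast_1d(rhat[v].values))
                         for v in post))
    min_ess = float(min(np.nanmin(np.atleast_1d(ess[v].values))
                        for v in post))
    return {"max_rhat": max_rhat, "min_ess": min_ess}


def pointwise_loglik(samples: PosteriorSamples, template: ModelTemplate,
                     data: MeasurementTable) -> np.ndarray:
    """Per-draw pointwise log-likelihood of ``data`` rows (S, N_new).

    Uses the stored alpha draw of each patient, so rows must belong to
    patients present in the fit — this is the predictive density used by
    the exact leave-one-out oracle.
    """
    df = data.df
    pid_index = {p: i for i, p in enumerate(samples.patient_ids)}
    try:
        cols = np.array([pid_index[p] for p in df["patient_id"]])
    except KeyError as exc:
        raise ValueError(f"unknown patient {exc.args[0]!r}") from exc
    day = df["day"].to_numpy()
    arm = df["arm"].to_numpy()
    logy = np.log(df["area_cm2"].to_numpy())
    mu = samples.flat("mu")
    omega = samples.flat("omega")
    rho0 = samples.flat("rho0")
    rho1 = samples.flat("rho1")
    alpha = samples.flat("alpha")
    S = mu.shape[0]
    out = np.empty((S, len(df)))
    for s in range(S):
        logf = np.empty(len(df))
        ok = True
        for a, rho in ((0, rho0[s]), (1, rho1[s])):
            m = arm == a
            if not m.any():
                continue
            f = np.atleast_1d(f_eval(template.function_spec(rho), day[m]))
            if np.any(f <= 0):
                ok = False
                break
            logf[m] = np.log(f)
        if not ok:
            out[s] = -np.inf
            continue
        mean = (mu[s] - omega[s]**2 / 2.0) + alpha[s, cols] + logf
        out[s] = (-0.5 * _LOG2PI - np.log(omega[s])
                  - 0.5 * ((logy - mean) / omega[s]) ** 2)
    return out
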