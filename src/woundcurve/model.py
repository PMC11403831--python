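"""Hierarchical log-linear model of wound area.

The observed area of patient i's wound at day t is modelled as

    log y_i(t) = beta0 + alpha_i + log f(t; rho_arm(i)) + e_it

with patient random intercept alpha_i ~ N(0, tau^2), multiplicative
measurement error e_it ~ N(0, omega^2), and a healing-rate function
f shared within each trial arm.  The underlying generative story is
y_i(t) = y*_i(0) f(t) u_i(t) with log-baseline w_i(0) ~ N(mu, tau^2) and
lognormal error u centred so E[u] = 1 (i.e. log u ~ N(-omega^2/2, omega^2)).
Collecting terms gives beta0 = mu - omega^2/2, the convention used
throughout so that the mean-area estimand exp(beta0 + (tau^2+omega^2)/2)
equals exp(mu + tau^2/2), the population mean baseline area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .functions import (
    Family,
    HealingFunctionSpec,
    SplineBasis,
    evaluate,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["patient_id", "arm", "day", "area_cm2", "method"]


@dataclass
class MeasurementTable:
    """Long-format wound-area observations.

    One row per measurement: patient id, arm (0 control / 1 treatment),
    days post-randomisation, measured area in cm^2, and the measurement
    method label (e.g. "PUSH", "ARANZ Manual", "ARANZ Automatic").
    An optional boolean ``censored`` column marks areas recorded below a
    detection limit (see the zero-area policy in :mod:`woundcurve.io`).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        df = self.df.reset_index(drop=True).copy()
        df["arm"] = df["arm"].astype(int)
        df["day"] = df["day"].astype(float)
        df["area_cm2"] = df["area_cm2"].astype(float)
        if not df["arm"].isin([0, 1]).all():
            raise ValueError("arm must be 0 or 1")
        if (df["day"] < 0).any():
            raise ValueError("day must be non-negative")
        if "censored" not in df.columns:
            df["censored"] = False
        uncens = ~df["censored"]
        if (df.loc[uncens, "area_cm2"] <= 0).any():
            raise ValueError(
                "area_cm2 must be positive; apply the zero-area policy first"
            )
        arms_per_patient = df.groupby("patient_id")["arm"].nunique()
        bad = arms_per_patient[arms_per_patient > 1]
        if len(bad):
            raise ValueError(
                f"patient(s) appear in both arms: {list(bad.index)[:5]}"
            )
        self.df = df

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].unique()

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    def patient_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes per row, ordered unique ids) for vectorised group ops."""
        codes, uniques = pd.factorize(self.df["patient_id"])
        return codes, np.asarray(uniques)

    def filter_method(self, method: str) -> "MeasurementTable":
        sub = self.df[self.df["method"] == method]
        if sub.empty:
            raise ValueError(f"no rows with method {method!r}")
        return MeasurementTable(sub)

    def summary(self) -> dict:
        return {
            "n_rows": len(self.df),
            "n_patients": self.n_patients,
            "methods": sorted(self.df["method"].unique()),
            "day_range": (float(self.df["day"].min()), float(self.df["day"].max())),
            "arms": self.df.groupby("arm")["patient_id"].nunique().to_dict(),
        }


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for the shared parameters.

    mu ~ N(1, 2^2); tau ~ N(0, 2^2) truncated to [0, inf);
    omega ~ N(0, 0.5^2) truncated to [0, inf); each rho component
    ~ N(0, rho_sd^2) with a configurable sd (default 1) since the
    per-day rates in the function families are of small magnitude.
    """

    mu_mean: float = 1.0
    mu_sd: float = 2.0
    tau_sd: float = 2.0
    omega_sd: float = 0.5
    rho_sd: float = 1.0

    def log_density(self, mu: float, tau: float, omega: float,
                    rho: np.ndarray) -> float:
        """Joint log prior density (up to the truncation constants)."""
        if tau < 0 or omega < 0:
            return -np.inf
        lp = stats.norm.logpdf(mu, self.mu_mean, self.mu_sd)
        lp += stats.norm.logpdf(tau, 0.0, self.tau_sd)
        lp += stats.norm.logpdf(omega, 0.0, self.omega_sd)
        lp += stats.norm.logpdf(np.asarray(rho), 0.0, self.rho_sd).sum()
        return float(lp)

    def sample(self, rng: np.random.Generator, n_rho: int) -> dict:
        """One draw from the (truncated) priors."""
        return {
            "mu": rng.normal(self.mu_mean, self.mu_sd),
            "tau": abs(rng.normal(0.0, self.tau_sd)),
            "omega": abs(rng.normal(0.0, self.omega_sd)),
            "rho": rng.normal(0.0, self.rho_sd, size=n_rho),
        }


@dataclass(frozen=True)
class ModelSpec:
    """Fully parameterised hierarchical model.

    Both arms share the function family and the nuisance parameters
    (mu, tau, omega); only rho is arm-specific.  ``beta0`` is derived,
    never free: beta0 = mu - omega^2 / 2.
    """

    family: Family
    mu: float
    tau: float
    omega: float
    arm_rho: Mapping[int, np.ndarray]
    priors: PriorSpec = field(default_factory=PriorSpec)
    t_max: float = 100.0
    basis: SplineBasis | None = None

    def __post_init__(self) -> None:
        if self.tau < 0 or self.omega < 0:
            raise ValueError("tau and omega must be non-negative")
        if set(self.arm_rho) != {0, 1}:
            raise ValueError("arm_rho must provide rho for arms 0 and 1")
        rho = {a: np.atleast_1d(np.asarray(r, float)) for a, r in self.arm_rho.items()}
        if rho[0].shape != rho[1].shape:
            raise ValueError("both arms must use the same family arity")
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "arm_rho", rho)

    @property
    def beta0(self) -> float:
        return self.mu - self.omega**2 / 2.0

    def function_spec(self, arm: int) -> HealingFunctionSpec:
        return HealingFunctionSpec(
            family=self.family, rho=self.arm_rho[arm],
            t_max=self.t_max, basis=self.basis,
        )

    def with_params(self, mu=None, tau=None, omega=None, arm_rho=None) -> "ModelSpec":
        return replace(
            self,
            mu=self.mu if mu is None else mu,
            tau=self.tau if tau is None else tau,
            omega=self.omega if omega is None else omega,
            arm_rho=self.arm_rho if arm_rho is None else arm_rho,
        )


def _mean_log_area(spec: ModelSpec, data: MeasurementTable,
                   alpha_per_row: np.ndarray) -> np.ndarray:
    """beta0 + alpha_i + log f(t; rho_arm); -inf where f <= 0."""
    df = data.df
    out = np.empty(len(df))
    for arm in (0, 1):
        mask = (df["arm"] == arm).to_numpy()
        if not mask.any():
            continue
        f = evaluate(spec.function_spec(arm), df.loc[mask, "day"].to_numpy())
        f = np.atleast_1d(f)
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = np.where(f > 0, np.log(np.clip(f, 1e-300, None)), -np.inf)
        out[mask] = spec.beta0 + alpha_per_row[mask] + logf
    return out


def log_likelihood_pointwise(
    spec: ModelSpec,
    alpha: Mapping | np.ndarray,
    data: MeasurementTable,
    detection_limit: float | None = None,
) -> np.ndarray:
    """Per-observation log density of log(area) under the model.

    ``alpha`` maps patient id to its random intercept (or is an array
    aligned with the table's unique patient order).  Observations at times
    where f(t; rho) <= 0 get -inf (soft rejection), never an exception.
    Computed on the log-area scale without the lognormal Jacobian -log(y):
    the Jacobian is parameter-free and cancels in all model comparisons.

    Rows flagged ``censored`` contribute the left-tail probability
    P(area <= detection_limit) via the Normal log-CDF.
    """
    df = data.df
    codes, uniques = data.patient_codes()
    if isinstance(alpha, Mapping):
        try:
            alpha_vec = np.array([alpha[u] for u in uniques], dtype=float)
        except KeyError as exc:
            raise ValueError(f"alpha missing patient {exc.args[0]!r}") from exc
    else:
        alpha_vec = np.asarray(alpha, dtype=float)
        if alpha_vec.shape != (len(uniques),):
            raise ValueError(
                f"alpha has shape {alpha_vec.shape}, expected ({len(uniques)},)"
            )
    if not spec.omega > 0:
        raise ValueError("omega must be positive to evaluate the likelihood")
    mean = _mean_log_area(spec, data, alpha_vec[codes])
    logy = np.log(df["area_cm2"].to_numpy())
    ll = np.where(
        np.isfinite(mean),
        stats.norm.logpdf(logy, loc=np.where(np.isfinite(mean), mean, 0.0),
                          scale=spec.omega),
        -np.inf,
    )
    cens = df["censored"].to_numpy()
    if cens.any():
        if detection_limit is None or detection_limit <= 0:
            raise ValueError("censored rows require a positive detection_limit")
        z = (np.log(detection_limit) - mean[cens]) / spec.omega
        ll[cens] = np.where(np.isfinite(mean[cens]), stats.norm.logcdf(z), -np.inf)
    return ll


def simulate_from_model(
    spec: ModelSpec,
    schedule: np.ndarray,
    arms: np.ndarray,
    seed: int | np.random.Generator,
    method: str = "simulated",
    patient_ids: np.ndarray | None = None,
) -> MeasurementTable:
    """Simulate a measurement table from the generative model.

    Draws log-baselines w_i(0) ~ N(mu, tau^2) and per-observation errors
    eps ~ N(-omega^2/2, omega^2), returning areas
    y = exp(w_i(0)) * f(t; rho_arm) * exp(eps) on the common visit
    ``schedule`` for each patient in ``arms``.  Reproducible given a seed.
    """
    schedule = np.atleast_1d(np.asarray(schedule, dtype=float))
    arms = np.atleast_1d(np.asarray(arms, dtype=int))
    if schedule.size == 0:
        raise ValueError("visit schedule is empty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(arms)
    if patient_ids is None:
        patient_ids = np.array([f"P{i:04d}" for i in range(n)])
    f_by_arm = {}
    for arm in (0, 1):
        f = np.atleast_1d(evaluate(spec.function_spec(arm), schedule))
        if np.any(f <= 0):
            raise ValueError(f"f(t; rho_{arm}) is non-positive on the schedule")
        f_by_arm[arm] = f
    w0 = rng.normal(spec.mu, spec.tau, size=n)
    eps = rng.normal(-spec.omega**2 / 2.0, spec.omega, size=(n, schedule.size))
    rows = []
    for i in range(n):
        y = np.exp(w0[i]) * f_by_arm[arms[i]] * np.exp(eps[i])
        rows.append(pd.DataFrame({
            "patient_id": patient_ids[i],
            "arm": arms[i],
            "day": schedule,
            "area_cm2": y,
            "method": method,
        }))
    return MeasurementTable(pd.concat(rows, ignore_index=True))
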