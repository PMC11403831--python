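"""Synthetic trial generator.

Emulates the structure of a two-arm ulcer-healing RCT: ~130 patients,
1:1 randomisation, dressing changes (and area measurements) every 3-4
days out to a 70-day horizon, baseline ulcer area restricted to
2-20 cm^2 by the inclusion criteria, and up to three measurement methods
per visit with independent lognormal measurement error.  The generating
parameters are returned alongside the table so parameter-recovery and
operating-characteristics experiments can compare against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .functions import evaluate as f_eval
from .model import MeasurementTable, ModelSpec


def default_schedule(horizon: float = 70.0) -> np.ndarray:
    """Visit days 0, 3, 7, 10, 14, ... (alternating 3/4-day gaps)."""
    days = [0.0]
    gap = 3.0
    while days[-1] + gap <= horizon:
        days.append(days[-1] + gap)
        gap = 7.0 - gap  # alternate 3 and 4
    return np.array(days)


@dataclass(frozen=True)
class TrialDesign:
    """Design of a synthetic two-arm trial.

    ``methods`` maps each measurement-method label to its lognormal error
    sd; ``None`` means "use the generating model's omega".  The baseline
    inclusion window [2, 20] cm^2 truncates the lognormal baseline
    distribution (a mild, realistic model misspecification) —
    ``truncate_baseline=False`` restores the untruncated model exactly.
    """

    n_patients: int = 130
    visit_schedule: np.ndarray = field(default_factory=default_schedule)
    baseline_range: tuple[float, float] = (2.0, 20.0)
    methods: Mapping[str, float | None] = field(
        default_factory=lambda: {"PUSH": None, "ARANZ Manual": None,
                                 "ARANZ Automatic": None})
    dropout_rate: float = 0.0           # per-visit probability after baseline
    healing_stop: bool = False          # stop visits once healed
    healing_threshold: float = 0.25     # cm^2, "healed" for healing_stop
    truncate_baseline: bool = True

    def __post_init__(self) -> None:
        sched = np.sort(np.atleast_1d(np.asarray(self.visit_schedule, float)))
        if sched[0] != 0.0:
            raise ValueError("visit schedule must start at day 0")
        if sched[-1] > 70.0 + 1e-9:
            raise ValueError("visits must end by the 70-day horizon")
        object.__setattr__(self, "visit_schedule", sched)
        lo, hi = self.baseline_range
        if not (0 < lo < hi):
            raise ValueError("baseline_range must be 0 < lo < hi")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def _baseline_logareas(design: TrialDesign, truth: ModelSpec,
                       rng: np.random.Generator) -> np.ndarray:
    lo, hi = np.log(design.baseline_range[0]), np.log(design.baseline_range[1])
    mu, tau = truth.mu, truth.tau
    if not design.truncate_baseline:
        return rng.normal(mu, tau, size=design.n_patients)
    if tau == 0:
        if lo <= mu <= hi:
            return np.full(design.n_patients, mu)
        raise ValueError("tau = 0 with mu outside the baseline window")
    a, b = (lo - mu) / tau, (hi - mu) / tau
    if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
        raise ValueError(
            "baseline truncation is infeasible: N(mu, tau^2) places no "
            "mass on the inclusion window"
        )
    return stats.truncnorm.rvs(a, b, loc=mu, scale=tau,
                               size=design.n_patients, random_state=rng)


def generate_trial(
    design: TrialDesign,
    truth: ModelSpec,
    seed: int,
) -> tuple[MeasurementTable, dict]:
    """Simulate a full trial; returns (table, truth record).

    The truth record carries the generating parameters, the seed, and the
    per-patient arm allocation, for use by recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = design.n_patients
    sched = design.visit_schedule

    arms = np.zeros(n, dtype=int)
    arms[: n // 2] = 1
    arms = rng.permutation(arms)

    f_by_arm = {}
    for arm in (0, 1):
        f = np.atleast_1d(f_eval(truth.function_spec(arm), sched))
        if np.any(f <= 0):
            raise ValueError(f"f(t; rho_{arm}) non-positive on the schedule")
        f_by_arm[arm] = f

    w0 = _baseline_logareas(design, truth, rng)
    pids = np.array([f"P{i:04d}" for i in range(n)])

    frames = []
    for i in range(n):
        true_area = np.exp(w0[i]) * f_by_arm[arms[i]]
        n_vis = len(sched)
        if design.dropout_rate > 0:
            # patient attends visit j only if not dropped at any k <= j
            stay = rng.random(n_vis - 1) >= design.dropout_rate
            attended = int(np.argmin(stay)) + 1 if not stay.all() else n_vis
        else:
            attended = n_vis
        if design.healing_stop:
            healed = true_area < design.healing_threshold
            if healed.any():
                attended = min(attended, int(np.argmax(healed)) + 1)
        days = sched[:attended]
        ta = true_area[:attended]
        for method, sd in design.methods.items():
            s = truth.omega if sd is None else float(sd)
            eps = rng.normal(-s**2 / 2.0, s, size=attended)
            frames.append(pd.DataFrame({
                "patient_id": pids[i], "arm": arms[i], "day": days,
                "area_cm2": ta * np.exp(eps), "method": method,
            }))

    table = MeasurementTable(pd.concat(frames, ignore_index=True))
    truth_record = {
        "family": truth.family.value,
        "mu": truth.mu, "tau": truth.tau, "omega": truth.omega,
        "rho0": np.asarray(truth.arm_rho[0]).tolist(),
        "rho1": np.asarray(truth.arm_rho[1]).tolist(),
        "t_max": truth.t_max,
        "seed": seed,
        "n_patients": n,
        "arms": dict(zip(pids.tolist(), arms.tolist())),
        "design": {
            "visit_schedule": sched.tolist(),
            "baseline_range": list(design.baseline_range),
            "methods": {k: v for k, v in design.methods.items()},
            "dropout_rate": design.dropout_rate,
            "healing_stop": design.healing_stop,
            "healing_threshold": design.healing_threshold,
            "truncate_baseline": design.truncate_baseline,
        },
    }
    return table, truth_record
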