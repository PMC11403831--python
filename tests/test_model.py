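"""Hierarchical model: likelihood, error structure, generative simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from woundcurve import (
    Family,
    MeasurementTable,
    ModelSpec,
    log_likelihood_pointwise,
    simulate_from_model,
)


def toy_table(rows):
    return MeasurementTable(pd.DataFrame(
        rows, columns=["patient_id", "arm", "day", "area_cm2", "method"]))


def exp_spec(**kw):
    defaults = dict(family=Family.EXPONENTIAL, mu=1.4, tau=0.5, omega=0.3,
                    arm_rho={0: [0.03], 1: [0.02]})
    defaults.update(kw)
    return ModelSpec(**defaults)


class TestPointwiseLogLikelihood:
    def test_zero_residual_single_observation(self):
        """alpha=0, f=1, beta0=log(area): density of N(0, omega^2) at 0."""
        omega = 0.5
        area = 3.0
        spec = ModelSpec(family=Family.EXPONENTIAL,
                         mu=np.log(area) + omega**2 / 2.0,  # beta0 = log(area)
                         tau=0.4, omega=omega, arm_rho={0: [0.0], 1: [0.0]})
        table = toy_table([("A", 0, 5.0, area, "m")])
        ll = log_likelihood_pointwise(spec, {"A": 0.0}, table)
        assert ll[0] == pytest.approx(-np.log(omega * np.sqrt(2 * np.pi)),
                                      abs=1e-12)

    def test_matches_independent_normal_density(self):
        """3-observation table vs a directly coded Normal log-pdf oracle."""
        spec = exp_spec()
        table = toy_table([("A", 0, 0.0, 4.1, "m"), ("A", 0, 7.0, 3.0, "m"),
                           ("B", 1, 14.0, 2.2, "m")])
        alpha = {"A": 0.21, "B": -0.1}
        ll = log_likelihood_pointwise(spec, alpha, table)
        beta0 = spec.mu - spec.omega**2 / 2
        expected = [
            stats.norm.logpdf(np.log(4.1), beta0 + 0.21 + np.log(np.exp(-0.03 * 0)),
                              spec.omega),
            stats.norm.logpdf(np.log(3.0), beta0 + 0.21 + np.log(np.exp(-0.03 * 7)),
                              spec.omega),
            stats.norm.logpdf(np.log(2.2), beta0 - 0.1 + np.log(np.exp(-0.02 * 14)),
                              spec.omega),
        ]
        assert np.allclose(ll, expected, atol=1e-10)
        assert ll.sum() == pytest.approx(np.sum(expected), abs=1e-10)

    def test_nonpositive_f_yields_minus_inf_not_exception(self):
        spec = ModelSpec(family=Family.LINEAR, mu=1.4, tau=0.5, omega=0.3,
                         arm_rho={0: [-0.1], 1: [-0.1]})
        table = toy_table([("A", 0, 20.0, 1.0, "m"),  # f = 1 - 2 = -1
                           ("A", 0, 2.0, 1.0, "m")])  # f = 0.8 > 0
        ll = log_likelihood_pointwise(spec, {"A": 0.0}, table)
        assert np.isneginf(ll[0]) and np.isfinite(ll[1])

    def test_alpha_dimension_error(self):
        table = toy_table([("A", 0, 0.0, 4.0, "m"), ("B", 1, 0.0, 4.0, "m")])
        with pytest.raises(ValueError, match="alpha"):
            log_likelihood_pointwise(exp_spec(), np.array([0.1]), table)
        with pytest.raises(ValueError, match="missing patient"):
            log_likelihood_pointwise(exp_spec(), {"A": 0.1}, table)

    def test_censored_rows_use_normal_logcdf(self):
        spec = exp_spec()
        df = pd.DataFrame({
            "patient_id": ["A", "A"], "arm": [0, 0], "day": [0.0, 7.0],
            "area_cm2": [4.0, 0.01], "method": "m",
            "censored": [False, True],
        })
        table = MeasurementTable(df)
        ll = log_likelihood_pointwise(spec, {"A": 0.0}, table,
                                      detection_limit=0.01)
        beta0 = spec.mu - spec.omega**2 / 2
        mean1 = beta0 + np.log(np.exp(-0.03 * 7.0))
        assert ll[1] == pytest.approx(
            stats.norm.logcdf((np.log(0.01) - mean1) / spec.omega), abs=1e-10)
        with pytest.raises(ValueError, match="detection_limit"):
            log_likelihood_pointwise(spec, {"A": 0.0}, table)


class TestSimulateFromModel:
    SCHED = np.array([0.0, 7.0, 21.0, 42.0])

    def test_degenerate_noise_gives_exact_trajectories(self):
        spec = exp_spec(tau=0.0, omega=0.0)
        table = simulate_from_model(spec, self.SCHED, np.array([0, 1]), seed=5)
        for arm in (0, 1):
            sub = table.df[table.df["arm"] == arm]
            expected = np.exp(spec.mu) * np.exp(-spec.arm_rho[arm][0] * self.SCHED)
            assert np.allclose(sub["area_cm2"].to_numpy(), expected, rtol=1e-12)

    def test_same_seed_reproduces_table(self):
        spec = exp_spec()
        arms = np.array([0, 1, 0, 1])
        t1 = simulate_from_model(spec, self.SCHED, arms, seed=11)
        t2 = simulate_from_model(spec, self.SCHED, arms, seed=11)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        t3 = simulate_from_model(spec, self.SCHED, arms, seed=12)
        assert not np.allclose(t1.df["area_cm2"], t3.df["area_cm2"])

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError, match="schedule"):
            simulate_from_model(exp_spec(), np.array([]), np.array([0, 1]), 1)

    @pytest.mark.parametrize("omega", [0.1, 0.5])
    def test_mean_one_multiplicative_error(self, omega):
        """E[u] = 1: closed form for any omega, and Monte Carlo."""
        assert np.exp(-omega**2 / 2 + omega**2 / 2) == 1.0
        rng = np.random.default_rng(100 + int(omega * 10))
        u = np.exp(rng.normal(-omega**2 / 2, omega, size=200_000))
        se = u.std(ddof=1) / np.sqrt(u.size)
        assert abs(u.mean() - 1.0) < 4 * se

    def test_marginal_mean_identity(self):
        """E[y(t)] = exp(mu + tau^2/2) f(t), the algebra behind delta1."""
        spec = exp_spec(tau=0.4, omega=0.5)
        n = 40_000
        table = simulate_from_model(spec, np.array([14.0]),
                                    np.zeros(n, dtype=int), seed=8)
        y = table.df["area_cm2"].to_numpy()
        f = np.exp(-spec.arm_rho[0][0] * 14.0)
        expected = np.exp(spec.mu + spec.tau**2 / 2) * f
        se = y.std(ddof=1) / np.sqrt(n)
        assert abs(y.mean() - expected) < 4 * se

    def test_generating_spec_beats_perturbed_spec(self):
        """Total log-likelihood prefers the truth over a 2-prior-sd shift."""
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            spec = exp_spec()
            arms = np.tile([0, 1], 25)
            table = simulate_from_model(spec, self.SCHED, arms, seed=300 + rep)
            alpha = {p: 0.0 for p in table.patient_ids}
            ll_true = log_likelihood_pointwise(spec, alpha, table).sum()
            shifted = spec.with_params(
                arm_rho={0: spec.arm_rho[0] + 2.0, 1: spec.arm_rho[1] + 2.0})
            ll_shift = log_likelihood_pointwise(shifted, alpha, table).sum()
            wins += ll_true > ll_shift
        assert wins >= 0.95 * n_rep


class TestMeasurementTable:
    def test_patient_in_both_arms_rejected(self):
        with pytest.raises(ValueError, match="both arms"):
            toy_table([("A", 0, 0.0, 4.0, "m"), ("A", 1, 3.0, 3.5, "m")])

    def test_nonpositive_area_rejected_without_policy(self):
        with pytest.raises(ValueError, match="positive"):
            toy_table([("A", 0, 0.0, 0.0, "m")])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing required"):
            MeasurementTable(pd.DataFrame({"patient_id": ["A"]}))

    def test_beta0_is_derived(self):
        spec = exp_spec(mu=1.5, omega=0.4)
        assert spec.beta0 == pytest.approx(1.5 - 0.08)
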