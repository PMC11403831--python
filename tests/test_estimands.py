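"""Treatment-effect estimands: closed forms, identities, comparator."""

import numpy as np
import pandas as pd
import pytest

from woundcurve import (
    Family,
    MeasurementTable,
    ModelTemplate,
    PosteriorSamples,
    delta1,
    delta2,
    nonparametric_difference,
    proportion_healed,
    rate_difference,
)


def manual_samples(mu, tau, omega, rho0, rho1, family=Family.EXPONENTIAL):
    """A single-draw PosteriorSamples with explicit parameter values."""
    k = len(rho0)
    return PosteriorSamples(
        mu=np.array([[mu]], float), tau=np.array([[tau]], float),
        omega=np.array([[omega]], float),
        rho0=np.array(rho0, float).reshape(1, 1, k),
        rho1=np.array(rho1, float).reshape(1, 1, k),
        alpha=np.zeros((1, 1, 0)), loglik=np.zeros((1, 1, 0)),
        patient_ids=np.array([]), meta={"family": family.value},
    ), ModelTemplate(family=family)


class TestDelta1:
    def test_identical_arms_give_zero(self):
        samples, tmpl = manual_samples(1.2, 0.4, 0.3, [0.03], [0.03])
        curve = delta1(samples, tmpl, np.linspace(0, 70, 15))
        assert np.allclose(curve.mean, 0.0) and np.allclose(curve.upper, 0.0)

    def test_single_draw_hand_value(self):
        """mu=1, tau=omega=0.5, f1=0.8, f0=0.9 -> exp(1.125) * (-0.1)."""
        t = 10.0
        rho1 = [-np.log(0.8) / t]
        rho0 = [-np.log(0.9) / t]
        samples, tmpl = manual_samples(1.0, 0.5, 0.5, rho0, rho1)
        curve = delta1(samples, tmpl, np.array([t]))
        assert curve.mean[0] == pytest.approx(np.exp(1.125) * (-0.1), abs=1e-6)
        assert curve.mean[0] == pytest.approx(-0.30802, abs=1e-5)

    def test_monte_carlo_oracle_agreement(self):
        """Closed form matches 10^5-wound simulation within 3 SE."""
        rng = np.random.default_rng(12)
        mu, tau, omega = 1.3, 0.45, 0.35
        rho0, rho1 = [0.030], [0.022]
        samples, tmpl = manual_samples(mu, tau, omega, rho0, rho1)
        t = 28.0
        curve = delta1(samples, tmpl, np.array([t]))
        n = 100_000
        sims = {}
        for rho in (rho0, rho1):
            w = rng.normal(mu, tau, n)
            e = rng.normal(-omega**2 / 2, omega, n)
            sims[tuple(rho)] = np.exp(w) * np.exp(-rho[0] * t) * np.exp(e)
        mc = sims[tuple(rho1)].mean() - sims[tuple(rho0)].mean()
        se = np.sqrt(sims[tuple(rho1)].var() / n + sims[tuple(rho0)].var() / n)
        assert abs(curve.mean[0] - mc) < 3 * se

    def test_identity_with_delta2(self, small_fit):
        """delta1 = exp(mu + tau^2/2) * delta2, draw by draw."""
        tmpl, _, samples = small_fit
        grid = np.array([7.0, 21.0, 42.0, 63.0])
        d1 = delta1(samples, tmpl, grid, keep_draws=True)
        d2 = delta2(samples, tmpl, grid, keep_draws=True)
        mu = samples.flat("mu")
        tau = samples.flat("tau")
        scale = np.exp(mu + tau**2 / 2)
        assert np.allclose(d1.draws, scale[:, None] * d2.draws, rtol=1e-10)


class TestDelta2:
    def test_exponential_hand_value(self):
        samples, tmpl = manual_samples(1.0, 0.3, 0.3, [0.03], [0.05])
        curve = delta2(samples, tmpl, np.array([10.0]))
        assert curve.mean[0] == pytest.approx(np.exp(-0.5) - np.exp(-0.3),
                                              abs=1e-12)
        assert curve.mean[0] == pytest.approx(-0.13428, abs=1e-5)

    def test_normalized_log_family_starts_at_zero(self):
        samples, tmpl = manual_samples(1.0, 0.3, 0.3, [-0.02], [-0.03],
                                       family=Family.LOG_LINEAR)
        raw = delta2(samples, tmpl, np.array([0.0]))
        norm = delta2(samples, tmpl, np.array([0.0]), normalize=True)
        assert raw.mean[0] == pytest.approx(0.0)  # e - e for equal f(0)
        assert norm.mean[0] == pytest.approx(0.0, abs=1e-14)


class TestRateDifference:
    def test_linear_hand_value(self):
        """scale = 4 (tau=0, mu=log 4); p1=-0.02, p0=-0.01 -> -0.04."""
        samples, tmpl = manual_samples(np.log(4.0), 0.0, 0.3,
                                       [-0.01], [-0.02], family=Family.LINEAR)
        curve = rate_difference(samples, tmpl, np.array([5.0, 30.0]))
        assert np.allclose(curve.mean, -0.04, atol=1e-12)
        assert curve.units == "cm^2/day"

    def test_identical_arms_zero(self):
        samples, tmpl = manual_samples(1.0, 0.3, 0.3, [0.04], [0.04])
        curve = rate_difference(samples, tmpl, np.array([10.0]))
        assert np.allclose(curve.mean, 0.0)

    def test_average_converges_to_instantaneous(self):
        samples, tmpl = manual_samples(1.1, 0.2, 0.3, [0.03], [0.05])
        t = np.array([1e-3])
        inst = rate_difference(samples, tmpl, t, mode="instantaneous")
        avg = rate_difference(samples, tmpl, t, mode="average")
        assert avg.mean[0] == pytest.approx(inst.mean[0], rel=1e-3)

    def test_sqrt_family_rejects_origin(self):
        samples, tmpl = manual_samples(1.0, 0.3, 0.3, [0.005, -0.1],
                                       [0.004, -0.09],
                                       family=Family.SQUARE_ROOT)
        with pytest.raises(ValueError, match="t > 0"):
            rate_difference(samples, tmpl, np.array([0.0]))


class TestProportionHealed:
    def test_boundary_case_is_half(self):
        """mu=log 4, tau->0, f=0.5, c=2: log c equals the median exactly."""
        rho = [np.log(2.0) / 10.0]  # f(10) = 0.5
        samples, tmpl = manual_samples(np.log(4.0), 0.0, 0.3, rho, rho)
        curves = proportion_healed(samples, tmpl, np.array([10.0]),
                                   healing_threshold=2.0)
        assert curves["control"].mean[0] == pytest.approx(0.5)
        assert curves["treatment"].mean[0] == pytest.approx(0.5)
        assert curves["difference"].mean[0] == pytest.approx(0.0)

    def test_generous_threshold_means_all_healed(self):
        samples, tmpl = manual_samples(np.log(4.0), 0.3, 0.3, [0.03], [0.02])
        curves = proportion_healed(samples, tmpl, np.array([10.0]),
                                   healing_threshold=1e4)
        assert curves["control"].mean[0] == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_time_for_decaying_f(self):
        samples, tmpl = manual_samples(np.log(4.0), 0.4, 0.3, [0.03], [0.02])
        grid = np.linspace(0, 70, 30)
        curves = proportion_healed(samples, tmpl, grid, healing_threshold=0.25)
        for key in ("control", "treatment"):
            assert np.all(np.diff(curves[key].mean) >= -1e-12)

    def test_invalid_threshold(self):
        samples, tmpl = manual_samples(1.0, 0.3, 0.3, [0.03], [0.02])
        with pytest.raises(ValueError, match="threshold"):
            proportion_healed(samples, tmpl, np.array([10.0]),
                              healing_threshold=0.0)


class TestNonparametricDifference:
    @staticmethod
    def table_from(rows):
        return MeasurementTable(pd.DataFrame(
            rows, columns=["patient_id", "arm", "day", "area_cm2", "method"]))

    def test_matches_hand_welch_computation(self):
        rows = [("A", 0, 42.0, 4.0, "m"), ("B", 0, 41.0, 6.0, "m"),
                ("C", 1, 42.0, 3.0, "m"), ("D", 1, 43.0, 5.0, "m")]
        est = nonparametric_difference(self.table_from(rows), day=42.0,
                                       window=3.0)
        # treatment mean 4, control mean 5; each var 2, n 2
        assert est.estimate == pytest.approx(-1.0)
        se = np.sqrt(2 / 2 + 2 / 2)
        from scipy import stats
        dof = se**4 / ((1.0) ** 2 / 1 + (1.0) ** 2 / 1)
        half = stats.t.ppf(0.975, dof) * se
        assert est.lower == pytest.approx(-1.0 - half)
        assert est.upper == pytest.approx(-1.0 + half)

    def test_relabelled_identical_arms_centre_on_zero(self):
        rows = []
        for i, area in enumerate([3.0, 4.0, 5.0, 6.0]):
            rows.append((f"C{i}", 0, 42.0, area, "m"))
            rows.append((f"T{i}", 1, 42.0, area, "m"))
        est = nonparametric_difference(self.table_from(rows), day=42.0)
        assert est.estimate == pytest.approx(0.0)
        assert est.lower == pytest.approx(-est.upper)

    def test_nearest_visit_selection_within_window(self):
        rows = [("A", 0, 40.0, 10.0, "m"), ("A", 0, 42.5, 4.0, "m"),
                ("B", 0, 41.0, 6.0, "m"),
                ("C", 1, 42.0, 3.0, "m"), ("D", 1, 44.0, 5.0, "m")]
        est = nonparametric_difference(self.table_from(rows), day=42.0,
                                       window=3.0)
        # patient A contributes its nearest measurement (4.0), not 10.0
        assert est.estimate == pytest.approx(4.0 - 5.0)

    def test_insufficient_data_error_reports_arm_counts(self):
        rows = [("A", 0, 42.0, 4.0, "m"), ("C", 1, 42.0, 3.0, "m")]
        with pytest.raises(ValueError, match="1 control / 1 treatment"):
            nonparametric_difference(self.table_from(rows), day=42.0)


def test_effect_curve_quantiles_ordered(small_fit):
    tmpl, _, samples = small_fit
    curve = delta1(samples, tmpl, np.linspace(1, 70, 20))
    assert np.all(curve.lower <= curve.mean) and np.all(curve.mean <= curve.upper)
    assert curve.width(42.0) > 0
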