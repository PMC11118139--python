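"""Tests for Bell-line fitting, its closed-form oracles, and parameter recovery."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from electrorupture import (
    DataValidationError,
    ModelFitError,
    PhysicalContext,
    SimulationTruth,
    SpontaneousRuptureError,
    bell_slope,
    fit_bell,
    most_probable_tension,
    recover_parameters,
    rupture_tension_distribution,
)
from electrorupture.bell_fit import TensionPoint, aggregate_by_rate, characteristic_value
from electrorupture.pipeline import make_tension_converter, run_synthetic_condition
from electrorupture.rupture_detect import RuptureEvent
from electrorupture.synthetic_data import PopulationSpec, make_population, simulate_rupture_events

PHYS = PhysicalContext()
AREA_107 = math.pi * 1.07e-9**2


def exact_line_points(slope, intercept, rates=(1e-5, 1e-4, 1e-3, 1e-2)):
    """Tension points lying exactly on sigma = slope*ln(R) + intercept."""
    return [
        TensionPoint(
            loading_rate_vpp_per_s=float(i),
            char_voltage_vpp=6.5,
            sigma_e_n_per_m=slope * math.log(r) + intercept,
            r_sigma_n_per_m_s=r,
            n=100,
            voltage_sd_vpp=0.1,
            voltage_se_vpp=0.01,
            sigma_se_n_per_m=1e-5,
        )
        for i, r in enumerate(rates)
    ]


class TestFitBell:
    def test_exact_line_recovers_radius_to_machine_precision(self):
        slope = PHYS.kT / AREA_107  # ~1.1445e-3 N/m for r = 1.07 nm
        fit = fit_bell(exact_line_points(slope, 0.06), PHYS)
        assert fit.pore_radius_m == pytest.approx(1.07e-9, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_to_radius_direct(self):
        fit = fit_bell(exact_line_points(2.047e-3, 0.06), PHYS)
        assert fit.pore_radius_nm == pytest.approx(0.800, abs=1e-3)

    def test_k0_round_trip(self):
        """Intercept generated from (A, k0) is inverted back to k0 exactly."""
        area, k0 = AREA_107, 3.7e-12
        slope = PHYS.kT / area
        intercept = (PHYS.kT / area) * math.log(area / (PHYS.kT * k0))
        fit = fit_bell(exact_line_points(slope, intercept), PHYS)
        assert fit.k0_per_s == pytest.approx(k0, rel=1e-9)
        assert fit.tau0_s * fit.k0_per_s == pytest.approx(1.0, rel=1e-12)
        assert fit.w0_kbt == pytest.approx(math.log(1e13 / k0), rel=1e-12)

    def test_two_points_rejected(self):
        pts = exact_line_points(1e-3, 0.05)[:2]
        with pytest.raises(DataValidationError):
            fit_bell(pts, PHYS)

    def test_negative_slope_raises_model_error(self):
        pts = exact_line_points(-1e-3, 0.05)
        with pytest.raises(ModelFitError):
            fit_bell(pts, PHYS)

    def test_weighted_fit_matches_on_exact_line(self):
        slope = PHYS.kT / AREA_107
        pts = exact_line_points(slope, 0.06)
        unweighted = fit_bell(pts, PHYS)
        weighted = fit_bell(pts, PHYS, weighting="by-se")
        assert weighted.slope_n_per_m == pytest.approx(unweighted.slope_n_per_m, rel=1e-10)


class TestBellSlope:
    @pytest.mark.parametrize(
        "radius_nm, expected",
        [(1.07, 1.1445e-3), (0.80, 2.0473e-3), (0.58, 3.8950e-3)],
    )
    def test_slope_magnitudes(self, radius_nm, expected):
        assert bell_slope(radius_nm * 1e-9, PHYS) == pytest.approx(expected, rel=1e-4)


class TestMostProbableTension:
    def test_reference_value(self):
        # (kT/A) ln(R A / (kT k0)) with the log term ~29.80
        sigma = most_probable_tension(AREA_107, 1e-13, 1e-3, PHYS)
        assert sigma == pytest.approx(0.03410, abs=2e-5)

    def test_rate_times_e_shifts_by_kt_over_area(self):
        s1 = most_probable_tension(AREA_107, 1e-13, 1e-3, PHYS)
        s2 = most_probable_tension(AREA_107, 1e-13, 1e-3 * math.e, PHYS)
        assert s2 - s1 == pytest.approx(PHYS.kT / AREA_107, rel=1e-9)

    def test_spontaneous_regime_raises(self):
        with pytest.raises(SpontaneousRuptureError):
            most_probable_tension(AREA_107, 1.0, 1e-12, PHYS)

    def test_fit_of_exact_modes_returns_generating_area(self):
        """sigma*(ln R) has slope exactly kT/A: the fit inverts it."""
        rates = [1e-5, 3e-5, 1e-4, 3e-4, 1e-3]
        pts = [
            TensionPoint(i, 6.5, most_probable_tension(AREA_107, 1e-13, r, PHYS),
                         r, 100, 0.1, 0.01, 1e-5)
            for i, r in enumerate(rates)
        ]
        fit = fit_bell(pts, PHYS)
        assert fit.pore_area_m2 == pytest.approx(AREA_107, rel=1e-10)
        assert fit.k0_per_s == pytest.approx(1e-13, rel=1e-8)


class TestRuptureTensionDistribution:
    DIST = rupture_tension_distribution(AREA_107, 1e-13, 1e-3, PHYS)

    def test_survival_starts_at_one_and_decreases(self):
        assert self.DIST.survival(0.0) == 1.0
        sig = np.linspace(0, 0.05, 200)
        assert np.all(np.diff(self.DIST.survival(sig)) <= 0)

    def test_density_integrates_to_one(self):
        mode = self.DIST.mode
        total, err = quad(self.DIST.pdf, 0, 5 * mode, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_density_argmax_matches_most_probable_tension(self):
        mode = self.DIST.mode
        res = minimize_scalar(
            lambda s: -self.DIST.pdf(s),
            bounds=(0.5 * mode, 1.5 * mode),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(mode, rel=1e-6)


class TestAggregateByRate:
    @staticmethod
    def _converter():
        from electrorupture.config import default_settings

        s = default_settings()
        return make_tension_converter(s.cell.representative_cell(), s), s

    def _events(self, volts_by_rate):
        out = []
        for rate, volts in volts_by_rate.items():
            for i, v in enumerate(volts):
                out.append(
                    RuptureEvent(
                        f"r{rate}-{i}", v, censored=np.isnan(v),
                        loading_rate_vpp_per_s=rate,
                    )
                )
        return out

    def test_mean_of_two_voltages(self):
        conv, _ = self._converter()
        events = self._events({0.05: [6.0, 7.0], 0.025: [6.0, 6.2], 0.1: [6.5, 6.7]})
        points = aggregate_by_rate(events, conv, "mean")
        by_rate = {p.loading_rate_vpp_per_s: p for p in points}
        assert by_rate[0.05].char_voltage_vpp == pytest.approx(6.5)

    def test_identical_voltages_give_zero_sd_and_single_conversion(self):
        conv, _ = self._converter()
        events = self._events({0.05: [6.5, 6.5], 0.025: [6.0, 6.0], 0.1: [7.0, 7.0]})
        points = aggregate_by_rate(events, conv, "mean")
        p = {q.loading_rate_vpp_per_s: q for q in points}[0.05]
        assert p.voltage_sd_vpp == 0.0
        assert p.sigma_e_n_per_m == pytest.approx(conv(6.5, 0.05)[0], rel=1e-14)

    def test_censored_excluded_but_counted(self):
        conv, _ = self._converter()
        events = self._events({0.05: [6.0, 7.0, np.nan], 0.1: [6.5, 6.6]})
        points = aggregate_by_rate(events, conv, "mean")
        p = {q.loading_rate_vpp_per_s: q for q in points}[0.05]
        assert p.n == 2 and p.n_censored == 1

    def test_sparse_rate_dropped_with_warning(self):
        conv, _ = self._converter()
        events = self._events({0.05: [6.0, 7.0], 0.1: [6.5]})
        with pytest.warns(UserWarning, match="dropped"):
            points = aggregate_by_rate(events, conv, "mean")
        assert len(points) == 1

    def test_all_rates_dropped_is_fatal(self):
        conv, _ = self._converter()
        events = self._events({0.05: [6.0], 0.1: [6.5]})
        with pytest.warns(UserWarning):
            with pytest.raises(DataValidationError):
                aggregate_by_rate(events, conv, "mean")

    def test_mode_estimator_matches_closed_form_mode(self, run_settings):
        """KDE mode of 1e4 simulated constant-rate ruptures ~ analytic sigma*."""
        truth = SimulationTruth(1.07e-9, 1e-13)
        cells = make_population(PopulationSpec(n_cells=10_000, seed=21))
        events = simulate_rupture_events(
            cells, run_settings.protocol, run_settings.field_model,
            run_settings.medium, truth, mode="tension-ramp",
            tension_rate_n_per_m_s=1e-3, seed=22,
        )
        tensions = np.array([e.rupture_tension_n_per_m for e in events if not e.censored])
        mode = characteristic_value(tensions, "mode")
        expected = most_probable_tension(truth.pore_area_m2, 1e-13, 1e-3, PHYS)
        scale = PHYS.kT / truth.pore_area_m2
        assert abs(mode - expected) < 1.0 * scale
        # left-skewed (reversed Gumbel): the mean sits gamma*scale below the mode
        assert tensions.mean() - expected == pytest.approx(-0.5772 * scale, abs=0.15 * scale)

    def test_mean_vs_mode_leaves_slope_nearly_unbiased(self, run_settings):
        """Aggregating by mean vs mode shifts the intercept, not the slope."""
        res_mean = run_synthetic_condition(
            1.07e-9, 1e-13, seed=30, n_cells_per_rate=10_000, detect=False,
            estimator="mean",
        )
        res_mode = run_synthetic_condition(
            1.07e-9, 1e-13, seed=30, n_cells_per_rate=10_000, detect=False,
            estimator="mode",
        )
        rel = abs(res_mode.fit.slope_n_per_m / res_mean.fit.slope_n_per_m - 1)
        assert rel < 0.03
        assert res_mode.fit.intercept_n_per_m > res_mean.fit.intercept_n_per_m - 1e-3


class TestRecoverParameters:
    def _events_and_converter(self, seed, n=500, heterogeneity=False, dt=0.01):
        from electrorupture.config import default_settings

        s = default_settings()
        truth = SimulationTruth(1.07e-9, 1e-13)
        conv = make_tension_converter(s.cell.representative_cell(), s)
        events = []
        rng = np.random.default_rng(seed)
        for rate in (0.003, 0.006, 0.012, 0.025, 0.05, 0.1):
            cells = make_population(
                PopulationSpec(n_cells=n, seed=int(rng.integers(2**31)),
                               heterogeneity=heterogeneity)
            )
            events.extend(
                simulate_rupture_events(
                    cells, s.protocol.with_rate(rate), s.field_model, s.medium,
                    truth, seed=int(rng.integers(2**31)), dt=dt,
                )
            )
        return events, conv, truth

    def test_radius_recovered_within_ten_percent(self):
        events, conv, truth = self._events_and_converter(seed=40)
        report = recover_parameters(events, conv, truth, n_bootstrap=300, seed=41)
        assert abs(report.rel_err_radius) < 0.10
        lo, hi = report.ci_radius_nm
        assert lo < hi

    def test_heterogeneity_degrades_but_stays_in_tolerance(self):
        events, conv, truth = self._events_and_converter(
            seed=42, n=200, heterogeneity=True, dt=0.005
        )
        report = recover_parameters(events, conv, truth, n_bootstrap=200, seed=43)
        assert abs(report.rel_err_radius) < 0.10

    def test_bootstrap_ci_covers_truth(self):
        """Percentile CI on the radius covers the generating value in >= 80%
        of seeded replicates (slope is unbiased under mean aggregation)."""
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            events, conv, truth = self._events_and_converter(seed=100 + rep, n=300)
            report = recover_parameters(events, conv, truth, n_bootstrap=200, seed=rep)
            lo, hi = report.ci_radius_nm
            covered += lo <= truth.pore_radius_m * 1e9 <= hi
        assert covered / n_rep >= 0.8
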