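"""Tests for amplification-rate inference, calibration and diagnostics."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phorce.curves import CollapseEstimate, InsufficientDataError, detect_collapse
from phorce.inference import (
    NotIdentifiableError,
    YieldEstimate,
    approximate_ratio,
    estimate_kadsorb,
    fit_calibration,
    joint_fit_rate,
    phage_ratio_from_collapse,
    rate_from_single_curve,
    reconstruct_trajectory,
    regime_diagnostic,
)
from phorce.model import (
    InitialState,
    PredationParams,
    collapse_phage_density,
    collapse_time_adsorption,
    collapse_time_latency,
)
from phorce.synth import generate_curve, generate_gradient_plate, serial_levels


def _collapse(t_col, signal=1e4, se=0.0):
    return CollapseEstimate(t_col=t_col, signal_at_collapse=signal, se_t_col=se)


class TestSingleCurveRate:
    def test_exact_roundtrip(self, base_params, standard_init):
        t = collapse_time_adsorption(base_params, standard_init, 1e4)
        est = rate_from_single_curve(t, 1.0, 1e5, YieldEstimate(p_ratio=1e4))
        assert est.r_pha == pytest.approx(1e-7, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        r=st.floats(0.2, 2.0),
        log_rpha=st.floats(-9.0, -5.0),
        log_b0=st.floats(3.0, 7.0),
        log_ratio=st.floats(0.5, 6.0),
    )
    def test_roundtrip_identity_over_parameter_space(self, r, log_rpha, log_b0, log_ratio):
        params = PredationParams(r_bac=r, k_adsorb=10**log_rpha / 100, n_burst=100.0)
        init = InitialState(b0=10**log_b0, p0=1.0)
        p_ratio = 10**log_ratio
        t = collapse_time_adsorption(params, init, p_ratio)
        est = rate_from_single_curve(t, r, init.b0, YieldEstimate(p_ratio=p_ratio))
        assert abs(est.r_pha - params.r_pha) / params.r_pha < 1e-10

    def test_worked_example(self):
        est = rate_from_single_curve(6.83, 1.0, 1e5, YieldEstimate(p_ratio=1e4))
        assert est.r_pha == pytest.approx(1e-7, rel=5e-3)

    def test_doubling_b0_halves_rate(self):
        a = rate_from_single_curve(5.0, 1.0, 1e5, YieldEstimate(p_ratio=1e4))
        b = rate_from_single_curve(5.0, 1.0, 2e5, YieldEstimate(p_ratio=1e4))
        assert b.r_pha == pytest.approx(a.r_pha / 2, rel=1e-12)

    def test_censored_collapse_is_below_detection(self):
        censored = CollapseEstimate(float("nan"), float("nan"), censored=True)
        est = rate_from_single_curve(censored, 1.0, 1e5, YieldEstimate(p_ratio=1e4))
        assert est.below_detection
        assert est.detection_limit == pytest.approx(3e-10)

    def test_se_propagation_scales_with_se_t(self):
        est1 = rate_from_single_curve(_collapse(5.0, se=0.05), 1.0, 1e5, YieldEstimate(p_ratio=1e4))
        est2 = rate_from_single_curve(_collapse(5.0, se=0.10), 1.0, 1e5, YieldEstimate(p_ratio=1e4))
        assert est2.se_r_pha == pytest.approx(2 * est1.se_r_pha, rel=1e-9)


class TestJointFit:
    def _surface_collapses(self, params, b0s, p_ratios):
        out = []
        for b0, pr in zip(b0s, p_ratios):
            init = InitialState(b0=b0, p0=1.0)
            t = collapse_time_adsorption(params, init, pr)
            out.append((_collapse(t), init, YieldEstimate(p_ratio=pr)))
        return out

    def test_exact_surface_gives_r2_one(self, base_params, rng):
        b0s = 10 ** rng.uniform(4, 6, size=12)
        prs = 10 ** rng.uniform(2, 5, size=12)
        fit = joint_fit_rate(self._surface_collapses(base_params, b0s, prs), r_bac=1.0)
        assert fit.r_pha == pytest.approx(1e-7, rel=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.t_predicted, fit.t_observed, atol=1e-8)

    def test_noise_on_t_col_leaves_estimate_unbiased(self, base_params, rng):
        b0s = 10 ** rng.uniform(4, 6, size=20)
        prs = 10 ** rng.uniform(2, 5, size=20)
        estimates = []
        for _ in range(100):
            collapses = []
            for b0, pr in zip(b0s, prs):
                init = InitialState(b0=b0, p0=1.0)
                t = collapse_time_adsorption(base_params, init, pr) + rng.normal(0, 0.05)
                collapses.append((_collapse(t), init, YieldEstimate(p_ratio=pr)))
            fit = joint_fit_rate(collapses, r_bac=1.0)
            estimates.append(fit.r_pha)
        bias = abs(np.mean(estimates) - 1e-7)
        se_of_mean = np.std(estimates, ddof=1) / 10
        assert bias < 3 * se_of_mean + 0.005e-7

    def test_plate_recovery_with_known_growth_rate(self, base_params):
        """8x10 gradient plate: recovery within 5%, r2 >= 0.98."""
        dataset = generate_gradient_plate(base_params, seed=42, include_controls=False)
        collapses = []
        for curve in dataset.curves:
            cond = curve.condition
            est = detect_collapse(curve)
            if est.censored or not est.usable or cond["t_col_true"] is None:
                continue
            collapses.append(
                (
                    est,
                    InitialState(cond["b0"], cond["p0"]),
                    YieldEstimate(p_ratio=cond["p_at_collapse_true"] / cond["p0"]),
                )
            )
        fit = joint_fit_rate(collapses, r_bac=1.0)
        assert abs(fit.r_pha - 1e-7) / 1e-7 < 0.05
        assert fit.r2 >= 0.98
        assert fit.n_curves >= 70

    def test_needs_two_usable_collapses(self):
        censored = CollapseEstimate(float("nan"), float("nan"), censored=True)
        with pytest.raises(InsufficientDataError):
            joint_fit_rate(
                [(censored, InitialState(1e5, 1.0), YieldEstimate(p_ratio=10.0))],
                r_bac=1.0,
            )


class TestCalibration:
    def test_exact_line_recovery(self):
        dilutions = np.array([1e2, 1e3, 1e4, 1e5])
        t_cols = -0.5 * (-np.log(dilutions)) + 9.0
        cal = fit_calibration(dilutions, t_cols)
        assert cal.a == pytest.approx(-0.5, rel=1e-10)
        assert cal.b_intercept == pytest.approx(9.0, rel=1e-10)
        assert cal.fit_residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance(self, rng):
        dilutions = np.array([1e2, 3e2, 1e3, 3e3, 1e4])
        t_cols = 0.4 * np.log(dilutions) + 2.0 + rng.normal(0, 0.01, size=5)
        cal1 = fit_calibration(dilutions, t_cols)
        perm = rng.permutation(5)
        cal2 = fit_calibration(dilutions[perm], t_cols[perm])
        assert cal1.a == pytest.approx(cal2.a)
        assert cal1.b_intercept == pytest.approx(cal2.b_intercept)

    def test_degenerate_dilutions_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_calibration([100.0, 100.0, 100.0], [5.0, 5.1, 5.2])

    def test_synthetic_dilution_series_residuals(self, base_params, quiet_signal):
        """Noiseless 3x dilution series: residuals below one sampling interval."""
        p_stock = 2.6e8
        dilutions = np.array([100.0 * 3**i for i in range(9)])
        t_cols = [
            detect_collapse(
                generate_curve(base_params, InitialState(4e5, p_stock / d), quiet_signal, seed=i)
            ).t_col
            for i, d in enumerate(dilutions)
        ]
        cal = fit_calibration(dilutions, t_cols)
        assert cal.a < 0
        assert cal.fit_residual_sd < 5 / 60


class TestPhageRatio:
    def test_roundtrip_inverse_of_calibration(self):
        dilutions = np.array([1e2, 1e3, 1e4, 1e5])
        t_cols = -0.4 * (-np.log(dilutions)) + 8.0
        cal = fit_calibration(dilutions, t_cols)
        # a sample at exactly 1e3-fold dilution of the stock, assayed undiluted
        t = cal.predict_t_col(1e3)
        est = phage_ratio_from_collapse(cal, t, d=1.0)
        assert est.p_ratio == pytest.approx(1e-3, rel=1e-9)

    def test_reinoculation_dilution_factor(self):
        dilutions = np.array([1e2, 1e3, 1e4, 1e5])
        cal = fit_calibration(dilutions, -0.4 * (-np.log(dilutions)) + 8.0)
        t = cal.predict_t_col(1e3)
        undiluted = phage_ratio_from_collapse(cal, t, d=1.0)
        diluted = phage_ratio_from_collapse(cal, t, d=100.0)
        assert diluted.p_ratio == pytest.approx(100.0 * undiluted.p_ratio, rel=1e-9)

    def test_zero_slope_invalid(self):
        dilutions = np.array([1e2, 1e3, 1e4])
        cal = fit_calibration(dilutions, [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            phage_ratio_from_collapse(cal, 5.0, d=1.0)

    def test_extrapolation_warns(self):
        dilutions = np.array([1e2, 1e3, 1e4])
        cal = fit_calibration(dilutions, -0.4 * (-np.log(dilutions)) + 8.0)
        with pytest.warns(UserWarning, match="outside the calibrated range"):
            phage_ratio_from_collapse(cal, 30.0, d=1.0)

    def test_end_to_end_yield_recovery(self, base_params):
        """Simulate -> purify -> redilute -> reinoculate recovers p_inf within 2x."""
        p_stock = 2.6e8
        b0 = 4e5
        dilutions = np.array([100.0 * 3**i for i in range(9)])
        t_cols = [
            detect_collapse(
                generate_curve(base_params, InitialState(b0, p_stock / d), seed=100 + i)
            ).t_col
            for i, d in enumerate(dilutions)
        ]
        cal = fit_calibration(dilutions, t_cols)
        experiment_dilution = 2600.0
        first = generate_curve(base_params, InitialState(b0, p_stock / experiment_dilution), seed=7)
        p_inf_true = first.condition["p_final_true"]
        d = 100.0
        reinoculated = generate_curve(base_params, InitialState(b0, p_inf_true / d), seed=8)
        t_re = detect_collapse(reinoculated).t_col
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = phage_ratio_from_collapse(cal, t_re, d=d, stock_dilution=experiment_dilution)
        p_inf_recovered = est.p_ratio * (p_stock / experiment_dilution)
        assert 0.5 < p_inf_recovered / p_inf_true < 2.0


class TestApproximateRatio:
    def test_flag_and_value(self):
        est = approximate_ratio(1e5)
        assert est.p_ratio == 1e5 and est.approximated
        rate = rate_from_single_curve(5.0, 1.0, 1e5, est)
        assert rate.approximated_ratio

    def test_log_sensitivity(self):
        """A 10x error in the fold increase rescales the rate by ln(10x)/ln(x)."""
        x = 1e4
        r1 = rate_from_single_curve(5.0, 1.0, 1e5, YieldEstimate(p_ratio=x))
        r2 = rate_from_single_curve(5.0, 1.0, 1e5, YieldEstimate(p_ratio=10 * x))
        assert r2.r_pha / r1.r_pha == pytest.approx(math.log(10 * x) / math.log(x), rel=1e-12)

    def test_correlates_with_exact_ratio_across_decades(self, rng):
        """Stock-dilution approximation tracks exact fold increases (3 decades)."""
        approx_rates, exact_rates = [], []
        for log_rpha in np.linspace(-9, -6, 16):
            r_pha = 10**log_rpha
            params = PredationParams(r_bac=1.0, k_adsorb=r_pha / 100, n_burst=100.0)
            p_col = collapse_phage_density(params)
            stock_dilution = 2600.0
            p0 = 2.6e8 / stock_dilution
            init = InitialState(b0=4e5, p0=p0)
            exact_ratio = p_col / p0
            t = collapse_time_adsorption(params, init, exact_ratio) + rng.normal(0, 5 / 60)
            approx_rates.append(
                rate_from_single_curve(t, 1.0, init.b0, approximate_ratio(stock_dilution)).r_pha
            )
            exact_rates.append(
                rate_from_single_curve(t, 1.0, init.b0, YieldEstimate(p_ratio=exact_ratio)).r_pha
            )
        rho = np.corrcoef(np.log(approx_rates), np.log(exact_rates))[0, 1]
        assert rho > 0.9


class TestRegimeDiagnostic:
    def test_adsorption_limited_sweep(self, base_params):
        collapses = []
        for i, b0 in enumerate(serial_levels(3e6, 11, 2.0)):
            curve = generate_curve(base_params, InitialState(b0, 0.4 * b0), seed=60 + i)
            collapses.append((detect_collapse(curve), InitialState(b0, 0.4 * b0)))
        report = regime_diagnostic(collapses)
        assert report.call == "adsorption-limited"
        assert report.pearson_rho <= -0.99

    def test_latency_limited_sweep(self, latency_params):
        t_col = collapse_time_latency(latency_params, 0.01)
        collapses = [
            (_collapse(t_col), InitialState(b0, 0.01 * b0))
            for b0 in serial_levels(1e7, 10, 2.0)
        ]
        report = regime_diagnostic(collapses)
        assert report.call == "latency-limited"
        assert abs(report.slope) < 1e-3

    def test_duplicate_conditions_no_crash(self):
        collapses = [
            (_collapse(5.0), InitialState(1e4, 1e3)),
            (_collapse(5.0), InitialState(1e4, 1e3)),
            (_collapse(4.0), InitialState(1e5, 1e4)),
            (_collapse(3.0), InitialState(1e6, 1e5)),
            (_collapse(2.0), InitialState(1e7, 1e6)),
        ]
        report = regime_diagnostic(collapses)
        assert math.isfinite(report.pearson_rho)

    def test_insufficient_span_indeterminate(self):
        collapses = [
            (_collapse(5.0 - 0.1 * i), InitialState(1e5 * 1.5**i, 1e4)) for i in range(5)
        ]
        report = regime_diagnostic(collapses)
        assert report.call == "indeterminate"
        assert "span" in report.reason


class TestKAdsorb:
    def _plate_collapses(self, base_params, seed=11):
        dataset = generate_gradient_plate(base_params, seed=seed, include_controls=False)
        out = []
        for curve in dataset.curves:
            cond = curve.condition
            est = detect_collapse(curve)
            if est.usable and not est.censored:
                out.append((est, InitialState(cond["b0"], cond["p0"])))
        return out

    def test_recovery_within_factor_two(self, base_params):
        est = estimate_kadsorb(self._plate_collapses(base_params), r_bac=1.0)
        assert 0.5 <= est.k_adsorb / 1e-9 <= 2.0

    def test_p0_independent_collapse_not_identifiable(self):
        """Flat fold growth across p0 (infinite-burst limit) is flagged."""
        collapses = [
            (_collapse(math.log(300.0)), InitialState(1e5, p0))
            for p0 in serial_levels(1e6, 10, 3.0)
        ]
        with pytest.raises(NotIdentifiableError):
            estimate_kadsorb(collapses, r_bac=1.0)

    def test_narrow_p0_span_rejected(self):
        collapses = [
            (_collapse(5.0 - 0.1 * i), InitialState(1e5, 1e4 * 1.5**i)) for i in range(6)
        ]
        with pytest.raises(NotIdentifiableError):
            estimate_kadsorb(collapses, r_bac=1.0)

    def test_trajectory_overlay_matches_synthetic_curve(self, base_params):
        dataset = generate_gradient_plate(base_params, seed=11, include_controls=False)
        collapses = self._plate_collapses(base_params, seed=11)
        kest = estimate_kadsorb(collapses, r_bac=1.0)
        worst = 0.0
        for curve in dataset.curves[:6]:
            cond = curve.condition
            init = InitialState(cond["b0"], cond["p0"])
            est = detect_collapse(curve)
            traj = reconstruct_trajectory(
                1.0, kest.r_pha, kest.k_adsorb, init, curve.times, start_index=10
            )
            n = np.searchsorted(traj.times, est.t_col)
            model_signal = traj.b[:n] * dataset.signal_model.scale
            rms = np.sqrt(
                np.mean((np.log(curve.signal[10 : 10 + n]) - np.log(model_signal)) ** 2)
            )
            worst = max(worst, rms)
        assert worst < 0.2
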