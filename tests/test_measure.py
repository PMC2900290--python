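import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

import threshkit as tk
from threshkit import dynamics, measure, theory
from threshkit.errors import AlignmentError, FitError, ParameterError


def eif_dc_trace(p, factor=1.3, duration=500.0, dt=0.005):
    rheo = -float(np.min(theory.F_exp(p, np.linspace(-90.0, p.V_a, 2001))))
    I = factor * rheo
    return tk.simulate_eif(p, I=I, duration=duration, dt=dt), I


class TestOnsetDetection:
    def test_subthreshold_trace_yields_empty_set(self):
        tr = tk.Trace(dt=0.025, V=-70.0 + np.sin(np.linspace(0, 30, 2000)))
        ons = measure.detect_onsets(tr, "d1", k_th=10.0)
        assert len(ons) == 0

    def test_eif_onsets_match_empirical_threshold_closed_form(self, eif_params):
        trace, I = eif_dc_trace(eif_params)
        ons = measure.detect_onsets(trace, "d1", k_th=10.0)
        assert len(ons) >= 5
        predicted = tk.empirical_threshold(eif_params, 10.0, I=I)
        np.testing.assert_allclose(ons.voltages, predicted, atol=0.15)
        # onsets precede peaks and are strictly increasing in time
        assert np.all(np.diff(ons.times) > 0)

    def test_criterion_shifts_onsets_but_preserves_variations(self, spiking_setup):
        _, _, trace = spiking_setup
        low = measure.detect_onsets(trace, "d1", k_th=10.0)
        high = measure.detect_onsets(trace, "d1", k_th=15.0)
        # align by onset time (both detect nearly the same spikes)
        common = []
        for t_lo, v_lo in zip(low.times, low.voltages):
            j = np.argmin(np.abs(high.times - t_lo))
            if abs(high.times[j] - t_lo) < 5.0:
                common.append((v_lo, high.voltages[j]))
        lo_v, hi_v = np.array(common).T
        assert lo_v.size >= 20
        assert np.mean(hi_v - lo_v) > 0  # higher criterion -> later, higher onset
        assert np.corrcoef(lo_v, hi_v)[0, 1] > 0.8

    def test_detection_methods_are_rank_consistent(self, spiking_setup):
        """First-, second- and third-derivative onsets differ in absolute
        value but give the same relative threshold variations."""
        _, _, trace = spiking_setup
        sets = {
            "d1": measure.detect_onsets(trace, "d1", k_th=10.0),
            "d2": measure.detect_onsets(trace, "d2", smooth=9),
            "d3": measure.detect_onsets(trace, "d3", smooth=9),
        }
        base = sets["d2"]
        for other, floor in (("d3", 0.95), ("d1", 0.7)):
            a, b = [], []
            for t0, v0 in zip(base.times, base.voltages):
                j = np.argmin(np.abs(sets[other].times - t0))
                if abs(sets[other].times[j] - t0) < 5.0:
                    a.append(v0)
                    b.append(sets[other].voltages[j])
            rho = spearmanr(a, b).statistic
            assert rho > floor

    def test_invalid_method_and_criterion(self):
        tr = tk.Trace(dt=0.025, V=np.full(100, -70.0))
        with pytest.raises(ParameterError):
            measure.detect_onsets(tr, "d4")
        with pytest.raises(ParameterError):
            measure.detect_onsets(tr, "d1", k_th=0.0)


class TestExcitabilityCurve:
    def test_leak_only_single_stable_point(self):
        from threshkit.channels import GateModel, NaChannel
        from threshkit.simulate import MembraneModel

        na = NaChannel(
            g_max=0.0, E_rev=50.0,
            activation=GateModel(polarity="activation", V_half=-30.0, k=6.0, tau=0.2),
        )
        model = MembraneModel(C=250.0, g_L=20.0, E_L=-80.0, Na=na)
        exc = measure.excitability_curve(model, I=200.0)
        assert len(exc["roots"]) == 1
        root, kind = exc["roots"][0]
        assert kind == "stable"
        assert root == pytest.approx(-80.0 + 200.0 / 20.0, abs=1e-6)

    def test_fixed_points_below_rheobase(self, destexhe):
        model, _ = destexhe
        exc = measure.excitability_curve(model, I=0.0, h=1.0)
        assert not exc["supra_rheobase"]
        assert exc["rest"] is not None and exc["theta_fast"] is not None
        assert exc["rest"] < exc["V_T"] < exc["theta_fast"]
        # the curve minimum matches an independent scalar minimization
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda v: float(measure.membrane_F(model, v, h=1.0)),
            bounds=(-90.0, -30.0), method="bounded",
        )
        assert exc["V_T"] == pytest.approx(res.x, abs=0.1)

    def test_rheobase_tangency(self, destexhe):
        model, _ = destexhe
        exc = measure.excitability_curve(model, I=0.0, h=1.0)
        at = measure.excitability_curve(model, I=exc["rheobase"], h=1.0)
        roots = [r for r, _ in at["roots"]]
        if roots:  # double root collapses near V_T
            assert all(abs(r - exc["V_T"]) < 1.0 for r in roots)
        above = measure.excitability_curve(model, I=1.2 * exc["rheobase"], h=1.0)
        assert above["supra_rheobase"]


class TestPulseProbe:
    def test_eif_probe_recovers_fast_threshold(self, eif_params):
        thf = tk.fast_threshold(eif_params)
        levels = np.arange(thf - 3.0, thf + 3.0, 0.25)
        measured = measure.eif_probe_threshold(eif_params, levels)
        assert abs(measured - thf) <= 0.25 + 1e-9  # within one grid step

    def test_probe_flags_and_monotone_resolution(self, destexhe):
        model, bg = destexhe
        m6, bg6 = tk.apply_modifications(model, shift_Vi=-12.5, background=bg)
        probes, trace = measure.pulse_probe_threshold(
            m6, bg6, seed=1, run_length=60.0, probe_period=2.4,
            levels=np.linspace(-57.0, -38.0, 39), response_window=0.6,
        )
        assert probes.times.size == len(probes.flags)
        resolved = probes.flags == ""
        assert resolved.sum() >= 10
        assert np.all(np.isfinite(probes.threshold[resolved]))
        assert np.all(np.isnan(probes.threshold[probes.flags == "all"]))
        # probes inside spike windows are excluded
        for t_on in trace.spikes:
            inside = (probes.times >= t_on) & (probes.times <= t_on + 7.0)
            assert np.all(probes.flags[inside] == "spike")

    def test_probe_thresholds_at_or_above_slow_prediction(self, destexhe):
        """Fast (charge) thresholds measured by probing sit above the
        slow-input threshold-equation prediction at the same instant."""
        model, bg = destexhe
        m6, bg6 = tk.apply_modifications(model, shift_Vi=-12.5, background=bg)
        from threshkit.cli_io import calibrate_threshold_params

        p = calibrate_threshold_params(m6)
        probes, trace = measure.pulse_probe_threshold(
            m6, bg6, seed=2, run_length=60.0, probe_period=1.2,
            levels=np.linspace(-57.0, -38.0, 39), response_window=0.6,
        )
        kc = [(m6.K_delayed.g_max, m6.K_delayed.E_rev, m6.K_delayed.gate),
              (m6.K_slow.g_max, m6.K_slow.E_rev, m6.K_slow.gate)]
        ser = dynamics.integrate_threshold(
            p, m6.Na.inactivation, trace, k_channels=kc,
            syn_conductances=[(trace.g_e, bg6.E_e), (trace.g_i, bg6.E_i)],
        )
        ok = probes.flags == ""
        idx = np.round(probes.times[ok] / trace.dt).astype(int)
        assert np.all(probes.threshold[ok] >= ser.theta[idx] - 0.25)


class TestComparisonStatistics:
    def test_perfect_and_shifted_predictions(self):
        rng = np.random.default_rng(1)
        x = rng.normal(-45.0, 2.0, 200)
        st = measure.compare_prediction(x, x)
        assert st["variance_explained"] == pytest.approx(1.0)
        assert st["mean_shift"] == pytest.approx(0.0, abs=1e-12)
        st5 = measure.compare_prediction(x, x - 5.0)
        assert st5["variance_explained"] == pytest.approx(1.0)
        assert st5["mean_shift"] == pytest.approx(5.0)
        assert st5["r2_sse"] < st["r2_sse"]  # SSE metric is not shift-invariant

    def test_alignment_errors(self):
        with pytest.raises(AlignmentError):
            measure.compare_prediction(np.ones(5), np.ones(6))
        with pytest.raises(AlignmentError):
            measure.compare_prediction(np.full(5, np.nan), np.ones(5))


class TestLogHRegression:
    def test_exact_threshold_equation_slope(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0.2, 0.9, 50)
        v = -55.0 - 3.7 * np.log(h)
        slope, intercept = measure.regress_threshold_on_log_h(v, h)
        assert slope == pytest.approx(-3.7, abs=1e-12)
        assert intercept == pytest.approx(-55.0, abs=1e-9)

    def test_voltage_noise_leaves_slope_unbiased(self):
        """Monte-Carlo: additive measurement noise on the onset voltage does
        not bias the OLS slope."""
        rng = np.random.default_rng(3)
        slopes = []
        for _ in range(200):
            h = rng.uniform(0.2, 0.9, 60)
            v = -55.0 - 3.7 * np.log(h) + rng.normal(0.0, 1.0, 60)
            slopes.append(measure.regress_threshold_on_log_h(v, h)[0])
        assert np.mean(slopes) == pytest.approx(-3.7, abs=0.1)

    def test_degenerate_inputs(self):
        with pytest.raises(FitError):
            measure.regress_threshold_on_log_h(np.ones(5), np.full(5, 0.5))
        with pytest.raises(FitError):
            measure.regress_threshold_on_log_h(np.ones(20), np.full(20, 0.5))
        with pytest.raises(ParameterError):
            measure.regress_threshold_on_log_h(np.ones(20), np.zeros(20))


class TestSharpness:
    def test_recovers_eif_slope_factor(self, eif_params):
        trace, I = eif_dc_trace(eif_params)
        fit = measure.sharpness_fit(
            trace, I=I, g_L=eif_params.g_L, E_L=eif_params.E_L, C=eif_params.C
        )
        assert fit["Delta_T"] == pytest.approx(eif_params.k_a, rel=0.05)

    def test_monotone_in_true_slope_factor(self, eif_params):
        fits = []
        for ka in (2.0, 4.0, 6.0):
            p = dataclasses.replace(eif_params, k_a=ka)
            trace, I = eif_dc_trace(p)
            fits.append(
                measure.sharpness_fit(trace, I=I, g_L=p.g_L, E_L=p.E_L, C=p.C)["Delta_T"]
            )
        assert fits[0] < fits[1] < fits[2]

    def test_subthreshold_trace_has_no_exponential_branch(self, eif_params):
        trace = tk.simulate_eif(eif_params, I=0.0, duration=100.0)
        with pytest.raises(FitError):
            measure.sharpness_fit(
                trace, I=0.0, g_L=eif_params.g_L, E_L=eif_params.E_L, C=eif_params.C
            )
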