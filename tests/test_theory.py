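import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import threshkit as tk
from threshkit import theory
from threshkit.errors import NoThresholdError, ParameterError

P = tk.ThresholdParams(
    V_a=-30.0, k_a=6.0, g_Na=5000.0, g_L=50.0, E_Na=55.0, C=250.0, E_L=-80.0
)


def random_params(rng):
    while True:
        V_a = rng.uniform(-40.0, -20.0)
        p = tk.ThresholdParams(
            V_a=V_a,
            k_a=rng.uniform(2.0, 8.0),
            g_Na=10 ** rng.uniform(2.5, 4.5),
            g_L=10 ** rng.uniform(0.8, 2.0),
            E_Na=rng.uniform(45.0, 65.0),
            C=rng.uniform(100.0, 500.0),
            E_L=rng.uniform(-85.0, -70.0),
        )
        try:
            vt = tk.base_threshold(p)
        except NoThresholdError:
            continue
        if vt > -90.0 and vt < p.V_a - 3 * p.k_a and p.E_L < vt - p.k_a:
            return p


def random_state(p, rng):
    extra = [(p.g_L, p.E_L)]
    for _ in range(rng.integers(0, 3)):
        extra.append((10 ** rng.uniform(0.0, 2.0), rng.uniform(-90.0, 0.0)))
    return tk.ThresholdState(h=rng.uniform(0.2, 1.0), conductances=tuple(extra))


class TestEffectiveChannel:
    def test_worked_examples(self):
        assert tk.effective_channel([(10.0, -70.0)]) == (10.0, -70.0)
        assert tk.effective_channel([(10.0, -80.0), (10.0, -60.0)]) == (20.0, -70.0)
        g, e = tk.effective_channel([(5.0, 0.0), (15.0, -75.0), (20.0, -70.0)])
        assert g == pytest.approx(40.0) and e == pytest.approx(-63.125)

    def test_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            tk.effective_channel([])
        with pytest.raises(ParameterError):
            tk.effective_channel([(0.0, -70.0), (0.0, -60.0)])
        with pytest.raises(ParameterError):
            tk.effective_channel([(-1.0, -70.0)])


class TestBaseThreshold:
    def test_logarithmic_density_dependence(self):
        vt = tk.base_threshold(P)
        doubled = dataclasses.replace(P, g_Na=2 * P.g_Na)
        assert tk.base_threshold(doubled) == pytest.approx(vt - P.k_a * math.log(2), abs=1e-12)

    def test_invariance_under_joint_conductance_scaling(self):
        vt = tk.base_threshold(P)
        scaled = dataclasses.replace(P, g_Na=7.3 * P.g_Na, g_L=7.3 * P.g_L)
        assert tk.base_threshold(scaled) == pytest.approx(vt, abs=1e-12)

    def test_matches_critical_point_oracle(self):
        assert tk.base_threshold(P) == pytest.approx(tk.base_threshold_numeric(P), abs=1e-6)

    def test_matches_golden_section_minimum_of_F(self):
        res = minimize_scalar(
            lambda v: float(theory.F_exp(P, v)),
            bounds=(-90.0, P.V_a),
            method="bounded",
            options={"xatol": 1e-9},
        )
        assert tk.base_threshold(P) == pytest.approx(res.x, abs=1e-6)

    def test_no_threshold_when_na_too_weak(self):
        weak = dataclasses.replace(P, g_Na=1e-3)
        with pytest.raises(NoThresholdError):
            tk.base_threshold(weak)

    def test_calibrated_override_is_returned(self):
        p = dataclasses.replace(P, V_T=-55.0)
        assert tk.base_threshold(p) == -55.0
        assert tk.threshold(p, tk.ThresholdState(h=0.5, conductances=((P.g_L, P.E_L),))) == (
            pytest.approx(-55.0 + P.k_a * math.log(2))
        )


class TestThresholdEquation:
    def test_reductions(self):
        vt = tk.base_threshold(P)
        leak = ((P.g_L, P.E_L),)
        assert tk.threshold(P, tk.ThresholdState(1.0, leak)) == pytest.approx(vt)
        assert tk.threshold(P, tk.ThresholdState(0.5, leak)) == pytest.approx(
            vt + P.k_a * math.log(2)
        )
        assert tk.threshold(
            P, tk.ThresholdState(1.0, ((2 * P.g_L, P.E_L),))
        ) == pytest.approx(vt + P.k_a * math.log(2))

    def test_log_sensitivities_by_finite_differences(self):
        leak = ((P.g_L, P.E_L),)
        eps = 1e-6
        th = lambda h, g: tk.threshold(P, tk.ThresholdState(h, ((g, P.E_L),)))
        d_lnh = (th(0.7 * (1 + eps), P.g_L) - th(0.7 * (1 - eps), P.g_L)) / (2 * eps)
        d_lng = (th(0.7, P.g_L * (1 + eps)) - th(0.7, P.g_L * (1 - eps))) / (2 * eps)
        assert d_lnh == pytest.approx(-P.k_a, rel=1e-5)
        assert d_lng == pytest.approx(P.k_a, rel=1e-5)

    def test_random_states_match_critical_point_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_params(rng)
            s = random_state(p, rng)
            assert tk.threshold(p, s) == pytest.approx(tk.threshold_numeric(p, s), abs=1e-6)

    def test_scale_invariance_with_extra_conductances(self):
        s = tk.ThresholdState(0.8, ((P.g_L, P.E_L), (30.0, -90.0), (12.0, 0.0)))
        th = tk.threshold(P, s)
        c = 3.7
        p2 = dataclasses.replace(P, g_Na=c * P.g_Na, g_L=c * P.g_L)
        s2 = tk.ThresholdState(0.8, tuple((c * g, E) for g, E in s.conductances))
        assert tk.threshold(p2, s2) == pytest.approx(th, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            tk.ThresholdState(h=0.0, conductances=((10.0, -70.0),))
        with pytest.raises(ParameterError):
            tk.ThresholdState(h=1.2, conductances=((10.0, -70.0),))

    def test_decomposition_levels(self):
        vt = tk.base_threshold(P)
        lv = tk.threshold_decomposition(P)
        assert lv == pytest.approx((vt, vt, vt, vt))
        lv = tk.threshold_decomposition(
            P, h=0.6, k_conductances=((40.0, -90.0),), syn_conductances=((20.0, 0.0), (60.0, -75.0))
        )
        assert lv[0] <= lv[1] <= lv[2] <= lv[3]
        full = tk.ThresholdState(
            0.6, ((P.g_L, P.E_L), (40.0, -90.0), (20.0, 0.0), (60.0, -75.0))
        )
        assert lv[3] == pytest.approx(tk.threshold(P, full), abs=1e-12)


class TestThresholdDefinitions:
    def test_ordering_slow_fast_va(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_params(rng)
            vt, tf = tk.base_threshold(p), tk.fast_threshold(p)
            assert vt < tf < p.V_a

    def test_fast_threshold_matches_bisection_root(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = random_params(rng)
            assert tk.fast_threshold(p) == pytest.approx(tk.fast_threshold_numeric(p), abs=1e-6)

    def test_rest_and_fast_bracket_the_dynamics(self):
        r, f = tk.rest_potential(P), tk.fast_threshold(P)
        assert r < tk.base_threshold(P) < f
        assert theory.F_exp(P, (r + f) / 2) < 0  # between roots F < 0

    def test_empirical_threshold_properties(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            p = random_params(rng)
            th = [tk.empirical_threshold(p, k) for k in (1.0, 5.0, 10.0, 20.0)]
            assert all(a < b for a, b in zip(th, th[1:]))  # increasing in k_th
            assert tk.empirical_threshold(p, 1e-9) == pytest.approx(
                tk.fast_threshold(p), abs=1e-4
            )
            assert tk.empirical_threshold(p, 10.0) == pytest.approx(
                tk.empirical_threshold_numeric(p, 10.0), abs=1e-6
            )

    def test_fast_and_slow_covary_almost_linearly(self):
        """Across a density sweep the two definitions move nearly 1:1."""
        ratios = np.linspace(30.0, 250.0, 20)
        vts, tfs = [], []
        for r in ratios:
            p = dataclasses.replace(P, g_Na=r * P.g_L, E_L=-90.0)
            vts.append(tk.base_threshold(p))
            tfs.append(tk.fast_threshold(p))
        slope = np.polyfit(vts, tfs, 1)[0]
        assert 0.8 < slope < 1.5
        assert np.corrcoef(vts, tfs)[0, 1] > 0.999

    def test_no_resting_state_raises(self):
        hot = dataclasses.replace(P, g_Na=1e7)
        with pytest.raises(NoThresholdError):
            tk.fast_threshold(hot)


class TestMorphology:
    def test_electrotonic_length_of_ais(self):
        geom = tk.GeometryParams(d=1.5, R_i=150.0, R_m=35000.0, S_AIS=871.3)
        assert tk.electrotonic_length(geom) == pytest.approx(935.0, abs=1.0)

    def test_square_root_scalings(self):
        geom = tk.GeometryParams(d=1.5, R_i=150.0, R_m=35000.0)
        lam = tk.electrotonic_length(geom)
        assert tk.electrotonic_length(
            dataclasses.replace(geom, R_i=4 * geom.R_i)
        ) == pytest.approx(lam / 2)
        assert tk.electrotonic_length(
            dataclasses.replace(geom, d=4 * geom.d)
        ) == pytest.approx(2 * lam)
        with pytest.raises(ParameterError):
            tk.GeometryParams(d=-1.0, R_i=150.0, R_m=35000.0)

    def test_na_density_inversion_round_trip(self):
        vt = tk.base_threshold(P)
        geom = tk.GeometryParams(d=1.5, R_i=150.0, R_m=35000.0, S_AIS=500.0)
        dens = tk.invert_for_Na_density(vt, P.g_L, geom, P.V_a, P.k_a, P.E_Na)
        g_rec = dens * geom.S_AIS / 1e3
        assert g_rec == pytest.approx(P.g_Na, rel=1e-12)
        p2 = dataclasses.replace(P, g_Na=g_rec)
        assert tk.base_threshold(p2) == pytest.approx(vt, abs=1e-9)

    def test_inversion_linear_in_total_conductance(self):
        geom = tk.GeometryParams(d=1.5, R_i=150.0, R_m=35000.0, S_AIS=871.3)
        d1 = tk.invert_for_Na_density(-55.0, 59.0, geom, -31.1, 6.5, 55.0)
        d2 = tk.invert_for_Na_density(-55.0, 29.5, geom, -31.1, 6.5, 55.0)
        assert d1 == pytest.approx(2 * d2, rel=1e-12)
        with pytest.raises(ParameterError):
            tk.invert_for_Na_density(-20.0, 59.0, geom, -31.1, 6.5, 55.0)


class TestChannelTable:
    def test_threshold_curves_over_density_ratio(self):
        table = pd.DataFrame(
            {"name": ["a", "b"], "V_a_mV": [-30.0, -25.0], "k_a_mV": [6.0, 6.0]}
        )
        ratios = [50.0, 100.0, 200.0, 400.0]
        out = tk.channel_table_thresholds(table, ratios, E_Na=55.0)
        assert len(out) == len(table) * len(ratios)
        for name, grp in out.groupby("name"):
            assert np.all(np.diff(grp.sort_values("g_ratio").V_T_mV) < 0)
        a = out[out.name == "a"].sort_values("g_ratio").V_T_mV.to_numpy()
        b = out[out.name == "b"].sort_values("g_ratio").V_T_mV.to_numpy()
        # same k_a: curves offset by Delta V_a plus the driving-force term
        offs = b - a
        assert np.allclose(offs, offs[0], atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            tk.channel_table_thresholds(pd.DataFrame({"name": ["a"]}), [100.0])
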