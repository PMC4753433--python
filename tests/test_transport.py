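"""The 4-state ping-pong cycle: steady state, saturation, and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from asymx.transport import (DoseResponse, ExchangeMode, PingPongParams, Side,
                             default_concentration_grid, pingpong_initial_rate,
                             predicted_saturation_rate, rate_matrix,
                             simulate_dose_response, steady_state_distribution)

PARAM_GRID = [
    dict(Kd_ext=400.0, Kd_cyt=60.0, k_transloc_in=1.0, k_transloc_out=1.0,
         k_return_Na=4.0),
    dict(Kd_ext=50.0, Kd_cyt=900.0, k_transloc_in=0.1, k_transloc_out=2.0,
         k_return_Na=0.5),
    dict(Kd_ext=1500.0, Kd_cyt=1500.0, k_transloc_in=5.0, k_transloc_out=0.02,
         k_return_Na=30.0),
]


def _params(d, name="X"):
    return PingPongParams(construct_name=name, Et=1.0, **d)


class TestSteadyState:
    @pytest.mark.parametrize("pd", PARAM_GRID)
    @pytest.mark.parametrize("mode", [ExchangeMode.CaCa, ExchangeMode.NaCa])
    def test_matches_ode_relaxation(self, pd, mode):
        """Linear-solve stationary distribution equals long-time relaxation
        of the mass-action ODE (exact propagator), to 1e-6 relative."""
        p = _params(pd)
        c_cyt = 0.0 if mode is ExchangeMode.NaCa else 250.0
        Q = rate_matrix(p, 300.0, c_cyt, mode, binding_relax=1e3)
        direct = steady_state_distribution(Q)
        slowest = min(x for x in (p.k_transloc_in, p.k_transloc_out,
                                  p.k_return_Na) if x > 0)
        # dp/dt = Q^T p  =>  p(t) = expm(Q^T t) p(0); t >> 1/slowest rate
        relaxed = expm(Q.T * (200.0 / slowest)) @ np.array([1.0, 0, 0, 0])
        assert np.allclose(direct, relaxed, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("pd", PARAM_GRID)
    def test_saturation_limit_caca(self, pd):
        """conc -> inf rate approaches Et*kin*kout/(kin+kout)."""
        p = _params(pd)
        v = pingpong_initial_rate(p, 1e9, ExchangeMode.CaCa, Side.extracellular)
        assert v == pytest.approx(predicted_saturation_rate(p, ExchangeMode.CaCa),
                                  rel=1e-4)

    @pytest.mark.parametrize("pd", PARAM_GRID)
    def test_saturation_limit_naca(self, pd):
        p = _params(pd)
        v = pingpong_initial_rate(p, 1e9, ExchangeMode.NaCa, Side.extracellular)
        assert v == pytest.approx(predicted_saturation_rate(p, ExchangeMode.NaCa),
                                  rel=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(kd=st.floats(10.0, 2000.0), kin=st.floats(0.01, 10.0),
           kout=st.floats(0.01, 10.0))
    def test_monotone_saturating(self, kd, kin, kout):
        """Rate is monotone increasing and bounded by the saturation limit."""
        p = PingPongParams("H", Kd_ext=kd, Kd_cyt=60.0, k_transloc_in=kin,
                           k_transloc_out=kout)
        concs = np.geomspace(1.0, 1e5, 12)
        rates = [pingpong_initial_rate(p, c) for c in concs]
        assert all(b > a for a, b in zip(rates, rates[1:]))
        assert rates[-1] <= predicted_saturation_rate(p) * (1 + 1e-6)

    def test_half_saturation_at_operational_km(self, wt_params):
        """At the operational Km (Kd'' * kout/(kin+kout)) the rate is Vmax/2."""
        km = wt_params.Kd_ext * wt_params.k_transloc_out / (
            wt_params.k_transloc_in + wt_params.k_transloc_out)
        v = pingpong_initial_rate(wt_params, km)
        assert v == pytest.approx(
            0.5 * predicted_saturation_rate(wt_params), rel=1e-4)

    def test_symmetric_parameters_give_equal_sides(self):
        """Kd_ext = Kd_cyt and kin = kout make the two half-saturations equal
        (K_int = 1 by symmetry)."""
        p = PingPongParams("sym", Kd_ext=300.0, Kd_cyt=300.0,
                           k_transloc_in=0.7, k_transloc_out=0.7)
        for c in (30.0, 150.0, 900.0):
            v_ext = pingpong_initial_rate(p, c, ExchangeMode.CaCa,
                                          Side.extracellular)
            v_cyt = pingpong_initial_rate(p, c, ExchangeMode.CaCa,
                                          Side.cytosolic)
            assert v_ext == pytest.approx(v_cyt, rel=1e-5)

    def test_rate_scales_with_et(self, wt_params):
        doubled = wt_params.scaled(Et=2.0)
        assert pingpong_initial_rate(doubled, 100.0) == pytest.approx(
            2.0 * pingpong_initial_rate(wt_params, 100.0), rel=1e-12)

    def test_invalid_inputs_raise(self, wt_params):
        with pytest.raises(ValueError):
            pingpong_initial_rate(wt_params, -5.0)
        with pytest.raises(ValueError):
            pingpong_initial_rate(wt_params, 0.0)
        with pytest.raises(ValueError):
            PingPongParams("bad", Kd_ext=-1.0, Kd_cyt=60.0,
                           k_transloc_in=1.0, k_transloc_out=1.0)
        with pytest.raises(ValueError):
            # the Na limb is an effective return rate; no cytosolic titration
            pingpong_initial_rate(wt_params, 100.0, ExchangeMode.NaCa,
                                  Side.cytosolic)


class TestSimulation:
    def test_zero_noise_lies_on_model_curve(self, wt_params):
        dr = simulate_dose_response(wt_params, noise_cv=0.0, seed=5)
        for conc, rate, sd, n in dr.points:
            assert rate == pytest.approx(
                pingpong_initial_rate(wt_params, conc), rel=1e-12)
            assert sd == 0.0 and n == 3

    def test_default_design(self, wt_params):
        """Default design: 8 concentrations spanning 20-2000 uM, n = 3."""
        dr = simulate_dose_response(wt_params, seed=0)
        concs = dr.concentrations
        assert len(concs) == 8
        assert concs.min() == pytest.approx(20.0)
        assert concs.max() == pytest.approx(2000.0)
        assert all(p[3] == 3 for p in dr.points)

    def test_seed_reproducibility(self, wt_params):
        a = simulate_dose_response(wt_params, seed=42)
        b = simulate_dose_response(wt_params, seed=42)
        assert a.points == b.points
        c = simulate_dose_response(wt_params, seed=43)
        assert a.points != c.points

    def test_noise_is_unit_mean_multiplicative(self, wt_params):
        rng = np.random.default_rng(11)
        dr = simulate_dose_response(wt_params, [500.0], n_replicates=4000,
                                    noise_cv=0.10, seed=rng)
        truth = pingpong_initial_rate(wt_params, 500.0)
        _, mean, sd, _ = dr.points[0]
        assert mean == pytest.approx(truth, rel=0.01)
        assert sd / mean == pytest.approx(0.10, rel=0.06)

    def test_empty_design_rejected(self, wt_params):
        with pytest.raises(ValueError):
            simulate_dose_response(wt_params, [], seed=0)

    def test_dose_response_validation(self):
        with pytest.raises(ValueError):
            DoseResponse("x", ExchangeMode.CaCa, Side.extracellular,
                         [(100.0, 1.0, 0.1, 3), (100.0, 1.1, 0.1, 3)])
        with pytest.raises(ValueError):
            DoseResponse("x", ExchangeMode.CaCa, Side.extracellular,
                         [(-1.0, 1.0, 0.1, 3)])


def test_concentration_grid_spans_assay_range():
    g = default_concentration_grid()
    assert g[0] == 20.0 and g[-1] == 2000.0 and len(g) == 8
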