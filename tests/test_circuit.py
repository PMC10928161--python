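"""Lumped-circuit model: DC oracle, dynamics, Windkessel response, scaling."""

import math

import numpy as np
import pytest

from fetopulm import circuit
from fetopulm.circuit import (
    CircuitError,
    dc_solve,
    flow_from_velocity,
    harmonic_steady_state,
    nominal_parameters,
    simulate,
    simulate_windkessel,
    windkessel_impedance,
)
from fetopulm.doppler import Waveform

TERM = dict(ga_weeks=39.0, efw_g=3300.0)


@pytest.fixture(scope="module")
def p_term():
    return nominal_parameters(**TERM)


class TestNominalParameters:
    def test_all_positive_across_range(self):
        for ga, efw in [(24, 600), (30, 1500), (37, 2800), (41, 4000)]:
            p = nominal_parameters(ga, efw)
            assert min(p.r_mpa, p.rp_p, p.cp_s, p.a_da, p.l_ipa) > 0

    def test_resistances_halve_when_weight_doubles(self):
        p1 = nominal_parameters(32, 1500)
        p2 = nominal_parameters(32, 3000)
        assert p2.rp_p == pytest.approx(p1.rp_p / 2, rel=1e-12)
        assert p2.rc_s == pytest.approx(p1.rc_s / 2, rel=1e-12)
        assert p2.cp_p == pytest.approx(2 * p1.cp_p, rel=1e-12)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(CircuitError):
            nominal_parameters(15, 1000)
        with pytest.raises(CircuitError):
            nominal_parameters(30, -5)

    def test_term_resting_pressure_is_physiological(self, p_term):
        """Mean MPA pressure of a term fetus at resting RV output sits in the
        accepted prenatal 35-55 mmHg window."""
        q = np.full(128, 13.0)  # resting RV output ~780 mL/min
        res = simulate(p_term, q, 0.43)
        assert res.periodic
        assert 35.0 <= res.mean_pressure("P1") <= 55.0


class TestFlowFromVelocity:
    def _wave(self, v):
        return Waveform(site="MPA", condition="baseline", dt_s=1e-3,
                        v_cm_s=np.asarray(v, float), cycle_s=len(v) * 1e-3)

    def test_zero_velocity_zero_flow(self):
        assert np.all(flow_from_velocity(self._wave(np.zeros(100)), 5.0) == 0)

    def test_direct_arithmetic(self):
        # 60 cm/s through a 5.66 mm valve: Q = 60 * pi * 0.283^2 ~ 15.1 mL/s
        q = flow_from_velocity(self._wave(np.full(100, 60.0)), 5.66)
        assert q[0] == pytest.approx(60 * math.pi * 0.283 ** 2, rel=1e-3)
        assert q[0] == pytest.approx(15.1, rel=0.01)

    def test_doubling_diameter_quadruples_flow(self):
        w = self._wave(np.linspace(10, 80, 100))
        assert np.allclose(flow_from_velocity(w, 8.0),
                           4 * flow_from_velocity(w, 4.0), rtol=1e-12)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(CircuitError):
            flow_from_velocity(self._wave(np.ones(100)), 0.0)


class TestDCSolve:
    def test_zero_flow_zero_pressures(self, p_term):
        out = dc_solve(p_term, 0.0)
        assert all(v == 0 for v in out["pressures"].values())

    def test_symmetric_branches_split_evenly(self, p_term):
        from dataclasses import replace

        p = replace(p_term, r_ipa=p_term.r_da, rc_p=p_term.rc_s,
                    rp_p=p_term.rp_s, k_da=0.0)
        out = dc_solve(p, 10.0)
        assert out["flows"]["q_ipa"] == pytest.approx(5.0, rel=1e-12)

    def test_matches_hand_computed_current_divider(self, p_term):
        out = dc_solve(p_term, 12.0)
        r1 = p_term.r_ipa + p_term.rc_p + p_term.rp_p
        r2 = p_term.r_da + p_term.rc_s + p_term.rp_s
        assert out["flows"]["q_da"] == pytest.approx(12.0 * r1 / (r1 + r2), rel=1e-12)
        assert out["pressures"]["P1"] == pytest.approx(
            12.0 * r1 * r2 / (r1 + r2), rel=1e-12)

    def test_kcl_holds_with_nonlinear_ductus(self, p_term):
        from dataclasses import replace

        p = replace(p_term, k_da=0.05)
        out = dc_solve(p, 12.0)
        f = out["flows"]
        assert f["q_ipa"] + f["q_da"] == pytest.approx(12.0, rel=1e-12)
        # ductus drop includes the quadratic term
        dp = p.r_da * f["q_da"] + p.k_da * f["q_da"] ** 2
        assert out["pressures"]["P1"] - out["pressures"]["P4"] == pytest.approx(
            dp, rel=1e-9)


class TestSimulate:
    def test_constant_input_converges_to_dc_solution(self, p_term):
        """Periodic steady state of the ODE system reproduces the resistive
        network solution when driven by constant flow (started well away
        from it)."""
        q = np.full(64, 13.0)
        dc = dc_solve(p_term, 13.0)
        res = simulate(p_term, q, 0.43, y0=np.zeros(7), max_cycles=200,
                       periodicity_tol=1e-11)
        assert res.periodic
        for node in ("P1", "P2", "P3", "P4", "P5"):
            assert res.pressures[node].mean() == pytest.approx(
                dc["pressures"][node], rel=1e-6)

    def test_zero_input_decays_to_rest(self, p_term):
        res = simulate(p_term, np.zeros(64), 0.43, y0=np.array([40., 3., 39., 38., 10., 38., 36.]),
                       max_cycles=100, periodicity_tol=1e-10)
        assert res.periodic
        assert abs(res.pressures["P1"]).max() < 1e-6

    def test_passivity_nonnegative_mean_pressures(self, p_term):
        t = np.arange(128) / 128
        q = np.clip(15 * np.sin(2 * math.pi * t), 0, None)
        res = simulate(p_term, q, 0.4)
        for node in ("P1", "P2", "P3", "P4", "P5"):
            assert res.pressures[node].mean() >= 0

    def test_flow_conservation_at_steady_state(self, p_term):
        t = np.arange(128) / 128
        q = 10 + 6 * np.sin(2 * math.pi * t)
        res = simulate(p_term, q, 0.4, max_cycles=100, periodicity_tol=1e-8)
        inflow = res.flows["q_in"].mean()
        outflow = res.flows["q_out_p"].mean() + res.flows["q_out_s"].mean()
        assert outflow == pytest.approx(inflow, rel=1e-3)

    def test_raising_peripheral_resistance_reduces_lung_flow(self, p_term):
        from dataclasses import replace

        t = np.arange(128) / 128
        q = 10 + 6 * np.sin(2 * math.pi * t)
        flows = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            p = replace(p_term, rp_p=p_term.rp_p * scale)
            flows.append(simulate(p, q, 0.4).flows["q_ipa"].mean())
        assert all(a > b for a, b in zip(flows, flows[1:]))

    def test_harmonic_solution_matches_time_domain(self, p_term):
        t = np.arange(256) / 256
        q = 10 + 5 * np.sin(2 * math.pi * t) + 2 * np.sin(6 * math.pi * t)
        res = simulate(p_term, q, 0.4, max_cycles=200, periodicity_tol=1e-10,
                       n_out=256)
        h = harmonic_steady_state(p_term, q, 0.4)
        scale = np.abs(h.v_ipa_cm_s).max()
        assert np.abs(h.v_ipa_cm_s - res.v_ipa_cm_s).max() / scale < 5e-3
        assert np.abs(h.pressures["P1"] - res.pressures["P1"]).max() < 0.05

    def test_nonlinear_ductus_needs_time_domain(self, p_term):
        from dataclasses import replace

        with pytest.raises(CircuitError, match="k_da"):
            harmonic_steady_state(replace(p_term, k_da=0.1), np.full(64, 10.0), 0.4)


class TestWindkessel:
    @pytest.mark.parametrize("freq", [0.5, 2.0, 8.0, 20.0])
    def test_frequency_response_matches_analytic_impedance(self, freq):
        """Sinusoidal flow into an isolated three-element Windkessel:
        simulated pressure amplitude and phase match
        Z(w) = Rc + Rp / (1 + i w Rp Cp) within 1%."""
        rc, rp, cp = 1.5, 15.5, 0.016
        cycle = 1.0 / freq
        m = max(int(2048 * min(freq, 4)), 256)
        tq = np.arange(m) / m * cycle
        q = 5.0 + 2.0 * np.sin(2 * math.pi * freq * tq)
        t, p = simulate_windkessel(rc, rp, cp, q, cycle)
        # project the periodic pressure onto the drive harmonic;
        # q = 2 sin(wt) has complex amplitude -2j, so Z = P_c / (-2j)
        ph = np.exp(-2j * math.pi * freq * t[:-1])
        p_c = 2.0 * np.mean(p[:-1] * ph)
        z_sim = p_c / (-2j)
        z_ref = windkessel_impedance(rc, rp, cp, freq)
        assert abs(z_sim) == pytest.approx(abs(z_ref), rel=0.01)
        assert np.angle(z_sim) == pytest.approx(np.angle(z_ref), abs=0.01)

    def test_dc_impedance_is_total_resistance(self):
        z = windkessel_impedance(1.5, 15.5, 0.016, 0.0)
        assert z == pytest.approx(17.0)
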