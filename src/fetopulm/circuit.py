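"""0-D lumped model of the fetal pulmonary circulation.

The circuit has one flow input (right-ventricular output entering the main
pulmonary artery), three arterial segments and two peripheral beds::

    Q_in --[R_MPA,L_MPA]--(P1,C_MPA)--+--[R_IPA,L_IPA]--(P2,C_IPA)--WK_pulm
                                      |
                                      +--[R_DA*,L_DA]---(P4,C_DA)---WK_sys

Each arterial segment is a series resistor-inductor with a shunt capacitor at
its distal node (standard L-section).  The ductus arteriosus resistor is
nonlinear, ``dP = R_DA*q + k_DA*q*|q|`` (sign-preserving quadratic).  Each
peripheral bed is a three-element Windkessel: characteristic resistance Rc in
series with a parallel pair (compliance Cp, peripheral resistance Rp).  The
distal reference pressure is 0, so node pressures are transmural.

Because the input is an ideal flow source feeding the MPA R-L directly, the
MPA segment flow equals the input flow and the dynamic state has seven
components: ``(P1, q_IPA, P2, P3, q_DA, P4, P5)``.

Units are fixed throughout: pressure mmHg, flow mL/s, time s, velocity cm/s,
resistance mmHg*s/mL, inertance mmHg*s^2/mL, compliance mL/mmHg, area cm^2.

Nominal element values scale allometrically with estimated fetal weight,
``X = X_ref * (EFW / 3000 g)**alpha`` (alpha = -1 for resistances and
inertances, +1 for compliances, +2/3 for cross-sectional areas).  The
reference constants are calibrated so that a term fetus at resting input flow
runs a mean main-pulmonary-artery pressure of ~45 mmHg with ~20% of
right-ventricular output perfusing the lungs, the accepted prenatal
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .doppler import Waveform

REFERENCE_EFW_G = 3000.0

#: Reference element values at EFW = 3 kg (see module docstring).
DEFAULT_REFERENCE_VALUES: dict = {
    "r_mpa": 0.10, "l_mpa": 0.005, "c_mpa": 0.020,
    "r_ipa": 0.30, "l_ipa": 0.007, "c_ipa": 0.005,
    "r_da": 0.25, "l_da": 0.007, "c_da": 0.010,
    "k_da": 0.0,
    "rc_p": 1.5, "rp_p": 15.5, "cp_p": 0.016,
    "rc_s": 0.40, "rp_s": 3.6, "cp_s": 0.10,
    "a_da": 0.22, "a_ipa": 0.11,
}

DEFAULT_EXPONENTS: dict = {"r": -1.0, "l": -1.0, "c": 1.0, "a": 2.0 / 3.0}


class CircuitError(ValueError):
    """Invalid circuit parameters or simulation inputs."""


@dataclass(frozen=True)
class CircuitParameters:
    """All element values of the circuit (units as in the module docstring)."""

    r_mpa: float
    l_mpa: float
    c_mpa: float
    r_ipa: float
    l_ipa: float
    c_ipa: float
    r_da: float
    l_da: float
    c_da: float
    k_da: float
    rc_p: float
    rp_p: float
    cp_p: float
    rc_s: float
    rp_s: float
    cp_s: float
    a_da: float
    a_ipa: float

    def __post_init__(self) -> None:
        for name in (
            "r_mpa", "l_mpa", "c_mpa", "r_ipa", "l_ipa", "c_ipa",
            "r_da", "l_da", "c_da", "rc_p", "rp_p", "cp_p",
            "rc_s", "rp_s", "cp_s", "a_da", "a_ipa",
        ):
            if not (getattr(self, name) > 0):
                raise CircuitError(f"parameter {name} must be > 0, got {getattr(self, name)}")
        if self.k_da < 0:
            raise CircuitError(f"k_da must be >= 0, got {self.k_da}")

    @property
    def r_pulm(self) -> float:
        """Total pulmonary bed resistance Rc_p + Rp_p."""
        return self.rc_p + self.rp_p

    @property
    def r_sys(self) -> float:
        """Total systemic bed resistance Rc_s + Rp_s."""
        return self.rc_s + self.rp_s

    def with_factors(
        self,
        f_rpulm: float = 1.0,
        f_rsys: float = 1.0,
        f_cpulm: float = 1.0,
        f_csys: float = 1.0,
    ) -> "CircuitParameters":
        """Scale bed elements by multiplicative factors.

        A resistance factor scales Rc and Rp of that bed jointly, preserving
        their nominal ratio; a compliance factor scales Cp.
        """
        return replace(
            self,
            rc_p=self.rc_p * f_rpulm, rp_p=self.rp_p * f_rpulm,
            rc_s=self.rc_s * f_rsys, rp_s=self.rp_s * f_rsys,
            cp_p=self.cp_p * f_cpulm, cp_s=self.cp_s * f_csys,
        )


def nominal_parameters(
    ga_weeks: float,
    efw_g: float,
    reference: dict | None = None,
    exponents: dict | None = None,
) -> CircuitParameters:
    """Nominal circuit parameters for a fetus of given gestational age/weight.

    Allometric power laws in EFW (see module docstring); gestational age is
    validated against the viable range but the laws are weight-driven, GA and
    EFW being strongly collinear prenatally.
    """
    if not (20.0 <= ga_weeks <= 42.0):
        raise CircuitError(f"ga_weeks {ga_weeks} outside supported range [20, 42]")
    if not (efw_g > 0):
        raise CircuitError(f"efw_g must be positive, got {efw_g}")
    ref = dict(DEFAULT_REFERENCE_VALUES)
    if reference:
        ref.update(reference)
    exp = dict(DEFAULT_EXPONENTS)
    if exponents:
        exp.update(exponents)
    w = efw_g / REFERENCE_EFW_G
    scaled = {}
    for name, x in ref.items():
        if name == "k_da":
            scaled[name] = x * w ** exp["r"] if x else 0.0
            continue
        kind = "a" if name.startswith("a_") else name[0]
        scaled[name] = x * w ** exp[kind]
    return CircuitParameters(**scaled)


def flow_from_velocity(v: Waveform, d_valve_mm: float) -> np.ndarray:
    """Convert an MPA velocity envelope to volumetric input flow (mL/s).

    ``Q(t) = V(t) * pi * (D/2)^2`` with the pulmonary valve diameter ``D``
    converted from mm to cm.
    """
    if not (d_valve_mm > 0):
        raise CircuitError(f"valve diameter must be positive, got {d_valve_mm}")
    area_cm2 = math.pi * (0.1 * d_valve_mm / 2.0) ** 2
    return v.cycle_velocity() * area_cm2


def dc_solve(p: CircuitParameters, q_const: float) -> dict:
    """Steady-state (DC) network solution for a constant input flow.

    Inductors are shorts and capacitors open; the flow split between the
    pulmonary branch (q_ipa) and the ductus branch (q_da) balances the branch
    pressure drops, including the quadratic ductus term when ``k_da > 0``
    (scalar quadratic, solved in closed form).  Kirchhoff's current law holds
    exactly at every node.
    """
    if q_const < 0:
        raise CircuitError("q_const must be >= 0")
    r1 = p.r_ipa + p.rc_p + p.rp_p          # pulmonary branch series R
    r2 = p.r_da + p.rc_s + p.rp_s           # systemic branch series R
    # q_da solves k*q^2 + (r1 + r2)*q - r1*Q = 0  (q_da >= 0 root)
    if p.k_da > 0:
        a, b, c = p.k_da, r1 + r2, -r1 * q_const
        q_da = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    else:
        q_da = q_const * r1 / (r1 + r2)
    q_ipa = q_const - q_da
    p1 = q_ipa * r1
    pressures = {
        "P0": p1 + q_const * p.r_mpa,
        "P1": p1,
        "P2": p1 - q_ipa * p.r_ipa,
        "P3": q_ipa * p.rp_p,
        "P4": q_da * (p.rc_s + p.rp_s),
        "P5": q_da * p.rp_s,
    }
    flows = {"q_in": q_const, "q_ipa": q_ipa, "q_da": q_da}
    return {"pressures": pressures, "flows": flows}


def windkessel_impedance(rc: float, rp: float, cp: float, freq_hz) -> np.ndarray:
    """Analytic input impedance ``Z(w) = Rc + Rp / (1 + i*w*Rp*Cp)``."""
    w = 2.0 * math.pi * np.asarray(freq_hz, dtype=float)
    return rc + rp / (1.0 + 1j * w * rp * cp)


@dataclass
class SimulationResult:
    """Periodic-steady-state traces over one cycle plus convergence info."""

    t: np.ndarray
    pressures: dict
    flows: dict
    v_da_cm_s: np.ndarray
    v_ipa_cm_s: np.ndarray
    cycle_s: float
    cycles_run: int
    periodic: bool
    residual: float

    def mean_pressure(self, node: str = "P1") -> float:
        return float(self.pressures[node].mean())

    def to_frame(self):
        """One-cycle traces as a DataFrame (t_s, pressures, flows,
        velocities); write with ``.to_csv(path, index=False)``."""
        import pandas as pd

        data = {"t_s": self.t}
        data.update({f"p_{k.lower()}_mmhg": v for k, v in self.pressures.items()})
        data.update({f"{k}_ml_s": v for k, v in self.flows.items()})
        data["v_da_cm_s"] = self.v_da_cm_s
        data["v_ipa_cm_s"] = self.v_ipa_cm_s
        return pd.DataFrame(data)


def _resolve_qin(q_in, cycle_s, n_steps: int):
    """Input flow samples on the RK4 full/half-step grid (periodic interp)."""
    if isinstance(q_in, Waveform):
        raise CircuitError("pass flow in mL/s (use flow_from_velocity), not a velocity Waveform")
    q = np.asarray(q_in, dtype=float)
    if q.ndim != 1 or q.size < 2:
        raise CircuitError("q_in must be a 1-D sample array over one cycle")
    if not np.all(np.isfinite(q)):
        raise CircuitError("q_in contains non-finite values")
    t_native = np.arange(q.size) * (cycle_s / q.size)
    t_half = np.arange(2 * n_steps + 1) * (cycle_s / (2 * n_steps))
    return np.interp(t_half, t_native, q, period=cycle_s)


def _rhs(y: np.ndarray, qin: float, p: CircuitParameters) -> np.ndarray:
    p1, qi, p2, p3, qd, p4, p5 = y
    dp_da = p.r_da * qd + p.k_da * qd * abs(qd)
    return np.array([
        (qin - qi - qd) / p.c_mpa,
        (p1 - p2 - p.r_ipa * qi) / p.l_ipa,
        (qi - (p2 - p3) / p.rc_p) / p.c_ipa,
        ((p2 - p3) / p.rc_p - p3 / p.rp_p) / p.cp_p,
        (p1 - p4 - dp_da) / p.l_da,
        (qd - (p4 - p5) / p.rc_s) / p.c_da,
        ((p4 - p5) / p.rc_s - p5 / p.rp_s) / p.cp_s,
    ])


def simulate(
    p: CircuitParameters,
    q_in,
    cycle_s: float,
    *,
    max_cycles: int = 50,
    min_cycles: int = 5,
    periodicity_tol: float = 1e-4,
    dt: float = 2e-4,
    n_out: int = 200,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the circuit ODEs cycle by cycle to periodic steady state.

    Classical RK4 with fixed step ``dt`` (input flow pre-sampled on the
    half-step grid); after each cycle the relative L2 change of the state
    vector at the cycle boundary is compared against ``periodicity_tol``.
    Returns the last simulated cycle resampled to ``n_out`` points.  On
    non-convergence the result is returned with ``periodic=False`` and the
    achieved residual for diagnosis.
    """
    if not (cycle_s > 0):
        raise CircuitError("cycle_s must be positive")
    n_steps = max(int(math.ceil(cycle_s / dt)), 16)
    qin_grid = _resolve_qin(q_in, cycle_s, n_steps)
    h = cycle_s / n_steps

    if y0 is None:
        # Start from the DC solution of the mean flow: cuts transients roughly in half.
        dc = dc_solve(p, float(max(np.mean(qin_grid[:-1:2]), 0.0)))
        y = np.array([
            dc["pressures"]["P1"], dc["flows"]["q_ipa"], dc["pressures"]["P2"],
            dc["pressures"]["P3"], dc["flows"]["q_da"], dc["pressures"]["P4"],
            dc["pressures"]["P5"],
        ])
    else:
        y = np.asarray(y0, dtype=float).copy()
        if y.shape != (7,):
            raise CircuitError("y0 must have shape (7,): (P1, q_IPA, P2, P3, q_DA, P4, P5)")

    periodic = False
    residual = math.inf
    cycles = 0
    keep = None
    for cycle in range(max_cycles):
        y_start = y.copy()
        states = np.empty((n_steps + 1, 7))
        states[0] = y
        for i in range(n_steps):
            q0, qh, q1 = qin_grid[2 * i], qin_grid[2 * i + 1], qin_grid[2 * i + 2]
            k1 = _rhs(y, q0, p)
            k2 = _rhs(y + 0.5 * h * k1, qh, p)
            k3 = _rhs(y + 0.5 * h * k2, qh, p)
            k4 = _rhs(y + h * k3, q1, p)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            states[i + 1] = y
        cycles = cycle + 1
        keep = states
        scale = np.linalg.norm(y) + 1e-12
        residual = float(np.linalg.norm(y - y_start) / scale)
        if cycles >= min_cycles and residual < periodicity_tol:
            periodic = True
            break

    t_fine = np.arange(n_steps + 1) * h
    t = np.arange(n_out) * (cycle_s / n_out)
    cols = [np.interp(t, t_fine, keep[:, j]) for j in range(7)]
    p1, qi, p2, p3, qd, p4, p5 = cols
    qin_t = np.interp(t, np.arange(2 * n_steps + 1) * (h / 2), qin_grid)
    pressures = {
        "P0": p1 + p.r_mpa * qin_t,  # inductor term omitted in the report node
        "P1": p1, "P2": p2, "P3": p3, "P4": p4, "P5": p5,
    }
    flows = {
        "q_in": qin_t, "q_ipa": qi, "q_da": qd,
        "q_bed_p": (p2 - p3) / p.rc_p, "q_bed_s": (p4 - p5) / p.rc_s,
        "q_out_p": p3 / p.rp_p, "q_out_s": p5 / p.rp_s,
    }
    return SimulationResult(
        t=t, pressures=pressures, flows=flows,
        v_da_cm_s=qd / p.a_da, v_ipa_cm_s=qi / p.a_ipa,
        cycle_s=cycle_s, cycles_run=cycles, periodic=periodic, residual=residual,
    )


def harmonic_steady_state(p: CircuitParameters, q_in, cycle_s: float) -> SimulationResult:
    """Exact periodic steady state of the linearised circuit (k_da = 0).

    Solves the ladder network harmonic-by-harmonic from the rFFT of the input
    flow.  This is the fast path used inside personalisation; it is exact for
    the linear circuit and is cross-checked against :func:`simulate` in the
    test suite.
    """
    if p.k_da != 0:
        raise CircuitError("harmonic solution requires a linear ductus (k_da = 0)")
    q = np.asarray(q_in, dtype=float)
    if q.ndim != 1 or q.size < 8:
        raise CircuitError("q_in must be a 1-D sample array over one cycle")
    m = q.size
    qk = np.fft.rfft(q)
    w = 2.0 * math.pi * np.arange(qk.size) / cycle_s
    jw = 1j * w

    z_wk_p = p.rc_p + p.rp_p / (1.0 + jw * p.rp_p * p.cp_p)
    z_wk_s = p.rc_s + p.rp_s / (1.0 + jw * p.rp_s * p.cp_s)
    z_b1 = (p.r_ipa + jw * p.l_ipa) + 1.0 / (jw * p.c_ipa + 1.0 / z_wk_p)
    z_b2 = (p.r_da + jw * p.l_da) + 1.0 / (jw * p.c_da + 1.0 / z_wk_s)
    y1 = jw * p.c_mpa + 1.0 / z_b1 + 1.0 / z_b2
    p1k = qk / y1
    qik = p1k / z_b1
    qdk = p1k / z_b2
    p2k = p1k - qik * (p.r_ipa + jw * p.l_ipa)
    p4k = p1k - qdk * (p.r_da + jw * p.l_da)
    qb1k = p2k / z_wk_p
    qb2k = p4k / z_wk_s
    p3k = p2k - qb1k * p.rc_p
    p5k = p4k - qb2k * p.rc_s

    def back(x):
        return np.fft.irfft(x, n=m)

    p1, p2, p3, p4, p5 = (back(x) for x in (p1k, p2k, p3k, p4k, p5k))
    qi, qd, qb1, qb2 = (back(x) for x in (qik, qdk, qb1k, qb2k))
    t = np.arange(m) * (cycle_s / m)
    pressures = {"P0": p1 + p.r_mpa * q, "P1": p1, "P2": p2, "P3": p3, "P4": p4, "P5": p5}
    flows = {
        "q_in": q, "q_ipa": qi, "q_da": qd,
        "q_bed_p": qb1, "q_bed_s": qb2,
        "q_out_p": p3 / p.rp_p, "q_out_s": p5 / p.rp_s,
    }
    return SimulationResult(
        t=t, pressures=pressures, flows=flows,
        v_da_cm_s=qd / p.a_da, v_ipa_cm_s=qi / p.a_ipa,
        cycle_s=cycle_s, cycles_run=0, periodic=True, residual=0.0,
    )


def simulate_windkessel(
    rc: float, rp: float, cp: float, q_in, cycle_s: float,
    *, max_cycles: int = 400, periodicity_tol: float = 1e-10, dt: float = 1e-4,
):
    """Time-domain periodic solution of an isolated three-element Windkessel.

    Single-state ODE ``Cp*dPw/dt = q - Pw/Rp`` with input pressure
    ``P = Pw + Rc*q``; integrated cycle by cycle (RK4) until periodic.
    Returns ``(t, P)`` over one cycle.  Used as the time-domain side of the
    frequency-response check against :func:`windkessel_impedance`.
    """
    q = np.asarray(q_in, dtype=float)
    n_steps = max(int(math.ceil(cycle_s / dt)), 32)
    t_half = np.arange(2 * n_steps + 1) * (cycle_s / (2 * n_steps))
    t_native = np.arange(q.size) * (cycle_s / q.size)
    qg = np.interp(t_half, t_native, q, period=cycle_s)
    h = cycle_s / n_steps

    def f(pw, qv):
        return (qv - pw / rp) / cp

    pw = float(np.mean(q)) * rp
    trace = None
    for _ in range(max_cycles):
        start = pw
        tr = np.empty(n_steps + 1)
        tr[0] = pw
        for i in range(n_steps):
            q0, qh, q1 = qg[2 * i], qg[2 * i + 1], qg[2 * i + 2]
            k1 = f(pw, q0)
            k2 = f(pw + 0.5 * h * k1, qh)
            k3 = f(pw + 0.5 * h * k2, qh)
            k4 = f(pw + h * k3, q1)
            pw = pw + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            tr[i + 1] = pw
        trace = tr
        if abs(pw - start) < periodicity_tol * (abs(pw) + 1e-12):
            break
    t = np.arange(n_steps + 1) * h
    p_in = trace + rc * qg[::2]
    return t, p_in
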