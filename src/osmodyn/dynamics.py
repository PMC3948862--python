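"""Governing pressure ODE, its integration, event detection and derived quantities.

The model couples the osmotic water flux across the membrane with the
compartment's capacity to absorb that water, either by expanding
(dV/dP) or by compressing the fluid (V/K):

    dP/dt = rho_solvent * A * L_p0 * (1 - f(c)) * (sigma * dPi(c) - P)
            -------------------------------------------------------
                     rho_atm * (dV/dP + V(P) / K(c, P))

with c = n / V(P) (constant solute amount, diluted by expansion) and
dPi = Pi_inside(c) - Pi_external.  Pressurization, depressurization
(the osmotic gradient collapsed to zero, as in stimulated plant motor
cells) and open-outlet volume delivery are the three scenario modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .submodels import (
    ConfigurationError,
    DomainError,
    IntegrationError,
    Membrane,
    VolumeLaw,
    WorkingFluid,
    bulk_modulus,
    concentration,
    effective_lp,
    fouling_factor,
    osmotic_pressure,
    volume_and_derivative,
)

MODES = ("pressurize", "depressurize", "deliver")

#: Minimum number of evenly spaced report points in a trajectory; keeps the
#: trapezoidal energy quadrature and CSV output well resolved.
MIN_REPORT_POINTS = 200


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive RK45 tolerances.  The ODE is non-stiff at all shipped
    parameterizations, so no stiffness switching is provided."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-4  # Pa; keeps low-pressure transients (P ~ 1 Pa) accurate
    max_step: float = math.inf  # s
    seed: int | None = None  # fixtures only; the integrator itself is deterministic


@dataclass(frozen=True)
class Scenario:
    """A complete, runnable parameterization of the pressure generator."""

    fluid: WorkingFluid
    membrane: Membrane
    volume_law: VolumeLaw
    mode: str = "pressurize"
    p_initial: float = 0.0  # Pa gauge
    external_osmotic_pressure: float = 0.0  # Pa
    t_end: float = 3600.0  # s
    solver: SolverSettings = field(default_factory=SolverSettings)
    events: tuple[float, ...] = ()  # pressure-gain thresholds, Pa
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; expected {MODES}")
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be positive")
        if self.volume_law.variant == "plant_exp_log" and self.p_initial <= 0:
            raise ConfigurationError(
                "p_initial must be positive with the plant_exp_log volume law"
            )
        if self.events:
            gains = list(self.events)
            if any(g <= 0 for g in gains) or any(
                b <= a for a, b in zip(gains, gains[1:])
            ):
                raise ConfigurationError(
                    "event thresholds must be strictly positive and increasing"
                )

    # -- convenience accessors -------------------------------------------------

    def initial_volume(self) -> float:
        p0 = self.p_initial if self.mode != "deliver" else self._deliver_pressure()
        return volume_and_derivative(p0, self.volume_law)[0]

    def initial_concentration(self) -> float:
        return concentration(self.fluid.moles_solute, self.initial_volume())

    def rho_atm(self) -> float:
        """Working-fluid density at atmosphere, evaluated at the initial
        concentration (fixed over a run)."""
        return self.fluid.rho_atm(self.initial_concentration())

    def _deliver_pressure(self) -> float:
        # Open outlet: gauge pressure pinned at ~0; the plant law cannot be
        # evaluated at exactly 0, so use its p_initial as the reference.
        if self.volume_law.variant == "plant_exp_log":
            return self.p_initial
        return 0.0


@dataclass(frozen=True)
class EventResult:
    """Crossing time of one pressure-gain threshold (gain over p_initial)."""

    threshold: float  # Pa
    time: float | None  # s; None => not reached before t_end

    @property
    def reached(self) -> bool:
        return self.time is not None


@dataclass
class TimeSeries:
    """Aligned trajectories of every model quantity on the report grid.

    ``stored_energy`` is the cumulative pressure-volume work int P dV
    (trapezoidal) up to each report time; ``delivered_volume`` is non-zero
    only in deliver mode.
    """

    t: np.ndarray  # s
    p_in: np.ndarray  # Pa
    v_in: np.ndarray  # m^3
    c: np.ndarray  # mol m^-3
    delta_pi: np.ndarray  # Pa
    f: np.ndarray  # dimensionless
    lp_eff: np.ndarray  # m Pa^-1 s^-1
    influx_rate: np.ndarray  # m^3 s^-1
    delivered_volume: np.ndarray  # m^3
    stored_energy: np.ndarray  # J
    scenario: Scenario | None = None
    dense: Callable[[float], float] | None = None  # t -> P (or delivered vol)

    def to_frame(self):
        """Trajectory as a pandas DataFrame with the canonical CSV columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.t,
                "pressure_Pa": self.p_in,
                "volume_m3": self.v_in,
                "conc_mol_m3": self.c,
                "delta_pi_Pa": self.delta_pi,
                "fouling": self.f,
                "lp_eff": self.lp_eff,
                "influx_m3_s": self.influx_rate,
                "delivered_m3": self.delivered_volume,
                "energy_J": self.stored_energy,
            }
        )


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def governing_rhs(p: float, scenario: Scenario, *, force_zero_dpi: bool = False) -> float:
    """dP/dt (Pa s^-1) of the governing equation at gauge pressure ``p``.

    ``force_zero_dpi`` implements the depressurization protocol in which
    the osmotic gradient is instantaneously collapsed (dPi = 0 for all t)
    while the compartment drains against its own pressure.
    """
    fluid, mem = scenario.fluid, scenario.membrane
    v, dvdp = volume_and_derivative(p, scenario.volume_law)
    c = concentration(fluid.moles_solute, v)
    if force_zero_dpi or scenario.mode == "depressurize":
        dpi = 0.0
    else:
        dpi = osmotic_pressure(c, fluid.osmotic_law) - scenario.external_osmotic_pressure
    f = fouling_factor(c, fluid.fouling_law)
    lp = effective_lp(mem.lp0, f)
    k = bulk_modulus(c, p, fluid.bulk_law)
    numerator = fluid.rho_solvent * mem.area * lp * (mem.sigma * dpi - p)
    denominator = scenario.rho_atm() * (dvdp + v / k)
    return numerator / denominator


def _rhs_factory(scenario: Scenario) -> Callable[[float, np.ndarray], list[float]]:
    """Closure over scenario constants for the integrator (avoids re-deriving
    rho_atm and law lookups on every evaluation)."""
    fluid, mem = scenario.fluid, scenario.membrane
    vol_law = scenario.volume_law
    n = fluid.moles_solute
    rho_ratio_num = fluid.rho_solvent * mem.area
    rho_atm = scenario.rho_atm()
    zero_dpi = scenario.mode == "depressurize"
    pi_ext = scenario.external_osmotic_pressure

    def rhs(t: float, y: np.ndarray) -> list[float]:
        p = float(y[0])
        v, dvdp = volume_and_derivative(p, vol_law)
        c = n / v
        dpi = 0.0 if zero_dpi else osmotic_pressure(c, fluid.osmotic_law) - pi_ext
        lp = mem.lp0 * (1.0 - fouling_factor(c, fluid.fouling_law))
        k = bulk_modulus(c, p, fluid.bulk_law)
        return [rho_ratio_num * lp * (mem.sigma * dpi - p) / (rho_atm * (dvdp + v / k))]

    return rhs


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(scenario: Scenario, report_points: int = 512) -> TimeSeries:
    """Integrate the governing ODE and return the full trajectory.

    Uses adaptive explicit Runge-Kutta (RK45) with dense output; the
    trajectory is reported on ``report_points`` evenly spaced times
    (at least 200).  Solute moles are constant in pressurize/depressurize
    modes; concentration is recomputed from V(P) at every report point.
    """
    if scenario.mode == "deliver":
        return simulate_volume_delivery(scenario, report_points)
    report_points = max(int(report_points), MIN_REPORT_POINTS)
    s = scenario.solver
    sol = solve_ivp(
        _rhs_factory(scenario),
        (0.0, scenario.t_end),
        [scenario.p_initial],
        method="RK45",
        rtol=s.rel_tol,
        atol=s.abs_tol,
        max_step=s.max_step,
        dense_output=True,
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        raise IntegrationError(
            f"integration failed at t = {t_fail:.6g} s: {sol.message}"
        )
    t = np.linspace(0.0, scenario.t_end, report_points)
    p = sol.sol(t)[0]
    if not np.all(np.isfinite(p)):
        bad = t[~np.isfinite(p)][0]
        raise IntegrationError(f"non-finite pressure at t = {bad:.6g} s")
    ts = _bookkeep(scenario, t, p)
    ts.dense = lambda tt: float(sol.sol(tt)[0])
    return ts


def _bookkeep(scenario: Scenario, t: np.ndarray, p: np.ndarray) -> TimeSeries:
    """Derive all reported quantities from the pressure trajectory."""
    fluid, mem = scenario.fluid, scenario.membrane
    npts = len(t)
    v = np.empty(npts)
    for i, pi_ in enumerate(p):
        v[i] = volume_and_derivative(float(pi_), scenario.volume_law)[0]
    c = fluid.moles_solute / v
    if scenario.mode == "depressurize":
        # Solute tracking is disabled: the gradient is collapsed for all t.
        c = np.full(npts, scenario.initial_concentration())
        dpi = np.zeros(npts)
    else:
        dpi = np.array(
            [osmotic_pressure(float(ci), fluid.osmotic_law) for ci in c]
        ) - scenario.external_osmotic_pressure
    f = np.array([fouling_factor(float(ci), fluid.fouling_law) for ci in c])
    lp = mem.lp0 * (1.0 - f)
    influx = mem.area * lp * (mem.sigma * dpi - p)
    energy = np.concatenate(
        [[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(v))]
    )
    return TimeSeries(
        t=t,
        p_in=p,
        v_in=v,
        c=c,
        delta_pi=dpi,
        f=f,
        lp_eff=lp,
        influx_rate=influx,
        delivered_volume=np.zeros(npts),
        stored_energy=energy,
        scenario=scenario,
    )


def simulate_depressurization(scenario: Scenario, report_points: int = 512) -> TimeSeries:
    """Integrate the stimulated-release protocol (dPi forced to 0 for all t).

    The scenario must be in ``depressurize`` mode with a positive initial
    pressure; the trajectory decays monotonically toward zero gauge.
    """
    if scenario.mode != "depressurize":
        raise ConfigurationError(
            f"simulate_depressurization requires mode='depressurize', "
            f"got {scenario.mode!r}"
        )
    if scenario.p_initial <= 0:
        raise ConfigurationError("depressurization requires p_initial > 0")
    return simulate(scenario, report_points)


def simulate_volume_delivery(
    scenario: Scenario, report_points: int = 512, solute_washout: bool = True
) -> TimeSeries:
    """Open-outlet pumping: the compartment stays at ~0 gauge and pushes
    fluid out at the osmotic influx rate.

    The compartment volume is pinned at V(0+); the solute washes out with
    the displaced working fluid (n' = -c * Q), so the delivered-volume
    curve is concave: flow decays as the osmotic driver dilutes away.
    ``solute_washout=False`` models a hypothetical non-dilutable solute
    (n held constant), giving constant-rate delivery.
    State: y = [delivered volume, moles of solute].
    """
    if scenario.mode != "deliver":
        raise ConfigurationError(
            f"simulate_volume_delivery requires mode='deliver', got {scenario.mode!r}"
        )
    report_points = max(int(report_points), MIN_REPORT_POINTS)
    fluid, mem = scenario.fluid, scenario.membrane
    p_ref = scenario._deliver_pressure()
    v_fix = volume_and_derivative(p_ref, scenario.volume_law)[0]

    def rhs(t: float, y: np.ndarray) -> list[float]:
        n = max(float(y[1]), 0.0)
        c = n / v_fix
        dpi = osmotic_pressure(c, fluid.osmotic_law) - scenario.external_osmotic_pressure
        lp = mem.lp0 * (1.0 - fouling_factor(c, fluid.fouling_law))
        q = max(mem.area * lp * mem.sigma * dpi, 0.0)
        return [q, -c * q if solute_washout else 0.0]

    s = scenario.solver
    sol = solve_ivp(
        rhs,
        (0.0, scenario.t_end),
        [0.0, fluid.moles_solute],
        method="RK45",
        rtol=s.rel_tol,
        atol=min(s.abs_tol, 1e-12),  # state is ~1e-6 m^3 and ~1e-4 mol
        max_step=s.max_step,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"delivery integration failed at t = {sol.t[-1]:.6g} s: {sol.message}"
        )
    t = np.linspace(0.0, scenario.t_end, report_points)
    delivered, n_t = sol.sol(t)
    n_t = np.clip(n_t, 0.0, None)
    c = n_t / v_fix
    dpi = np.array(
        [osmotic_pressure(float(ci), fluid.osmotic_law) for ci in c]
    ) - scenario.external_osmotic_pressure
    f = np.array([fouling_factor(float(ci), fluid.fouling_law) for ci in c])
    lp = mem.lp0 * (1.0 - f)
    q = np.clip(mem.area * lp * mem.sigma * dpi, 0.0, None)
    ts = TimeSeries(
        t=t,
        p_in=np.zeros_like(t),
        v_in=np.full_like(t, v_fix),
        c=c,
        delta_pi=dpi,
        f=f,
        lp_eff=lp,
        influx_rate=q,
        delivered_volume=delivered,
        stored_energy=np.zeros_like(t),
        scenario=scenario,
    )
    ts.dense = lambda tt: float(sol.sol(tt)[0])
    return ts


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def time_to_pressure_gain(
    scenario: Scenario,
    gains: Sequence[float] | None = None,
    ts: TimeSeries | None = None,
) -> list[EventResult]:
    """First times at which P(t) reaches p_initial + gain, for each gain.

    Crossings are located on the integrator's dense output by bracketed
    bisection (Brent), so the result does not depend on step placement.
    Gains not reached before ``t_end`` are reported with ``time=None``.
    """
    if gains is None:
        gains = scenario.events
    gains = list(gains)
    if not gains:
        return []
    if any(g <= 0 for g in gains) or any(b <= a for a, b in zip(gains, gains[1:])):
        raise ConfigurationError("gains must be strictly positive and increasing")
    if ts is None:
        ts = simulate(scenario)
    assert ts.dense is not None
    dense = ts.dense
    results: list[EventResult] = []
    for gain in gains:
        target = scenario.p_initial + gain
        # locate a bracketing report interval first
        above = ts.p_in >= target
        if not above.any():
            results.append(EventResult(gain, None))
            continue
        i = int(np.argmax(above))
        if i == 0:
            results.append(EventResult(gain, 0.0))
            continue
        lo, hi = ts.t[i - 1], ts.t[i]
        t_cross = brentq(
            lambda tt: dense(tt) - target, lo, hi, xtol=1e-12, rtol=1e-12
        )
        results.append(EventResult(gain, float(t_cross)))
    return results


def stored_energy(ts: TimeSeries) -> float:
    """Total pressure-volume work int P dV along the trajectory, in J."""
    if len(ts.t) < 2:
        raise DomainError("trajectory needs at least 2 points")
    return float(np.trapezoid(ts.p_in, ts.v_in))


def equilibrium_pressure(scenario: Scenario) -> float:
    """Gauge pressure at which the osmotic driving force is balanced:
    Pi(n / V(p)) - Pi_external = p.

    Solved by bracketed root-finding; the simulated trajectory approaches
    this value from below in pressurize mode.  Raises ``DomainError`` if no
    finite balance point exists below 1 GPa.
    """
    if scenario.mode != "pressurize":
        raise ConfigurationError("equilibrium_pressure applies to pressurize mode")
    fluid = scenario.fluid

    def g(p: float) -> float:
        v = volume_and_derivative(p, scenario.volume_law)[0]
        c = concentration(fluid.moles_solute, v)
        return (
            osmotic_pressure(c, fluid.osmotic_law)
            - scenario.external_osmotic_pressure
            - p
        )

    p_lo = scenario.p_initial if scenario.volume_law.variant == "plant_exp_log" else 1e-9
    g_lo = g(p_lo)
    if g_lo <= 0:
        return float(p_lo)  # already at/above balance
    p_hi = max(2 * p_lo, 1e3)
    while g(p_hi) > 0:
        p_hi *= 2.0
        if p_hi > 1e9:
            raise DomainError("no equilibrium pressure found below 1 GPa")
    return float(brentq(g, p_lo, p_hi, xtol=1e-9, rtol=1e-12))


def mass_conservation_error(scenario: Scenario) -> float:
    """Relative mismatch between the compartment fluid mass inferred from
    state, m = rho_atm * (1 + P/K) * V(P), and the time-integrated membrane
    mass influx rho_solvent * A * L_p * (sigma*dPi - P).

    The two agree exactly only in the K >> P limit under which the
    governing equation is derived, so this quantifies the model's internal
    consistency.  Returned as |mismatch| / max |mass change| at t_end.
    """
    if scenario.mode == "deliver":
        raise ConfigurationError("mass_conservation_error applies to closed modes")
    fluid, mem = scenario.fluid, scenario.membrane
    rho_atm = scenario.rho_atm()
    base = _rhs_factory(scenario)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        p = float(y[0])
        v, _ = volume_and_derivative(p, scenario.volume_law)
        c = fluid.moles_solute / v
        dpi = (
            0.0
            if scenario.mode == "depressurize"
            else osmotic_pressure(c, fluid.osmotic_law)
            - scenario.external_osmotic_pressure
        )
        lp = mem.lp0 * (1.0 - fouling_factor(c, fluid.fouling_law))
        influx_mass = fluid.rho_solvent * mem.area * lp * (mem.sigma * dpi - p)
        return [base(t, y[:1])[0], influx_mass]

    s = scenario.solver
    sol = solve_ivp(
        rhs,
        (0.0, scenario.t_end),
        [scenario.p_initial, 0.0],
        method="RK45",
        rtol=min(s.rel_tol, 1e-10),
        atol=[s.abs_tol, 1e-18],
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"mass-balance integration failed: {sol.message}")

    def state_mass(p: float) -> float:
        v, _ = volume_and_derivative(p, scenario.volume_law)
        c = fluid.moles_solute / v
        k = bulk_modulus(c, p, fluid.bulk_law)
        return rho_atm * (1.0 + p / k) * v

    m0 = state_mass(scenario.p_initial)
    dm_state = np.array([state_mass(float(p)) - m0 for p in sol.y[0]])
    dm_flux = sol.y[1]
    scale = max(np.max(np.abs(dm_state)), np.max(np.abs(dm_flux)), 1e-300)
    return float(np.max(np.abs(dm_state - dm_flux)) / scale)


def with_area(scenario: Scenario, area: float) -> Scenario:
    """Copy of ``scenario`` with the membrane area replaced (fitting helper)."""
    return replace(scenario, membrane=replace(scenario.membrane, area=area))


__all__ = [
    "MODES",
    "SolverSettings",
    "Scenario",
    "EventResult",
    "TimeSeries",
    "governing_rhs",
    "simulate",
    "simulate_depressurization",
    "simulate_volume_delivery",
    "time_to_pressure_gain",
    "stored_energy",
    "equilibrium_pressure",
    "mass_conservation_error",
    "with_area",
]
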