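"""Reduction of bench measurements to model parameters.

Four calibrations feed the governing equation: the osmotic pressure curve
Pi(c) (freezing-point osmometry pairs -> zero-intercept cubic), the
fouling curve f(c) (effective-permeability pairs -> Hill equation), the
clean-membrane permeability L_p0 (constant-pressure pumping run), and the
fluid bulk modulus (pressure-wave speed).  The fifth operation fits the
one genuinely uncertain geometric parameter — the effective membrane
area A — to an experimental pressure trace by minimizing the residual
sum of squares against the simulated curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit, minimize_scalar

from .dynamics import Scenario, simulate, with_area
from .submodels import (
    DataError,
    DomainError,
    FitError,
    FoulingLaw,
    OsmoticLaw,
)

#: Default membrane-area search interval, m^2.  Spans 5-100 cm^2, i.e. all
#: areas recovered for the dialysis-cassette experiments with margin.
DEFAULT_AREA_BOUNDS = (5e-4, 100e-4)


@dataclass
class PressureTrace:
    """An experimental (or synthetic) pressure-vs-time record."""

    t: np.ndarray  # s
    p: np.ndarray  # Pa gauge
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.p.shape:
            raise DataError("trace t and p must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise DataError("trace needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("trace times must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.p))):
            raise DataError("trace contains non-finite values")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "PressureTrace":
        df = pd.read_csv(path, comment="#")
        missing = {"time_s", "pressure_Pa"} - set(df.columns)
        if missing:
            raise DataError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["pressure_Pa"].to_numpy(), label=label)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "pressure_Pa": self.p}).to_csv(
            path, index=False, float_format="%.9e"
        )


@dataclass
class PumpingRun:
    """A constant-pressure pumping experiment: water driven out of the
    compartment through a thin tube whose meniscus is tracked over time."""

    tube_radius: float  # m
    applied_dp: float  # Pa
    meniscus_t: np.ndarray  # s
    meniscus_x: np.ndarray  # m, position along the tube
    membrane_area: float  # m^2

    def __post_init__(self) -> None:
        self.meniscus_t = np.asarray(self.meniscus_t, dtype=float)
        self.meniscus_x = np.asarray(self.meniscus_x, dtype=float)
        if self.tube_radius <= 0 or self.membrane_area <= 0:
            raise DataError("tube radius and membrane area must be positive")
        if self.applied_dp <= 0:
            raise DataError("applied pressure difference must be positive")
        if len(self.meniscus_t) < 2:
            raise DataError("pumping run needs at least 2 meniscus samples")
        if np.any(np.diff(self.meniscus_t) <= 0):
            raise DataError("meniscus times must be strictly increasing")


@dataclass(frozen=True)
class AreaFitResult:
    """Outcome of the membrane-area fit."""

    area: float  # m^2
    rss: float  # Pa^2
    n_points: int
    converged: bool

    @property
    def area_cm2(self) -> float:
        return self.area * 1e4

    def to_dict(self) -> dict:
        return {
            "area_m2": self.area,
            "area_cm2": self.area_cm2,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Osmotic pressure calibration
# ---------------------------------------------------------------------------

def fit_pi_cubic(pairs) -> tuple[OsmoticLaw, float]:
    """Zero-intercept cubic least squares on (c, Pi) calibration pairs.

    Returns the fitted ``OsmoticLaw`` (cubic mode) and the coefficient of
    determination R^2.  At least three distinct positive concentrations
    are required for the 3-parameter design to have full rank.
    """
    pairs = [(float(c), float(pi)) for c, pi in pairs]
    c = np.array([p[0] for p in pairs])
    pi = np.array([p[1] for p in pairs])
    if np.any(c <= 0):
        raise DataError("calibration concentrations must be positive")
    if len(np.unique(c)) < 3:
        raise FitError(
            "cubic fit needs >= 3 distinct concentrations "
            f"(got {len(np.unique(c))})"
        )
    design = np.column_stack([c, c**2, c**3])
    coef, _, rank, _ = np.linalg.lstsq(design, pi, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient design: concentrations too clustered")
    pred = design @ coef
    ss_res = float(np.sum((pi - pred) ** 2))
    ss_tot = float(np.sum((pi - pi.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    law = OsmoticLaw(
        mode="cubic_polynomial", a1=float(coef[0]), a2=float(coef[1]), a3=float(coef[2])
    )
    return law, r2


# ---------------------------------------------------------------------------
# Fouling calibration
# ---------------------------------------------------------------------------

def fit_fouling_hill(pairs, lp0: float) -> FoulingLaw:
    """Fit the Hill fouling curve to (c, effective L_p) measurements.

    Fouling factors f_i = 1 - lp_eff_i / lp0 are computed first; any f_i
    below -0.05 indicates the measured permeability exceeds the clean
    value beyond noise and is rejected.  The (f_max, c_half, hill_n)
    parameters are then fit by bounded nonlinear least squares with
    f_max in (0, 1], c_half > 0, hill_n in (0, 10].
    """
    if lp0 <= 0:
        raise DomainError("lp0 must be positive")
    pairs = [(float(c), float(lp)) for c, lp in pairs]
    if len(pairs) < 3:
        raise FitError("Hill fit needs >= 3 concentrations")
    c = np.array([p[0] for p in pairs])
    lp_eff = np.array([p[1] for p in pairs])
    if np.any(c < 0):
        raise DataError("concentrations must be non-negative")
    f = 1.0 - lp_eff / lp0
    if np.any(f < -0.05):
        raise DataError(
            "effective L_p exceeds lp0 by more than 5%: check lp0 or the data"
        )
    f = np.clip(f, 0.0, None)

    def hill(cc, f_max, c_half, n):
        ch = np.power(cc, n)
        return f_max * ch / (np.power(c_half, n) + ch)

    f_max0 = min(max(float(f.max()), 1e-3), 1.0)
    c_half0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    try:
        with warnings.catch_warnings():
            # the covariance is not used; it is singular when f == 0 everywhere
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                hill,
                c,
                f,
                p0=[f_max0, c_half0, 1.5],
                bounds=([1e-9, 1e-9, 1e-3], [1.0, np.inf, 10.0]),
                maxfev=20000,
            )
    except RuntimeError as exc:  # pragma: no cover - optimizer pathologies
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    return FoulingLaw(f_max=float(popt[0]), c_half=float(popt[1]), hill_n=float(popt[2]))


# ---------------------------------------------------------------------------
# Clean-membrane permeability from a pumping run
# ---------------------------------------------------------------------------

def lp0_from_pumping(run: PumpingRun, monotone_tol: float = 0.01) -> float:
    """Clean-membrane permeability from a constant-pressure pumping run.

    The volumetric flux is Q = pi r^2 * (meniscus speed), with the speed
    taken as the ordinary least-squares slope of position vs time over all
    samples (robust to reading noise).  Then L_p0 = Q / (A * dP).
    Positions must be monotone within ``monotone_tol`` of the total travel.
    """
    x = run.meniscus_x
    span = float(np.max(x) - np.min(x))
    if span > 0:
        backtrack = float(np.max(np.maximum(0.0, -np.diff(x))))
        if backtrack > monotone_tol * span:
            raise DataError(
                f"meniscus positions reverse by {backtrack:.3g} m, beyond "
                f"{monotone_tol:.0%} of the total travel"
            )
    slope = float(np.polyfit(run.meniscus_t, x, 1)[0])
    q = math.pi * run.tube_radius**2 * abs(slope)
    return q / (run.membrane_area * run.applied_dp)


# ---------------------------------------------------------------------------
# Bulk modulus from wave speed
# ---------------------------------------------------------------------------

def bulk_modulus_from_wave_speed(v_wave: float, rho: float) -> float:
    """Bulk modulus K = rho * v^2 from the pressure-wave speed in the fluid.

    Assumes a rigid conduit (no Korteweg compliance correction); ``v_wave``
    is taken as already reduced from the transducer time-delay measurement.
    """
    if v_wave <= 0:
        raise DomainError(f"wave speed must be positive, got {v_wave}")
    if rho <= 0:
        raise DomainError(f"density must be positive, got {rho}")
    return rho * v_wave**2


# ---------------------------------------------------------------------------
# Membrane-area fit
# ---------------------------------------------------------------------------

def area_rss(trace: PressureTrace, scenario: Scenario, area: float) -> float:
    """Residual sum of squares between the trace and the simulated curve
    with the membrane area set to ``area`` (all other parameters fixed)."""
    ts = simulate(with_area(scenario, area))
    assert ts.dense is not None
    p_model = np.array([ts.dense(float(tt)) for tt in trace.t])
    return float(np.sum((p_model - trace.p) ** 2))


def fit_area(
    trace: PressureTrace,
    scenario: Scenario,
    bounds: tuple[float, float] = DEFAULT_AREA_BOUNDS,
) -> AreaFitResult:
    """Fit the effective membrane area A to a pressure trace.

    Bounded scalar minimization (Brent) of RSS(A) with the model curve
    evaluated on the trace's own time grid via the integrator's dense
    output.  A minimizer that lands at (or hugs) a search bound is flagged
    ``converged=False``: the true area lies outside the interval or the
    trace does not constrain it.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise DomainError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    if trace.t[-1] > scenario.t_end:
        raise DomainError(
            f"trace extends to {trace.t[-1]:.6g} s beyond scenario t_end "
            f"{scenario.t_end:.6g} s"
        )
    res = minimize_scalar(
        lambda a: area_rss(trace, scenario, a),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": max(1e-7 * (hi - lo), 1e-16)},
    )
    area = float(res.x)
    margin = 1e-3 * (hi - lo)
    converged = bool(res.success) and (lo + margin < area < hi - margin)
    return AreaFitResult(
        area=area, rss=float(res.fun), n_points=len(trace.t), converged=converged
    )


__all__ = [
    "DEFAULT_AREA_BOUNDS",
    "PressureTrace",
    "PumpingRun",
    "AreaFitResult",
    "fit_pi_cubic",
    "fit_fouling_hill",
    "lp0_from_pumping",
    "bulk_modulus_from_wave_speed",
    "area_rss",
    "fit_area",
]
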