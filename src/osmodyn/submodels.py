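"""Constitutive laws for osmotic pressure generation in a membrane-bound compartment.

Everything algebraic that enters the governing pressure ODE lives here:
the osmotic pressure law Pi(c), the Hill fouling factor f(c) that discounts
the membrane's hydraulic permeability, the working-fluid bulk modulus
K(c, P), fluid densities, the compartment pressure-volume relation
V_in(P_in), and solute bookkeeping (c = n/V).

Units are strict SI throughout: concentrations in mol m^-3 (numerically
equal to mM for aqueous solutions), pressures in Pa gauge (external bath
at 0), volumes in m^3, permeabilities in m Pa^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
WATER_DENSITY = 998.0  # kg m^-3 at room temperature
WATER_BULK_MODULUS = 2.2e9  # Pa, textbook value at ambient conditions


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OsmoDynError(Exception):
    """Base class for all errors raised by osmodyn."""


class DomainError(OsmoDynError, ValueError):
    """An input is outside the physical or mathematical domain of a law."""


class ConfigurationError(OsmoDynError, ValueError):
    """A law or scenario is internally inconsistent or incomplete."""


class DataError(OsmoDynError, ValueError):
    """Measured input data violate the assumptions of a reduction."""


class FitError(OsmoDynError, RuntimeError):
    """A parameter fit could not be carried out (degenerate design, etc.)."""


class IntegrationError(OsmoDynError, RuntimeError):
    """The ODE integrator failed to advance the solution."""


# ---------------------------------------------------------------------------
# Osmotic pressure Pi(c)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OsmoticLaw:
    """Osmotic pressure as a function of solute concentration.

    Two modes are supported.  ``vant_hoff`` is the ideal-solution law
    Pi = phi * c * R * T, appropriate for small osmolytes (sugars, ions)
    such as those pressurizing plant motor cells.  ``cubic_polynomial``
    is a zero-intercept cubic Pi = a1*c + a2*c^2 + a3*c^3, which captures
    the strongly super-linear osmotic response of aqueous polymer
    solutions such as PEG-4000.

    Parameters
    ----------
    mode:
        ``"vant_hoff"`` or ``"cubic_polynomial"``.
    a1, a2, a3:
        Cubic coefficients, Pa per (mol m^-3)^k.  Required (non-trivial)
        in cubic mode, ignored in van't Hoff mode.
    osmotic_coefficient:
        Dimensionless van't Hoff multiplier phi (default 1, ideal).
    temperature:
        Absolute temperature in K (default 298.15).
    """

    mode: str = "vant_hoff"
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    osmotic_coefficient: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.mode not in ("vant_hoff", "cubic_polynomial"):
            raise ConfigurationError(
                f"unknown osmotic law mode {self.mode!r}; "
                "expected 'vant_hoff' or 'cubic_polynomial'"
            )
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive (K)")
        if self.osmotic_coefficient <= 0:
            raise ConfigurationError("osmotic_coefficient must be positive")

    def __call__(self, c: float) -> float:
        return osmotic_pressure(c, self)


def osmotic_pressure(c: float, law: OsmoticLaw) -> float:
    """Osmotic pressure Pi(c) in Pa for concentration ``c`` in mol m^-3.

    Zero intercept is guaranteed in both modes: Pi(0) = 0 exactly.
    """
    if c < 0:
        raise DomainError(f"concentration must be non-negative, got {c}")
    if law.mode == "vant_hoff":
        return law.osmotic_coefficient * c * GAS_CONSTANT * law.temperature
    # cubic_polynomial
    if law.a1 == 0.0 and law.a2 == 0.0 and law.a3 == 0.0:
        raise ConfigurationError(
            "cubic_polynomial osmotic law requires coefficients a1, a2, a3; "
            "all are zero/unset"
        )
    return law.a1 * c + law.a2 * c * c + law.a3 * c * c * c


# ---------------------------------------------------------------------------
# Membrane fouling f(c)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoulingLaw:
    """Hill-equation fouling factor: the fraction of membrane pores blocked.

    f(c) = f_max * c^h / (c_half^h + c^h), modelling cooperative binding of
    the solute (e.g. PEG) to membrane pores.  The effective hydraulic
    permeability is L_p = L_p0 * (1 - f).  ``NO_FOULING`` (f_max = 0) is the
    clean-membrane default used when no fouling calibration is available.
    """

    f_max: float = 0.0
    c_half: float = 1.0  # mol m^-3
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_max <= 1.0:
            raise ConfigurationError(f"f_max must lie in [0, 1], got {self.f_max}")
        if self.c_half <= 0:
            raise ConfigurationError(f"c_half must be positive, got {self.c_half}")
        if self.hill_n <= 0:
            raise ConfigurationError(f"hill_n must be positive, got {self.hill_n}")

    def __call__(self, c: float) -> float:
        return fouling_factor(c, self)


NO_FOULING = FoulingLaw(f_max=0.0)


def fouling_factor(c: float, law: FoulingLaw) -> float:
    """Fouling factor f(c) in [0, 1) for concentration ``c`` in mol m^-3."""
    if c < 0:
        raise DomainError(f"concentration must be non-negative, got {c}")
    if c == 0.0 or law.f_max == 0.0:
        return 0.0
    ch = c ** law.hill_n
    f = law.f_max * ch / (law.c_half ** law.hill_n + ch)
    # f_max <= 1 and the Hill ratio < 1 for finite c, so f < 1 strictly;
    # guard against rounding at extreme c.
    return min(f, math.nextafter(1.0, 0.0))


def effective_lp(lp0: float, f: float) -> float:
    """Effective hydraulic permeability L_p = L_p0 * (1 - f)."""
    if not 0.0 <= f < 1.0:
        raise DomainError(f"fouling factor must lie in [0, 1), got {f}")
    if lp0 <= 0:
        raise DomainError(f"lp0 must be positive, got {lp0}")
    return lp0 * (1.0 - f)


# ---------------------------------------------------------------------------
# Bulk modulus K(c, P)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkModulusLaw:
    """Working-fluid bulk modulus: quadratic in concentration, linear in pressure.

    K(c, P) = k0 + k1*c + k2*c^2 + kp*P.  The default is pure water
    (k0 = 2.2 GPa, other coefficients zero); solution-specific
    coefficients can be supplied after calibration.  The compressibility
    term V/K is a small correction whenever the compartment is at all
    compliant (dV/dP >> V/K), but it is what sets the pressurization
    timescale of a perfectly rigid compartment.
    """

    k0: float = WATER_BULK_MODULUS
    k1: float = 0.0  # Pa per (mol m^-3)
    k2: float = 0.0  # Pa per (mol m^-3)^2
    kp: float = 0.0  # dimensionless

    def __call__(self, c: float, p: float) -> float:
        return bulk_modulus(c, p, self)


def bulk_modulus(c: float, p: float, law: BulkModulusLaw) -> float:
    """Bulk modulus K(c, P) in Pa; must be positive on the operating range."""
    if c < 0:
        raise DomainError(f"concentration must be non-negative, got {c}")
    k = law.k0 + law.k1 * c + law.k2 * c * c + law.kp * p
    if k <= 0:
        raise ConfigurationError(
            f"bulk modulus is non-positive ({k:.3g} Pa) at c={c:.3g}, p={p:.3g}"
        )
    return k


# ---------------------------------------------------------------------------
# Working fluid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkingFluid:
    """Solute inventory plus every concentration-dependent law of the fluid.

    ``moles_solute`` is the (constant) solute amount n; the instantaneous
    concentration is n / V_in(P_in), so volume expansion dilutes the
    osmotic driving force.  ``rho_atm_intercept``/``rho_atm_slope`` give the
    density of the working fluid at atmospheric pressure as an affine
    function of the *initial* concentration (the default slope 0.17
    kg m^-3 per mol m^-3 is typical aqueous-PEG densification; set it to 0
    for dilute ionic/sugar saps).
    """

    moles_solute: float
    osmotic_law: OsmoticLaw = field(default_factory=OsmoticLaw)
    fouling_law: FoulingLaw = NO_FOULING
    bulk_law: BulkModulusLaw = field(default_factory=BulkModulusLaw)
    rho_solvent: float = WATER_DENSITY
    rho_atm_intercept: float = WATER_DENSITY
    rho_atm_slope: float = 0.17  # kg m^-3 per mol m^-3

    def __post_init__(self) -> None:
        if self.moles_solute < 0:
            raise ConfigurationError("moles_solute must be non-negative")
        if self.rho_solvent <= 0:
            raise ConfigurationError("rho_solvent must be positive")
        if self.rho_atm_intercept < self.rho_solvent:
            raise ConfigurationError(
                "rho_atm intercept must be at least the solvent density"
            )
        if self.rho_atm_slope < 0:
            raise ConfigurationError("rho_atm_slope must be non-negative")

    def rho_atm(self, c_initial: float) -> float:
        """Density of the working fluid at atmospheric pressure, kg m^-3."""
        if c_initial < 0:
            raise DomainError("initial concentration must be non-negative")
        return self.rho_atm_intercept + self.rho_atm_slope * c_initial


def concentration(n: float, v: float) -> float:
    """Solute concentration c = n / v in mol m^-3."""
    if v <= 0:
        raise DomainError(f"volume must be positive, got {v}")
    if n < 0:
        raise DomainError(f"moles must be non-negative, got {n}")
    return n / v


# ---------------------------------------------------------------------------
# Membrane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Membrane:
    """Semipermeable membrane: clean permeability, area, reflection coefficient.

    sigma = 1 (leak-free) in every shipped scenario; it is stored so the
    flux law J_v = L_p (sigma * dPi - dP) is explicit.
    """

    lp0: float  # m Pa^-1 s^-1
    area: float  # m^2
    sigma: float = 1.0
    mwco_label: str = ""

    def __post_init__(self) -> None:
        if self.lp0 <= 0:
            raise ConfigurationError(f"lp0 must be positive, got {self.lp0}")
        if self.area <= 0:
            raise ConfigurationError(f"area must be positive, got {self.area}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ConfigurationError(f"sigma must lie in [0, 1], got {self.sigma}")


# ---------------------------------------------------------------------------
# Pressure-volume relation V_in(P_in)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeLaw:
    """Compartment pressure-volume relation V_in(P_in) and its derivative.

    Variants
    --------
    constant:
        Rigid compartment, V = v_ref, dV/dP = 0.
    affine:
        Linearly compliant, V = v_ref + compliance * P.
    plant_exp_log:
        Plant-cell wall law V = v_ref * exp(alpha*P + beta*ln P),
        developed from bulk elastic modulus measurements of motor cells;
        requires P > 0 (the ln P term is singular at zero gauge pressure).
    tabulated:
        Monotone piecewise-linear interpolation of measured (P, V) pairs;
        no extrapolation outside the table.
    """

    variant: str = "constant"
    v_ref: float = 0.0  # m^3
    alpha: float = 0.0  # Pa^-1
    beta: float = 0.0  # dimensionless
    compliance: float = 0.0  # m^3 Pa^-1, affine variant only
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("constant", "affine", "plant_exp_log", "tabulated"):
            raise ConfigurationError(f"unknown volume law variant {self.variant!r}")
        if self.variant == "tabulated":
            if self.table is None or len(self.table) < 2:
                raise ConfigurationError("tabulated volume law needs >= 2 (P, V) pairs")
            ps = [p for p, _ in self.table]
            vs = [v for _, v in self.table]
            if any(b <= a for a, b in zip(ps, ps[1:])):
                raise ConfigurationError(
                    "tabulated volume law requires strictly increasing pressures"
                )
            if any(b <= a for a, b in zip(vs, vs[1:])):
                raise ConfigurationError(
                    "tabulated volume law requires strictly increasing volumes "
                    "(dV/dP must be positive)"
                )
            if vs[0] <= 0:
                raise ConfigurationError("tabulated volumes must be positive")
        else:
            if self.v_ref <= 0:
                raise ConfigurationError(f"v_ref must be positive, got {self.v_ref}")
            if self.compliance < 0:
                raise ConfigurationError("compliance must be non-negative")

    def __call__(self, p: float) -> tuple[float, float]:
        return volume_and_derivative(p, self)


def volume_and_derivative(p: float, law: VolumeLaw) -> tuple[float, float]:
    """Return (V_in(p), dV/dP) for gauge pressure ``p`` in Pa."""
    if law.variant == "constant":
        return law.v_ref, 0.0
    if law.variant == "affine":
        return law.v_ref + law.compliance * p, law.compliance
    if law.variant == "plant_exp_log":
        if p <= 0:
            raise DomainError(
                f"plant_exp_log volume law requires P > 0 (ln P term), got {p}"
            )
        v = law.v_ref * math.exp(law.alpha * p + law.beta * math.log(p))
        return v, v * (law.alpha + law.beta / p)
    # tabulated
    table = law.table
    assert table is not None
    ps = np.array([q for q, _ in table])
    vs = np.array([v for _, v in table])
    if p < ps[0] or p > ps[-1]:
        raise DomainError(
            f"pressure {p:.6g} Pa outside tabulated range "
            f"[{ps[0]:.6g}, {ps[-1]:.6g}] (no extrapolation)"
        )
    v = float(np.interp(p, ps, vs))
    # derivative: slope of the containing segment (finite difference)
    i = int(np.searchsorted(ps, p, side="right")) - 1
    i = min(max(i, 0), len(ps) - 2)
    dvdp = float((vs[i + 1] - vs[i]) / (ps[i + 1] - ps[i]))
    return v, dvdp


__all__ = [
    "GAS_CONSTANT",
    "WATER_DENSITY",
    "WATER_BULK_MODULUS",
    "OsmoDynError",
    "DomainError",
    "ConfigurationError",
    "DataError",
    "FitError",
    "IntegrationError",
    "OsmoticLaw",
    "FoulingLaw",
    "NO_FOULING",
    "BulkModulusLaw",
    "WorkingFluid",
    "Membrane",
    "VolumeLaw",
    "osmotic_pressure",
    "fouling_factor",
    "effective_lp",
    "bulk_modulus",
    "volume_and_derivative",
    "concentration",
]
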