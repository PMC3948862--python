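"""Shipped parameterizations and a synthetic-trace generator.

Two families of presets are provided:

* ``pulvinus_*`` — a plant motor (pulvinus extensor) cell, with literature
  hydraulic permeability, cell geometry, and an exponential-log
  pressure-volume law derived from bulk elastic modulus measurements.
  Osmotic pressure follows the van't Hoff relation (sugar/ion osmolytes),
  fouling is zero, and the solute amount is chosen so the initial osmotic
  gradient is 1 MPa (or 1.98 MPa in the alternate preset, the value
  implied by ~1000 mOsm/kg sap at the printed osmotic pressure).

* ``cassette_*`` — restrained dialysis-cassette pressure generators with
  aqueous PEG-4000 working fluid: cubic osmotic law calibrated to the
  printed osmometry table, per-MWCO clean permeabilities, and nominal fill
  volumes.  No fouling defaults are shipped (the Hill coefficients must be
  calibrated from the user's own delivery data), so these scenarios
  pressurize much faster than a fouled membrane would.

Every number is either a published value or a documented default; see the
methods note for provenance of each.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import PressureTrace, fit_pi_cubic
from .dynamics import Scenario, SolverSettings, simulate, with_area
from .submodels import (
    GAS_CONSTANT,
    NO_FOULING,
    BulkModulusLaw,
    DomainError,
    Membrane,
    OsmoticLaw,
    VolumeLaw,
    WorkingFluid,
    volume_and_derivative,
)

#: Freezing-point osmometry calibration pairs for aqueous PEG-4000:
#: (concentration mol m^-3, osmotic pressure Pa).
PEG4000_PI_PAIRS: tuple[tuple[float, float], ...] = (
    (30.0, 0.38e6),
    (50.0, 1.31e6),
    (70.0, 3.09e6),
    (125.0, 14.73e6),
)

# Pulvinus extensor cell (literature values)
PULVINUS_LP0 = 3.6e-14  # m Pa^-1 s^-1
PULVINUS_AREA = 2.02e-8  # m^2
PULVINUS_VREF = 3.23e-13  # m^3
PULVINUS_ALPHA = 1.06e-6  # Pa^-1
PULVINUS_BETA = 0.047
PULVINUS_P_INITIAL = 1.0  # Pa; floor above the ln P singularity

# Dialysis cassettes
LP0_3P5KDA = 6.26e-13  # m Pa^-1 s^-1
LP0_2KDA = 1.70e-13  # m Pa^-1 s^-1
AREA_3ML = 21.9e-4  # m^2
AREA_30ML = 60.0e-4  # m^2
#: Placeholder compliance for the optional affine cassette law (m^3 Pa^-1):
#: ~1 mL of expansion at 50 kPa, plausible for a restrained cassette.
CASSETTE_COMPLIANCE = 2e-11

_cubic_cache: OsmoticLaw | None = None


def default_pi_cubic() -> OsmoticLaw:
    """Cubic PEG-4000 osmotic law, least-squares fit to ``PEG4000_PI_PAIRS``."""
    global _cubic_cache
    if _cubic_cache is None:
        _cubic_cache, _ = fit_pi_cubic(PEG4000_PI_PAIRS)
    return _cubic_cache


@dataclass(frozen=True)
class Preset:
    name: str
    scenario: Scenario
    provenance: str


def _pulvinus(name: str, dpi_initial: float) -> Preset:
    vol_law = VolumeLaw(
        variant="plant_exp_log",
        v_ref=PULVINUS_VREF,
        alpha=PULVINUS_ALPHA,
        beta=PULVINUS_BETA,
    )
    law = OsmoticLaw(mode="vant_hoff")
    v0 = volume_and_derivative(PULVINUS_P_INITIAL, vol_law)[0]
    c0 = dpi_initial / (GAS_CONSTANT * law.temperature)
    fluid = WorkingFluid(
        moles_solute=c0 * v0,
        osmotic_law=law,
        fouling_law=NO_FOULING,
        bulk_law=BulkModulusLaw(),
        rho_atm_slope=0.0,  # sugar/ion sap treated as water-density
    )
    scenario = Scenario(
        fluid=fluid,
        membrane=Membrane(lp0=PULVINUS_LP0, area=PULVINUS_AREA, mwco_label="cell membrane"),
        volume_law=vol_law,
        mode="pressurize",
        p_initial=PULVINUS_P_INITIAL,
        t_end=3600.0,
        events=(10e3, 50e3),
        name=name,
    )
    prov = (
        f"Lp0 {PULVINUS_LP0} and cell geometry (V {PULVINUS_VREF} m^3, A "
        f"{PULVINUS_AREA} m^2) from published motor-cell measurements; volume law "
        f"V = v_ref*exp({PULVINUS_ALPHA}*P + {PULVINUS_BETA}*ln P) from bulk "
        f"elastic modulus literature; initial osmotic gradient {dpi_initial:.3g} Pa "
        "(van't Hoff, zero fouling); p_initial 1 Pa is a documented floor above "
        "the ln P singularity."
    )
    return Preset(name, scenario, prov)


def _cassette(name: str, lp0: float, area: float, v_ml: float, mwco: str) -> Preset:
    v_ref = v_ml * 1e-6
    c0 = 70.0  # mol m^-3; the routinely used working concentration
    fluid = WorkingFluid(
        moles_solute=c0 * v_ref,
        osmotic_law=default_pi_cubic(),
        fouling_law=NO_FOULING,
        bulk_law=BulkModulusLaw(),
    )
    scenario = Scenario(
        fluid=fluid,
        membrane=Membrane(lp0=lp0, area=area, mwco_label=mwco),
        volume_law=VolumeLaw(variant="constant", v_ref=v_ref),
        mode="pressurize",
        p_initial=0.0,
        t_end=600.0,
        events=(10e3, 50e3),
        name=name,
    )
    prov = (
        f"Lp0 {lp0} m/Pa/s for {mwco} MWCO from pumping experiments; membrane area "
        f"{area * 1e4:.1f} cm^2 (estimated bulging area); nominal fill {v_ml:.0f} mL "
        "(measured initial volumes in the experiments ran higher due to overfill "
        "and dead volume; override moles/volume per experiment); cubic PEG-4000 "
        "osmotic law from the shipped osmometry pairs at 70 mM; fouling and "
        "compartment compliance require user calibration and default to zero."
    )
    return Preset(name, scenario, prov)


def _build_presets() -> dict[str, Preset]:
    return {
        p.name: p
        for p in (
            _pulvinus("pulvinus_1MPa", 1.0e6),
            _pulvinus("pulvinus_1p98MPa", 1.98e6),
            _cassette("cassette_3ml_3p5kDa", LP0_3P5KDA, AREA_3ML, 3.0, "3.5 kDa"),
            _cassette("cassette_3ml_2kDa", LP0_2KDA, AREA_3ML, 3.0, "2.0 kDa"),
            _cassette("cassette_30ml_3p5kDa", LP0_3P5KDA, AREA_30ML, 30.0, "3.5 kDa"),
        )
    }


_PRESETS: dict[str, Preset] | None = None


def _presets() -> dict[str, Preset]:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _build_presets()
    return _PRESETS


def preset_names() -> list[str]:
    return list(_presets())


def preset(name: str) -> Scenario:
    """Return a fully populated scenario for one of the shipped presets."""
    presets = _presets()
    if name not in presets:
        raise DomainError(
            f"unknown preset {name!r}; valid names: {', '.join(presets)}"
        )
    return presets[name].scenario


def preset_info(name: str) -> Preset:
    presets = _presets()
    if name not in presets:
        raise DomainError(
            f"unknown preset {name!r}; valid names: {', '.join(presets)}"
        )
    return presets[name]


def affine_cassette(scenario: Scenario, compliance: float = CASSETTE_COMPLIANCE) -> Scenario:
    """Swap a cassette scenario's rigid volume law for the optional affine
    law with the documented placeholder compliance."""
    if scenario.volume_law.variant != "constant":
        raise DomainError("affine_cassette expects a constant-volume scenario")
    return replace(
        scenario,
        volume_law=VolumeLaw(
            variant="affine", v_ref=scenario.volume_law.v_ref, compliance=compliance
        ),
    )


def synth_pressure_trace(
    scenario: Scenario,
    a_true: float,
    noise_sd: float,
    n_points: int,
    seed: int,
) -> PressureTrace:
    """Simulate with the membrane area overridden to ``a_true`` and sample a
    noisy pressure trace: ``n_points`` evenly spaced times with i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` (Pa).  Deterministic
    for a given seed."""
    if a_true <= 0:
        raise DomainError("a_true must be positive")
    if n_points < 10:
        raise DomainError("n_points must be at least 10")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    ts = simulate(with_area(scenario, a_true))
    assert ts.dense is not None
    t = np.linspace(0.0, scenario.t_end, n_points + 1)[1:]  # skip t=0
    p = np.array([ts.dense(float(tt)) for tt in t])
    rng = np.random.default_rng(seed)
    p_noisy = p + rng.normal(0.0, noise_sd, size=p.shape) if noise_sd > 0 else p
    return PressureTrace(t, p_noisy, label=f"synthetic A={a_true:.4g} seed={seed}")


__all__ = [
    "PEG4000_PI_PAIRS",
    "PULVINUS_LP0",
    "PULVINUS_AREA",
    "PULVINUS_VREF",
    "PULVINUS_ALPHA",
    "PULVINUS_BETA",
    "LP0_3P5KDA",
    "LP0_2KDA",
    "AREA_3ML",
    "AREA_30ML",
    "CASSETTE_COMPLIANCE",
    "Preset",
    "default_pi_cubic",
    "preset",
    "preset_info",
    "preset_names",
    "affine_cassette",
    "synth_pressure_trace",
]
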