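import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import osmodyn as od

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pulvinus():
    return od.preset("pulvinus_1MPa")


@pytest.fixture(scope="session")
def pulvinus_long(pulvinus):
    """Pulvinus scenario run out to 2 h (covers the equilibrium approach)."""
    return dataclasses.replace(pulvinus, t_end=7200.0)


@pytest.fixture(scope="session")
def cassette():
    return od.preset("cassette_3ml_3p5kDa")


@pytest.fixture(scope="session")
def cassette_affine(cassette):
    """Compliant-cassette variant, run length matched to its transient."""
    return dataclasses.replace(od.affine_cassette(cassette), t_end=20.0)


@pytest.fixture(scope="session")
def rigid_vant_hoff():
    """Rigid compartment + van't Hoff solute: the linear-ODE benchmark.

    Constant volume means constant concentration, so the governing
    equation becomes dP/dt = (dPi - P)/tau with
    tau = rho_atm * V / (rho_s * A * Lp0 * K) and the trajectory is the
    closed-form exponential P(t) = dPi * (1 - exp(-t/tau)).
    """
    fluid = od.WorkingFluid(
        moles_solute=100.0 * 3e-6,  # c0 = 100 mol/m^3
        osmotic_law=od.OsmoticLaw(mode="vant_hoff"),
        fouling_law=od.NO_FOULING,
        bulk_law=od.BulkModulusLaw(),
    )
    return od.Scenario(
        fluid=fluid,
        membrane=od.Membrane(lp0=6.26e-13, area=21.9e-4),
        volume_law=od.VolumeLaw(variant="constant", v_ref=3e-6),
        mode="pressurize",
        p_initial=0.0,
        t_end=10.0,
        name="rigid benchmark",
    )


def rigid_tau_dpi(scenario):
    """Analytic time constant and driving force of the rigid benchmark."""
    fluid = scenario.fluid
    c0 = scenario.initial_concentration()
    dpi = od.osmotic_pressure(c0, fluid.osmotic_law)
    v = scenario.volume_law.v_ref
    k = fluid.bulk_law.k0
    tau = (
        scenario.rho_atm()
        * v
        / (fluid.rho_solvent * scenario.membrane.area * scenario.membrane.lp0 * k)
    )
    return tau, dpi
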