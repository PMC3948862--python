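"""Governing ODE: sign contracts, closed-form limits, events, energy, delivery."""

import dataclasses

import numpy as np
import pytest

import osmodyn as od
from osmodyn.submodels import ConfigurationError

from conftest import rigid_tau_dpi


class TestGoverningRhs:
    def test_pulvinus_initial_rate(self, pulvinus):
        # Hand evaluation at p = 1 Pa: the water-mass influx is
        # rho_s*A*Lp0*(dPi - p) = 998 * 2.02e-8 * 3.6e-14 * (1e6 - 1)
        # = 7.2575e-13 kg/s, and the mass capacity is
        # rho_atm*(dV/dP + V/K) = 998 * (1.5185e-14 + 1.47e-22)
        # = 1.5155e-11 kg/Pa, giving dP/dt = 4.789e-2 Pa/s.
        assert od.governing_rhs(1.0, pulvinus) == pytest.approx(4.789e-2, rel=1e-3)

    def test_zero_at_osmotic_balance(self, rigid_vant_hoff):
        _, dpi = rigid_tau_dpi(rigid_vant_hoff)
        assert od.governing_rhs(dpi, rigid_vant_hoff) == pytest.approx(0.0, abs=1e-12)

    def test_sign_matches_driving_force(self, rigid_vant_hoff):
        _, dpi = rigid_tau_dpi(rigid_vant_hoff)
        assert od.governing_rhs(dpi * 0.5, rigid_vant_hoff) > 0
        assert od.governing_rhs(dpi * 1.5, rigid_vant_hoff) < 0

    def test_depressurize_mode_always_negative(self, pulvinus):
        dep = dataclasses.replace(pulvinus, mode="depressurize", p_initial=1e6)
        for p in (1e3, 1e5, 1e6):
            assert od.governing_rhs(p, dep) < 0


class TestRigidClosedForm:
    """Constant volume => constant concentration => linear ODE with
    exponential solution P(t) = dPi * (1 - exp(-t/tau))."""

    def test_trajectory_matches_exponential(self, rigid_vant_hoff):
        tau, dpi = rigid_tau_dpi(rigid_vant_hoff)
        ts = od.simulate(rigid_vant_hoff)
        expected = dpi * (1.0 - np.exp(-ts.t / tau))
        mask = ts.t > 0
        rel = np.abs(ts.p_in[mask] - expected[mask]) / dpi
        assert rel.max() < 1e-5

    def test_gain_time_matches_analytic_inversion(self, rigid_vant_hoff):
        tau, dpi = rigid_tau_dpi(rigid_vant_hoff)
        gain = 1e5
        t_analytic = tau * np.log(dpi / (dpi - gain))
        (res,) = od.time_to_pressure_gain(rigid_vant_hoff, [gain])
        assert res.time == pytest.approx(t_analytic, rel=1e-5)

    def test_unreachable_gain_reported_not_reached(self, rigid_vant_hoff):
        _, dpi = rigid_tau_dpi(rigid_vant_hoff)
        (res,) = od.time_to_pressure_gain(rigid_vant_hoff, [dpi * 1.1])
        assert not res.reached
        assert res.time is None


class TestSimulateInvariants:
    @pytest.mark.parametrize(
        "name", ["pulvinus_1MPa", "pulvinus_1p98MPa", "cassette_3ml_3p5kDa"]
    )
    def test_monotone_increase_bounded_by_equilibrium(self, name):
        scenario = od.preset(name)
        ts = od.simulate(scenario)
        p_eq = od.equilibrium_pressure(scenario)
        # strictly increasing until the trajectory is numerically at
        # equilibrium (the plateau carries solver noise at the rel_tol level)
        rising = ts.p_in[:-1] < 0.999 * p_eq
        assert np.all(np.diff(ts.p_in)[rising] > 0)
        assert np.all(ts.p_in <= p_eq * (1 + 1e-6))

    def test_trajectory_bookkeeping_consistent(self, pulvinus):
        ts = od.simulate(pulvinus)
        assert np.all(np.diff(ts.t) > 0)
        assert np.all(ts.v_in > 0)
        assert np.all(ts.c >= 0)
        # dilution: concentration falls as the compartment swells
        assert np.all(np.diff(ts.c) < 0)
        np.testing.assert_allclose(
            ts.c, pulvinus.fluid.moles_solute / ts.v_in, rtol=1e-12
        )
        np.testing.assert_allclose(
            ts.influx_rate,
            ts.scenario.membrane.area * ts.lp_eff * (ts.delta_pi - ts.p_in),
            rtol=1e-12,
        )

    def test_no_driving_force_stays_flat(self):
        fluid = od.WorkingFluid(moles_solute=0.0)
        scenario = od.Scenario(
            fluid=fluid,
            membrane=od.Membrane(lp0=1e-13, area=1e-4),
            volume_law=od.VolumeLaw(variant="constant", v_ref=1e-6),
            p_initial=0.0,
            t_end=100.0,
        )
        ts = od.simulate(scenario)
        assert np.allclose(ts.p_in, 0.0, atol=1e-9)

    def test_mass_conservation_all_presets(self):
        for name in od.preset_names():
            assert od.mass_conservation_error(od.preset(name)) < 1e-3


class TestDepressurization:
    def test_pressure_strictly_decreasing_toward_zero(self, pulvinus):
        dep = dataclasses.replace(pulvinus, mode="depressurize", p_initial=1e6)
        ts = od.simulate_depressurization(dep)
        assert np.all(np.diff(ts.p_in) < 0)
        assert ts.p_in[-1] > 0
        assert np.all(ts.delta_pi == 0.0)

    def test_halving_lp0_doubles_fractional_loss_time(self, pulvinus):
        # dP/dt is proportional to Lp0, so time axes rescale exactly.
        def loss_time(lp0):
            mem = dataclasses.replace(pulvinus.membrane, lp0=lp0)
            dep = dataclasses.replace(
                pulvinus, mode="depressurize", p_initial=1e6, membrane=mem
            )
            ts = od.simulate_depressurization(dep)
            from scipy.optimize import brentq

            return brentq(lambda t: ts.dense(t) - 0.9e6, 0.0, dep.t_end)

        t_full = loss_time(3.6e-14)
        t_half = loss_time(1.8e-14)
        assert t_half == pytest.approx(2 * t_full, rel=1e-5)

    def test_requires_depressurize_mode(self, pulvinus):
        with pytest.raises(ConfigurationError):
            od.simulate_depressurization(pulvinus)


class TestEvents:
    def test_threshold_times_monotone_in_gain(self, pulvinus):
        results = od.time_to_pressure_gain(pulvinus, [5e3, 10e3, 50e3, 100e3])
        times = [r.time for r in results if r.reached]
        assert len(times) >= 3
        assert all(b > a for a, b in zip(times, times[1:]))

    @pytest.mark.parametrize("factor_field", ["area", "lp0"])
    def test_times_decrease_with_area_and_permeability(self, pulvinus, factor_field):
        (base,) = od.time_to_pressure_gain(pulvinus, [10e3])
        mem = dataclasses.replace(
            pulvinus.membrane, **{factor_field: getattr(pulvinus.membrane, factor_field) * 2}
        )
        (fast,) = od.time_to_pressure_gain(
            dataclasses.replace(pulvinus, membrane=mem), [10e3]
        )
        assert fast.time < base.time

    def test_gains_must_be_increasing(self, pulvinus):
        with pytest.raises(ConfigurationError):
            od.time_to_pressure_gain(pulvinus, [50e3, 10e3])


class TestEquilibrium:
    def test_rigid_equilibrium_is_initial_osmotic_pressure(self, rigid_vant_hoff):
        _, dpi = rigid_tau_dpi(rigid_vant_hoff)
        assert od.equilibrium_pressure(rigid_vant_hoff) == pytest.approx(dpi, rel=1e-9)

    def test_expanding_compartment_equilibrates_below(self, cassette, cassette_affine):
        p_rigid = od.equilibrium_pressure(cassette)
        p_soft = od.equilibrium_pressure(cassette_affine)
        assert p_soft < p_rigid

    def test_long_time_pressure_approaches_equilibrium(self, pulvinus):
        long = dataclasses.replace(pulvinus, t_end=14400.0)
        ts = od.simulate(long)
        p_eq = od.equilibrium_pressure(long)
        assert ts.p_in[-1] == pytest.approx(p_eq, rel=1e-3)


class TestStoredEnergy:
    def test_rigid_compartment_stores_nothing(self, rigid_vant_hoff):
        ts = od.simulate(rigid_vant_hoff)
        assert od.stored_energy(ts) == pytest.approx(0.0, abs=1e-18)

    def test_affine_law_energy_is_half_gamma_p_squared(self, cassette_affine):
        # With V = V0 + gamma*P, int P dV = gamma * (P1^2 - P0^2) / 2
        # along any trajectory; the trapezoid on a linear P-V relation is
        # exact, so only solver error should remain.
        ts = od.simulate(cassette_affine)
        gamma = cassette_affine.volume_law.compliance
        expected = gamma * (ts.p_in[-1] ** 2 - ts.p_in[0] ** 2) / 2
        assert od.stored_energy(ts) == pytest.approx(expected, rel=1e-6)
        np.testing.assert_allclose(ts.stored_energy[-1], expected, rtol=1e-6)

    def test_softer_compartment_stores_order_of_magnitude_more(self, cassette):
        # Restrained vs unrestrained at the same final 5 kPa: energy scales
        # with the compliance, so a 10x softer law stores ~10x the energy.
        def energy_at_5kpa(compliance):
            s = od.affine_cassette(cassette, compliance=compliance)
            (res,) = od.time_to_pressure_gain(
                dataclasses.replace(s, t_end=600.0), [5e3]
            )
            ts = od.simulate(dataclasses.replace(s, t_end=res.time))
            return od.stored_energy(ts)

        e_restrained = energy_at_5kpa(2e-11)
        e_unrestrained = energy_at_5kpa(2e-10)
        assert e_unrestrained > 5 * e_restrained


@pytest.fixture(scope="module")
def deliver_scenario():
    return od.apply_overrides(
        od.preset("cassette_3ml_3p5kDa"),
        {"concentration_mM": 125.0, "mode": "deliver", "t_end": "48 h"},
    )


class TestVolumeDelivery:
    def test_nondilutable_solute_delivers_linearly(self, deliver_scenario):
        s = dataclasses.replace(deliver_scenario, t_end=3600.0)
        ts = od.simulate_volume_delivery(s, solute_washout=False)
        c0 = s.initial_concentration()
        slope = s.membrane.area * s.membrane.lp0 * od.osmotic_pressure(
            c0, s.fluid.osmotic_law
        )
        np.testing.assert_allclose(
            ts.delivered_volume[1:], slope * ts.t[1:], rtol=1e-6
        )

    def test_washout_concave_and_below_initial_rate(self, deliver_scenario):
        ts = od.simulate_volume_delivery(deliver_scenario)
        d = np.diff(ts.delivered_volume)
        assert np.all(d >= 0)
        assert np.all(np.diff(d) <= 1e-15)  # concave: flow decays
        c0 = deliver_scenario.initial_concentration()
        slope0 = (
            deliver_scenario.membrane.area
            * deliver_scenario.membrane.lp0
            * od.osmotic_pressure(c0, deliver_scenario.fluid.osmotic_law)
        )
        assert np.all(ts.delivered_volume[1:] < slope0 * ts.t[1:])

    def test_multi_fold_turnover_at_two_days(self, deliver_scenario):
        ts = od.simulate_volume_delivery(deliver_scenario)
        assert ts.delivered_volume[-1] > 2 * deliver_scenario.volume_law.v_ref

    def test_mode_mismatch_rejected(self, pulvinus):
        with pytest.raises(ConfigurationError):
            od.simulate_volume_delivery(pulvinus)


class TestScenarioValidation:
    def test_plant_law_needs_positive_initial_pressure(self, pulvinus):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(pulvinus, p_initial=0.0)

    def test_event_thresholds_validated(self, pulvinus):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(pulvinus, events=(50e3, 10e3))
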