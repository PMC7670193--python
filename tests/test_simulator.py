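"""Quasi-steady interface solver and protocol simulation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from blisterdry import (
    Protocol,
    SimulationSetup,
    simulate_protocol,
    solve_interface,
    ice_vapor_pressure,
    latent_heat_sublimation,
)
from blisterdry.errors import ValidationError
from blisterdry.simulator import DryingState, advance_state


@pytest.fixture()
def setup_center(highdose_config):
    return highdose_config.build_setup("center")


class TestSolveInterface:
    def test_equilibrium_zero_flux(self, setup_center):
        # shelf at the temperature whose equilibrium vapor pressure equals
        # the chamber pressure: no driving force, no sublimation
        t_eq = brentq(
            lambda t: ice_vapor_pressure(t) - setup_center.chamber_pressure,
            210.0,
            280.0,
        )
        sol = solve_interface(t_eq, 3e-3, 1e-3, setup_center)
        assert sol.sublimation_rate == pytest.approx(0.0, abs=1e-15)
        assert sol.interface_temp == pytest.approx(t_eq, abs=1e-6)
        assert sol.delta_T == pytest.approx(0.0, abs=1e-9)

    def test_energy_mass_identity(self, setup_center):
        # heat delivered through the shelf equals sublimation enthalpy flow
        kv = setup_center.kv_value
        area_b = setup_center.geometry.projected_area
        m = setup_center.constants.molecular_weight_water
        for shelf_temp, lice, ldr in [
            (263.15, 4e-3, 3e-4),
            (283.15, 2e-3, 2.3e-3),
            (308.15, 1e-3, 3.3e-3),
        ]:
            sol = solve_interface(shelf_temp, lice, ldr, setup_center)
            heat = area_b * kv * (shelf_temp - sol.bottom_temp)
            sublimation = (
                sol.sublimation_rate
                * latent_heat_sublimation(sol.bottom_temp, setup_center.enthalpy)
                / m
            )
            assert abs(heat - sublimation) <= 1e-8 * max(abs(heat), abs(sublimation))

    def test_early_drying_sanity(self, setup_center):
        sol = solve_interface(263.15, 4.2e-3, 1e-4, setup_center)
        assert sol.interface_temp < 263.15
        assert sol.interface_pressure > setup_center.chamber_pressure
        assert sol.sublimation_rate > 0.0

    def test_temperature_ordering(self, setup_center):
        sol = solve_interface(273.15, 3e-3, 1e-3, setup_center)
        assert sol.interface_temp < sol.bottom_temp < 273.15

    def test_requires_ice(self, setup_center):
        with pytest.raises(ValidationError):
            solve_interface(263.15, 0.0, 4e-3, setup_center)


class TestAdvanceState:
    def _state(self, setup, rate):
        total = setup.initial_ice_thickness
        return DryingState(
            time=0.0,
            ice_thickness=total,
            dried_thickness=0.0,
            shelf_temp=263.15,
            bottom_temp=250.0,
            interface_temp=249.5,
            delta_T=0.5,
            interface_pressure=50.0,
            sublimation_rate=rate,
            sublimated_mass=0.0,
        )

    def test_zero_rate_only_advances_time(self, setup_center):
        state = self._state(setup_center, 0.0)
        advanced = advance_state(state, 60.0, setup_center)
        assert advanced.time == 60.0
        assert advanced.ice_thickness == state.ice_thickness
        assert advanced.dried_thickness == state.dried_thickness
        assert advanced.sublimated_mass == 0.0

    def test_step_matches_geometry_inverse(self, setup_center):
        from blisterdry import frozen_volume, ice_thickness_from_volume

        rate = 5e-8
        state = self._state(setup_center, rate)
        advanced = advance_state(state, 60.0, setup_center)
        theta = setup_center.formulation.porosity
        expected_volume = frozen_volume(
            state.ice_thickness, setup_center.geometry
        ) - rate * 60.0 / (theta * setup_center.constants.rho_ice)
        assert advanced.ice_thickness == pytest.approx(
            ice_thickness_from_volume(expected_volume, setup_center.geometry),
            abs=1e-12,
        )
        # layer bookkeeping: total thickness is conserved
        assert advanced.ice_thickness + advanced.dried_thickness == pytest.approx(
            state.ice_thickness + state.dried_thickness
        )

    def test_clamps_at_exhaustion(self, setup_center):
        state = self._state(setup_center, 1.0)  # absurd rate empties the pocket
        advanced = advance_state(state, 60.0, setup_center)
        assert advanced.ice_thickness == 0.0
        theta = setup_center.formulation.porosity
        from blisterdry import frozen_volume

        available = (
            frozen_volume(state.ice_thickness, setup_center.geometry)
            * theta
            * setup_center.constants.rho_ice
        )
        assert advanced.sublimated_mass == pytest.approx(available, rel=1e-12)


class TestSimulateProtocol:
    def test_mass_conservation(self, traditional_result, highdose_config):
        # total sublimated mass equals the ice fraction of the initial
        # frozen volume (minus the negligible end-threshold remnant)
        setup = highdose_config.build_setup("center")
        expected = (
            setup.initial_frozen_volume
            * setup.formulation.porosity
            * setup.constants.rho_ice
        )
        assert traditional_result.sublimated_mass == pytest.approx(
            expected, rel=1e-3
        )

    def test_temperature_ordering_along_trace(self, traditional_result):
        trace = traditional_result.trace
        active = trace["mdot_kg_s"] > 0
        assert (trace.loc[active, "Ti_K"] < trace.loc[active, "Tb_K"]).all()
        assert (trace.loc[active, "Tb_K"] < trace.loc[active, "Ts_K"]).all()

    def test_hotter_shelf_dries_faster(self, highdose_config):
        setup = highdose_config.build_setup("center")
        times = [
            simulate_protocol(Protocol.constant(t), setup).completion_time
            for t in (261.15, 266.15, 271.15)
        ]
        assert times[0] > times[1] > times[2]

    def test_time_step_convergence(self, highdose_config, traditional_result):
        import dataclasses

        setup = dataclasses.replace(highdose_config.build_setup("center"))
        setup.time_step = 30.0
        halved = simulate_protocol(highdose_config.build_protocol(), setup)
        assert halved.completion_time == pytest.approx(
            traditional_result.completion_time, rel=5e-3
        )

    def test_sensitivity_to_kv_and_rp(self, highdose_config):
        import dataclasses

        base = highdose_config.build_setup("center")
        protocol = highdose_config.build_protocol()
        t_base = simulate_protocol(protocol, base).completion_time

        hot = highdose_config.build_setup("center")
        hot.kv = base.kv_value * 1.2
        assert simulate_protocol(protocol, hot).completion_time < t_base

        resistive = highdose_config.build_setup("center")
        resistive.rp_model = dataclasses.replace(
            base.rp_model, rp0=base.rp_model.rp0 * 5.0
        )
        assert simulate_protocol(protocol, resistive).completion_time > t_base

    def test_incomplete_protocol_warns(self, highdose_config):
        setup = highdose_config.build_setup("center")
        with pytest.warns(UserWarning, match="remaining"):
            result = simulate_protocol(
                highdose_config.build_protocol(), setup, max_time=1800.0
            )
        assert not result.completed
        assert result.remaining_ice_thickness > 0


class TestProtocol:
    def test_ramp_hold_values(self):
        protocol = Protocol.ramp_hold(243.15, 263.15, ramp_rate=1.0)
        assert protocol.shelf_temperature(0.0) == 243.15
        assert protocol.shelf_temperature(600.0) == pytest.approx(253.15)
        assert protocol.shelf_temperature(1e6) == 263.15

    def test_staircase_interpolation(self):
        protocol = Protocol(
            times=np.array([0.0, 30.0, 60.0]),
            setpoints=np.array([243.15, 244.0, 245.0]),
            interpolation="previous",
        )
        assert protocol.shelf_temperature(29.9) == 243.15
        assert protocol.shelf_temperature(30.0) == 244.0

    def test_validation(self):
        with pytest.raises(ValidationError):
            Protocol(times=np.array([0.0, 0.0]), setpoints=np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            Protocol.ramp_hold(243.15, 263.15, ramp_rate=0.0)
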