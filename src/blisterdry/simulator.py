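"""Quasi-steady one-dimensional primary-drying simulator.

A planar sublimation interface recedes from the top of the frozen product
to the bottom of the blister pocket.  At each time step the coupled
interface balance is solved for the interface temperature T_i:

* the interface vapor pressure equals the equilibrium vapor pressure over
  ice at T_i;
* the heat delivered through the shelf (Kv) and conducted through the
  frozen layer sustains the sublimation mass flow through the dried layer
  (resistance Rp);
* the temperature drop over the frozen layer follows the empirical
  balance with conversion factors a and b.

The sublimation rate then advances the ice front through the blister
geometry until the frozen layer is exhausted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import geometry as geom_mod
from .errors import SolverError, ValidationError
from .geometry import BlisterGeometry
from .kv_estimation import KvPressureModel
from .rp_estimation import FormulationSpec, RpModel
from .thermo import (
    PhysicalConstants,
    SublimationEnthalpyModel,
    VaporPressureModel,
    ice_vapor_pressure,
    latent_heat_sublimation,
)

__all__ = [
    "Protocol",
    "SimulationSetup",
    "DryingState",
    "InterfaceSolution",
    "SimulationResult",
    "solve_interface",
    "advance_state",
    "simulate_protocol",
]

logger = logging.getLogger(__name__)

#: Ice-thickness threshold [m] below which primary drying counts as complete.
END_THRESHOLD = 1e-7

#: Solver bracket for the interface temperature [K].
T_BRACKET = (210.0, 280.0)


@dataclass(frozen=True)
class Protocol:
    """Piecewise shelf-temperature schedule at constant chamber pressure.

    ``times`` (strictly increasing, [s]) and ``setpoints`` [K] define the
    schedule; ``interpolation`` is ``"linear"`` (ramps between setpoints)
    or ``"previous"`` (staircase, as executed by a freeze-dryer loading a
    setpoint table).  The last setpoint is held indefinitely.
    """

    times: np.ndarray
    setpoints: np.ndarray
    interpolation: Literal["linear", "previous"] = "linear"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        setpoints = np.asarray(self.setpoints, float)
        if times.shape != setpoints.shape or times.ndim != 1 or len(times) == 0:
            raise ValidationError("protocol times/setpoints must be equal-length 1-D")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("protocol setpoint times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "setpoints", setpoints)

    @classmethod
    def constant(cls, shelf_temp: float) -> "Protocol":
        return cls(times=np.array([0.0]), setpoints=np.array([shelf_temp]))

    @classmethod
    def ramp_hold(
        cls, start_temp: float, hold_temp: float, ramp_rate: float
    ) -> "Protocol":
        """Linear ramp from ``start_temp`` to ``hold_temp`` at ``ramp_rate``
        [K/min], then hold."""
        if ramp_rate <= 0.0:
            raise ValidationError("ramp_rate must be positive [K/min]")
        duration = abs(hold_temp - start_temp) / (ramp_rate / 60.0)
        return cls(
            times=np.array([0.0, duration]),
            setpoints=np.array([start_temp, hold_temp]),
        )

    def shelf_temperature(self, t: float) -> float:
        """Shelf setpoint [K] at time ``t`` [s]; end values extend outward."""
        if self.interpolation == "linear":
            return float(np.interp(t, self.times, self.setpoints))
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.setpoints[max(idx, 0)])


@dataclass
class SimulationSetup:
    """Everything needed to march the drying model forward in time."""

    geometry: BlisterGeometry
    formulation: FormulationSpec
    kv: KvPressureModel | float
    rp_model: RpModel
    chamber_pressure: float = 10.0  # Pa
    time_step: float = 60.0  # s
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    enthalpy: SublimationEnthalpyModel = field(default_factory=SublimationEnthalpyModel)
    vapor: VaporPressureModel = field(default_factory=VaporPressureModel)

    def __post_init__(self) -> None:
        if self.time_step <= 0.0:
            raise ValidationError("time_step must be positive")
        if self.chamber_pressure <= 0.0:
            raise ValidationError("chamber_pressure must be positive")
        if self.initial_frozen_volume > self.geometry.full_volume * (1.0 + 1e-9):
            raise ValidationError(
                f"fill volume {self.formulation.fill_volume} m^3 freezes to "
                f"{self.initial_frozen_volume} m^3, exceeding the pocket "
                f"capacity {self.geometry.full_volume} m^3"
            )

    @property
    def kv_value(self) -> float:
        """Heat-transfer coefficient at the setup's chamber pressure."""
        if isinstance(self.kv, KvPressureModel):
            return self.kv.evaluate(self.chamber_pressure, warn=False)
        return float(self.kv)

    @property
    def initial_frozen_volume(self) -> float:
        """Frozen volume after solidification: fill expanded by density ratio."""
        return (
            self.formulation.fill_volume
            * self.constants.rho_solution
            / self.constants.rho_ice
        )

    @cached_property
    def initial_ice_thickness(self) -> float:
        """Total frozen thickness L_tot [m] from the fill volume."""
        return geom_mod.ice_thickness_from_volume(
            self.initial_frozen_volume, self.geometry
        )


@dataclass(frozen=True)
class InterfaceSolution:
    """Converged quasi-steady interface balance at one instant."""

    interface_temp: float  # T_i [K]
    delta_T: float  # T_b - T_i over the frozen layer [K]
    interface_pressure: float  # P_i [Pa]
    sublimation_rate: float  # kg/s
    sublimation_area: float  # A_p [m^2]

    @property
    def bottom_temp(self) -> float:
        return self.interface_temp + self.delta_T


@dataclass(frozen=True)
class DryingState:
    """Time-indexed state of one drying unit."""

    time: float  # s
    ice_thickness: float  # L_ice [m]
    dried_thickness: float  # L_dr [m]
    shelf_temp: float  # K
    bottom_temp: float  # K
    interface_temp: float  # K
    delta_T: float  # K
    interface_pressure: float  # Pa
    sublimation_rate: float  # kg/s
    sublimated_mass: float  # cumulative kg


def solve_interface(
    shelf_temp: float,
    ice_thickness: float,
    dried_thickness: float,
    setup: SimulationSetup,
) -> InterfaceSolution:
    """Solve the coupled interface balance for T_i at one instant.

    For a trial T_i the interface pressure and frozen-layer temperature
    drop form a linear 2x2 system (the pressure balance rearranged to its
    stable explicit form, and the empirical delta-T balance); the residual
    is the difference between the equilibrium vapor pressure at T_i and
    the balance pressure, root-solved by a bracketed method on
    [210, 280] K.  The sublimation enthalpy is evaluated at the bottom
    product temperature via a short inner fixed point.
    """
    if ice_thickness <= 0.0:
        raise ValidationError("solve_interface requires ice_thickness > 0")
    c = setup.constants
    pc = setup.chamber_pressure
    kv = setup.kv_value
    rp = setup.rp_model.evaluate(dried_thickness)
    area_b = setup.geometry.projected_area
    area_p = geom_mod.sublimation_area(ice_thickness, setup.geometry)
    denom = 1.0 - c.conversion_b * ice_thickness
    if denom <= 0.0:
        raise SolverError(
            f"frozen-layer balance denominator 1 - b*L_ice = {denom} <= 0: "
            "model invalid for this ice thickness"
        )
    d_coef = c.conversion_a * ice_thickness / (rp * denom)
    e_coef = c.conversion_b * ice_thickness / denom

    def balance(interface_temp: float) -> tuple[float, float, float]:
        """(pressure_excess, delta_T, dh) for a trial interface temperature."""
        dh = latent_heat_sublimation(interface_temp, setup.enthalpy, warn=False)
        pressure_excess = delta_T = 0.0
        for _ in range(3):
            c_coef = area_b * kv * rp * c.molecular_weight_water / (area_p * dh)
            pressure_excess = (
                c_coef
                * (1.0 + e_coef)
                * (shelf_temp - interface_temp)
                / (1.0 + c_coef * d_coef)
            )
            delta_T = d_coef * pressure_excess - e_coef * (shelf_temp - interface_temp)
            dh = latent_heat_sublimation(
                interface_temp + delta_T, setup.enthalpy, warn=False
            )
        return pressure_excess, delta_T, dh

    def residual(interface_temp: float) -> float:
        pressure_excess, _, _ = balance(interface_temp)
        return ice_vapor_pressure(interface_temp, setup.vapor, warn=False) - (
            pc + pressure_excess
        )

    lo, hi = T_BRACKET
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0.0:
        raise SolverError(
            "no sign change for the interface balance on "
            f"[{lo}, {hi}] K (residuals {r_lo:.3g}, {r_hi:.3g}; "
            f"Ts={shelf_temp}, Pc={pc}, L_ice={ice_thickness}, "
            f"L_dr={dried_thickness}, Kv={kv}, Rp={rp})"
        )
    interface_temp = brentq(residual, lo, hi, xtol=1e-10)
    pressure_excess, delta_T, _ = balance(interface_temp)
    interface_pressure = pc + pressure_excess
    rate = max(area_p * (interface_pressure - pc) / rp, 0.0)
    return InterfaceSolution(
        interface_temp=float(interface_temp),
        delta_T=float(delta_T),
        interface_pressure=float(interface_pressure),
        sublimation_rate=float(rate),
        sublimation_area=float(area_p),
    )


def advance_state(
    state: DryingState, time_step: float, setup: SimulationSetup
) -> DryingState:
    """Advance the ice front by one time step at the state's current rate.

    The removed frozen-layer volume is ``mdot dt / (theta rho_ice)`` (only
    the ice fraction of each cake layer sublimes); the new ice level comes
    from the geometry inversion.  Clamps at zero ice (logged) and credits
    only the actually removable mass.
    """
    c = setup.constants
    total = state.ice_thickness + state.dried_thickness
    if state.sublimation_rate == 0.0:
        return replace(state, time=state.time + time_step)
    removed = (
        state.sublimation_rate
        * time_step
        / (setup.formulation.porosity * c.rho_ice)
    )
    current_volume = geom_mod.frozen_volume(state.ice_thickness, setup.geometry)
    new_volume = current_volume - removed
    if new_volume <= 0.0:
        logger.info("ice exhausted within step at t = %.0f s; clamping", state.time)
        new_volume = 0.0
        removed = current_volume
    new_ice = geom_mod.ice_thickness_from_volume(new_volume, setup.geometry)
    mass_removed = removed * setup.formulation.porosity * c.rho_ice
    return replace(
        state,
        time=state.time + time_step,
        ice_thickness=new_ice,
        dried_thickness=total - new_ice,
        sublimated_mass=state.sublimated_mass + mass_removed,
    )


@dataclass(frozen=True)
class SimulationResult:
    """Trace and completion summary of one simulated drying run."""

    trace: pd.DataFrame
    completion_time: float | None  # s; None if ice remained at max_time
    completed: bool
    sublimated_mass: float  # kg
    remaining_ice_thickness: float  # m

    @property
    def completion_hours(self) -> float | None:
        return None if self.completion_time is None else self.completion_time / 3600.0


_TRACE_COLUMNS = (
    "time_s",
    "Ts_K",
    "Tb_K",
    "Ti_K",
    "Pi_Pa",
    "Lice_m",
    "Ldr_m",
    "mdot_kg_s",
)


def simulate_protocol(
    protocol: Protocol,
    setup: SimulationSetup,
    *,
    max_time: float = 24 * 3600.0,
    end_threshold: float = END_THRESHOLD,
) -> SimulationResult:
    """March the drying model under a shelf-temperature protocol.

    Steps at ``setup.time_step`` until the ice thickness falls to
    ``end_threshold``; the completion time is linearly interpolated inside
    the final step from the remaining frozen volume.  If ``max_time`` is
    reached first, an incomplete-drying warning is issued and the partial
    trace returned.
    """
    total_thickness = setup.initial_ice_thickness
    threshold_volume = geom_mod.frozen_volume(end_threshold, setup.geometry)
    ice = total_thickness
    t = 0.0
    mass = 0.0
    dt = setup.time_step
    rows: list[tuple] = []
    completion: float | None = None

    while t <= max_time:
        shelf_temp = protocol.shelf_temperature(t)
        sol = solve_interface(shelf_temp, ice, total_thickness - ice, setup)
        rows.append(
            (
                t,
                shelf_temp,
                sol.bottom_temp,
                sol.interface_temp,
                sol.interface_pressure,
                ice,
                total_thickness - ice,
                sol.sublimation_rate,
            )
        )
        current_volume = geom_mod.frozen_volume(ice, setup.geometry)
        removable = current_volume - threshold_volume
        step_volume = (
            sol.sublimation_rate * dt / (setup.formulation.porosity * setup.constants.rho_ice)
        )
        if sol.sublimation_rate > 0.0 and step_volume >= removable:
            fraction = removable / step_volume
            completion = t + fraction * dt
            mass += (
                sol.sublimation_rate
                * fraction
                * dt
            )
            ice = end_threshold
            break
        mass += sol.sublimation_rate * dt
        ice = geom_mod.ice_thickness_from_volume(
            current_volume - step_volume, setup.geometry
        )
        t += dt

    if completion is None:
        warnings.warn(
            f"protocol ended at {max_time} s with {ice:.3e} m of ice remaining",
            stacklevel=2,
        )
    trace = pd.DataFrame(rows, columns=list(_TRACE_COLUMNS))
    return SimulationResult(
        trace=trace,
        completion_time=completion,
        completed=completion is not None,
        sublimated_mass=mass,
        remaining_ice_thickness=ice if completion is None else end_threshold,
    )
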