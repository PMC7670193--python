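"""Greedy dynamic shelf-temperature optimization of primary drying.

Every prediction interval the controller enumerates the shelf setpoints
reachable from the previous one within the machine's ramp and resolution
limits, simulates each candidate one interval ahead for the edge blister
population (the warmest, fastest-drying units), discards candidates whose
sublimation-interface temperature would exceed the collapse temperature,
and commits the feasible candidate with the highest sublimation rate.

Edge Kv coefficients guard product safety; the slower-drying center
population, simulated afterwards under the committed trajectory, defines
the total primary-drying duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geom_mod
from .errors import SolverError, ValidationError
from .simulator import (
    END_THRESHOLD,
    InterfaceSolution,
    Protocol,
    SimulationResult,
    SimulationSetup,
    simulate_protocol,
    solve_interface,
)

__all__ = [
    "MachineLimits",
    "OptimizationResult",
    "candidate_setpoints",
    "select_setpoint",
    "optimize_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MachineLimits:
    """Shelf-temperature actuation limits of the freeze-dryer."""

    max_ramp: float = 1.4  # K/min
    setpoint_resolution: float = 0.1  # K
    prediction_interval: float = 30.0  # s
    shelf_temp_max: float = 313.15  # K (40 degC)
    shelf_temp_min: float = 223.15  # K (-50 degC)

    def __post_init__(self) -> None:
        if min(self.max_ramp, self.setpoint_resolution, self.prediction_interval) <= 0:
            raise ValidationError("machine limits must be positive")
        if self.shelf_temp_min >= self.shelf_temp_max:
            raise ValidationError("shelf_temp_min must be below shelf_temp_max")
        if self.setpoint_resolution > self.max_ramp * self.prediction_interval / 60.0:
            raise ValidationError(
                "setpoint resolution coarser than one interval's ramp reach"
            )


def candidate_setpoints(previous_setpoint: float, limits: MachineLimits) -> np.ndarray:
    """Reachable setpoint grid around ``previous_setpoint`` [K], ascending.

    Steps of ``setpoint_resolution`` out to the ramp reach
    ``max_ramp * prediction_interval`` on either side, clipped to the
    absolute shelf-temperature bounds.
    """
    reach = limits.max_ramp * limits.prediction_interval / 60.0
    k_max = int(np.floor(reach / limits.setpoint_resolution + 1e-9))
    grid = previous_setpoint + limits.setpoint_resolution * np.arange(
        -k_max, k_max + 1
    )
    grid = np.clip(grid, limits.shelf_temp_min, limits.shelf_temp_max)
    return np.unique(grid)


@dataclass(frozen=True)
class SetpointChoice:
    """Outcome of one greedy setpoint selection."""

    shelf_temp: float
    solution: InterfaceSolution
    feasible: bool  # False when every candidate violated the constraint


def select_setpoint(
    candidates: np.ndarray,
    ice_thickness: float,
    dried_thickness: float,
    setup_edge: SimulationSetup,
    collapse_temp: float,
    *,
    interval: float | None = None,
) -> SetpointChoice:
    """Pick the feasible candidate with the highest sublimation rate.

    Each candidate is solved at the current state; when ``interval`` is
    given the ice front is additionally advanced one interval and the
    candidate re-solved there, so the collapse constraint is enforced at
    the end-of-interval state (the controller must not react a step late
    while the dried-layer resistance climbs).  Candidates whose
    edge-population interface temperature exceeds the collapse temperature
    are invalidated; ties break toward the colder setpoint.  If no
    candidate is feasible, the coldest one is returned flagged, so the
    controller cools as fast as the machine allows.
    """
    if ice_thickness <= 0.0:
        raise ValidationError("select_setpoint requires remaining ice")
    geometry = setup_edge.geometry
    theta_rho = setup_edge.formulation.porosity * setup_edge.constants.rho_ice
    threshold_volume = geom_mod.frozen_volume(END_THRESHOLD, geometry)
    total = ice_thickness + dried_thickness
    best: SetpointChoice | None = None
    coldest: SetpointChoice | None = None
    for shelf_temp in np.sort(candidates):
        try:
            sol = solve_interface(
                float(shelf_temp), ice_thickness, dried_thickness, setup_edge
            )
            constraint_temp = sol.interface_temp
            if interval is not None:
                volume = geom_mod.frozen_volume(ice_thickness, geometry)
                next_volume = volume - sol.sublimation_rate * interval / theta_rho
                if next_volume > threshold_volume:
                    next_ice = geom_mod.ice_thickness_from_volume(
                        next_volume, geometry
                    )
                    sol_end = solve_interface(
                        float(shelf_temp), next_ice, total - next_ice, setup_edge
                    )
                    constraint_temp = max(constraint_temp, sol_end.interface_temp)
        except SolverError as exc:
            logger.warning("candidate %.2f K discarded: %s", shelf_temp, exc)
            continue
        choice = SetpointChoice(float(shelf_temp), sol, feasible=True)
        if coldest is None:
            coldest = choice
        if constraint_temp <= collapse_temp:
            if best is None or sol.sublimation_rate > best.solution.sublimation_rate:
                best = choice
    if best is not None:
        return best
    if coldest is None:
        raise SolverError("every candidate setpoint failed to solve")
    logger.debug(
        "no feasible setpoint at L_dr = %.4g m; cooling at machine maximum",
        dried_thickness,
    )
    return SetpointChoice(coldest.shelf_temp, coldest.solution, feasible=False)


@dataclass(frozen=True)
class OptimizationResult:
    """Dynamic trajectory plus edge/center completion summaries."""

    protocol: Protocol  # staircase at prediction-interval resolution
    edge_completion_time: float  # s
    center_completion_time: float  # s
    edge_trace: pd.DataFrame
    center_trace: pd.DataFrame
    collapse_temp: float  # K
    max_edge_interface_temp: float  # K
    constraint_violated: bool
    verification_hold: float = 3600.0  # s appended when executing on hardware

    @property
    def center_completion_hours(self) -> float:
        return self.center_completion_time / 3600.0

    @property
    def edge_completion_hours(self) -> float:
        return self.edge_completion_time / 3600.0


def optimize_trajectory(
    setup_edge: SimulationSetup,
    setup_center: SimulationSetup,
    limits: MachineLimits = MachineLimits(),
    collapse_temp: float = 263.15,
    initial_shelf_temp: float = 243.15,
    *,
    max_time: float = 24 * 3600.0,
) -> OptimizationResult:
    """Greedily optimize the shelf-temperature trajectory.

    The greedy loop marches the edge setup at the prediction-interval
    resolution until its ice is exhausted; the committed setpoints form a
    staircase protocol whose last value is held.  The center setup is then
    simulated under that protocol (at its own, typically coarser, time
    step) to give the nominal primary-drying duration.
    """
    if setup_edge.geometry != setup_center.geometry:
        raise ValidationError("edge and center setups must share the geometry")
    if setup_edge.formulation != setup_center.formulation:
        raise ValidationError("edge and center setups must share the formulation")
    if not limits.shelf_temp_min <= initial_shelf_temp <= limits.shelf_temp_max:
        raise ValidationError("initial shelf temperature outside machine bounds")

    dt = limits.prediction_interval
    total_thickness = setup_edge.initial_ice_thickness
    threshold_volume = geom_mod.frozen_volume(END_THRESHOLD, setup_edge.geometry)
    theta_rho = setup_edge.formulation.porosity * setup_edge.constants.rho_ice

    ice = total_thickness
    t = 0.0
    previous = initial_shelf_temp
    times: list[float] = []
    setpoints: list[float] = []
    rows: list[tuple] = []
    max_interface_temp = -np.inf
    violated = False
    edge_completion: float | None = None

    while t <= max_time:
        choice = select_setpoint(
            candidate_setpoints(previous, limits),
            ice,
            total_thickness - ice,
            setup_edge,
            collapse_temp,
            interval=dt,
        )
        violated = violated or not choice.feasible
        sol = choice.solution
        max_interface_temp = max(max_interface_temp, sol.interface_temp)
        times.append(t)
        setpoints.append(choice.shelf_temp)
        rows.append(
            (
                t,
                choice.shelf_temp,
                sol.bottom_temp,
                sol.interface_temp,
                sol.interface_pressure,
                ice,
                total_thickness - ice,
                sol.sublimation_rate,
                choice.feasible,
            )
        )
        previous = choice.shelf_temp

        current_volume = geom_mod.frozen_volume(ice, setup_edge.geometry)
        removable = current_volume - threshold_volume
        step_volume = sol.sublimation_rate * dt / theta_rho
        if sol.sublimation_rate > 0.0 and step_volume >= removable:
            edge_completion = t + (removable / step_volume) * dt
            break
        ice = geom_mod.ice_thickness_from_volume(
            current_volume - step_volume, setup_edge.geometry
        )
        t += dt

    if edge_completion is None:
        raise SolverError(
            f"edge population not dry within the {max_time} s horizon"
        )
    if violated:
        n_flagged = sum(1 for row in rows if not row[-1])
        logger.warning(
            "collapse constraint unattainable for %d of %d intervals "
            "(machine-limited cooling); max edge interface temperature "
            "%.3f K vs limit %.3f K",
            n_flagged,
            len(rows),
            max_interface_temp,
            collapse_temp,
        )

    protocol = Protocol(
        times=np.array(times), setpoints=np.array(setpoints), interpolation="previous"
    )
    center: SimulationResult = simulate_protocol(
        protocol, setup_center, max_time=max_time
    )
    if not center.completed:
        raise SolverError(
            f"center population not dry within the {max_time} s horizon"
        )
    edge_trace = pd.DataFrame(
        rows,
        columns=[
            "time_s",
            "Ts_K",
            "Tb_K",
            "Ti_K",
            "Pi_Pa",
            "Lice_m",
            "Ldr_m",
            "mdot_kg_s",
            "feasible",
        ],
    )
    return OptimizationResult(
        protocol=protocol,
        edge_completion_time=float(edge_completion),
        center_completion_time=float(center.completion_time),
        edge_trace=edge_trace,
        center_trace=center.trace,
        collapse_temp=collapse_temp,
        max_edge_interface_temp=float(max_interface_temp),
        constraint_violated=violated,
    )
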