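"""Synthetic gravimetric runs and process traces from known ground truth.

The estimation pipelines (Kv and Rp) are exercised end-to-end without any
experimental data by generating the two experiment types they consume:

* gravimetric heat-transfer runs: water-filled pockets partially sublimated
  at several chamber pressures, with per-blister Kv dispersion emulating
  the large blister-to-blister contact variability, plus thermocouple and
  weighing noise;
* full process traces of a conservative drying cycle consistent with a
  known Rp(L_dr) law, including a Pirani/capacitance pressure pair whose
  ratio decays to one as sublimation ends.

Process traces use the Fourier-conduction closure for the frozen-layer
temperature drop - the same relation the estimation pipeline inverts - so
that at zero noise the pipeline recovers the generating parameters exactly
up to time discretization.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import geometry as geom_mod
from .errors import ValidationError
from .geometry import BlisterGeometry
from .kv_estimation import KvPressureModel, GravimetricRun
from .rp_estimation import FormulationSpec, ProcessTrace, RpModel, TRACE_COLUMNS
from .simulator import Protocol, SimulationSetup, simulate_protocol
from .thermo import (
    PhysicalConstants,
    SublimationEnthalpyModel,
    VaporPressureModel,
    ice_vapor_pressure,
    latent_heat_sublimation,
)

__all__ = ["SyntheticSpec", "generate_gravimetric_runs", "generate_process_trace"]

#: Printed reference coefficients for the two blister populations.
REFERENCE_KV_EDGE = KvPressureModel(
    alpha=10.1917, beta=1.1408, gamma=0.0614, population="edge"
)
REFERENCE_KV_CENTER = KvPressureModel(
    alpha=12.7208, beta=0.3015, gamma=0.0261, population="center"
)
#: Printed high-dose Rp coefficients.
REFERENCE_RP_HIGHDOSE = RpModel(rp0=7.05e4, a=1.92e8, b=-68.30)

REFERENCE_GEOMETRY = BlisterGeometry(
    total_length=40.5e-3, chord_length=23.5e-3, height=7.2e-3
)
#: Resistance-characterization fill: 2.5 mL of the high-dose suspension.
REFERENCE_FORMULATION = FormulationSpec(
    label="high-dose",
    solids={"drug": 33.00, "pva": 3.39, "mannitol": 2.76, "xanthan": 0.075},
    fill_volume=2.5e-6,
)

#: Sublimation of open water is essentially resistance-free; a tiny
#: constant stands in for Rp in the pure-ice gravimetric simulations.
PURE_ICE_RP = RpModel(rp0=1e3, a=0.0, b=0.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise model for the synthetic experiments."""

    kv_edge: KvPressureModel = REFERENCE_KV_EDGE
    kv_center: KvPressureModel = REFERENCE_KV_CENTER
    rp_model: RpModel = REFERENCE_RP_HIGHDOSE
    geometry: BlisterGeometry = REFERENCE_GEOMETRY
    formulation: FormulationSpec = REFERENCE_FORMULATION
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    enthalpy: SublimationEnthalpyModel = field(default_factory=SublimationEnthalpyModel)
    vapor: VaporPressureModel = field(default_factory=VaporPressureModel)
    chamber_pressure: float = 10.0  # Pa
    time_step: float = 60.0  # s
    water_fill_volume: float = 2.3e-6  # m^3 per gravimetric blister
    kv_dispersion: float = 0.10  # relative per-blister spread
    temperature_sigma: float = 0.1  # K thermocouple noise
    weighing_sigma: float = 1e-6  # kg balance noise
    ratio_sigma: float = 0.005  # relative Pirani noise
    pirani_overread: float = 0.6  # Pirani over-read factor in water vapor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "kv_dispersion",
            "temperature_sigma",
            "weighing_sigma",
            "ratio_sigma",
        ):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be nonnegative")


def _water_formulation(spec: SyntheticSpec) -> FormulationSpec:
    return FormulationSpec(
        label="water", solids={}, fill_volume=spec.water_fill_volume
    )


def generate_gravimetric_runs(
    spec: SyntheticSpec,
    pressures: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0),
    n_blisters: int = 20,
    *,
    population: str = "center",
    seed: int | None = None,
    hold_duration: float = 2.5 * 3600.0,
) -> tuple[list[GravimetricRun], dict]:
    """Simulate water-filled gravimetric Kv runs at several pressures.

    Each blister draws its own Kv around the truth-model value (relative
    dispersion ``spec.kv_dispersion``), is sublimated from -30 degC up to a
    -15 degC hold for ``hold_duration``, and reports its noisy sublimated
    mass and bottom-temperature trace.  The truth record carries the
    generating model and every per-blister Kv.
    """
    if n_blisters < 1:
        raise ValidationError("n_blisters must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth_model = spec.kv_center if population == "center" else spec.kv_edge
    formulation = _water_formulation(spec)
    water_constants = replace(spec.constants, rho_solution=1000.0)
    protocol = Protocol.ramp_hold(243.15, 258.15, ramp_rate=1.4)
    duration = float(protocol.times[-1]) + hold_duration

    runs: list[GravimetricRun] = []
    truth: dict = {"model": truth_model, "population": population, "blisters": {}}
    for pc in pressures:
        kv_nominal = truth_model.evaluate(pc, warn=False)
        for j in range(n_blisters):
            kv_true = kv_nominal * (1.0 + rng.normal(0.0, spec.kv_dispersion))
            setup = SimulationSetup(
                geometry=spec.geometry,
                formulation=formulation,
                kv=kv_true,
                rp_model=PURE_ICE_RP,
                chamber_pressure=pc,
                time_step=spec.time_step,
                constants=water_constants,
                enthalpy=spec.enthalpy,
                vapor=spec.vapor,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # partial sublimation intended
                result = simulate_protocol(protocol, setup, max_time=duration)
            if result.completed:
                raise ValidationError(
                    "gravimetric run sublimated the whole fill; shorten the "
                    "hold or increase the fill volume"
                )
            trace = result.trace[["time_s", "Ts_K", "Tb_K"]].copy()
            trace["Tb_K"] += rng.normal(0.0, spec.temperature_sigma, len(trace))
            mass = result.sublimated_mass + rng.normal(0.0, spec.weighing_sigma)
            blister_id = f"{population}-P{pc:g}-{j:03d}"
            runs.append(
                GravimetricRun(
                    blister_id=blister_id,
                    position_class=population,  # type: ignore[arg-type]
                    sublimated_mass=float(mass),
                    chamber_pressure=float(pc),
                    trace=trace,
                    projected_area=spec.geometry.projected_area,
                )
            )
            truth["blisters"][blister_id] = {
                "kv_true": float(kv_true),
                "sublimated_mass_true": float(result.sublimated_mass),
            }
    return runs, truth


def _bottom_temp_fourier(
    shelf_temp: float,
    ice_thickness: float,
    dried_thickness: float,
    kv: float,
    spec: SyntheticSpec,
) -> tuple[float, float]:
    """Quasi-steady (T_b, mdot) under the Fourier frozen-layer closure.

    Finds the bottom temperature at which the heat-limited sublimation
    rate pushed through the dried layer (truth Rp) raises the interface
    vapor pressure to exactly the equilibrium value at the Fourier
    interface temperature.
    """
    c = spec.constants
    area_b = spec.geometry.projected_area
    area_p = geom_mod.sublimation_area(ice_thickness, spec.geometry)
    rp = spec.rp_model.evaluate(dried_thickness)
    pc = spec.chamber_pressure

    def rate(bottom_temp: float) -> float:
        dh = latent_heat_sublimation(bottom_temp, spec.enthalpy, warn=False)
        return (
            kv
            * area_b
            * c.molecular_weight_water
            * (shelf_temp - bottom_temp)
            / dh
        )

    def residual(bottom_temp: float) -> float:
        interface_temp = bottom_temp - (
            shelf_temp - bottom_temp
        ) * kv * ice_thickness / c.lambda_ice
        return area_p * (
            ice_vapor_pressure(interface_temp, spec.vapor, warn=False) - pc
        ) - rate(
            bottom_temp
        ) * rp

    upper = shelf_temp - 1e-9
    if residual(upper) <= 0.0:  # shelf too cold to sustain sublimation
        return shelf_temp, 0.0
    bottom_temp = brentq(residual, 205.0, upper, xtol=1e-11)
    return float(bottom_temp), float(rate(bottom_temp))


def generate_process_trace(
    spec: SyntheticSpec,
    protocol: Protocol | None = None,
    *,
    seed: int | None = None,
    tail_duration: float = 2 * 3600.0,
    max_time: float = 72 * 3600.0,
) -> tuple[ProcessTrace, dict]:
    """Forward-simulate a drying cycle into a noisy process trace.

    Default protocol is the conservative resistance-characterization
    cycle: -30 degC ramped to -25 degC over 30 min, then held until the
    frozen layer is exhausted (center-population Kv).  The emitted trace
    carries bottom-temperature noise and a synthetic Pirani channel
    ``P_pir = P_cap (1 + r s(t))`` with ``s`` the normalized sublimation
    rate, so the pressure ratio decays to one at the endpoint.  The truth
    record holds the exact exhaustion time and the noiseless ratio
    midpoint.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if protocol is None:
        protocol = Protocol(
            times=np.array([0.0, 1800.0]), setpoints=np.array([243.15, 248.15])
        )
    kv = spec.kv_center.evaluate(spec.chamber_pressure, warn=False)
    dt = spec.time_step
    c = spec.constants
    theta = spec.formulation.porosity
    frozen0 = spec.formulation.fill_volume * c.rho_solution / c.rho_ice
    if frozen0 > spec.geometry.full_volume:
        raise ValidationError("fill volume exceeds pocket capacity")
    ice = geom_mod.ice_thickness_from_volume(frozen0, spec.geometry)
    initial_ice = ice

    times: list[float] = []
    shelf: list[float] = []
    bottom: list[float] = []
    rates: list[float] = []
    t = 0.0
    exhaustion_time = None
    while t <= max_time:
        shelf_temp = protocol.shelf_temperature(t)
        bottom_temp, rate = _bottom_temp_fourier(
            shelf_temp, ice, initial_ice - ice, kv, spec
        )
        times.append(t)
        shelf.append(shelf_temp)
        bottom.append(bottom_temp)
        rates.append(rate)
        volume = geom_mod.frozen_volume(ice, spec.geometry)
        step_volume = rate * dt / (theta * c.rho_ice)
        if rate > 0.0 and step_volume >= volume:
            exhaustion_time = t + (volume / step_volume) * dt
            break
        ice = geom_mod.ice_thickness_from_volume(volume - step_volume, spec.geometry)
        t += dt
    if exhaustion_time is None:
        raise ValidationError(
            f"protocol did not dry the product within {max_time} s"
        )

    # post-exhaustion tail: thermocouple couples to the shelf, rate is zero
    tail_steps = int(tail_duration / dt)
    for k in range(1, tail_steps + 1):
        tk = times[-1] + dt
        times.append(tk)
        shelf.append(protocol.shelf_temperature(tk))
        bottom.append(shelf[-1])
        rates.append(0.0)

    times_arr = np.array(times)
    rates_arr = np.array(rates)
    s = rates_arr / rates_arr.max()
    ratio_true = 1.0 + spec.pirani_overread * s
    cap = np.full_like(times_arr, spec.chamber_pressure)
    pir = cap * ratio_true * (1.0 + rng.normal(0.0, spec.ratio_sigma, len(times_arr)))
    data = pd.DataFrame(
        {
            "time_s": times_arr,
            "Ts_K": np.array(shelf),
            "Tb_K": np.array(bottom)
            + rng.normal(0.0, spec.temperature_sigma, len(times_arr)),
            "Pc_cap_Pa": cap,
            "Pc_pir_Pa": pir,
        }
    )
    truth = {
        "kv": float(kv),
        "rp_model": spec.rp_model,
        "exhaustion_time_s": float(exhaustion_time),
        "initial_ice_thickness_m": float(initial_ice),
        "ratio_midpoint_time_s": _ratio_midpoint(times_arr, ratio_true),
        "seed": int(spec.seed if seed is None else seed),
    }
    metadata = {"synthetic": True, **{k: v for k, v in truth.items() if k != "rp_model"}}
    return ProcessTrace(data=data, metadata=metadata), truth


def _ratio_midpoint(times: np.ndarray, ratio: np.ndarray) -> float:
    """Halfway-crossing time of a noiseless ratio curve (same rule as the
    endpoint detector)."""
    k = max(len(ratio) // 10, 3)
    high = float(np.median(ratio[:k]))
    low = float(np.median(ratio[-k:]))
    halfway = 0.5 * (high + low)
    below = ratio <= halfway
    i = int(np.flatnonzero(below[1:] & ~below[:-1])[0]) + 1
    frac = (ratio[i - 1] - halfway) / (ratio[i - 1] - ratio[i])
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))
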