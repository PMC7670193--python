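"""Dried-product mass-resistance (Rp) estimation from thermocouple traces.

During primary drying the receding ice front leaves behind a porous dried
layer whose resistance to vapor flow, Rp [m/s], grows with the dried-layer
thickness L_dr.  The pipeline reconstructs the Rp(L_dr) curve from a
recorded process trace:

1. invert the heat-transfer relation to get the sublimation rate from the
   shelf-to-bottom temperature difference;
2. accumulate sublimated volume (divided by the cake porosity) and solve
   the blister geometry for the instantaneous frozen-layer thickness;
3. estimate the interface temperature by Fourier conduction through the
   frozen layer, and from it the interface vapor pressure;
4. Rp = A_p (P_i - P_c) / mdot at each time point.

The resulting curve is regressed with Rp = Rp0 + A L_dr / (1 + B L_dr),
truncated to the first few millimetres where thermocouple readings are
trustworthy.  A Pirani/capacitance pressure-ratio endpoint detector for
the end of sublimation is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import geometry as geom_mod
from .errors import EndpointError, FitError, TraceError, ValidationError
from .geometry import BlisterGeometry
from .thermo import (
    PhysicalConstants,
    SublimationEnthalpyModel,
    VaporPressureModel,
    ice_vapor_pressure,
    latent_heat_sublimation,
)

__all__ = [
    "FormulationSpec",
    "ProcessTrace",
    "RpModel",
    "RpCurve",
    "TRACE_COLUMNS",
    "porosity_from_composition",
    "sublimation_rate_trace",
    "dried_volume_cumulative",
    "ice_thickness_trace",
    "interface_temperature",
    "rp_trace",
    "fit_rp_model",
    "endpoint_from_pressure_ratio",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_s", "Ts_K", "Tb_K", "Pc_cap_Pa", "Pc_pir_Pa")

#: Default truncation of the Rp(L_dr) regression range [m]; beyond this the
#: thermocouple-derived curve shows an artifactual exponential upswing.
DEFAULT_FIT_RANGE = 4.5e-3


def porosity_from_composition(fractions: Mapping[str, float]) -> float:
    """Porosity of the dried cake from bulk-suspension mass fractions.

    The porosity is approximated by the water mass fraction of the initial
    suspension: ``theta = 1 - sum(solid %w/w)/100``.  ``fractions`` maps
    component names to %w/w values; a ``"water"`` entry is optional
    (ad-100), but if present the total must close to 100 +/- 0.01.
    """
    solids = {k: v for k, v in fractions.items() if k.lower() != "water"}
    if any(v < 0.0 for v in fractions.values()):
        raise ValidationError("mass fractions must be nonnegative")
    solid_total = sum(solids.values())
    if "water" in {k.lower() for k in fractions}:
        water = next(v for k, v in fractions.items() if k.lower() == "water")
        total = solid_total + water
        if abs(total - 100.0) > 0.01:
            raise ValidationError(
                f"mass fractions sum to {total} %w/w, expected 100 +/- 0.01"
            )
    elif solid_total > 100.0:
        raise ValidationError(
            f"solid fractions sum to {solid_total} %w/w, exceeding 100"
        )
    theta = 1.0 - solid_total / 100.0
    if not 0.0 < theta <= 1.0:
        raise ValidationError(f"derived porosity {theta} outside (0, 1]")
    return theta


@dataclass(frozen=True)
class FormulationSpec:
    """A bulk suspension dosed into the blister pocket.

    ``solids`` maps component names (drug, binder, bulking agent, ...) to
    %w/w mass fractions; water makes up the remainder.  ``porosity``
    defaults to the water mass fraction of the suspension.
    """

    label: str
    solids: Mapping[str, float]
    fill_volume: float  # m^3
    porosity: float | None = None

    def __post_init__(self) -> None:
        if self.fill_volume <= 0.0:
            raise ValidationError("fill_volume must be positive")
        derived = porosity_from_composition(dict(self.solids))
        if self.porosity is None:
            object.__setattr__(self, "porosity", derived)
        elif not 0.0 < self.porosity <= 1.0:
            raise ValidationError(f"porosity {self.porosity} outside (0, 1]")


@dataclass(frozen=True)
class ProcessTrace:
    """A recorded (or synthesized) primary-drying process trace.

    ``data`` must hold the columns ``time_s, Ts_K, Tb_K, Pc_cap_Pa,
    Pc_pir_Pa`` with strictly increasing time.  ``metadata`` carries
    free-form provenance (Kv model, geometry, formulation, seed).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TRACE_COLUMNS) - set(self.data.columns)
        if missing:
            raise TraceError(f"trace missing columns {sorted(missing)}")
        t = self.data["time_s"].to_numpy(float)
        if len(t) < 2:
            raise TraceError("trace needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise TraceError("trace time must be strictly increasing")


@dataclass(frozen=True)
class RpModel:
    """Dried-layer resistance model ``Rp(L_dr) = Rp0 + A L_dr/(1 + B L_dr)``.

    ``B`` may be negative; the model is only valid where ``1 + B L_dr > 0``,
    which is enforced on ``[0, fit_range_max]``.
    """

    rp0: float  # m/s
    a: float  # 1/s
    b: float  # 1/m
    rmse: float | None = None
    fit_range_max: float = DEFAULT_FIT_RANGE

    def __post_init__(self) -> None:
        for level in np.linspace(0.0, self.fit_range_max, 10):
            if 1.0 + self.b * level <= 0.0:
                raise ValidationError(
                    f"Rp model singular at L_dr = {level} m inside its fit range"
                )
            if self._evaluate(float(level)) <= 0.0:
                raise ValidationError(
                    f"Rp model non-positive at L_dr = {level} m"
                )

    def _evaluate(self, dried_thickness: float) -> float:
        return self.rp0 + self.a * dried_thickness / (1.0 + self.b * dried_thickness)

    def evaluate(self, dried_thickness) -> float | np.ndarray:
        """Rp [m/s] at dried-layer thickness ``dried_thickness`` [m]."""
        denom = 1.0 + self.b * np.asarray(dried_thickness, float)
        if np.any(denom <= 0.0):
            raise ValidationError(
                "Rp model evaluated beyond its singularity (1 + B L_dr <= 0)"
            )
        out = self.rp0 + self.a * np.asarray(dried_thickness, float) / denom
        return float(out) if np.isscalar(dried_thickness) else out


@dataclass(frozen=True)
class RpCurve:
    """Paired dried-layer thickness and resistance series from one trace."""

    dried_thickness: np.ndarray  # m
    resistance: np.ndarray  # m/s
    time_s: np.ndarray
    n_dropped: int = 0


def sublimation_rate_trace(
    trace: ProcessTrace,
    kv: float,
    projected_area: float,
    enthalpy: SublimationEnthalpyModel = SublimationEnthalpyModel(),
    molecular_weight: float = PhysicalConstants.molecular_weight_water,
) -> np.ndarray:
    """Sublimation-rate series [kg/s] by inverting the heat-transfer relation.

    ``mdot(t) = Kv A_b M (T_s - T_b) / dH_sub(T_b)``; negative values
    (product warmer than shelf) are clipped to zero and counted in the log.
    """
    ts = trace.data["Ts_K"].to_numpy(float)
    tb = trace.data["Tb_K"].to_numpy(float)
    dh = np.array([latent_heat_sublimation(x, enthalpy) for x in tb])
    rate = kv * projected_area * molecular_weight * (ts - tb) / dh
    negative = int(np.sum(rate < 0.0))
    if negative:
        logger.info("clipped %d negative sublimation-rate points to zero", negative)
    return np.clip(rate, 0.0, None)


def dried_volume_cumulative(
    rates: np.ndarray, time_step: float, porosity: float, rho_ice: float
) -> np.ndarray:
    """Cumulative sublimated (frozen-layer) volume series [m^3].

    ``V_i = sum_{t0..ti} mdot dt / (theta rho_ice)``: the ice removed from
    a cake layer of porosity ``theta`` frees the whole layer volume, hence
    the porosity division.  Nondecreasing by construction.
    """
    if not 0.0 < porosity <= 1.0:
        raise ValidationError(f"porosity {porosity} outside (0, 1]")
    return np.cumsum(np.asarray(rates, float) * time_step) / (porosity * rho_ice)


def ice_thickness_trace(
    volumes: np.ndarray,
    fill_volume: float,
    rho_solution: float,
    rho_ice: float,
    geometry: BlisterGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen-layer thickness and dried-layer thickness series [m].

    The initial frozen volume is the fill expanded by the solution-to-ice
    density ratio; each cumulative sublimated volume is subtracted and the
    geometry root-solved for the remaining ice level.  If the frozen volume
    is exhausted mid-trace the series is truncated there (logged).
    """
    frozen0 = fill_volume * rho_solution / rho_ice
    if frozen0 > geometry.full_volume * (1.0 + 1e-9):
        raise ValidationError(
            f"initial frozen volume {frozen0} m^3 exceeds pocket capacity "
            f"{geometry.full_volume} m^3"
        )
    remaining = frozen0 - np.asarray(volumes, float)
    exhausted = remaining <= 0.0
    if np.any(exhausted):
        cut = int(np.argmax(exhausted))
        logger.info("frozen volume exhausted at sample %d; truncating series", cut)
        remaining = remaining[:cut]
    levels = np.array(
        [geom_mod.ice_thickness_from_volume(v, geometry) for v in remaining]
    )
    # the dried thickness is referenced to the series' own first level, so
    # the cumulative-sum convention cancels out of L_dr
    if len(levels) == 0:
        return levels, levels
    return levels, levels[0] - levels


def interface_temperature(
    bottom_temp: float,
    shelf_temp: float,
    kv: float,
    ice_thickness: float,
    lambda_ice: float = PhysicalConstants.lambda_ice,
) -> float:
    """Sublimation-interface temperature [K] by Fourier conduction.

    The shelf heat flux ``Kv (T_s - T_b)`` conducts through the frozen
    layer: ``T_i = T_b - (T_s - T_b) Kv L_ice / lambda_ice``.
    """
    if ice_thickness < 0.0:
        raise ValidationError("ice_thickness must be nonnegative")
    return bottom_temp - (shelf_temp - bottom_temp) * kv * ice_thickness / lambda_ice


def rp_trace(
    trace: ProcessTrace,
    geometry: BlisterGeometry,
    kv: float,
    formulation: FormulationSpec,
    constants: PhysicalConstants = PhysicalConstants(),
    enthalpy: SublimationEnthalpyModel = SublimationEnthalpyModel(),
    vapor: VaporPressureModel = VaporPressureModel(),
) -> RpCurve:
    """Full pipeline from a process trace to an Rp-versus-L_dr curve.

    Chains rate inversion, cumulative volume, geometry inversion, Fourier
    interface temperature, interface vapor pressure and the resistance
    definition ``Rp = A_p (P_i - P_c) / mdot``.  Points with non-positive
    rate or ``P_i <= P_c`` are dropped (the definition is undefined there)
    and counted.
    """
    time = trace.data["time_s"].to_numpy(float)
    steps = np.diff(time)
    time_step = float(np.median(steps))
    ts = trace.data["Ts_K"].to_numpy(float)
    tb = trace.data["Tb_K"].to_numpy(float)
    pc = trace.data["Pc_cap_Pa"].to_numpy(float)

    rates = sublimation_rate_trace(
        trace, kv, geometry.projected_area, enthalpy, constants.molecular_weight_water
    )
    volumes = dried_volume_cumulative(
        rates, time_step, formulation.porosity, constants.rho_ice
    )
    ice_levels, dried = ice_thickness_trace(
        volumes,
        formulation.fill_volume,
        constants.rho_solution,
        constants.rho_ice,
        geometry,
    )
    n = len(ice_levels)

    interface_temps = np.array(
        [
            interface_temperature(tb[i], ts[i], kv, ice_levels[i], constants.lambda_ice)
            for i in range(n)
        ]
    )
    interface_pressures = np.array(
        [ice_vapor_pressure(t, vapor) for t in interface_temps]
    )
    areas = np.array([geom_mod.sublimation_area(lv, geometry) for lv in ice_levels])

    valid = (rates[:n] > 0.0) & (interface_pressures > pc[:n])
    n_dropped = int(n - np.sum(valid))
    if n_dropped:
        logger.info(
            "dropped %d trace points with mdot <= 0 or P_i <= P_c", n_dropped
        )
    resistance = (
        areas[valid] * (interface_pressures[valid] - pc[:n][valid]) / rates[:n][valid]
    )
    return RpCurve(
        dried_thickness=dried[valid],
        resistance=resistance,
        time_s=time[:n][valid],
        n_dropped=n_dropped,
    )


def _rp_form(dried, rp0, a, b):
    return rp0 + a * dried / (1.0 + b * dried)


def fit_rp_model(curve: RpCurve, max_dried_thickness: float = DEFAULT_FIT_RANGE) -> RpModel:
    """Unweighted nonlinear fit of the Rp(L_dr) model on a truncated curve.

    Only points with ``L_dr <= max_dried_thickness`` are used (at least
    four required).  The fit is rejected if the fitted hyperbola is
    singular anywhere on the fit range.
    """
    mask = curve.dried_thickness <= max_dried_thickness
    dried = curve.dried_thickness[mask]
    resistance = curve.resistance[mask]
    if len(dried) < 4:
        raise FitError(
            f"Rp fit needs >= 4 points with L_dr <= {max_dried_thickness} m, "
            f"got {len(dried)}"
        )
    span = float(dried.max() - dried.min()) or max_dried_thickness
    slope0 = (float(resistance[-1]) - float(resistance[0])) / span
    p0 = [max(float(resistance.min()), 1.0), max(slope0, 1.0), 0.0]
    # keep the hyperbola regular on the fit range: 1 + B L_dr > 0
    b_floor = -0.999 / float(dried.max() if dried.max() > 0 else max_dried_thickness)
    try:
        popt, pcov = curve_fit(
            _rp_form,
            dried,
            resistance,
            p0=p0,
            bounds=([0.0, 0.0, b_floor], [np.inf, np.inf, np.inf]),
            maxfev=40000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy nonconvergence
        raise FitError(f"Rp fit did not converge: {exc}") from exc
    rp0, a, b = (float(v) for v in popt)
    if np.any(1.0 + b * dried <= 0.0):
        raise FitError(
            f"fitted Rp model singular on the fit range (B = {b:.4g} 1/m)"
        )
    rmse = float(np.sqrt(np.mean((resistance - _rp_form(dried, *popt)) ** 2)))
    return RpModel(rp0=rp0, a=a, b=b, rmse=rmse, fit_range_max=max_dried_thickness)


def endpoint_from_pressure_ratio(trace: ProcessTrace) -> float:
    """Primary-drying endpoint [s] from the Pirani/capacitance ratio midpoint.

    A Pirani gauge over-reads in water vapor, so the ratio
    ``P_pir / P_cap`` sits above one while sublimation is active and decays
    to one as it ends.  Plateau levels are estimated as medians of the
    first and last 10% of the trace; the endpoint is the first time the
    ratio crosses halfway between them (linear interpolation between
    samples).
    """
    time = trace.data["time_s"].to_numpy(float)
    ratio = (
        trace.data["Pc_pir_Pa"].to_numpy(float)
        / trace.data["Pc_cap_Pa"].to_numpy(float)
    )
    k = max(len(ratio) // 10, 3)
    high = float(np.median(ratio[:k]))
    low = float(np.median(ratio[-k:]))
    if high - low < 0.02 * high:
        raise EndpointError(
            f"pressure-ratio plateaus indistinguishable (high {high:.4f}, "
            f"low {low:.4f}): no endpoint detected"
        )
    halfway = 0.5 * (high + low)
    below = ratio <= halfway
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        raise EndpointError("trace starts below the halfway ratio level")
    if len(crossings) == 0:
        raise EndpointError("pressure ratio never crosses the halfway level")
    i = int(crossings[0])
    frac = (ratio[i - 1] - halfway) / (ratio[i - 1] - ratio[i])
    return float(time[i - 1] + frac * (time[i] - time[i - 1]))
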