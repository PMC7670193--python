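"""Structured run configuration: TOML loading, units, validation.

All quantities are SI internally.  Config files may tag values with units
as ``"23.5 mm"`` or ``"-10 C"`` strings; bare numbers are taken as SI
(metres, kelvin, pascal, seconds, cubic metres).  Two reference configs
(``paper_highdose``, ``paper_lowdose``) bundle the printed parameter sets
of the modeled blister product so simulations and optimizations are
one-command runs.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict
from pydantic import ValidationError as PydanticValidationError

from .errors import ConfigError
from .geometry import BlisterGeometry
from .kv_estimation import KvPressureModel
from .optimizer import MachineLimits
from .rp_estimation import FormulationSpec, RpModel
from .simulator import Protocol, SimulationSetup
from .thermo import PhysicalConstants, SublimationEnthalpyModel, VaporPressureModel

__all__ = ["RunConfig", "load_config", "load_reference_config", "parse_quantity"]

logger = logging.getLogger(__name__)

_SCALE = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3},
    "volume": {"m3": 1.0, "L": 1e-3, "l": 1e-3, "mL": 1e-6, "ml": 1e-6},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "mbar": 1e2},
    "time": {"s": 1.0, "min": 60.0, "h": 3600.0},
}


def parse_quantity(value: float | int | str, kind: str) -> float:
    """Convert a config value to SI.

    Numbers pass through unchanged (assumed SI).  Strings must be
    ``"<number> <unit>"``; temperature accepts ``K`` and ``C``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) != 2:
        raise ConfigError(f"malformed quantity {value!r}: expected '<number> <unit>'")
    try:
        number = float(parts[0])
    except ValueError as exc:
        raise ConfigError(f"malformed quantity {value!r}") from exc
    unit = parts[1]
    if kind == "temperature":
        if unit == "K":
            return number
        if unit == "C":
            return number + 273.15
        raise ConfigError(f"unknown temperature unit {unit!r} in {value!r}")
    scales = _SCALE.get(kind)
    if scales is None or unit not in scales:
        raise ConfigError(f"unknown {kind} unit {unit!r} in {value!r}")
    return number * scales[unit]


Quantity = float | str


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometrySection(_Section):
    # required when a [geometry] section is given; the RunConfig default
    # supplies the reference blister dimensions
    total_length: Quantity
    chord_length: Quantity
    height: Quantity


class FormulationSection(_Section):
    label: str = "high-dose"
    solids: dict[str, float] = {
        "drug": 33.00,
        "pva": 3.39,
        "mannitol": 2.76,
        "xanthan": 0.075,
    }
    fill_volume: Quantity = "1.52 mL"
    porosity: float | None = None  # derived from solids when omitted


class ConstantsSection(_Section):
    molecular_weight_water: float = 18.01528e-3
    rho_ice: float = 918.0
    rho_solution: float = 1018.0
    lambda_ice: float = 2.3
    conversion_a: float = 889_200.0
    conversion_b: float = 1.02


class EnthalpySection(_Section):
    alpha: float = 4.68e4
    beta: float = 35.9
    gamma: float = 0.0741
    delta: float = 542.0
    epsilon: float = 124.0


class VaporPressureSection(_Section):
    alpha: float = 9.550426
    beta: float = 5723.2658
    gamma: float = 3.53068
    delta: float = 0.00728332


class KvCoefficients(_Section):
    alpha: float
    beta: float
    gamma: float


class KvSection(_Section):
    edge: KvCoefficients = KvCoefficients(alpha=10.1917, beta=1.1408, gamma=0.0614)
    center: KvCoefficients = KvCoefficients(alpha=12.7208, beta=0.3015, gamma=0.0261)
    pressure_range: tuple[float, float] = (10.0, 30.0)


class RpSection(_Section):
    rp0: float = 7.05e4
    a: float = 1.92e8
    b: float = -68.30
    fit_range_max: Quantity = "4.5 mm"


class ProcessSection(_Section):
    chamber_pressure: Quantity = "10 Pa"
    time_step: Quantity = "60 s"
    collapse_temperature: Quantity = "-10 C"


class MachineSection(_Section):
    max_ramp: float = 1.4  # K/min
    setpoint_resolution: float = 0.1  # K
    prediction_interval: Quantity = "30 s"
    shelf_temp_max: Quantity = "40 C"
    shelf_temp_min: Quantity = "-50 C"


class OptimizerSection(_Section):
    initial_shelf_temp: Quantity = "-30 C"


class ProtocolSection(_Section):
    start: Quantity = "-30 C"
    hold: Quantity = "-10 C"
    ramp_rate: float = 0.25  # K/min


class RunConfig(_Section):
    """Validated, unit-normalized run configuration."""

    geometry: GeometrySection = GeometrySection(
        total_length="40.5 mm", chord_length="23.5 mm", height="7.2 mm"
    )
    formulation: FormulationSection = FormulationSection()
    constants: ConstantsSection = ConstantsSection()
    enthalpy: EnthalpySection = EnthalpySection()
    vapor_pressure: VaporPressureSection = VaporPressureSection()
    kv: KvSection = KvSection()
    rp: RpSection = RpSection()
    process: ProcessSection = ProcessSection()
    machine: MachineSection = MachineSection()
    optimizer: OptimizerSection = OptimizerSection()
    protocol: ProtocolSection = ProtocolSection()

    # -- builders -------------------------------------------------------

    def build_geometry(self) -> BlisterGeometry:
        g = self.geometry
        return BlisterGeometry(
            total_length=parse_quantity(g.total_length, "length"),
            chord_length=parse_quantity(g.chord_length, "length"),
            height=parse_quantity(g.height, "length"),
        )

    def build_formulation(self) -> FormulationSpec:
        f = self.formulation
        return FormulationSpec(
            label=f.label,
            solids=f.solids,
            fill_volume=parse_quantity(f.fill_volume, "volume"),
            porosity=f.porosity,
        )

    def build_constants(self) -> PhysicalConstants:
        return PhysicalConstants(**self.constants.model_dump())

    def build_enthalpy(self) -> SublimationEnthalpyModel:
        return SublimationEnthalpyModel(**self.enthalpy.model_dump())

    def build_vapor(self) -> VaporPressureModel:
        return VaporPressureModel(**self.vapor_pressure.model_dump())

    def build_kv_model(self, population: Literal["edge", "center"]) -> KvPressureModel:
        coeffs = getattr(self.kv, population)
        return KvPressureModel(
            alpha=coeffs.alpha,
            beta=coeffs.beta,
            gamma=coeffs.gamma,
            population=population,
            valid_pressure_range=self.kv.pressure_range,
        )

    def build_rp_model(self) -> RpModel:
        return RpModel(
            rp0=self.rp.rp0,
            a=self.rp.a,
            b=self.rp.b,
            fit_range_max=parse_quantity(self.rp.fit_range_max, "length"),
        )

    def build_setup(self, population: Literal["edge", "center"]) -> SimulationSetup:
        return SimulationSetup(
            geometry=self.build_geometry(),
            formulation=self.build_formulation(),
            kv=self.build_kv_model(population),
            rp_model=self.build_rp_model(),
            chamber_pressure=parse_quantity(self.process.chamber_pressure, "pressure"),
            time_step=parse_quantity(self.process.time_step, "time"),
            constants=self.build_constants(),
            enthalpy=self.build_enthalpy(),
            vapor=self.build_vapor(),
        )

    def build_limits(self) -> MachineLimits:
        m = self.machine
        return MachineLimits(
            max_ramp=m.max_ramp,
            setpoint_resolution=m.setpoint_resolution,
            prediction_interval=parse_quantity(m.prediction_interval, "time"),
            shelf_temp_max=parse_quantity(m.shelf_temp_max, "temperature"),
            shelf_temp_min=parse_quantity(m.shelf_temp_min, "temperature"),
        )

    def build_protocol(self) -> Protocol:
        p = self.protocol
        return Protocol.ramp_hold(
            start_temp=parse_quantity(p.start, "temperature"),
            hold_temp=parse_quantity(p.hold, "temperature"),
            ramp_rate=p.ramp_rate,
        )

    @property
    def collapse_temperature(self) -> float:
        return parse_quantity(self.process.collapse_temperature, "temperature")

    @property
    def initial_shelf_temp(self) -> float:
        return parse_quantity(self.optimizer.initial_shelf_temp, "temperature")


def _from_mapping(raw: dict, origin: str) -> RunConfig:
    try:
        config = RunConfig(**raw)
    except PydanticValidationError as exc:
        first = exc.errors()[0]
        location = ".".join(str(p) for p in first["loc"])
        raise ConfigError(
            f"{origin}: invalid config at '{location}': {first['msg']}"
        ) from exc
    digest = hashlib.sha256(repr(raw).encode()).hexdigest()[:12]
    logger.info("loaded config %s (sha256 %s)", origin, digest)
    return config


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: not valid TOML: {exc}") from exc
    return _from_mapping(raw, str(path))


def load_reference_config(name: Literal["highdose", "lowdose"]) -> RunConfig:
    """Load a bundled reference configuration (``highdose`` or ``lowdose``)."""
    resource = resources.files("blisterdry.data").joinpath(f"paper_{name}.toml")
    try:
        text = resource.read_text()
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown reference config {name!r}") from exc
    return _from_mapping(tomllib.loads(text), f"paper_{name}")
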