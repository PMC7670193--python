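"""Temperature-dependent ice properties and fixed physical constants.

Two empirical correlations drive the sublimation model: the latent heat of
sublimation of ice and the equilibrium vapor pressure over ice, both
functions of the (absolute) ice temperature.  The coefficient defaults are
the values used throughout the primary-drying model; they agree with the
Murphy & Koop ice correlations (vapor pressure at the triple point
611.657 Pa, sublimation enthalpy about 51.1 kJ/mol near 0 degC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "SublimationEnthalpyModel",
    "VaporPressureModel",
    "PhysicalConstants",
    "latent_heat_sublimation",
    "ice_vapor_pressure",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SublimationEnthalpyModel:
    """Coefficients of the sublimation-enthalpy correlation.

    ``dH(T) = alpha + beta T - gamma T^2 + delta exp(-(T/epsilon)^2)``
    with ``dH`` in J/mol and ``T`` in K.  The quadratic sign/power follows
    the coefficient units (gamma in J/(mol K^2)).
    """

    alpha: float = 4.68e4  # J/mol
    beta: float = 35.9  # J/(mol K)
    gamma: float = 0.0741  # J/(mol K^2)
    delta: float = 542.0  # J/mol
    epsilon: float = 124.0  # K

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "epsilon"):
            if getattr(self, name) <= 0.0:
                raise ValidationError(f"enthalpy coefficient {name} must be positive")


@dataclass(frozen=True)
class VaporPressureModel:
    """Coefficients of the ice vapor-pressure correlation.

    ``P(T) = exp(alpha - beta/T + gamma ln T - delta T)`` with ``P`` in Pa
    and ``T`` in K (the Murphy & Koop functional form).
    """

    alpha: float = 9.550426  # -
    beta: float = 5723.2658  # K
    gamma: float = 3.53068  # -
    delta: float = 0.00728332  # 1/K


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants of the drying model.

    ``conversion_a`` and ``conversion_b`` are the empirical factors of the
    frozen-layer temperature-difference balance; ``conversion_b`` carries
    an implicit 1/m so that ``b * L_ice`` is dimensionless.
    """

    molecular_weight_water: float = 18.01528e-3  # kg/mol
    rho_ice: float = 918.0  # kg/m^3
    rho_solution: float = 1018.0  # kg/m^3
    lambda_ice: float = 2.3  # W/(m K)
    conversion_a: float = 889_200.0
    conversion_b: float = 1.02


def latent_heat_sublimation(
    temperature: float,
    model: SublimationEnthalpyModel = SublimationEnthalpyModel(),
    *,
    warn: bool = True,
) -> float:
    """Latent heat of sublimation of ice [J/mol] at ``temperature`` [K].

    The correlation is calibrated for 150-280 K; outside that range the
    value is still returned but a warning is logged (suppressed with
    ``warn=False`` for solver bracket probes).
    """
    if warn and not 150.0 <= temperature <= 280.0:
        logger.warning(
            "latent_heat_sublimation evaluated at %.2f K, outside the "
            "correlation's sensible range [150, 280] K",
            temperature,
        )
    return (
        model.alpha
        + model.beta * temperature
        - model.gamma * temperature**2
        + model.delta * math.exp(-((temperature / model.epsilon) ** 2))
    )


def ice_vapor_pressure(
    temperature: float,
    model: VaporPressureModel = VaporPressureModel(),
    *,
    warn: bool = True,
) -> float:
    """Equilibrium vapor pressure over ice [Pa] at ``temperature`` [K].

    Strictly increasing in temperature.  Raises for non-positive absolute
    temperatures; logs a warning outside the calibrated 200-280 K range.
    """
    if temperature <= 0.0:
        raise ValidationError(
            f"absolute temperature must be positive, got {temperature}"
        )
    if warn and not 200.0 <= temperature <= 280.0:
        logger.warning(
            "ice_vapor_pressure evaluated at %.2f K, outside the "
            "correlation's sensible range [200, 280] K",
            temperature,
        )
    return math.exp(
        model.alpha
        - model.beta / temperature
        + model.gamma * math.log(temperature)
        - model.delta * temperature
    )
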