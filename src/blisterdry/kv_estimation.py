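"""Heat-transfer-coefficient (Kv) estimation and pressure regression.

The blister heat-transfer coefficient is measured gravimetrically: pockets
filled with water are partially sublimated at constant chamber pressure,
and Kv follows from the sublimated mass and the integrated shelf-to-product
temperature difference,

    Kv = m_sub * dH_sub / (A_b * M * integral(T_s - T_b) dt).

Per-pressure Kv means (edge and center blister populations separately) are
then regressed against chamber pressure with the rational form

    Kv(P_c) = (alpha + beta * P_c) / (1 + gamma * P_c),

using inverse-variance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import EstimationError, FitError, ValidationError
from .thermo import PhysicalConstants, SublimationEnthalpyModel, latent_heat_sublimation

__all__ = [
    "GravimetricRun",
    "KvPressureModel",
    "kv_from_gravimetric",
    "evaluate_kv",
    "fit_kv_pressure_model",
]

logger = logging.getLogger(__name__)

GRAVIMETRIC_TRACE_COLUMNS = ("time_s", "Ts_K", "Tb_K")


@dataclass(frozen=True)
class GravimetricRun:
    """One blister's gravimetric sublimation experiment.

    ``trace`` holds the recorded time series with columns ``time_s``,
    ``Ts_K`` and ``Tb_K`` covering the sublimation window.
    """

    blister_id: str
    position_class: Literal["edge", "center"]
    sublimated_mass: float  # kg
    chamber_pressure: float  # Pa
    trace: pd.DataFrame
    projected_area: float  # m^2

    def __post_init__(self) -> None:
        if self.sublimated_mass <= 0.0:
            raise ValidationError("sublimated_mass must be positive")
        if self.projected_area <= 0.0:
            raise ValidationError("projected_area must be positive")
        missing = set(GRAVIMETRIC_TRACE_COLUMNS) - set(self.trace.columns)
        if missing:
            raise ValidationError(f"gravimetric trace missing columns {sorted(missing)}")
        t = self.trace["time_s"].to_numpy(float)
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValidationError("gravimetric trace time must be strictly increasing")


@dataclass(frozen=True)
class KvPressureModel:
    """Rational pressure dependence of the heat-transfer coefficient.

    ``Kv(P) = (alpha + beta P)/(1 + gamma P)`` [J/(m^2 s K)]; ``alpha`` is
    the free-molecular (zero-pressure) limit and ``beta/gamma`` the
    continuum saturation value.
    """

    alpha: float  # J/(m^2 s K)
    beta: float  # J/(m^2 s K Pa)
    gamma: float  # 1/Pa
    population: Literal["edge", "center"] = "center"
    valid_pressure_range: tuple[float, float] = (10.0, 30.0)
    stderr: tuple[float, float, float] | None = None
    weighted_sse: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0.0:
            raise ValidationError("Kv model requires alpha > 0")
        lo, hi = self.valid_pressure_range
        for pressure in np.linspace(lo, hi, 11):
            if self.evaluate(float(pressure), warn=False) <= 0.0:
                raise ValidationError(
                    f"Kv model non-positive at {pressure} Pa inside its valid range"
                )

    def evaluate(self, chamber_pressure: float, *, warn: bool = True) -> float:
        """Kv at ``chamber_pressure`` [Pa]; warns outside the fitted range."""
        if chamber_pressure < 0.0:
            raise ValidationError("chamber pressure must be nonnegative")
        lo, hi = self.valid_pressure_range
        if warn and not lo <= chamber_pressure <= hi:
            logger.warning(
                "Kv model (%s) evaluated at %.3g Pa, outside its fitted "
                "range [%g, %g] Pa",
                self.population,
                chamber_pressure,
                lo,
                hi,
            )
        return (self.alpha + self.beta * chamber_pressure) / (
            1.0 + self.gamma * chamber_pressure
        )


def evaluate_kv(chamber_pressure: float, model: KvPressureModel) -> float:
    """Functional alias for :meth:`KvPressureModel.evaluate`."""
    return model.evaluate(chamber_pressure)


def kv_from_gravimetric(
    run: GravimetricRun,
    enthalpy: SublimationEnthalpyModel = SublimationEnthalpyModel(),
    molecular_weight: float = PhysicalConstants.molecular_weight_water,
) -> float:
    """Heat-transfer coefficient [J/(m^2 s K)] from one gravimetric run.

    The temperature-difference integral is evaluated by the trapezoidal
    rule on the recorded timestamps; the sublimation enthalpy is taken at
    the time-averaged bottom product temperature.
    """
    t = run.trace["time_s"].to_numpy(float)
    delta_t = run.trace["Ts_K"].to_numpy(float) - run.trace["Tb_K"].to_numpy(float)
    driving = float(np.trapezoid(delta_t, t))
    if driving <= 0.0:
        raise EstimationError(
            "non-positive driving-force integral: shelf colder than product "
            "over the whole run"
        )
    mean_tb = float(np.trapezoid(run.trace["Tb_K"].to_numpy(float), t) / (t[-1] - t[0]))
    dh = latent_heat_sublimation(mean_tb, enthalpy)
    return run.sublimated_mass * dh / (run.projected_area * molecular_weight * driving)


def _kv_form(pressure, alpha, beta, gamma):
    return (alpha + beta * pressure) / (1.0 + gamma * pressure)


def fit_kv_pressure_model(
    points: Sequence[tuple[float, float, float]],
    population: Literal["edge", "center"],
) -> KvPressureModel:
    """Weighted fit of the Kv-vs-pressure model.

    ``points`` is a sequence of ``(chamber_pressure, kv_mean, kv_variance)``
    triples, one per pressure level; weights are the inverse variances.
    Requires at least three distinct pressure levels.
    """
    pressures = np.array([p[0] for p in points], float)
    kv_means = np.array([p[1] for p in points], float)
    variances = np.array([p[2] for p in points], float)
    if len(np.unique(pressures)) < 3:
        raise FitError(
            "Kv-vs-pressure fit needs >= 3 distinct pressure levels, got "
            f"{len(np.unique(pressures))}"
        )
    if np.any(variances <= 0.0):
        raise FitError("Kv variances must be positive (inverse-variance weights)")

    # Rational-form fits are sensitive to the start: anchor alpha at the
    # lowest-pressure Kv, gamma at a small curvature, beta from the two
    # extreme pressure points.
    order = np.argsort(pressures)
    p_lo, p_hi = pressures[order[0]], pressures[order[-1]]
    kv_lo, kv_hi = kv_means[order[0]], kv_means[order[-1]]
    gamma0 = 0.01
    alpha0 = kv_lo
    beta0 = max((kv_hi * (1.0 + gamma0 * p_hi) - alpha0) / p_hi, 1e-6)
    try:
        popt, pcov = curve_fit(
            _kv_form,
            pressures,
            kv_means,
            p0=[alpha0, beta0, gamma0],
            sigma=np.sqrt(variances),
            absolute_sigma=False,
            # physical branch: positive free-molecular limit, Kv increasing
            # and saturating with pressure
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy nonconvergence
        raise FitError(f"Kv-vs-pressure fit did not converge: {exc}") from exc
    residuals = kv_means - _kv_form(pressures, *popt)
    wsse = float(np.sum(residuals**2 / variances))
    stderr = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(pcov), 0.0)))
    return KvPressureModel(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        gamma=float(popt[2]),
        population=population,
        valid_pressure_range=(float(p_lo), float(p_hi)),
        stderr=stderr,
        weighted_sse=wsse,
    )
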