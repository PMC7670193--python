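"""Dried-layer resistance pipeline: porosity, rate inversion, Rp fit,
pressure-ratio endpoint detection."""

import numpy as np
import pandas as pd
import pytest

from blisterdry import (
    FormulationSpec,
    ProcessTrace,
    RpModel,
    fit_rp_model,
    endpoint_from_pressure_ratio,
    porosity_from_composition,
)
from blisterdry.errors import EndpointError, FitError, TraceError, ValidationError
from blisterdry.rp_estimation import (
    RpCurve,
    dried_volume_cumulative,
    ice_thickness_trace,
    interface_temperature,
    sublimation_rate_trace,
)

LOWDOSE = {"drug": 1.25, "pva": 2.96, "mannitol": 9.98, "xanthan": 0.250}
HIGHDOSE = {"drug": 33.00, "pva": 3.39, "mannitol": 2.76, "xanthan": 0.075}


class TestPorosity:
    def test_lowdose(self):
        assert porosity_from_composition(LOWDOSE) == pytest.approx(0.8556, abs=1e-6)

    def test_highdose(self):
        # exact arithmetic gives 0.60775; the reference value rounds to 0.6079
        theta = porosity_from_composition(HIGHDOSE)
        assert theta == pytest.approx(0.60775, abs=1e-6)
        assert theta == pytest.approx(0.6079, rel=3e-4)

    def test_pure_water(self):
        assert porosity_from_composition({"water": 100.0}) == 1.0

    def test_closure_enforced_when_water_given(self):
        with pytest.raises(ValidationError):
            porosity_from_composition({"drug": 30.0, "water": 60.0})

    def test_formulation_derives_porosity(self):
        spec = FormulationSpec(label="hd", solids=HIGHDOSE, fill_volume=1.52e-6)
        assert spec.porosity == pytest.approx(0.60775, abs=1e-6)


def _trace(ts, tb, n=61, dt=60.0, pc=10.0, pir=None):
    time = np.arange(n) * dt
    return ProcessTrace(
        data=pd.DataFrame(
            {
                "time_s": time,
                "Ts_K": np.broadcast_to(ts, (n,)),
                "Tb_K": np.broadcast_to(tb, (n,)),
                "Pc_cap_Pa": pc,
                "Pc_pir_Pa": pc if pir is None else pir,
            }
        )
    )


class TestPipelineSteps:
    def test_rate_hand_calculation(self):
        # Kv 13.38, 10 K driving force, enthalpy at 0 degC -> 3.93e-8 kg/s
        trace = _trace(283.15, 273.15)
        rate = sublimation_rate_trace(trace, kv=13.38, projected_area=8.33e-4)
        assert rate[0] == pytest.approx(3.9307e-8, rel=1e-3)

    def test_rate_zero_and_clipped(self):
        assert np.all(sublimation_rate_trace(_trace(263.15, 263.15), 13.0, 8e-4) == 0)
        assert np.all(sublimation_rate_trace(_trace(260.0, 263.15), 13.0, 8e-4) == 0)

    def test_cumulative_volume_hand_calculation(self):
        rates = np.full(60, 3.93e-8)
        volumes = dried_volume_cumulative(rates, 60.0, 0.6079, 918.0)
        assert volumes[-1] == pytest.approx(2.535e-7, rel=1e-3)
        assert np.all(np.diff(volumes) >= 0)

    def test_halving_porosity_doubles_volume(self):
        rates = np.full(10, 1e-8)
        full = dried_volume_cumulative(rates, 60.0, 0.6, 918.0)
        half = dried_volume_cumulative(rates, 60.0, 0.3, 918.0)
        assert half == pytest.approx(2.0 * full)

    def test_ice_thickness_roundtrip(self, geometry):
        from blisterdry import frozen_volume, ice_thickness_from_volume

        frozen0 = 2.5e-6 * 1018.0 / 918.0
        level0 = ice_thickness_from_volume(frozen0, geometry)
        sublimated = np.array([0.0, 0.2, 0.5]) * frozen0
        levels, dried = ice_thickness_trace(
            sublimated, 2.5e-6, 1018.0, 918.0, geometry
        )
        assert levels[0] == pytest.approx(level0, abs=1e-12)
        assert dried[0] == 0.0
        for lv, v in zip(levels, frozen0 - sublimated):
            assert frozen_volume(lv, geometry) == pytest.approx(v, rel=1e-9)

    def test_ice_exhaustion_truncates(self, geometry):
        frozen0 = 2.5e-6 * 1018.0 / 918.0
        levels, _ = ice_thickness_trace(
            np.array([0.0, 0.5 * frozen0, 1.5 * frozen0]),
            2.5e-6, 1018.0, 918.0, geometry,
        )
        assert len(levels) == 2

    def test_interface_temperature(self):
        assert interface_temperature(263.0, 283.0, 13.38, 5e-3, 2.3) == pytest.approx(
            262.4183, abs=1e-3
        )
        assert interface_temperature(263.0, 283.0, 13.38, 0.0) == 263.0
        assert interface_temperature(263.0, 263.0, 13.38, 5e-3) == 263.0


class TestRpFit:
    def _curve(self, model, noise=0.0, rng=None, n=46):
        dried = np.linspace(0.0, 4.5e-3, n)
        resistance = np.array([model.evaluate(x) for x in dried])
        if noise:
            resistance = resistance + rng.normal(0.0, noise, n)
        return RpCurve(
            dried_thickness=dried, resistance=resistance, time_s=np.arange(n) * 60.0
        )

    def test_noiseless_exact_recovery(self, rp_highdose):
        fitted = fit_rp_model(self._curve(rp_highdose))
        assert fitted.rp0 == pytest.approx(rp_highdose.rp0, rel=1e-6)
        assert fitted.a == pytest.approx(rp_highdose.a, rel=1e-6)
        assert fitted.b == pytest.approx(rp_highdose.b, rel=1e-6)

    def test_noisy_median_recovery_and_rmse(self, rp_highdose):
        # noise at the reported high-dose regression scatter scale
        sigma = 1.9e4
        rng = np.random.default_rng(11)
        rp0s, a_s, rmses = [], [], []
        for _ in range(50):
            fitted = fit_rp_model(self._curve(rp_highdose, noise=sigma, rng=rng))
            rp0s.append(fitted.rp0)
            a_s.append(fitted.a)
            rmses.append(fitted.rmse)
        assert abs(np.median(rp0s) - rp_highdose.rp0) / rp_highdose.rp0 < 0.10
        assert abs(np.median(a_s) - rp_highdose.a) / rp_highdose.a < 0.10
        assert np.median(rmses) == pytest.approx(sigma, rel=0.15)

    def test_intercept_is_rp0(self, rp_highdose):
        fitted = fit_rp_model(self._curve(rp_highdose))
        assert fitted.evaluate(0.0) == pytest.approx(fitted.rp0)

    def test_too_few_points_rejected(self, rp_highdose):
        curve = self._curve(rp_highdose, n=8)
        with pytest.raises(FitError):
            fit_rp_model(curve, max_dried_thickness=1e-4)

    def test_singular_model_rejected(self):
        with pytest.raises(ValidationError):
            RpModel(rp0=1e5, a=1e8, b=-300.0)  # singular at 3.3 mm < fit range


class TestEndpointDetector:
    def _sigmoid_trace(self, t_star=7200.0, n=241, dt=60.0, shift=0.0):
        time = np.arange(n) * dt + shift
        ratio = 1.0 + 0.6 / (1.0 + np.exp((time - shift - t_star) / 300.0))
        return ProcessTrace(
            data=pd.DataFrame(
                {
                    "time_s": time,
                    "Ts_K": 263.15,
                    "Tb_K": 258.15,
                    "Pc_cap_Pa": 10.0,
                    "Pc_pir_Pa": 10.0 * ratio,
                }
            )
        )

    def test_sigmoid_midpoint(self):
        # symmetric logistic decay: the halfway crossing is the inflection
        detected = endpoint_from_pressure_ratio(self._sigmoid_trace())
        assert abs(detected - 7200.0) <= 60.0

    def test_time_shift_equivariance(self):
        base = endpoint_from_pressure_ratio(self._sigmoid_trace())
        shifted = endpoint_from_pressure_ratio(self._sigmoid_trace(shift=1800.0))
        assert shifted - base == pytest.approx(1800.0, abs=1e-6)

    def test_flat_ratio_rejected(self):
        with pytest.raises(EndpointError):
            endpoint_from_pressure_ratio(_trace(263.15, 258.15, pir=10.5))


class TestTraceValidation:
    def test_missing_column(self):
        with pytest.raises(TraceError):
            ProcessTrace(data=pd.DataFrame({"time_s": [0, 60], "Ts_K": [1, 2]}))

    def test_non_monotone_time(self):
        frame = _trace(263.15, 258.15).data.copy()
        frame.loc[3, "time_s"] = 0.0
        with pytest.raises(TraceError):
            ProcessTrace(data=frame)
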