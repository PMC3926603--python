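"""Calibration model: evaluation, inversion, fitting, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from insolekit import sensor_model as sm
from insolekit.sensor_model import (
    AGGREGATE_MODEL,
    CalibrationModel,
    aggregate_calibration,
    default_layout,
    fit_calibration,
    force_from_voltage,
    summarize_models,
    threshold_force,
    voltage_from_force,
    worst_case_errors,
)


class TestDefaultLayout:
    def test_cardinality_and_bounds(self):
        lay = default_layout()
        assert len(lay.cell_ids) == 64
        assert lay.y_mm.min() >= 0 and lay.y_mm.max() <= 250
        assert np.all(lay.area_cm2 == 1.0)

    def test_deterministic(self):
        assert default_layout() == default_layout()

    def test_unique_coordinates(self):
        lay = default_layout()
        assert len({(x, y) for x, y in zip(lay.x_mm, lay.y_mm)}) == 64


class TestForceFromVoltage:
    def test_threshold_force_value(self, model):
        # jump magnitude at the -0.02 V noise threshold
        assert abs(force_from_voltage(-0.02, model)) == pytest.approx(3.06, abs=0.005)

    def test_above_threshold_is_zero(self, model):
        assert force_from_voltage(0.10, model) == 0.0
        assert force_from_voltage(-0.019, model) == 0.0

    def test_deep_compression_value(self, model):
        # independent high-precision evaluation of the two-exponential law
        expected = 21.386 * math.exp(-4.834) - 22.30 * math.exp(0.401)
        assert force_from_voltage(-1.0, model) == pytest.approx(expected, abs=1e-9)
        assert force_from_voltage(-1.0, model) == pytest.approx(-33.13, abs=0.005)

    def test_nonfinite_rejected(self, model):
        with pytest.raises(ValueError):
            force_from_voltage(float("nan"), model)

    def test_vectorized_matches_scalar(self, model):
        v = np.array([-1.0, -0.02, -0.019, 0.3])
        f = force_from_voltage(v, model)
        assert f.tolist() == [force_from_voltage(x, model) for x in v]

    @settings(derandomize=True, max_examples=40)
    @given(
        a1=st.floats(1.0, 50.0),
        c1=st.floats(0.5, 10.0),
        a2=st.floats(-50.0, -1.0),
        c2=st.floats(-1.5, -0.05),
        v=st.floats(-3.0, -0.02),
        dv=st.floats(1e-6, 0.5),
    )
    def test_strictly_increasing_on_loaded_branch(self, a1, c1, a2, c2, v, dv):
        m = CalibrationModel(A1=a1, c1=c1, A2=a2, c2=c2)
        assert force_from_voltage(v - dv, m) < force_from_voltage(v, m)


class TestVoltageFromForce:
    def test_round_trip(self, model):
        for v in (-0.02, -0.1, -0.5, -1.3, -2.0):
            f = force_from_voltage(v, model)
            assert voltage_from_force(f, model) == pytest.approx(v, abs=1e-9)

    def test_threshold_identity(self, model):
        assert voltage_from_force(-threshold_force(model), model) == pytest.approx(-0.02, abs=1e-9)

    def test_below_threshold_force_is_domain_error(self, model):
        with pytest.raises(ValueError):
            voltage_from_force(-1.0, model)  # |F| < 3.06 N is unrepresentable

    def test_positive_force_is_domain_error(self, model):
        with pytest.raises(ValueError):
            voltage_from_force(5.0, model)

    def test_batch_agrees_with_scalar(self, model):
        F = np.array([force_from_voltage(v, model) for v in (-0.02, -0.3, -1.0, -2.5)])
        vb = sm.voltage_from_force_batch(F, model)
        vs = [voltage_from_force(f, model) for f in F]
        np.testing.assert_allclose(vb, vs, atol=1e-10)


def _forward_samples(model, n=40, v_lo=-1.3, v_hi=-0.05):
    v = np.linspace(v_lo, v_hi, n)
    return list(zip(v, force_from_voltage(v, model)))


class TestFitCalibration:
    def test_noise_free_parameter_recovery(self, model):
        rep = fit_calibration(_forward_samples(model))
        for name in ("A1", "c1", "A2", "c2"):
            assert getattr(rep.model, name) == pytest.approx(getattr(model, name), rel=1e-4)
        assert rep.r2 == pytest.approx(1.0, abs=1e-9)

    def test_duplication_invariance(self, model):
        samples = _forward_samples(model)
        rep1 = fit_calibration(samples)
        rep2 = fit_calibration(samples * 2)
        for name in ("A1", "c1", "A2", "c2"):
            assert getattr(rep2.model, name) == pytest.approx(getattr(rep1.model, name), rel=1e-6)

    def test_noisy_rmse_magnitude(self, model):
        rng = np.random.default_rng(42)
        v = np.linspace(-1.3, -0.05, 200)
        F = force_from_voltage(v, model) + rng.normal(0.0, 1.0, size=200)
        rep = fit_calibration(list(zip(v, F)))
        assert 0.5 <= rep.rmse_N <= 2.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(-0.5, -10.0)] * 10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(-0.5, -10.0), (-0.6, -12.0)])

    def test_rmse_pct_fsr_consistency(self, model):
        rep = fit_calibration(_forward_samples(model))
        assert rep.rmse_pct_fsr == pytest.approx(2.0 * rep.rmse_N)


class TestAggregateCalibration:
    def test_identical_sets_give_per_cell_model(self, model):
        samples = _forward_samples(model)
        agg = aggregate_calibration([samples] * 64)
        single = fit_calibration(samples)
        for name in ("A1", "c1", "A2", "c2"):
            assert getattr(agg.model, name) == pytest.approx(getattr(single.model, name), rel=1e-5)

    def test_differing_cells_have_residuals(self):
        m1 = CalibrationModel(A1=21.0, c1=4.8, A2=-22.0, c2=-0.40)
        m2 = CalibrationModel(A1=18.0, c1=6.5, A2=-20.0, c2=-0.60)
        agg = aggregate_calibration([_forward_samples(m1), _forward_samples(m2)])
        assert agg.rmse_N > 0.01

    def test_aggregate_rmse_exceeds_mean_per_cell_rmse(self):
        # pooled fit over heterogeneous cells cannot beat per-cell fits
        rng = np.random.default_rng(7)
        from insolekit.synthetic import sample_cell_models

        models = sample_cell_models(rng, n=8)
        sets = [_forward_samples(m) for m in models]
        per_cell = [fit_calibration(s) for s in sets]
        agg = aggregate_calibration(sets)
        assert agg.rmse_N >= np.mean([r.rmse_N for r in per_cell])
        assert agg.rmse_pct_fsr > np.mean([r.rmse_pct_fsr for r in per_cell])


class TestSummarizeModels:
    def test_identical_models_zero_sd(self, model):
        reps = [fit_calibration(_forward_samples(model)) for _ in range(3)]
        summary = summarize_models(reps)
        for name in ("A1", "c1", "A2", "c2"):
            assert summary[name]["sd"] == pytest.approx(0.0, abs=1e-6)

    def test_two_model_hand_arithmetic(self):
        m1 = CalibrationModel(A1=19.0, c1=4.8, A2=-22.0, c2=-0.4)
        m2 = CalibrationModel(A1=21.0, c1=4.8, A2=-22.0, c2=-0.4)
        reps = [
            fit_calibration(_forward_samples(m1)),
            fit_calibration(_forward_samples(m2)),
        ]
        summary = summarize_models(reps)
        assert summary["A1"]["mean"] == pytest.approx(20.0, abs=1e-3)
        assert summary["A1"]["sd"] == pytest.approx(math.sqrt(2.0), abs=1e-3)


class TestWorstCaseErrors:
    def test_calibration_error_closed_form(self, model):
        # 64 cells x 5% of the 50 N full scale
        assert worst_case_errors(model)["vgrf_calibration_error_N"] == 160.0

    def test_threshold_error_is_64x_per_cell(self, model):
        wc = worst_case_errors(model)
        assert wc["vgrf_threshold_error_N"] == pytest.approx(64 * wc["per_cell_threshold_N"])


class TestModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"A1": -1.0, "c1": 4.8, "A2": -22.0, "c2": -0.4},
            {"A1": 21.0, "c1": -4.8, "A2": -22.0, "c2": -0.4},
            {"A1": 21.0, "c1": 4.8, "A2": 22.0, "c2": -0.4},
            {"A1": 21.0, "c1": 4.8, "A2": -22.0, "c2": 0.4},
        ],
    )
    def test_sign_pattern_enforced(self, kwargs):
        with pytest.raises(ValueError):
            CalibrationModel(**kwargs)
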