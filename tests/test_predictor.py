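import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import linear_map_dataset
from ipidyn.predictor import (MLPModel, Split, TrainingConfig, WindowConfig,
                              _jacobian, evaluate, load_model, make_windowed,
                              save_model, split_series, train_lm, window_pairs)
from ipidyn.preprocess import IPISeries
from ipidyn.synthetic import StateProfile, generate_ipi_sequence
from ipidyn.signal_io import SleepState


class TestSplitSeries:
    def test_60_15_25_proportions(self):
        ipi = IPISeries(np.arange(1, 111))
        data = split_series(ipi, WindowConfig(k=10))
        assert data.counts() == {"TRAIN": 60, "VAL": 15, "TEST": 25}
        # chronological order
        tags = data.split
        assert list(tags[:60]) == ["TRAIN"] * 60
        assert list(tags[60:75]) == ["VAL"] * 15
        assert list(tags[75:]) == ["TEST"] * 25

    def test_windowing_definition(self):
        inputs, targets = window_pairs(np.arange(1, 13), k=10)
        assert inputs.shape == (2, 10)
        assert inputs[0].tolist() == list(range(1, 11))
        assert targets.tolist() == [11, 12]

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(min_value=20, max_value=400), k=st.integers(1, 12))
    def test_pair_count_is_series_length_minus_k(self, n, k):
        if n - k < 7:  # too short to split
            return
        data = make_windowed(np.arange(n, dtype=float), WindowConfig(k=k))
        assert data.inputs.shape[0] == n - k

    def test_norm_stats_come_from_training_portion_only(self):
        series = np.concatenate([np.zeros(70), np.full(40, 100.0)])
        data = make_windowed(series, WindowConfig(k=10))
        mean, sd = data.norm_stats
        # training pairs live entirely in the leading zeros
        assert mean < 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_windowed(np.arange(12.0), WindowConfig(k=10))


class TestTrainLM:
    def test_accepted_sse_sequence_is_non_increasing(self, linear_dataset):
        _, trace = train_lm(linear_dataset, TrainingConfig(seed=1, max_epochs=60))
        sses = trace.train_sse
        assert len(sses) >= 2
        assert all(b <= a for a, b in zip(sses, sses[1:]))

    def test_lambda_schedule_decrease_and_increase_factors(self, linear_dataset):
        cfg = TrainingConfig(seed=1, max_epochs=40)
        _, trace = train_lm(linear_dataset, cfg)
        for attempts in trace.attempted_lambdas:
            # every retry within an epoch escalates lambda by the increase factor
            for a, b in zip(attempts, attempts[1:]):
                assert b == pytest.approx(a * cfg.lambda_increase)
        # the first attempt starts at lambda0; an accepted epoch ends at
        # (accepted lambda) * lambda_decrease, which seeds the next epoch
        assert trace.attempted_lambdas[0][0] == cfg.lambda0
        for e in range(len(trace.lambdas)):
            assert trace.lambdas[e] == pytest.approx(
                trace.attempted_lambdas[e][-1] * cfg.lambda_decrease)
            if e + 1 < len(trace.attempted_lambdas):
                assert trace.attempted_lambdas[e + 1][0] == pytest.approx(
                    trace.lambdas[e])

    def test_reaches_tiny_mse_on_noiseless_linear_map(self, linear_dataset):
        # a plain least-squares fit achieves zero error, so the target is feasible
        x, y = linear_dataset.pairs(Split.TRAIN)
        design = np.column_stack([x, np.ones(len(y))])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.max(np.abs(design @ coef - y)) < 1e-9
        model, trace = train_lm(
            linear_dataset, TrainingConfig(seed=0, max_epochs=200, patience=200))
        errors = evaluate(model, linear_dataset, Split.TRAIN)
        assert np.mean(errors.signed_errors**2) < 1e-6
        assert trace.epochs <= 200

    def test_bit_reproducible_with_fixed_seed(self, linear_dataset):
        m1, _ = train_lm(linear_dataset, TrainingConfig(seed=3, max_epochs=30))
        m2, _ = train_lm(linear_dataset, TrainingConfig(seed=3, max_epochs=30))
        assert np.array_equal(m1.to_vector(), m2.to_vector())

    def test_large_damping_step_follows_negative_gradient(self, linear_dataset):
        x, y = linear_dataset.pairs(Split.TRAIN)
        mean, sd = linear_dataset.norm_stats
        xn, yn = (x - mean) / sd, (y - mean) / sd
        model = MLPModel.init_random(x.shape[1], 10, np.random.default_rng(0))
        jac = _jacobian(model, xn)
        r = yn - model.forward(xn)
        grad_descent_dir = jac.T @ r  # negative gradient of 0.5*SSE
        lam = 1e8
        step = np.linalg.solve(jac.T @ jac + lam * np.eye(jac.shape[1]),
                               grad_descent_dir)
        cos = step @ grad_descent_dir / (
            np.linalg.norm(step) * np.linalg.norm(grad_descent_dir))
        assert cos > 0.99

    def test_needs_minimum_training_pairs(self):
        data = linear_map_dataset(n=12)
        with pytest.raises(ValueError, match="10 training pairs"):
            train_lm(data)

    def test_error_floor_approaches_innovation_scale_with_length(self):
        profile = StateProfile(SleepState.UNKNOWN, innovation_sd=0.5,
                               noise_sd=2.0, amplitude_mean=40.0)
        errs = {}
        for n in (300, 2500):
            ipi = IPISeries(generate_ipi_sequence(profile, n, seed=11))
            data = split_series(ipi)
            model, _ = train_lm(data, TrainingConfig(seed=11))
            errs[n] = float(np.mean(evaluate(model, data).abs_errors))
        assert errs[2500] <= errs[300] + 0.1
        assert errs[2500] < 2 * profile.innovation_sd + 0.5


class TestEvaluate:
    def test_constant_model_on_constant_series_has_zero_error(self):
        data = make_windowed(np.full(60, 12.0), WindowConfig(k=10))
        model = MLPModel(np.zeros((10, 10)), np.zeros(10), np.zeros(10), 0.0)
        errors = evaluate(model, data)
        np.testing.assert_allclose(errors.signed_errors, 0.0, atol=1e-12)

    def test_mean_abs_bounds_abs_mean(self, linear_dataset):
        model, _ = train_lm(linear_dataset, TrainingConfig(seed=5, max_epochs=20))
        errors = evaluate(model, linear_dataset)
        assert np.mean(errors.abs_errors) >= abs(np.mean(errors.signed_errors))
        np.testing.assert_array_equal(errors.abs_errors,
                                      np.abs(errors.signed_errors))

    def test_errors_are_in_original_units(self):
        # a well-trained model on a wide-magnitude series must err in raw units
        data = make_windowed(np.full(60, 500.0), WindowConfig(k=10))
        model = MLPModel(np.zeros((10, 10)), np.zeros(10), np.zeros(10), 0.0)
        errors = evaluate(model, data)
        # de-normalized constant prediction == 500, not the z-scored 0
        np.testing.assert_allclose(errors.signed_errors, 0.0, atol=1e-12)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = MLPModel.init_random(10, 10, rng)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.to_vector(), model.to_vector())
        assert back.k == 10 and back.hidden_units == 10
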