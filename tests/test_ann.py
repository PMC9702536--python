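"""Feedforward yield surrogate: prediction, training, selection, persistence."""

import numpy as np
import pytest

from atpex import (
    AnnModel,
    FactorialDataset,
    ann_predict,
    ann_select_hidden,
    ann_train,
    fit_metrics,
    load_model,
    load_reference_model,
    save_model,
)
from atpex.ann import _scale, _unscale
from atpex.exceptions import DomainError, ParseError


def toy_model(**overrides):
    kwargs = dict(
        input_weights=np.array([[1.0, 0.0, 0.0]]),
        hidden_bias=np.zeros(1),
        layer_weights=np.array([[1.0]]),
        output_bias=0.0,
    )
    kwargs.update(overrides)
    return AnnModel(**kwargs)


def grid_dataset(table):
    return FactorialDataset(
        aed=table["aed_w_per_l"].to_numpy(),
        temperature=table["temp_c"].to_numpy(),
        time_min=table["time_min"].to_numpy(),
        yield_mg_per_g=table["yield_mg_per_g"].to_numpy(),
    )


class TestPredict:
    def test_zero_network_returns_zero(self):
        m = toy_model(input_weights=np.zeros((1, 3)), layer_weights=np.zeros((1, 1)))
        assert ann_predict((50.0, 30.0, 10.0), m) == 0.0

    def test_single_neuron_hand_evaluation(self):
        m = toy_model()
        assert ann_predict((1.0, 99.0, -5.0), m) == pytest.approx(np.tanh(1.0))
        assert ann_predict((1.0, 0.0, 0.0), m) == pytest.approx(0.76159, abs=1e-5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ann_predict((1.0, 2.0), toy_model())

    def test_reference_network_loads_and_predicts(self):
        """The published 8-neuron reference network must load with
        consistent shapes (8x3 input weights, 8 hidden biases, 1x8 layer
        weights, scalar output bias) and evaluate without error."""
        m = load_reference_model()
        assert m.n_hidden == 8
        assert m.input_weights.shape == (8, 3)
        assert m.layer_weights.shape == (1, 8)
        assert m.output_bias == pytest.approx(-1.0773)
        y = ann_predict((96.1, 30.0, 30.0), m)
        assert np.isfinite(y)

    def test_bounded_slope_on_probe_grid(self):
        """tansig hidden units give a continuous, bounded-slope response:
        finite differences on a fine probe grid stay below the analytic
        Lipschitz bound of the network."""
        m = load_reference_model()
        aed = np.linspace(41.1, 111.2, 200)
        X = np.column_stack([aed, np.full_like(aed, 30.0), np.full_like(aed, 30.0)])
        y = ann_predict(X, m)
        slopes = np.abs(np.diff(y) / np.diff(aed))
        # |dy/dAED| <= sum_h |LW_h * IW_h1| * d(scaled)/d(aed)
        bound = np.sum(
            np.abs(m.layer_weights.ravel() * m.input_weights[:, 0])
        ) * 2.0 / (111.2 - 41.1)
        assert np.all(slopes <= bound * (1.0 + 1e-9))


class TestScaling:
    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        scaling = [(41.1, 111.2), (20.0, 40.0), (0.0, 60.0)]
        x = rng.uniform([41.1, 20.0, 0.0], [111.2, 40.0, 60.0], size=(50, 3))
        back = _unscale(_scale(x, scaling), scaling)
        assert np.allclose(back, x, atol=1e-12)
        xs = _scale(x, scaling)
        assert xs.min() >= -1.0 - 1e-12 and xs.max() <= 1.0 + 1e-12


class TestTrain:
    def test_noiseless_factorial_fit(self, noiseless_grid):
        table, _ = noiseless_grid
        data = grid_dataset(table)
        model, metrics = ann_train(data, n_hidden=8, seed=7)
        overall = fit_metrics(data.y, ann_predict(data.X, model))
        assert overall.r_squared >= 0.99
        assert metrics["train"].r_squared >= 0.99

    def test_same_seed_gives_identical_weights(self, noiseless_grid):
        table, _ = noiseless_grid
        data = grid_dataset(table)
        m1, _ = ann_train(data, n_hidden=4, seed=11, n_restarts=1, max_iter=200)
        m2, _ = ann_train(data, n_hidden=4, seed=11, n_restarts=1, max_iter=200)
        assert np.array_equal(m1.input_weights, m2.input_weights)
        assert np.array_equal(m1.hidden_bias, m2.hidden_bias)
        assert np.array_equal(m1.layer_weights, m2.layer_weights)
        assert m1.output_bias == m2.output_bias

    def test_constant_target_flagged_not_fatal(self):
        rng = np.random.default_rng(2)
        data = FactorialDataset(
            aed=rng.uniform(41, 111, 40),
            temperature=rng.uniform(20, 40, 40),
            time_min=rng.uniform(0, 60, 40),
            yield_mg_per_g=np.full(40, 7.5),
        )
        model, metrics = ann_train(data, n_hidden=2, seed=1)
        assert metrics["train"].r_squared is None  # zero observed variance
        assert metrics["train"].rmse < 1e-6
        assert ann_predict((60.0, 30.0, 30.0), model) == pytest.approx(7.5, abs=1e-6)

    def test_function_recovery_from_frozen_network(self):
        """Training on data generated by a frozen random 8-unit network
        recovers the function (not the weights) on held-out points."""
        rng = np.random.default_rng(11)
        frozen = AnnModel(
            input_weights=rng.normal(0, 1, (8, 3)),
            hidden_bias=rng.normal(0, 1, 8),
            layer_weights=rng.normal(0, 1, (1, 8)),
            output_bias=0.3,
            input_scaling=[(41.1, 111.2), (20.0, 40.0), (0.0, 60.0)],
        )
        X = np.column_stack(
            [rng.uniform(41.1, 111.2, 300), rng.uniform(20, 40, 300), rng.uniform(0, 60, 300)]
        )
        y = ann_predict(X, frozen)
        y = y - y.min() + 0.1  # shift into the physical (positive-yield) range
        data = FactorialDataset(
            aed=X[:, 0], temperature=X[:, 1], time_min=X[:, 2], yield_mg_per_g=y
        )
        _, metrics = ann_train(data, n_hidden=8, seed=3)
        assert metrics["test"].r_squared >= 0.999

    def test_invalid_split_rejected(self, noiseless_grid):
        table, _ = noiseless_grid
        with pytest.raises(DomainError):
            ann_train(grid_dataset(table), n_hidden=2, seed=0, split=(0.5, 0.2, 0.1))


class TestSelectHidden:
    def test_single_candidate_returned(self, noiseless_grid):
        table, _ = noiseless_grid
        best, results = ann_select_hidden(
            grid_dataset(table), [8], seed=5, n_restarts=1, max_iter=300
        )
        assert best == 8
        assert set(results) == {8}

    @pytest.mark.filterwarnings("ignore:108 rows is fewer")
    def test_scan_returns_size_in_range_with_metrics(self, noiseless_grid):
        table, _ = noiseless_grid
        sizes = [5, 8, 12]
        best, results = ann_select_hidden(
            grid_dataset(table), sizes, seed=5, n_restarts=1, max_iter=300
        )
        assert best in sizes
        assert all("metrics" in results[s] or "error" in results[s] for s in sizes)
        # the winner minimises validation RMSE among successful sizes
        rmses = {
            s: r["metrics"]["validation"].rmse
            for s, r in results.items()
            if "metrics" in r
        }
        assert rmses[best] == min(rmses.values())

    def test_empty_candidates_rejected(self, noiseless_grid):
        table, _ = noiseless_grid
        with pytest.raises(DomainError):
            ann_select_hidden(grid_dataset(table), [], seed=0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, noiseless_grid):
        table, _ = noiseless_grid
        data = grid_dataset(table)
        model, _ = ann_train(data, n_hidden=3, seed=2, n_restarts=1, max_iter=200)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        probe = np.column_stack(
            [np.linspace(41.1, 111.2, 9), np.linspace(20, 40, 9), np.linspace(0, 60, 9)]
        )
        assert np.array_equal(ann_predict(probe, model), ann_predict(probe, loaded))
        assert loaded.input_scaling == model.input_scaling

    def test_missing_field_named_in_error(self, tmp_path):
        import json

        from atpex.ann import model_to_dict

        payload = model_to_dict(load_reference_model())
        del payload["output_bias"]
        path = tmp_path / "broken.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ParseError, match="output_bias"):
            load_model(path)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "garbage.json"
        path.write_text("{not json")
        with pytest.raises(ParseError):
            load_model(path)
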