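"""Feedforward neural-network surrogate of extraction yield.

A single-hidden-layer network maps the three process inputs — acoustic
energy density (W/L), temperature (°C) and sonication time (min) — to the
phenolic yield (mg/g):

    y = purelin( LW · tansig( IW · x_s + b1 ) + b2 )

where ``tansig`` is the hyperbolic tangent, ``purelin`` the identity,
``IW`` the (hidden × 3) input-weight matrix, ``LW`` the (1 × hidden)
layer-weight matrix, and x_s the min-max-scaled inputs.  Models always
carry explicit scaling metadata so a serialized network is a complete,
portable function.

Training minimises mean-squared error with a quasi-Newton optimiser
(L-BFGS) from seeded random initial weights, with early stopping on the
validation RMSE; given the same data and seed the trained weights are
bit-identical.  Hidden-layer size is selected by validation RMSE over a
candidate range, following the usual practice of scanning 5–20 neurons
for small process-modelling datasets.

A published reference network for the grape-pomace system (8 hidden
neurons, output bias −1.0773) ships with the package; its original input
scaling was not published, so the loader attaches min-max scaling over
the experimental ranges as a documented, non-authoritative default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.optimize import minimize

from .exceptions import DomainError, ParseError, TrainingError
from .metrics import FitMetrics, fit_metrics

__all__ = [
    "AnnModel",
    "FactorialDataset",
    "ann_predict",
    "ann_train",
    "ann_select_hidden",
    "save_model",
    "load_model",
    "load_reference_model",
    "TRANSFERS",
]


def _tansig(x):
    return np.tanh(x)


def _logsig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _purelin(x):
    return x


TRANSFERS = {"tansig": _tansig, "logsig": _logsig, "purelin": _purelin}


def _check_scaling(scaling, n: int, what: str):
    if scaling == "identity":
        return
    pairs = list(scaling)
    if len(pairs) != n:
        raise DomainError(f"{what} scaling must have {n} (min, max) pairs")
    for lo, hi in pairs:
        if not lo < hi:
            raise DomainError(f"{what} scaling requires min < max, got ({lo}, {hi})")


@dataclass(frozen=True)
class AnnModel:
    """A 3-input / 1-output single-hidden-layer feedforward network.

    ``input_scaling`` is either the string ``"identity"`` or a list of
    (min, max) pairs, one per input, mapping each input to [−1, 1];
    ``output_scaling`` is analogous for the single output.
    """

    input_weights: np.ndarray        # (hidden, n_in)
    hidden_bias: np.ndarray          # (hidden,)
    layer_weights: np.ndarray        # (1, hidden)
    output_bias: float
    input_scaling: object = "identity"
    output_scaling: object = "identity"
    hidden_transfer: str = "tansig"

    def __post_init__(self):
        iw = np.atleast_2d(np.asarray(self.input_weights, dtype=float))
        b1 = np.asarray(self.hidden_bias, dtype=float).ravel()
        lw = np.atleast_2d(np.asarray(self.layer_weights, dtype=float))
        object.__setattr__(self, "input_weights", iw)
        object.__setattr__(self, "hidden_bias", b1)
        object.__setattr__(self, "layer_weights", lw)
        h = iw.shape[0]
        if b1.shape != (h,):
            raise DomainError(f"hidden bias must have length {h}, got {b1.shape}")
        if lw.shape != (1, h):
            raise DomainError(f"layer weights must have shape (1, {h}), got {lw.shape}")
        if self.hidden_transfer not in TRANSFERS:
            raise DomainError(f"unknown hidden transfer {self.hidden_transfer!r}")
        _check_scaling(self.input_scaling, iw.shape[1], "input")
        _check_scaling(self.output_scaling, 1, "output")

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1]


def _scale(x: np.ndarray, scaling) -> np.ndarray:
    if scaling == "identity":
        return x
    lo = np.array([p[0] for p in scaling])
    hi = np.array([p[1] for p in scaling])
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _unscale(xs: np.ndarray, scaling) -> np.ndarray:
    if scaling == "identity":
        return xs
    lo = np.array([p[0] for p in scaling])
    hi = np.array([p[1] for p in scaling])
    return (xs + 1.0) / 2.0 * (hi - lo) + lo


def ann_predict(x, model: AnnModel):
    """Predict yield for one input triple or an (n, 3) array of triples.

    Applies input scaling, the hidden transfer, the linear output layer,
    and the inverse output scaling.  Deterministic.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != model.n_inputs:
        raise DomainError(
            f"expected {model.n_inputs} inputs per row, got {arr.shape[1]}"
        )
    xs = _scale(arr, model.input_scaling)
    transfer = TRANSFERS[model.hidden_transfer]
    hidden = transfer(xs @ model.input_weights.T + model.hidden_bias)
    ys = hidden @ model.layer_weights.ravel() + model.output_bias
    y = _unscale(ys, model.output_scaling)
    return float(y[0]) if single else y


@dataclass(frozen=True)
class FactorialDataset:
    """Rows of (AED W/L, temperature °C, time min) → yield mg/g."""

    aed: np.ndarray
    temperature: np.ndarray
    time_min: np.ndarray
    yield_mg_per_g: np.ndarray

    def __post_init__(self):
        cols = {}
        for name in ("aed", "temperature", "time_min", "yield_mg_per_g"):
            cols[name] = np.asarray(getattr(self, name), dtype=float).ravel()
            object.__setattr__(self, name, cols[name])
        n = cols["aed"].size
        if any(c.size != n for c in cols.values()) or n == 0:
            raise DomainError("dataset columns must be equal-length and non-empty")
        if not all(np.all(np.isfinite(c)) for c in cols.values()):
            raise DomainError("dataset values must be finite")
        if np.any(cols["yield_mg_per_g"] < 0.0):
            raise DomainError("yields must be non-negative")

    def __len__(self) -> int:
        return self.aed.size

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.aed, self.temperature, self.time_min])

    @property
    def y(self) -> np.ndarray:
        return self.yield_mg_per_g


def _minmax_pairs(X: np.ndarray) -> list:
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    # guard degenerate (constant) columns with a unit-width window
    flat = hi - lo <= 0.0
    lo = np.where(flat, lo - 0.5, lo)
    hi = np.where(flat, hi + 0.5, hi)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


def _unpack(theta: np.ndarray, n_hidden: int, n_in: int):
    i = 0
    iw = theta[i : i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = theta[i : i + n_hidden]; i += n_hidden
    lw = theta[i : i + n_hidden]; i += n_hidden
    b2 = theta[i]
    return iw, b1, lw, b2


def _mse_and_grad(theta, Xs, ys, n_hidden, n_in):
    iw, b1, lw, b2 = _unpack(theta, n_hidden, n_in)
    z = Xs @ iw.T + b1
    a = np.tanh(z)
    pred = a @ lw + b2
    err = pred - ys
    n = ys.size
    mse = float(np.mean(err * err))
    # backprop
    d_pred = 2.0 * err / n
    g_lw = a.T @ d_pred
    g_b2 = d_pred.sum()
    d_a = np.outer(d_pred, lw)
    d_z = d_a * (1.0 - a * a)
    g_iw = d_z.T @ Xs
    g_b1 = d_z.sum(axis=0)
    grad = np.concatenate([g_iw.ravel(), g_b1, g_lw, [g_b2]])
    return mse, grad


def _rmse(theta, Xs, ys, n_hidden, n_in) -> float:
    iw, b1, lw, b2 = _unpack(theta, n_hidden, n_in)
    pred = np.tanh(Xs @ iw.T + b1) @ lw + b2
    return float(np.sqrt(np.mean((pred - ys) ** 2)))


def _split_indices(n: int, split, rng: np.random.Generator):
    fracs = np.asarray(split, dtype=float)
    if fracs.size != 3 or np.any(fracs < 0.0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise DomainError("split must be three non-negative fractions summing to 1")
    perm = rng.permutation(n)
    n_train = max(int(round(fracs[0] * n)), 1)
    n_val = int(round(fracs[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def ann_train(
    data: FactorialDataset,
    n_hidden: int,
    seed: int,
    split=(0.70, 0.15, 0.15),
    n_restarts: int = 4,
    max_iter: int = 2000,
    patience: int = 50,
) -> tuple[AnnModel, dict[str, FitMetrics | None]]:
    """Train the yield surrogate; fully reproducible for a given seed.

    The data are shuffled once into train/validation/test splits, min-max
    scaling to [−1, 1] is fitted on the training split, and L-BFGS
    minimises the training MSE from ``n_restarts`` seeded initialisations.
    Along each run the validation RMSE is monitored and the best-so-far
    parameters kept (early stopping with the given iteration ``patience``
    when a validation split exists); the restart with the lowest
    validation RMSE (training RMSE when the validation split is empty)
    wins.

    Returns the trained model and per-split :class:`FitMetrics` (``None``
    for empty splits).
    """
    if n_hidden < 1:
        raise DomainError("n_hidden must be at least 1")
    import warnings as _warnings

    n = len(data)
    if n < 10 * n_hidden:
        _warnings.warn(
            f"{n} rows is fewer than the recommended 10x hidden size "
            f"({10 * n_hidden}); the fit may be under-determined",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx_train, idx_val, idx_test = _split_indices(n, split, rng)

    in_scaling = _minmax_pairs(data.X[idx_train])
    out_scaling = _minmax_pairs(data.y[idx_train, None])
    Xs = _scale(data.X, in_scaling)
    ys = _scale(data.y[:, None], out_scaling).ravel()

    n_in = 3
    n_par = n_hidden * n_in + n_hidden + n_hidden + 1
    best = None  # (selection_rmse, theta)
    have_val = idx_val.size > 0
    for _ in range(max(n_restarts, 1)):
        theta0 = rng.uniform(-0.5, 0.5, size=n_par)
        state = {"best_rmse": np.inf, "best_theta": theta0.copy(), "stall": 0}

        def callback(theta, _state=state):
            if have_val:
                r = _rmse(theta, Xs[idx_val], ys[idx_val], n_hidden, n_in)
                if r < _state["best_rmse"] - 1e-12:
                    _state["best_rmse"] = r
                    _state["best_theta"] = theta.copy()
                    _state["stall"] = 0
                else:
                    _state["stall"] += 1
                    if _state["stall"] >= patience:
                        raise StopIteration

        try:
            res = minimize(
                _mse_and_grad,
                theta0,
                args=(Xs[idx_train], ys[idx_train], n_hidden, n_in),
                jac=True,
                method="L-BFGS-B",
                callback=callback,
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12},
            )
            theta_end = res.x
        except StopIteration:
            theta_end = state["best_theta"]
        if not np.all(np.isfinite(theta_end)):
            continue
        if have_val:
            # the early-stopping snapshot may beat the final iterate
            cand = min(
                (state["best_theta"], theta_end),
                key=lambda t: _rmse(t, Xs[idx_val], ys[idx_val], n_hidden, n_in),
            )
            score = _rmse(cand, Xs[idx_val], ys[idx_val], n_hidden, n_in)
        else:
            cand = theta_end
            score = _rmse(cand, Xs[idx_train], ys[idx_train], n_hidden, n_in)
        if not np.isfinite(score):
            continue
        if best is None or score < best[0]:
            best = (score, cand)

    if best is None:
        raise TrainingError("all restarts produced non-finite losses")

    iw, b1, lw, b2 = _unpack(best[1], n_hidden, n_in)
    model = AnnModel(
        input_weights=iw,
        hidden_bias=b1,
        layer_weights=lw.reshape(1, -1),
        output_bias=float(b2),
        input_scaling=in_scaling,
        output_scaling=out_scaling,
        hidden_transfer="tansig",
    )
    metrics: dict[str, FitMetrics | None] = {}
    for name, idx in (("train", idx_train), ("validation", idx_val), ("test", idx_test)):
        if idx.size == 0:
            metrics[name] = None
            continue
        pred = ann_predict(data.X[idx], model)
        metrics[name] = fit_metrics(data.y[idx], pred)
    return model, metrics


def ann_select_hidden(
    data: FactorialDataset, candidate_sizes, seed: int, **train_kwargs
) -> tuple[int, dict[int, dict]]:
    """Pick the hidden-layer size with the lowest validation RMSE.

    Every candidate is trained with the same seed (hence identical
    splits).  Ties break toward the smallest size.  Per-size results are
    returned under ``{"metrics": ..., "model": ...}`` or ``{"error": ...}``;
    only if every size fails is :class:`TrainingError` raised.
    """
    sizes = sorted(set(int(s) for s in candidate_sizes))
    if not sizes:
        raise DomainError("candidate_sizes must be non-empty")
    results: dict[int, dict] = {}
    best_size, best_rmse = None, np.inf
    for size in sizes:
        try:
            model, metrics = ann_train(data, size, seed=seed, **train_kwargs)
        except (TrainingError, DomainError) as exc:
            results[size] = {"error": str(exc)}
            continue
        val = metrics["validation"] or metrics["train"]
        results[size] = {"model": model, "metrics": metrics}
        if val.rmse < best_rmse - 1e-15:
            best_size, best_rmse = size, val.rmse
    if best_size is None:
        raise TrainingError("no candidate hidden size trained successfully")
    return best_size, results


# ---------------------------------------------------------------------------
# persistence

_REQUIRED_FIELDS = (
    "n_hidden",
    "input_weights",
    "hidden_bias",
    "layer_weights",
    "output_bias",
    "input_scaling",
    "output_scaling",
    "hidden_transfer",
)


def model_to_dict(model: AnnModel) -> dict:
    def scaling_out(s):
        return s if s == "identity" else [[float(a), float(b)] for a, b in s]

    return {
        "n_hidden": model.n_hidden,
        "input_weights": model.input_weights.tolist(),
        "hidden_bias": model.hidden_bias.tolist(),
        "layer_weights": model.layer_weights.tolist(),
        "output_bias": model.output_bias,
        "input_scaling": scaling_out(model.input_scaling),
        "output_scaling": scaling_out(model.output_scaling),
        "hidden_transfer": model.hidden_transfer,
    }


def model_from_dict(payload: dict) -> AnnModel:
    for name in _REQUIRED_FIELDS:
        if name not in payload:
            raise ParseError(f"ANN model file is missing field {name!r}")

    def scaling_in(s):
        return s if s == "identity" else [tuple(map(float, p)) for p in s]

    model = AnnModel(
        input_weights=np.array(payload["input_weights"], dtype=float),
        hidden_bias=np.array(payload["hidden_bias"], dtype=float),
        layer_weights=np.array(payload["layer_weights"], dtype=float),
        output_bias=float(payload["output_bias"]),
        input_scaling=scaling_in(payload["input_scaling"]),
        output_scaling=scaling_in(payload["output_scaling"]),
        hidden_transfer=str(payload["hidden_transfer"]),
    )
    if model.n_hidden != int(payload["n_hidden"]):
        raise ParseError(
            f"declared n_hidden={payload['n_hidden']} does not match "
            f"weight shape {model.n_hidden}"
        )
    return model


def save_model(model: AnnModel, path) -> None:
    """Serialize a model to JSON, preserving every field exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> AnnModel:
    """Load a model saved by :func:`save_model`."""
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed ANN model JSON: {exc}") from exc
    return model_from_dict(payload)


def load_reference_model() -> AnnModel:
    """Load the published 8-hidden-neuron reference network for the
    grape-pomace system.

    The source publication lists the weight matrices and biases but not
    the input/output scaling used during training, so the packaged file
    attaches min-max scaling over the experimental ranges
    (AED ∈ [41.1, 111.2] W/L, T ∈ [20, 40] °C, time ∈ [0, 60] min) with
    identity output scaling.  Predictions are therefore structurally
    faithful but not numerically authoritative.
    """
    with resources.files("atpex.data").joinpath("reference_ann.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return model_from_dict(json.load(fh))
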