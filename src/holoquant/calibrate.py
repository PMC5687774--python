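"""MLP calibration from hybrid colour descriptors to analyte concentration.

A small fully connected network maps the 9-dimensional hybrid colour
descriptor of the recognised sensor region to pH: two hidden layers with
log-sigmoid activations and a linear output, trained by full-batch
backpropagation on the mean squared error with classical momentum (plain
gradient descent when ``momentum=0``).  Training stops at ``max_iters``
iterations (default 10,000) or when the training MSE falls below
``error_limit`` (default 1e-6).  Inputs are z-scored with training statistics
stored in the model; the network is deliberately written out in NumPy so the
stopping rule (an absolute training-error threshold) and seeding are exactly
as specified rather than approximated through a generic library fit.

Datasets are split by sensor identity: whole sensors are held out (default
two of six), so the test set simulates genuinely unseen devices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPConfig", "MLPCalibrator", "split_dataset", "evaluate", "OPERATING_RANGE"]

#: pH interval the sensor is calibrated over; predictions outside a slightly
#: wider reporting band are flagged.
OPERATING_RANGE = (3.00, 6.50)
REPORT_RANGE = (2.5, 7.0)


@dataclass(frozen=True)
class MLPConfig:
    n_inputs: int = 9
    hidden_sizes: tuple[int, int] = (10, 5)
    max_iters: int = 10_000
    error_limit: float = 1e-6
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 2 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("exactly two positive hidden layer sizes are required")
        if self.error_limit <= 0:
            raise ValueError("error_limit must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def split_dataset(descriptors: np.ndarray, ph: np.ndarray, sensor_ids: np.ndarray,
                  n_test_sensors: int = 2, seed: int = 0):
    """Hold out whole sensors (default 2 of 6, a 2:1 train:test sensor ratio).

    Every sensor must appear at every pH level; returns
    ``(X_train, y_train, X_test, y_test, train_sensors, test_sensors)``.
    """
    descriptors = np.asarray(descriptors, dtype=float)
    ph = np.asarray(ph, dtype=float)
    sensor_ids = np.asarray(sensor_ids)
    sensors = np.unique(sensor_ids)
    if sensors.size < 3:
        raise ValueError("need at least 3 sensors to hold any out")
    levels = np.unique(ph)
    for s in sensors:
        if np.unique(ph[sensor_ids == s]).size != levels.size:
            raise ValueError(f"sensor {s!r} is missing pH levels")
    rng = np.random.default_rng(seed)
    test_sensors = rng.choice(sensors, size=n_test_sensors, replace=False)
    is_test = np.isin(sensor_ids, test_sensors)
    return (descriptors[~is_test], ph[~is_test], descriptors[is_test], ph[is_test],
            sensors[~np.isin(sensors, test_sensors)], np.sort(test_sensors))


class MLPCalibrator:
    """Two-hidden-layer perceptron regressor (sklearn-style).

    Attributes after ``fit``: ``weights_``/``biases_`` per layer, ``mean_``
    and ``scale_`` (input standardisation), ``n_iter_``, ``loss_curve_`` and
    ``final_error_`` (training MSE at the stop).
    """

    def __init__(self, config: MLPConfig = MLPConfig()):
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **kw) -> "MLPCalibrator":
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPCalibrator":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != cfg.n_inputs:
            raise ValueError(f"descriptors must be (n, {cfg.n_inputs})")
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("need a nonempty training set with one target per row")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = (X - self.mean_) / self.scale_

        h1, h2 = cfg.hidden_sizes
        rng = np.random.default_rng(cfg.seed)
        sizes = [cfg.n_inputs, h1, h2, 1]
        W = [rng.normal(0, np.sqrt(1.0 / sizes[i]), (sizes[i], sizes[i + 1])) for i in range(3)]
        b = [np.zeros(sizes[i + 1]) for i in range(3)]
        # start the linear read-out at the target mean so early iterations
        # shape the hidden layers instead of chasing the offset
        W[2][:] = 0.0
        b[2][:] = y.mean()

        n = len(Z)
        lr = cfg.learning_rate
        vel_W = [np.zeros_like(w) for w in W]
        vel_b = [np.zeros_like(v) for v in b]
        self.loss_curve_ = []
        for it in range(1, cfg.max_iters + 1):
            a1 = _sigmoid(Z @ W[0] + b[0])
            a2 = _sigmoid(a1 @ W[1] + b[1])
            out = (a2 @ W[2] + b[2]).ravel()
            err = out - y
            mse = float(np.mean(err**2))
            if not np.isfinite(mse):
                raise FloatingPointError("training diverged: try a smaller learning rate")
            self.loss_curve_.append(mse)
            if mse < cfg.error_limit:
                break
            delta3 = (2.0 / n) * err[:, None]
            delta2 = (delta3 @ W[2].T) * a2 * (1 - a2)
            delta1 = (delta2 @ W[1].T) * a1 * (1 - a1)
            grads_W = [Z.T @ delta1, a1.T @ delta2, a2.T @ delta3]
            grads_b = [delta1.sum(axis=0), delta2.sum(axis=0), delta3.sum(axis=0)]
            for layer in range(3):
                vel_W[layer] = cfg.momentum * vel_W[layer] - lr * grads_W[layer]
                vel_b[layer] = cfg.momentum * vel_b[layer] - lr * grads_b[layer]
                W[layer] += vel_W[layer]
                b[layer] += vel_b[layer]
        self.weights_ = W
        self.biases_ = b
        self.n_iter_ = it
        self.final_error_ = self.loss_curve_[-1]
        return self

    def predict(self, X: np.ndarray, return_flags: bool = False):
        """Forward pass; out-of-band values are flagged but still returned."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("MLPCalibrator is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.n_inputs:
            raise ValueError(f"descriptors must have {self.config.n_inputs} values")
        if not np.all(np.isfinite(X)):
            raise ValueError("descriptor contains non-finite values")
        Z = (X - self.mean_) / self.scale_
        a1 = _sigmoid(Z @ self.weights_[0] + self.biases_[0])
        a2 = _sigmoid(a1 @ self.weights_[1] + self.biases_[1])
        out = (a2 @ self.weights_[2] + self.biases_[2]).ravel()
        if return_flags:
            flags = (out < REPORT_RANGE[0]) | (out > REPORT_RANGE[1])
            return out, flags
        return out

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Coefficient of determination R^2."""
        return evaluate(self, X, y)["r2"]


def evaluate(model: MLPCalibrator, X: np.ndarray, y: np.ndarray) -> dict:
    """RMSE, R^2 and a per-level predicted-vs-true residual table."""
    y = np.asarray(y, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    pred = model.predict(X)
    resid = pred - y
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("-inf"))
    levels = np.unique(y)
    table = [
        {
            "true_ph": float(lv),
            "mean_predicted": float(pred[y == lv].mean()),
            "mean_residual": float(resid[y == lv].mean()),
            "n": int((y == lv).sum()),
        }
        for lv in levels
    ]
    return {"rmse": float(np.sqrt(np.mean(resid**2))), "r2": float(r2), "per_level": table,
            "predicted": pred, "true": y}
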