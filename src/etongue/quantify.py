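"""Feed-forward ANN multivariate calibration on DWT feature blocks.

A single-hidden-layer perceptron maps the compressed array response to
the analyte concentrations.  Transfer functions follow the Matlab
nomenclature used in the chemometrics literature: ``purelin`` (identity),
``tansig`` (tanh), ``logsig`` (logistic) and ``satlins`` (symmetric
saturating linear, clamp to [-1, 1]).  Inputs are z-scored per feature;
targets are affinely mapped into [-0.9, 0.9] per analyte so a ``satlins``
output layer trains in its linear region while still clamping
out-of-domain predictions.  Training minimizes full-batch mean squared
error with a deterministic seeded initialization and a quasi-Newton
(L-BFGS) optimizer, so identical seeds give identical weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .compression import FeatureBlockMatrix
from .core_data import ValidationError

__all__ = [
    "AnnTopology",
    "AnnModel",
    "TrainingError",
    "train_ann",
    "predict",
    "topology_search",
]

TARGET_RANGE = (-0.9, 0.9)


class TrainingError(RuntimeError):
    """Raised when network optimization fails (e.g. NaN loss)."""


def _identity(x):
    return x


def _d_identity(x):
    return np.ones_like(x)


def _tansig(x):
    return np.tanh(x)


def _d_tansig(x):
    return 1.0 - np.tanh(x) ** 2


def _logsig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _d_logsig(x):
    s = _logsig(x)
    return s * (1.0 - s)


def _satlins(x):
    return np.clip(x, -1.0, 1.0)


def _d_satlins(x):
    return ((x > -1.0) & (x < 1.0)).astype(float)


TRANSFERS: dict[str, tuple[Callable, Callable]] = {
    "purelin": (_identity, _d_identity),
    "tansig": (_tansig, _d_tansig),
    "logsig": (_logsig, _d_logsig),
    "satlins": (_satlins, _d_satlins),
}


@dataclass(frozen=True)
class AnnTopology:
    """Hidden-layer size and transfer-function pair of the perceptron."""

    n_hidden: int = 6
    hidden_transfer: str = "purelin"
    output_transfer: str = "satlins"

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValidationError(f"n_hidden must be >= 1, got {self.n_hidden}")
        for name in (self.hidden_transfer, self.output_transfer):
            if name not in TRANSFERS:
                raise ValidationError(
                    f"unknown transfer {name!r}; choose from {sorted(TRANSFERS)}"
                )


@dataclass
class AnnModel:
    """Trained network with its scalers and training metadata."""

    topology: AnnTopology
    analytes: list[str]
    n_features_in: int
    kept_columns: np.ndarray  # indices of non-degenerate input features
    input_mean: np.ndarray
    input_sd: np.ndarray
    target_low: np.ndarray  # per-analyte affine map to TARGET_RANGE
    target_high: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    seed: int = 0
    n_iterations: int = 0
    final_loss: float = float("nan")

    # -- scaling -------------------------------------------------------
    def scale_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_columns]
        return (X - self.input_mean) / self.input_sd

    def scale_targets(self, Y: np.ndarray) -> np.ndarray:
        lo, hi = TARGET_RANGE
        span = self.target_high - self.target_low
        return lo + (hi - lo) * (np.asarray(Y, dtype=float) - self.target_low) / span

    def unscale_targets(self, Ys: np.ndarray) -> np.ndarray:
        lo, hi = TARGET_RANGE
        span = self.target_high - self.target_low
        return self.target_low + (np.asarray(Ys, dtype=float) - lo) * span / (hi - lo)

    # -- forward pass --------------------------------------------------
    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        f, _ = TRANSFERS[self.topology.hidden_transfer]
        g, _ = TRANSFERS[self.topology.output_transfer]
        A1 = f(Xs @ self.W1.T + self.b1)
        return g(A1 @ self.W2.T + self.b2)

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "topology": {
                "n_hidden": self.topology.n_hidden,
                "hidden_transfer": self.topology.hidden_transfer,
                "output_transfer": self.topology.output_transfer,
            },
            "analytes": self.analytes,
            "n_features_in": self.n_features_in,
            "kept_columns": self.kept_columns.tolist(),
            "input_mean": self.input_mean.tolist(),
            "input_sd": self.input_sd.tolist(),
            "target_low": self.target_low.tolist(),
            "target_high": self.target_high.tolist(),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "final_loss": self.final_loss,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnModel":
        d = json.loads(Path(path).read_text())
        return cls(
            topology=AnnTopology(**d["topology"]),
            analytes=list(d["analytes"]),
            n_features_in=int(d["n_features_in"]),
            kept_columns=np.asarray(d["kept_columns"], dtype=int),
            input_mean=np.asarray(d["input_mean"], dtype=float),
            input_sd=np.asarray(d["input_sd"], dtype=float),
            target_low=np.asarray(d["target_low"], dtype=float),
            target_high=np.asarray(d["target_high"], dtype=float),
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            seed=int(d["seed"]),
            n_iterations=int(d["n_iterations"]),
            final_loss=float(d["final_loss"]),
        )


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta: np.ndarray, d: int, h: int, o: int):
    i = 0
    W1 = theta[i : i + h * d].reshape(h, d)
    i += h * d
    b1 = theta[i : i + h]
    i += h
    W2 = theta[i : i + o * h].reshape(o, h)
    i += o * h
    b2 = theta[i : i + o]
    return W1, b1, W2, b2


def train_ann(
    train_fb: FeatureBlockMatrix | np.ndarray,
    targets: np.ndarray | None = None,
    topology: AnnTopology | None = None,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    analytes: Sequence[str] | None = None,
    init_scale: float = 0.01,
    variance_floor: float = 1e-2,
) -> AnnModel:
    """Train the perceptron on a feature-block matrix.

    ``targets`` (samples × analytes, µM) defaults to the concentrations
    carried by the feature blocks.  Training is full-batch MSE
    minimization by L-BFGS with analytic gradients from a seeded uniform
    initialization in ``[-init_scale, init_scale]``; the result is
    deterministic for a given seed.  The small default initialization
    matters when features outnumber samples: gradient-based training
    that starts near zero stays close to the minimal-norm interpolant,
    which is what keeps an exactly-fitting network well behaved on new
    samples.

    Degenerate input columns are dropped with a warning.  Degeneracy is
    judged relative to the data scale: a column whose training standard
    deviation is below ``variance_floor`` times the largest column's
    carries no usable signal, and per-feature z-scoring would otherwise
    amplify it into a unit-variance pure-noise input — a classic failure
    mode when wavelet coefficients from flat trace regions meet a small
    calibration set.  Set ``variance_floor=0`` to keep every non-constant
    column.
    """
    if isinstance(train_fb, FeatureBlockMatrix):
        X = train_fb.values
        if targets is None:
            targets = train_fb.concentrations
        if analytes is None:
            analytes = train_fb.analytes
    else:
        X = np.asarray(train_fb, dtype=float)
    if targets is None:
        raise ValidationError("training targets are required")
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if analytes is None:
        analytes = [f"analyte_{j + 1}" for j in range(Y.shape[1])]
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("feature and target row counts differ")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training samples")
    if not np.isfinite(Y).all() or (Y < 0).any():
        raise ValidationError("targets must be finite and >= 0")
    topology = topology or AnnTopology()

    sd = X.std(axis=0, ddof=0)
    threshold = max(1e-12, variance_floor * float(sd.max()))
    kept = np.flatnonzero(sd > threshold)
    if kept.size == 0:
        raise ValidationError("all feature columns are degenerate (zero variance)")
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} degenerate feature column(s) "
            f"(sd below {variance_floor:g} of the largest column's)",
            stacklevel=2,
        )
    mean = X[:, kept].mean(axis=0)
    scale = X[:, kept].std(axis=0, ddof=0)
    Xs = (X[:, kept] - mean) / scale

    t_lo = Y.min(axis=0)
    t_hi = Y.max(axis=0)
    if np.any(t_hi - t_lo <= 0):
        raise ValidationError("each analyte needs a nonzero target range")

    model = AnnModel(
        topology=topology,
        analytes=list(analytes),
        n_features_in=X.shape[1],
        kept_columns=kept,
        input_mean=mean,
        input_sd=scale,
        target_low=t_lo,
        target_high=t_hi,
        W1=np.zeros((topology.n_hidden, kept.size)),
        b1=np.zeros(topology.n_hidden),
        W2=np.zeros((Y.shape[1], topology.n_hidden)),
        b2=np.zeros(Y.shape[1]),
        seed=seed,
    )
    Ys = model.scale_targets(Y)

    d, h, o = kept.size, topology.n_hidden, Y.shape[1]
    f, df = TRANSFERS[topology.hidden_transfer]
    g, dg = TRANSFERS[topology.output_transfer]
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-init_scale, init_scale, size=h * d + h + o * h + o)

    def loss_grad(theta):
        W1, b1, W2, b2 = _unpack(theta, d, h, o)
        Z1 = Xs @ W1.T + b1
        A1 = f(Z1)
        Z2 = A1 @ W2.T + b2
        Yp = g(Z2)
        R = Yp - Ys
        L = float(np.mean(R**2))
        dZ2 = (2.0 / R.size) * R * dg(Z2)
        gW2 = dZ2.T @ A1
        gb2 = dZ2.sum(axis=0)
        dZ1 = (dZ2 @ W2) * df(Z1)
        gW1 = dZ1.T @ Xs
        gb1 = dZ1.sum(axis=0)
        return L, _pack(gW1, gb1, gW2, gb2)

    res = minimize(
        loss_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
    )
    if not np.isfinite(res.fun):
        raise TrainingError(f"training diverged (loss = {res.fun})")
    model.W1, model.b1, model.W2, model.b2 = _unpack(res.x, d, h, o)
    model.n_iterations = int(res.nit)
    model.final_loss = float(res.fun)
    return model


def predict(model: AnnModel, fb: FeatureBlockMatrix | np.ndarray) -> np.ndarray:
    """Predicted concentrations (µM) for new samples.

    The feature layout must match training.  A saturating output transfer
    clamps predictions to the calibrated concentration domain (up to the
    affine margin of the target scaling).
    """
    X = fb.values if isinstance(fb, FeatureBlockMatrix) else np.asarray(fb, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise ValidationError(
            f"feature count {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"training layout ({model.n_features_in})"
        )
    Ys = model.forward_scaled(model.scale_inputs(X))
    return model.unscale_targets(Ys)


def topology_search(
    train_fb: FeatureBlockMatrix,
    train_targets: np.ndarray | None,
    test_fb: FeatureBlockMatrix,
    test_targets: np.ndarray | None,
    grid: Sequence[AnnTopology],
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
):
    """Train every topology in ``grid`` and rank by total test RMSE.

    All candidates share the same seed policy so the comparison isolates
    the topology.  Returns ``(results, best_model)`` where ``results`` is
    a DataFrame with one RMSE-sorted row per candidate.
    """
    import pandas as pd

    grid = list(grid)
    if not grid:
        raise ValidationError("topology grid must be non-empty")
    if train_targets is None:
        train_targets = train_fb.concentrations
    if test_targets is None:
        test_targets = test_fb.concentrations
    test_targets = np.asarray(test_targets, dtype=float)

    rows = []
    models = []
    for topo in grid:
        model = train_ann(
            train_fb, train_targets, topology=topo, seed=seed, max_iter=max_iter, tol=tol
        )
        pred = predict(model, test_fb)
        rmse_total = float(np.sqrt(np.mean((pred - test_targets) ** 2)))
        rows.append(
            {
                "n_hidden": topo.n_hidden,
                "hidden_transfer": topo.hidden_transfer,
                "output_transfer": topo.output_transfer,
                "test_rmse_total_uM": rmse_total,
                "train_loss": model.final_loss,
            }
        )
        models.append(model)
    results = pd.DataFrame(rows)
    order = results["test_rmse_total_uM"].to_numpy().argsort(kind="stable")
    results = results.iloc[order].reset_index(drop=True)
    best_model = models[int(order[0])]
    return results, best_model
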