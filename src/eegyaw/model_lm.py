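"""Feedforward 30-10-1 network trained with Levenberg-Marquardt.

The decoding function f is a single-hidden-layer perceptron with tanh
hidden units and a linear output,

    yhat = W2 . tanh(W1 x + b1) + b2 ,

fitted by full-batch Levenberg-Marquardt on the sum of squared errors.
The residual Jacobian is computed analytically by backpropagation; each LM
step solves

    (J'J + mu I) d = J'e ,      e = y - yhat,   J = d yhat / d theta,

accepting the candidate only when the SSE decreases (mu /= 10 on accept,
mu *= 10 and retry otherwise).  As mu -> 0 the step approaches Gauss-Newton;
as mu -> infinity it approaches a scaled gradient step.  Training is
deterministic given the initialisation seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg as sla

from .dataset import WindowedDataset

__all__ = [
    "MLPModel",
    "FitReport",
    "TrainConfig",
    "forward",
    "jacobian",
    "lm_step",
    "train",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

HIDDEN_DIM = 10


@dataclass
class MLPModel:
    """Weights of the one-hidden-layer network (the decoding function f)."""

    W1: np.ndarray   # (hidden, input)
    b1: np.ndarray   # (hidden,)
    W2: np.ndarray   # (hidden,)
    b2: float
    hidden_activation: str = "tanh"

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = float(self.b2)
        h, i = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (h,):
            raise ValueError("inconsistent parameter shapes")
        if self.hidden_activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        for p in (self.W1, self.b1, self.W2, (self.b2,)):
            if not np.all(np.isfinite(p)):
                raise ValueError("parameters must be finite")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + 1

    def pack(self) -> np.ndarray:
        """Flatten parameters as [W1.ravel, b1, W2, b2]."""
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2, [self.b2]]
        )

    def with_params(self, theta: np.ndarray) -> "MLPModel":
        h, i = self.W1.shape
        w1 = theta[: h * i].reshape(h, i)
        b1 = theta[h * i : h * i + h]
        w2 = theta[h * i + h : h * i + 2 * h]
        b2 = theta[-1]
        return MLPModel(
            W1=w1, b1=b1, W2=w2, b2=b2, hidden_activation=self.hidden_activation
        )


@dataclass
class FitReport:
    epochs_run: int
    sse_trajectory: list[float]      # SSE after each accepted step
    final_mu: float
    stop_reason: str                 # max_epochs | gradient_tol | mu_overflow | sse_tol
    seed: int


@dataclass(frozen=True)
class TrainConfig:
    """LM hyperparameters (conventional damped Gauss-Newton defaults)."""

    hidden_dim: int = HIDDEN_DIM
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 10.0
    mu_max: float = 1e10
    max_epochs: int = 1000
    grad_tol: float = 1e-7
    sse_tol: float = 1e-12


def _activation(model: MLPModel, z: np.ndarray) -> np.ndarray:
    return np.tanh(z) if model.hidden_activation == "tanh" else z


def _activation_deriv(model: MLPModel, h: np.ndarray) -> np.ndarray:
    return 1.0 - h**2 if model.hidden_activation == "tanh" else np.ones_like(h)


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Evaluate yhat = W2 . act(W1 x + b1) + b2 row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.input_dim}"
        )
    h = _activation(model, X @ model.W1.T + model.b1)
    return h @ model.W2 + model.b2


def jacobian(
    model: MLPModel, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals e = y - yhat and the output Jacobian J = d yhat / d theta.

    Columns follow the ``pack`` ordering [W1.ravel, b1, W2, b2].  Computed
    in one backpropagation pass; J has shape (n_examples, n_params).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    h = _activation(model, X @ model.W1.T + model.b1)    # (n, H)
    yhat = h @ model.W2 + model.b2
    e = y - yhat
    d = _activation_deriv(model, h) * model.W2           # (n, H)
    n, H = h.shape
    J = np.empty((n, model.n_params))
    # d yhat / d W1[k, j] = W2_k act'(z_k) x_j
    J[:, : H * model.input_dim] = (
        d[:, :, None] * X[:, None, :]
    ).reshape(n, H * model.input_dim)
    J[:, H * model.input_dim : H * model.input_dim + H] = d
    J[:, H * model.input_dim + H : H * model.input_dim + 2 * H] = h
    J[:, -1] = 1.0
    return e, J


def lm_step(
    model: MLPModel, X: np.ndarray, y: np.ndarray, mu: float
) -> tuple[MLPModel, float]:
    """One damped Gauss-Newton step: theta + (J'J + mu I)^-1 J'e.

    Returns the candidate model and the SSE predicted by the local linear
    model, ``|e - J d|^2``.  With mu = 0 and a singular normal matrix the
    underlying solve raises; the caller should increase mu.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    e, J = jacobian(model, X, y)
    A = J.T @ J
    A[np.diag_indices_from(A)] += mu
    g = J.T @ e
    delta = sla.solve(A, g, assume_a="pos")
    predicted_sse = float(np.sum((e - J @ delta) ** 2))
    return model.with_params(model.pack() + delta), predicted_sse


def init_model(input_dim: int, hidden_dim: int, seed: int) -> MLPModel:
    """Small uniform init, scaled by fan-in; seeded and deterministic."""
    rng = np.random.default_rng(seed)
    return MLPModel(
        W1=rng.uniform(-0.5, 0.5, (hidden_dim, input_dim)) / np.sqrt(input_dim),
        b1=rng.uniform(-0.5, 0.5, hidden_dim),
        W2=rng.uniform(-0.5, 0.5, hidden_dim) / np.sqrt(hidden_dim),
        b2=0.0,
    )


def train(
    ds_train: WindowedDataset | tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[MLPModel, FitReport]:
    """Fit the network to a windowed dataset by full-batch LM.

    Candidates are accepted only on SSE decrease, so the accepted-step SSE
    trajectory is non-increasing.  Stops on ``max_epochs`` accepted steps,
    gradient infinity-norm below ``grad_tol``, SSE below ``sse_tol`` or
    damping overflow (``mu > mu_max``).
    """
    if isinstance(ds_train, tuple):
        X, y = ds_train
    else:
        X, y = ds_train.X, ds_train.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(X) == 0:
        raise ValueError("training set is empty")

    model = init_model(X.shape[1], config.hidden_dim, seed)
    mu = config.mu0
    e, J = jacobian(model, X, y)
    sse = float(e @ e)
    if not np.isfinite(sse):
        raise FloatingPointError("non-finite initial loss")
    trajectory = [sse]
    stop_reason = "max_epochs"
    epochs = 0
    while epochs < config.max_epochs:
        g = J.T @ e
        if np.max(np.abs(g)) < config.grad_tol:
            stop_reason = "gradient_tol"
            break
        if sse < config.sse_tol:
            stop_reason = "sse_tol"
            break
        A = J.T @ J
        diag = np.diag_indices_from(A)
        accepted = False
        while mu <= config.mu_max:
            A_damped = A.copy()
            A_damped[diag] += mu
            try:
                delta = sla.solve(A_damped, g, assume_a="pos")
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            candidate = model.with_params(model.pack() + delta)
            e_c = y - forward(candidate, X)
            sse_c = float(e_c @ e_c)
            if not np.isfinite(sse_c):
                raise FloatingPointError("non-finite loss during training")
            if sse_c < sse:
                model, sse = candidate, sse_c
                mu = max(mu / config.mu_dec, 1e-20)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            stop_reason = "mu_overflow"
            break
        epochs += 1
        trajectory.append(sse)
        logger.debug("epoch %d: sse=%.6g mu=%.3g", epochs, sse, mu)
        e, J = jacobian(model, X, y)
    report = FitReport(
        epochs_run=epochs,
        sse_trajectory=trajectory,
        final_mu=mu,
        stop_reason=stop_reason,
        seed=seed,
    )
    return model, report


def save_model(model: MLPModel, path: str | Path) -> None:
    """Serialise topology and weights to JSON."""
    payload = {
        "input_dim": model.input_dim,
        "hidden_dim": model.hidden_dim,
        "hidden_activation": model.hidden_activation,
        "theta": model.pack().tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> MLPModel:
    payload = json.loads(Path(path).read_text())
    template = MLPModel(
        W1=np.zeros((payload["hidden_dim"], payload["input_dim"])),
        b1=np.zeros(payload["hidden_dim"]),
        W2=np.zeros(payload["hidden_dim"]),
        b2=0.0,
        hidden_activation=payload["hidden_activation"],
    )
    return template.with_params(np.asarray(payload["theta"]))
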