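"""A small feed-forward network for disease-status regression.

One hidden layer of sigmoidal units and a linear output trained by
full-batch L-BFGS on a mean-squared-error objective with a light L2
penalty.  The target is the binary health status coded 0/1 (or the 0-5
vet score rescaled internally), so predictions are clipped to the target
range.  Training is bit-reproducible given the seed: the only randomness
is the weight initialization, and the optimizer is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["AnnConfig", "AnnModel", "train_model"]


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the network.

    hidden_units : width of the single hidden layer (default 5 — small
        enough for cohorts of a few dozen fish).
    l2 : ridge penalty on the weights (biases unpenalized); keeps the
        76-odd parameters from interpolating n~27 training points exactly.
    max_iter : L-BFGS iteration cap; hitting it flags non-convergence.
    """

    hidden_units: int = 5
    l2: float = 2e-2
    max_iter: int = 400
    tol: float = 1e-10


def _unpack(theta: np.ndarray, d: int, h: int):
    i = 0
    w1 = theta[i:i + d * h].reshape(d, h); i += d * h
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + h]; i += h
    b2 = theta[i]
    return w1, b1, w2, b2


def _loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, h: int, l2: float):
    n, d = X.shape
    w1, b1, w2, b2 = _unpack(theta, d, h)
    z = expit(X @ w1 + b1)
    yhat = z @ w2 + b2
    r = (yhat - y) / n
    loss = 0.5 * n * float(r @ r) + 0.5 * l2 * (float((w1 * w1).sum()) + float(w2 @ w2))
    gw2 = z.T @ r + l2 * w2
    gb2 = r.sum()
    dz = np.outer(r, w2) * z * (1.0 - z)
    gw1 = X.T @ dz + l2 * w1
    gb1 = dz.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


@dataclass
class AnnModel:
    """A trained network plus the min-max scaling learned on its training set."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_min: np.ndarray
    x_range: np.ndarray
    config: AnnConfig
    seed: int
    n_iter: int
    converged: bool
    loss_history: list[float] = field(default_factory=list)
    output_clip: tuple[float, float] = (0.0, 1.0)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_min) / self.x_range

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Unclipped network output for raw-unit inputs."""
        Xs = self._scale(np.atleast_2d(X))
        return expit(Xs @ self.w1 + self.b1) @ self.w2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted status for raw-unit inputs, clipped to the target range."""
        lo, hi = self.output_clip
        return np.clip(self.predict_raw(X), lo, hi)


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    config: AnnConfig | None = None,
    output_clip: tuple[float, float] = (0.0, 1.0),
) -> AnnModel:
    """Fit the network to a complete-case feature matrix.

    Inputs are min-max scaled to [0, 1] using this training set only, so a
    model can later be applied to held-out records without leakage.  The
    recorded loss history (initial value plus one entry per accepted
    L-BFGS iterate) is non-increasing.  Raises on missing cells, a
    constant target, or fewer than 10 training records.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (records x features)")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) < 10:
        raise ValueError(f"need at least 10 training records, got {len(X)}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite cells in training data")
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant target")
    cfg = config or AnnConfig()
    n, d = X.shape
    h = cfg.hidden_units

    x_min = X.min(axis=0)
    x_range = X.max(axis=0) - x_min
    x_range = np.where(x_range == 0.0, 1.0, x_range)  # constant feature -> maps to 0
    Xs = (X - x_min) / x_range

    rng = np.random.default_rng(seed)
    theta0 = np.concatenate([
        rng.normal(scale=1.0 / np.sqrt(d), size=d * h),
        np.zeros(h),
        rng.normal(scale=1.0 / np.sqrt(h), size=h),
        [float(y.mean())],
    ])

    history: list[float] = [_loss_grad(theta0, Xs, y, h, cfg.l2)[0]]

    def cb(theta_k: np.ndarray) -> None:
        history.append(_loss_grad(theta_k, Xs, y, h, cfg.l2)[0])

    res = minimize(
        _loss_grad, theta0, args=(Xs, y, h, cfg.l2), jac=True,
        method="L-BFGS-B", callback=cb,
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-8},
    )
    converged = bool(res.success) or res.nit < cfg.max_iter
    if not converged:
        warnings.warn(
            f"network did not converge within {cfg.max_iter} iterations "
            f"(final loss {res.fun:.3g})"
        )
    w1, b1, w2, b2 = _unpack(res.x, d, h)
    return AnnModel(
        w1=w1, b1=b1, w2=w2, b2=float(b2),
        x_min=x_min, x_range=x_range,
        config=cfg, seed=seed, n_iter=int(res.nit), converged=converged,
        loss_history=history, output_clip=output_clip,
    )
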