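"""Gaussian radial-basis-function network regression.

Architecture: one hidden layer of Gaussian units sharing a single width r,
h_j(x) = exp(−‖x − c_j‖² / r²), followed by a linear output layer
y(x) = Σ_j w_j h_j(x) + b. Training is the classical greedy scheme: hidden
units are recruited one at a time from the training points themselves, at
each step admitting the candidate centre whose addition — with the output
layer re-solved exactly by linear least squares — most reduces the training
SSE, until an error goal or a maximum hidden-layer size is reached. Ties
are broken by the lowest training-row index, so training is deterministic
given the input order.

Inputs are z-scored per column before any distance computation (the
standardisation parameters are stored in the model); Euclidean distances
over raw heterogeneous descriptors would otherwise be dominated by the
largest-scaled column.

The width scan retrains the network over a grid of widths (0.1–4.0 in
steps of 0.1 by default, 40 values) and picks the width with the best
leave-one-out q², computed in closed form on the linear output layer with
the chosen centres held fixed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._linear import loo_q2_linear
from .exceptions import InvalidWidthError, UndefinedStatisticError

__all__ = [
    "RBFNNModel",
    "rbf_activation",
    "train_rbfnn",
    "predict_rbfnn",
    "scan_width",
    "default_width_grid",
]


def rbf_activation(x, c, r: float) -> float:
    """Gaussian unit response exp(−‖x−c‖²/r²) ∈ (0, 1]."""
    if r <= 0:
        raise InvalidWidthError(f"width must be positive, got {r}")
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {c.shape}")
    return float(np.exp(-np.sum((x - c) ** 2) / r**2))


def _design(X: np.ndarray, centers: np.ndarray, r: float) -> np.ndarray:
    """Hidden-layer design matrix with trailing bias column."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    H = np.exp(-d2 / r**2)
    return np.column_stack([H, np.ones(len(X))])


@dataclass
class RBFNNModel:
    """Trained network: centres, shared width, output weights and bias."""

    centers: np.ndarray          # n_h × p, in standardised coordinates
    width: float
    weights: np.ndarray          # n_h output weights
    bias: float
    x_mean: np.ndarray
    x_std: np.ndarray
    descriptor_names: list[str] | None = None
    center_indices: list[int] | None = None  # training rows used as centres

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.x_std = np.asarray(self.x_std, dtype=float)
        if self.width <= 0:
            raise InvalidWidthError(f"width must be positive, got {self.width}")
        if len(self.weights) != len(self.centers):
            raise ValueError("one output weight per hidden unit required")

    @property
    def architecture(self) -> tuple[int, int, int]:
        """(inputs, hidden units, outputs)."""
        return (self.centers.shape[1], self.centers.shape[0], 1)

    @property
    def p(self) -> int:
        return self.centers.shape[1]

    def _standardise(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.descriptor_names is not None:
                missing = [c for c in self.descriptor_names if c not in X.columns]
                if missing:
                    raise ValueError(f"missing descriptor columns {missing}")
                X = X[self.descriptor_names]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} input columns, got {X.shape[1]}")
        return (X - self.x_mean) / self.x_std

    def predict(self, X) -> np.ndarray:
        Z = self._standardise(X)
        if len(Z) == 0:
            return np.empty(0)
        H = _design(Z, self.centers, self.width)
        return H @ np.append(self.weights, self.bias)

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "width": self.width,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "descriptor_names": self.descriptor_names,
            "center_indices": self.center_indices,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RBFNNModel":
        return cls(**payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RBFNNModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _coerce(X, y=None):
    names = None
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X rows must align with y")
    return names, X, y


def train_rbfnn(
    X,
    y,
    width: float,
    n_hidden_max: int | None = None,
    sse_goal: float = 0.0,
) -> RBFNNModel:
    """Train by greedy centre recruitment with exact output-layer solves.

    Duplicate training rows can serve as a centre only once; an
    ill-conditioned output solve falls back to the least-norm solution with
    a warning.
    """
    if width <= 0:
        raise InvalidWidthError(f"width must be positive, got {width}")
    names, X, y = _coerce(X, y)
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    if n_hidden_max is None:
        n_hidden_max = n
    if n_hidden_max > n:
        raise ValueError(f"n_hidden_max={n_hidden_max} exceeds n={n}")

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=0)
    x_std = np.where(x_std == 0, 1.0, x_std)
    Z = (X - x_mean) / x_std

    # candidate centres = unique training rows (first occurrence wins)
    _, first_idx = np.unique(Z, axis=0, return_index=True)
    candidate_pool = sorted(first_idx.tolist())

    selected: list[int] = []
    best_beta = np.array([y.mean()])
    sse = float(np.sum((y - y.mean()) ** 2))
    rank_warned = False

    while len(selected) < n_hidden_max and sse > sse_goal:
        best = None
        for idx in candidate_pool:
            if idx in selected:
                continue
            trial = selected + [idx]
            H = _design(Z, Z[trial], width)
            beta, _, rank, _ = np.linalg.lstsq(H, y, rcond=None)
            if rank < H.shape[1] and not rank_warned:
                warnings.warn(
                    "ill-conditioned output solve; using least-norm solution",
                    stacklevel=2,
                )
                rank_warned = True
            res = y - H @ beta
            trial_sse = float(res @ res)
            if best is None or trial_sse < best[0] - 1e-12:
                best = (trial_sse, idx, beta)
        if best is None:
            break
        trial_sse, idx, beta = best
        if trial_sse > sse + 1e-12:
            break  # no candidate reduces the error further
        sse, best_beta = trial_sse, beta
        selected.append(idx)

    if not selected:
        raise UndefinedStatisticError(
            "no hidden unit reduced the training error (constant response?)"
        )
    return RBFNNModel(
        centers=Z[selected],
        width=width,
        weights=best_beta[:-1],
        bias=float(best_beta[-1]),
        x_mean=x_mean,
        x_std=x_std,
        descriptor_names=names,
        center_indices=selected,
    )


def predict_rbfnn(model: RBFNNModel, X) -> np.ndarray:
    """Functional alias for :meth:`RBFNNModel.predict`."""
    return model.predict(X)


def default_width_grid() -> np.ndarray:
    """Published scan grid: 0.1 to 4.0 in steps of 0.1 (40 widths)."""
    return np.arange(1, 41) / 10.0


def loo_q2_rbf(model: RBFNNModel, X, y) -> float:
    """LOO q² of the linear output layer, centres held fixed."""
    _, Xv, y = _coerce(X, y)
    Z = (Xv - model.x_mean) / model.x_std
    H = _design(Z, model.centers, model.width)
    return loo_q2_linear(H, y)


def scan_width(
    X,
    y,
    grid=None,
    *,
    n_hidden_max: int | None = None,
    sse_goal: float = 0.0,
    criterion: str = "loo_q2",
) -> tuple[float, RBFNNModel, pd.DataFrame]:
    """Train across a width grid and select the best width.

    ``criterion`` is ``"loo_q2"`` (default; maximise the output-layer
    leave-one-out q²) or ``"sse"`` (minimise training SSE, which degenerates
    toward small widths and is provided for comparison only). Returns
    ``(best_width, best_model, table)`` where ``table`` has one row per
    width with its score. Ties prefer the smaller width.
    """
    if grid is None:
        grid = default_width_grid()
    grid = np.asarray(list(grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("width grid is empty")
    if np.any(grid <= 0):
        raise InvalidWidthError("all widths must be positive")
    if criterion not in ("loo_q2", "sse"):
        raise ValueError(f"unknown criterion {criterion!r}")

    rows = []
    best = None
    last_error: Exception | None = None
    for r in grid:
        try:
            model = train_rbfnn(X, y, float(r), n_hidden_max=n_hidden_max, sse_goal=sse_goal)
        except Exception as exc:  # noqa: BLE001 - propagate last failure if all fail
            last_error = exc
            rows.append({"width": float(r), "score": np.nan, "n_hidden": 0})
            continue
        yhat = model.predict(X)
        sse = float(np.sum((np.asarray(y, dtype=float) - yhat) ** 2))
        if criterion == "loo_q2":
            try:
                score = loo_q2_rbf(model, X, y)
            except UndefinedStatisticError:
                score = -np.inf
        else:
            score = -sse
        rows.append(
            {
                "width": float(r),
                "score": float(score),
                "sse": sse,
                "n_hidden": model.architecture[1],
            }
        )
        if best is None or score > best[0] + 1e-12:
            best = (score, float(r), model)

    table = pd.DataFrame(rows)
    if best is None:
        raise last_error if last_error is not None else RuntimeError("no width trained")
    _, best_width, best_model = best
    return best_width, best_model, table
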