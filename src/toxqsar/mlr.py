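"""Multiple linear regression with heuristic forward descriptor selection.

The selection procedure mirrors the classical heuristic-method search used
in descriptor-based QSAR: single descriptors are ranked by their
one-variable regression F, the best one seeds the model, and candidates are
then added one at a time — each step admits the descriptor that maximises
the overall F of the enlarged model, skipping any candidate whose absolute
Pearson correlation with an already-selected descriptor reaches the
intercorrelation bound (0.8 by default) — until the requested model size is
reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linear import augment, loo_q2_linear, ols_solve
from .exceptions import UnderdeterminedError, UndefinedStatisticError
from .validation import f_statistic, r_squared, rms_error

__all__ = ["FitStatistics", "MLRModel", "fit_mlr", "heuristic_select", "loo_q2"]

INTERCORRELATION_BOUND = 0.8


@dataclass
class FitStatistics:
    """Training-set summary of a least-squares fit."""

    n: int
    p: int
    r2: float
    q2_loo: float
    f: float
    rms: float


@dataclass
class MLRModel:
    """Ordinary least squares model Y = b0 + Σ b_i x_i."""

    descriptor_names: list[str]
    b0: float
    b: np.ndarray
    se: np.ndarray
    t: np.ndarray
    train_stats: FitStatistics

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if not len(self.descriptor_names) == len(self.b) == len(self.se) == len(self.t):
            raise ValueError("names, coefficients, se and t must have equal length")

    @property
    def p(self) -> int:
        return len(self.b)

    def predict(self, X) -> np.ndarray:
        X = self._as_matrix(X)
        return self.b0 + X @ self.b

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.descriptor_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing descriptor columns {missing}")
            X = X[self.descriptor_names]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} descriptor columns, got {X.shape[1]}")
        return X

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "b0": self.b0,
            "b": self.b.tolist(),
            "se": self.se.tolist(),
            "t": self.t.tolist(),
            "train_stats": vars(self.train_stats),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MLRModel":
        data = dict(payload)
        data["train_stats"] = FitStatistics(**data["train_stats"])
        return cls(**data)


def _coerce_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        names = [f"x{j + 1}" for j in range(values.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(values) != len(y):
        raise ValueError(f"X has {len(values)} rows but y has {len(y)}")
    return names, values, y


def fit_mlr(X, y, *, rms_ddof: int = 0) -> MLRModel:
    """Fit an intercept OLS model and populate coefficient and fit statistics.

    ``rms_ddof=0`` (default) uses the divisor-n RMS; pass ``rms_ddof=p+1``
    for the residual-degrees-of-freedom form. Standard errors and t values
    use the unbiased residual variance regardless.
    """
    names, values, y = _coerce_xy(X, y)
    n, p = values.shape
    if n <= p + 1:
        raise UnderdeterminedError(f"need n > p + 1 (got n={n}, p={p})")
    design = augment(values)
    beta, _ = ols_solve(design, y)  # raises SingularDesignError if rank deficient

    fitted = design @ beta
    residuals = y - fitted
    dof = n - p - 1
    sigma2 = float(residuals @ residuals) / dof
    gram_inv = np.linalg.inv(design.T @ design)
    se_all = np.sqrt(sigma2 * np.diag(gram_inv))
    t_all = np.zeros_like(beta)
    nonzero_se = se_all > 0
    t_all[nonzero_se] = beta[nonzero_se] / se_all[nonzero_se]
    exact = ~nonzero_se & (beta != 0)  # exact fit: zero residual variance
    t_all[exact] = np.inf * np.sign(beta[exact])

    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant response: fit is the mean, every summary degenerates
        r2 = 0.0
        q2 = 0.0
        f = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot  # equals corr(y, fitted)² for intercept OLS
        q2 = loo_q2_linear(design, y)
        f = f_statistic(min(r2, 1.0 - 1e-15), n, p) if r2 < 1.0 else float("inf")
    rms = float(np.sqrt(ss_res / (n - rms_ddof)))

    stats = FitStatistics(n=n, p=p, r2=r2, q2_loo=q2, f=f, rms=rms)
    return MLRModel(
        descriptor_names=names,
        b0=float(beta[0]),
        b=beta[1:],
        se=se_all[1:],
        t=t_all[1:],
        train_stats=stats,
    )


def loo_q2(X, y) -> float:
    """Leave-one-out q² = 1 − PRESS/SStot for an intercept OLS model.

    Uses the closed-form deleted residual e_i/(1−h_ii); numerically equal to
    refitting the model n times.
    """
    _, values, y = _coerce_xy(X, y)
    if len(y) < 3:
        raise ValueError("need at least three observations")
    return loo_q2_linear(augment(values), y)


def heuristic_select(
    matrix: pd.DataFrame,
    y,
    n_target: int,
    *,
    intercorrelation_bound: float = INTERCORRELATION_BOUND,
) -> list[str]:
    """Forward stepwise descriptor selection ranked by regression F.

    Descriptors are assumed pre-screened (no constant columns). Returns the
    ordered list of selected names; if no admissible candidate remains
    before ``n_target`` descriptors are reached, the shorter list is
    returned with a warning.
    """
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
        matrix.columns = [f"x{j + 1}" for j in range(matrix.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(matrix) != len(y):
        raise ValueError("matrix rows must align with y")

    names = list(matrix.columns)
    values = matrix.to_numpy(dtype=float)
    corr = np.corrcoef(values, rowvar=False)
    if corr.ndim == 0:  # single column
        corr = np.array([[1.0]])

    def model_f(cols: list[int]) -> float:
        design = augment(values[:, cols])
        beta, _ = ols_solve(design, y)
        res = y - design @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            raise UndefinedStatisticError("constant response")
        r2 = 1.0 - float(res @ res) / ss_tot
        n, p = len(y), len(cols)
        if r2 >= 1.0:
            return float("inf")
        return f_statistic(r2, n, p)

    selected: list[int] = []
    candidates = list(range(len(names)))
    while len(selected) < n_target:
        admissible = [
            j
            for j in candidates
            if j not in selected
            and all(abs(corr[j, s]) < intercorrelation_bound for s in selected)
        ]
        if not admissible:
            warnings.warn(
                f"no admissible candidate left after {len(selected)} descriptors "
                f"(requested {n_target})",
                stacklevel=2,
            )
            break
        scores = [model_f(selected + [j]) for j in admissible]
        best = admissible[int(np.argmax(scores))]  # argmax is stable: first max wins
        selected.append(best)
    return [names[j] for j in selected]
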