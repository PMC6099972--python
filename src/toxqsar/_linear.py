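"""Shared linear-algebra helpers: intercept-augmented OLS, hat diagonals, PRESS.

These back the MLR module, the RBF-network output layer and the
applicability-domain leverages; they are deliberately free of any model
bookkeeping.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SingularDesignError, UndefinedStatisticError

_RANK_TOL = 1e-10


def augment(X: np.ndarray) -> np.ndarray:
    """Prepend the intercept column of ones."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def ols_solve(design: np.ndarray, y: np.ndarray, *, require_full_rank: bool = True):
    """Least-squares coefficients for an explicit design matrix.

    Returns ``(beta, rank)``. With ``require_full_rank`` a rank-deficient
    design raises :class:`SingularDesignError`; otherwise the least-norm
    solution is returned (used by the RBF output solve).
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if require_full_rank and rank < design.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]} columns)"
        )
    return beta, rank


def hat_diagonal(design: np.ndarray, query: np.ndarray | None = None) -> np.ndarray:
    """Diagonal of the projection (hat) matrix ``x (XᵀX)⁻¹ xᵀ``.

    ``query`` rows, if given, are evaluated against the Gram matrix of
    ``design`` (the training matrix); otherwise the training diagonal is
    returned.
    """
    design = np.asarray(design, dtype=float)
    gram = design.T @ design
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("XᵀX is singular") from exc
    # guard against numerically singular but invertible-in-floats designs
    if np.linalg.matrix_rank(design, tol=_RANK_TOL * max(design.shape)) < design.shape[1]:
        raise SingularDesignError("design matrix is numerically rank deficient")
    rows = design if query is None else np.asarray(query, dtype=float)
    return np.einsum("ij,jk,ik->i", rows, gram_inv, rows)


def press_statistic(design: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out PRESS via the deleted-residual identity e_i/(1−h_ii)."""
    beta, _ = ols_solve(design, y)
    residuals = y - design @ beta
    h = hat_diagonal(design)
    if np.any(h >= 1.0 - 1e-12):
        # a point with h=1 determines its own fit; deleted residual undefined
        raise UndefinedStatisticError("leverage of 1 encountered in PRESS")
    deleted = residuals / (1.0 - h)
    return float(np.sum(deleted**2))


def loo_q2_linear(design: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out q² = 1 − PRESS/SStot for a linear-in-parameters model."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("total sum of squares is zero (constant response)")
    return 1.0 - press_statistic(design, y) / ss_tot
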