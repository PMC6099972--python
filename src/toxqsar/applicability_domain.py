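"""Leverage-based applicability domain and Williams-plot data.

The leverage of a compound is the diagonal element of the hat matrix
h_i = x_i (XᵀX)⁻¹ x_iᵀ over the intercept-augmented training design; the
warning leverage is h* = 3m/n with m = p + 1 model parameters (intercept
included). A compound is an X-outlier when h_i > h* and a Y-outlier when
its standardized residual exceeds ±3; σ is the training residual standard
deviation with divisor n − p − 1. Test compounds are evaluated against the
training Gram matrix and the training σ, so they can be placed on the same
Williams plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linear import augment, hat_diagonal
from .dataset_io import Dataset
from .exceptions import UnderdeterminedError

__all__ = ["ADReport", "leverages", "williams_report", "remove_and_refit"]

STD_RESIDUAL_LIMIT = 3.0


def leverages(X_train, X_query=None) -> np.ndarray:
    """Hat-matrix diagonal of the intercept-augmented design.

    ``X_query`` rows, if given, are scored against the training Gram
    matrix. Training leverages sum to m = p + 1.
    """
    X_train = _as_array(X_train)
    design = augment(X_train)
    query = None if X_query is None else augment(_as_array(X_query))
    return hat_diagonal(design, query)


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


@dataclass
class ADReport:
    """Williams-plot coordinates and outlier flags for every compound."""

    ids: list[str]
    subsets: list[str]
    leverage: list[float]
    h_star: float
    residual: list[float]
    sigma: float
    std_residual: list[float]
    flags: list[str]            # in-domain | X-outlier | Y-outlier | both
    m: int
    n_train: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "subset": self.subsets,
                "leverage": self.leverage,
                "residual": self.residual,
                "std_residual": self.std_residual,
                "flag": self.flags,
            }
        )


def williams_report(model, X, y, subset_labels, ids=None) -> ADReport:
    """Leverages, standardized residuals and outlier flags for a fitted model.

    ``model`` must expose ``predict(X)`` and a descriptor count ``p``; the
    training portion is every row whose subset label is not ``"T"``.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(list(subset_labels))
    X_arr = _as_array(X)  # leverage uses the raw descriptor design
    if not (len(X_arr) == len(y) == len(labels)):
        raise ValueError("X, y and subset_labels must align")
    train_mask = labels != "T"
    if not np.any(train_mask):
        raise ValueError("no training rows (every label is 'T')")

    p = int(getattr(model, "p"))
    m = p + 1
    n_train = int(train_mask.sum())
    h_train_design = X_arr[train_mask]
    h = np.empty(len(X_arr))
    h[train_mask] = leverages(h_train_design)
    if np.any(~train_mask):
        h[~train_mask] = leverages(h_train_design, X_arr[~train_mask])

    residual = np.asarray(model.predict(X), dtype=float) - y
    dof = n_train - p - 1
    if dof <= 0:
        raise UnderdeterminedError(f"n_train={n_train} leaves no residual dof for p={p}")
    sigma = float(np.sqrt(np.sum(residual[train_mask] ** 2) / dof))
    std_residual = residual / sigma if sigma > 0 else np.zeros_like(residual)

    h_star = 3.0 * m / n_train
    flags = []
    for hi, ri in zip(h, std_residual):
        x_out = hi > h_star
        y_out = abs(ri) > STD_RESIDUAL_LIMIT
        flags.append(
            "both" if (x_out and y_out) else "X-outlier" if x_out else
            "Y-outlier" if y_out else "in-domain"
        )

    if ids is None:
        ids = [str(i) for i in range(len(X_arr))]
    return ADReport(
        ids=list(ids),
        subsets=labels.tolist(),
        leverage=h.tolist(),
        h_star=h_star,
        residual=residual.tolist(),
        sigma=sigma,
        std_residual=std_residual.tolist(),
        flags=list(flags),
        m=m,
        n_train=n_train,
    )


def remove_and_refit(dataset: Dataset, model_factory, flagged_ids) -> tuple[Dataset, object, list[str]]:
    """Drop flagged training compounds and refit.

    ``flagged_ids`` are CAS identifiers; all must belong to the training
    portion (subset ≠ T). Refuses removal that would leave n ≤ p + 1.
    Returns ``(reduced dataset, refitted model, removed ids)`` as the audit
    trail.
    """
    if dataset.descriptors is None:
        raise ValueError("dataset has no descriptor matrix to fit on")
    flagged = list(flagged_ids)
    if not flagged:
        raise ValueError("no compounds flagged for removal")
    cas = dataset.cas
    unknown = [f for f in flagged if f not in cas]
    if unknown:
        raise ValueError(f"unknown compound ids {unknown}")
    subsets = dataset.subsets
    in_test = [f for f in flagged if subsets[cas.index(f)] == "T"]
    if in_test:
        raise ValueError(f"flagged compounds {in_test} are test-set members")

    keep = ~np.isin(cas, flagged)
    reduced = dataset.select(keep)
    train = reduced.training()
    p = train.descriptors.shape[1]
    if len(train) <= p + 1:
        raise UnderdeterminedError(
            f"removal leaves n={len(train)} ≤ p+1={p + 1}; refusing to refit"
        )
    model = model_factory(train.descriptors, train.y)
    return reduced, model, flagged
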