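"""Fit and predictivity statistics.

Covers the training statistics (R², RMS, Fisher F), the external-test
block of Golbraikh & Tropsha (q²ext, through-origin determination
coefficients and slopes k/k′ with their four pass conditions), and the
five-fold subset rotation used to probe model stability.

Conventions
-----------
* ``r_squared`` is the squared Pearson correlation between observed and
  predicted values. On the fitted values of an intercept OLS model this is
  identical to 1 − SSres/SStot; on externally supplied predictions the two
  diverge, and the squared correlation is the convention the reference
  results follow.
* ``rms_error`` uses divisor *n* (population form).
* ``q_squared_external`` is the Q²F1 form: the denominator centres the test
  responses on the *training* mean.
* Orientation of the through-origin statistics: k and R0² come from
  regressing observed on predicted through the origin (k = Σyŷ/Σŷ²);
  the primed quantities use the opposite orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import SUBSET_LABELS, Dataset
from .exceptions import InvalidPartitionError, UndefinedStatisticError

__all__ = [
    "r_squared",
    "rms_error",
    "f_statistic",
    "q_squared_external",
    "ExternalValidationReport",
    "external_validation",
    "gt_check",
    "FoldResult",
    "RotationReport",
    "fivefold_rotation",
    "ROTATION_FOLDS",
]


def _paired(y_obs, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_obs.shape} vs {y_pred.shape}")
    return y_obs, y_pred


def r_squared(y_obs, y_pred) -> float:
    """Coefficient of determination as the squared Pearson correlation."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    if len(y_obs) < 2:
        raise ValueError("need at least two observations")
    sy = y_obs - y_obs.mean()
    sp = y_pred - y_pred.mean()
    denom = np.sqrt((sy**2).sum() * (sp**2).sum())
    if denom == 0.0:
        raise UndefinedStatisticError("constant vector: correlation undefined")
    return float(((sy * sp).sum() / denom) ** 2)


def rms_error(y_obs, y_pred) -> float:
    """Root-mean-square error with divisor n."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    if len(y_obs) == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_pred - y_obs) ** 2)))


def f_statistic(r2: float, n: int, p: int) -> float:
    """Overall regression F from R², sample size n and descriptor count p.

    F = (R²/p) / ((1−R²)/(n−p−1)).
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    if r2 == 1.0:
        raise UndefinedStatisticError("R² = 1 gives an infinite F")
    return float((r2 / p) / ((1.0 - r2) / (n - p - 1)))


def q_squared_external(y_obs, y_pred, y_train_mean: float) -> float:
    """External q² (Q²F1): 1 − Σ(y−ŷ)² / Σ(y−ȳ_train)²."""
    y_obs, y_pred = _paired(y_obs, y_pred)
    ss_tot = float(np.sum((y_obs - y_train_mean) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("test responses equal the training mean")
    return 1.0 - float(np.sum((y_obs - y_pred) ** 2)) / ss_tot


@dataclass
class ExternalValidationReport:
    """Golbraikh–Tropsha external-validation block for one test set."""

    n_ext: int
    r2: float
    q2_ext: float
    r0_sq: float
    r0p_sq: float
    k: float
    k_prime: float
    ratio: float
    ratio_prime: float
    passes: dict = field(default_factory=dict)
    #: orientation convention: k regresses observed on predicted through origin
    orientation: str = "k: obs ~ pred (through origin)"


def external_validation(y_obs, y_pred, y_train_mean: float) -> ExternalValidationReport:
    """Compute the external-predictivity block for a test set.

    The four pass conditions are: q²ext > 0.5; R² > 0.6;
    (R²−R0²)/R² < 0.1 in at least one orientation; and at least one
    through-origin slope within [0.85, 1.15].
    """
    y_obs, y_pred = _paired(y_obs, y_pred)
    if len(y_obs) < 3:
        raise ValueError("need at least three external compounds")
    sum_oo = float(np.sum(y_obs**2))
    sum_pp = float(np.sum(y_pred**2))
    sum_op = float(np.sum(y_obs * y_pred))
    if sum_pp == 0.0 or sum_oo == 0.0:
        raise UndefinedStatisticError("zero denominator in through-origin slope")

    r2 = r_squared(y_obs, y_pred)
    q2 = q_squared_external(y_obs, y_pred, y_train_mean)

    k = sum_op / sum_pp            # observed regressed on predicted
    k_prime = sum_op / sum_oo      # predicted regressed on observed

    ss_obs = float(np.sum((y_obs - y_obs.mean()) ** 2))
    ss_pred = float(np.sum((y_pred - y_pred.mean()) ** 2))
    if ss_obs == 0.0 or ss_pred == 0.0:
        raise UndefinedStatisticError("constant vector in through-origin R0²")
    r0_sq = 1.0 - float(np.sum((y_obs - k * y_pred) ** 2)) / ss_obs
    r0p_sq = 1.0 - float(np.sum((y_pred - k_prime * y_obs) ** 2)) / ss_pred

    ratio = (r2 - r0_sq) / r2
    ratio_prime = (r2 - r0p_sq) / r2

    report = ExternalValidationReport(
        n_ext=len(y_obs),
        r2=r2,
        q2_ext=q2,
        r0_sq=r0_sq,
        r0p_sq=r0p_sq,
        k=k,
        k_prime=k_prime,
        ratio=ratio,
        ratio_prime=ratio_prime,
    )
    report.passes = {
        "q2": q2 > 0.5,
        "r2": r2 > 0.6,
        "r0": ratio < 0.1 or ratio_prime < 0.1,
        "k": 0.85 <= k <= 1.15 or 0.85 <= k_prime <= 1.15,
    }
    return report


def gt_check(report: ExternalValidationReport) -> tuple[bool, list[str]]:
    """Overall pass/fail of the four external-predictivity conditions.

    Returns ``(passed, failed_condition_names)``.
    """
    failed = [name for name, ok in report.passes.items() if not ok]
    return (not failed, failed)


# --- five-fold subset rotation -------------------------------------------

#: hold-out order of the published rotation: T first, then D, A, B, C
ROTATION_FOLDS = ("T", "D", "A", "B", "C")


@dataclass
class FoldResult:
    held_out: str
    n_train: int
    n_test: int
    r2_train: float
    f_train: float
    rms_train: float
    r2_test: float
    f_test: float
    rms_test: float


@dataclass
class RotationReport:
    folds: list[FoldResult]
    r2_train_avg: float = 0.0
    f_train_avg: float = 0.0
    rms_train_avg: float = 0.0
    r2_test_avg: float = 0.0
    f_test_avg: float = 0.0
    rms_test_avg: float = 0.0

    def __post_init__(self) -> None:
        if self.folds and self.r2_train_avg == 0.0 and self.rms_train_avg == 0.0:
            for name in ("r2_train", "f_train", "rms_train", "r2_test", "f_test", "rms_test"):
                setattr(self, f"{name}_avg", float(np.mean([getattr(f, name) for f in self.folds])))


def fivefold_rotation(dataset: Dataset, model_factory) -> RotationReport:
    """Hold out each subset (T, then D, A, B, C) in turn and refit.

    ``model_factory(X_train, y_train)`` must return an object with a
    ``predict(X)`` method and an integer attribute ``p`` (descriptor count,
    used for the per-fold F statistic).
    """
    if dataset.descriptors is None:
        raise ValueError("dataset has no descriptor matrix to fit on")
    labels = dataset.subsets
    for label in SUBSET_LABELS:
        if not np.any(labels == label):
            raise InvalidPartitionError(f"subset {label!r} is empty")

    X = dataset.descriptors
    y = dataset.y
    folds = []
    for held in ROTATION_FOLDS:
        test_mask = labels == held
        X_tr, y_tr = X.loc[~test_mask], y[~test_mask]
        X_te, y_te = X.loc[test_mask], y[test_mask]
        model = model_factory(X_tr, y_tr)
        p = int(getattr(model, "p"))
        yhat_tr = np.asarray(model.predict(X_tr), dtype=float)
        yhat_te = np.asarray(model.predict(X_te), dtype=float)
        r2_tr = r_squared(y_tr, yhat_tr)
        r2_te = r_squared(y_te, yhat_te)
        folds.append(
            FoldResult(
                held_out=held,
                n_train=int(len(y_tr)),
                n_test=int(len(y_te)),
                r2_train=r2_tr,
                f_train=f_statistic(r2_tr, len(y_tr), p),
                rms_train=rms_error(y_tr, yhat_tr),
                r2_test=r2_te,
                f_test=f_statistic(r2_te, len(y_te), p),
                rms_test=rms_error(y_te, yhat_te),
            )
        )
    return RotationReport(folds=folds)
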