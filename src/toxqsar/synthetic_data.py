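"""Seeded synthetic descriptor matrices and responses.

The generators emulate the statistical shape of a computed-descriptor QSAR
table so the whole pipeline is testable without proprietary descriptor
software: a small set of "signal" descriptors that truly drive the
response, a larger block of correlated nuisance descriptors (one common
latent factor, so any nuisance pair has expected correlation equal to the
requested ``collinearity``), Gaussian noise on the response, and optional
Gaussian-bump nonlinearity for exercising the RBF network.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``spec.seed``, so a spec reproduces its dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import SUBSET_LABELS, CompoundRecord, Dataset

__all__ = [
    "GaussianBump",
    "SyntheticSpec",
    "make_linear_dataset",
    "make_rbf_dataset",
    "make_grouped_dataset",
]


@dataclass
class GaussianBump:
    """One radial feature of the response surface: amp·exp(−‖x−c‖²/w²)."""

    center: Sequence[float]
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bump width must be positive")


@dataclass
class SyntheticSpec:
    """Study-condition parameters for the generators.

    Defaults mimic the nitroaromatic training group of the packaged study:
    36 compounds, 3 true descriptors among ~50 candidates, and residual
    noise of 0.19 log units (the training RMS scale of the published
    models).
    """

    n: int = 36
    p_signal: int = 3
    p_noise: int = 47
    b0: float = 0.5
    coefficients: Sequence[float] = (1.0, -2.0, 0.5)
    collinearity: float = 0.3
    nonlinearity: Sequence[GaussianBump] = ()
    noise_sd: float = 0.19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= self.p_signal + 1:
            raise ValueError("need n > p_signal + 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.collinearity < 1.0:
            raise ValueError("collinearity must be in [0, 1)")
        if len(self.coefficients) != self.p_signal:
            raise ValueError("one coefficient per signal descriptor required")


def _draw_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    signal = rng.standard_normal((spec.n, spec.p_signal))
    names = [f"sig{j + 1}" for j in range(spec.p_signal)]
    blocks = [signal]
    if spec.p_noise:
        c = spec.collinearity
        latent = rng.standard_normal((spec.n, 1))
        eps = rng.standard_normal((spec.n, spec.p_noise))
        # one common factor: corr(x_j, x_k) = c for j ≠ k in the nuisance block
        noise = np.sqrt(c) * latent + np.sqrt(1.0 - c) * eps
        blocks.append(noise)
        names += [f"nui{j + 1}" for j in range(spec.p_noise)]
    return pd.DataFrame(np.hstack(blocks), columns=names)


def _records(n: int, subsets: Sequence[str], y: np.ndarray, group: int = 1):
    return [
        CompoundRecord(
            cas=f"SYN-{i + 1:04d}",
            name=f"synthetic compound {i + 1}",
            group=group,
            subset=subsets[i],
            y_obs=float(y[i]),
        )
        for i in range(n)
    ]


def make_linear_dataset(spec: SyntheticSpec) -> tuple[Dataset, dict]:
    """Descriptor matrix with a planted linear signal.

    Returns ``(dataset, truth)`` where ``truth`` records the generating
    intercept, coefficients and signal column names. All records carry the
    placeholder subset label "A"; use :func:`make_grouped_dataset` for
    rotation-ready labels.
    """
    rng = np.random.default_rng(spec.seed)
    matrix = _draw_matrix(spec, rng)
    signal_names = [f"sig{j + 1}" for j in range(spec.p_signal)]
    b = np.asarray(spec.coefficients, dtype=float)
    y = spec.b0 + matrix[signal_names].to_numpy() @ b
    y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    dataset = Dataset(_records(spec.n, ["A"] * spec.n, y), matrix)
    truth = {"b0": spec.b0, "b": b.copy(), "signal_names": signal_names}
    return dataset, truth


def make_rbf_dataset(spec: SyntheticSpec) -> tuple[Dataset, dict]:
    """Response built from Gaussian bumps over the signal descriptors.

    ``spec.nonlinearity`` must be non-empty; a spec whose bumps all have
    zero amplitude (and zero noise) would produce a constant response and
    is rejected.
    """
    if not spec.nonlinearity:
        raise ValueError("spec.nonlinearity must list at least one GaussianBump")
    rng = np.random.default_rng(spec.seed)
    matrix = _draw_matrix(spec, rng)
    signal_names = [f"sig{j + 1}" for j in range(spec.p_signal)]
    Xs = matrix[signal_names].to_numpy()
    y = np.full(spec.n, spec.b0, dtype=float)
    for bump in spec.nonlinearity:
        center = np.asarray(bump.center, dtype=float)
        if center.shape != (spec.p_signal,):
            raise ValueError(
                f"bump center must have {spec.p_signal} coordinates, got {center.shape}"
            )
        d2 = ((Xs - center) ** 2).sum(axis=1)
        y += bump.amplitude * np.exp(-d2 / bump.width**2)
    y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    if np.std(y) == 0.0:
        raise ValueError("generated response is constant (zero-amplitude bumps?)")
    dataset = Dataset(_records(spec.n, ["A"] * spec.n, y), matrix)
    truth = {"b0": spec.b0, "bumps": list(spec.nonlinearity), "signal_names": signal_names}
    return dataset, truth


def make_grouped_dataset(
    spec: SyntheticSpec, subset_fractions: Mapping[str, float]
) -> tuple[Dataset, dict]:
    """Linear dataset with seeded A–D/T subset labels.

    ``subset_fractions`` maps each of the five labels to its share of the
    compounds; shares must sum to 1 and give every subset at least one
    compound. Counts use largest-remainder rounding, assignment is a seeded
    permutation.
    """
    missing = [s for s in SUBSET_LABELS if s not in subset_fractions]
    if missing:
        raise ValueError(f"missing subset fractions for {missing}")
    fracs = np.array([subset_fractions[s] for s in SUBSET_LABELS], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"subset fractions sum to {fracs.sum():.6f}, expected 1")

    exact = fracs * spec.n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for idx in np.argsort(-remainder)[: spec.n - counts.sum()]:
        counts[idx] += 1
    if np.any(counts < 1):
        empty = [s for s, c in zip(SUBSET_LABELS, counts) if c < 1]
        raise ValueError(f"fractions give no compounds to subset(s) {empty}")

    dataset, truth = make_linear_dataset(spec)
    labels = np.repeat(list(SUBSET_LABELS), counts)
    rng = np.random.default_rng(spec.seed + 1)  # independent of matrix draws
    rng.shuffle(labels)
    for record, label in zip(dataset.records, labels):
        record.subset = str(label)
    truth["subset_counts"] = dict(zip(SUBSET_LABELS, counts.tolist()))
    return dataset, truth
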