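"""Compound tables: the packaged toxicity fixture and user CSV I/O.

The packaged fixture is the published 160-compound table of substituted
aromatic toxicants assayed against *Tetrahymena pyriformis*: CAS number,
name, experimental −log IGC50 (log10 of the reciprocal 50 % growth-inhibitory
concentration), the predicted values of the published MLR and RBF-network
models, their residuals, the structural group (1: nitro-substituted,
2: halogen-substituted, 3: both) and the subset label A–D (training) or
T (external test set).

User tables follow a fixed CSV dialect (RFC 4180, UTF-8, header row) with
the column contract ``cas,name,group,subset,y_obs,y_pred_mlr,y_pred_rbfnn``;
any further numeric columns are treated as molecular descriptors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError

__all__ = [
    "SUBSET_LABELS",
    "CompoundRecord",
    "Dataset",
    "load_table1",
    "read_dataset",
    "write_dataset",
    "write_report",
    "read_report",
]

SUBSET_LABELS = ("A", "B", "C", "D", "T")

#: canonical column order for compound tables
_CONTRACT = ("cas", "name", "group", "subset", "y_obs", "y_pred_mlr", "y_pred_rbfnn")


def _normalize_minus(text: str) -> str:
    # published tables use U+2212; normalise to ASCII hyphen-minus
    return text.replace("−", "-")


@dataclass
class CompoundRecord:
    """One compound: identity, group/subset membership and endpoint values.

    ``y_obs`` is the experimental −log IGC50 in log units; the two predicted
    columns are optional and carry the same units.
    """

    cas: str
    name: str
    group: int
    subset: str
    y_obs: float
    y_pred_mlr: float | None = None
    y_pred_rbfnn: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise ValueError(f"unknown group {self.group!r}; expected 1, 2 or 3")
        if self.subset not in SUBSET_LABELS:
            raise ValueError(
                f"unknown subset {self.subset!r}; expected one of {SUBSET_LABELS}"
            )

    @property
    def is_test(self) -> bool:
        """True iff the compound belongs to the external test set (subset T)."""
        return self.subset == "T"


@dataclass
class Dataset:
    """Ordered compound records plus an optional aligned descriptor matrix."""

    records: list[CompoundRecord]
    descriptors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            key = (rec.group, rec.cas)
            if key in seen:
                raise ValueError(f"duplicate CAS {rec.cas} within group {rec.group}")
            seen.add(key)
        if self.descriptors is not None and len(self.descriptors) != len(self.records):
            raise ValueError(
                f"descriptor matrix has {len(self.descriptors)} rows for "
                f"{len(self.records)} records"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cas(self) -> list[str]:
        return [r.cas for r in self.records]

    @property
    def y(self) -> np.ndarray:
        return np.array([r.y_obs for r in self.records], dtype=float)

    @property
    def subsets(self) -> np.ndarray:
        return np.array([r.subset for r in self.records])

    def column(self, which: str) -> np.ndarray:
        """Predicted column ('mlr' or 'rbfnn') as an array (NaN where absent)."""
        attr = {"mlr": "y_pred_mlr", "rbfnn": "y_pred_rbfnn"}[which]
        return np.array(
            [np.nan if getattr(r, attr) is None else getattr(r, attr) for r in self.records],
            dtype=float,
        )

    def subset_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.subsets, labels)

    def select(self, mask: Iterable[bool]) -> "Dataset":
        mask = np.asarray(list(mask), dtype=bool)
        records = [r for r, keep in zip(self.records, mask) if keep]
        descriptors = None
        if self.descriptors is not None:
            descriptors = self.descriptors.loc[mask].reset_index(drop=True)
        return Dataset(records, descriptors)

    def training(self) -> "Dataset":
        """Rows not flagged as external test compounds."""
        return self.select(~self.subset_mask("T"))

    def test(self) -> "Dataset":
        """External test rows (subset T)."""
        return self.select(self.subset_mask("T"))

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        base = base[list(_CONTRACT)]
        if self.descriptors is not None:
            base = pd.concat([base, self.descriptors.reset_index(drop=True)], axis=1)
        return base


def _fixture_frame() -> pd.DataFrame:
    with resources.files("toxqsar.data").joinpath("table1.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        text = _normalize_minus(fh.read())
    from io import StringIO

    return pd.read_csv(StringIO(text))


def load_table1(group: int) -> Dataset:
    """Load one group of the packaged toxicity table.

    Parameters
    ----------
    group : {1, 2, 3}
        1: nitro-substituted aromatics (46 compounds), 2: halogenated
        aromatics (75), 3: compounds bearing both substituents (39).

    Returns
    -------
    Dataset
        All rows of the group, in published order, with subset labels and
        both predicted columns populated.
    """
    if group not in (1, 2, 3):
        raise ValueError(f"unknown group {group!r}; expected 1, 2 or 3")
    frame = _fixture_frame()
    frame = frame[frame["group"] == group]
    records = [
        CompoundRecord(
            cas=row.cas,
            name=row.name,
            group=int(row.group),
            subset=row.subset,
            y_obs=float(row.y_obs),
            y_pred_mlr=float(row.y_pred_mlr),
            y_pred_rbfnn=float(row.y_pred_rbfnn),
        )
        for row in frame.itertuples(index=False)
    ]
    return Dataset(records)


def load_table1_residuals(group: int) -> pd.DataFrame:
    """Published residual columns (prediction − experiment) for one group.

    Kept separate from :func:`load_table1` because the residuals are
    redundant with the value columns; they are retained verbatim so the
    transcription can be audited.
    """
    if group not in (1, 2, 3):
        raise ValueError(f"unknown group {group!r}; expected 1, 2 or 3")
    frame = _fixture_frame()
    frame = frame[frame["group"] == group].reset_index(drop=True)
    return frame[["cas", "res_mlr", "res_rbfnn"]]


_DEFAULT_SCHEMA = {name: name for name in _CONTRACT}


def read_dataset(path: str | Path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a compound table from CSV.

    ``schema`` maps the canonical field names (``cas``, ``name``, ``group``,
    ``subset``, ``y_obs``; optionally ``y_pred_mlr`` / ``y_pred_rbfnn``) to
    the file's column names. Columns not named in the schema become the
    descriptor matrix and must be numeric.
    """
    path = Path(path)
    schema = dict(_DEFAULT_SCHEMA, **(schema or {}))
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip() for c in frame.columns]

    required = ("cas", "name", "group", "subset", "y_obs")
    for key in required:
        if schema[key] not in frame.columns:
            raise SchemaError(f"missing required column {schema[key]!r} in {path}")

    def _num(column: str, row: int, value: str, optional: bool = False) -> float | None:
        value = _normalize_minus(value.strip())
        if value == "":
            if optional:
                return None
            raise ParseError(f"blank value in column {column!r} at row {row}")
        try:
            return float(value)
        except ValueError as exc:
            raise ParseError(
                f"non-numeric value {value!r} in column {column!r} at row {row}"
            ) from exc

    records = []
    for i, row in frame.iterrows():
        rec_kwargs: dict = {
            "cas": row[schema["cas"]].strip(),
            "name": row[schema["name"]].strip(),
            "subset": row[schema["subset"]].strip(),
            "y_obs": _num(schema["y_obs"], i, row[schema["y_obs"]]),
        }
        try:
            rec_kwargs["group"] = int(row[schema["group"]])
        except ValueError as exc:
            raise ParseError(f"non-integer group at row {i}") from exc
        for opt in ("y_pred_mlr", "y_pred_rbfnn"):
            col = schema.get(opt)
            if col and col in frame.columns:
                rec_kwargs[opt] = _num(col, i, row[col], optional=True)
        records.append(CompoundRecord(**rec_kwargs))

    mapped = {schema[k] for k in schema if schema[k] in frame.columns}
    extra = [c for c in frame.columns if c not in mapped]
    descriptors = None
    if extra:
        values = np.empty((len(frame), len(extra)))
        for j, col in enumerate(extra):
            for i, raw in enumerate(frame[col]):
                values[i, j] = _num(col, i, raw)
        descriptors = pd.DataFrame(values, columns=extra)
    return Dataset(records, descriptors)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the canonical CSV dialect (descriptors appended)."""
    dataset.to_frame().to_csv(path, index=False)


# --- report serialisation ------------------------------------------------

def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_report(report, path: str | Path) -> None:
    """Serialise a report dataclass to JSON (round-trippable).

    Works with any of the package's report types (external-validation,
    applicability-domain, rotation, fit statistics); the class name is
    stored under ``"kind"`` so :func:`read_report` can reconstruct it.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory {path.parent} does not exist")
    if not dataclasses.is_dataclass(report):
        raise TypeError(f"expected a report dataclass, got {type(report).__name__}")
    payload = {"kind": type(report).__name__}
    payload.update(_jsonable(dataclasses.asdict(report)))
    path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def _report_registry() -> dict:
    from .applicability_domain import ADReport
    from .mlr import FitStatistics
    from .validation import ExternalValidationReport, FoldResult, RotationReport

    return {
        cls.__name__: cls
        for cls in (ADReport, FitStatistics, ExternalValidationReport, RotationReport, FoldResult)
    }


def read_report(path: str | Path):
    """Read back a report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    kind = payload.pop("kind")
    registry = _report_registry()
    if kind not in registry:
        raise SchemaError(f"unknown report kind {kind!r}")
    cls = registry[kind]
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise SchemaError(f"unexpected fields {sorted(unknown)} for {kind}")
    if kind == "RotationReport":
        payload["folds"] = [registry["FoldResult"](**f) for f in payload["folds"]]
    return cls(**payload)
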