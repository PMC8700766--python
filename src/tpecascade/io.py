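"""Dataset loading, run configuration and run manifests.

CSV in, CSV out (header required, one binary label column).  Missing
values are rejected with a cell-level report — the pipeline never
imputes silently.  Non-numeric feature columns are label-encoded with
the mapping recorded, since all base learners are tree models that split
on encoded integers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .base_pool import derive_seed


class DatasetFormatError(ValueError):
    """The input table violates the loader's contract."""


@dataclass
class ColumnMetadata:
    name: str
    kind: str  # "continuous" or "categorical"
    encoding: dict[str, int] | None = None  # for label-encoded text columns


def load_dataset(
    path: str | Path,
    label_col: str = "label",
    label_mapping: Mapping[str, int] | None = None,
    categorical_columns: set[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[ColumnMetadata]]:
    """Read a CSV into (X, y, column metadata).

    Labels must be coercible to {0, 1}, directly or through
    ``label_mapping``.  Column types are inferred (integer-valued columns
    with few distinct values count as categorical) unless overridden via
    ``categorical_columns``.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise DatasetFormatError(
            f"label column {label_col!r} not found; columns are {list(df.columns)}"
        )
    na = df.isna()
    if na.to_numpy().any():
        cells = [
            f"(row {i}, column {c!r})"
            for c in df.columns
            for i in df.index[na[c]][:3]
        ]
        raise DatasetFormatError(
            "missing values are not accepted; first offending cells: "
            + ", ".join(cells[:10])
        )

    raw_labels = df[label_col]
    if label_mapping:
        unknown = set(raw_labels.astype(str)) - set(label_mapping)
        if unknown:
            raise DatasetFormatError(f"labels {sorted(unknown)} missing from mapping")
        y = raw_labels.astype(str).map(label_mapping).to_numpy()
    else:
        try:
            y = raw_labels.astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise DatasetFormatError(
                f"labels are not numeric and no label mapping was given: {exc}"
            ) from None
    if not set(np.unique(y)) <= {0, 1}:
        raise DatasetFormatError(
            f"labels must be binary 0/1 after coercion, got {sorted(set(y))}"
        )

    X = df.drop(columns=[label_col]).copy()
    metadata: list[ColumnMetadata] = []
    for col in X.columns:
        series = X[col]
        encoding = None
        if not pd.api.types.is_numeric_dtype(series):
            levels = sorted(series.astype(str).unique())
            encoding = {level: i for i, level in enumerate(levels)}
            X[col] = series.astype(str).map(encoding)
            kind = "categorical"
        elif categorical_columns and col in categorical_columns:
            kind = "categorical"
        else:
            values = series.to_numpy()
            is_integral = np.allclose(values, np.round(values))
            kind = "categorical" if is_integral and series.nunique() <= 10 else "continuous"
        metadata.append(ColumnMetadata(name=col, kind=kind, encoding=encoding))
    return X, y.astype(int), metadata


@dataclass
class RunConfig:
    """Structured settings for a full pipeline run.

    Every stochastic component derives its seed from the single global
    ``seed``, so a config file fully determines a run.
    """

    data: str | None = None
    label_col: str = "label"
    seed: int = 0
    counts: list[int] | None = None  # fixed composition; None means tune
    cascade: dict[str, Any] = field(default_factory=dict)
    tpe: dict[str, Any] = field(default_factory=dict)
    cv: dict[str, Any] = field(default_factory=lambda: {"n_folds": 10, "n_repeats": 10})
    output: str | None = None
    log_level: str = "INFO"

    def component_seed(self, component: str) -> int:
        return derive_seed(self.seed, component)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise DatasetFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    options: Mapping[str, Any],
    inputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Write a deterministic JSON manifest next to a run's outputs.

    Records the command, its options, the package version and SHA-256
    digests of input files.  Deliberately timestamp-free so identical
    runs produce byte-identical manifests.
    """
    manifest = {
        "command": command,
        "options": {k: options[k] for k in sorted(options)},
        "version": __version__,
        "inputs": {
            name: file_digest(p) for name, p in sorted((inputs or {}).items())
        },
    }
    path = Path(out_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
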