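"""Data preparation: interval discretization and importance-based selection.

Real-valued attributes can be binned into clinician-chosen half-open
intervals (e.g. age into (-inf, 30), [30, 60), [60, inf)), and features
can be filtered by normalized gradient-boosted-tree importance above a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from xgboost import XGBClassifier


class EmptySelectionError(ValueError):
    """No feature cleared the importance threshold; carries the full table."""

    def __init__(self, message: str, importances: pd.Series):
        super().__init__(message)
        self.importances = importances


@dataclass(frozen=True)
class BinningScheme:
    """Interior cut points per feature, defining half-open intervals.

    Cuts (c_1, ..., c_m) map a value v to the unique bin i with
    c_i <= v < c_{i+1}, taking c_0 = -inf and c_{m+1} = +inf.  An empty
    cut list is the single-bin identity.
    """

    cuts: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, c in self.cuts.items():
            arr = np.asarray(c, dtype=float)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"cut points for {name!r} must be strictly increasing")


def discretize(values: Sequence[float], cuts: Sequence[float]) -> np.ndarray:
    """Map each value to its half-open interval index.

    With cuts (30, 60): 29 -> 0, 30 -> 1, 59.9 -> 1, 60 -> 2.
    """
    cuts = np.asarray(cuts, dtype=float)
    if cuts.size and np.any(np.diff(cuts) <= 0):
        raise ValueError("cut points must be strictly increasing")
    return np.searchsorted(cuts, np.asarray(values, dtype=float), side="right")


def apply_binning(df: pd.DataFrame, scheme: BinningScheme) -> pd.DataFrame:
    """Return a copy of ``df`` with each configured column replaced by bin
    indices; columns without cuts pass through unchanged."""
    out = df.copy()
    for name, cuts in scheme.cuts.items():
        if name not in out.columns:
            raise KeyError(f"binning config names unknown column {name!r}")
        out[name] = discretize(out[name].to_numpy(), cuts)
    return out


def feature_importances(X, y, seed: int = 0) -> pd.Series:
    """Normalized gain-based importances from a seeded gradient-boosted
    tree model, indexed by column (name if a DataFrame, else position)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        names = list(range(values.shape[1]))
    model = XGBClassifier(
        n_estimators=100,
        importance_type="gain",
        random_state=seed,
        verbosity=0,
        eval_metric="logloss",
    )
    model.fit(values, np.asarray(y).astype(int))
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=names, name="importance")


def select_features_by_importance(
    X, y, threshold: float = 0.01, seed: int = 0
) -> list[int]:
    """Indices of columns whose normalized importance exceeds ``threshold``,
    in original column order.

    Importances are normalized to sum to one, so the threshold is on the
    relative (not raw) scale.  Raises :class:`EmptySelectionError`, with
    the importance table attached, when nothing passes.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    imp = feature_importances(X, y, seed=seed)
    selected = [i for i, v in enumerate(imp.to_numpy()) if v > threshold]
    if not selected:
        raise EmptySelectionError(
            f"no feature has normalized importance > {threshold}", imp
        )
    return selected
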