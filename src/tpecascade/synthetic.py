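"""Seeded generator of tabular binary-classification datasets.

Emulates the *shapes* of six clinical benchmark tables — row counts from
a few hundred to 7,200, 10-54 mixed continuous/categorical features, and
class imbalance from near-balanced (170:164) to severe (55:803) — with a
controllable signal so models can genuinely learn.  Feature semantics are
not simulated, only volume, dimensionality, type mix and imbalance.

The latent model is class-conditional Gaussian: informative features get
a per-class mean shift whose Euclidean norm equals ``signal_strength``
(so signal_strength is the Mahalanobis distance between class centroids
under the identity covariance); categorical columns arise by tertile
discretization of latent continuous draws; noise features are
class-independent.  Labels are laid out by exact stratified construction,
never Bernoulli draws, so class counts match the profile exactly for
every seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base_pool import derive_seed

# tertile boundaries of the standard normal, used to cut latent draws
# into three ordered categories
_TERTILE_CUTS = (-0.4307272992954576, 0.4307272992954576)


@dataclass(frozen=True)
class DatasetProfile:
    """Shape and signal description of a synthetic dataset."""

    name: str
    n_rows: int
    n_features: int
    n_positive: int
    n_negative: int
    fraction_categorical: float = 0.4
    signal_strength: float = 2.0
    noise_feature_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative != self.n_rows:
            raise ValueError("class counts must sum to n_rows")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if self.n_positive <= 0 or self.n_negative <= 0:
            raise ValueError("degenerate profile: both classes need members")
        if not 0.0 <= self.fraction_categorical <= 1.0:
            raise ValueError("fraction_categorical must be in [0, 1]")
        if not 0.0 <= self.noise_feature_fraction <= 1.0:
            raise ValueError("noise_feature_fraction must be in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")

    def replace(self, **changes) -> "DatasetProfile":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def builtin_profiles() -> dict[str, DatasetProfile]:
    """The six built-in shape profiles, keyed by name.

    Shapes mirror well-known clinical benchmark tables: a near-balanced
    334-row breast-mass table, a 54-feature coronary table, a liver-panel
    table, a 32-feature breast-cytology table, a severely imbalanced
    cervical screening table, and a large thyroid screening table.
    """
    shapes = [
        ("breast-like", 334, 10, 170, 164),
        ("coronary-like", 303, 54, 216, 87),
        ("liver-like", 583, 10, 416, 167),
        ("wisconsin-like", 569, 32, 212, 357),
        ("cervical-like", 858, 36, 55, 803),
        ("thyroid-like", 7200, 21, 6644, 556),
    ]
    return {
        name: DatasetProfile(
            name=name,
            n_rows=rows,
            n_features=feats,
            n_positive=pos,
            n_negative=neg,
        )
        for name, rows, feats, pos, neg in shapes
    }


def make_dataset(
    profile: DatasetProfile, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Generate one dataset; bit-reproducible given (profile, seed).

    Returns (X, y, metadata) where metadata records which columns are
    informative and which are categorical.
    """
    rng = np.random.default_rng(derive_seed("synthetic", profile.name, seed))

    n = profile.n_rows
    p = profile.n_features
    n_noise = int(round(profile.noise_feature_fraction * p))
    n_inform = max(1, p - n_noise)
    n_noise = p - n_inform
    n_cat = int(round(profile.fraction_categorical * p))

    # exact stratified label layout, shuffled into a seeded row order
    y = np.concatenate([np.ones(profile.n_positive, dtype=int),
                        np.zeros(profile.n_negative, dtype=int)])
    rng.shuffle(y)

    # class-centroid shift with Euclidean norm == signal_strength,
    # random sign per informative feature
    signs = rng.choice([-1.0, 1.0], size=n_inform)
    delta = signs * profile.signal_strength / np.sqrt(n_inform)

    latent = rng.standard_normal((n, p))
    inform_cols = np.arange(n_inform)
    latent[:, inform_cols] += np.outer(y, delta)

    cat_cols = np.sort(rng.choice(p, size=n_cat, replace=False)) if n_cat else np.array([], dtype=int)
    cat_set = set(cat_cols.tolist())

    columns: dict[str, np.ndarray] = {}
    names: list[str] = []
    for j in range(p):
        if j in cat_set:
            name = f"cat{j}"
            columns[name] = np.searchsorted(_TERTILE_CUTS, latent[:, j], side="right")
        else:
            name = f"num{j}"
            columns[name] = latent[:, j]
        names.append(name)

    X = pd.DataFrame(columns, columns=names)
    metadata = {
        "profile": profile.name,
        "seed": int(seed),
        "informative_columns": [names[j] for j in inform_cols],
        "categorical_columns": [names[j] for j in cat_cols],
        "signal_strength": profile.signal_strength,
        "class_counts": {"positive": profile.n_positive, "negative": profile.n_negative},
    }
    return X, y, metadata
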