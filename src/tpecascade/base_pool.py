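"""Pool of tree-ensemble base learners and per-layer instantiation.

Four families make up the pool: random forest (RF), extremely randomized
trees (ET), AdaBoost (ADA) and gradient-boosted decision trees (GBDT).
A layer's composition is a :class:`CountVector` — how many replicates of
each family to instantiate.  Replicates of one family differ only by seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)


class InvalidConfigurationError(ValueError):
    """A learner-pool configuration that violates its invariants."""


class DegenerateTrainingError(ValueError):
    """Training data that no classifier can be fitted on (e.g. one class)."""


class Family(str, Enum):
    RF = "RF"
    ET = "ET"
    ADA = "ADA"
    GBDT = "GBDT"


#: Canonical ordering used everywhere a count vector is unpacked.
FAMILY_ORDER: tuple[Family, ...] = (Family.RF, Family.ET, Family.ADA, Family.GBDT)

#: Fixed, versioned default hyperparameters per family.  These are recorded
#: in every spec/fitted model rather than inherited silently from the ML
#: library, so a model file documents exactly what was trained.
FAMILY_DEFAULTS: dict[Family, dict[str, Any]] = {
    Family.RF: {"n_estimators": 100},
    Family.ET: {"n_estimators": 100},
    Family.ADA: {"n_estimators": 50},
    Family.GBDT: {"n_estimators": 100},
}

_CONSTRUCTORS = {
    Family.RF: RandomForestClassifier,
    Family.ET: ExtraTreesClassifier,
    Family.ADA: AdaBoostClassifier,
    Family.GBDT: GradientBoostingClassifier,
}

_SEED_MOD = 2**31 - 1


def derive_seed(*parts: Any) -> int:
    """Stable, platform-independent seed derived from a tuple of parts.

    Used to fan a single global seed out to every stochastic component so
    that replicates differ from each other but whole runs reproduce.
    """
    key = "/".join(str(p) for p in parts)
    return zlib.crc32(key.encode("utf-8")) % _SEED_MOD


@dataclass(frozen=True)
class CountVector:
    """Per-family replicate counts, ordered (RF, ET, ADA, GBDT).

    This 4-tuple is the hyperparameter the TPE searches: it fixes the
    composition of every cascade layer.  A zero entry means the family is
    not used; an all-zero vector is invalid (nothing would vote).
    """

    rf: int
    et: int
    ada: int
    gbdt: int

    def __post_init__(self) -> None:
        for name, value in zip(("rf", "et", "ada", "gbdt"), self.as_tuple()):
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise InvalidConfigurationError(
                    f"count '{name}' must be an integer, got {value!r}"
                )
            if value < 0:
                raise InvalidConfigurationError(
                    f"count '{name}' must be non-negative, got {value}"
                )
        if self.total == 0:
            raise InvalidConfigurationError(
                "all-zero count vector: at least one learner is required"
            )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (int(self.rf), int(self.et), int(self.ada), int(self.gbdt))

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    def count_for(self, family: Family) -> int:
        return self.as_tuple()[FAMILY_ORDER.index(family)]

    def __iter__(self) -> Iterator[int]:
        return iter(self.as_tuple())

    @classmethod
    def from_iterable(cls, counts: Sequence[int]) -> "CountVector":
        values = list(counts)
        if len(values) != 4:
            raise InvalidConfigurationError(
                f"count vector needs exactly 4 entries, got {len(values)}"
            )
        return cls(*(int(v) for v in values))

    def __str__(self) -> str:
        return "[" + ", ".join(str(c) for c in self) + "]"


@dataclass(frozen=True)
class LearnerSpec:
    """An unfitted learner: family, replicate slot, seed and hyperparameters."""

    family: Family
    replicate_index: int  # 1-based within its family
    seed: int
    params: Mapping[str, Any] = field(default_factory=dict)


@dataclass
class FittedLearner:
    """A trained base learner plus the metadata needed to reproduce it."""

    family: Family
    replicate_index: int
    seed: int
    params: Mapping[str, Any]
    estimator: Any
    n_features_in: int

    def spec(self) -> LearnerSpec:
        return LearnerSpec(self.family, self.replicate_index, self.seed, dict(self.params))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected {self.n_features_in} feature columns, "
                f"got shape {X.shape}"
            )
        if X.shape[0] == 0:
            return np.zeros((0, 2))
        return self.estimator.predict_proba(X)


def instantiate_pool(
    counts: CountVector,
    seed: int,
    params_override: Mapping[Family, Mapping[str, Any]] | None = None,
) -> list[LearnerSpec]:
    """Expand a count vector into an ordered list of learner specifications.

    Pure function of its arguments: family *i* appears ``counts[i]`` times,
    in the canonical (RF, ET, ADA, GBDT) order, each replicate with a
    distinct seed derived from ``(seed, family, replicate_index)``.
    """
    if not isinstance(counts, CountVector):
        counts = CountVector.from_iterable(counts)
    specs: list[LearnerSpec] = []
    for family in FAMILY_ORDER:
        params = dict(FAMILY_DEFAULTS[family])
        if params_override and family in params_override:
            params.update(params_override[family])
        for replicate in range(1, counts.count_for(family) + 1):
            specs.append(
                LearnerSpec(
                    family=family,
                    replicate_index=replicate,
                    seed=derive_seed(seed, family.value, replicate),
                    params=params,
                )
            )
    return specs


def build_estimator(spec: LearnerSpec):
    """Construct the (unfitted) sklearn estimator described by a spec."""
    cls = _CONSTRUCTORS[spec.family]
    return cls(random_state=spec.seed, **dict(spec.params))


def fit_learner(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> FittedLearner:
    """Fit one base learner; deterministic given ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise DegenerateTrainingError("need at least 2 training samples")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateTrainingError(
            f"training labels contain a single class ({classes.tolist()}); "
            "both classes are required"
        )
    est = build_estimator(spec)
    est.fit(X, y)
    return FittedLearner(
        family=spec.family,
        replicate_index=spec.replicate_index,
        seed=spec.seed,
        params=dict(spec.params),
        estimator=est,
        n_features_in=X.shape[1],
    )
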