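"""Sklearn-style wrappers around the library's estimators.

These give every model in the comparison harness the same
fit/predict/predict_proba surface: single-family ensembles, the
fixed-composition cascade, the TPE-weighted flat voter, and the
TPE-tuned cascade.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np

from .base_pool import (
    FAMILY_DEFAULTS,
    FAMILY_ORDER,
    CountVector,
    Family,
    LearnerSpec,
    derive_seed,
    fit_learner,
)
from .cascade import CascadeConfig, CascadeModel, fit_cascade
from .tpe import TPEConfig, TrialHistory, optimize, tune_cascade


class SingleFamilyClassifier:
    """One base ensemble on its own (RF, ET, AdaBoost or GBDT)."""

    def __init__(self, family: Family, seed: int = 0,
                 params: Mapping[str, Any] | None = None):
        self.family = family
        self.seed = seed
        self.params = dict(FAMILY_DEFAULTS[family]) | dict(params or {})
        self._fitted = None

    def fit(self, X, y):
        spec = LearnerSpec(self.family, 1, derive_seed(self.seed, self.family.value),
                           self.params)
        self._fitted = fit_learner(spec, np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict_proba(self, X):
        return self._fitted.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


class CascadeClassifier:
    """Deep cascade with a fixed layer composition."""

    def __init__(self, counts: CountVector, config: CascadeConfig | None = None):
        self.counts = counts
        self.config = config or CascadeConfig()
        self.model_: CascadeModel | None = None

    def fit(self, X, y):
        self.model_ = fit_cascade(X, y, self.counts, self.config)
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


class TunedCascadeClassifier:
    """Cascade whose layer composition is selected by TPE at fit time."""

    def __init__(self, tpe_config: TPEConfig | None = None,
                 cascade_config: CascadeConfig | None = None, k_tune: int = 3):
        self.tpe_config = tpe_config or TPEConfig()
        self.cascade_config = cascade_config or CascadeConfig()
        self.k_tune = k_tune
        self.best_counts_: CountVector | None = None
        self.model_: CascadeModel | None = None
        self.history_: TrialHistory | None = None

    def fit(self, X, y):
        self.best_counts_, self.model_, self.history_ = tune_cascade(
            X, y, self.tpe_config, self.cascade_config, self.k_tune
        )
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


class TPEVotingClassifier:
    """Flat soft voting over one learner per family with TPE-tuned
    non-negative integer weights (no cascade).

    The weight vector reuses the count-vector machinery: weight w_i scales
    family i's probability vector in the vote, and w_i = 0 drops the
    family.  Weights are chosen by minimizing internal stratified k-fold
    error, mirroring how the cascade's composition is tuned.
    """

    def __init__(self, tpe_config: TPEConfig | None = None, seed: int = 0,
                 params: Mapping[Family, Mapping[str, Any]] | None = None,
                 k_tune: int = 3):
        self.tpe_config = tpe_config or TPEConfig()
        self.seed = seed
        self.params = params or {}
        self.k_tune = k_tune
        self.weights_: CountVector | None = None
        self.learners_ = None
        self.history_: TrialHistory | None = None

    def _specs(self, seed_tag: Any) -> list[LearnerSpec]:
        specs = []
        for family in FAMILY_ORDER:
            params = dict(FAMILY_DEFAULTS[family]) | dict(self.params.get(family, {}))
            specs.append(
                LearnerSpec(family, 1, derive_seed(self.seed, "vote", family.value, seed_tag), params)
            )
        return specs

    def fit(self, X, y):
        from sklearn.model_selection import StratifiedKFold

        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        skf = StratifiedKFold(n_splits=self.k_tune, shuffle=True,
                              random_state=derive_seed(self.seed, "vote-folds"))
        folds = list(skf.split(X, y))
        # per-fold family probabilities are fixed, so precompute them once
        fold_probs = []
        for f_idx, (tr, te) in enumerate(folds):
            fitted = [fit_learner(s, X[tr], y[tr]) for s in self._specs(f_idx)]
            fold_probs.append((te, [m.predict_proba(X[te]) for m in fitted]))

        def objective(weights: CountVector) -> float:
            w = np.asarray(weights.as_tuple(), dtype=float)
            errors = []
            for te, probs in fold_probs:
                score = sum(wi * p for wi, p in zip(w, probs))
                pred = np.argmax(score, axis=1)
                errors.append(1.0 - float(np.mean(pred == y[te])))
            return float(np.mean(errors))

        self.weights_, self.history_ = optimize(objective, self.tpe_config)
        self.learners_ = [fit_learner(s, X, y) for s in self._specs("final")]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        w = np.asarray(self.weights_.as_tuple(), dtype=float)
        score = sum(wi * m.predict_proba(X) for wi, m in zip(w, self.learners_))
        return score / w.sum()

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)
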