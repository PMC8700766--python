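"""Deep cascade ensemble with class-probability feature augmentation.

Each layer holds the same composition of base learners (one shared
:class:`~tpecascade.base_pool.CountVector`).  A layer's learners emit
class-probability vectors which are concatenated with the *original*
features to form the next layer's input.  Depth grows automatically until
accuracy on an internal stratified holdout stops improving; the read-out
at any layer is soft majority voting: the predicted class maximizes the
sum of predicted class probabilities over all learners of that layer.

Training-time augmented features are produced out-of-fold (k-fold within
the layer) so the probability block of a training row never comes from a
learner that saw that row's label; the layer's learners are then refitted
on the full layer input for inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .base_pool import (
    CountVector,
    DegenerateTrainingError,
    Family,
    FittedLearner,
    InvalidConfigurationError,
    LearnerSpec,
    derive_seed,
    fit_learner,
    instantiate_pool,
)

N_CLASSES = 2  # binary tasks throughout; parameterized internally


class UsageError(RuntimeError):
    """An operation invoked outside its contract (e.g. OOF mode at inference)."""


@dataclass
class CascadeConfig:
    """Growth settings for the cascade.

    max_depth: hard cap on the number of layers.
    patience: consecutive non-improving layers tolerated before stopping.
    k_inner: folds for out-of-fold training-time augmentation.
    holdout_fraction: share of the training partition held out (stratified)
        to score each layer for the depth decision; never the outer test fold.
    learner_params: optional per-family hyperparameter overrides applied to
        every layer (e.g. smaller tree counts for quick experiments).
    """

    max_depth: int = 10
    patience: int = 1
    k_inner: int = 3
    holdout_fraction: float = 0.2
    seed: int = 0
    learner_params: Mapping[Family, Mapping[str, Any]] | None = None

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise InvalidConfigurationError("max_depth must be >= 1")
        if self.patience < 1:
            raise InvalidConfigurationError("patience must be >= 1")
        if self.k_inner < 2:
            raise InvalidConfigurationError("k_inner must be >= 2")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise InvalidConfigurationError("holdout_fraction must be in (0, 1)")


@dataclass
class CascadeLayer:
    index: int  # 1-based
    learners: list[FittedLearner]
    input_width: int
    original_width: int

    @property
    def augment_width(self) -> int:
        return len(self.learners) * N_CLASSES


@dataclass
class LayerRecord:
    index: int
    val_accuracy: float
    discarded: bool = False


@dataclass
class AugmentedFeatureMatrix:
    values: np.ndarray
    original_width: int
    augment_width: int


def majority_vote(prob_stack: Sequence[Sequence[float]]) -> int:
    """Soft majority vote for one sample.

    Given one normalized class-probability row per learner, return the
    class whose summed probability is largest; ties break toward the
    smaller class index.
    """
    rows = np.asarray(prob_stack, dtype=float)
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise UsageError("majority_vote needs a non-empty stack of probability rows")
    totals = rows.sum(axis=0)
    return int(np.argmax(totals))  # argmax returns the first (smallest) index on ties


def _vote_scores(prob_blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Average the per-learner probability matrices into normalized scores."""
    stacked = np.stack([np.asarray(b, dtype=float) for b in prob_blocks])
    return stacked.mean(axis=0)


def _layer_prob_blocks(learners: Sequence[FittedLearner], X: np.ndarray) -> list[np.ndarray]:
    return [lrn.predict_proba(X) for lrn in learners]


def _oof_prob_blocks(
    specs: Sequence[LearnerSpec],
    X: np.ndarray,
    y: np.ndarray,
    k_inner: int,
    seed: int,
) -> list[np.ndarray]:
    """Out-of-fold probability matrix per spec: row i predicted by the fold
    model that did not train on row i."""
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed % (2**31 - 1))
    blocks = [np.zeros((X.shape[0], N_CLASSES)) for _ in specs]
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        for s_idx, spec in enumerate(specs):
            fold_spec = LearnerSpec(
                spec.family,
                spec.replicate_index,
                derive_seed(spec.seed, "oof", fold_idx),
                spec.params,
            )
            fitted = fit_learner(fold_spec, X[tr], y[tr])
            blocks[s_idx][te] = fitted.predict_proba(X[te])
    return blocks


def augment_features(
    X_input: np.ndarray,
    layer: CascadeLayer,
    mode: str = "direct",
    y: np.ndarray | None = None,
    k_inner: int = 3,
    seed: int = 0,
) -> AugmentedFeatureMatrix:
    """Concatenate the layer's class-probability block to the original features.

    ``direct`` mode (inference) uses the layer's refitted learners.
    ``out_of_fold`` mode (training) requires ``y`` and produces each row's
    probabilities from fold models not trained on that row.
    """
    X_input = np.asarray(X_input, dtype=float)
    if X_input.ndim != 2 or X_input.shape[1] != layer.input_width:
        raise ValueError(
            f"layer {layer.index} expects input width {layer.input_width}, "
            f"got {X_input.shape}"
        )
    if mode == "direct":
        blocks = _layer_prob_blocks(layer.learners, X_input)
    elif mode == "out_of_fold":
        if y is None:
            raise UsageError(
                "out_of_fold augmentation needs training labels; "
                "use mode='direct' at inference time"
            )
        blocks = _oof_prob_blocks([l.spec() for l in layer.learners], X_input,
                                  np.asarray(y), k_inner, seed)
    else:
        raise UsageError(f"unknown augmentation mode {mode!r}")
    original = X_input[:, : layer.original_width]
    values = np.hstack([original] + blocks)
    return AugmentedFeatureMatrix(
        values=values,
        original_width=layer.original_width,
        augment_width=len(blocks) * N_CLASSES,
    )


@dataclass
class CascadeModel:
    """A fitted cascade: shared composition, retained layers, growth history."""

    counts: CountVector
    layers: list[CascadeLayer]
    history: list[LayerRecord]
    config: CascadeConfig
    n_original_features: int
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    @property
    def depth(self) -> int:
        return len(self.layers)

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_original_features:
            raise ValueError(
                f"expected {self.n_original_features} feature columns, got {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Pass X through all layers (direct augmentation) and average the
        final layer's learner probabilities into normalized class scores."""
        X = self._check_width(X)
        current = X
        blocks: list[np.ndarray] = []
        for layer in self.layers:
            blocks = _layer_prob_blocks(layer.learners, current)
            if layer.index < self.depth:
                current = np.hstack([X] + blocks)
        return _vote_scores(blocks)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_proba(X)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_cascade(
    X: np.ndarray,
    y: np.ndarray,
    counts: CountVector,
    config: CascadeConfig | None = None,
) -> CascadeModel:
    """Grow a cascade layer by layer, stopping when holdout accuracy stalls.

    The training partition is split (stratified, seeded) into a growth set
    and a holdout; each trained layer is scored by soft-vote accuracy on
    the holdout, and the returned model is truncated to the best-scoring
    depth (earliest layer on ties, preferring the shallower model).
    """
    config = config or CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateTrainingError("both classes required to fit a cascade")
    min_class = np.bincount(y).min()
    if min_class < config.k_inner:
        raise InvalidConfigurationError(
            f"minority class has {min_class} samples; "
            f"k_inner={config.k_inner} folds need at least that many per class"
        )
    split_seed = derive_seed(config.seed, "holdout")
    X_grow, X_val, y_grow, y_val = train_test_split(
        X,
        y,
        test_size=config.holdout_fraction,
        stratify=y,
        random_state=split_seed,
    )

    n_original = X.shape[1]
    layers: list[CascadeLayer] = []
    history: list[LayerRecord] = []
    grow_input = X_grow
    val_input = X_val
    best_acc = -np.inf
    best_depth = 0
    stall = 0

    for depth in range(1, config.max_depth + 1):
        layer_seed = derive_seed(config.seed, "layer", depth)
        specs = instantiate_pool(counts, layer_seed, config.learner_params)
        # out-of-fold block for the *next* layer's training input
        oof_blocks = _oof_prob_blocks(specs, grow_input, y_grow, config.k_inner,
                                      derive_seed(layer_seed, "kfold"))
        learners = [fit_learner(spec, grow_input, y_grow) for spec in specs]
        layer = CascadeLayer(
            index=depth,
            learners=learners,
            input_width=grow_input.shape[1],
            original_width=n_original,
        )
        val_blocks = _layer_prob_blocks(learners, val_input)
        val_pred = np.argmax(_vote_scores(val_blocks), axis=1)
        acc = float(np.mean(val_pred == y_val))
        layers.append(layer)
        history.append(LayerRecord(index=depth, val_accuracy=acc))

        if acc > best_acc:
            best_acc = acc
            best_depth = depth
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        grow_input = np.hstack([X_grow] + oof_blocks)
        val_input = np.hstack([X_val] + val_blocks)

    for record in history:
        record.discarded = record.index > best_depth
    return CascadeModel(
        counts=counts,
        layers=layers[:best_depth],
        history=history,
        config=config,
        n_original_features=n_original,
        classes_=classes,
    )
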