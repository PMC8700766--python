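"""Tree-structured Parzen Estimator over the 4-dimensional count space.

The search space is the flat integer grid {0..max_count}^4 of per-family
learner counts (all-zero excluded).  Trials are split at the gamma
quantile of observed losses into "good" and "bad" sets; each dimension
gets a smoothed categorical Parzen density estimated separately from the
good trials (l) and the bad trials (g), and candidates drawn from l are
ranked by the density ratio l(x)/g(x).  With a flat 4-tuple space the
tree-structured conditionality of the general method is vacuous, so the
joint densities are per-dimension products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .base_pool import CountVector, InvalidConfigurationError, derive_seed
from .cascade import CascadeConfig, CascadeModel, UsageError, fit_cascade


@dataclass(frozen=True)
class Trial:
    x: CountVector
    loss: float
    index: int
    flagged: bool = False  # True when the objective returned a non-finite loss


@dataclass
class TrialHistory:
    trials: list[Trial] = field(default_factory=list)

    def append(self, trial: Trial) -> None:
        if self.trials and trial.index <= self.trials[-1].index:
            raise UsageError("trial indices must be strictly increasing")
        self.trials.append(trial)

    def best(self) -> Trial:
        if not self.trials:
            raise UsageError("empty history has no best trial")
        return min(self.trials, key=lambda t: (t.loss, t.index))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)


@dataclass
class TPEConfig:
    """Settings for the optimizer.

    gamma: quantile separating good from bad trials.
    n_candidates: candidates drawn from l per suggestion.
    n_startup: uniform-random evaluations before the density model kicks in.
    budget: total objective evaluations.
    max_count: per-dimension upper bound of the search range 0..max_count.
    prior_weight: Laplace-style smoothing mass added to every grid value.
    """

    gamma: float = 0.25
    n_candidates: int = 24
    n_startup: int = 10
    budget: int = 50
    seed: int = 0
    max_count: int = 8
    prior_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise InvalidConfigurationError("gamma must be in (0, 1)")
        if self.n_candidates < 1:
            raise InvalidConfigurationError("n_candidates must be >= 1")
        if self.budget < 1:
            raise InvalidConfigurationError("budget must be >= 1")
        # budget 1 is a single startup draw; with a larger budget the model
        # phase must get at least one evaluation
        if self.budget > 1 and self.n_startup >= self.budget:
            raise InvalidConfigurationError("n_startup must be < budget")
        if self.max_count < 1:
            raise InvalidConfigurationError("max_count must be >= 1")
        if self.prior_weight <= 0:
            raise InvalidConfigurationError("prior_weight must be > 0")


def split_trials(history: TrialHistory, gamma: float) -> tuple[list[Trial], list[Trial]]:
    """Split trials at the gamma quantile of loss.

    good = the n_good lowest-loss trials with n_good = max(1, ceil(gamma*n));
    bad = the remainder.  Ties in loss break by evaluation order, so the
    split is deterministic and conserves the history.
    """
    if len(history) == 0:
        raise UsageError("cannot split an empty history")
    n = len(history)
    n_good = max(1, math.ceil(gamma * n))
    ranked = sorted(history, key=lambda t: (t.loss, t.index))
    return ranked[:n_good], ranked[n_good:]


def estimate_discrete_density(
    trials: Sequence[Trial],
    dimension: int,
    max_count: int,
    prior_weight: float = 1.0,
) -> np.ndarray:
    """Smoothed categorical Parzen estimate over the grid 0..max_count.

    P(v) = (count_of_v + prior_weight) / (n + prior_weight * range_size),
    a proper distribution for any trial set including the empty one (where
    it reduces to the uniform prior).
    """
    range_size = max_count + 1
    counts = np.zeros(range_size)
    for t in trials:
        v = t.x.as_tuple()[dimension]
        if not 0 <= v <= max_count:
            raise InvalidConfigurationError(
                f"trial value {v} outside range 0..{max_count} in dimension {dimension}"
            )
        counts[v] += 1
    density = (counts + prior_weight) / (len(trials) + prior_weight * range_size)
    return density


def _random_count_vector(rng: np.random.Generator, max_count: int) -> CountVector:
    while True:
        draw = rng.integers(0, max_count + 1, size=4)
        if draw.sum() > 0:
            return CountVector.from_iterable(draw.tolist())


def _sample_from_densities(
    rng: np.random.Generator, densities: list[np.ndarray], max_count: int
) -> CountVector:
    grid = np.arange(max_count + 1)
    for _ in range(1000):
        draw = [int(rng.choice(grid, p=d)) for d in densities]
        if sum(draw) > 0:
            return CountVector.from_iterable(draw)
    # densities essentially collapsed onto zero everywhere; force one learner
    draw[int(np.argmax([d[1:].sum() for d in densities]))] = 1
    return CountVector.from_iterable(draw)


def _log_ratio(counts: Sequence[int], l_d: list[np.ndarray], g_d: list[np.ndarray]) -> float:
    return float(sum(math.log(l_d[d][v]) - math.log(g_d[d][v]) for d, v in enumerate(counts)))


def suggest(history: TrialHistory, config: TPEConfig, call_index: int | None = None) -> CountVector:
    """Propose the next count vector.

    Below ``n_startup`` observed trials the proposal is a seeded uniform
    draw over the valid space.  Afterwards the proposal has two stages:

    1. Exploitation: if the incumbent (lowest-loss trial) still has
       unevaluated one-step neighbors on the integer grid, propose the
       neighbor with the largest density ratio l(x)/g(x).  On a discrete
       grid the cells adjacent to the best observation are exactly where
       the good-density mass is concentrated, and evaluating them
       systematically is far more informative than re-sampling near-mode
       duplicates.
    2. Otherwise, draw ``n_candidates`` vectors from the good-trial
       densities l and return the unevaluated one maximizing
       prod_d l_d(x)/g_d(x) (the top candidate if all were already
       evaluated — duplicates are harmless since objectives are
       deterministic and memoized).

    All-zero vectors are rejected throughout.  Deterministic given
    (history, config.seed, call index); the call index defaults to the
    history length.
    """
    if call_index is None:
        call_index = len(history)
    rng = np.random.default_rng(derive_seed(config.seed, "suggest", call_index))
    if len(history) < config.n_startup:
        return _random_count_vector(rng, config.max_count)

    good, bad = split_trials(history, config.gamma)
    l_d = [
        estimate_discrete_density(good, d, config.max_count, config.prior_weight)
        for d in range(4)
    ]
    g_d = [
        estimate_discrete_density(bad, d, config.max_count, config.prior_weight)
        for d in range(4)
    ]
    seen = {t.x.as_tuple() for t in history}

    incumbent = history.best().x.as_tuple()
    neighbors: list[tuple[int, ...]] = []
    for d in range(4):
        for step in (-1, 1):
            cell = list(incumbent)
            cell[d] += step
            if 0 <= cell[d] <= config.max_count and sum(cell) > 0:
                if tuple(cell) not in seen:
                    neighbors.append(tuple(cell))
    if neighbors:
        neighbors.sort(key=lambda c: (-_log_ratio(c, l_d, g_d), c))
        return CountVector.from_iterable(neighbors[0])

    scored: list[tuple[float, int, CountVector]] = []
    for c_idx in range(config.n_candidates):
        cand = _sample_from_densities(rng, l_d, config.max_count)
        scored.append((_log_ratio(cand.as_tuple(), l_d, g_d), -c_idx, cand))
    scored.sort(reverse=True)
    for _, _, cand in scored:
        if cand.as_tuple() not in seen:
            return cand
    return scored[0][2]


def optimize(
    objective: Callable[[CountVector], float],
    config: TPEConfig,
) -> tuple[CountVector, TrialHistory]:
    """Sequentially minimize ``objective`` over the count space.

    The objective is evaluated exactly ``config.budget`` times (duplicate
    suggestions are memoized — our objectives are seeded-deterministic, so
    re-evaluation would return the same loss).  A non-finite objective
    value is recorded as loss 1.0 with the trial flagged.  Returns the
    argmin trial's vector and the full history for audit.
    """
    history = TrialHistory()
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in range(config.budget):
        x = suggest(history, config, call_index=i)
        key = x.as_tuple()
        flagged = False
        if key in cache:
            loss = cache[key]
        else:
            loss = float(objective(x))
            if not np.isfinite(loss):
                loss = 1.0
                flagged = True
            cache[key] = loss
        history.append(Trial(x=x, loss=loss, index=i, flagged=flagged))
    return history.best().x, history


def tune_cascade(
    X: np.ndarray,
    y: np.ndarray,
    tpe_config: TPEConfig | None = None,
    cascade_config: CascadeConfig | None = None,
    k_tune: int = 3,
) -> tuple[CountVector, CascadeModel, TrialHistory]:
    """Search the layer composition by TPE, then refit on all training data.

    The objective is the mean (1 - accuracy) of ``fit_cascade`` over an
    internal stratified ``k_tune``-fold split of the supplied training
    partition; the outer evaluation's test fold must never be passed in
    here.  After the search the cascade is refitted on the full training
    partition with the best composition.
    """
    from sklearn.model_selection import StratifiedKFold

    tpe_config = tpe_config or TPEConfig()
    cascade_config = cascade_config or CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(
        n_splits=k_tune,
        shuffle=True,
        random_state=derive_seed(tpe_config.seed, "tune-folds"),
    )
    folds = list(skf.split(X, y))

    def objective(counts: CountVector) -> float:
        errors = []
        for tr, te in folds:
            model = fit_cascade(X[tr], y[tr], counts, cascade_config)
            acc = float(np.mean(model.predict(X[te]) == y[te]))
            errors.append(1.0 - acc)
        return float(np.mean(errors))

    best, history = optimize(objective, tpe_config)
    model = fit_cascade(X, y, best, cascade_config)
    return best, model, history
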