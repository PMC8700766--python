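"""Let the Tree-structured Parzen Estimator choose the layer composition.

The TPE treats the per-family learner counts (RF, ET, AdaBoost, GBDT) as
a 4-dimensional integer hyperparameter, splits its trial history into
good and bad halves at the loss quantile, and proposes vectors where the
good-trial density dominates.  The objective is internal cross-validated
cascade error on the training data only.
"""

from tpecascade import (
    CascadeConfig,
    Family,
    TPEConfig,
    builtin_profiles,
    make_dataset,
    tune_cascade,
)

profile = builtin_profiles()["breast-like"].replace(signal_strength=3.0)
X, y, _ = make_dataset(profile, seed=1)

small_trees = {family: {"n_estimators": 15} for family in Family}
best, model, history = tune_cascade(
    X.to_numpy(float), y,
    TPEConfig(budget=8, seed=0, max_count=3, n_startup=4),
    CascadeConfig(max_depth=2, k_inner=2, seed=0, learner_params=small_trees),
    k_tune=2,
)

print("trial history (composition -> CV error):")
for trial in history:
    marker = "  <- best" if trial.x == best else ""
    print(f"  {trial.index:2d}: {trial.x} -> {trial.loss:.4f}{marker}")
print(f"selected composition {best}, refitted cascade depth {model.depth}")
# Lower loss is better: loss = mean (1 - accuracy) over the internal folds.
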