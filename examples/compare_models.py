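"""Compare the tuned cascade against its baselines under shared CV folds.

All models are evaluated on identical stratified partitions so the
per-run metric differences support paired t-tests.  Stars mark baselines
whose runs differ significantly from the tuned cascade (* p<0.05,
** p<0.01).
"""

from tpecascade import (
    CascadeConfig,
    Family,
    TPEConfig,
    builtin_profiles,
    make_dataset,
    run_benchmark,
)

profile = builtin_profiles()["breast-like"].replace(signal_strength=3.0)
X, y, _ = make_dataset(profile, seed=0)

small_trees = {family: {"n_estimators": 15} for family in Family}
result = run_benchmark(
    X.to_numpy(float), y, seed=0, n_folds=3, n_repeats=1,
    models=["rf", "adaboost", "et", "gbdt", "tpe_voting", "dem", "tpe_dem"],
    learner_params=small_trees,
    cascade_config=CascadeConfig(max_depth=2, k_inner=2, seed=0,
                                 learner_params=small_trees),
    tpe_config=TPEConfig(budget=6, seed=0, max_count=2, n_startup=4),
    k_tune=2,
)
print(result.formatted().to_string())
# 'dem' is the fixed-composition cascade (one learner of each family per
# layer); 'tpe_voting' is flat TPE-weighted soft voting without a cascade;
# 'tpe_dem' is the cascade with TPE-selected composition.
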