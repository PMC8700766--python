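"""Generate synthetic clinical-shaped datasets.

Each built-in profile mirrors the shape of a familiar tabular benchmark:
row count, feature count, continuous/categorical mix and class imbalance.
The label-conditional signal is controllable, so the same shapes can be
produced as pure noise (signal 0) or as strongly learnable data.
"""

from tpecascade import builtin_profiles, make_dataset

for name, profile in builtin_profiles().items():
    X, y, meta = make_dataset(profile, seed=0)
    print(
        f"{name:15s} rows={len(X):5d} features={X.shape[1]:3d} "
        f"positives={int(y.sum()):5d} negatives={int((y == 0).sum()):5d} "
        f"categorical={len(meta['categorical_columns']):3d}"
    )

# The class counts match each profile exactly (stratified construction,
# not Bernoulli draws), and the same seed always reproduces the same table.
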