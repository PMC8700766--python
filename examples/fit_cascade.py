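"""Fit a deep cascade with a fixed layer composition.

Every layer holds the same mix of base learners — here 2 random forests,
1 extra-trees and 1 AdaBoost — and augments the original features with
each learner's class probabilities before the next layer.  Depth grows
until the internal holdout accuracy stops improving.
"""

import numpy as np

from tpecascade import (
    CascadeConfig,
    CountVector,
    builtin_profiles,
    fit_cascade,
    make_dataset,
)

profile = builtin_profiles()["breast-like"].replace(signal_strength=3.0)
X, y, _ = make_dataset(profile, seed=0)
Xv = X.to_numpy(float)

model = fit_cascade(Xv, y, CountVector(2, 1, 1, 0),
                    CascadeConfig(max_depth=4, patience=1, seed=0))

print(f"composition {model.counts} -> retained depth {model.depth}")
for record in model.history:
    tag = " (discarded)" if record.discarded else ""
    print(f"  layer {record.index}: holdout accuracy {record.val_accuracy:.3f}{tag}")

train_acc = np.mean(model.predict(Xv) == y)
print(f"training accuracy {train_acc:.3f}")
# The retained depth is the layer with the best holdout accuracy; layers
# trained after it (non-improving) are flagged discarded.
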