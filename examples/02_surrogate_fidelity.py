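"""Train the performance-prediction surrogate and check its fidelity.

Builds the surrogate's training table from random feature subsets (one real
LASSO fit per subset), trains the random forest, then scores held-out subsets
with the surrogate and compares against their true measured performance. The
surrogate only needs to *rank* subsets well - its predictions gate which
candidates earn a real fit - so the figure of merit is the correlation.
"""

import numpy as np
from scipy.stats import spearmanr

from aiwrap import (
    CVConfig,
    PPMConfig,
    build_performance_dataset,
    get_scenario,
    predict_performance,
    sample_random_subsets,
    simulate_dataset,
    train_ppm,
)

train, _, _ = simulate_dataset(get_scenario("1_I", seed=1))
cv = CVConfig(seed=1)
cfg = PPMConfig(n_trees=300, seed=1)

k = cfg.k(train.p)  # 15 * p = 225 initial subsets
subsets = sample_random_subsets(train.p, k, seed=2)
dperf = build_performance_dataset(train, subsets, cv=cv)
ppm = train_ppm(dperf, cfg)
print(f"surrogate trained on {len(dperf)} (subset, performance) pairs")

held = sample_random_subsets(train.p, 60, seed=3)
held_truth = build_performance_dataset(train, held, cv=cv)
preds = predict_performance(ppm, held_truth.masks)

rho = spearmanr(preds, held_truth.performances).statistic
r = np.corrcoef(preds, held_truth.performances)[0, 1]
print(f"held-out subsets: Pearson r = {r:.3f}, Spearman rho = {rho:.3f}")
print("predicted ", np.round(preds[:6], 3))
print("measured  ", np.round(held_truth.performances[:6], 3))
print("A strongly positive correlation means the surrogate can steer the search;")
print("exact agreement is not required because gate-passing candidates are re-fitted.")
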