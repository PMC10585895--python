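"""Generate one of the standard simulation scenarios and inspect its structure.

Draws the small interaction scenario (p=15 features, the first 15 of which are
pairwise correlated at 0.5; ten marginal effects +-0.5 plus nine adjacent-pair
interaction effects; noise sd 0.25) and prints the empirical moments next to
their generating values.
"""

import numpy as np

from aiwrap import get_scenario, rmse, simulate_dataset

scenario = get_scenario("1_I", seed=42)
train, test, targets = simulate_dataset(scenario)

print(f"scenario {scenario.name}: train {train.n}x{train.p}, test {test.n}x{test.p}")
print(f"targets: {len(targets.marginal_targets)} marginal, "
      f"{len(targets.interaction_targets)} interaction")

# empirical check of the correlated block (generating correlation = 0.5)
corr = np.corrcoef(test.X["x1"], test.X["x2"])[0, 1]
print(f"corr(x1, x2) on the test draw: {corr:.3f} (generating value 0.50)")

# the oracle predictor: true coefficients applied to fresh data.
# Its test RMSE is the irreducible noise level sigma = 0.25 - no selection
# method can do better than this.
beta = np.array(scenario.beta_marginal)
pred = test.X.to_numpy() @ beta
for i, j, b in scenario.beta_interaction:
    pred += b * test.X.iloc[:, i - 1] * test.X.iloc[:, j - 1]
print(f"oracle test RMSE: {rmse(test.y.to_numpy(), pred):.3f} (sigma = {scenario.sigma})")
print(f"sd(y) on test:    {test.y.std():.3f} (what an intercept-only model would score)")
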