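"""Select a surrogate family by 10-fold CV on seed data and score candidates.

Five families compete — gradient boosting, SVM, neural network, random
forest, Gaussian process — on out-of-fold MSE; the winner provides the
mu/sigma predictions the acquisition functions consume.
"""

import numpy as np

from enzymof import (
    AcquisitionConfig,
    Oracle,
    default_families,
    fit,
    lhs_sample,
    propose_batch,
    select_model,
)
from enzymof.design_space import Axis, enumerate_grid
from enzymof.oracle import OracleConfig

grid = enumerate_grid(
    [
        Axis("ca_mM", 2.0, 98.0, 6.0),
        Axis("idc_mM", 22.5, 122.5, 5.0),
        Axis.from_levels("enzyme_mg_per_ml", 0.2, 1.96, 15),
    ]
)
oracle = Oracle(OracleConfig(noise_sd=1.7, seed=5), grid)
seeds = [oracle(r) for r in lhs_sample(grid, 15, seed=5).recipes]

family, table = select_model(default_families(), seeds, target="EE", k=10, seed=5)
print("10-fold CV comparison on the 15-recipe seed set (MSE, %²):")
print(table[["family", "mean_mse"]].to_string(index=False))
print(f"\nselected family: {family.name}")

sfit = fit(family, seeds, target="EE", seed=5)
mu_seed, _ = sfit.predict(np.array([t.recipe.as_array() for t in seeds]))
batch = propose_batch(sfit, grid, [t.recipe for t in seeds], AcquisitionConfig(), float(mu_seed.max()))
print("\nnext batch (30 EI-generated candidates, top 10 by predicted EE):")
for c in batch[:3]:
    print(f"  {c.recipe.as_tuple()}  mu={c.mu:.1f}%  sigma={c.sigma:.1f}  EI={c.score:.3f}")
print("  ...")
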