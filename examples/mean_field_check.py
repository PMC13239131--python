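"""Validate the stochastic engine against the deterministic mean-field recursion.

At large carrying capacity the replicate-mean resident-allele frequency of
the individual-based model should track the infinite-population genotype
recursion (same event order, expectations only). This is the package's core
internal consistency check.
"""

import numpy as np

from floodsim import ModelParams, run_replicate
from floodsim.oracle import oracle_trajectory

params = ModelParams(K=5000, m=0.1, generations=30)
oracle_w = np.array([s.resident_frequency for s in oracle_trajectory(params, 30)])

n_reps = 4
mean_w = np.zeros(31)
for seed in range(n_reps):
    result = run_replicate(params.replace(seed=seed))
    freqs = [
        (c.counts["W1"] + c.counts["W2"]) / (2 * c.pop_size)
        for c in result.trajectory
    ]
    mean_w += np.array(freqs) / n_reps

print("gen   oracle   IBM-mean   |diff|")
for g in range(0, 31, 5):
    print(f"{g:3d}   {oracle_w[g]:.4f}   {mean_w[g]:.4f}    {abs(oracle_w[g]-mean_w[g]):.4f}")
print(f"\nmax |IBM mean - oracle| over 30 generations: {np.abs(mean_w - oracle_w).max():.4f}")
print(
    "\nThe oracle is deterministic; the individual-based model fluctuates\n"
    "around it with sampling noise that shrinks as K grows. Deviations well\n"
    "below 0.03 confirm the engine implements the intended expectations."
)
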