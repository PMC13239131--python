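"""Run one stochastic replicate of the gene-flooding model and inspect it.

A resident population of K = 1000 diploids (alleles W1/W2) receives a pulse
of 150 migrants (alleles L1/L2) every generation for 100 generations.
The trajectory records the census of all four alleles each generation;
"collapse" means both resident alleles were lost by the final generation.
"""

from floodsim import ModelParams, run_replicate

params = ModelParams(m=0.15, seed=42)
result = run_replicate(params)

print(f"migration fraction m = {params.m}, K = {params.K}, seed = {params.seed}")
print(f"collapsed: {result.collapsed}  (generation {result.collapse_generation})")
print(f"extinct:   {result.extinct}")
print()
print("generation     n    W1    W2    L1    L2")
for snap in result.trajectory[:: max(1, params.generations // 10)]:
    c = snap.counts
    print(
        f"{snap.generation:10d} {snap.pop_size:5d} {c['W1']:5d} {c['W2']:5d} "
        f"{c['L1']:5d} {c['L2']:5d}"
    )
print()
print(
    "Each row is one generation: n is the post-cull population size and the\n"
    "four columns count allele copies (they always sum to 2n). Watch W1 and\n"
    "W2 shrink as repeated pulses of L alleles dilute the residents."
)
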