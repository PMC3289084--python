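"""Generate a synthetic weighted PPI network with planted complexes.

The generator builds a scale-free background (preferential attachment),
plants complexes shaped as cliques, stars or clique-plus-pendant hybrids
with high internal edge weights, sprinkles noise edges, and assigns every
protein a random sequence (complex members get a polar-residue bias).
"""

import numpy as np

from ppicomplex import SynthConfig, generate

cfg = SynthConfig(n_background_nodes=500, n_planted_complexes=10, seed=42)
network, ground_truth = generate(cfg)

degrees = [len(nb) for nb in network.adjacency().values()]
print(f"network: {network.n_nodes} proteins, {network.n_edges} interactions")
print(f"mean degree {np.mean(degrees):.1f}, max degree {max(degrees)} "
      "(heavy tail = scale-free-like)")
print(f"planted complexes: {len(ground_truth)}, sizes {sorted(ground_truth.sizes())}")

# the ground truth is the answer key later used to benchmark predictions
name, members = ground_truth.complexes[0]
print(f"example complex {name}: {sorted(members)[:6]} ...")
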