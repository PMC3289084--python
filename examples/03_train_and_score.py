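"""Train the 43-11-7-1 backpropagation classifier and score subgraphs.

Known complexes are the positive examples; random connected subgraphs with
matching sizes are the negatives.  The trained network maps any candidate
subgraph to a probability-like complex score in (0, 1).
"""

import numpy as np

from ppicomplex import (
    FeatureExtractor, MLPModel, TrainingSet, SynthConfig,
    generate, generate_negatives, make_scorer, train,
)

cfg = SynthConfig(n_background_nodes=500, n_planted_complexes=10, seed=42)
network, ground_truth = generate(cfg)
extractor = FeatureExtractor(network)

positives = ground_truth.member_sets()
negatives = generate_negatives(
    network, len(positives), ground_truth.sizes(), seed=3, forbidden=positives
)
X = np.array([extractor.vector(m) for m in positives + negatives])
y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

model = MLPModel(rng_seed=0)  # 43 -> 11 -> 7 -> 1 logistic units
train(model, TrainingSet(X, y))
print(f"trained for {model.epochs_run} epochs "
      "(stops when every weight change in an epoch is below 1e-4)")

score = make_scorer(model, extractor)
pos_scores = [score(m) for m in positives]
neg_scores = [score(m) for m in negatives]
print(f"median score of true complexes:  {np.median(pos_scores):.3f}")
print(f"median score of random patches:  {np.median(neg_scores):.3f}")
print("scores near 1 mean the subgraph looks like a complex to the model.")
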