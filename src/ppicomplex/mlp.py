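"""Feed-forward logistic network trained with classic online backpropagation.

The complex/non-complex classifier is a 43-11-7-1 multilayer perceptron: one
input unit per subgraph feature, two hidden layers (11 and 7 units, sizes
settled empirically), one logistic output unit read as the probability that
the subgraph is a complex.

Every unit j computes a net input I_j = sum_i w_ij O_i + theta_j and output
O_j = 1 / (1 + exp(-I_j)).  Training is stochastic gradient descent on the
squared error: after each example the output-unit error is
Err_j = O_j (1 - O_j)(T_j - O_j), hidden-unit errors are
Err_j = O_j (1 - O_j) sum_k Err_k w_jk, and parameters move by
Delta w_ij = l Err_j O_i and Delta theta_j = l Err_j with learning rate l.
An epoch shuffles the examples (seeded); training stops when the largest
absolute weight change within an epoch falls below a threshold, or at the
epoch cap.

Features are z-scored with statistics frozen from the training set; the
scaler is stored on the model so prediction always sees the training scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import DEFAULT_CUTOFFS, FeatureExtractor, N_FEATURES, Subgraph, featurize

__all__ = ["MLPModel", "TrainingSet", "forward", "backprop_epoch", "train",
           "predict_score", "save_model", "load_model"]

DEFAULT_LAYER_SIZES: tuple[int, ...] = (N_FEATURES, 11, 7, 1)


@dataclass
class TrainingSet:
    """Feature matrix plus binary targets (1 = complex, 0 = non-complex)."""

    features: np.ndarray  # (n_examples, n_features)
    targets: np.ndarray   # (n_examples,), values in {0, 1}

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.features.ndim != 2 or len(self.features) != len(self.targets):
            raise ValueError("features and targets are shape-incompatible")
        if not set(np.unique(self.targets)) <= {0.0, 1.0}:
            raise ValueError("targets must be 0/1")

    def require_both_classes(self) -> None:
        if len(set(self.targets)) < 2:
            raise ValueError("training needs at least one example of each class")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class MLPModel:
    """Weights, biases and training state of the logistic feed-forward net."""

    layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    learning_rate: float = 0.1
    convergence_threshold: float = 1e-4
    rng_seed: int = 0
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    scaler_mean: Optional[np.ndarray] = None
    scaler_sd: Optional[np.ndarray] = None
    epochs_run: int = 0
    trained: bool = False

    def __post_init__(self) -> None:
        if not self.weights:
            self.initialize()

    def initialize(self, seed: Optional[int] = None) -> None:
        """Fresh uniform(-0.5, 0.5) weights and biases from the seeded RNG."""
        if seed is not None:
            self.rng_seed = int(seed)
        rng = np.random.default_rng(self.rng_seed)
        self.weights = [
            rng.uniform(-0.5, 0.5, size=(a, b))
            for a, b in zip(self.layer_sizes, self.layer_sizes[1:])
        ]
        self.biases = [rng.uniform(-0.5, 0.5, size=b) for b in self.layer_sizes[1:]]
        self.epochs_run = 0
        self.trained = False

    # -- scaling ---------------------------------------------------------

    def fit_scaler(self, X: np.ndarray) -> None:
        self.scaler_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant features pass through unscaled
        self.scaler_sd = sd

    def scale(self, x: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return x
        return (x - self.scaler_mean) / self.scaler_sd

    def check_finite(self) -> None:
        for arr in (*self.weights, *self.biases):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError("network parameters diverged (non-finite)")


def _logistic(x: np.ndarray) -> np.ndarray:
    # clip keeps exp() finite; logistic saturates anyway beyond +-500
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def forward(model: MLPModel, x: np.ndarray, *, scaled: bool = False) -> float:
    """Output-unit activation for one (scaled) feature vector, in (0, 1)."""
    return float(_activations(model, x if scaled else model.scale(np.asarray(x, float)))[-1][0])


def _activations(model: MLPModel, x: np.ndarray) -> list[np.ndarray]:
    """Per-layer outputs [O_0 .. O_L]; O_0 is the input pattern itself."""
    if x.shape != (model.layer_sizes[0],):
        raise ValueError(
            f"input length {x.shape} does not match {model.layer_sizes[0]} input units"
        )
    acts = [x]
    for W, b in zip(model.weights, model.biases):
        acts.append(_logistic(acts[-1] @ W + b))
    return acts


def example_deltas(
    model: MLPModel, x: np.ndarray, target: float
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Weight/bias updates for a single (already scaled) example.

    Returns (delta_W per layer, delta_b per layer, output activation); the
    deltas already include the learning-rate factor.
    """
    acts = _activations(model, x)
    out = acts[-1]
    err = out * (1 - out) * (target - out)
    dWs: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    dbs: list[np.ndarray] = [None] * len(model.biases)   # type: ignore[list-item]
    l = model.learning_rate
    for layer in range(len(model.weights) - 1, -1, -1):
        dWs[layer] = l * np.outer(acts[layer], err)
        dbs[layer] = l * err
        if layer > 0:
            o = acts[layer]
            err = o * (1 - o) * (model.weights[layer] @ err)
    return dWs, dbs, float(out[0])


def backprop_epoch(
    model: MLPModel,
    data: TrainingSet,
    order: Optional[Sequence[int]] = None,
) -> float:
    """One online pass over the training set; returns the epoch's max |Δw|.

    Updates are applied example by example (stochastic backpropagation), in
    the given order or the natural one.  All layer errors for one example
    are computed from the pre-update weights, then the updates are applied.
    """
    X = data.features
    y = data.targets
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError("feature width does not match the input layer")
    idx = range(len(y)) if order is None else order
    weights = model.weights
    biases = model.biases
    n_layers = len(weights)
    l = model.learning_rate
    max_dw = 0.0
    for i in idx:
        # forward
        acts = [X[i]]
        a = X[i]
        for W, b in zip(weights, biases):
            z = a @ W
            z += b
            np.negative(z, out=z)
            np.clip(z, -500, 500, out=z)
            np.exp(z, out=z)
            z += 1.0
            a = np.reciprocal(z, out=z)
            acts.append(a)
        out = acts[-1]
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(f"non-finite activation at example {i}")
        # backward: per-layer scaled errors g = l * Err, pre-update weights
        err = out * (1 - out) * (y[i] - out)
        gs: list[np.ndarray] = [np.empty(0)] * n_layers
        for layer in range(n_layers - 1, -1, -1):
            gs[layer] = l * err
            if layer > 0:
                o = acts[layer]
                err = o * (1 - o) * (weights[layer] @ err)
        # apply; |Δw_ij| = |O_i|·|g_j| so the epoch max factorizes
        for layer in range(n_layers):
            a_prev = acts[layer]
            g = gs[layer]
            weights[layer] += a_prev[:, None] * g
            biases[layer] += g
            step = float(np.abs(a_prev).max() * np.abs(g).max())
            if step > max_dw:
                max_dw = step
    return max_dw


def train(
    model: MLPModel,
    data: TrainingSet,
    max_epochs: int = 5000,
    *,
    fit_scaler: bool = True,
) -> MLPModel:
    """Train in place until all weight changes within an epoch are tiny.

    Convergence: the largest |Δw| of an epoch drops below the model's
    threshold.  Example order is reshuffled every epoch from the model's
    seeded RNG, so a (model seed, data) pair trains bit-reproducibly.
    """
    data.require_both_classes()
    if fit_scaler:
        model.fit_scaler(data.features)
    scaled = TrainingSet(model.scale(data.features), data.targets)
    rng = np.random.default_rng(np.random.SeedSequence([model.rng_seed, 0x5AD0]))
    n = len(scaled)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        max_dw = backprop_epoch(model, scaled, order)
        model.epochs_run += 1
        model.check_finite()
        if max_dw < model.convergence_threshold:
            break
    model.trained = True
    return model


def predict_score(
    model: MLPModel,
    s: Subgraph,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> float:
    """Model score of a candidate subgraph, in (0, 1)."""
    if not model.trained:
        raise ValueError("model is untrained; call train() first")
    return forward(model, featurize(s, cutoffs))


def make_scorer(model: MLPModel, extractor: FeatureExtractor):
    """Bind a trained model to a network's feature extractor.

    Returns ``score(members) -> float`` for the discovery loop.
    """
    if not model.trained:
        raise ValueError("model is untrained; call train() first")
    vector = extractor.vector
    mean = model.scaler_mean
    sd = model.scaler_sd
    weights = model.weights
    biases = model.biases

    def score(members) -> float:
        x = vector(members)
        if mean is not None:
            x = (x - mean) / sd
        for W, b in zip(weights, biases):
            x = _logistic(x @ W + b)
        return float(x[0])

    return score


_ENSEMBLE_VOTES = {"min": np.min, "mean": np.mean, "median": np.median}


def make_ensemble_scorer(
    models: Sequence[MLPModel],
    extractor: FeatureExtractor,
    vote: str = "min",
):
    """Aggregate several independently trained networks into one scorer.

    A single logistic network extrapolates confidently into feature regions
    with no training data, and a score-maximizing search will find exactly
    those regions.  Networks trained from different random initializations
    disagree there, while agreeing on data-supported predictions, so an
    aggregated vote suppresses the artifacts.  The conservative ``min`` vote
    (a candidate scores only as high as its most sceptical network allows)
    works best against a search that actively exploits blind spots.
    """
    if vote not in _ENSEMBLE_VOTES:
        raise ValueError(f"vote must be one of {sorted(_ENSEMBLE_VOTES)}")
    agg = _ENSEMBLE_VOTES[vote]
    scorers = [make_scorer(m, extractor) for m in models]
    if len(scorers) == 1:
        return scorers[0]

    def score(members) -> float:
        return float(agg([s(members) for s in scorers]))

    return score


# -- serialization -------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: MLPModel, path: str | Path) -> None:
    """Serialize to a versioned JSON file (exact float round-trip via repr)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "learning_rate": model.learning_rate,
        "convergence_threshold": model.convergence_threshold,
        "rng_seed": model.rng_seed,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "scaler_mean": None if model.scaler_mean is None else model.scaler_mean.tolist(),
        "scaler_sd": None if model.scaler_sd is None else model.scaler_sd.tolist(),
        "epochs_run": model.epochs_run,
        "trained": model.trained,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> MLPModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    model = MLPModel(
        layer_sizes=tuple(payload["layer_sizes"]),
        learning_rate=payload["learning_rate"],
        convergence_threshold=payload["convergence_threshold"],
        rng_seed=payload["rng_seed"],
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
    )
    model.scaler_mean = None if payload["scaler_mean"] is None else np.array(payload["scaler_mean"])
    model.scaler_sd = None if payload["scaler_sd"] is None else np.array(payload["scaler_sd"])
    model.epochs_run = payload["epochs_run"]
    model.trained = payload["trained"]
    return model
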