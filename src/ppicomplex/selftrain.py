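"""Recursive self-training: train → discover → promote → retrain.

The labeled data available for complex detection are scarce — a benchmark
catalog of known complexes and nothing else — so the classifier bootstraps
itself.  Iteration 0 trains the network on the known complexes (positives)
plus randomly sampled connected subgraphs (negatives).  Each later iteration
runs the greedy discovery over the network, promotes predictions whose score
clears a confidence cutoff into the positive set, regenerates matched
negatives, and retrains from scratch with a fresh iteration-derived seed.
The loop ends when an iteration adds no new positive or the iteration cap is
reached.

The promotion cutoff (default 0.9) is deliberately stricter than the
discovery threshold (0.5): only confident predictions become pseudo-labels,
limiting confirmation-bias drift.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureExtractor
from .mlp import MLPModel, TrainingSet, make_ensemble_scorer, train
from .network import ComplexSet, ProteinNetwork
from .search import PredictedComplex, SearchConfig, discover, overlap_rate

__all__ = ["LoopConfig", "LoopState", "derive_seed", "generate_negatives",
           "build_training_set", "run_loop"]

logger = logging.getLogger(__name__)


def derive_seed(stage: str, seed: int) -> int:
    """Deterministic per-stage seed fan-out (stable across processes)."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2**31)


@dataclass
class LoopConfig:
    """Self-training settings.

    ``promotion_overlap_dedup``: a confident prediction joins the positive
    set only if its overlap rate with every existing positive is at or below
    this value.  Deduplicating by overlap rather than exact node-set
    equality matters: successive retrainings produce slightly different
    member sets for the same complex, and promoting every variant teaches
    the model that complex-plus-random-neighbor sets are positives — a
    feedback that inflates the positive set without adding information.

    ``promotion_size_guard``: when true, a prediction larger than the
    largest initially known complex is never promoted.  Greedy growth can
    coast on a saturated score and pad a genuine complex with background
    nodes up to the size cap; such oversized pseudo-labels lie outside the
    size support of the labeled data, and training on them rapidly erodes
    the decision boundary.

    ``n_models`` / ``ensemble_vote``: the subgraph scorer is an ensemble of
    independently initialized networks combined by this vote (see
    :func:`ppicomplex.mlp.make_ensemble_scorer`); ``n_models = 1`` recovers
    a single network.

    ``drift_guard``: the stream of confident new predictions should dry up
    as the catalog of complexes saturates; an iteration that promotes *more*
    than its predecessor signals that mislabeled pseudo-positives have begun
    eroding the decision boundary (each one claims a patch of background as
    positive territory, which breeds further false promotions).  With the
    guard on, such an iteration is discarded: the loop stops and returns the
    previous iteration's discoveries.
    """

    max_iterations: int = 10
    confidence_cutoff: float = 0.9
    negatives_per_positive: float = 1.0
    promotion_overlap_dedup: float = 0.8
    promotion_size_guard: bool = True
    n_models: int = 5
    ensemble_vote: str = "min"
    drift_guard: bool = True
    seed: int = 0
    learning_rate: float = 0.1
    convergence_threshold: float = 1e-4
    max_epochs: int = 5000
    warm_start: bool = False


@dataclass
class LoopState:
    """Where the self-training loop ended up."""

    iteration: int
    models: list[MLPModel]
    positives: list[frozenset[str]]
    negatives: list[frozenset[str]]
    discovered: list[PredictedComplex] = field(default_factory=list)
    confidence_cutoff: float = 0.9
    initial_positive_count: int = 0

    @property
    def model(self) -> MLPModel:
        """The first ensemble member (the whole ensemble is ``models``)."""
        return self.models[0]


def generate_negatives(
    network: ProteinNetwork,
    n: int,
    size_distribution: Sequence[int],
    seed: int,
    forbidden: Sequence[frozenset] = (),
) -> list[frozenset[str]]:
    """Sample random connected subgraphs as non-complex examples.

    Sizes are drawn (with replacement) from the positives' size distribution
    so negatives are not separable by size alone.  Sampling is a seeded
    random walk: grow a node set by stepping to a uniformly random neighbor
    of a uniformly random current member.  A sampled set identical to any
    known positive is resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    adj = network.adjacency()
    nodes = sorted(adj)
    if not nodes:
        raise ValueError("network is empty")
    max_needed = max(size_distribution)
    forbidden_set = set(forbidden)
    rng = np.random.default_rng(seed)
    out: list[frozenset[str]] = []
    attempts = 0
    max_attempts = 200 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not sample {n} connected subgraphs of sizes up to "
                f"{max_needed}; network too small or too fragmented"
            )
        target = int(size_distribution[rng.integers(len(size_distribution))])
        start = nodes[rng.integers(len(nodes))]
        members = {start}
        stuck = 0
        while len(members) < target and stuck < 50:
            cur = sorted(members)[rng.integers(len(members))]
            nbrs = list(adj[cur])
            if not nbrs:
                break
            nxt = nbrs[rng.integers(len(nbrs))]
            if nxt in members:
                stuck += 1
            else:
                members.add(nxt)
        if len(members) != target:
            continue
        fs = frozenset(members)
        if fs in forbidden_set:
            continue
        out.append(fs)
    return out


def build_training_set(
    extractor: FeatureExtractor,
    positives: Sequence[frozenset[str]],
    negatives: Sequence[frozenset[str]],
) -> TrainingSet:
    X = np.array([extractor.vector(m) for m in (*positives, *negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    return TrainingSet(X, y)


def _train_ensemble(
    extractor: FeatureExtractor,
    positives: Sequence[frozenset[str]],
    negatives: Sequence[frozenset[str]],
    cfg: LoopConfig,
    iteration: int,
    previous: Optional[list[MLPModel]],
) -> list[MLPModel]:
    data = build_training_set(extractor, positives, negatives)
    models: list[MLPModel] = []
    for k in range(cfg.n_models):
        if cfg.warm_start and previous is not None:
            model = previous[k]
        else:
            model = MLPModel(
                learning_rate=cfg.learning_rate,
                convergence_threshold=cfg.convergence_threshold,
                rng_seed=derive_seed(f"init:{iteration}:{k}", cfg.seed),
            )
        models.append(train(model, data, max_epochs=cfg.max_epochs))
    return models


def run_loop(
    network: ProteinNetwork,
    initial_positives: ComplexSet,
    cfg: SearchConfig,
    loop_cfg: Optional[LoopConfig] = None,
) -> tuple[list[PredictedComplex], LoopState]:
    """Run the full semi-supervised pipeline on one network.

    Returns the final discovery pass's predictions and the loop state.  The
    initial known positives always remain in the positive set, which only
    ever grows.  Bit-reproducible for a fixed ``loop_cfg.seed``.
    """
    if len(initial_positives) == 0:
        raise ValueError("initial positive set is empty")
    loop_cfg = loop_cfg or LoopConfig()
    extractor = FeatureExtractor(network, cfg.cutoffs)

    initial_sets: list[frozenset[str]] = list(initial_positives.member_sets())
    positives: list[frozenset[str]] = list(initial_sets)
    positive_keys: set[frozenset[str]] = set(positives)
    sizes = [len(p) for p in positives]

    n_neg = max(1, int(round(loop_cfg.negatives_per_positive * len(positives))))
    negatives = generate_negatives(
        network, n_neg, sizes, derive_seed("neg:0", loop_cfg.seed), positives
    )
    models = _train_ensemble(extractor, positives, negatives, loop_cfg, 0, None)
    logger.info("iteration 0: trained %d nets on %d positives / %d negatives",
                len(models), len(positives), len(negatives))

    state = LoopState(
        iteration=0,
        models=models,
        positives=positives,
        negatives=negatives,
        confidence_cutoff=loop_cfg.confidence_cutoff,
        initial_positive_count=len(initial_positives),
    )
    found: list[PredictedComplex] = []
    seen_discovered: set[frozenset[str]] = set()
    prev_promoted_count: Optional[int] = None
    prev_found: Optional[list[PredictedComplex]] = None

    for iteration in range(1, loop_cfg.max_iterations + 1):
        scorer = make_ensemble_scorer(models, extractor, loop_cfg.ensemble_vote)
        found = discover(network, scorer, cfg, iteration=iteration)
        for c in found:
            if c.members not in seen_discovered:
                seen_discovered.add(c.members)
                state.discovered.append(c)
        max_known_size = max(len(p) for p in initial_sets)
        promoted = []
        for c in sorted(found, key=lambda c: (-c.score, tuple(sorted(c.members)))):
            if c.score < loop_cfg.confidence_cutoff or c.members in positive_keys:
                continue
            if loop_cfg.promotion_size_guard and len(c.members) > max_known_size:
                continue
            if any(
                overlap_rate(c.members, p) > loop_cfg.promotion_overlap_dedup
                for p in positives + promoted
            ):
                continue
            promoted.append(c.members)
        state.iteration = iteration
        logger.info(
            "iteration %d: %d complexes found, %d promoted to positives",
            iteration, len(found), len(promoted),
        )
        if (
            loop_cfg.drift_guard
            and prev_promoted_count is not None
            and len(promoted) > prev_promoted_count
        ):
            logger.info(
                "iteration %d: promotions rebounded (%d > %d); discarding the "
                "iteration and keeping the previous predictions",
                iteration, len(promoted), prev_promoted_count,
            )
            found = prev_found if prev_found is not None else found
            state.iteration = iteration - 1
            break
        if not promoted or iteration == loop_cfg.max_iterations:
            break
        prev_promoted_count = len(promoted)
        prev_found = found
        for m in promoted:
            positives.append(m)
            positive_keys.add(m)
        sizes = [len(p) for p in positives]
        n_neg = max(1, int(round(loop_cfg.negatives_per_positive * len(positives))))
        negatives = generate_negatives(
            network, n_neg, sizes,
            derive_seed(f"neg:{iteration}", loop_cfg.seed), positives,
        )
        models = _train_ensemble(
            extractor, positives, negatives, loop_cfg, iteration, models
        )
        state.models = models
        state.negatives = negatives
        logger.info("iteration %d: retrained on %d positives", iteration, len(positives))

    return found, state
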