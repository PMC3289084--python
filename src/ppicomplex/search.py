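"""Greedy seed-and-grow discovery of high-scoring candidate complexes.

Finding the maximally scoring subgraphs of a large graph is NP-hard, so the
search is heuristic: seeds are the nodes with the largest summed incident
edge weight; from each seed the cluster absorbs, one at a time, the
neighboring node whose addition gives the highest model score.  Before the
cluster reaches the minimum complex size the best neighbor is added
unconditionally (small subgraphs score poorly no matter what); afterwards a
neighbor is accepted only if the score does not decrease.  Growth stops when
no neighbor qualifies or the size cap is hit, and the grown cluster is kept
only if its final score clears the decision threshold.  Clusters that
overlap heavily are merged, so predictions may overlap each other but only
below the merge threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .features import DEFAULT_CUTOFFS
from .network import ProteinNetwork

__all__ = [
    "SearchConfig",
    "PredictedComplex",
    "Scorer",
    "node_weight",
    "select_seeds",
    "grow_cluster",
    "merge_overlapping",
    "discover",
]

Scorer = Callable[[frozenset], float]
"""Maps a member set to a complex score in (0, 1) (a bound trained model)."""


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the discovery heuristic.

    ``score_threshold`` is the decision threshold for calling a grown cluster
    a complex; ``merge_overlap_threshold`` applies to the overlap rate
    |A∩B| / min(|A|, |B|); sizes bound the clusters considered (complexes
    below 4 members are too likely by chance to be meaningful).
    """

    score_threshold: float = 0.5
    merge_overlap_threshold: float = 0.8
    max_complex_size: int = 20
    min_complex_size: int = 4
    max_seeds: int = 100
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold must be in (0, 1)")
        if not 0.0 < self.merge_overlap_threshold <= 1.0:
            raise ValueError("merge_overlap_threshold must be in (0, 1]")
        if self.min_complex_size > self.max_complex_size:
            raise ValueError("min_complex_size exceeds max_complex_size")


@dataclass(frozen=True)
class PredictedComplex:
    members: frozenset[str]
    score: float
    seed: str
    iteration_found: int = 0

    def __len__(self) -> int:
        return len(self.members)


def node_weight(network: ProteinNetwork, v: str) -> float:
    """Sum of the weights of the edges incident to ``v``."""
    adj = network.adjacency()
    if v not in adj:
        raise KeyError(f"unknown node {v!r}")
    return float(sum(adj[v].values()))


def select_seeds(
    network: ProteinNetwork,
    k: int,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Top-k nodes by descending node weight, ties broken lexicographically.

    ``exclude`` drops nodes already absorbed into accepted complexes.
    """
    excl = set(exclude)
    adj = network.adjacency()
    ranked = sorted(
        (v for v in adj if v not in excl),
        key=lambda v: (-sum(adj[v].values()), v),
    )
    return ranked[:k]


def grow_cluster(
    network: ProteinNetwork,
    scorer: Scorer,
    seed: str,
    cfg: SearchConfig,
) -> Optional[PredictedComplex]:
    """Grow one candidate cluster from a seed node.

    Returns the grown cluster if it reaches the minimum size with a score at
    or above the threshold, else ``None``.  Deterministic: score ties among
    neighbors break toward the lexicographically smallest node.
    """
    adj = network.adjacency()
    if seed not in adj:
        raise KeyError(f"seed {seed!r} not in network")
    members: set[str] = {seed}
    frontier: set[str] = set(adj[seed])
    current = scorer(frozenset(members))
    while len(members) < cfg.max_complex_size and frontier:
        best_node: Optional[str] = None
        best_score = -1.0
        for v in sorted(frontier):
            sc = scorer(frozenset(members | {v}))
            if sc > best_score:
                best_node, best_score = v, sc
        assert best_node is not None
        if len(members) >= cfg.min_complex_size and best_score < current:
            break
        members.add(best_node)
        frontier.update(adj[best_node])
        frontier -= members
        current = best_score
    if len(members) >= cfg.min_complex_size and current >= cfg.score_threshold:
        return PredictedComplex(frozenset(members), current, seed)
    return None


def overlap_rate(a: frozenset, b: frozenset) -> float:
    """|A∩B| / min(|A|, |B|) — the merge criterion (not the benchmark score)."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def merge_overlapping(
    found: Sequence[PredictedComplex],
    cfg: SearchConfig,
    scorer: Scorer,
) -> list[PredictedComplex]:
    """Union any pair whose overlap rate exceeds the merge threshold.

    Processing order is deterministic (descending score, then lexicographic
    members); a merged cluster is re-scored by the model.  Unions whose
    re-scored value falls below the decision threshold are dropped at the
    end: every reported complex must score above the threshold.
    """
    pool = sorted(found, key=lambda c: (-c.score, tuple(sorted(c.members))))
    merged = True
    while merged:
        merged = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if overlap_rate(pool[i].members, pool[j].members) > cfg.merge_overlap_threshold:
                    union = pool[i].members | pool[j].members
                    new = PredictedComplex(
                        union,
                        scorer(union),
                        pool[i].seed,
                        min(pool[i].iteration_found, pool[j].iteration_found),
                    )
                    pool = [c for k, c in enumerate(pool) if k not in (i, j)]
                    pool.append(new)
                    pool.sort(key=lambda c: (-c.score, tuple(sorted(c.members))))
                    merged = True
                    break
            if merged:
                break
    return [c for c in pool if c.score >= cfg.score_threshold]


def discover(
    network: ProteinNetwork,
    scorer: Scorer,
    cfg: SearchConfig,
    iteration: int = 0,
) -> list[PredictedComplex]:
    """Full discovery pass: seeds in priority order, grow, then merge.

    Nodes already absorbed into an accepted cluster are skipped as seeds;
    rejected clusters leave their nodes available.  The pass processes at
    most ``cfg.max_seeds`` seeds.
    """
    adj = network.adjacency()
    ranked = sorted(adj, key=lambda v: (-sum(adj[v].values()), v))
    absorbed: set[str] = set()
    accepted: list[PredictedComplex] = []
    processed = 0
    for v in ranked:
        if processed >= cfg.max_seeds:
            break
        if v in absorbed:
            continue
        processed += 1
        grown = grow_cluster(network, scorer, v, cfg)
        if grown is not None:
            grown = PredictedComplex(grown.members, grown.score, grown.seed, iteration)
            accepted.append(grown)
            absorbed |= grown.members
    return merge_overlapping(accepted, cfg, scorer)
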