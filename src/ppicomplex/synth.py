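"""Seeded synthetic PPI data: scale-free background, planted complexes, sequences.

The generator emulates the statistical shape of a curated interactome well
enough to exercise the whole pipeline without any database download:

* a preferential-attachment (Barabási–Albert) background gives the
  heavy-tailed degree distribution typical of PPI networks;
* planted complexes are new node groups wired as cliques, stars, or hybrids
  (clique core plus pendant proteins) — complexes in real networks are not
  all dense — with internal edge weights drawn from a high truncated normal,
  mimicking the GO-similarity enrichment seen inside true complexes, and
  anchored to the background by 1–3 low-weight edges;
* noise edges with background-level weights are sprinkled uniformly;
* every protein gets a random amino-acid sequence; planted-complex members
  draw polar residues with elevated probability, echoing the polar
  composition of complex-forming binding interfaces.

All randomness flows from a single seed; regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .features import AMINO_ACIDS, POLAR_RESIDUES
from .network import ComplexSet, ProteinNetwork, write_complexes, write_network

__all__ = ["SynthConfig", "generate", "split_ground_truth", "write_dataset"]

_POLAR = sorted(POLAR_RESIDUES)
_NONPOLAR = sorted(set(AMINO_ACIDS) - POLAR_RESIDUES)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults describe the standard study conditions."""

    n_background_nodes: int = 1000
    attachment_edges_per_node: int = 2
    n_planted_complexes: int = 20
    complex_size_range: tuple[int, int] = (4, 12)
    complex_shapes: tuple[str, ...] = ("clique", "star", "hybrid")
    within_complex_weight: tuple[float, float] = (0.8, 0.1)   # mean, sd
    background_weight: tuple[float, float] = (0.3, 0.15)
    noise_edge_rate: float = 0.1
    sequence_length_range: tuple[int, int] = (50, 400)
    planted_polar_bias: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if not 2 <= lo <= hi:
            raise ValueError("complex_size_range must satisfy 2 <= min <= max")
        lo, hi = self.sequence_length_range
        if not 1 <= lo <= hi:
            raise ValueError("sequence_length_range must be ordered and positive")
        if not 0.0 <= self.noise_edge_rate:
            raise ValueError("noise_edge_rate must be non-negative")
        if not 0.0 <= self.planted_polar_bias <= 1.0:
            raise ValueError("planted_polar_bias must be in [0, 1]")
        unknown = set(self.complex_shapes) - {"clique", "star", "hybrid"}
        if unknown:
            raise ValueError(f"unknown complex shapes: {sorted(unknown)}")


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Draw from a normal truncated to [0, 1]."""
    if sd <= 0:
        return np.full(size, min(max(mean, 0.0), 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _shape_edges(shape: str, members: Sequence[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    """Internal wiring of one planted complex."""
    k = len(members)
    if shape == "clique":
        return [(members[i], members[j]) for i in range(k) for j in range(i + 1, k)]
    if shape == "star":
        hub = members[0]
        return [(hub, m) for m in members[1:]]
    # hybrid: clique core + pendants hanging off random core members
    core_n = max(2, math.ceil(k / 2))
    core = members[:core_n]
    edges = [(core[i], core[j]) for i in range(core_n) for j in range(i + 1, core_n)]
    for pendant in members[core_n:]:
        anchor = core[rng.integers(core_n)]
        edges.append((anchor, pendant))
    return edges


def _random_sequence(rng: np.random.Generator, length: int, polar_bias: float) -> str:
    """Uniform residues; a positive bias raises the polar-residue probability."""
    base_polar = len(_POLAR) / len(AMINO_ACIDS)
    p_polar = min(1.0, base_polar + polar_bias)
    polar_mask = rng.random(length) < p_polar
    polar_picks = rng.integers(len(_POLAR), size=length)
    nonpolar_picks = rng.integers(len(_NONPOLAR), size=length)
    return "".join(
        _POLAR[polar_picks[i]] if polar_mask[i] else _NONPOLAR[nonpolar_picks[i]]
        for i in range(length)
    )


def generate(cfg: SynthConfig) -> tuple[ProteinNetwork, ComplexSet]:
    """Build the synthetic network and its ground-truth complex memberships."""
    rng = np.random.default_rng(cfg.seed)
    sizes = rng.integers(
        cfg.complex_size_range[0], cfg.complex_size_range[1] + 1,
        size=cfg.n_planted_complexes,
    )
    n_total = cfg.n_background_nodes + int(sizes.sum())
    width = max(4, len(str(n_total)))
    names = [f"P{i:0{width}d}" for i in range(n_total)]
    bg_nodes = names[: cfg.n_background_nodes]

    # scale-free background
    bg = nx.barabasi_albert_graph(
        cfg.n_background_nodes,
        cfg.attachment_edges_per_node,
        seed=int(rng.integers(2**31)),
    )
    edges: dict[frozenset, float] = {}
    bg_edge_list = list(bg.edges())
    bg_w = _truncnorm01(rng, *cfg.background_weight, len(bg_edge_list))
    for (i, j), w in zip(bg_edge_list, bg_w):
        edges[frozenset((bg_nodes[i], bg_nodes[j]))] = float(w)

    # planted complexes: fresh nodes, internal high weights, low-weight anchors
    truth: list[tuple[str, list[str]]] = []
    cursor = cfg.n_background_nodes
    for c in range(cfg.n_planted_complexes):
        k = int(sizes[c])
        members = names[cursor: cursor + k]
        cursor += k
        shape = cfg.complex_shapes[rng.integers(len(cfg.complex_shapes))]
        internal = _shape_edges(shape, members, rng)
        w_in = _truncnorm01(rng, *cfg.within_complex_weight, len(internal))
        for (a, b), w in zip(internal, w_in):
            edges[frozenset((a, b))] = float(w)
        n_anchor = int(rng.integers(1, 4))
        anchors_from = rng.choice(len(members), size=n_anchor)
        anchors_to = rng.choice(cfg.n_background_nodes, size=n_anchor, replace=False)
        w_anchor = _truncnorm01(rng, *cfg.background_weight, n_anchor)
        for idx in range(n_anchor):
            key = frozenset((members[int(anchors_from[idx])], bg_nodes[int(anchors_to[idx])]))
            edges.setdefault(key, float(w_anchor[idx]))
        truth.append((f"complex_{c:02d}", members))

    # uniform noise edges at background weights
    n_noise = int(round(cfg.noise_edge_rate * len(edges)))
    w_noise = _truncnorm01(rng, *cfg.background_weight, n_noise)
    added = 0
    while added < n_noise:
        i, j = rng.integers(n_total, size=2)
        if i == j:
            continue
        key = frozenset((names[int(i)], names[int(j)]))
        if key in edges:
            continue
        edges[key] = float(w_noise[added])
        added += 1

    member_of_complex = {m for _, ms in truth for m in ms}
    sequences = {}
    lens = rng.integers(
        cfg.sequence_length_range[0], cfg.sequence_length_range[1] + 1, size=n_total
    )
    for idx, name in enumerate(names):
        bias = cfg.planted_polar_bias if name in member_of_complex else 0.0
        sequences[name] = _random_sequence(rng, int(lens[idx]), bias)

    net = ProteinNetwork.from_edges(
        ((tuple(sorted(e))[0], tuple(sorted(e))[1], w) for e, w in edges.items()),
        sequences=sequences,
    )
    for name in names:  # keep isolated nodes, if any
        net.graph.add_node(name)
    net._adj_cache = None
    return net, ComplexSet.from_iterable(truth)


def split_ground_truth(
    gt: ComplexSet, train_fraction: float, seed: int
) -> tuple[ComplexSet, ComplexSet]:
    """Seeded disjoint split of complexes into a training and a held-out part."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(gt) < 2:
        raise ValueError("need at least 2 complexes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gt))
    n_train = int(round(train_fraction * len(gt)))
    n_train = min(max(n_train, 1), len(gt) - 1)
    items = list(gt)
    train = ComplexSet.from_iterable(items[i] for i in order[:n_train])
    test = ComplexSet.from_iterable(items[i] for i in order[n_train:])
    return train, test


def write_dataset(
    net: ProteinNetwork, gt: ComplexSet, cfg: SynthConfig, outdir: str | Path
) -> dict[str, Path]:
    """Emit edge list, FASTA, ground-truth complexes and the config (YAML)."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "fasta": out / "sequences.fasta",
        "complexes": out / "complexes.txt",
        "config": out / "synth_config.yaml",
    }
    write_network(net, paths["edges"])
    with open(paths["fasta"], "w") as fh:
        for name in sorted(net.sequences):
            fh.write(f">{name}\n{net.sequences[name]}\n")
    write_complexes(gt, paths["complexes"])
    paths["config"].write_text(yaml.safe_dump(asdict(cfg)))
    return paths
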