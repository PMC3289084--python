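import numpy as np
import pytest

from ppicomplex import ComplexSet, ProteinNetwork, SynthConfig, generate


@pytest.fixture
def triangle_net() -> ProteinNetwork:
    """Three proteins, fully connected, with sequences."""
    return ProteinNetwork.from_edges(
        [("a", "b", 0.5), ("b", "c", 0.9), ("a", "c", 0.1)],
        sequences={"a": "AAAA", "b": "DDDD", "c": "ADAD"},
    )


@pytest.fixture
def star_net() -> ProteinNetwork:
    """A hub with three leaves plus one isolated extra node."""
    net = ProteinNetwork.from_edges(
        [("hub", "x", 0.5), ("hub", "y", 0.9), ("hub", "z", 0.4)]
    )
    net.add_node("lonely")
    return net


def random_weighted_net(rng: np.random.Generator, n_max: int = 6) -> ProteinNetwork:
    """A random connected graph on 2..n_max nodes with random weights."""
    n = int(rng.integers(2, n_max + 1))
    names = [f"n{i}" for i in range(n)]
    edges = []
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree keeps it connected
        j = int(rng.integers(i))
        a, b = names[order[i]], names[order[j]]
        edges.append((a, b, float(rng.random())))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges.append((names[i], names[j], float(rng.random())))
    seqs = {
        v: "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(5, 40))))
        for v in names
    }
    return ProteinNetwork.from_edges(edges, sequences=seqs)


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-complex network shared across tests (fast to search)."""
    cfg = SynthConfig(
        n_background_nodes=200,
        n_planted_complexes=6,
        complex_size_range=(4, 8),
        seed=11,
    )
    net, gt = generate(cfg)
    return net, gt, cfg


@pytest.fixture
def benchmark_set() -> ComplexSet:
    return ComplexSet.from_iterable(
        [
            ("c1", {"a", "b", "c", "d"}),
            ("c2", {"e", "f", "g", "h", "i"}),
            ("c3", {"x", "y", "z", "w"}),
        ]
    )
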