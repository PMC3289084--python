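"""Fixed 43-dimensional feature vectors for candidate complex subgraphs.

A candidate complex is a node subset of the PPI network; its feature vector
concatenates eight groups computed on the *induced* subgraph:

====================  =====  ==========================================
group                 width  contents
====================  =====  ==========================================
graph density             1  2|E| / (|V|(|V|-1))
degree statistics         4  mean, variance, median, max of degrees
edge weight stats         2  mean, variance of positive edge weights
topological change        7  relative edge loss between weight cutoffs
clustering coefficient    3  mean, variance, max of per-node c(v)
topological coefficient   3  mean, variance, max of per-node TC(v)
protein length            2  mean, variance of sequence lengths
amino-acid polarity      21  20 composition means + polar fraction mean
====================  =====  ==========================================

All variances are population variances (divide by n).  Topological change
uses eight ascending weight cutoffs (default 0.1 … 0.8) giving seven deltas
T_i = (|E_i| - |E_{i+1}|) / |E_i| where E_i is the induced edge set at
cutoff i; T_i is 0 when E_i is empty.  The polar residue set is the standard
hydrophilic group {R, N, D, C, Q, E, H, K, S, T, Y}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import ProteinNetwork

__all__ = [
    "Subgraph",
    "FeatureExtractor",
    "AMINO_ACIDS",
    "POLAR_RESIDUES",
    "DEFAULT_CUTOFFS",
    "FEATURE_GROUPS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "graph_density",
    "degree_stats",
    "weight_stats",
    "topological_change",
    "clustering_coeff_stats",
    "topological_coeff_stats",
    "protein_length_stats",
    "polarity_features",
    "featurize",
]

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
POLAR_RESIDUES: frozenset[str] = frozenset("RNDCQEHKSTY")
DEFAULT_CUTOFFS: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

FEATURE_GROUPS: tuple[tuple[str, int], ...] = (
    ("density", 1),
    ("degree_stats", 4),
    ("weight_stats", 2),
    ("topo_change", 7),
    ("clustering_coeff", 3),
    ("topo_coeff", 3),
    ("protein_length", 2),
    ("polarity", 21),
)
N_FEATURES: int = sum(n for _, n in FEATURE_GROUPS)  # 43

FEATURE_NAMES: tuple[str, ...] = (
    "density",
    "degree_mean", "degree_var", "degree_median", "degree_max",
    "weight_mean", "weight_var",
    *(f"topo_change_{i}" for i in range(1, 8)),
    "clustcoef_mean", "clustcoef_var", "clustcoef_max",
    "topocoef_mean", "topocoef_var", "topocoef_max",
    "length_mean", "length_var",
    *(f"comp_{aa}" for aa in AMINO_ACIDS),
    "polar_fraction",
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class Subgraph:
    """A candidate complex: a node subset indexing into a parent network.

    The induced edge set is always derived from the parent, never stored.
    """

    members: frozenset[str]
    parent: ProteinNetwork

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("subgraph must be non-empty")
        missing = self.members - self.parent.nodes
        if missing:
            raise ValueError(f"members not in network: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    def induced_edges(self) -> list[tuple[str, str, float]]:
        adj = self.parent.adjacency()
        out = []
        for v in sorted(self.members):
            nbrs = adj[v]
            for w in self.members:
                if v < w and w in nbrs:
                    out.append((v, w, nbrs[w]))
        return out


def _pop_stats(values: Sequence[float]) -> tuple[float, float]:
    """(mean, population variance); (0, 0) for an empty sequence."""
    if not len(values):
        return 0.0, 0.0
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.var())


# -- topological groups --------------------------------------------------


def graph_density(s: Subgraph) -> float:
    """Induced density 2|E|/(|V|(|V|-1)); 0 for a singleton."""
    n = len(s)
    if n < 2:
        return 0.0
    return 2.0 * len(s.induced_edges()) / (n * (n - 1))


def degree_stats(s: Subgraph) -> np.ndarray:
    """(mean, variance, median, max) of degrees within the induced subgraph."""
    deg = dict.fromkeys(sorted(s.members), 0)
    for a, b, _ in s.induced_edges():
        deg[a] += 1
        deg[b] += 1
    d = np.array(list(deg.values()), dtype=float)
    return np.array([d.mean(), d.var(), float(np.median(d)), d.max()])


def weight_stats(s: Subgraph) -> np.ndarray:
    """(mean, variance) of strictly positive induced edge weights; (0,0) if none."""
    ws = [w for _, _, w in s.induced_edges() if w > 0]
    return np.array(_pop_stats(ws))


def topological_change(
    s: Subgraph, cutoffs: Sequence[float] = DEFAULT_CUTOFFS
) -> np.ndarray:
    """Relative edge loss between successive weight cutoffs.

    The profile summarizes the shape of the weight distribution: a subgraph
    whose edges are all high-confidence barely changes as the cutoff rises.
    """
    cuts = list(cutoffs)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutoffs must be strictly ascending")
    ws = np.array([w for _, _, w in s.induced_edges()], dtype=float)
    counts = [int((ws >= c).sum()) for c in cuts]
    out = np.zeros(len(cuts) - 1)
    for i in range(len(cuts) - 1):
        if counts[i] > 0:
            out[i] = (counts[i] - counts[i + 1]) / counts[i]
    return out


def clustering_coeff_stats(s: Subgraph) -> np.ndarray:
    """(mean, variance, max) of per-node clustering coefficients.

    c(v) = (#edges among neighbors of v) / (d(v)(d(v)-1)/2); 0 when d(v) < 2.
    """
    adj = _induced_adjacency(s)
    coeffs = []
    for v, nbrs in adj.items():
        d = len(nbrs)
        if d < 2:
            coeffs.append(0.0)
            continue
        nbr_list = list(nbrs)
        links = 0
        for i, a in enumerate(nbr_list):
            a_nbrs = adj[a]
            for b in nbr_list[i + 1:]:
                if b in a_nbrs:
                    links += 1
        coeffs.append(links / (d * (d - 1) / 2))
    arr = np.asarray(coeffs)
    return np.array([arr.mean(), arr.var(), arr.max()])


def topological_coeff_stats(s: Subgraph) -> np.ndarray:
    """(mean, variance, max) of per-node topological coefficients.

    TC(v) averages J(v,w)/d(v) over every other node w that shares at least
    one neighbor with v, where J(v,w) is the shared-neighbor count plus one
    if v and w are adjacent.  It measures how much a protein shares its
    interaction partners; hubs with exclusive partners score 0.
    """
    adj = _induced_adjacency(s)
    tcs = []
    for v in sorted(s.members):
        nv = adj[v]
        d = len(nv)
        if d == 0:
            tcs.append(0.0)
            continue
        js = []
        for w in sorted(s.members):
            if w == v:
                continue
            shared = len(nv & adj[w])
            if shared == 0:
                continue
            js.append(shared + (1 if w in nv else 0))
        tcs.append(sum(js) / (len(js) * d) if js else 0.0)
    arr = np.asarray(tcs)
    return np.array([arr.mean(), arr.var(), arr.max()])


def _induced_adjacency(s: Subgraph) -> dict[str, set[str]]:
    adj_full = s.parent.adjacency()
    members = s.members
    return {v: members & set(adj_full[v]) for v in sorted(members)}


# -- biological groups ---------------------------------------------------


def protein_length_stats(s: Subgraph) -> np.ndarray:
    """(mean, variance) of member sequence lengths; missing sequence counts 0."""
    seqs = s.parent.sequences
    lengths = []
    for v in sorted(s.members):
        seq = seqs.get(v)
        if seq is None:
            warnings.warn(f"no sequence for {v!r}; length treated as 0", stacklevel=2)
            lengths.append(0)
        else:
            lengths.append(len(seq))
    return np.array(_pop_stats(lengths))


def polarity_features(s: Subgraph) -> np.ndarray:
    """Mean amino-acid composition (20 values) plus mean polar fraction.

    Complementary binding interfaces are enriched in polar residues, so the
    overall residue make-up carries a weak complex signal.  Composition is
    averaged per protein first, then over members, so a short protein counts
    as much as a long one.
    """
    comps = [_composition(s.parent, v) for v in sorted(s.members)]
    return np.mean(comps, axis=0)


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_POLAR_IDX = np.array([aa in POLAR_RESIDUES for aa in AMINO_ACIDS])


def _composition(net: ProteinNetwork, v: str) -> np.ndarray:
    """Per-protein 21-vector: residue fractions + polar fraction, cached."""
    cache = net.__dict__.setdefault("_composition_cache", {})
    vec = cache.get(v)
    if vec is None:
        seq = net.sequences.get(v, "")
        vec = np.zeros(21)
        if seq:
            counts = np.zeros(20)
            for ch in seq:
                i = _AA_INDEX.get(ch)
                if i is not None:
                    counts[i] += 1
            frac = counts / len(seq)
            vec[:20] = frac
            vec[20] = frac[_POLAR_IDX].sum()
        cache[v] = vec
    return vec


# -- the full vector -----------------------------------------------------


def featurize(s: Subgraph, cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> np.ndarray:
    """Concatenate all eight groups into the 43-vector, fixed layout order."""
    vec = np.concatenate([
        [graph_density(s)],
        degree_stats(s),
        weight_stats(s),
        topological_change(s, cutoffs),
        clustering_coeff_stats(s),
        topological_coeff_stats(s),
        protein_length_stats(s),
        polarity_features(s),
    ])
    assert vec.shape == (N_FEATURES,)
    return vec


class FeatureExtractor:
    """Fast repeated featurization of node subsets of one network.

    Semantics are identical to :func:`featurize`; this class inlines the
    induced-subgraph computation over a cached adjacency dict because the
    greedy discovery loop evaluates tens of thousands of candidates.
    """

    def __init__(
        self,
        network: ProteinNetwork,
        cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    ) -> None:
        cuts = [float(c) for c in cutoffs]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly ascending")
        self.network = network
        self.cutoffs = np.array(cuts)
        self._adj = network.adjacency()
        nodes = sorted(self._adj)
        self._node_index = {v: i for i, v in enumerate(nodes)}
        self._len_arr = np.array(
            [len(network.sequences.get(v, "")) for v in nodes], dtype=float
        )
        self._comp = np.array([_composition(network, v) for v in nodes])
        self._triu: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._eye: dict[int, np.ndarray] = {}

    def vector(self, members: Iterable[str]) -> np.ndarray:
        # canonical order: float accumulation must not depend on set
        # iteration order, or permutation invariance and cross-process
        # reproducibility break in the last bit
        mem = sorted(members)
        k = len(mem)
        pos = {v: i for i, v in enumerate(mem)}
        adj = self._adj

        # induced adjacency (B) and weights (W); a 0-weight edge is still an edge
        B = np.zeros((k, k), dtype=bool)
        W = np.zeros((k, k))
        for i, v in enumerate(mem):
            av = adj[v]
            if len(av) <= k:
                for w, wt in av.items():
                    j = pos.get(w)
                    if j is not None and j > i:
                        B[i, j] = B[j, i] = True
                        W[i, j] = W[j, i] = wt
            else:
                for w, j in pos.items():
                    if j > i:
                        wt = av.get(w)
                        if wt is not None:
                            B[i, j] = B[j, i] = True
                            W[i, j] = W[j, i] = wt

        d = B.sum(axis=1).astype(float)
        m2 = float(d.sum())  # 2|E|
        out = np.empty(N_FEATURES)
        out[0] = m2 / (k * (k - 1)) if k > 1 else 0.0
        mu_d = m2 / k
        out[1] = mu_d
        out[2] = max(float(d @ d) / k - mu_d * mu_d, 0.0)
        ds = np.sort(d)
        out[3] = ds[k // 2] if k % 2 else 0.5 * (ds[k // 2 - 1] + ds[k // 2])
        out[4] = ds[-1]

        iu = self._triu.get(k)
        if iu is None:
            iu = self._triu[k] = np.triu_indices(k, 1)
            self._eye[k] = ~np.eye(k, dtype=bool)
        ws = W[iu][B[iu]]
        pos_ws = ws[ws > 0]
        n_pos = pos_ws.size
        if n_pos:
            mu_w = float(pos_ws.sum()) / n_pos
            out[5] = mu_w
            out[6] = max(float(pos_ws @ pos_ws) / n_pos - mu_w * mu_w, 0.0)
        else:
            out[5] = out[6] = 0.0

        ws_sorted = np.sort(ws)
        counts = ws.size - np.searchsorted(ws_sorted, self.cutoffs, side="left")
        for i in range(len(self.cutoffs) - 1):
            out[7 + i] = (
                (counts[i] - counts[i + 1]) / counts[i] if counts[i] > 0 else 0.0
            )

        A = B.astype(float)
        S = A @ A                            # shared-neighbor counts
        links = (S * A).sum(axis=1) * 0.5    # edges among each node's neighbors
        cc = np.zeros(k)
        cmask = d >= 2
        if cmask.any():
            cc[cmask] = 2.0 * links[cmask] / (d[cmask] * (d[cmask] - 1.0))
        qual = (S > 0) & self._eye[k]
        j_sum = ((S + A) * qual).sum(axis=1)
        cnt = qual.sum(axis=1).astype(float)
        tc = np.zeros(k)
        tmask = (d > 0) & (cnt > 0)
        if tmask.any():
            tc[tmask] = j_sum[tmask] / (cnt[tmask] * d[tmask])
        mu = float(cc.sum()) / k
        out[14] = mu
        out[15] = max(float(cc @ cc) / k - mu * mu, 0.0)
        out[16] = cc.max()
        mu = float(tc.sum()) / k
        out[17] = mu
        out[18] = max(float(tc @ tc) / k - mu * mu, 0.0)
        out[19] = tc.max()

        idxs = [self._node_index[v] for v in mem]
        lens = self._len_arr[idxs]
        mu = float(lens.sum()) / k
        out[20] = mu
        out[21] = max(float(lens @ lens) / k - mu * mu, 0.0)
        out[22:] = self._comp[idxs].sum(axis=0)
        out[22:] /= k
        return out
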