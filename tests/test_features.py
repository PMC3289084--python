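"""Subgraph feature vector: fixed examples, layout, and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brute
from conftest import random_weighted_net
from ppicomplex import (
    DEFAULT_CUTOFFS,
    FEATURE_GROUPS,
    N_FEATURES,
    FeatureExtractor,
    ProteinNetwork,
    Subgraph,
    featurize,
)
from ppicomplex.features import (
    clustering_coeff_stats,
    degree_stats,
    graph_density,
    polarity_features,
    protein_length_stats,
    topological_change,
    topological_coeff_stats,
    weight_stats,
)


def _net(edges, sequences=None):
    return ProteinNetwork.from_edges(edges, sequences=sequences)


def _sub(net, members):
    return Subgraph(frozenset(members), net)


@pytest.fixture
def path4():
    """Path a-b-c-d: 3 edges over 4 nodes."""
    return _net([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5)])


@pytest.fixture
def star4():
    """Hub h with leaves x, y, z."""
    return _net([("h", "x", 0.5), ("h", "y", 0.5), ("h", "z", 0.5)])


class TestDensity:
    def test_triangle_is_complete(self, triangle_net):
        assert graph_density(_sub(triangle_net, "abc")) == 1.0

    def test_edgeless_subgraph(self, path4):
        assert graph_density(_sub(path4, ["a", "c"])) == 0.0

    def test_path_of_four(self, path4):
        assert graph_density(_sub(path4, "abcd")) == pytest.approx(0.5)

    def test_singleton_defined_zero(self, path4):
        assert graph_density(_sub(path4, ["a"])) == 0.0


class TestDegreeStats:
    def test_triangle(self, triangle_net):
        assert degree_stats(_sub(triangle_net, "abc")).tolist() == [2, 0, 2, 2]

    def test_star(self, star4):
        # degrees {3,1,1,1}
        assert degree_stats(_sub(star4, "hxyz")).tolist() == [1.5, 0.75, 1, 3]

    def test_single_node(self, star4):
        assert degree_stats(_sub(star4, ["x"])).tolist() == [0, 0, 0, 0]


class TestWeightStats:
    def test_equal_weights_zero_variance(self, path4):
        m, v = weight_stats(_sub(path4, "abc"))
        assert (m, v) == (0.5, 0.0)

    def test_zero_weight_edges_excluded(self):
        net = _net([("a", "b", 0.2), ("b", "c", 0.4), ("c", "d", 0.0), ("d", "a", 0.6)])
        m, v = weight_stats(_sub(net, "abcd"))
        assert m == pytest.approx(0.4)
        assert v == pytest.approx(np.var([0.2, 0.4, 0.6]))

    def test_no_edges_fallback(self, path4):
        assert weight_stats(_sub(path4, ["a", "c"])).tolist() == [0, 0]


class TestTopologicalChange:
    def test_no_loss_when_all_heavy(self):
        net = _net([("a", "b", 1.0), ("b", "c", 1.0)])
        assert topological_change(_sub(net, "abc")).tolist() == [0] * 7

    def test_half_lost_at_second_cutoff(self):
        net = _net([("a", "b", 0.15), ("b", "c", 0.95)])
        t = topological_change(_sub(net, "abc"))
        assert t[0] == pytest.approx(0.5)
        assert t[1:].tolist() == [0] * 6

    def test_empty_edge_set_convention(self, path4):
        assert topological_change(_sub(path4, ["a", "c"])).tolist() == [0] * 7

    def test_non_ascending_cutoffs_rejected(self, path4):
        with pytest.raises(ValueError):
            topological_change(_sub(path4, "abc"), cutoffs=[0.1, 0.1, 0.3])


class TestClusteringCoeff:
    def test_triangle(self, triangle_net):
        assert clustering_coeff_stats(_sub(triangle_net, "abc")).tolist() == [1, 0, 1]

    def test_star_has_no_triangles(self, star4):
        assert clustering_coeff_stats(_sub(star4, "hxyz")).tolist() == [0, 0, 0]

    def test_k4_minus_edge(self):
        net = _net([
            ("a", "b", 0.5), ("a", "c", 0.5), ("a", "d", 0.5),
            ("b", "c", 0.5), ("b", "d", 0.5),
        ])  # missing c-d: a,b keep 2 of 3 neighbor pairs, c,d keep their 1
        cs = [2 / 3, 2 / 3, 1.0, 1.0]
        got = clustering_coeff_stats(_sub(net, "abcd"))
        assert got == pytest.approx([np.mean(cs), np.var(cs), 1.0])


class TestTopologicalCoeff:
    def test_triangle(self, triangle_net):
        assert topological_coeff_stats(_sub(triangle_net, "abc")) == pytest.approx(
            [1, 0, 1]
        )

    def test_edgeless(self, path4):
        assert topological_coeff_stats(_sub(path4, ["a", "c"])).tolist() == [0, 0, 0]

    def test_star_leaves_share_hub(self, star4):
        # each leaf pairs with the other two leaves: J=1, d=1 -> TC=1; hub 0
        tcs = [0.0, 1.0, 1.0, 1.0]
        got = topological_coeff_stats(_sub(star4, "hxyz"))
        assert got == pytest.approx([np.mean(tcs), np.var(tcs), 1.0])


class TestSequenceFeatures:
    def test_equal_lengths(self):
        net = _net([("a", "b", 0.5)], sequences={"a": "M" * 100, "b": "K" * 100})
        assert protein_length_stats(_sub(net, "ab")).tolist() == [100, 0]

    def test_variance_of_two(self):
        net = _net([("a", "b", 0.5)], sequences={"a": "M" * 50, "b": "K" * 150})
        assert protein_length_stats(_sub(net, "ab")).tolist() == [100, 2500]

    def test_missing_sequence_counts_zero_with_warning(self):
        net = _net([("a", "b", 0.5)], sequences={"a": "M" * 100})
        with pytest.warns(UserWarning):
            got = protein_length_stats(_sub(net, "ab"))
        assert got.tolist() == [50, 2500]

    def test_homopolymer_compositions(self):
        net = _net([("a", "b", 0.5)], sequences={"a": "AAAA", "b": "DDDD"})
        va = polarity_features(_sub(net, ["a"]))
        assert va[0] == 1.0 and va[1:20].sum() == 0 and va[20] == 0.0
        vd = polarity_features(_sub(net, ["b"]))
        assert vd[2] == 1.0 and vd[20] == 1.0  # D is polar

    def test_average_over_proteins(self):
        net = _net([("a", "b", 0.5)], sequences={"a": "AD", "b": "DD"})
        v = polarity_features(_sub(net, "ab"))
        assert v[0] == pytest.approx(0.25)   # A
        assert v[2] == pytest.approx(0.75)   # D
        assert v[20] == pytest.approx(0.75)  # polar fraction


class TestFullVector:
    def test_length_and_group_layout(self, triangle_net):
        vec = featurize(_sub(triangle_net, "abc"))
        assert vec.shape == (43,)
        assert N_FEATURES == 43
        assert [n for _, n in FEATURE_GROUPS] == [1, 4, 2, 7, 3, 3, 2, 21]

    def test_permutation_invariance(self, small_synth):
        net, gt, _ = small_synth
        members = sorted(gt.member_sets()[0])
        ex = FeatureExtractor(net)
        v1 = ex.vector(members)
        v2 = ex.vector(members[::-1])
        assert np.array_equal(v1, v2)

    def test_isolated_node_rules(self, triangle_net):
        triangle_net.add_node("iso")
        triangle_net.sequences["iso"] = "MMMM"
        with_iso = featurize(_sub(triangle_net, ["a", "b", "c", "iso"]))
        without = featurize(_sub(triangle_net, "abc"))
        assert with_iso[5] == without[5] and with_iso[6] == without[6]  # weights
        assert with_iso[0] < without[0]  # density can only drop


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 10_000))
def test_extractor_matches_brute_force_on_random_graphs(seed):
    """Vectorized features equal direct enumeration on small random graphs."""
    rng = np.random.default_rng(seed)
    net = random_weighted_net(rng)
    nodes = sorted(net.nodes)
    k = int(rng.integers(1, len(nodes) + 1))
    members = list(rng.choice(nodes, size=k, replace=False))
    expected = brute.full_vector(net, members, DEFAULT_CUTOFFS)
    got_slow = featurize(Subgraph(frozenset(members), net))
    got_fast = FeatureExtractor(net).vector(members)
    assert got_slow == pytest.approx(expected, abs=1e-12)
    assert got_fast == pytest.approx(expected, abs=1e-12)
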