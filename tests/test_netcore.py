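"""Data model, duality transform, link classes and multidegree centralities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nldual as nd
from nldual import (
    MultilayerNetwork,
    ValidationError,
    build_supra,
    classify_edge,
    commutation_matrix,
    dual_network,
    dual_transform,
    link_class_counts,
    multidegree,
)
from conftest import random_network


# ---------------------------------------------------------------------------
# hypothesis strategy: small random multilayer/multiplex networks
# ---------------------------------------------------------------------------


@st.composite
def small_networks(draw):
    N = draw(st.integers(2, 5))
    M = draw(st.integers(1, 4))
    nature = draw(st.sampled_from(["multilayer", "multiplex"]))
    S = nd.admissible_slots(N, M, nature)
    n_edges = draw(st.integers(0, min(S, 10)))
    seed = draw(st.integers(0, 10_000))
    return random_network(N, M, n_edges, nature, seed)


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------


class TestValidation:
    def test_self_edge_rejected(self):
        with pytest.raises(ValidationError, match="self-edge"):
            MultilayerNetwork(3, 2, [((0, 0), (0, 0))])

    def test_out_of_range_duplet_rejected(self):
        with pytest.raises(ValidationError, match="out of range"):
            MultilayerNetwork(3, 2, [((0, 0), (3, 1))])

    def test_multiplex_forbids_non_replica_interlayer(self):
        with pytest.raises(ValidationError, match="non-replica"):
            MultilayerNetwork(3, 2, [((0, 0), (1, 1))], nature="multiplex")
        # replicas and intralayer edges are fine
        net = MultilayerNetwork(
            3, 2, [((0, 0), (0, 1)), ((0, 0), (1, 0))], nature="multiplex"
        )
        assert net.L == 2

    def test_duplicate_edges_collapse_to_first(self):
        net = MultilayerNetwork(3, 2, [((0, 0), (1, 0), 2.0), ((1, 0), (0, 0), 9.0)])
        assert net.L == 1
        assert net.edges[((0, 0), (1, 0))] == 2.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError, match="negative weight"):
            MultilayerNetwork(2, 1, [((0, 0), (1, 0), -1.0)])


class TestClassifyEdge:
    @pytest.mark.parametrize(
        "edge,expected",
        [
            (((1, 0), (1, 1)), "replica"),
            (((1, 0), (2, 0)), "intralayer"),
            (((1, 0), (2, 1)), "interlayer"),
        ],
    )
    def test_classes(self, edge, expected):
        assert classify_edge(edge) == expected

    def test_self_edge_errors(self):
        with pytest.raises(ValidationError):
            classify_edge(((1, 0), (1, 0)))


# ---------------------------------------------------------------------------
# supra-adjacency and duality
# ---------------------------------------------------------------------------


class TestSupra:
    def test_toy_supra_has_two_entries_per_edge(self, toy_net):
        X = build_supra(toy_net, "primal")
        assert X.matrix.shape == (6, 6)
        assert np.count_nonzero(X.matrix) == 2 * toy_net.L
        assert np.allclose(X.matrix, X.matrix.T)
        assert np.all(np.diag(X.matrix) == 0)

    def test_empty_network_gives_zero_matrix(self):
        net = MultilayerNetwork(3, 2)
        assert not build_supra(net).matrix.any()

    def test_weighted_edge_mirrors_weight(self):
        net = MultilayerNetwork(3, 2, [((0, 0), (1, 1), 2.5)])
        X = build_supra(net)
        assert X[((0, 0), (1, 1))] == 2.5
        assert X[((1, 1), (0, 0))] == 2.5

    def test_primal_is_layer_major_dual_is_node_major(self, toy_net):
        X = build_supra(toy_net, "primal")
        Y = build_supra(toy_net, "dual")
        # intralayer edge (0,I)-(1,I): primal rows a*N+i
        assert X.matrix[0, 1] == 1.0
        # same edge in node-major indexing: rows i*M+a
        assert Y.matrix[0, 2] == 1.0


class TestDualTransform:
    def test_toy_duplet_invariance(self, toy_net):
        X = build_supra(toy_net, "primal")
        Y = dual_transform(X)
        assert Y.side == "dual"
        # the same duplet pair reads identically in both representations
        for (d1, d2) in toy_net.edges:
            assert Y[(d1, d2)] == X[(d1, d2)] == toy_net.edges[(d1, d2)]
        # the stored positions differ: (1,I)-(1,II) replica sits at rows
        # (a*N+i) in the primal and (i*M+a) in the dual
        assert X.matrix[0, 3] == 1.0  # (0,0) vs (0,1) layer-major
        assert Y.matrix[0, 1] == 1.0  # same edge node-major

    def test_matches_explicit_commutation_matrix(self, toy_net):
        X = build_supra(toy_net, "primal")
        P = commutation_matrix(toy_net.N, toy_net.M).toarray()
        assert np.allclose(P.T @ X.matrix @ P, dual_transform(X).matrix)
        # P is a permutation matrix
        assert np.all(P.sum(axis=0) == 1) and np.all(P.sum(axis=1) == 1)

    def test_asymmetric_matrix_rejected(self):
        bad = nd.SupraAdjacency(np.arange(4.0).reshape(2, 2), 2, 1)
        with pytest.raises(ValidationError, match="symmetric"):
            dual_transform(bad)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(small_networks())
    def test_involution_and_invariants(self, net):
        X = build_supra(net, "primal")
        Y = dual_transform(X)
        # involution
        assert np.array_equal(dual_transform(Y).matrix, X.matrix)
        # total sum invariant
        assert Y.matrix.sum() == pytest.approx(X.matrix.sum())
        # duplet invariance on every edge
        for (d1, d2), w in net.edges.items():
            assert Y[(d1, d2)] == w

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(small_networks())
    def test_class_counts_swap_under_duality(self, net):
        before = link_class_counts(net)
        after = link_class_counts(dual_network(net))
        assert after["replica"] == before["intralayer"]
        assert after["intralayer"] == before["replica"]
        assert after["interlayer"] == before["interlayer"]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(small_networks())
    def test_dual_network_is_involutive_and_nature_preserving(self, net):
        dd = dual_network(dual_network(net))
        assert dd == net
        assert dual_network(net).nature == net.nature


# ---------------------------------------------------------------------------
# multidegree centrality
# ---------------------------------------------------------------------------


def brute_force_multidegree(net, side):
    """Oracle: full row-block sums over the explicit dense supra matrix."""
    if side == "nodewise":
        X = build_supra(net, "primal")
        return np.array(
            [X.matrix[[a * net.N + i for a in range(net.M)]].sum() for i in range(net.N)]
        )
    Y = build_supra(net, "dual")
    return np.array(
        [Y.matrix[[i * net.M + a for i in range(net.N)]].sum() for a in range(net.M)]
    )


class TestMultidegree:
    def test_toy_values_match_brute_force(self, toy_net):
        kx = multidegree(toy_net, "nodewise")
        ky = multidegree(toy_net, "layerwise")
        assert kx.values.tolist() == [3, 2, 1]
        assert ky.values.tolist() == [4, 2]
        assert np.array_equal(kx.values, brute_force_multidegree(toy_net, "nodewise"))
        assert np.array_equal(ky.values, brute_force_multidegree(toy_net, "layerwise"))
        assert kx.values.sum() == ky.values.sum() == 2 * toy_net.L

    def test_empty_network_zero_profile(self):
        net = MultilayerNetwork(4, 3)
        k = multidegree(net, "nodewise")
        assert not k.values.any()
        assert k.sigma == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(small_networks())
    def test_conservation_and_oracle_on_random_networks(self, net):
        kx = multidegree(net, "nodewise")
        ky = multidegree(net, "layerwise")
        assert kx.values.sum() == pytest.approx(2 * net.total_weight)
        assert ky.values.sum() == pytest.approx(2 * net.total_weight)
        assert np.allclose(kx.values, brute_force_multidegree(net, "nodewise"))
        assert np.allclose(ky.values, brute_force_multidegree(net, "layerwise"))

    def test_weighted_totals(self, weighted_toy_net):
        kx = multidegree(weighted_toy_net, "nodewise")
        assert kx.values.sum() == pytest.approx(2 * weighted_toy_net.total_weight)

    def test_population_sigma_convention(self):
        prof = nd.CentralityProfile([1.0, 3.0], "nodewise")
        assert prof.sigma == pytest.approx(1.0)  # /n, not /(n-1)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------


class TestEdgelistIO:
    def test_read_basic_rows(self, tmp_path):
        p = tmp_path / "net.edges"
        p.write_text("# comment\n0 0 1 0\n0 0 0 1\n1 0 2 1\n")
        net = nd.read_edgelist(p)
        assert (net.N, net.M, net.L) == (3, 2, 3)

    def test_empty_file_with_explicit_sizes(self, tmp_path):
        p = tmp_path / "empty.edges"
        p.write_text("# nothing\n")
        net = nd.read_edgelist(p, N=3, M=2)
        assert (net.N, net.M, net.L) == (3, 2, 0)

    def test_self_edge_row_rejected(self, tmp_path):
        p = tmp_path / "bad.edges"
        p.write_text("0 0 0 0\n")
        with pytest.raises(ValidationError, match="self-edge"):
            nd.read_edgelist(p)

    def test_multiplex_violation_names_the_row(self, tmp_path):
        p = tmp_path / "bad.edges"
        p.write_text("0 0 0 1\n0 0 1 1\n")
        with pytest.raises(ValidationError, match=":2"):
            nd.read_edgelist(p, nature="multiplex")

    def test_string_labels_mapped_first_seen(self, tmp_path):
        p = tmp_path / "lab.edges"
        p.write_text("alice fb bob fb\nbob tw carol tw\n")
        net = nd.read_edgelist(p)
        assert net.node_labels == ["alice", "bob", "carol"]
        assert net.layer_labels == ["fb", "tw"]
        assert ((0, 0), (1, 0)) in net

    def test_directed_duplicates_symmetrized(self, tmp_path):
        p = tmp_path / "dir.edges"
        p.write_text("0 0 1 0 2.0\n1 0 0 0 5.0\n")
        net = nd.read_edgelist(p)
        assert net.L == 1
        assert net.edges[((0, 0), (1, 0))] == 2.0  # first row wins

    def test_round_trip_identity(self, tmp_path, weighted_toy_net):
        p = tmp_path / "rt.edges"
        nd.write_edgelist(weighted_toy_net, p)
        back = nd.read_edgelist(p)
        assert back == weighted_toy_net

    def test_weights_preserved_to_full_precision(self, tmp_path):
        w = 1 / 3
        net = MultilayerNetwork(2, 1, [((0, 0), (1, 0), w)])
        p = tmp_path / "w.edges"
        nd.write_edgelist(net, p)
        assert nd.read_edgelist(p).edges[((0, 0), (1, 0))] == w

    def test_empty_network_writes_header_only(self, tmp_path):
        p = tmp_path / "e.edges"
        nd.write_edgelist(MultilayerNetwork(3, 2), p)
        lines = p.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)


class TestSupraTSV:
    def test_round_trip(self, tmp_path, weighted_toy_net):
        X = build_supra(weighted_toy_net, "primal")
        p = tmp_path / "supra.tsv"
        nd.write_supra_tsv(X, p)
        back = nd.read_supra_tsv(p)
        assert back.side == "primal"
        assert (back.N, back.M) == (3, 2)
        assert np.allclose(back.matrix, X.matrix)

    def test_network_from_supra_recovers_edges(self, weighted_toy_net):
        X = build_supra(weighted_toy_net, "primal")
        back = nd.network_from_supra(X)
        assert back == weighted_toy_net

    def test_network_from_dual_supra(self, toy_net):
        Y = dual_transform(build_supra(toy_net, "primal"))
        assert nd.network_from_supra(Y) == toy_net
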