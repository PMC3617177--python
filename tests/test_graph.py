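"""Network container, betweenness (vs a path-enumeration oracle),
comparison, impulse responses, export round-trips."""

import itertools

import networkx as nx
import numpy as np
import pytest

import mlvarnet as m
from mlvarnet.graph import NetworkGraph


def brute_force_betweenness(labels, weights):
    """Exhaustive oracle: enumerate every simple path between every ordered
    node pair, find the shortest by summed 1/|w| distance, and give each
    intermediate node equal fractional credit among tied shortest paths."""
    J = len(labels)
    nodes = range(J)
    score = np.zeros(J)
    # edge k->j exists iff weights[j,k] != 0, j != k
    dist = {}
    for j in range(J):
        for k in range(J):
            if j != k and weights[j, k] != 0:
                dist[(k, j)] = 1.0 / abs(weights[j, k])
    for s, t in itertools.permutations(nodes, 2):
        best, paths = np.inf, []
        for r in range(J - 2 + 1):
            for mid in itertools.permutations([v for v in nodes if v not in (s, t)], r):
                path = (s, *mid, t)
                try:
                    d = sum(dist[(a, b)] for a, b in zip(path, path[1:]))
                except KeyError:
                    continue
                if d < best - 1e-12:
                    best, paths = d, [path]
                elif abs(d - best) <= 1e-12:
                    paths.append(path)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def random_graph(seed, J=6):
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 0.3, (J, J))
    w[rng.random((J, J)) < 0.3] = 0.0
    return NetworkGraph([f"v{i}" for i in range(J)], w)


class TestBetweenness:
    def test_three_node_chain(self):
        w = np.zeros((3, 3))
        w[1, 0] = 1.0  # a -> b
        w[2, 1] = 1.0  # b -> c
        g = NetworkGraph(["a", "b", "c"], w)
        assert m.betweenness(g).tolist() == [0.0, 1.0, 0.0]

    def test_two_nodes_no_intermediaries(self):
        g = NetworkGraph(["a", "b"], np.array([[0.5, 0.9], [0.2, 0.5]]))
        assert (m.betweenness(g) == 0).all()

    def test_all_zero_offdiagonals_score_zero(self):
        g = NetworkGraph(["a", "b", "c"], np.eye(3) * 0.4)
        assert (m.betweenness(g) == 0).all()

    @pytest.mark.parametrize("seed", [13, 5, 99])
    def test_matches_exhaustive_path_enumeration(self, seed):
        g = random_graph(seed)
        oracle = brute_force_betweenness(g.labels, g.weights)
        np.testing.assert_allclose(m.betweenness(g).to_numpy(), oracle, atol=1e-9)

    @pytest.mark.parametrize("factor", [0.1, 3.7])
    def test_invariant_under_positive_rescaling(self, factor):
        g = random_graph(13)
        scaled = NetworkGraph(g.labels, factor * g.weights)
        np.testing.assert_allclose(
            m.betweenness(g).to_numpy(), m.betweenness(scaled).to_numpy(), atol=1e-9
        )

    def test_unit_weights_match_unweighted_algorithm(self):
        rng = np.random.default_rng(3)
        w = (rng.random((6, 6)) < 0.4).astype(float)
        np.fill_diagonal(w, 0.0)
        g = NetworkGraph([f"v{i}" for i in range(6)], w)
        expected = nx.betweenness_centrality(
            g.to_networkx(include_self_loops=False), normalized=False
        )
        got = m.betweenness(g)
        for lab in g.labels:
            assert got[lab] == pytest.approx(expected[lab])

    def test_node_permutation_permutes_scores(self):
        g = random_graph(7)
        perm = [3, 1, 5, 0, 2, 4]
        P = np.eye(6)[perm]
        gp = NetworkGraph([g.labels[i] for i in perm], P @ g.weights @ P.T)
        np.testing.assert_allclose(
            m.betweenness(gp).to_numpy(), m.betweenness(g).to_numpy()[perm], atol=1e-9
        )

    def test_mask_restriction_changes_graph(self):
        w = np.zeros((3, 3))
        w[1, 0] = 1.0
        w[2, 1] = 1.0
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 0] = True  # only a->b significant
        g = NetworkGraph(["a", "b", "c"], w, mask)
        assert m.betweenness(g, use_mask=True).sum() == 0.0
        assert m.betweenness(g, use_mask=False)["b"] == 1.0


class TestGraphContainer:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            NetworkGraph(["a", "a"], np.zeros((2, 2)))

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            NetworkGraph(["a", "b"], np.array([[0.0, np.inf], [0.0, 0.0]]))

    def test_edge_orientation(self):
        g = NetworkGraph(["a", "b"], np.array([[0.0, 0.7], [0.0, 0.0]]))
        assert g.edge("b", "a") == 0.7  # weights[0,1] is b -> a
        assert g.edge("a", "b") == 0.0


class TestCompareNetworks:
    def test_identical_networks_correlate_perfectly(self):
        g = random_graph(1)
        res = m.compare_networks(g, g)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_affine_transform_keeps_pearson_one(self):
        g = random_graph(2)
        h = NetworkGraph(g.labels, 2.0 * g.weights + 0.1)
        assert m.compare_networks(g, h).pearson_r == pytest.approx(1.0)

    def test_permuted_entries_match_formula_oracle(self):
        g = random_graph(3)
        rng = np.random.default_rng(3)
        wb = g.weights.ravel().copy()
        rng.shuffle(wb)
        h = NetworkGraph(g.labels, wb.reshape(g.weights.shape))
        res = m.compare_networks(g, h)
        a, b = g.weights.ravel(), h.weights.ravel()
        oracle = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert res.pearson_r == pytest.approx(oracle)
        assert abs(res.pearson_r) < 0.5

    def test_alignment_by_label_intersection(self):
        g = random_graph(4)
        perm = [5, 4, 3, 2, 1, 0]
        h = NetworkGraph(
            [g.labels[i] for i in perm], np.eye(6)[perm] @ g.weights @ np.eye(6)[perm].T
        )
        assert m.compare_networks(g, h).pearson_r == pytest.approx(1.0)

    def test_too_few_common_links_error(self):
        g = NetworkGraph(["a", "b"], np.zeros((2, 2)))
        h = NetworkGraph(["c", "d"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="links"):
            m.compare_networks(g, h)


class TestIrf:
    def test_zero_matrix_gives_zero_response(self):
        r = m.irf(np.zeros((3, 3)), 5)
        assert np.all(r.responses[1:] == 0)
        np.testing.assert_array_equal(r.responses[0], np.eye(3))

    def test_scalar_autoregression_closed_form(self):
        r = m.irf(0.5 * np.eye(2), 6)
        for h in range(7):
            np.testing.assert_allclose(r.responses[h], 0.5**h * np.eye(2))

    def test_stable_matrix_decays(self):
        rng = np.random.default_rng(5)
        phi = rng.normal(0, 0.15, (4, 4))
        assert np.max(np.abs(np.linalg.eigvals(phi))) < 1
        r = m.irf(phi, 50)
        assert np.abs(r.responses[50]).max() < 1e-6
        assert r.warning is None

    def test_unstable_matrix_warns(self):
        with pytest.warns(UserWarning, match="spectral radius"):
            r = m.irf(1.1 * np.eye(2), 3)
        assert r.warning is not None


class TestExport:
    def test_edgelist_has_all_ordered_pairs_including_self_loops(self, tmp_path):
        g = NetworkGraph(["a", "b"], np.array([[0.3, -0.2], [0.1, 0.4]]))
        path = m.export_graph(g, tmp_path / "g.tsv", "edgelist-tsv")
        lines = [l for l in path.read_text().splitlines() if l and not l.startswith("#")]
        assert len(lines) == 1 + 4  # header + 4 edges

    def test_edgelist_roundtrip_preserves_weights_and_mask(self, tmp_path):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(4, 4))
        pv = rng.random((4, 4))
        g = NetworkGraph(list("abcd"), w, pv < 0.3, "fixed", pv)
        path = m.export_graph(g, tmp_path / "g.tsv", metadata={"seed": 9})
        h = m.read_graph_edgelist(path)
        assert h.labels == g.labels
        np.testing.assert_array_equal(h.weights, g.weights)
        np.testing.assert_array_equal(h.mask, g.mask)
        np.testing.assert_array_equal(h.pvalues, g.pvalues)

    def test_graphml_is_wellformed_and_typed(self, tmp_path):
        g = NetworkGraph(["a", "b"], np.array([[0.3, -0.2], [0.1, 0.4]]))
        path = m.export_graph(g, tmp_path / "g.graphml", "graphml")
        back = nx.read_graphml(path)
        assert back["b"]["a"]["weight"] == pytest.approx(-0.2)
        assert isinstance(back["b"]["a"]["sign"], int)

    def test_dot_output_mentions_edges(self, tmp_path):
        g = NetworkGraph(["a", "b"], np.array([[0.0, -0.2], [0.1, 0.0]]))
        text = m.export_graph(g, tmp_path / "g.dot", "dot").read_text()
        assert '"b" -> "a"' in text and "dashed" in text

    def test_unknown_format_lists_options(self, tmp_path):
        g = NetworkGraph(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="edgelist-tsv"):
            m.export_graph(g, tmp_path / "g.x", "xml")

    def test_export_is_byte_stable(self, tmp_path):
        g = random_graph(11)
        p1 = m.export_graph(g, tmp_path / "a.tsv")
        p2 = m.export_graph(g, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()
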