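"""Classical centralities under the package's ordered-pair/raw conventions."""

import numpy as np
import pytest

from danglecent.classical import (
    betweenness_centrality,
    closeness_centrality,
    default_katz_alpha,
    degree_centrality,
    eigenvector_centrality,
    katz_centrality,
)
from danglecent.graph_io import UndirectedGraph
from danglecent.synthetic import GeneratorSpec, generate
from conftest import power_method_domain, random_graphs

ABS = 5e-5  # 4-decimal printed values
ABS_LAMBDA = 5e-4


class TestDegree:
    def test_six_node(self, six_node):
        assert [degree_centrality(six_node)[l] for l in six_node.labels] == [2, 4, 3, 4, 4, 3]

    def test_five_node(self, five_node):
        assert [degree_centrality(five_node)[l] for l in five_node.labels] == [3, 2, 2, 2, 1]

    def test_edgeless(self):
        g = UndirectedGraph(["a", "b"], [])
        assert set(degree_centrality(g).values.values()) == {0.0}


class TestCloseness:
    def test_six_node_vector(self, six_node):
        cc = closeness_centrality(six_node)
        expected = {"1": 0.1250, "2": 0.1667, "3": 0.1428, "4": 0.1667, "5": 0.1667, "6": 0.1428}
        for lab, want in expected.items():
            assert cc[lab] == pytest.approx(want, abs=1e-4)

    def test_five_node_hub(self, five_node):
        assert closeness_centrality(five_node)["0"] == pytest.approx(0.2)

    def test_single_edge(self):
        g = UndirectedGraph(["a", "b"], [("a", "b")])
        cc = closeness_centrality(g)
        assert cc["a"] == cc["b"] == 1.0

    def test_disconnected_excludes_unreachable(self):
        g = UndirectedGraph(["a", "b", "c", "x"], [("a", "b"), ("b", "c")])
        cc = closeness_centrality(g)
        assert cc["b"] == pytest.approx(0.5)  # only a and c counted
        assert cc["x"] == 0.0


class TestBetweenness:
    def test_six_node_worked_sums(self, six_node):
        bc = betweenness_centrality(six_node)
        assert bc["2"] == pytest.approx(3.6667, abs=ABS)
        assert bc["4"] == pytest.approx(1.3333, abs=ABS)
        assert bc["5"] == pytest.approx(3.6667, abs=ABS)
        assert bc["1"] == 0.0
        assert bc["3"] == pytest.approx(0.6667, abs=ABS)
        assert bc["6"] == pytest.approx(0.6667, abs=ABS)

    def test_star_center_ordered_pairs(self):
        g = generate(GeneratorSpec("star", n=4))
        assert betweenness_centrality(g)["0"] == pytest.approx(6.0)  # (n-1)(n-2)

    def test_twice_reference_brandes(self):
        import networkx as nx

        for g in random_graphs(25, n_max=15, p=0.3, seed0=40):
            ours = betweenness_centrality(g)
            ref = nx.betweenness_centrality(g.to_networkx(), normalized=False)
            for lab in g.labels:
                assert ours[lab] == pytest.approx(2 * ref[lab], abs=1e-9)


class TestEigenvector:
    def test_six_node_five_iterations(self, six_node):
        vec, lam = eigenvector_centrality(six_node, fixed_iterations=5)
        expected = [0.2615, 0.4551, 0.3789, 0.4799, 0.4551, 0.3789]
        assert [vec[l] for l in six_node.labels] == pytest.approx(expected, abs=ABS)
        assert lam == pytest.approx(3.4679, abs=ABS_LAMBDA)

    def test_single_edge(self):
        g = UndirectedGraph(["a", "b"], [("a", "b")])
        vec, lam = eigenvector_centrality(g)
        assert vec["a"] == pytest.approx(0.7071, abs=ABS)
        assert lam == pytest.approx(1.0)

    def test_triangle(self):
        g = generate(GeneratorSpec("complete", n=3))
        vec, lam = eigenvector_centrality(g)
        assert all(v == pytest.approx(0.5774, abs=ABS) for v in vec.values.values())
        assert lam == pytest.approx(2.0)

    def test_convergence_residual_and_norm(self):
        checked = 0
        for g in random_graphs(20, n_max=10, p=0.4, seed0=77):
            if not power_method_domain(g):
                continue
            checked += 1
            vec, lam = eigenvector_centrality(g)
            a = g.adjacency_matrix().astype(float)
            v = vec.as_array(g.labels)
            assert np.linalg.norm(v) == pytest.approx(1.0)
            assert np.max(np.abs(a @ v - lam * v)) < 1e-6
        assert checked >= 5

    def test_lambda_matches_numpy_eig(self, six_node):
        _, lam = eigenvector_centrality(six_node)
        ref = max(np.linalg.eigvalsh(six_node.adjacency_matrix().astype(float)))
        assert lam == pytest.approx(ref, abs=1e-8)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(UndirectedGraph(["a"], []))


class TestKatz:
    def test_six_node_table_values(self, six_node):
        kc = katz_centrality(six_node, alpha=0.2, beta=1.0)
        expected = [2.4059, 3.5146, 3.0335, 3.6192, 3.5146, 3.0335]
        assert [kc[l] for l in six_node.labels] == pytest.approx(expected, abs=ABS)

    def test_alpha_zero_gives_beta_everywhere(self, six_node):
        kc = katz_centrality(six_node, alpha=0.0, beta=1.0)
        assert set(round(v, 12) for v in kc.values.values()) == {1.0}

    def test_edgeless_any_alpha_gives_beta(self):
        g = UndirectedGraph(["a", "b"], [])
        kc = katz_centrality(g, alpha=0.5, beta=2.0)
        assert set(kc.values.values()) == {2.0}

    def test_alpha_at_or_above_inverse_lambda_rejected(self, six_node):
        with pytest.raises(ValueError, match="diverges"):
            katz_centrality(six_node, alpha=0.3)  # 1/lambda ~ 0.2884

    def test_small_alpha_orders_like_degree(self):
        # first-order expansion: katz ~ beta(1 + alpha*deg), so strict degree
        # inequalities must be preserved (degree ties may split at O(alpha^2))
        for g in random_graphs(10, n_max=10, p=0.4, seed0=300):
            if g.n_edges == 0:
                continue
            kc = katz_centrality(g, alpha=1e-6)
            dc = degree_centrality(g)
            for u in g.labels:
                for v in g.labels:
                    if dc[u] > dc[v]:
                        assert kc[u] > kc[v]

    def test_default_alpha_rule(self, six_node):
        assert default_katz_alpha(six_node) == 0.2
        k3 = generate(GeneratorSpec("complete", n=8))  # lambda = 7 > 5
        assert default_katz_alpha(k3) == pytest.approx(0.85 / 7)


class TestStructuralInvariants:
    @pytest.mark.parametrize("spec", [
        GeneratorSpec("cycle", n=6),
        GeneratorSpec("complete", n=5),
    ])
    def test_vertex_transitive_graphs_constant_metrics(self, spec):
        g = generate(spec)
        for vec in (degree_centrality(g), closeness_centrality(g),
                    betweenness_centrality(g), eigenvector_centrality(g)[0],
                    katz_centrality(g, alpha=0.1)):
            vals = [round(v, 9) for v in vec.values.values()]
            assert len(set(vals)) == 1, vec.metric

    def test_six_node_automorphism_orbits(self, six_node):
        # the swap 2<->5, 3<->6 is an automorphism; every metric must agree
        vecs = [degree_centrality(six_node), closeness_centrality(six_node),
                betweenness_centrality(six_node),
                eigenvector_centrality(six_node)[0],
                katz_centrality(six_node, alpha=0.2)]
        for vec in vecs:
            assert vec["2"] == pytest.approx(vec["5"], abs=1e-8), vec.metric
            assert vec["3"] == pytest.approx(vec["6"], abs=1e-8), vec.metric
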