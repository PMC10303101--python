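import itertools

import networkx as nx
import numpy as np
import pytest

from autocmap.autocm import (
    AutoCMModel,
    AutoCMParams,
    export_map,
    link_strengths,
    minimum_spanning_tree,
    strengths_to_distances,
    train_autocm,
)


def all_spanning_tree_costs(d: np.ndarray):
    """Brute-force oracle: total cost of every spanning tree of K_n (Prüfer)."""
    n = d.shape[0]
    if n == 2:
        yield d[0, 1]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        total = 0.0
        ptr = list(seq)
        avail = sorted(i for i in range(n) if degree[i] == 1)
        deg = degree[:]
        for x in ptr:
            leaf = min(i for i in range(n) if deg[i] == 1)
            total += d[leaf, x]
            deg[leaf] -= 1
            deg[x] -= 1
        rest = [i for i in range(n) if deg[i] == 1]
        total += d[rest[0], rest[1]]
        yield total


class TestTraining:
    def test_weight_matrix_shape(self, trained):
        model, labels = trained
        n = len(labels)
        assert model.w.shape == (n, n)
        assert model.v.shape == (n,)

    def test_deterministic_retrain(self, encoded):
        matrix, _ = encoded
        small = matrix[:30, :10]
        a = train_autocm(small, AutoCMParams())
        b = train_autocm(small, AutoCMParams())
        assert np.array_equal(a.w, b.w) and np.array_equal(a.v, b.v)

    def test_duplicated_column_binds_stronger_than_noise(self, rng):
        """Rank agreement with a co-occurrence oracle: A=B must out-link A-C."""
        a = rng.integers(0, 2, 300).astype(float)
        c = rng.integers(0, 2, 300).astype(float)
        model = train_autocm(np.column_stack([a, a, c]), AutoCMParams())
        s = link_strengths(model).strengths
        assert s[0, 1] > s[0, 2]
        assert s[0, 1] > s[1, 2]

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            train_autocm(np.array([[0.0, 1.5], [1.0, 0.0]]))

    def test_convergence_trace_decays_after_transient(self, trained):
        """Mean weight change decays monotonically once the early transient
        (the hump while the monoconnections saturate) has passed, and the
        transient itself is bounded to the first ~100 epochs."""
        model, _ = trained
        trace = np.array(model.training_trace)
        assert model.converged
        blocks = [trace[i:i + 50].mean() for i in range(0, len(trace), 50)]
        assert (np.diff(blocks) <= 0).all()
        assert trace[-1] < AutoCMParams().tolerance


class TestLinkStrengths:
    def test_bounds_and_symmetry(self, strengths):
        s = strengths.strengths
        assert s.min() >= 0.0 and s.max() <= 1.0
        assert np.array_equal(s, s.T)
        assert (np.diag(s) == 1.0).all()

    def test_scale_invariance(self, trained):
        model, _ = trained
        doubled = AutoCMModel(v=model.v, w=2.0 * model.w,
                              contraction=model.contraction,
                              epochs_run=model.epochs_run, converged=True)
        assert np.allclose(link_strengths(model).strengths,
                           link_strengths(doubled).strengths)

    def test_degenerate_all_zero_raises(self):
        model = AutoCMModel(v=np.zeros(3), w=np.zeros((3, 3)),
                            contraction=3.0, epochs_run=1, converged=True)
        with pytest.raises(ValueError, match="degenerate"):
            link_strengths(model)


class TestDistances:
    def test_endpoints(self):
        s = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert strengths_to_distances(s)[0, 1] == 0.0
        s = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert strengths_to_distances(s)[0, 1] == 1.0

    def test_order_reversal(self, strengths):
        s = strengths.strengths
        d = strengths_to_distances(strengths)
        iu = np.triu_indices_from(s, k=1)
        assert np.array_equal(np.argsort(-s[iu]), np.argsort(d[iu]))
        assert (np.diag(d) == 0).all()


class TestMST:
    def test_three_node_example(self):
        d = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.2], [0.5, 0.2, 0.0]])
        smap = minimum_spanning_tree(d, ["A", "B", "C"])
        assert {(e[0], e[1]) for e in smap.edges} == {("A", "B"), ("B", "C")}

    @pytest.mark.parametrize("n", [2, 10, 37, 60])
    def test_tree_properties(self, n, rng):
        d = rng.uniform(0.01, 1.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"N{i:02d}" for i in range(n)]
        smap = minimum_spanning_tree(d, labels)
        assert len(smap.edges) == n - 1
        g = nx.Graph([(a, b) for a, b, _, _ in smap.edges])
        assert nx.is_connected(g) and nx.is_tree(g)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n, rng):
        for _ in range(25):
            d = rng.uniform(0.0, 1.0, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            smap = minimum_spanning_tree(d, [f"N{i}" for i in range(n)])
            ours = sum(e[3] for e in smap.edges)
            best = min(all_spanning_tree_costs(d))
            assert ours == pytest.approx(best, abs=1e-12)

    def test_equal_distances_tie_broken_lexicographically(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        smap = minimum_spanning_tree(d, ["A", "B", "C", "D"])
        assert {(e[0], e[1]) for e in smap.edges} == \
            {("A", "B"), ("A", "C"), ("A", "D")}
        assert smap.central_node == "A"


class TestExport:
    def test_graphml_round_trip(self, strengths, tmp_path):
        smap = minimum_spanning_tree(strengths_to_distances(strengths),
                                     strengths.labels)
        path = export_map(smap, "graphml", str(tmp_path / "m.graphml"))
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == len(smap.nodes)
        for a, b, s, _ in smap.edges:
            assert g.has_edge(a, b)
            assert g[a][b]["strength"] == pytest.approx(s, abs=1e-6)

    def test_dot_parses_and_formats_two_decimals(self, strengths, tmp_path):
        smap = minimum_spanning_tree(strengths_to_distances(strengths),
                                     strengths.labels)
        path = export_map(smap, "dot", str(tmp_path / "m.dot"))
        text = open(path).read()
        assert text.startswith("graph")
        top = max(smap.edges, key=lambda e: e[2])
        assert f'label="{top[2]:.2f}"' in text
        # parse with networkx's DOT-independent check: balanced braces + edges
        assert text.count("--") == len(smap.edges)

    def test_unknown_format_raises(self, strengths, tmp_path):
        smap = minimum_spanning_tree(strengths_to_distances(strengths),
                                     strengths.labels)
        with pytest.raises(ValueError):
            export_map(smap, "svg", str(tmp_path / "x"))
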