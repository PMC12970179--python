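import networkx as nx
import numpy as np
import pytest

from mvmol.chem_io import parse_and_canonicalize
from mvmol.pretrain_tasks import (
    betti_of_graph,
    betti_targets,
    corrupt_edges,
    mask_graph_features,
    mlm_mask,
    _round_count,
)
from mvmol.views import GraphView, featurize_graph, tokenize_smiles


def _random_graph_view(rng: np.random.Generator, n_max: int = 20) -> GraphView:
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.5)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    edges = np.array(sorted(tuple(sorted(e)) for e in g.edges()), dtype=np.int64)
    if len(edges) == 0:
        edges = edges.reshape(0, 2)
    return GraphView(
        n_atoms=n,
        node_features=np.zeros((n, 5), dtype=np.int64),
        edges=edges,
        edge_features=np.zeros((len(edges), 5), dtype=np.int64),
    )


class TestRounding:
    @pytest.mark.parametrize(
        "rate,n,expected", [(0.15, 20, 3), (0.85, 12, 10), (0.15, 10, 1), (0.5, 3, 1), (0.0, 9, 0), (1.0, 7, 7)]
    )
    def test_nearest_integer_ties_down(self, rate, n, expected):
        assert _round_count(rate, n) == expected


class TestMlmMask:
    def test_rate_zero_empty(self):
        view = tokenize_smiles("CC(=O)Oc1ccccc1C(=O)O")
        assert mlm_mask(view, rate=0.0).n_masked == 0

    def test_rate_one_masks_all_maskable(self):
        view = tokenize_smiles("c1ccccc1CO")
        plan = mlm_mask(view, rate=1.0)
        assert plan.n_masked == len(view)

    def test_seeded_determinism(self):
        view = tokenize_smiles("CC(=O)Oc1ccccc1C(=O)O")
        assert mlm_mask(view, 0.15, seed=4).positions == mlm_mask(view, 0.15, seed=4).positions

    def test_count_follows_rounding_rule(self):
        view = tokenize_smiles("CCOC(=O)c1ccc(N)cc1")
        plan = mlm_mask(view, rate=0.15)
        assert plan.n_masked == _round_count(0.15, len(view))

    def test_reserved_tokens_never_masked(self):
        from mvmol.views import TextView, Vocabulary, PAD

        vocab = Vocabulary()
        tokens = ["C", PAD, "O", PAD]
        view = TextView(tokens=tokens, token_ids=[vocab.id_of(t) for t in tokens], vocabulary=vocab)
        plan = mlm_mask(view, rate=1.0)
        assert plan.positions == {0, 2}


class TestGraphFeatureMask:
    def test_benzene_85_percent_masks_10_of_12(self, benzene):
        view = featurize_graph(benzene)
        plan = mask_graph_features(view, rate=0.85)
        assert view.n_tokens == 12 and plan.n_masked == 10

    def test_rate_zero(self, aspirin):
        assert mask_graph_features(featurize_graph(aspirin), rate=0.0).n_masked == 0

    def test_positions_span_nodes_and_edges(self, aspirin):
        view = featurize_graph(aspirin)
        plan = mask_graph_features(view, rate=1.0)
        assert plan.positions == set(range(view.n_tokens))

    def test_same_seed_same_plan(self, aspirin):
        view = featurize_graph(aspirin)
        assert (
            mask_graph_features(view, seed=9).positions
            == mask_graph_features(view, seed=9).positions
        )


class TestEdgeCorruption:
    def test_20_edges_rate_015_corrupts_3(self, rng):
        # build a 20-edge graph
        view = None
        while view is None or view.n_edges != 20:
            view = _random_graph_view(rng)
        plan = corrupt_edges(view, rate=0.15, seed=1)
        assert len(plan.corrupted_edges) == 3
        assert int(plan.labels.sum()) == 3
        assert len(plan.labels) == 20

    def test_rate_zero_all_original(self, aspirin):
        plan = corrupt_edges(featurize_graph(aspirin), rate=0.0)
        assert plan.labels.sum() == 0 and not plan.corrupted_edges

    def test_every_corruption_differs_from_original(self, rng):
        for _ in range(30):
            view = _random_graph_view(rng)
            plan = corrupt_edges(view, rate=0.5, seed=int(rng.integers(2**31)))
            for e, new_pair in plan.replacement_endpoints.items():
                assert set(new_pair) != set(map(int, view.edges[e]))

    def test_tiny_graph_empty_plan(self):
        view = featurize_graph(parse_and_canonicalize("C"))
        plan = corrupt_edges(view, rate=1.0)
        assert not plan.corrupted_edges and len(plan.labels) == 0


class TestBettiTargets:
    def test_ring_node_example(self, benzene):
        # any benzene node's 2-hop subgraph is 5 atoms of the ring: a path,
        # but radius >= 3 closes the cycle -> (1, 1)
        targets = betti_targets(featurize_graph(benzene), radius=3)
        assert np.all(targets.values == [1, 1])

    def test_path_graph_tree(self):
        targets = betti_targets(featurize_graph(parse_and_canonicalize("CCC")), radius=2)
        assert np.all(targets.values[:, 1] == 0)
        assert np.all(targets.values[:, 0] == 1)

    def test_naphthalene_full_graph(self, naphthalene):
        view = featurize_graph(naphthalene)
        assert view.n_atoms == 10 and view.n_edges == 11
        assert betti_of_graph(view) == (1, 2)
        targets = betti_targets(view, radius=10)
        assert np.all(targets.values == [1, 2])

    def test_euler_identity_and_spanning_forest_oracle(self, rng):
        """beta1 equals the independent cycle-basis size on random graphs."""
        for _ in range(100):
            view = _random_graph_view(rng)
            g = nx.Graph()
            g.add_nodes_from(range(view.n_atoms))
            g.add_edges_from(map(tuple, view.edges))
            targets = betti_targets(view, radius=2)
            for v in range(view.n_atoms):
                nodes = set(
                    nx.single_source_shortest_path_length(g, v, cutoff=2)
                )
                sub = g.subgraph(nodes)
                b0 = nx.number_connected_components(sub)
                b1 = len(nx.cycle_basis(sub))
                assert targets.values[v, 0] == b0
                assert targets.values[v, 1] == b1
                assert (
                    targets.values[v, 1]
                    == sub.number_of_edges() - sub.number_of_nodes() + b0
                )

    def test_clipping_for_classification_labels(self, rng):
        view = _random_graph_view(rng, n_max=20)
        targets = betti_targets(view, radius=5, clip=2)
        assert targets.clipped.max() <= 2
        assert np.all(targets.values >= targets.clipped)


class TestRelabelingInvariance:
    def test_plan_sizes_invariant_under_node_relabeling(self, rng):
        view = _random_graph_view(rng)
        perm = rng.permutation(view.n_atoms)
        edges = np.sort(perm[view.edges], axis=1)
        relabeled = GraphView(
            n_atoms=view.n_atoms,
            node_features=view.node_features[np.argsort(perm)],
            edges=edges,
            edge_features=view.edge_features,
        )
        for seed in range(5):
            a = mask_graph_features(view, seed=seed)
            b = mask_graph_features(relabeled, seed=seed)
            assert a.n_masked == b.n_masked
            ca = corrupt_edges(view, seed=seed)
            cb = corrupt_edges(relabeled, seed=seed)
            assert len(ca.corrupted_edges) == len(cb.corrupted_edges)
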