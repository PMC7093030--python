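import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tcrpair import bayesnet as bn
from tcrpair import validation


def dataset(cols: dict, weights=None, alphabets=None):
    frame = pd.DataFrame({k: [str(x) for x in v] for k, v in cols.items()})
    return bn.DiscreteDataset(frame, weights, alphabets=alphabets)


class TestLearnStructure:
    def test_independent_variables_give_empty_graph(self):
        rng = np.random.default_rng(0)
        data = dataset({"a1": rng.integers(0, 4, 1000),
                        "b1": rng.integers(0, 4, 1000)})
        assert not list(bn.learn_structure(data).edges)

    def test_exact_copy_gives_single_edge(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 500)
        g = bn.learn_structure(dataset({"a1": x, "b1": x}))
        assert {frozenset(e) for e in g.edges} == {frozenset({"a1", "b1"})}

    def test_hill_climbing_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            data = validation.random_small_dataset(rng)
            hc = bn.score_network(bn.learn_structure(data), data).aic
            assert hc == pytest.approx(
                validation.exhaustive_optimum_score(data), abs=1e-9)

    def test_whitelist_blacklist_contracts(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 400)
        data = dataset({"a1": x, "a2": x, "b1": rng.integers(0, 3, 400)})
        g = bn.learn_structure(data, whitelist={("a1", "b1")},
                               blacklist={("a1", "a2"), ("a2", "a1")})
        assert g.has_edge("a1", "b1")          # kept despite no signal
        assert not g.has_edge("a1", "a2")      # blocked despite strong signal
        assert not g.has_edge("a2", "a1")

    def test_cyclic_whitelist_rejected(self):
        data = dataset({"a1": [0, 1], "b1": [0, 1]})
        with pytest.raises(ValueError, match="cyclic"):
            bn.learn_structure(data, whitelist={("a1", "b1"), ("b1", "a1")})

    def test_record_order_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 300)
        y = np.where(rng.random(300) < 0.8, x, rng.integers(0, 3, 300))
        d1 = dataset({"a1": x, "b1": y})
        perm = rng.permutation(300)
        d2 = dataset({"a1": x[perm], "b1": y[perm]})
        assert sorted(bn.learn_structure(d1).edges) == \
            sorted(bn.learn_structure(d2).edges)


class TestTwoPhase:
    def test_blacklisted_non_contact_pair_never_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, 2000)
        data = dataset({"a1": x, "b1": x})     # strong coupling, not a contact
        g = bn.two_phase_structure(data, contact_pairs=[])
        assert not any(bn.chain_of(u) != bn.chain_of(v) for u, v in g.edges)

    def test_empty_contacts_fall_back_to_intra_phase(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, 500)
        data = dataset({"a1": x, "a2": x, "b1": rng.integers(0, 3, 500)})
        g = bn.two_phase_structure(data, contact_pairs=[])
        assert {frozenset(e) for e in g.edges} == {frozenset({"a1", "a2"})}

    def test_weak_inter_edge_needs_two_phases(self):
        res = validation.two_phase_study(seed=11)
        assert res["single_phase_inter_edges"] == 0
        assert res["single_phase_intra_recovered"] == 1
        assert res["two_phase_recovered_planted"] == 1


class TestFitAndLikelihood:
    def test_laplace_smoothing_values(self):
        data = dataset({"x": ["A"] * 3 + ["B"]})
        g = nx.DiGraph()
        g.add_node("x")
        net = bn.fit_parameters(g, data, pseudocount=0.5)
        np.testing.assert_allclose(net.cpts["x"][0], [0.7, 0.3])

    def test_zero_pseudocount_indicator_rows(self):
        x = ["A", "B", "A", "B"]
        data = dataset({"p": x, "c": x})
        g = nx.DiGraph([("p", "c")])
        net = bn.fit_parameters(g, data, pseudocount=0.0)
        np.testing.assert_allclose(net.cpts["c"], np.eye(2))

    def test_single_node_log_likelihood(self):
        data = dataset({"x": ["A", "B", "C", "D"]})
        g = nx.DiGraph()
        g.add_node("x")
        net = bn.fit_parameters(g, data, pseudocount=0.0)
        assert bn.log_likelihood(net, {"x": "A"}) == pytest.approx(math.log(0.25))

    def test_independent_chains_ll_factorizes(self):
        rng = np.random.default_rng(7)
        data = dataset({"a1": rng.integers(0, 3, 200),
                        "b1": rng.integers(0, 3, 200)})
        g = nx.DiGraph()
        g.add_nodes_from(["a1", "b1"])
        net = bn.fit_parameters(g, data)
        a_net, b_net = bn.split_networks(net, data)
        rec = {"a1": "0", "b1": "2"}
        assert bn.log_likelihood(net, rec) == pytest.approx(
            bn.log_likelihood(a_net, {"a1": "0"})
            + bn.log_likelihood(b_net, {"b1": "2"}))

    def test_probabilities_normalise_over_enumerable_joint(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, 150)
        y = np.where(rng.random(150) < 0.6, x, rng.integers(0, 3, 150))
        data = dataset({"a1": x, "a2": y, "b1": rng.integers(0, 2, 150)})
        net = bn.fit_parameters(bn.learn_structure(data), data)
        total = 0.0
        for combo in itertools.product(*(net.alphabets[v] for v in net.nodes())):
            rec = dict(zip(net.nodes(), combo))
            total += math.exp(bn.log_likelihood(net, rec))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_vectorised_ll_matches_scalar(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 3, 100)
        data = dataset({"a1": x, "b1": (x + rng.integers(0, 2, 100)) % 3})
        net = bn.fit_parameters(bn.learn_structure(data), data)
        frame = data.configs
        vec = bn.log_likelihoods(net, frame)
        for i in range(len(frame)):
            assert vec[i] == pytest.approx(
                bn.log_likelihood(net, dict(frame.iloc[i])))

    def test_split_refits_to_marginal(self):
        x = ["A", "A", "B", "B"]
        y = ["C", "C", "C", "D"]
        data = dataset({"a1": x, "b1": y})
        g = nx.DiGraph([("b1", "a1")])
        net = bn.fit_parameters(g, data, pseudocount=0.0)
        a_net, _ = bn.split_networks(net, data)
        assert not list(a_net.graph.edges)
        np.testing.assert_allclose(a_net.cpts["a1"][0], [0.5, 0.5])


class TestEntropy:
    def _uniform_pair_net(self):
        data = dataset({"a1": list("0123") * 16,
                        "b1": [str((i // 4) % 4) for i in range(64)]})
        g = nx.DiGraph()
        g.add_nodes_from(["a1", "b1"])
        return bn.fit_parameters(g, data, pseudocount=0.0), data

    def test_independent_uniform_nodes(self):
        net, _ = self._uniform_pair_net()
        h, se = bn.model_entropy(net)
        assert h == pytest.approx(2 * math.log(4))
        assert se == 0.0

    def test_copied_node_adds_nothing(self):
        x = list("0123") * 25
        data = dataset({"a1": x, "a2": x})
        net = bn.fit_parameters(nx.DiGraph([("a1", "a2")]), data, pseudocount=0.0)
        h, _ = bn.model_entropy(net)
        assert h == pytest.approx(math.log(4))

    def test_single_node_entropy_is_marginal_entropy(self):
        data = dataset({"x": ["A", "A", "B", "C"]})
        g = nx.DiGraph()
        g.add_node("x")
        net = bn.fit_parameters(g, data, pseudocount=0.0)
        h, _ = bn.model_entropy(net)
        p = np.array([0.5, 0.25, 0.25])
        assert h == pytest.approx(float(-(p * np.log(p)).sum()))

    def test_monte_carlo_fallback_agrees_with_exact(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 3, 500)
        y = np.where(rng.random(500) < 0.7, x, rng.integers(0, 3, 500))
        data = dataset({"a1": x, "a2": y})
        net = bn.fit_parameters(nx.DiGraph([("a1", "a2")]), data)
        h_exact, se0 = bn.model_entropy(net)
        h_mc, se = bn.model_entropy(net, state_limit=1, mc_samples=200_000,
                                    seed=3)
        assert se0 == 0.0
        assert se > 0
        assert h_mc == pytest.approx(h_exact, abs=4 * se + 1e-3)

    def test_pairing_information_additive_for_independent_nets(self):
        net, data = self._uniform_pair_net()
        a_net, b_net = bn.split_networks(net, data)
        report = bn.pairing_information(net, a_net, b_net)
        assert report.delta == pytest.approx(0.0, abs=1e-9)


class TestScore:
    def test_aic_penalises_parameters(self):
        rng = np.random.default_rng(12)
        data = dataset({"a1": rng.integers(0, 4, 200),
                        "b1": rng.integers(0, 4, 200)})
        empty = nx.DiGraph()
        empty.add_nodes_from(["a1", "b1"])
        full = nx.DiGraph([("a1", "b1")])
        s_empty = bn.score_network(empty, data)
        s_full = bn.score_network(full, data)
        assert s_full.n_params > s_empty.n_params
        assert s_full.aic < s_empty.aic     # no signal: extra edge only costs

    def test_json_roundtrip(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 3, 100)
        data = dataset({"a1": x, "b1": x})
        net = bn.fit_parameters(bn.learn_structure(data), data)
        back = bn.BayesNet.from_json(net.to_json())
        assert sorted(back.graph.edges) == sorted(net.graph.edges)
        for v in net.nodes():
            np.testing.assert_allclose(back.cpts[v], net.cpts[v])
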