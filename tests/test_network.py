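"""Discrete Bayesian-network stage: discretization, BDeu correctness against
closed forms and a sequential Dirichlet-multinomial oracle, hill climbing,
subnetwork extraction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from longomics import network as net
from longomics import simulate_discrete_dag
from tests.conftest import toy_matrix


class TestDiscretize:
    def test_equal_width_identity_grid(self):
        m = toy_matrix(np.arange(20.0).reshape(-1, 1), columns=["v"])
        d = net.discretize(m, "equal_width", 20)
        assert d.data["v"].tolist() == list(range(20))

    def test_max_value_lands_in_last_bin(self):
        m = toy_matrix([[0.0], [1.0], [10.0]], columns=["v"])
        d = net.discretize(m, "equal_width", 4)
        assert d.data["v"].iloc[2] == 3

    def test_equal_frequency_balances_bins(self, rng):
        m = toy_matrix(rng.uniform(size=(100, 1)), columns=["v"])
        d = net.discretize(m, "equal_frequency", 20)
        counts = d.data["v"].value_counts()
        assert set(d.data["v"]) == set(range(20))
        assert counts.min() >= 4 and counts.max() <= 6

    def test_constant_variable_named(self):
        m = toy_matrix([[1.0, 1.0], [2.0, 1.0]], columns=["ok", "flatline"])
        with pytest.raises(ValueError, match="flatline"):
            net.discretize(m, "equal_width", 4)

    def test_warns_when_samples_fewer_than_intervals(self, rng):
        m = toy_matrix(rng.normal(size=(9, 1)), columns=["v"])
        with pytest.warns(UserWarning, match="intervals"):
            net.discretize(m, "equal_width", 20)


def sequential_marginal(child, parents, r, parent_arities, ess):
    """Independent oracle: Dirichlet-multinomial marginal likelihood computed
    as a running product of predictive probabilities, one sample at a time."""
    q = int(np.prod(parent_arities)) if parent_arities else 1
    a_jk = ess / (r * q)
    counts = {}
    logp = 0.0
    for row_idx in range(len(child)):
        j = tuple(int(p[row_idx]) for p in parents)
        k = int(child[row_idx])
        n_jk = counts.get((j, k), 0)
        n_j = sum(counts.get((j, kk), 0) for kk in range(r))
        logp += math.log((a_jk + n_jk) / (r * a_jk + n_j))
        counts[(j, k)] = n_jk + 1
    return logp


class TestBdeScore:
    def test_single_binary_node_closed_form(self):
        data = pd.DataFrame({"A": [0, 1]})
        dag = net.Dag(nodes=["A"])
        total, local = net.bde_score(data, dag, ess=1.0)
        assert total == pytest.approx(math.log(1 / 8), abs=1e-12)
        assert local["A"] == pytest.approx(total)

    def test_likelihood_equivalence_of_orientation(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            data = pd.DataFrame(r.integers(0, 2, size=(8, 2)), columns=["A", "B"])
            ab, _ = net.bde_score(data, net.Dag(["A", "B"], [("A", "B", 1.0)]))
            ba, _ = net.bde_score(data, net.Dag(["A", "B"], [("B", "A", 1.0)]))
            assert ab == pytest.approx(ba, abs=1e-10)

    def test_decomposability(self, rng):
        data = pd.DataFrame(rng.integers(0, 3, size=(15, 4)), columns=list("ABCD"))
        dag = net.Dag(list("ABCD"), [("A", "B", 1), ("A", "C", 1), ("B", "D", 1), ("C", "D", 1)])
        total, local = net.bde_score(data, dag)
        assert total == pytest.approx(sum(local.values()))

    def test_matches_sequential_oracle_on_all_small_count_patterns(self):
        """BDeu equals the sequential-predictive Dirichlet-multinomial
        marginal for every 3-binary-node dataset with n <= 6. The score
        depends on the data only through joint configuration counts, so
        enumerating all count vectors over the 8 cells covers all datasets."""
        dags = [
            net.Dag(list("ABC")),
            net.Dag(list("ABC"), [("A", "B", 1)]),
            net.Dag(list("ABC"), [("A", "B", 1), ("B", "C", 1)]),
            net.Dag(list("ABC"), [("A", "C", 1), ("B", "C", 1)]),
        ]
        cells = list(itertools.product((0, 1), repeat=3))
        checked = 0
        for n in range(1, 7):
            for counts in _compositions(n, 8):
                rows = []
                for cell, c in zip(cells, counts):
                    rows += [cell] * c
                data = pd.DataFrame(rows, columns=list("ABC"))
                arr = {v: data[v].to_numpy() for v in "ABC"}
                for dag in dags:
                    total, _ = net.bde_score(data, net.Dag(dag.nodes, dag.edges), ess=1.0,
                                             arities={v: 2 for v in "ABC"})
                    expected = 0.0
                    psets = dag.parent_sets()
                    for v in "ABC":
                        pars = sorted(psets[v])
                        expected += sequential_marginal(
                            arr[v], [arr[p] for p in pars], 2, [2] * len(pars), 1.0
                        )
                    assert total == pytest.approx(expected, abs=1e-9)
                    checked += 1
        assert checked > 10000

    def test_state_above_arity_rejected(self):
        ds = net.discretize(toy_matrix([[0.0], [5.0]], columns=["v"]), "equal_width", 2)
        ds.data.iloc[0, 0] = 7
        with pytest.raises(ValueError):
            net.bde_score(ds, net.Dag(["v"]))


def _compositions(n, k):
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


class TestHillClimb:
    def test_planted_edge_recovered_up_to_orientation(self):
        data, _ = simulate_discrete_dag(500, [("A", "B")], cpt_strength=0.9, seed=3)
        dag = net.hill_climb(data)
        assert dag.skeleton() == {frozenset(("A", "B"))}
        assert dag.score is not None

    def test_independent_data_stays_near_empty(self):
        data, _ = simulate_discrete_dag(500, [], nodes=list("ABC"), seed=4)
        dag = net.hill_climb(data)
        empty_score, _ = net.bde_score(data, net.Dag(list("ABC")))
        assert dag.score >= empty_score
        assert dag.score - empty_score < 0.01 * abs(empty_score)

    def test_max_parents_zero_returns_empty(self):
        data, _ = simulate_discrete_dag(100, [("A", "B")], seed=0)
        dag = net.hill_climb(data, max_parents=0)
        assert dag.edges == []

    def test_parent_bound_and_acyclicity(self):
        data, _ = simulate_discrete_dag(
            300,
            [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("B", "D")],
            cpt_strength=0.8, seed=6,
        )
        dag = net.hill_climb(data, max_parents=2)
        psets = dag.parent_sets()
        assert max(len(s) for s in psets.values()) <= 2
        # Dag construction itself validates acyclicity
        assert dag.score is not None

    def test_variable_order_invariance_of_score(self):
        data, _ = simulate_discrete_dag(300, [("A", "B"), ("B", "C")], seed=8)
        d1 = net.hill_climb(data)
        d2 = net.hill_climb(data[["C", "A", "B"]])
        assert d1.score == pytest.approx(d2.score, abs=1e-9)
        assert d1.skeleton() == d2.skeleton()

    def test_edge_weights_normalized(self):
        data, _ = simulate_discrete_dag(400, [("A", "B"), ("A", "C")], cpt_strength=0.85, seed=9)
        dag = net.hill_climb(data)
        assert dag.edges, "expected recovered edges"
        weights = [w for *_, w in dag.edges]
        assert all(0 <= w <= 1 for w in weights)
        assert max(weights) == 1.0
        for (u, v), d in dag.edge_deltas.items():
            assert d > 0


class TestExtractSubnetwork:
    def _chain(self):
        return net.Dag(
            list("ABC"), [("A", "B", 0.0005), ("B", "C", 0.5)],
            edge_deltas={("A", "B"): 0.1, ("B", "C"): 5.0},
        )

    def test_incoming_neighbors_retained(self):
        sub = net.extract_subnetwork(self._chain(), 0.001)
        assert set(sub.nodes) == {"A", "B", "C"}
        assert sub.edge_set() == {("A", "B"), ("B", "C")}  # A->B kept as the
        # edge justifying A's inclusion as incoming neighbor of B

    def test_threshold_extremes(self):
        dag = self._chain()
        assert net.extract_subnetwork(dag, 1.0).edges == []
        full = net.extract_subnetwork(dag, 0.0)
        assert full.edge_set() == dag.edge_set()

    def test_raw_delta_scale(self):
        sub = net.extract_subnetwork(self._chain(), 1.0, use="delta")
        assert sub.edge_set() == {("A", "B"), ("B", "C")}


def test_sif_and_graphml_round_trip(tmp_path):
    dag = net.Dag(list("ABC"), [("A", "B", 0.7)])
    sif = tmp_path / "g.sif"
    dag.to_sif(sif)
    lines = sif.read_text().strip().splitlines()
    assert "A\tcauses\tB" in lines and "C" in lines
    gml = tmp_path / "g.graphml"
    dag.to_graphml(gml)
    import networkx as nx

    g = nx.read_graphml(gml)
    assert set(g.edges) == {("A", "B")}
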