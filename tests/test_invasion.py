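"""Analytic survival/invasion conditions vs deterministic imitation dynamics."""

from __future__ import annotations

import itertools

import igraph as ig
import networkx as nx
import numpy as np
import pytest

from coopnet.invasion import (
    InvasionScenario,
    alpha_threshold,
    combined_condition_exact,
    cooperator_component_stable,
    defector_component_invadable,
    deterministic_dynamics_oracle,
)

B_VALUES = (1.1, 1.5, 2.0, 3.0)


def two_cliques(k=4):
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    g.add_edge(0, k)  # single bridge
    return g


def payoffs(graph, coop, b):
    """Independent payoff evaluation: 1 per cooperating neighbor for
    cooperators, b per cooperating neighbor for defectors."""
    out = {}
    for u in graph.nodes():
        n_coop = sum(1 for v in graph.neighbors(u) if v in coop)
        out[u] = n_coop if u in coop else b * n_coop
    return out


def connected_small_graphs(max_n=6):
    """All non-isomorphic connected graphs on 2..max_n nodes, by exhaustive
    enumeration of labeled edge sets with isomorphism dedup."""
    for n in range(2, max_n + 1):
        pairs = list(itertools.combinations(range(n), 2))
        seen: list[ig.Graph] = []
        for mask in range(1 << len(pairs)):
            edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
            if len(edges) < n - 1:
                continue
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            if not nx.is_connected(g):
                continue
            gi = ig.Graph(n, edges)
            if any(gi.isomorphic(h) for h in seen):
                continue
            seen.append(gi)
            yield g


SMALL_GRAPHS = list(connected_small_graphs(6))


class TestScenarioValidation:
    def test_empty_cooperator_set_rejected(self):
        with pytest.raises(ValueError):
            InvasionScenario(nx.path_graph(3), frozenset(), 1.5)

    def test_low_temptation_rejected(self):
        with pytest.raises(ValueError):
            InvasionScenario(nx.path_graph(3), frozenset({0}), 1.0)

    def test_alpha_and_degree_bookkeeping(self):
        g = two_cliques(4)
        sc = InvasionScenario(g, frozenset(range(4)), 1.5)
        assert sc.k_in(0) == 3 and sc.k_out(0) == 1
        assert sc.k_in(0) + sc.k_out(0) == g.degree(0)
        assert sc.alpha(0) == pytest.approx(3 / 4)
        assert sc.boundary_nodes() == [0]


class TestStability:
    def test_component_without_boundary_is_stable_for_any_b(self):
        g = nx.complete_graph(5)
        for b in (1.01, 5.0, 50.0):
            stable, cert = cooperator_component_stable(
                InvasionScenario(g, frozenset(g.nodes()), b)
            )
            assert stable and cert == []

    def test_two_clique_bridge_stable_at_low_temptation(self):
        # boundary cooperator has k_in = 3; its defecting neighbor touches
        # only that one cooperator, so it scores 1.5 * 1 < 3
        sc = InvasionScenario(two_cliques(4), frozenset(range(4)), 1.5)
        stable, cert = cooperator_component_stable(sc)
        assert stable and cert == []

    def test_two_clique_bridge_unstable_at_high_temptation(self):
        sc = InvasionScenario(two_cliques(4), frozenset(range(4)), 3.5)
        stable, cert = cooperator_component_stable(sc)
        assert not stable
        assert (0, 4) in cert


class TestInvadability:
    def test_all_defector_graph_not_invadable(self):
        g = nx.complete_graph(6)
        invadable, entries = defector_component_invadable(
            InvasionScenario(g, frozenset(g.nodes()), 1.5)
        )
        assert not invadable and entries == []

    def test_pendant_defector_on_clique_is_invaded(self):
        # lone defector hanging off a K6 clique: earns b * 1 = 1.5, while
        # its cooperating contact earns 5 from the clique
        g = nx.complete_graph(6)
        g.add_edge(0, 6)
        invadable, entries = defector_component_invadable(
            InvasionScenario(g, frozenset({6}), 1.5)
        )
        assert invadable
        assert (6, 0) in entries

    def test_increasing_b_only_removes_invadability(self, rng):
        for _ in range(50):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            nodes = list(g.nodes())
            size = int(rng.integers(1, len(nodes)))
            subset = frozenset(rng.choice(nodes, size=size, replace=False).tolist())
            flags = [
                defector_component_invadable(InvasionScenario(g, subset, b))[0]
                for b in (1.1, 1.8, 2.6, 4.0)
            ]
            # once invadability is lost it never comes back
            for a, b_ in zip(flags, flags[1:]):
                assert a or not b_


class TestAlphaThreshold:
    def test_strictly_increasing_in_temptation(self):
        bs = np.linspace(1.001, 5, 200)
        th = [alpha_threshold(b) for b in bs]
        assert np.all(np.diff(th) > 0)

    def test_limits(self):
        assert alpha_threshold(1 + 1e-9) == pytest.approx(0.5, abs=1e-6)
        assert alpha_threshold(1e6) == pytest.approx(1.0, abs=1e-9)
        assert 0 < alpha_threshold(1.5) < 1

    def test_rejects_non_dilemma_temptation(self):
        for b in (1.0, 0.5, -2.0):
            with pytest.raises(ValueError):
                alpha_threshold(b)


class TestDynamicsOracle:
    def test_all_cooperators_fixed_point(self):
        g = nx.petersen_graph()
        traj = deterministic_dynamics_oracle(g, set(g.nodes()), 1.5)
        assert traj[-1] == frozenset(g.nodes())

    def test_all_defectors_fixed_point(self):
        g = nx.petersen_graph()
        traj = deterministic_dynamics_oracle(g, set(), 1.5)
        assert traj[-1] == frozenset()

    def test_two_clique_cooperators_persist_at_low_b(self):
        g = two_cliques(4)
        traj = deterministic_dynamics_oracle(g, set(range(4)), 1.5)
        assert set(range(4)) <= traj[-1]


def connected_subsets(g):
    nodes = list(g.nodes())
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if nx.is_connected(g.subgraph(subset)):
                yield frozenset(subset)


class TestExhaustiveAgreement:
    """Predicates vs the deterministic dynamics on every connected graph with
    up to 6 nodes (every connected cooperator subset, four temptations),
    plus a random sample of 7- and 8-node graphs."""

    @pytest.mark.parametrize("b", B_VALUES)
    def test_worst_case_stability_implies_preservation(self, b):
        checked = 0
        for g in SMALL_GRAPHS:
            for coop in connected_subsets(g):
                if len(coop) == g.number_of_nodes():
                    continue
                sc = InvasionScenario(g, coop, b)
                worst_case = all(
                    sc.k_in(i) > b * g.degree(j)
                    for i in sc.boundary_nodes()
                    for j in g.neighbors(i)
                    if j not in coop
                )
                if not worst_case:
                    continue
                checked += 1
                traj = deterministic_dynamics_oracle(g, set(coop), b)
                assert all(coop <= state for state in traj), (g.edges(), coop, b)
        assert checked > 0 or b >= 2.0  # high b leaves few worst-case scenarios

    @pytest.mark.parametrize("b", B_VALUES)
    def test_invadability_predicate_matches_payoff_comparison(self, b):
        for g in SMALL_GRAPHS:
            for coop in connected_subsets(g):
                sc = InvasionScenario(g, coop, b)
                predicate, _ = defector_component_invadable(sc)
                pay = payoffs(g, set(g.nodes()) - coop, b)
                direct = any(
                    pay[i] < pay[j]
                    for i in coop
                    for j in g.neighbors(i)
                    if j not in coop
                )
                assert predicate == direct, (g.edges(), coop, b)

    @pytest.mark.parametrize("b", B_VALUES)
    def test_survive_and_spread_implies_combined_bound(self, b):
        """Whenever both exact per-pair conditions hold for a boundary pair,
        the chained requirement k_in > b^2 k_out + b follows, which is the
        content of the modularity threshold."""
        for g in SMALL_GRAPHS:
            for coop in connected_subsets(g):
                sc = InvasionScenario(g, coop, b)
                for i in sc.boundary_nodes():
                    k_in, k_out = sc.k_in(i), sc.k_out(i)
                    for j in g.neighbors(i):
                        if j in coop:
                            continue
                        k_j = g.degree(j)
                        if k_in > b * k_j and b * k_out < k_j - 1:
                            assert combined_condition_exact(k_in, k_out, b)
                            alpha = k_in / (k_in + k_out)
                            assert alpha > (b * b * k_out + b) / (
                                b * b * k_out + b + k_out
                            ) - 1e-12

    def test_sampled_larger_graphs_agree(self, rng):
        for trial in range(150):
            n = int(rng.integers(7, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            nodes = list(g.nodes())
            size = int(rng.integers(1, n))
            coop = frozenset(rng.choice(nodes, size=size, replace=False).tolist())
            if not nx.is_connected(g.subgraph(coop)):
                continue
            b = float(rng.choice(B_VALUES))
            sc = InvasionScenario(g, coop, b)
            worst_case = all(
                sc.k_in(i) > b * g.degree(j)
                for i in sc.boundary_nodes()
                for j in g.neighbors(i)
                if j not in coop
            )
            if worst_case and len(coop) < n:
                traj = deterministic_dynamics_oracle(g, set(coop), b)
                assert all(coop <= state for state in traj)
            predicate, _ = defector_component_invadable(sc)
            pay = payoffs(g, set(g.nodes()) - coop, b)
            direct = any(
                pay[i] < pay[j]
                for i in coop
                for j in g.neighbors(i)
                if j not in coop
            )
            assert predicate == direct
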