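"""Analytic conditions linking community structure to cooperator survival.

This module uses a deterministic simplification of the evolutionary system:
agents are pure cooperators or pure defectors, payoffs accumulate in one
shot (a cooperator earns 1 per cooperating neighbor, a defector earns
``b > 1`` per cooperating neighbor), and imitation flows from higher to
lower scores.

For a connected set of cooperators, a *boundary* node ``i`` with ``k_in``
cooperating and ``k_out`` defecting neighbors survives imitation pressure
when its score ``k_in`` beats the score ``b * k'_j`` of every defecting
neighbor ``j`` (``k'_j`` = number of cooperators adjacent to ``j``).  The
same component, seeded entirely with defectors, can be invaded by
cooperation when some boundary defector scores less than a cooperating
neighbor outside the set: ``b * k_out < k''_j``.

Chaining the worst case of the first condition (``k'_j = k_j``) with the
necessary consequence of the second (``b * k_out < k_j - 1``) gives the
combined requirement ``k_in > b**2 * k_out + b``; for ``b * k_out >> 1``
this becomes a bound on the modularity ratio ``alpha = k_in / k_i``:

    alpha > b**2 / (1 + b**2)

so the greater the temptation to defect, the more modular a component must
be for cooperation to both survive and spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "InvasionScenario",
    "cooperator_component_stable",
    "defector_component_invadable",
    "combined_condition_exact",
    "alpha_threshold",
    "deterministic_dynamics_oracle",
]


@dataclass
class InvasionScenario:
    """A graph, a node subset holding one strategy, and the temptation b."""

    graph: nx.Graph
    cooperator_set: frozenset
    b: float

    def __post_init__(self) -> None:
        self.cooperator_set = frozenset(self.cooperator_set)
        if not self.cooperator_set:
            raise ValueError("cooperator set must be non-empty")
        if not self.cooperator_set <= set(self.graph.nodes()):
            raise ValueError("cooperator set contains nodes outside the graph")
        if not self.b > 1:
            raise ValueError("temptation b must exceed 1")

    def k_in(self, node) -> int:
        """Neighbors of ``node`` inside the cooperator set."""
        return sum(1 for v in self.graph.neighbors(node) if v in self.cooperator_set)

    def k_out(self, node) -> int:
        return self.graph.degree(node) - self.k_in(node)

    def alpha(self, node) -> float:
        return self.k_in(node) / self.graph.degree(node)

    def boundary_nodes(self) -> list:
        return [u for u in self.cooperator_set if self.k_out(u) > 0]


def cooperator_component_stable(scenario: InvasionScenario) -> tuple[bool, list]:
    """Can the cooperator set resist imitation of its defecting neighbors?

    True iff every boundary cooperator ``i`` outscores every defecting
    neighbor ``j``: ``k_in(i) > b * k'_j``.  The certificate lists violating
    ``(i, j)`` pairs.
    """
    coop = scenario.cooperator_set
    violations = []
    for i in scenario.boundary_nodes():
        pay_i = scenario.k_in(i)
        for j in scenario.graph.neighbors(i):
            if j in coop:
                continue
            pay_j = scenario.b * scenario.k_in(j)
            if not pay_i > pay_j:
                violations.append((i, j))
    return (len(violations) == 0, violations)


def defector_component_invadable(scenario: InvasionScenario) -> tuple[bool, list]:
    """With the set's roles swapped to all-defectors, can cooperation enter?

    The set members are defectors, the rest of the graph cooperates.  True
    iff some boundary defector ``i`` is outscored by a cooperating neighbor
    ``j``: ``b * k_out(i) < k''_j`` where ``k''_j`` counts ``j``'s
    cooperating neighbors.  Certificates list the successful ``(i, j)``
    pairs.
    """
    defectors = scenario.cooperator_set  # roles swapped: the set defects
    cooperators = set(scenario.graph.nodes()) - defectors
    entries = []
    for i in defectors:
        k_out = sum(1 for v in scenario.graph.neighbors(i) if v in cooperators)
        if k_out == 0:
            continue
        pay_i = scenario.b * k_out
        for j in scenario.graph.neighbors(i):
            if j in defectors:
                continue
            pay_j = sum(1 for v in scenario.graph.neighbors(j) if v in cooperators)
            if pay_i < pay_j:
                entries.append((i, j))
    return (len(entries) > 0, entries)


def combined_condition_exact(k_in: int, k_out: int, b: float) -> bool:
    """Exact combined survive-and-spread requirement ``k_in > b**2 k_out + b``."""
    return k_in > b * b * k_out + b


def alpha_threshold(b: float) -> float:
    """Minimal modularity ratio alpha = k_in / k_i for survival-and-spread.

    Derived by combining the worst-case stability condition with the
    invadability requirement under the asymptotic assumption b * k_out >> 1;
    strictly increasing in b, from 1/2 at b -> 1 towards 1 as b -> inf.
    """
    if not b > 1:
        raise ValueError("temptation b must exceed 1")
    return b * b / (1.0 + b * b)


def deterministic_dynamics_oracle(
    graph: nx.Graph,
    cooperators: set,
    b: float,
    max_steps: int = 200,
) -> list[frozenset]:
    """Synchronous best-neighbor imitation to a fixed point or cycle.

    Each step every node adopts the strategy of its highest-scoring neighbor
    when that neighbor strictly beats the node's own score (ties between
    equal-scoring best neighbors only switch the node when those neighbors
    agree on a strategy).  Returns the trajectory of cooperator sets,
    ending when a configuration repeats.
    """
    state = frozenset(cooperators)
    seen = {state: 0}
    trajectory = [state]
    for _ in range(max_steps):
        coop = state
        payoff = {}
        for u in graph.nodes():
            n_coop = sum(1 for v in graph.neighbors(u) if v in coop)
            payoff[u] = n_coop if u in coop else b * n_coop
        nxt = set()
        for u in graph.nodes():
            best = max(payoff[v] for v in graph.neighbors(u))
            if best > payoff[u]:
                best_labels = {
                    (v in coop) for v in graph.neighbors(u) if payoff[v] == best
                }
                if len(best_labels) == 1:
                    if best_labels.pop():
                        nxt.add(u)
                    continue
            if u in coop:
                nxt.add(u)
        state = frozenset(nxt)
        trajectory.append(state)
        if state in seen:
            break
        seen[state] = len(trajectory) - 1
    return trajectory
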