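"""Evolutionary layer: degree-normalised pairwise-comparison imitation.

Each generation every edge of the network plays one fresh stochastic repeated
game; a node's aggregate payoff is the sum of its normalised scores against
its neighbors.  Nodes are then visited in random order, each compares itself
with one uniformly chosen neighbor and, when the neighbor scored better by
more than a small noise threshold, imitates with probability

    W(s_n -> s_o) = (Pi_n - Pi_o) / (k_max * Delta),

where ``k_max`` is the larger of the two degrees and ``Delta = T - S``.  The
degree normalisation evolves high- and low-degree nodes at the same rate.
Imitation is soft: the focal node adopts the component-wise average of its
own and the neighbor's (y, p, q), which damps strategy cycling and keeps all
components inside the unit cube.

A run converges when no more than one strategy update occurs within a
trailing window of 100 generations.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .game import PayoffMatrix, Strategy, simulate_pairs
from .netgen import GraphModel

__all__ = [
    "EvolutionConfig",
    "Population",
    "RunResult",
    "update_probability",
    "generation_step",
    "run_to_convergence",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the evolutionary process.

    ``noise_threshold`` is the payoff-difference floor below which nodes do
    not update; ``None`` means the default 0.01 * Delta of the payoff matrix
    in play.  ``g`` repeated rounds are played per edge per generation and
    each node draws its discount factor once from ``w_range``.

    ``update_tol`` defines what counts as an update for the convergence
    window: an imitation event must move some strategy component by more
    than this amount.  Payoffs stay stochastic forever, so imitation of an
    already-identical neighbor (a no-op) would otherwise keep the window
    criterion from ever being met.
    """

    window: int = 100
    max_updates_in_window: int = 1
    noise_threshold: float | None = None
    max_generations: int = 10_000
    g: int = 50
    w_range: tuple[float, float] = (0.9, 1.0)
    noise_rel: float = 0.01
    update_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_generations <= self.window:
            raise ValueError("max_generations must exceed the convergence window")
        if self.noise_threshold is not None and self.noise_threshold < 0:
            raise ValueError("noise_threshold must be >= 0")
        if self.g < 1:
            raise ValueError("g must be >= 1")

    def epsilon(self, matrix: PayoffMatrix) -> float:
        if self.noise_threshold is not None:
            return self.noise_threshold
        return self.noise_rel * matrix.delta


class Population:
    """Mutable population state bound to a fixed interaction graph."""

    def __init__(
        self,
        graph: GraphModel | nx.Graph,
        strategies: np.ndarray,
        w: np.ndarray,
    ) -> None:
        g = graph.graph if isinstance(graph, GraphModel) else graph
        self.nodes = sorted(g.nodes())
        index = {u: i for i, u in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.edge_u = np.array([index[u] for u, _ in g.edges()], dtype=np.intp)
        self.edge_v = np.array([index[v] for _, v in g.edges()], dtype=np.intp)
        self.neighbors = [
            np.array(sorted(index[v] for v in g.neighbors(u)), dtype=np.intp)
            for u in self.nodes
        ]
        self.degrees = np.array([len(nb) for nb in self.neighbors])
        if self.degrees.min() == 0:
            raise ValueError("population graph has an isolated node")
        self.strategies = np.asarray(strategies, dtype=float).copy()
        if self.strategies.shape != (self.n, 3):
            raise ValueError("strategies must have shape (n_nodes, 3)")
        self.w = np.asarray(w, dtype=float).copy()
        self.payoffs = np.zeros(self.n)

    @classmethod
    def random(
        cls,
        graph: GraphModel | nx.Graph,
        config: EvolutionConfig,
        rng: np.random.Generator,
    ) -> "Population":
        g = graph.graph if isinstance(graph, GraphModel) else graph
        n = g.number_of_nodes()
        strategies = rng.uniform(0.0, 1.0, size=(n, 3))
        w = rng.uniform(*config.w_range, size=n)
        return cls(graph, strategies, w)

    def strategy_of(self, i: int) -> Strategy:
        y, p, q = self.strategies[i]
        return Strategy(y, p, q)

    def mean_strategy(self) -> np.ndarray:
        return self.strategies.mean(axis=0)


@dataclass(frozen=True)
class RunResult:
    """Outcome of one evolutionary run on one structure."""

    structure_id: str
    T: float
    S: float
    y_bar: float
    p_bar: float
    q_bar: float
    final_strategies: np.ndarray
    convergence_generation: int
    converged: bool
    seed: int | None = None


def update_probability(
    pi_n: float, pi_o: float, k_max: int, matrix: PayoffMatrix
) -> float:
    """Imitation probability of the pairwise-comparison rule, in [0, 1]."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if matrix.delta <= 0:
        raise ValueError("payoff range Delta = T - S must be positive")
    w = max(0.0, pi_n - pi_o) / (k_max * matrix.delta)
    return min(w, 1.0)


def compute_payoffs(
    pop: Population, matrix: PayoffMatrix, g: int, rng: np.random.Generator
) -> np.ndarray:
    """Fresh stochastic aggregate payoff of every node (one game per edge)."""
    score_u, score_v = simulate_pairs(
        pop.strategies[pop.edge_u],
        pop.strategies[pop.edge_v],
        matrix,
        g,
        pop.w[pop.edge_u],
        pop.w[pop.edge_v],
        rng,
    )
    pi = np.zeros(pop.n)
    np.add.at(pi, pop.edge_u, score_u)
    np.add.at(pi, pop.edge_v, score_v)
    return pi


def generation_step(
    pop: Population,
    matrix: PayoffMatrix,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> int:
    """One generation: replay all edges, then one asynchronous update sweep.

    Payoffs are computed once, before any strategy changes; adoptions are
    applied immediately in sweep order.  Returns the number of nodes that
    updated their strategy.
    """
    pi = compute_payoffs(pop, matrix, config.g, rng)
    pop.payoffs = pi
    eps = config.epsilon(matrix)
    delta = matrix.delta
    order = rng.permutation(pop.n)
    picks = rng.random(pop.n)  # neighbor choice per node
    accept = rng.random(pop.n)
    updates = 0
    for o in order:
        nbrs = pop.neighbors[o]
        nb = nbrs[int(picks[o] * len(nbrs))]
        diff = pi[nb] - pi[o]
        if diff <= eps:
            continue
        k_max = max(pop.degrees[o], pop.degrees[nb])
        w_prob = min(diff / (k_max * delta), 1.0)
        if accept[o] < w_prob:
            new = 0.5 * (pop.strategies[o] + pop.strategies[nb])
            # imitating an (almost) identical neighbor does not change the
            # strategy; only material changes count towards convergence
            if np.max(np.abs(new - pop.strategies[o])) > config.update_tol:
                updates += 1
            pop.strategies[o] = new
    return updates


def run_to_convergence(
    graph: GraphModel | nx.Graph,
    matrix: PayoffMatrix,
    config: EvolutionConfig,
    rng: np.random.Generator | int,
    structure_id: str | None = None,
    engine: str = "auto",
    population: Population | None = None,
) -> RunResult:
    """Evolve a freshly initialised population until the window criterion.

    Every node starts from an independent uniform (y, p, q) and keeps a
    discount factor drawn once from ``config.w_range``.  The run stops when
    the trailing ``config.window`` generations contain at most
    ``config.max_updates_in_window`` updates, or is flagged unconverged at
    ``config.max_generations``.
    """
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    if structure_id is None:
        structure_id = (
            graph.structure_id if isinstance(graph, GraphModel) else "user-graph"
        )
    pop = population if population is not None else Population.random(graph, config, rng)
    if engine == "auto":
        from ._engine import NUMBA_AVAILABLE

        engine = "compiled" if NUMBA_AVAILABLE else "numpy"
    if engine == "compiled":
        from ._engine import run_compiled

        generation, converged = run_compiled(
            pop, matrix, config, int(rng.integers(2**31))
        )
    elif engine == "numpy":
        recent: deque[int] = deque(maxlen=config.window)
        generation = 0
        converged = False
        while generation < config.max_generations:
            generation += 1
            recent.append(generation_step(pop, matrix, config, rng))
            if (
                generation >= config.window
                and sum(recent) <= config.max_updates_in_window
            ):
                converged = True
                break
    else:
        raise ValueError(f"unknown engine {engine!r}")
    y_bar, p_bar, q_bar = pop.mean_strategy()
    return RunResult(
        structure_id=structure_id,
        T=matrix.T,
        S=matrix.S,
        y_bar=float(y_bar),
        p_bar=float(p_bar),
        q_bar=float(q_bar),
        final_strategies=pop.strategies.copy(),
        convergence_generation=generation,
        converged=converged,
        seed=seed,
    )
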