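"""Discounted repeated Prisoner's Dilemma between reactive stochastic strategies.

A strategy is the triple ``(y, p, q)``: the probability of cooperating on the
first move (*trust*), after an opponent's cooperation (*reciprocity*), and
after an opponent's defection (*forgiveness*).  Payoffs are the standard PD
matrix with reward R = 1 and punishment P = 0, while temptation T and sucker's
payoff S vary inside the PD quadrant 1 < T < 2, -1 < S < 0.

Repeated-game scores are discounted geometrically: round *i* contributes
``w**i`` of a first-round point.  Scores are normalised by the total discount
weight ``sum_i w**i`` so that every pairwise score lies in ``[S, T]``
regardless of the discount factor, which keeps the imitation probability of
the evolutionary layer a valid probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Strategy",
    "PayoffMatrix",
    "AgentState",
    "sample_payoffs",
    "play_repeated",
    "expected_payoff",
    "node_payoff",
]


@dataclass(frozen=True)
class Strategy:
    """Reactive stochastic strategy (trust, reciprocity, forgiveness)."""

    y: float
    p: float
    q: float

    def __post_init__(self) -> None:
        for name in ("y", "p", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"strategy component {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.y, self.p, self.q], dtype=float)


@dataclass(frozen=True)
class PayoffMatrix:
    """PD payoffs with R = 1, P = 0 and variable temptation/sucker payoffs."""

    T: float
    S: float
    R: float = 1.0
    P: float = 0.0

    def __post_init__(self) -> None:
        if not self.T > self.R > self.P > self.S:
            raise ValueError(
                f"payoffs must obey T > R > P > S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )

    @property
    def delta(self) -> float:
        """Score range T - S used to normalise imitation probabilities."""
        return self.T - self.S


@dataclass
class AgentState:
    """Per-node state: strategy, discount factor, accumulated payoff, degree."""

    strategy: Strategy
    w: float
    payoff: float = 0.0
    degree: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"discount factor w={self.w} outside (0, 1)")


def sample_payoffs(
    rng: np.random.Generator,
    t_range: tuple[float, float] = (1.0, 2.0),
    s_range: tuple[float, float] = (-1.0, 0.0),
) -> PayoffMatrix:
    """Draw (T, S) uniformly from the PD quadrant of the ST-plane."""
    return PayoffMatrix(T=rng.uniform(*t_range), S=rng.uniform(*s_range))


def _discount_norm(w: np.ndarray, g: int) -> np.ndarray:
    """Total discount weight sum_{i=0}^{g-1} w**i, stable at w == 1."""
    w = np.asarray(w, dtype=float)
    out = np.full_like(w, float(g))
    off = w != 1.0
    out[off] = (1.0 - w[off] ** g) / (1.0 - w[off])
    return out


def simulate_pairs(
    strat_a: np.ndarray,
    strat_b: np.ndarray,
    matrix: PayoffMatrix,
    g: int,
    w_a: np.ndarray,
    w_b: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Play E independent repeated games in parallel.

    ``strat_a`` / ``strat_b`` are ``(E, 3)`` arrays of (y, p, q) rows; the
    discount factors are per-pair.  Returns the pair of normalised discounted
    scores, each an ``(E,)`` array in ``[S, T]``.
    """
    if g < 1:
        raise ValueError(f"round count g={g} must be >= 1")
    strat_a = np.atleast_2d(np.asarray(strat_a, dtype=float))
    strat_b = np.atleast_2d(np.asarray(strat_b, dtype=float))
    E = strat_a.shape[0]
    w_a = np.broadcast_to(np.asarray(w_a, dtype=float), (E,))
    w_b = np.broadcast_to(np.asarray(w_b, dtype=float), (E,))

    ya, pa, qa = strat_a[:, 0], strat_a[:, 1], strat_a[:, 2]
    yb, pb, qb = strat_b[:, 0], strat_b[:, 1], strat_b[:, 2]
    T, S, R, P = matrix.T, matrix.S, matrix.R, matrix.P

    # one block of uniforms per player keeps the per-generation call count low
    ua = rng.random((g, E))
    ub = rng.random((g, E))

    act_a = ua[0] < ya
    act_b = ub[0] < yb
    score_a = np.zeros(E)
    score_b = np.zeros(E)
    wpow_a = np.ones(E)
    wpow_b = np.ones(E)
    for i in range(g):
        if i > 0:
            prob_a = np.where(act_b, pa, qa)
            prob_b = np.where(act_a, pb, qb)
            act_a = ua[i] < prob_a
            act_b = ub[i] < prob_b
        pi_a = np.where(act_a, np.where(act_b, R, S), np.where(act_b, T, P))
        pi_b = np.where(act_b, np.where(act_a, R, S), np.where(act_a, T, P))
        score_a += wpow_a * pi_a
        score_b += wpow_b * pi_b
        wpow_a *= w_a
        wpow_b *= w_b
    return score_a / _discount_norm(w_a, g), score_b / _discount_norm(w_b, g)


def play_repeated(
    a: Strategy,
    b: Strategy,
    matrix: PayoffMatrix,
    g: int,
    w_a: float,
    w_b: float,
    rng: np.random.Generator,
    n_replicates: int = 1,
) -> tuple[float, float] | tuple[np.ndarray, np.ndarray]:
    """Play the discounted repeated game between two strategies.

    With ``n_replicates == 1`` returns a pair of scalar normalised scores;
    larger values return score arrays from independent replicate games
    (useful for Monte-Carlo comparison against :func:`expected_payoff`).
    """
    sa = np.tile(a.as_array(), (n_replicates, 1))
    sb = np.tile(b.as_array(), (n_replicates, 1))
    score_a, score_b = simulate_pairs(
        sa, sb, matrix, g, np.full(n_replicates, w_a), np.full(n_replicates, w_b), rng
    )
    if n_replicates == 1:
        return float(score_a[0]), float(score_b[0])
    return score_a, score_b


def expected_payoff(
    a: Strategy,
    b: Strategy,
    matrix: PayoffMatrix,
    g: int,
    w_a: float,
    w_b: float,
) -> tuple[float, float]:
    """Exact expected normalised scores via the 4-state joint-action chain.

    The joint action of a round is one of CC, CD, DC, DD (focal player's
    action first).  Both players react only to the opponent's previous action,
    so the joint process is Markov; the initial distribution comes from the
    trust components and each transition factorises over the two players.
    """
    if g < 1:
        raise ValueError(f"round count g={g} must be >= 1")
    ya, pa, qa = a.y, a.p, a.q
    yb, pb, qb = b.y, b.p, b.q

    d = np.array(
        [ya * yb, ya * (1 - yb), (1 - ya) * yb, (1 - ya) * (1 - yb)], dtype=float
    )
    # P(a cooperates | state) depends on b's action in the state, and vice versa
    pa_next = np.array([pa, qa, pa, qa])
    pb_next = np.array([pb, pb, qb, qb])
    M = np.empty((4, 4))
    for s in range(4):
        ca, cb = pa_next[s], pb_next[s]
        M[s] = [ca * cb, ca * (1 - cb), (1 - ca) * cb, (1 - ca) * (1 - cb)]

    pi_a = np.array([matrix.R, matrix.S, matrix.T, matrix.P])
    pi_b = np.array([matrix.R, matrix.T, matrix.S, matrix.P])
    e_a = 0.0
    e_b = 0.0
    for i in range(g):
        e_a += w_a**i * float(d @ pi_a)
        e_b += w_b**i * float(d @ pi_b)
        if i < g - 1:
            d = d @ M
    norm_a = float(_discount_norm(np.array([w_a]), g)[0])
    norm_b = float(_discount_norm(np.array([w_b]), g)[0])
    return e_a / norm_a, e_b / norm_b


def node_payoff(
    strategy: Strategy,
    neighbor_strategies: list[Strategy],
    matrix: PayoffMatrix,
    g: int,
    w: float,
    neighbor_w: list[float],
    rng: np.random.Generator,
) -> float:
    """Aggregate payoff of a node: sum of its normalised repeated-game scores
    against each of its neighbors (one fresh stochastic game per neighbor)."""
    if len(neighbor_strategies) == 0:
        raise ValueError("node has no neighbors; payoff undefined")
    if len(neighbor_w) != len(neighbor_strategies):
        raise ValueError("neighbor_w and neighbor_strategies length mismatch")
    k = len(neighbor_strategies)
    sa = np.tile(strategy.as_array(), (k, 1))
    sb = np.stack([s.as_array() for s in neighbor_strategies])
    score, _ = simulate_pairs(
        sa, sb, matrix, g, np.full(k, w), np.asarray(neighbor_w, dtype=float), rng
    )
    return float(score.sum())
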