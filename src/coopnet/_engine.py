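"""Compiled inner loop for full evolutionary runs.

Semantically identical to the pure-numpy path in :mod:`coopnet.evolve`
(fresh stochastic edge games each generation, start-of-generation payoffs,
asynchronous update sweep, material-change update counting, trailing-window
convergence) but with the generation loop compiled by numba, which makes
full sweeps ~20x faster.  The two paths consume different random streams,
so they agree in distribution, not trajectory-by-trajectory; the test suite
checks both against the analytic expected-payoff oracle.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _run_compiled(
    indptr,
    indices,
    edge_u,
    edge_v,
    strategies,
    w,
    T,
    S,
    g,
    eps,
    update_tol,
    window,
    max_updates_in_window,
    max_generations,
    seed,
):
    np.random.seed(seed)
    n = strategies.shape[0]
    E = edge_u.size
    R = 1.0
    P = 0.0
    delta = T - S

    degrees = np.empty(n, dtype=np.int64)
    for i in range(n):
        degrees[i] = indptr[i + 1] - indptr[i]

    norm = np.empty(n)
    for i in range(n):
        wi = w[i]
        if wi == 1.0:
            norm[i] = g
        else:
            norm[i] = (1.0 - wi**g) / (1.0 - wi)

    payoffs = np.zeros(n)
    recent = np.zeros(window, dtype=np.int64)
    recent_sum = 0
    pos = 0
    generation = 0
    converged = False

    while generation < max_generations:
        generation += 1
        # --- play one fresh repeated game per edge ---
        for i in range(n):
            payoffs[i] = 0.0
        for e in range(E):
            u = edge_u[e]
            v = edge_v[e]
            yu = strategies[u, 0]
            pu = strategies[u, 1]
            qu = strategies[u, 2]
            yv = strategies[v, 0]
            pv = strategies[v, 1]
            qv = strategies[v, 2]
            wu = w[u]
            wv = w[v]
            act_u = np.random.random() < yu
            act_v = np.random.random() < yv
            su = 0.0
            sv = 0.0
            wpu = 1.0
            wpv = 1.0
            for _ in range(g):
                if act_u:
                    if act_v:
                        pi_u = R
                        pi_v = R
                    else:
                        pi_u = S
                        pi_v = T
                else:
                    if act_v:
                        pi_u = T
                        pi_v = S
                    else:
                        pi_u = P
                        pi_v = P
                su += wpu * pi_u
                sv += wpv * pi_v
                wpu *= wu
                wpv *= wv
                prob_u = pu if act_v else qu
                prob_v = pv if act_u else qv
                act_u = np.random.random() < prob_u
                act_v = np.random.random() < prob_v
            payoffs[u] += su / norm[u]
            payoffs[v] += sv / norm[v]

        # --- asynchronous pairwise-comparison sweep ---
        updates = 0
        order = np.random.permutation(n)
        for idx in range(n):
            o = order[idx]
            k_o = degrees[o]
            nb = indices[indptr[o] + np.int64(np.random.random() * k_o)]
            diff = payoffs[nb] - payoffs[o]
            if diff <= eps:
                continue
            k_max = k_o if k_o > degrees[nb] else degrees[nb]
            w_prob = diff / (k_max * delta)
            if w_prob > 1.0:
                w_prob = 1.0
            if np.random.random() < w_prob:
                changed = False
                for c in range(3):
                    new = 0.5 * (strategies[o, c] + strategies[nb, c])
                    if abs(new - strategies[o, c]) > update_tol:
                        changed = True
                    strategies[o, c] = new
                if changed:
                    updates += 1

        recent_sum += updates - recent[pos]
        recent[pos] = updates
        pos = (pos + 1) % window
        if generation >= window and recent_sum <= max_updates_in_window:
            converged = True
            break

    return generation, converged


def run_compiled(pop, matrix, config, seed: int):
    """Run a population to convergence in place; returns (generation, converged)."""
    n = pop.n
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i, nb in enumerate(pop.neighbors):
        indptr[i + 1] = indptr[i] + len(nb)
    indices = np.concatenate(pop.neighbors).astype(np.int64)
    generation, converged = _run_compiled(
        indptr,
        indices,
        pop.edge_u.astype(np.int64),
        pop.edge_v.astype(np.int64),
        pop.strategies,
        pop.w,
        float(matrix.T),
        float(matrix.S),
        int(config.g),
        float(config.epsilon(matrix)),
        float(config.update_tol),
        int(config.window),
        int(config.max_updates_in_window),
        int(config.max_generations),
        int(seed),
    )
    return int(generation), bool(converged)
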