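# Methods

## The model

`coopnet` simulates the evolution of cooperative behavior on a fixed
interaction network.  The model has four layers.

**Game.** Each edge of the network plays a repeated two-player Prisoner's
Dilemma.  Per round, mutual cooperation pays the reward R = 1, mutual
defection the punishment P = 0; a unilateral defector collects the
temptation T ∈ (1, 2) while the exploited cooperator collects the sucker's
payoff S ∈ (−1, 0).  Every simulation run draws a fresh (T, S) pair
uniformly from that quadrant of the ST-plane, so results aggregate over the
whole dilemma family rather than a single payoff choice.  Future rounds are
discounted: round *i* of a pairing is worth w^i of a first-round point,
with each node's discount factor w drawn once from U(0.9, 1.0) at
initialisation.  A pairing lasts g = 50 rounds.

**Strategy.**  A node's behavior is the stochastic reactive triple
(y, p, q) ∈ [0, 1]³: y is the probability of cooperating on the first move
of a pairing (*trust*), p the probability of cooperating after the
opponent's cooperation (*reciprocity*), q the probability of cooperating
after the opponent's defection (*forgiveness*).  All three components are
initialised independently from U(0, 1) for every node in every run — no
cooperative bias, and fresh starting strategies per run.

**Evolution.**  Each generation every edge replays its repeated game from
scratch (strategies are stochastic, so payoffs are re-sampled, not cached).
A node's aggregate payoff Π is the sum over its k neighbors of its
discount-normalised score (each pairwise score is divided by Σᵢ wⁱ, which
puts it in [S, T] for any w).  Nodes are then visited in a fresh random
order; each compares Π with one uniformly chosen neighbor and, if the
neighbor leads by more than a noise floor ε, imitates with the
degree-normalised pairwise-comparison probability

    W = (Π_n − Π_o) / (k_max · Δ),      Δ = T − S,

k_max being the larger of the two degrees — the normalisation that lets
high- and low-degree nodes evolve at the same rate.  Adoption is *soft*:
the updater moves to the component-wise average of its own and the model
strategy, which strongly damps strategy cycling.  Payoffs are computed once
per generation before the sweep; adoptions apply immediately in sweep
order.

**Network.**  A catalog of 21 named structures: the complete graph, four
Erdős–Rényi densities, a ring, ring lattices, eight Watts–Strogatz
rewiring levels, 2D/3D lattices, a preferential-attachment graph, and three
cubic graphs (McGee, Coxeter, and a synthetic 24-vertex girth-5 snark with
threefold symmetry standing in for Goldberg G₃ — see the limitations
section).  All graphs have 24 nodes except the 5×5 lattice (25), the
3×3×3 lattice (27) and the Coxeter graph (28).  Randomised generators are
re-drawn until connected.

## Convergence

A run stops when the trailing window of 100 generations contains at most
one strategy update, or is flagged unconverged at `max_generations`.
Because payoffs are re-sampled stochastically every generation, imitation
*events* never cease entirely: after the population homogenises, payoff
noise still triggers imitation of neighbors whose strategy is already
identical, which changes nothing.  An event therefore counts as an update
only when it moves the strategy by more than `update_tol = 1e-3` in some
component.  Without this reading the windowed criterion is unreachable on
any structure (we measured stable plateaus of ~0.5–4.5 no-op events per
generation out to 30 000 generations); with it, runs converge in roughly
2 000–10 000 generations depending on structure.

The noise floor defaults to ε = 0.01·Δ on the raw payoff difference.  Both
ε and `update_tol` are configurable on `EvolutionConfig`.

## Parameters that matter

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `g` | 50 | rounds per pairing per generation |
| `w_range` | (0.9, 1.0) | per-node discount factor; keeps a 50-round pairing meaningful (effective horizon 10–50 rounds) |
| `window` | 100 | convergence window, generations |
| `max_updates_in_window` | 1 | quiescence criterion |
| `noise_threshold` | 0.01·Δ | payoff-difference floor for imitation |
| `update_tol` | 1e-3 | minimum strategy change that counts as an update |
| `max_generations` | 10 000 | non-convergence cap (sweeps here use 30 000) |
| ER p | .10/.15/.25/.40 | sparse-to-dense ladder for the four ER entries |
| WS p | .0125–.8 | rewiring ladder (base ring degree 4) |
| BA m | 1 | preferential attachment; m = 1 gives walktrap Q ≈ 0.56, near the most modular end of the catalog |
| walktrap steps | 4 | random-walk length for community detection |

Lattices use open (non-periodic) boundaries; the 1D lattice entry is the
k = 4 ring lattice.

## Structural metrics and the PCA

Per structure we compute mean degree, transitivity (global clustering),
girth, mean shortest-path length, and Newman–Girvan modularity Q of the
walktrap partition.  Girth is undefined for acyclic graphs (the BA m = 1
graph is a tree); it is recorded as the sentinel `node_count` and flagged
`acyclic`, so the analysis keeps a monotone "longer cycles" axis instead
of dropping the structure.

The structure-vs-behavior PCA standardises eight run-level variables (the
five metrics joined to each run, plus the equilibrium means ȳ, p̄, q̄) and
eigendecomposes their correlation matrix — correlation, not covariance,
because the variables mix probabilities with unbounded graph metrics.
Biplot geometry is summarised by each variable's angle θ in the PC1–PC2
plane and cos(θ_mod − θ_var) against the modularity vector.  Eigenvector
signs are pinned by requiring modularity to load positively on PC1 and
trust non-negatively on PC2.

## The analytic invasion conditions

A deterministic simplification (pure C/D agents, one-shot accumulated
payoffs, imitation of better-scoring neighbors) yields structural
conditions for a connected cooperator set: a boundary cooperator with k_in
internal neighbors resists a defecting neighbor j iff k_in > b·k′_j, and
an all-defector set admits cooperation iff some boundary defector earns
b·k_out < k″_j against a cooperating neighbor.  Chaining the worst case
k′_j = k_j with the invadability consequence b·k_out < k_j − 1 gives
k_in > b²·k_out + b, i.e. for b·k_out ≫ 1 a modularity-ratio threshold
α = k_in/k_i > b²/(1 + b²) — increasing in the temptation b, 1/2 at b → 1,
approaching 1 as b → ∞.

Verification is dual-route: the invadability predicate is checked against
an independent payoff evaluation, and worst-case stability against
trajectory preservation under a synchronous best-neighbor imitation
oracle, exhaustively on every connected graph with ≤ 6 nodes (every
connected cooperator subset, four temptation values) plus random 7–8-node
graphs.  Exhausting all 8-node graphs would need an isomorph-free
generator; the sampled check covers that range instead.  Note the
asymptotic regime b·k_out ≥ 5 together with α above threshold forces a
degree above 10, so no graph small enough for the exhaustive oracle can
exercise the asymptotic form directly; the exact chained bound is what the
small-graph suite verifies.

## Scaled-down sweeps

The collect-until-stable protocol (append batches of fresh runs until the
cumulative per-structure means of ȳ, p̄, q̄ move less than
`stability_tolerance = 0.005`, first batch compared against zero) is
faithful to the original design, but the package's default problem sizes
are deliberately desk-scale: the bundled acceptance computation uses 12
runs per structure across the full catalog plus 20 extra runs on each of
the three structures entering forgiveness ratios, with
`max_generations = 30 000`.
Directional claims (all three components rise with modularity; forgiveness
rises fastest; PCA dominated by a modularity-aligned PC1) are stable at
this scale; point estimates of ratios carry Monte-Carlo error of order
±20–30% and should be read accordingly.

## What the generator does and does not emulate

All inputs are synthetic by design (the system is a simulation study; there
is no external data).  The catalog reproduces the named structure *types*
and node counts; the exact random instances of ER/WS/BA graphs are
seed-dependent, so their metric values (and hence PCA loadings) vary
slightly between structure seeds.  Passing tests demonstrate internal
consistency of the engine, analytics and analytic conditions, and
reproduction of the qualitative structure-behavior relationships at
reduced scale — not bit-level reproduction of any particular large-scale
sweep.

## Numerical choices

- Discount normalisation uses the closed form (1 − w^g)/(1 − w) with the
  w = 1 limit handled explicitly.
- Payoff ties (Π_n = Π_o) never trigger imitation; the noise floor makes
  the comparison strict.
- The compiled (numba) engine and the pure-numpy reference implement the
  same process with different random streams; they are checked against the
  same analytic oracle and against each other in distribution.
- Walktrap on the complete graph returns the single-community partition
  (Q = 0 exactly); two K₅ cliques joined by an edge reproduce the
  hand-computed Q = 2(10/21 − 1/4).
- Non-converged runs are excluded from equilibrium statistics but kept in
  the run table, flagged `converged = False`.

## Known limitations

- The deterministic invasion analysis is for pure strategies only; it is
  not a limit theorem for the stochastic (y, p, q) dynamics.
- Forgiveness ratios at desk scale are noisy for heterogeneous graphs
  (the BA hubs freeze early, so run-to-run variance is large).
- The snark catalog entry is a *synthetic stand-in*: the published
  Goldberg G₃ edge list is not obtainable offline, so the entry ships a
  24-vertex cubic girth-5 snark with a free threefold symmetry and
  |Aut| = 12 found by exhaustive search (`data/snark24_synthetic.edgelist`).
  It matches G₃ in order, degree, girth, chromatic index and symmetry
  order but is not verified isomorphic to it; its structural metrics are
  computed from the shipped edge list, so downstream analyses are
  self-consistent either way.
- No coevolution of topology: networks are static throughout a run.
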