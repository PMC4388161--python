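# coopnet

Evolution of **trust, reciprocity and forgiveness** in repeated games on
networks.

Cooperation is not a single behavior.  A stochastic reactive strategy
(y, p, q) decomposes it into three probabilities: cooperating on a first
encounter (*trust* y), returning cooperation (*reciprocity* p), and
cooperating after being defected against (*forgiveness* q).  `coopnet`
places such agents on the nodes of a network, lets every edge play a
discounted 50-round Prisoner's Dilemma each generation (payoffs R = 1,
P = 0, T ~ U(1, 2), S ~ U(−1, 0)), and evolves strategies with the
degree-normalised pairwise-comparison rule

    W(s_n → s_o) = (Π_n − Π_o) / (k_max · Δ),    Δ = T − S,

where imitators adopt the *average* of their own and the model strategy.
Runs converge when at most one material strategy update occurs in a
trailing 100-generation window.

The package is for researchers in evolutionary game theory and network
science who want to ask: *which structural property of the interaction
network — degree, transitivity, girth, path length, or community structure
(modularity Q) — controls the emergence of each cooperative component?*
It bundles:

- `coopnet.netgen` — a catalog of 21 named structures (complete graph, ER
  densities, Watts–Strogatz ladder, lattices, ring, preferential
  attachment, McGee / Coxeter cubic graphs and a synthetic girth-5 snark
  stand-in) and the five
  structural metrics, with modularity Q computed on walktrap partitions;
- `coopnet.game` — the stochastic engine plus an exact Markov-chain oracle
  for expected payoffs;
- `coopnet.evolve` — the evolutionary layer (pure-numpy reference and a
  numba-compiled fast path);
- `coopnet.experiments` — multi-structure sweeps with a
  collect-until-stable protocol, tidy CSV + JSON manifest output;
- `coopnet.analysis` — ST-plane cooperation maps, the structure-vs-behavior
  PCA/biplot, dispersion (σ/μ), strategy diversity, convergence summaries;
- `coopnet.invasion` — analytic conditions under which a cooperator
  community survives and spreads, including the modularity threshold
  α > b²/(1 + b²), verified against a deterministic imitation oracle.

## A worked example

```python
import numpy as np
from coopnet import (
    EvolutionConfig, PayoffMatrix, build_structure, compute_metrics,
    run_to_convergence,
)

lattice = build_structure("15-Lattice2D")      # 5x5 square lattice
full = build_structure("1-Full")               # well-mixed baseline
print(compute_metrics(lattice).modularity_q)   # walktrap Q
print(compute_metrics(full).modularity_q)

cfg = EvolutionConfig(max_generations=30_000)
m = PayoffMatrix(T=1.5, S=-0.5)
for g in (full, lattice):
    qs = [run_to_convergence(g, m, cfg, seed).q_bar for seed in (1, 2, 3)]
    print(g.structure_id, np.round(np.mean(qs), 2))
```

prints

```
0.4740625
0.0
1-Full 0.23
15-Lattice2D 0.53
```

— on the modular lattice the population retains more than twice the
forgiveness of the well-mixed population under identical payoffs: community
boundaries shield forgiving strategies from exploitation.  Sweeping all
structures with random (T, S) per run (`coopnet sweep`) and analysing the
results (`coopnet analyze --pca`) reproduces the package's headline
pattern: equilibrium forgiveness rises fastest with modularity, followed by
reciprocity and trust, while transitivity and degree oppose cooperation.

The same conclusion follows analytically for pure strategies:

```python
from coopnet import alpha_threshold
alpha_threshold(1.5)   # 0.692...: a cooperator cluster facing temptation
                       # b = 1.5 needs >= 69% of its links inside the module
```

## Command line

```sh
coopnet graphs --list            # catalog ids
coopnet graphs --metrics         # metric table for all 21 structures
coopnet run --structure 14-BA --runs 10 --seed 1 --out runs.csv
coopnet sweep --structures 1-Full,15-Lattice2D,14-BA --runs-per-batch 20 \
              --seed 7 --out sweep.csv
coopnet analyze --in sweep.csv --pca --stgrid --dispersion
coopnet invade --graph g.edgelist --coop coop.txt --b 1.5
```

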