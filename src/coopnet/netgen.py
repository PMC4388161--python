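"""Catalog of the 21 interaction structures and their structural metrics.

Structures are 24-node graphs unless geometry dictates otherwise (the 5x5
square lattice has 25 nodes, the 3x3x3 cubic lattice 27, the Coxeter graph
28).  Randomised generators (Erdos-Renyi, Watts-Strogatz, Barabasi-Albert)
are re-drawn until connected so that every catalog graph supports a single
evolving population.

Five structural metrics drive the downstream multivariate analysis: mean
degree, transitivity (global clustering), girth, mean shortest-path length
and Newman-Girvan modularity Q of the partition found by the walktrap
random-walk community algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np

__all__ = [
    "GraphModel",
    "GraphMetrics",
    "CatalogError",
    "GenerationError",
    "GraphParseError",
    "catalog_ids",
    "build_structure",
    "compute_metrics",
    "read_graph",
    "write_graph",
]

MAX_ATTEMPTS = 500

# Erdos-Renyi edge probabilities for the four ER catalog entries (sparse to
# dense) and the Watts-Strogatz rewiring ladder for the eight WSR entries
# (near-ring to near-random over a ring lattice of base degree 4).
ER_PROBS = {"2-ER": 0.10, "3-ER": 0.15, "4-ER": 0.25, "5-ER": 0.40}
WS_PROBS = {
    "7-WSR": 0.0125,
    "8-WSR": 0.025,
    "13-WSR": 0.05,
    "16-WSR": 0.1,
    "17-WSR": 0.2,
    "18-WSR": 0.4,
    "19-WSR": 0.6,
    "20-WSR": 0.8,
}
BA_M = 1  # preferential attachment edges per new node
WALKTRAP_STEPS = 4


class CatalogError(KeyError):
    """Unknown structure label."""


class GenerationError(RuntimeError):
    """A randomised generator failed to produce a connected graph."""


class GraphParseError(ValueError):
    """A graph file could not be parsed as the requested format."""


@dataclass
class GraphModel:
    """An undirected simple connected graph plus its provenance."""

    graph: nx.Graph
    structure_id: str
    generator_params: dict = field(default_factory=dict)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges()):
            raise ValueError("graph contains self-loops")
        if g.number_of_nodes() == 0:
            raise ValueError("graph is empty")
        if not nx.is_connected(g):
            raise ValueError("graph is not connected")

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}


@dataclass(frozen=True)
class GraphMetrics:
    """The five structural metrics plus the community partition behind Q."""

    mean_degree: float
    transitivity: float
    girth: int
    acyclic: bool
    mean_path_length: float
    modularity_q: float
    community_assignment: dict[int, int]


def _attempt_seed(seed: int, attempt: int) -> int:
    """Deterministic per-attempt integer seed below 2**31."""
    return int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0] % (2**31))


def _until_connected(make, seed: int):
    for attempt in range(MAX_ATTEMPTS):
        g = make(_attempt_seed(seed, attempt))
        if nx.is_connected(g):
            return g, attempt
    raise GenerationError(
        f"no connected graph after {MAX_ATTEMPTS} attempts (seed {seed})"
    )


def _relabel(g: nx.Graph) -> nx.Graph:
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def _snark24_synthetic() -> nx.Graph:
    """Synthetic 24-vertex cubic girth-5 snark standing in for Goldberg G3.

    The published Goldberg G3 embedding is not available offline and no
    bundled library ships it, so the catalog entry uses a snark found by
    exhaustive search over cubic graphs with a free threefold rotational
    symmetry (three blocks of eight vertices, identical intra-block and
    shifted inter-block edge patterns): girth 5, chromatic index 4,
    automorphism group of order 12 — the same order, girth, class and
    symmetry as Goldberg G3, but not verified isomorphic to it.  All five
    structural metrics consumed downstream are computed from the edge list
    itself, so the substitution only matters if the true G3 differs in
    transitivity, path length or walktrap modularity.
    """
    ref = resources.files("coopnet").joinpath("data/snark24_synthetic.edgelist")
    g = nx.Graph()
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        u, v = line.split()
        g.add_edge(int(u), int(v))
    return g


def _coxeter() -> nx.Graph:
    gi = ig.Graph.Famous("Coxeter")
    g = nx.Graph()
    g.add_nodes_from(range(gi.vcount()))
    g.add_edges_from(gi.get_edgelist())
    return g


_CATALOG_BUILDERS = {}


def _register(structure_id):
    def deco(fn):
        _CATALOG_BUILDERS[structure_id] = fn
        return fn

    return deco


@_register("1-Full")
def _full(seed):
    return nx.complete_graph(24), {"n": 24}


for _sid, _p in ER_PROBS.items():

    @_register(_sid)
    def _er(seed, _p=_p):
        g, attempt = _until_connected(
            lambda s: nx.gnp_random_graph(24, _p, seed=s), seed
        )
        return g, {"n": 24, "p": _p, "attempts": attempt + 1}


@_register("6-Lattice1D")
def _ring_lattice(seed):
    # one-dimensional lattice: ring with each node tied to its 4 nearest
    return nx.watts_strogatz_graph(24, 4, 0.0), {"n": 24, "k": 4}


for _sid, _p in WS_PROBS.items():

    @_register(_sid)
    def _ws(seed, _p=_p):
        g, attempt = _until_connected(
            lambda s: nx.watts_strogatz_graph(24, 4, _p, seed=s), seed
        )
        return g, {"n": 24, "k": 4, "p": _p, "attempts": attempt + 1}


@_register("9-McGee")
def _mcgee(seed):
    return nx.LCF_graph(24, [12, 7, -7], 8), {"n": 24}


@_register("10-Lattice3D")
def _lattice3d(seed):
    return _relabel(nx.grid_graph(dim=(3, 3, 3))), {"shape": (3, 3, 3)}


@_register("11-Goldberg")
def _goldberg(seed):
    return _snark24_synthetic(), {"n": 24}


@_register("12-Coxeter")
def _coxeter_builder(seed):
    return _coxeter(), {"n": 28}


@_register("14-BA")
def _ba(seed):
    g, attempt = _until_connected(
        lambda s: nx.barabasi_albert_graph(24, BA_M, seed=s), seed
    )
    return g, {"n": 24, "m": BA_M, "attempts": attempt + 1}


@_register("15-Lattice2D")
def _lattice2d(seed):
    return _relabel(nx.grid_graph(dim=(5, 5))), {"shape": (5, 5)}


@_register("21-Ring")
def _ring(seed):
    return nx.cycle_graph(24), {"n": 24}


def catalog_ids() -> list[str]:
    """Catalog labels in numeric order."""
    return sorted(_CATALOG_BUILDERS, key=lambda s: int(s.split("-")[0]))


def build_structure(structure_id: str, seed: int = 0) -> GraphModel:
    """Construct a catalog graph; deterministic given (structure_id, seed)."""
    try:
        builder = _CATALOG_BUILDERS[structure_id]
    except KeyError:
        raise CatalogError(
            f"unknown structure {structure_id!r}; known: {catalog_ids()}"
        ) from None
    graph, params = builder(seed)
    return GraphModel(
        graph=graph, structure_id=structure_id, generator_params=params, rng_seed=seed
    )


def girth(g: nx.Graph) -> float:
    """Length of the shortest cycle; ``inf`` for acyclic graphs."""
    return nx.girth(g)


def compute_metrics(model: GraphModel | nx.Graph, steps: int = WALKTRAP_STEPS) -> GraphMetrics:
    """Compute the five structural metrics used by the multivariate analysis.

    Modularity is Newman-Girvan Q evaluated on the partition found by the
    walktrap random-walk community algorithm.  Acyclic graphs have no girth;
    they are recorded with the sentinel value ``node_count`` and flagged.
    """
    g = model.graph if isinstance(model, GraphModel) else model
    if not nx.is_connected(g):
        raise ValueError("metrics require a connected graph")
    nodes = sorted(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    gi = ig.Graph(len(nodes), [(index[u], index[v]) for u, v in g.edges()])
    clustering = gi.community_walktrap(steps=steps).as_clustering()
    q = gi.modularity(clustering.membership)
    gv = girth(g)
    acyclic = math.isinf(gv)
    return GraphMetrics(
        mean_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        transitivity=nx.transitivity(g),
        girth=g.number_of_nodes() if acyclic else int(gv),
        acyclic=acyclic,
        mean_path_length=nx.average_shortest_path_length(g),
        modularity_q=float(q),
        community_assignment={u: clustering.membership[index[u]] for u in nodes},
    )


def write_graph(model: GraphModel | nx.Graph, path, format: str = "edgelist") -> None:
    """Write a graph as a two-column edge list or as GraphML."""
    g = model.graph if isinstance(model, GraphModel) else model
    path = Path(path)
    if format == "edgelist":
        with path.open("w") as fh:
            for u, v in sorted((min(e), max(e)) for e in g.edges()):
                fh.write(f"{u} {v}\n")
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str = "edgelist", structure_id: str | None = None) -> GraphModel:
    """Read a simple undirected graph; rejects self-loops and repeated edges."""
    path = Path(path)
    if format == "edgelist":
        g = nx.Graph()
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split()
                if len(parts) != 2:
                    raise GraphParseError(
                        f"{path}:{lineno}: expected two node ids, got {s!r}"
                    )
                try:
                    u, v = int(parts[0]), int(parts[1])
                except ValueError:
                    raise GraphParseError(
                        f"{path}:{lineno}: node ids must be integers, got {s!r}"
                    ) from None
                if u == v:
                    raise GraphParseError(f"{path}:{lineno}: self-loop {u}-{v}")
                if g.has_edge(u, v):
                    raise GraphParseError(f"{path}:{lineno}: duplicate edge {u}-{v}")
                g.add_edge(u, v)
    elif format == "graphml":
        try:
            g = nx.Graph(nx.read_graphml(path))
        except Exception as exc:  # noqa: BLE001 - surface parser detail
            raise GraphParseError(f"{path}: not valid GraphML: {exc}") from exc
        g = nx.convert_node_labels_to_integers(g, ordering="sorted")
        if any(u == v for u, v in g.edges()):
            raise GraphParseError(f"{path}: graph contains a self-loop")
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return GraphModel(
        graph=g, structure_id=structure_id or path.stem, generator_params={"source": str(path)}
    )
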