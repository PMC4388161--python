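"""Multi-structure sweeps with a collect-until-stable stopping rule.

A sweep runs batches of independent evolutionary runs per structure — each
run draws a fresh (T, S) payoff pair and fresh random starting strategies —
and keeps appending batches until the cumulative per-structure mean of
(y_bar, p_bar, q_bar) stops moving by more than ``stability_tolerance``
between consecutive batch cumulations.  Results are persisted as a tidy CSV
(one row per run) plus a JSON manifest of the full configuration and seeds,
so any single run can be replayed in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evolve import EvolutionConfig, run_to_convergence
from .game import sample_payoffs
from .netgen import GraphModel, build_structure, catalog_ids, compute_metrics

__all__ = ["SweepConfig", "run_sweep", "save_results", "load_results", "structure_table"]

RESULT_COLUMNS = [
    "structure_id",
    "T",
    "S",
    "y_bar",
    "p_bar",
    "q_bar",
    "conv_gen",
    "converged",
    "seed",
    "diversity",  # median pairwise distance between final node strategies
]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a multi-structure sweep."""

    structures: tuple[str, ...] = ()
    runs_per_batch: int = 50
    stability_tolerance: float = 0.005
    max_batches: int = 20
    base_seed: int = 0
    structure_seed: int = 0
    t_range: tuple[float, float] = (1.0, 2.0)
    s_range: tuple[float, float] = (-1.0, 0.0)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)

    def __post_init__(self) -> None:
        if self.runs_per_batch < 1:
            raise ValueError("runs_per_batch must be >= 1")
        if not self.stability_tolerance > 0:
            raise ValueError("stability_tolerance must be > 0")
        if self.max_batches < 1:
            raise ValueError("max_batches must be >= 1")

    def structure_list(self) -> list[str]:
        return list(self.structures) if self.structures else catalog_ids()


def _run_seed(base_seed: int, structure_id: str, run_index: int) -> int:
    """Stable per-run seed below 2**31, independent of execution order."""
    entropy = [base_seed, zlib.crc32(structure_id.encode()) % (2**31), run_index]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def run_single(
    graph: GraphModel,
    config: SweepConfig,
    run_index: int,
) -> dict:
    """Replay one sweep run (fresh payoffs + strategies) from its seed."""
    seed = _run_seed(config.base_seed, graph.structure_id, run_index)
    rng = np.random.default_rng(seed)
    matrix = sample_payoffs(rng, config.t_range, config.s_range)
    res = run_to_convergence(graph, matrix, config.evolution, rng)
    from .analysis import strategy_diversity

    return {
        "structure_id": graph.structure_id,
        "T": matrix.T,
        "S": matrix.S,
        "y_bar": res.y_bar,
        "p_bar": res.p_bar,
        "q_bar": res.q_bar,
        "conv_gen": res.convergence_generation,
        "converged": res.converged,
        "seed": seed,
        "diversity": strategy_diversity(res.final_strategies),
    }


def run_sweep(config: SweepConfig, progress: bool = False) -> pd.DataFrame:
    """Run the collect-until-stable protocol over the configured structures."""
    rows: list[dict] = []
    for sid in config.structure_list():
        graph = build_structure(sid, seed=config.structure_seed)
        # the first cumulation is compared against zero, so an infinite (or
        # very loose) tolerance is satisfied after a single batch
        prev_mean = np.zeros(3)
        run_index = 0
        for batch in range(config.max_batches):
            for _ in range(config.runs_per_batch):
                rows.append(run_single(graph, config, run_index))
                run_index += 1
            sub = pd.DataFrame([r for r in rows if r["structure_id"] == sid])
            sub = sub[sub["converged"]]
            if len(sub) == 0:
                continue
            mean = sub[["y_bar", "p_bar", "q_bar"]].mean().to_numpy()
            if np.all(np.abs(mean - prev_mean) < config.stability_tolerance):
                break
            prev_mean = mean
        if progress:
            print(f"{sid}: {run_index} runs")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def structure_table(
    structures: list[str] | None = None, structure_seed: int = 0
) -> pd.DataFrame:
    """Per-structure metric table (one row per catalog graph)."""
    rows = []
    for sid in structures or catalog_ids():
        model = build_structure(sid, seed=structure_seed)
        m = compute_metrics(model)
        rows.append(
            {
                "structure_id": sid,
                "n_nodes": model.node_count,
                "mean_degree": m.mean_degree,
                "transitivity": m.transitivity,
                "girth": m.girth,
                "acyclic": m.acyclic,
                "mean_path_length": m.mean_path_length,
                "modularity": m.modularity_q,
            }
        )
    return pd.DataFrame(rows)


def save_results(df: pd.DataFrame, path, config: SweepConfig | None = None) -> None:
    """Write the run table as CSV plus a JSON manifest next to it."""
    path = Path(path)
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write results to {path}: {exc}") from exc
    manifest = {
        "software": {"name": "coopnet", "version": __version__},
        "n_runs": int(len(df)),
        "structures": sorted(df["structure_id"].unique().tolist()),
    }
    if config is not None:
        manifest["config"] = asdict(config)
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def load_results(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"could not read results from {path}: {exc}") from exc
    missing = set(RESULT_COLUMNS) - {"diversity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing result columns {sorted(missing)}")
    return df
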