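"""Statistical summaries of sweep results.

All functions are pure functions of the tidy run table (plus the
per-structure metric table where structure-level covariates are needed), so
re-running the analysis on a saved CSV reproduces its outputs exactly.

The PCA operates on the correlation matrix of eight variables — the five
structural metrics (mean degree, transitivity, girth, path length,
modularity) and the three equilibrium strategy means (y_bar, p_bar, q_bar) —
because the variables mix probabilities with graph metrics on incompatible
scales.  Biplot geometry is reported as the angle of each variable's loading
vector in the PC1-PC2 plane and its cosine similarity to the modularity
vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "STGrid",
    "st_plane_grid",
    "pca_biplot",
    "improvement_vs_baseline",
    "dispersion_vs_modularity",
    "strategy_diversity",
    "convergence_summary",
    "attach_metrics",
]

PCA_VARIABLES = [
    "transitivity",
    "mean_degree",
    "girth",
    "mean_path_length",
    "modularity",
    "y_bar",
    "p_bar",
    "q_bar",
]
NETWORK_VARIABLES = PCA_VARIABLES[:5]
COMPONENTS = ["y_bar", "p_bar", "q_bar"]


@dataclass(frozen=True)
class PCAResult:
    """Loadings and biplot geometry of the structure-vs-behavior PCA."""

    variables: list[str]
    loadings: np.ndarray  # (n_vars, n_pcs), columns orthonormal
    variance_fraction: np.ndarray
    theta: dict[str, float]  # degrees, in the PC1-PC2 plane
    cos_to_modularity: dict[str, float]

    @property
    def pc1_loading(self) -> dict[str, float]:
        return {v: float(self.loadings[i, 0]) for i, v in enumerate(self.variables)}


@dataclass(frozen=True)
class STGrid:
    """Per-cell medians of one strategy component over the (T, S) plane."""

    component: str
    t_edges: np.ndarray
    s_edges: np.ndarray
    median: np.ndarray  # (n_s, n_t), NaN where empty
    count: np.ndarray


def attach_metrics(runs: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Join per-run rows with their structure's metric row."""
    return runs.merge(metrics, on="structure_id", how="left", validate="many_to_one")


def st_plane_grid(
    runs: pd.DataFrame,
    component: str = "y_bar",
    bins: int = 10,
    t_range: tuple[float, float] = (1.0, 2.0),
    s_range: tuple[float, float] = (-1.0, 0.0),
) -> STGrid:
    """Median of a strategy component per (T, S) bin."""
    if len(runs) == 0:
        raise ValueError("empty run table")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    t_edges = np.linspace(*t_range, bins + 1)
    s_edges = np.linspace(*s_range, bins + 1)
    ti = np.clip(np.digitize(runs["T"], t_edges) - 1, 0, bins - 1)
    si = np.clip(np.digitize(runs["S"], s_edges) - 1, 0, bins - 1)
    med = np.full((bins, bins), np.nan)
    cnt = np.zeros((bins, bins), dtype=int)
    values = runs[component].to_numpy()
    for s in range(bins):
        for t in range(bins):
            cell = values[(si == s) & (ti == t)]
            cnt[s, t] = len(cell)
            if len(cell):
                med[s, t] = np.median(cell)
    return STGrid(component=component, t_edges=t_edges, s_edges=s_edges, median=med, count=cnt)


def pca_biplot(table: pd.DataFrame, variables: list[str] | None = None) -> PCAResult:
    """PCA of standardized run-level variables with biplot geometry.

    Signs are fixed so that modularity loads positively on PC1 and trust
    (y_bar) non-negatively on PC2, which pins the otherwise arbitrary
    eigenvector orientation.
    """
    variables = variables or PCA_VARIABLES
    if "structure_id" in table.columns and table["structure_id"].nunique() < 2:
        raise ValueError("PCA needs runs from at least two structures")
    X = table[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"zero-variance variable(s) {bad}; PCA on the "
                         "correlation matrix is undefined for constants")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order]
    var_frac = eigval / eigval.sum()

    i_mod = variables.index("modularity") if "modularity" in variables else 0
    if loadings[i_mod, 0] < 0:
        loadings[:, 0] *= -1
    i_y = variables.index("y_bar") if "y_bar" in variables else None
    if i_y is not None and loadings.shape[1] > 1 and loadings[i_y, 1] < 0:
        loadings[:, 1] *= -1

    theta = {
        v: float(np.degrees(np.arctan2(loadings[i, 1], loadings[i, 0])))
        for i, v in enumerate(variables)
    }
    ref = theta.get("modularity", 0.0)
    cos = {v: float(np.cos(np.radians(ref - theta[v]))) for v in variables}
    return PCAResult(
        variables=list(variables),
        loadings=loadings,
        variance_fraction=var_frac,
        theta=theta,
        cos_to_modularity=cos,
    )


def improvement_vs_baseline(
    runs: pd.DataFrame, structure: str, baseline: str = "1-Full"
) -> dict[str, float]:
    """Fractional improvement of each component mean over the baseline
    structure: (mean(structure) - mean(baseline)) / mean(baseline)."""
    for sid in (structure, baseline):
        if not (runs["structure_id"] == sid).any():
            raise ValueError(f"structure {sid!r} not present in run table")
    out = {}
    for c in COMPONENTS:
        base = runs.loc[runs["structure_id"] == baseline, c].mean()
        if base == 0:
            raise ValueError(f"baseline mean of {c} is zero; improvement undefined")
        cur = runs.loc[runs["structure_id"] == structure, c].mean()
        out[c] = float((cur - base) / base)
    return out


def dispersion_vs_modularity(
    runs: pd.DataFrame, metrics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Coefficient of variation (sigma/mu) of each component across the runs
    of each structure, paired with the structure's modularity Q."""
    rows = []
    for sid, sub in runs.groupby("structure_id"):
        if len(sub) < 2:
            raise ValueError(f"structure {sid!r} has fewer than 2 runs")
        row = {"structure_id": sid}
        for c in COMPONENTS:
            mu = sub[c].mean()
            sigma = sub[c].std(ddof=1)
            row[f"cv_{c}"] = float(sigma / mu) if mu != 0 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if metrics is not None:
        out = out.merge(
            metrics[["structure_id", "modularity"]], on="structure_id", how="left"
        )
    return out


def strategy_diversity(final_strategies: np.ndarray) -> float:
    """Median pairwise 3D Euclidean distance between final (y, p, q) vectors."""
    from scipy.spatial.distance import pdist

    s = np.asarray(final_strategies, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("need at least two strategies")
    return float(np.median(pdist(s)))


def convergence_summary(
    runs: pd.DataFrame, metrics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Median and IQR of convergence time, grouped by zero vs positive
    transitivity and by mean degree (structure-level covariates)."""
    df = runs if metrics is None else attach_metrics(runs, metrics)
    if "transitivity" in df.columns:
        df = df.assign(transitive=df["transitivity"] > 0)
        keys = ["transitive", "mean_degree"]
    else:
        keys = ["structure_id"]
    rows = []
    for key, sub in df.groupby(keys):
        t = sub["conv_gen"]
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(
            n=len(sub),
            median=float(t.median()),
            q1=float(t.quantile(0.25)),
            q3=float(t.quantile(0.75)),
        )
        rows.append(rec)
    return pd.DataFrame(rows)
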