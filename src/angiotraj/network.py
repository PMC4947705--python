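"""Correlation networks of biomarker panels.

Pearson and partial-correlation networks of log-concentrations, built
separately for pre-treatment samples (both arms pooled) and for each arm's
on-treatment samples.  Progression samples are always excluded so the
networks reflect treatment effect rather than progression biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset

__all__ = [
    "SUBSETS",
    "CorrelationNetwork",
    "select_samples",
    "pearson_network",
    "partial_correlation_network",
    "threshold_edges",
]

SUBSETS = ("pretreatment", "standard_on_treatment", "experimental_on_treatment")


@dataclass(frozen=True)
class CorrelationNetwork:
    """Biomarker nodes with a symmetric signed weight matrix in [-1, 1]."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    method: str          # "pearson" | "partial"
    subset_label: str = ""

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node count")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.abs(w) > 1.0 + 1e-10):
            raise ValueError("correlation weights must lie in [-1, 1]")

    def weight(self, a: str, b: str) -> float:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return float(self.weights[i, j])

    def to_networkx(self, cutoff: float = 0.0):
        """Weighted undirected graph, optionally thresholded on |weight|."""
        import networkx as nx

        g = nx.Graph(method=self.method, subset=self.subset_label)
        g.add_nodes_from(self.nodes)
        for _, row in threshold_edges(self, cutoff)[0].iterrows():
            g.add_edge(row["node_a"], row["node_b"], weight=row["weight"],
                       sign=row["sign"])
        return g


def select_samples(dataset: LongitudinalDataset, subset_label: str) -> pd.DataFrame:
    """Sample-by-biomarker log-concentration matrix for one network subset.

    Rows are time-matched samples (one per patient visit) with every panel
    biomarker measured; visits missing any biomarker are dropped.
    Pre-treatment pools both arms; on-treatment subsets exclude both
    pre-treatment and progression samples.
    """
    if subset_label not in SUBSETS:
        raise ValueError(f"unknown subset {subset_label!r}; expected one of {SUBSETS}")
    s = dataset.samples
    if subset_label == "pretreatment":
        sel = s[s["time_days"] < 0]
    else:
        arm = subset_label.removesuffix("_on_treatment")
        sel = s[(s["arm"] == arm) & (s["time_days"] >= 0)
                & (~s["is_progression_sample"])]
    if sel.empty:
        raise ValueError(f"no samples in subset {subset_label!r}")
    wide = sel.pivot_table(
        index=["patient_id", "time_days"], columns="biomarker",
        values="concentration",
    ).dropna()
    if wide.empty:
        raise ValueError(
            f"subset {subset_label!r} has no visit with the full biomarker panel"
        )
    return np.log(wide)


def pearson_network(matrix: pd.DataFrame, subset_label: str = "") -> CorrelationNetwork:
    """Pairwise Pearson correlation network of a sample-by-biomarker matrix."""
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    constant = matrix.columns[matrix.std(ddof=0) == 0]
    if len(constant):
        raise ValueError(
            f"correlation undefined for constant biomarker(s): {list(constant)}"
        )
    corr = np.corrcoef(matrix.to_numpy(), rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CorrelationNetwork(tuple(matrix.columns), corr, "pearson", subset_label)


def _shrunk_correlation(x: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf-style shrinkage of the correlation matrix toward identity."""
    from sklearn.covariance import LedoitWolf

    std = x.std(axis=0, ddof=1)
    lw = LedoitWolf(assume_centered=False).fit(x / std)
    cov = lw.covariance_
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def partial_correlation_network(
    matrix: pd.DataFrame, subset_label: str = "", shrinkage: bool | None = None,
) -> CorrelationNetwork:
    """Partial correlations from the inverse (precision) correlation matrix.

    ``rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)`` with ``Omega`` the
    precision matrix.  When the sample count does not exceed the biomarker
    count (or on request) the correlation matrix is shrunk toward the
    identity before inversion; ``shrinkage=False`` forces plain inversion
    and raises on a singular matrix.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    p = matrix.shape[1]
    if p == 1:
        raise ValueError("partial correlations need at least 2 biomarkers")
    x = matrix.to_numpy(dtype=float)
    if shrinkage is None:
        shrinkage = matrix.shape[0] <= p
    if shrinkage:
        corr = _shrunk_correlation(x)
    else:
        corr = np.corrcoef(x, rowvar=False)
    try:
        omega = np.linalg.inv(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "correlation matrix is singular; enable shrinkage"
        ) from err
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = np.clip((partial + partial.T) / 2.0, -1.0, 1.0)
    return CorrelationNetwork(tuple(matrix.columns), partial, "partial", subset_label)


def partial_correlation_from_corr(corr: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a full correlation matrix."""
    omega = np.linalg.inv(np.asarray(corr, dtype=float))
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def threshold_edges(network: CorrelationNetwork, cutoff: float = 0.3):
    """Edges with |weight| at or above the display cut-off, plus a summary.

    Returns ``(edges, summary)``: an edge table (node_a, node_b, weight,
    sign, method, subset_label) sorted by |weight| descending, and a dict
    with the count, maximum and median of the displayed |weight| values.
    """
    rows = []
    n = len(network.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(network.weights[i, j])
            if abs(w) >= cutoff:
                a, b = sorted((network.nodes[i], network.nodes[j]))
                rows.append((a, b, w, "positive" if w >= 0 else "negative",
                             network.method, network.subset_label))
    edges = pd.DataFrame(
        rows, columns=["node_a", "node_b", "weight", "sign", "method", "subset_label"]
    )
    edges = edges.sort_values(
        by=["weight", "node_a", "node_b"], key=lambda c: -c.abs() if c.name == "weight" else c,
    ).reset_index(drop=True)
    summary = {
        "n_edges": len(edges),
        "max_abs_weight": float(edges["weight"].abs().max()) if len(edges) else np.nan,
        "median_abs_weight": float(edges["weight"].abs().median()) if len(edges) else np.nan,
    }
    return edges, summary
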