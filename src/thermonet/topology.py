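"""Network-level and node-level topological metrics.

The network-level panel — node/edge counts, average degree, average path
length over connected pairs, diameter (longest finite shortest path),
mean local clustering, Freeman degree/betweenness centralization, and
modularity of a detected partition — is the standard comparison panel
for microbial co-occurrence networks and their random counterparts.

Conventions (recorded in every summary):

* disconnected graphs: path length averages over pairs with a finite
  distance only; diameter is the largest finite distance — required for
  Erdős–Rényi null graphs, which may be disconnected;
* local clustering of degree-0/1 nodes contributes 0 to the mean
  (configurable to exclude such nodes instead);
* Freeman centralizations are normalised by the star-graph maximum, so
  a star scores 1 and any regular graph 0.  Betweenness centralization
  is invariant to whether node betweenness counts ordered or unordered
  source-target pairs, since numerator and normaliser scale together.

A fast array core (scipy BFS + dense triangle counting + C betweenness
via igraph) backs both the public API and the null-model ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import shortest_path

PANEL_METRICS = (
    "average_degree", "average_path_length", "diameter",
    "clustering_coefficient", "centralization_degree",
    "centralization_betweenness", "modularity",
)


@dataclass
class TopologySummary:
    """The network-level metric panel for one network."""

    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    diameter: float
    clustering_coefficient: float
    centralization_degree: float
    centralization_betweenness: float
    modularity: float | None = None
    conventions: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("conventions")
        return d

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


# ---------------------------------------------------------------------------
# fast core on edge arrays

def _csr_from_edges(n: int, a: np.ndarray, b: np.ndarray) -> sp.csr_matrix:
    data = np.ones(2 * len(a), dtype=np.int8)
    rows = np.concatenate([a, b])
    cols = np.concatenate([b, a])
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _clustering_from_dense(A: np.ndarray, include_low_degree: bool = True) -> float:
    deg = A.sum(axis=1)
    triangles = ((A @ A) * A).sum(axis=1) / 2.0
    possible = deg * (deg - 1) / 2.0
    local = np.zeros_like(deg, dtype=float)
    ok = possible > 0
    local[ok] = triangles[ok] / possible[ok]
    if include_low_degree:
        return float(local.mean()) if len(local) else 0.0
    return float(local[ok].mean()) if ok.any() else 0.0


def _path_stats(D: np.ndarray) -> tuple[float, float]:
    """(average path length over finite off-diagonal pairs, max finite)."""
    mask = np.isfinite(D)
    np.fill_diagonal(mask, False)
    finite = D[mask]
    if finite.size == 0:
        return float("nan"), float("nan")
    return float(finite.mean()), float(finite.max())


def degree_centralization(degrees: np.ndarray) -> float:
    """Freeman degree centralization, star-normalised: Σ(d_max − d_i) /
    ((n−1)(n−2))."""
    n = len(degrees)
    if n < 3:
        return 0.0
    return float((degrees.max() * n - degrees.sum()) / ((n - 1) * (n - 2)))


def betweenness_centralization(betweenness: np.ndarray) -> float:
    """Freeman betweenness centralization from raw (unordered-pair)
    betweenness: Σ(b_max − b_i) / ((n−1)²(n−2)/2), the star maximum."""
    n = len(betweenness)
    if n < 3:
        return 0.0
    denom = (n - 1) ** 2 * (n - 2) / 2.0
    return float((betweenness.max() * n - betweenness.sum()) / denom)


def panel_from_edges(n: int, a: np.ndarray, b: np.ndarray,
                     metrics=PANEL_METRICS, modularity_fn=None,
                     include_low_degree: bool = True) -> dict:
    """Compute the requested panel metrics for the graph with ``n`` nodes
    and edges ``(a[i], b[i])``.  ``modularity_fn`` maps an igraph Graph to
    a modularity score; required only when ``"modularity"`` is requested.
    """
    metrics = set(metrics)
    out: dict[str, float] = {}
    m = len(a)
    if "average_degree" in metrics:
        out["average_degree"] = 2.0 * m / n if n else float("nan")
    need_dist = metrics & {"average_path_length", "diameter"}
    A = None
    if need_dist or "clustering_coefficient" in metrics or \
            "centralization_degree" in metrics:
        A = _csr_from_edges(n, a, b)
    if need_dist:
        D = shortest_path(A, method="auto", unweighted=True, directed=False)
        apl, diam = _path_stats(D)
        if "average_path_length" in metrics:
            out["average_path_length"] = apl
        if "diameter" in metrics:
            out["diameter"] = diam
    if "clustering_coefficient" in metrics:
        out["clustering_coefficient"] = _clustering_from_dense(
            np.asarray(A.todense(), dtype=float), include_low_degree)
    if "centralization_degree" in metrics:
        deg = np.asarray(A.sum(axis=1)).ravel()
        out["centralization_degree"] = degree_centralization(deg)
    if "centralization_betweenness" in metrics or "modularity" in metrics:
        g = ig.Graph(n=n, edges=list(zip(a.tolist(), b.tolist())))
        if "centralization_betweenness" in metrics:
            bw = np.asarray(g.betweenness(), dtype=float)
            out["centralization_betweenness"] = betweenness_centralization(bw)
        if "modularity" in metrics:
            if modularity_fn is None:
                raise ValueError("modularity requested without a modularity_fn")
            out["modularity"] = modularity_fn(g)
    return out


def _graph_edge_arrays(G: nx.Graph) -> tuple[int, np.ndarray, np.ndarray, list]:
    nodes = list(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    if G.number_of_edges():
        a, b = zip(*((index[u], index[v]) for u, v in G.edges))
    else:
        a, b = (), ()
    return len(nodes), np.asarray(a, dtype=np.int64), np.asarray(b, dtype=np.int64), nodes


# ---------------------------------------------------------------------------
# public API

def network_summary(G: nx.Graph, partition=None,
                    include_low_degree: bool = True) -> TopologySummary:
    """The full metric panel for one network.

    ``partition`` is a ModulePartition (or anything with a ``q``
    attribute); its modularity is reported as-is.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n, a, b, _ = _graph_edge_arrays(G)
    metrics = set(PANEL_METRICS) - {"modularity"}
    panel = panel_from_edges(n, a, b, metrics=metrics,
                             include_low_degree=include_low_degree)
    q = getattr(partition, "q", partition) if partition is not None else None
    return TopologySummary(
        n_nodes=n, n_edges=len(a),
        average_degree=panel["average_degree"],
        average_path_length=panel["average_path_length"],
        diameter=panel["diameter"],
        clustering_coefficient=panel["clustering_coefficient"],
        centralization_degree=panel["centralization_degree"],
        centralization_betweenness=panel["centralization_betweenness"],
        modularity=None if q is None else float(q),
        conventions={
            "path_length": "mean over connected pairs",
            "diameter": "max finite shortest path",
            "clustering_low_degree": "included as 0" if include_low_degree else "excluded",
            "centralization": "Freeman, star-graph normalised",
            "betweenness_pairs": "unordered",
        },
    )


def node_metrics(G: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness centrality (raw, unordered pairs),
    local clustering, and eccentricity within the node's component."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n, a, b, nodes = _graph_edge_arrays(G)
    g = ig.Graph(n=n, edges=list(zip(a.tolist(), b.tolist())))
    bw = np.asarray(g.betweenness(), dtype=float)
    deg = np.asarray(g.degree(), dtype=int)
    A = _csr_from_edges(n, a, b) if len(a) else sp.csr_matrix((n, n), dtype=np.int8)
    D = shortest_path(A, method="auto", unweighted=True, directed=False)
    with np.errstate(invalid="ignore"):
        Dm = np.where(np.isfinite(D), D, -np.inf)
        ecc = Dm.max(axis=1)
    ecc[ecc == -np.inf] = 0.0
    clustering = np.array(
        [nx.clustering(G, v) for v in nodes], dtype=float)
    return pd.DataFrame(
        {"degree": deg, "betweenness": bw, "clustering": clustering,
         "eccentricity": ecc},
        index=pd.Index(nodes, name="otu_id"),
    )


def compare_groups(metrics: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per metric column between two
    groups.  Exact P where sample sizes permit (no ties), else the
    normal approximation.  Returns statistic, P and group medians.
    """
    labels = labels.reindex(metrics.index)
    groups = [g for g in labels.dropna().unique()]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = sorted(groups)
    i1, i2 = labels == g1, labels == g2
    if not i1.any() or not i2.any():
        raise ValueError("each group must be nonempty")
    rows = []
    for col in metrics.columns:
        x = metrics.loc[i1, col].to_numpy()
        y = metrics.loc[i2, col].to_numpy()
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append({"metric": col, "statistic": float(u), "p_value": float(p),
                     f"median_{g1}": float(np.median(x)),
                     f"median_{g2}": float(np.median(y))})
    return pd.DataFrame(rows).set_index("metric")


def summary_table(summaries: dict[str, TopologySummary]) -> pd.DataFrame:
    """Metric rows x network columns, the panel layout used for reporting."""
    return pd.DataFrame({name: s.to_series() for name, s in summaries.items()})
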