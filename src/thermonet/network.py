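"""Co-occurrence network construction.

Edges connect OTU pairs whose relative abundances are strongly,
significantly rank-correlated across samples: Spearman |R| > ``r_min``
(default 0.80) and BH-adjusted P < ``alpha`` (default 0.01), both strict.
The BH family is the set of all pairs with a defined correlation within
one network build.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import OTUTable

logger = logging.getLogger(__name__)


def pairwise_spearman(table: OTUTable, otu_set=None, samples=None):
    """All-pairs Spearman correlation of OTU abundance profiles.

    Ties are handled by average ranks; two-sided P-values come from the
    t-distribution approximation for Spearman's rho.  Zero-variance
    profiles yield NaN in both matrices and are excluded downstream.

    Returns
    -------
    (rho, p) : two symmetric ``pandas.DataFrame`` over the OTU set.
    """
    otus = list(otu_set) if otu_set is not None else list(table.otu_ids)
    sub = table.data[otus]
    if samples is not None:
        sub = sub.loc[list(samples)]
    n = sub.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation screening")
    x = sub.to_numpy(dtype=float)
    const = np.ptp(x, axis=0) == 0
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    ranks -= ranks.mean(axis=0)
    norm = np.sqrt((ranks**2).sum(axis=0))
    norm[norm == 0] = np.nan
    rho = (ranks.T @ ranks) / np.outer(norm, norm)
    rho = np.clip(rho, -1.0, 1.0)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    # two-sided P from t = rho * sqrt((n-2)/(1-rho^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    idx = pd.Index(otus, name="otu_id")
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sort ascending, multiply p(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of P-values")
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(rho: pd.DataFrame, p_adjust: pd.DataFrame,
                  r_min: float = 0.80, alpha: float = 0.01,
                  provenance: dict | None = None) -> nx.Graph:
    """Threshold the correlation screen into an undirected network.

    An edge is kept iff ``|rho| > r_min`` and ``p_adjust < alpha`` (both
    strict).  Nodes left with degree 0 are removed.  Edge attributes:
    ``rho``, ``p_adjust`` (and ``p_raw`` when present in provenance flow).
    """
    if rho.shape != p_adjust.shape:
        raise ValueError("rho and p_adjust matrices must have matching shape")
    otus = list(rho.index)
    G = nx.Graph()
    G.add_nodes_from(otus)
    r = rho.to_numpy()
    pa = p_adjust.to_numpy()
    iu = np.triu_indices(len(otus), 1)
    keep = (np.abs(r[iu]) > r_min) & (pa[iu] < alpha)
    keep &= ~np.isnan(r[iu])
    for a, b in zip(iu[0][keep], iu[1][keep]):
        G.add_edge(otus[a], otus[b], rho=float(r[a, b]), p_adjust=float(pa[a, b]))
    isolated = [v for v, d in G.degree() if d == 0]
    G.remove_nodes_from(isolated)
    G.graph["provenance"] = {
        "r_min": r_min, "alpha": alpha,
        "n_candidate_otus": len(otus),
        "n_isolated_removed": len(isolated),
        **(provenance or {}),
    }
    logger.info("network: %d nodes, %d edges (%d isolated removed)",
                G.number_of_nodes(), G.number_of_edges(), len(isolated))
    return G


def correlation_network(table: OTUTable, otu_set=None, samples=None,
                        r_min: float = 0.80, alpha: float = 0.01) -> nx.Graph:
    """One-call screen + BH adjustment + thresholding.

    The BH family is every pair with a defined correlation in this build.
    """
    rho, p = pairwise_spearman(table, otu_set=otu_set, samples=samples)
    iu = np.triu_indices(rho.shape[0], 1)
    pv = p.to_numpy()[iu]
    ok = ~np.isnan(pv)
    adj = np.full_like(pv, np.nan)
    adj[ok] = bh_adjust(pv[ok])
    pa = np.full(rho.shape, np.nan)
    pa[iu] = adj
    pa.T[iu] = adj
    np.fill_diagonal(pa, 0.0)
    p_adjust = pd.DataFrame(pa, index=rho.index, columns=rho.columns)
    G = build_network(rho, p_adjust, r_min=r_min, alpha=alpha,
                      provenance={"n_samples": len(samples) if samples is not None
                                  else table.data.shape[0]})
    for a, b in G.edges:
        G.edges[a, b]["p_raw"] = float(p.loc[a, b])
    return G


def edge_table(G: nx.Graph) -> pd.DataFrame:
    """Edge list with otu_a < otu_b lexicographically."""
    rows = []
    for a, b, d in G.edges(data=True):
        a, b = sorted((a, b))
        rows.append({"otu_a": a, "otu_b": b, "rho": d.get("rho"),
                     "p_raw": d.get("p_raw"), "p_adjust": d.get("p_adjust")})
    return (pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p_raw", "p_adjust"])
            .sort_values(["otu_a", "otu_b"]).reset_index(drop=True))
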