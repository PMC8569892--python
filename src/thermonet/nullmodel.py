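"""Erdős–Rényi G(n, m) null model and Z-tests of observed topology.

An observed network is compared against an ensemble of uniform random
simple graphs with the same node and edge counts.  Each replicate's
metric panel is summarised as mean ± SD, and the observed value is
scored with a Z-test against the ensemble:

    Z = (observed − ensemble mean) / ensemble SD,

with a two-sided P from the standard normal.  A degenerate ensemble
(SD = 0) yields P = 1 when the observation equals the mean and P = 0
otherwise, flagged in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import topology
from .modules import detect_modules, modularity_q

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Ensemble mean/SD per metric for G(n, m) random graphs."""

    n: int
    m: int
    reps: int
    seed: int
    stats: pd.DataFrame  # index = metric; columns = mean, sd

    def mean(self, metric: str) -> float:
        return float(self.stats.loc[metric, "mean"])

    def sd(self, metric: str) -> float:
        return float(self.stats.loc[metric, "sd"])


def _gnm_edges(n: int, m: int, rng: np.random.Generator,
               iu=None) -> tuple[np.ndarray, np.ndarray]:
    total = n * (n - 1) // 2
    if not 0 <= m <= total:
        raise ValueError(f"m={m} out of range for n={n} (max {total})")
    idx = rng.choice(total, size=m, replace=False)
    if iu is None:
        iu = np.triu_indices(n, 1)
    return iu[0][idx], iu[1][idx]


def erdos_renyi_gnm(n: int, m: int, seed: int) -> nx.Graph:
    """Uniform random simple graph with exactly ``n`` nodes and ``m``
    edges; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    a, b = _gnm_edges(n, m, rng)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(a.tolist(), b.tolist()))
    return G


def null_ensemble(n: int, m: int, reps: int = 999, seed: int = 0,
                  metrics=topology.PANEL_METRICS,
                  detect_method: str = "greedy") -> NullDistribution:
    """Mean ± SD of the topology panel over ``reps`` G(n, m) draws.

    Modularity of each replicate uses the same detection algorithm as
    the observed network (``detect_method``); it and betweenness
    centralization dominate the cost, so pass a reduced ``metrics``
    tuple for large ensembles.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    modularity_fn = None
    if "modularity" in metrics:
        def modularity_fn(g):
            G = nx.Graph()
            G.add_nodes_from(range(g.vcount()))
            G.add_edges_from(g.get_edgelist())
            part = detect_modules(G, method=detect_method, seed=seed)
            return part.q
    rows = []
    for _ in range(reps):
        a, b = _gnm_edges(n, m, rng, iu=iu)
        rows.append(topology.panel_from_edges(n, a, b, metrics=metrics,
                                              modularity_fn=modularity_fn))
    df = pd.DataFrame(rows)
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    return NullDistribution(n=n, m=m, reps=reps, seed=seed, stats=out)


def z_test(observed: float, mean: float, sd: float) -> dict:
    """Two-sided Z-test of one observation against an ensemble."""
    if sd < 0:
        raise ValueError("SD must be nonnegative")
    if sd == 0:
        p = 1.0 if observed == mean else 0.0
        return {"observed": observed, "null_mean": mean, "null_sd": sd,
                "z": 0.0 if observed == mean else np.inf * np.sign(observed - mean),
                "p_value": p, "significant": p < 0.05, "degenerate": True}
    z = (observed - mean) / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return {"observed": observed, "null_mean": mean, "null_sd": sd,
            "z": float(z), "p_value": float(p), "significant": p < 0.05,
            "degenerate": False}


def compare_to_null(summary: topology.TopologySummary,
                    null: NullDistribution) -> pd.DataFrame:
    """Z-test every panel metric of ``summary`` against ``null``.

    Only metrics present in the null distribution are compared; node and
    edge counts match by construction and are skipped.
    """
    rows = {}
    obs = summary.to_dict()
    for metric in null.stats.index:
        if metric == "average_degree":
            continue  # identical by construction in G(n, m)
        val = obs.get(metric)
        if val is None:
            continue
        rows[metric] = z_test(float(val), null.mean(metric), null.sd(metric))
    return pd.DataFrame(rows).T


def null_report(comparison: pd.DataFrame) -> pd.DataFrame:
    """Human-readable table with "mean ± SD" strings and significance
    asterisks (P < 0.05), the usual layout for real-vs-random panels."""
    out = pd.DataFrame(index=comparison.index)
    out["observed"] = comparison["observed"].map(lambda v: f"{v:.3f}")
    out["random"] = [
        f"{r['null_mean']:.3f} ± {r['null_sd']:.3f}" + ("*" if r["significant"] else "")
        for _, r in comparison.iterrows()
    ]
    return out
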