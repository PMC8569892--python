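"""Module detection and Zi–Pi node-role classification.

Modules are groups of densely interlinked OTUs found by heuristic
Newman–Girvan modularity maximisation.  Node roles follow the
within-module degree z-score (Zi) and participation coefficient (Pi):

* Zi = (k_is − mean_s) / sd_s, where k_is counts node i's links into its
  own module s and mean/sd are taken over the nodes of s;
* Pi = 1 − Σ_t (k_it / k_i)², summed over every module t.

Thresholds Zi ≥ 2.5 and Pi ≥ 0.62 split nodes into peripherals, module
hubs, connectors, and network hubs; the non-peripheral classes are the
putative keystone taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ROLE_ZI_CUT = 2.5
ROLE_PI_CUT = 0.62


@dataclass
class ModulePartition:
    """Node -> module assignment plus its modularity Q."""

    membership: dict
    q: float
    method: str = "greedy"
    seed: int | None = None

    def sizes(self) -> pd.Series:
        return pd.Series(self.membership).value_counts().sort_index()

    def modules(self) -> list:
        return sorted(set(self.membership.values()))

    def nodes_of(self, module) -> list:
        return [v for v, m in self.membership.items() if m == module]


def modularity_q(G: nx.Graph, communities) -> float:
    """Newman–Girvan modularity Q = Σ_s (e_ss − a_s²) of a partition."""
    return nx.community.modularity(G, communities)


def detect_modules(G: nx.Graph, method: str = "greedy",
                   seed: int = 0) -> ModulePartition:
    """Partition the network into modules by modularity maximisation.

    ``method="greedy"`` (default) is CNM greedy agglomeration, which is
    deterministic; ``method="louvain"`` uses Louvain with the given seed.
    Module ids are letters A, B, C... ordered by decreasing size (ties by
    smallest node id), matching the usual labelling of major modules.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(G)
    elif method == "louvain":
        comms = nx.community.louvain_communities(G, seed=seed)
    else:
        raise ValueError(f"unknown detection method {method!r}")
    comms = [set(c) for c in comms]
    comms.sort(key=lambda c: (-len(c), min(str(v) for v in c)))
    membership = {}
    for i, c in enumerate(comms):
        label = _module_label(i)
        for v in c:
            membership[v] = label
    q = modularity_q(G, comms)
    return ModulePartition(membership, q=float(q), method=method, seed=seed)


def _module_label(i: int) -> str:
    label = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        label = chr(ord("A") + r) + label
    return label


def major_modules(partition: ModulePartition, min_size: int = 11) -> list:
    """Modules with at least ``min_size`` nodes (default: strictly more
    than 10), in id order."""
    sizes = partition.sizes()
    return sorted(sizes.index[sizes >= min_size])


def zi_pi(G: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient
    (Pi) for every node.

    Conventions for degenerate cases, flagged in the ``degenerate``
    column: a module whose within-degrees have zero spread gives Zi = 0
    for all its nodes; an isolated node gets Zi = Pi = 0.
    """
    nodes = list(G.nodes)
    mods = partition.modules()
    mod_index = {m: j for j, m in enumerate(mods)}
    k_im = np.zeros((len(nodes), len(mods)))
    node_index = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        for u in G.neighbors(v):
            k_im[node_index[v], mod_index[partition.membership[u]]] += 1
    k = k_im.sum(axis=1)
    own = np.array([mod_index[partition.membership[v]] for v in nodes])
    k_own = k_im[np.arange(len(nodes)), own]

    zi = np.zeros(len(nodes))
    degenerate = np.zeros(len(nodes), dtype=bool)
    for j, m in enumerate(mods):
        members = own == j
        vals = k_own[members]
        sd = vals.std(ddof=0)
        if sd > 0:
            zi[members] = (vals - vals.mean()) / sd
        else:
            degenerate |= members
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 1.0 - ((k_im / k[:, None]) ** 2).sum(axis=1)
    isolated = k == 0
    pi[isolated] = 0.0
    zi[isolated] = 0.0
    degenerate |= isolated
    return pd.DataFrame(
        {"module": [partition.membership[v] for v in nodes],
         "degree": k.astype(int), "zi": zi, "pi": pi, "degenerate": degenerate},
        index=pd.Index(nodes, name="otu_id"),
    )


def classify_roles(roles: pd.DataFrame, zi_cut: float = ROLE_ZI_CUT,
                   pi_cut: float = ROLE_PI_CUT) -> pd.DataFrame:
    """Fill the four-way role label from Zi/Pi thresholds (cuts inclusive
    on the hub side: Zi >= zi_cut, Pi >= pi_cut)."""
    zi, pi = roles["zi"], roles["pi"]
    label = np.where(
        zi >= zi_cut,
        np.where(pi >= pi_cut, "network hub", "module hub"),
        np.where(pi >= pi_cut, "connector", "peripheral"),
    )
    out = roles.copy()
    out["role"] = label
    return out


def node_role_table(G: nx.Graph, partition: ModulePartition,
                    zi_cut: float = ROLE_ZI_CUT,
                    pi_cut: float = ROLE_PI_CUT) -> pd.DataFrame:
    """Zi/Pi plus role labels in one call."""
    return classify_roles(zi_pi(G, partition), zi_cut=zi_cut, pi_cut=pi_cut)


def plot_zi_pi(roles: pd.DataFrame, path, zi_cut: float = ROLE_ZI_CUT,
               pi_cut: float = ROLE_PI_CUT) -> None:
    """Scatter of Pi (x) vs Zi (y) with the role-threshold lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"peripheral": "0.6", "module hub": "tab:red",
              "connector": "tab:blue", "network hub": "tab:purple"}
    for role, sub in roles.groupby("role"):
        ax.scatter(sub["pi"], sub["zi"], s=12, label=role,
                   c=colors.get(role, "k"), alpha=0.8)
    ax.axhline(zi_cut, ls="--", c="k", lw=0.8)
    ax.axvline(pi_cut, ls="--", c="k", lw=0.8)
    ax.set_xlabel("Among-module connectivity (Pi)")
    ax.set_ylabel("Within-module connectivity (Zi)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
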