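"""TSV/JSON/GraphML input and output.

OTU tables are read from tab-separated text with OTUs as rows and
samples as columns, or transposed; orientation is auto-detected by
matching the header against the metadata's sample ids.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .preprocess import OTUTable

logger = logging.getLogger(__name__)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("lake", "habitat"):
        if col not in meta.columns:
            raise ValueError(f"metadata file {path} lacks required column {col!r}")
    return meta


def read_otu_table(path, meta: pd.DataFrame) -> OTUTable:
    """Read a count/abundance TSV; orientation auto-detected against the
    metadata sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = set(meta.index)
    cols_match = len(samples & set(df.columns))
    rows_match = len(samples & set(df.index))
    if cols_match >= rows_match and cols_match > 0:
        df = df.T  # file was OTUs x samples
    elif rows_match == 0:
        raise ValueError(
            f"OTU table {path}: neither rows nor columns match metadata sample ids")
    missing = set(df.index) - samples
    if missing:
        raise ValueError(f"OTU table {path}: samples without metadata: "
                         f"{sorted(missing)[:5]}")
    return OTUTable(df, meta.loc[df.index], is_relative=False)


def read_env_table(path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", index_col=0)
    if meta is not None:
        missing = set(meta.index) - set(env.index)
        if missing:
            raise ValueError(f"env table {path}: missing samples {sorted(missing)[:5]}")
    return env


def write_graphml(G: nx.Graph, path, node_attrs: pd.DataFrame | None = None) -> None:
    """GraphML export for external viewers; optional per-node attribute
    table (phylum, enrichment, module, role...) joined on node id."""
    H = G.copy()
    prov = H.graph.pop("provenance", None)
    if prov is not None:
        H.graph.update({f"provenance_{k}": str(v) for k, v in prov.items()})
    if node_attrs is not None:
        for node in H.nodes:
            if node in node_attrs.index:
                for col, val in node_attrs.loc[node].items():
                    if pd.notna(val):
                        H.nodes[node][str(col)] = val if not hasattr(val, "item") \
                            else val.item()
    nx.write_graphml(H, path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if hasattr(x, "item"):
        return x.item()
    if isinstance(x, (set, tuple)):
        return list(x)
    if isinstance(x, pd.DataFrame):
        return x.to_dict()
    return str(x)
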