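"""OTU-table preprocessing: rarefaction, relative abundance, retention
filters, and habitat-enrichment classification.

The analysis operates on paired sediment/water samples from a set of
lakes.  Two retention filters select the OTUs that enter network
construction:

* the *metacommunity* filter keeps OTUs present in both habitats of the
  same lake for at least ``min_lakes`` lakes, with mean relative
  abundance above ``min_ra`` in at least one habitat;
* the *per-habitat* filter keeps OTUs present in at least ``min_lakes``
  samples of one habitat with mean relative abundance above ``min_ra``
  in that habitat.

Both thresholds are strict in the directions the boundary examples
require: lake counts use ``>=``, abundance uses ``>``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HABITATS = ("sediment", "water")


@dataclass
class OTUTable:
    """Abundance matrix (samples x OTUs) with per-sample lake/habitat labels.

    Parameters
    ----------
    data:
        Non-negative matrix, rows indexed by sample id, columns by OTU id.
    meta:
        Per-sample metadata indexed by sample id with columns ``lake``
        and ``habitat`` (values ``"sediment"`` or ``"water"``).  Each
        (lake, habitat) pair occurs at most once.
    is_relative:
        True once rows have been normalised to proportions.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    is_relative: bool = False
    is_subset: bool = False  # OTU subset of a relative table; rows sum to <= 1

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundance matrix contains negative entries")
        missing = self.data.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"samples lacking metadata: {list(missing)[:5]}")
        self.meta = self.meta.loc[self.data.index]
        bad = set(self.meta["habitat"]) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")
        pairs = self.meta[["lake", "habitat"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate (lake, habitat) pair: {dup}")
        if self.is_relative and not self.is_subset:
            sums = self.data.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-abundance rows must sum to 1")

    @property
    def otu_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def samples_of(self, habitat: str) -> pd.Index:
        if habitat not in HABITATS:
            raise ValueError(f"unknown habitat {habitat!r}")
        return self.meta.index[self.meta["habitat"] == habitat]

    def subset_otus(self, otus) -> "OTUTable":
        sub = list(otus)
        shrunk = self.is_relative and len(sub) < self.data.shape[1]
        return OTUTable(self.data[sub], self.meta.copy(), self.is_relative,
                        is_subset=self.is_subset or shrunk)

    def subset_samples(self, samples) -> "OTUTable":
        return OTUTable(self.data.loc[list(samples)], self.meta.loc[list(samples)],
                        self.is_relative, is_subset=self.is_subset)


@dataclass
class EnrichmentLabels:
    """Per-OTU habitat-enrichment call with test statistic and BH-adjusted P."""

    table: pd.DataFrame  # columns: label, statistic, p_raw, p_adjusted
    alpha: float

    def labels(self) -> pd.Series:
        return self.table["label"]

    def counts(self) -> pd.Series:
        return self.table["label"].value_counts()


def rarefy(table: OTUTable, depth: int, seed: int) -> OTUTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning;
    a sample at exactly ``depth`` is returned unchanged (the subsample
    of the full set is the set itself).  Deterministic under ``seed``.
    """
    if table.is_relative:
        raise ValueError("rarefy requires a count table, not relative abundances")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.data.round().astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise ValueError("no samples at depth")
    if len(dropped):
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(dropped), depth, list(dropped),
        )
    rows = {}
    for s in keep:
        row = counts.loc[s].to_numpy()
        if row.sum() == depth:
            rows[s] = row
        else:
            rows[s] = rng.multivariate_hypergeometric(row, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    out = out.loc[keep]
    return OTUTable(out, table.meta.loc[keep].copy(), is_relative=False)


def relative_abundance(table: OTUTable) -> OTUTable:
    """Divide each sample by its total; rows then sum to one."""
    if table.is_relative:
        return table
    totals = table.data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    ra = table.data.div(totals, axis=0)
    return OTUTable(ra, table.meta.copy(), is_relative=True)


def _paired_lakes(table: OTUTable) -> list:
    """Lakes having both a sediment and a water sample."""
    by_lake = table.meta.groupby("lake")["habitat"].agg(set)
    paired = [lake for lake, habs in by_lake.items() if set(HABITATS) <= habs]
    unpaired = [lake for lake, habs in by_lake.items() if not set(HABITATS) <= habs]
    if unpaired:
        logger.warning(
            "%d lake(s) lack one habitat and cannot contribute to the "
            "joint-presence count: %s", len(unpaired), unpaired,
        )
    return paired


def filter_metacommunity(
    table: OTUTable, min_lakes: int = 8, min_ra: float = 1e-4
) -> pd.Index:
    """OTUs present in both habitats of the same lake in >= ``min_lakes``
    lakes, with mean relative abundance > ``min_ra`` in sediment or water.
    """
    if not table.is_relative:
        raise ValueError("metacommunity filter expects a relative-abundance table")
    lakes = _paired_lakes(table)
    if not lakes:
        raise ValueError("no lake has both a sediment and a water sample")
    meta = table.meta
    joint = np.zeros(table.data.shape[1], dtype=int)
    for lake in lakes:
        sed = meta.index[(meta["lake"] == lake) & (meta["habitat"] == "sediment")]
        wat = meta.index[(meta["lake"] == lake) & (meta["habitat"] == "water")]
        present_sed = (table.data.loc[sed] > 0).any(axis=0).to_numpy()
        present_wat = (table.data.loc[wat] > 0).any(axis=0).to_numpy()
        joint += present_sed & present_wat
    mean_sed = table.data.loc[table.samples_of("sediment")].mean(axis=0)
    mean_wat = table.data.loc[table.samples_of("water")].mean(axis=0)
    ok = (joint >= min_lakes) & ((mean_sed > min_ra) | (mean_wat > min_ra)).to_numpy()
    return table.otu_ids[ok]


def filter_habitat(
    table: OTUTable, habitat: str, min_lakes: int = 8, min_mean_ra: float = 1e-4
) -> pd.Index:
    """OTUs nonzero in >= ``min_lakes`` samples of ``habitat`` with mean
    relative abundance (over that habitat's samples) > ``min_mean_ra``."""
    if not table.is_relative:
        raise ValueError("habitat filter expects a relative-abundance table")
    samples = table.samples_of(habitat)
    sub = table.data.loc[samples]
    prevalence = (sub > 0).sum(axis=0)
    mean_ra = sub.mean(axis=0)
    ok = (prevalence >= min_lakes) & (mean_ra > min_mean_ra)
    return table.otu_ids[ok.to_numpy()]


def classify_enrichment(table: OTUTable, alpha: float = 0.05) -> EnrichmentLabels:
    """Call each OTU sediment-, water-, or not-enriched.

    Per OTU, a two-sided Wilcoxon rank-sum (Mann-Whitney U) test compares
    relative abundance between sediment and water samples; P-values are
    BH-adjusted across OTUs and an OTU is labelled with the habitat of
    higher median abundance when adjusted P < ``alpha``.  The test choice
    is a configurable operationalisation (recorded in the output), not a
    quantity with a single canonical definition.
    """
    if not table.is_relative:
        raise ValueError("enrichment test expects a relative-abundance table")
    sed = table.data.loc[table.samples_of("sediment")]
    wat = table.data.loc[table.samples_of("water")]
    if sed.empty or wat.empty:
        raise ValueError("both habitats are required for enrichment testing")
    labels, statistic, p_raw = [], [], []
    sed_m = sed.median(axis=0)
    wat_m = wat.median(axis=0)
    for otu in table.otu_ids:
        x, y = sed[otu].to_numpy(), wat[otu].to_numpy()
        if not (x.any() or y.any()):
            statistic.append(np.nan)
            p_raw.append(1.0)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                u, p = np.nan, 1.0
            else:
                u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        statistic.append(u)
        p_raw.append(p)
    p_raw = np.asarray(p_raw)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    for otu, pa in zip(table.otu_ids, p_adj):
        if pa < alpha and sed_m[otu] != wat_m[otu]:
            labels.append("sediment" if sed_m[otu] > wat_m[otu] else "water")
        else:
            labels.append("none")
    out = pd.DataFrame(
        {"label": labels, "statistic": statistic, "p_raw": p_raw, "p_adjusted": p_adj},
        index=table.otu_ids,
    )
    return EnrichmentLabels(out, alpha=alpha)
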