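"""Synthetic thermokarst-lake community generator.

Emulates the sampling design the downstream analysis assumes: a set of
lakes, each contributing one sediment and one water sample, an OTU count
table rarefied to a common depth, lake-level environmental variables,
planted co-occurrence modules, and habitat-enriched OTUs.

The generative model is a latent-factor copula:

* each planted module ``j`` has a latent driver per sample,
  ``L_j = sum_v c_jv * env_v + eps`` with ``eps ~ N(0, driver_noise_sd)``
  — the coefficients ``c_jv`` couple the module to environmental
  variables and form the ground-truth path structure;
* an OTU's expected abundance is
  ``baseline * exp(s * L_j) * enrichment * gamma_noise`` where
  ``s = module_strength`` scales the shared log-normal lake factor —
  OTUs of one module are co-monotone in the driver, so they are
  rank-correlated (Spearman-detectable) without assuming any particular
  marginal;
* observed counts are a multinomial draw of ``depth`` reads per sample,
  so every row of the count table sums to the rarefaction depth exactly.

Habitat enrichment is a multiplicative fold on expected relative
abundance, not presence/absence: enriched OTUs still occur in both
habitats, which the metacommunity joint-presence filter requires.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import OTUTable

logger = logging.getLogger(__name__)

ENV_VARIABLES = ("pH", "conductivity", "organic_carbon", "TN", "TP")


def _default_env_coupling() -> list:
    # one driving variable per module, cycling through conductivity/TN/TP/pH
    return [
        {"conductivity": 0.6},
        {"TN": 0.6},
        {"TP": 0.6},
        {"pH": 0.6},
    ]


@dataclass
class SynthConfig:
    """Parameters of the synthetic community.

    Defaults mirror the emulated field design: 23 lakes, paired
    sediment/water samples, counts normalised at 27,890 reads per sample.
    """

    n_lakes: int = 23
    n_otus_shared: int = 160
    n_otus_sediment: int = 120
    n_otus_water: int = 120
    n_modules: int = 4
    module_strength: float = 0.8
    enrichment_fold: float = 8.0
    env_coupling: list = field(default_factory=_default_env_coupling)
    depth: int = 27_890
    noise_dispersion: float = 0.25
    driver_noise_sd: float = 0.3
    frac_enriched: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lakes", "n_otus_shared", "n_otus_sediment",
                     "n_otus_water", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.module_strength <= 1.0:
            raise ValueError("module_strength must lie in [0, 1]")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")

    @property
    def n_otus(self) -> int:
        return self.n_otus_shared + self.n_otus_sediment + self.n_otus_water


@dataclass
class GroundTruth:
    """Planted structure of one synthetic community."""

    module_of: dict  # OTU id -> module id ("none" for background OTUs)
    enriched_in: dict  # OTU id -> "sediment" | "water" | "none"
    env_paths: dict  # module id -> {env variable: true coefficient}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"module_of": self.module_of, "enriched_in": self.enriched_in,
             "env_paths": self.env_paths}, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["module_of"], d["enriched_in"], d["env_paths"])


def generate_community(config: SynthConfig):
    """Draw one synthetic community.

    Returns
    -------
    (OTUTable, pandas.DataFrame, GroundTruth)
        The count table (2 x n_lakes samples, each summing to
        ``config.depth``), the per-sample environmental table, and the
        planted ground truth.  Bit-identical for identical config.
    """
    rng = np.random.default_rng(config.seed)
    lakes = [f"L{i + 1:02d}" for i in range(config.n_lakes)]
    samples = [f"{lake}_{hab}" for lake in lakes for hab in ("sediment", "water")]
    meta = pd.DataFrame(
        {"lake": [s.rsplit("_", 1)[0] for s in samples],
         "habitat": [s.rsplit("_", 1)[1] for s in samples]},
        index=pd.Index(samples, name="sample"),
    )

    # lake-level environment; organic carbon is habitat-specific
    # (SOC measured in sediment, DOC in water), so it is drawn per sample
    env = pd.DataFrame(index=meta.index, columns=ENV_VARIABLES, dtype=float)
    lake_vals = {v: dict(zip(lakes, rng.standard_normal(config.n_lakes)))
                 for v in ENV_VARIABLES if v != "organic_carbon"}
    for v, vals in lake_vals.items():
        env[v] = meta["lake"].map(vals)
    oc = {}
    for hab in ("sediment", "water"):
        draws = dict(zip(lakes, rng.standard_normal(config.n_lakes)))
        for lake in lakes:
            oc[f"{lake}_{hab}"] = draws[lake]
    env["organic_carbon"] = pd.Series(oc)

    # module drivers: linear in the environment plus lake-level noise
    module_ids = [f"M{j + 1}" for j in range(config.n_modules)]
    coupling = list(config.env_coupling)
    while len(coupling) < config.n_modules:
        coupling.append({})
    drivers = pd.DataFrame(index=meta.index, columns=module_ids, dtype=float)
    env_paths = {}
    for j, mod in enumerate(module_ids):
        coefs = coupling[j] if isinstance(coupling[j], dict) else {}
        env_paths[mod] = dict(coefs)
        lin = np.zeros(len(samples))
        for v, c in coefs.items():
            lin += c * env[v].to_numpy()
        eps = dict(zip(lakes, rng.normal(0.0, config.driver_noise_sd, config.n_lakes)))
        lin += meta["lake"].map(eps).to_numpy()
        drivers[mod] = lin

    # OTU roster: shared OTUs carry the planted modules; habitat pools are
    # background diversity only present (mostly) in one habitat
    otu_ids, module_of, enriched_in = [], {}, {}
    n_sh, n_se, n_wa = config.n_otus_shared, config.n_otus_sediment, config.n_otus_water
    per_mod = n_sh // (config.n_modules + 1)  # leave a background share
    k = 0
    for j, mod in enumerate(module_ids):
        for _ in range(per_mod):
            oid = f"OTU{k + 1:04d}"
            otu_ids.append(oid)
            module_of[oid] = mod
            k += 1
    while k < n_sh:
        oid = f"OTU{k + 1:04d}"
        otu_ids.append(oid)
        module_of[oid] = "none"
        k += 1
    for pool, hab in ((n_se, "sediment"), (n_wa, "water")):
        for _ in range(pool):
            oid = f"OTU{k + 1:04d}"
            otu_ids.append(oid)
            module_of[oid] = "none"
            k += 1

    # enrichment: a fraction of shared OTUs get a habitat fold; the
    # habitat pools are strongly skewed to their own habitat
    shared = otu_ids[:n_sh]
    n_enriched = int(round(config.frac_enriched * n_sh))
    enriched_idx = rng.choice(n_sh, size=n_enriched, replace=False)
    enriched_hab = rng.choice(["sediment", "water"], size=n_enriched)
    for oid in otu_ids:
        enriched_in[oid] = "none"
    for i, hab in zip(enriched_idx, enriched_hab):
        enriched_in[shared[i]] = hab

    # expected abundances
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_otus)
    expected = np.tile(baseline, (len(samples), 1))
    hab_arr = meta["habitat"].to_numpy()
    for i, oid in enumerate(otu_ids):
        mod = module_of[oid]
        if mod != "none":
            expected[:, i] = expected[:, i] * np.exp(
                config.module_strength * drivers[mod].to_numpy())
        lab = enriched_in[oid]
        if lab != "none":
            expected[hab_arr == lab, i] *= config.enrichment_fold
    # habitat pools: heavily favoured in their own habitat but never absent,
    # emulating taxa that dominate one habitat
    sed_cols = slice(n_sh, n_sh + n_se)
    wat_cols = slice(n_sh + n_se, config.n_otus)
    expected[hab_arr == "water", sed_cols] *= 0.02
    expected[hab_arr == "sediment", wat_cols] *= 0.02

    shape = 1.0 / config.noise_dispersion
    noise = rng.gamma(shape, scale=1.0 / shape, size=expected.shape)
    expected *= noise

    probs = expected / expected.sum(axis=1, keepdims=True)
    exp_counts = probs * config.depth
    frac_rare = float((exp_counts.mean(axis=0) < 1.0).mean())
    if frac_rare > 0.5:
        warnings.warn(
            f"depth {config.depth} is small for {config.n_otus} OTUs: "
            f"{frac_rare:.0%} have expected mean count < 1", stacklevel=2)

    counts = np.vstack([
        rng.multinomial(config.depth, probs[i]) for i in range(len(samples))
    ])
    table = OTUTable(
        pd.DataFrame(counts, index=meta.index, columns=otu_ids),
        meta, is_relative=False,
    )
    return table, env, GroundTruth(module_of, enriched_in, env_paths)


def write_community(outdir, table: OTUTable, env: pd.DataFrame,
                    truth: GroundTruth) -> None:
    """Write OTU table (OTUs x samples TSV), metadata, env table and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = table.data.T
    df.index.name = "otu_id"
    df.to_csv(outdir / "otu_table.tsv", sep="\t")
    table.meta.to_csv(outdir / "metadata.tsv", sep="\t")
    env.round(6).to_csv(outdir / "env.tsv", sep="\t")
    truth.to_json(outdir / "ground_truth.json")
    logger.info("wrote synthetic community to %s", outdir)
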