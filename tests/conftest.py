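import numpy as np
import pandas as pd
import pytest

import thermonet as tn


@pytest.fixture(scope="session")
def small_community():
    """A fast synthetic community: fewer OTUs, shallower depth."""
    cfg = tn.SynthConfig(
        n_lakes=23, n_otus_shared=80, n_otus_sediment=30, n_otus_water=30,
        depth=5000, seed=11,
    )
    table, env, truth = tn.generate_community(cfg)
    return cfg, table, env, truth


@pytest.fixture(scope="session")
def strong_community():
    """Strong planted-module signal, minimal confounds, for recovery checks."""
    cfg = tn.SynthConfig(
        seed=7, module_strength=0.95, noise_dispersion=0.05,
        frac_enriched=0.0, n_otus_sediment=2, n_otus_water=2,
    )
    table, env, truth = tn.generate_community(cfg)
    return cfg, table, env, truth


@pytest.fixture
def tiny_table():
    """Hand-built 3-lake paired table for filter boundary checks."""
    samples = [f"L{i}_{h}" for i in range(1, 4) for h in ("sediment", "water")]
    meta = pd.DataFrame(
        {"lake": [s.split("_")[0] for s in samples],
         "habitat": [s.split("_")[1] for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    data = pd.DataFrame(
        [[10, 30, 60], [20, 30, 50], [5, 5, 90],
         [10, 10, 80], [0, 50, 50], [25, 25, 50]],
        index=meta.index, columns=["otu1", "otu2", "otu3"],
    )
    return tn.OTUTable(data, meta)
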