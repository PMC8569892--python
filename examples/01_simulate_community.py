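"""Generate a synthetic paired sediment/water community.

Draws an OTU count table for 23 lakes (one sediment and one water
sample each, 27,890 reads per sample), lake-level environmental
variables, and the planted ground truth: which OTUs form co-occurrence
modules, which are habitat-enriched, and how each module couples to the
environment.
"""

import thermonet as tn

cfg = tn.SynthConfig(seed=1)
table, env, truth = tn.generate_community(cfg)

print(f"samples x OTUs: {table.data.shape}")
print(f"reads per sample: {sorted(set(table.data.sum(axis=1)))}")
habitats = {str(k): int(v) for k, v in table.meta["habitat"].value_counts().items()}
print(f"habitats: {habitats}")

import pandas as pd
planted = pd.Series(truth.module_of).value_counts()
print(f"planted module sizes: { {str(k): int(v) for k, v in planted.items()} }")
enriched = pd.Series(truth.enriched_in).value_counts()
print(f"enrichment labels: { {str(k): int(v) for k, v in enriched.items()} }")
print(f"module -> environment couplings: {truth.env_paths}")

# Every sample sums to the rarefaction depth exactly, so downstream
# relative abundances are directly comparable across samples.  The
# "none" module OTUs are background diversity with no planted structure.
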