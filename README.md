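# thermonet

Co-occurrence network analysis for paired sediment/water microbiome
surveys of thermokarst (permafrost-thaw) lakes — and for any study
design where each site contributes one sample from each of two
habitats.

Bacterial communities in lake sediment and water are taxonomically
distinct but tightly linked. Beyond composition, the *structure* of
their co-occurrence networks — how clustered, modular and centralised
the web of taxon–taxon associations is, which taxa act as hubs or
connectors, and how network modules respond to the environment — tells
us how these communities assemble and how vulnerable they may be to
environmental change. `thermonet` implements that entire analysis as a
tested, reusable Python library:

- **Preprocessing** — rarefaction to a fixed depth, relative
  abundances, the two OTU-retention filters (joint sediment+water
  presence in ≥ 8 lakes for the metacommunity network; per-habitat
  prevalence ≥ 8 lakes with mean relative abundance > 0.01% for the
  habitat networks), and Wilcoxon/BH habitat-enrichment calls.
- **Network construction** — all-pairs Spearman correlation of OTU
  relative abundances, Benjamini–Hochberg adjustment, and edge
  retention at |R| > 0.80 and adjusted P < 0.01 (both strict).
- **Topology panel** — average degree 2m/n, average path length over
  connected pairs, diameter, mean local clustering, Freeman degree and
  betweenness centralization, modularity.
- **Null model** — uniform Erdős–Rényi G(n, m) ensembles with the same
  node and edge counts; each observed metric is scored with a Z-test
  `Z = (obs − mean)/SD` against the ensemble.
- **Modules and keystones** — modularity-maximising module detection,
  major modules (> 10 nodes), within-module degree z-score
  Zi = (k_is − mean_s)/sd_s and participation coefficient
  Pi = 1 − Σ_t (k_it/k_i)², and the four-way role classification at
  Zi ≥ 2.5 / Pi ≥ 0.62 (peripheral, module hub, connector, network hub).
- **Environment–module–community linkage** — Bray–Curtis β-diversity
  per module and for the whole community, pairwise environmental
  distances, and a two-layer piecewise path model (env distances →
  module β-diversity → community β-diversity) with standardized path
  coefficients and optional Mantel-style permutation P-values.
- **Synthetic communities** — a latent-factor generator that plants
  co-occurrence modules, habitat-enriched OTUs and environment–module
  coupling in a 23-lake, 2-habitat, 27,890-reads-per-sample design, so
  every stage of the pipeline is testable without sequencing data.

## Worked example

```python
import thermonet as tn

table, env, truth = tn.generate_community(tn.SynthConfig(seed=1))
ra = tn.relative_abundance(table)
kept = tn.filter_metacommunity(ra)          # joint-presence filter
G = tn.correlation_network(ra, otu_set=kept)
part = tn.detect_modules(G)
print(tn.network_summary(G, partition=part).to_dict())
```

prints (seed 1):

```
{'n_nodes': 207, 'n_edges': 2390, 'average_degree': 23.092,
 'average_path_length': 2.224, 'diameter': 5.0,
 'clustering_coefficient': 0.321, 'centralization_degree': 0.147,
 'centralization_betweenness': 0.020, 'modularity': 0.308}
```

207 of the filtered OTUs carry at least one strong, significant
association; comparing the same panel against a 199-replicate
G(207, 2390) ensemble (`tn.compare_to_null`, see
`examples/03_null_model.py`) shows clustering 0.321 vs 0.112 ± 0.002
and modularity 0.308 vs 0.157 ± 0.004 — the synthetic community, like a
real one, is far more clustered and modular than random. The
`examples/` directory walks through each capability (simulation,
networks, null models, keystone roles, path models) as a short runnable
script; `thermonet --help` exposes the same pipeline as a command-line
tool (`simulate`, `nulls`, `all`).

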