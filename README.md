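# mycorrnet

Community-scale analysis of below-ground plant–fungus association networks
from root metabarcoding count tables.

Root-tip surveys recover, for each root sample, a host-plant identity and a
vector of fungal OTU read counts.  Ecologists ask how the resulting
bipartite plant–fungus networks are organized: how host-specific the
associations are, whether specialists interact with subsets of the partners
of generalists ("nested" architecture, the norm in pollination networks),
and how fungal host ranges are partitioned — and how these properties vary
across fungal functional guilds (arbuscular mycorrhizal, ectomycorrhizal,
saprotrophic/endophytic, pathogenic) and across forests.  A recurring
finding for below-ground networks is the opposite of the pollination
pattern: *anti-nested* architecture, with nestedness scores below the null
expectation.

`mycorrnet` implements the full pipeline:

* **Preprocessing** of sample × OTU count tables: a per-sample 0.1%
  rare-entry filter, rarefaction to 1000 reads per sample (multivariate
  hypergeometric), equalization to 240 samples per forest, and analytic
  species-accumulation curves.
* **Network construction**: species-level plant × OTU matrices whose cells
  count samples exhibiting each association, partitioned into seven
  categories (ALL, AM, AM.ex, ECM, EcM.ex, SAPENDO, PATHO) by fungal guild
  and plant mycorrhizal type; bipartite betweenness centralities for
  visualization.
* **Structural indices**: connectance; network-level interaction
  specificity H2′ = (H2_max − H2)/(H2_max − H2_min) on the interaction
  entropy, with marginal-constrained extremes; weighted NODF nestedness
  (0–100); and the checkerboard C-score,
  C̄ = mean over OTU pairs of (r_i − S_ij)(r_j − S_ij).
* **Null models**: host-label-shuffle randomizations (plant labels permuted
  across samples, OTU counts untouched) and relative indices

      relative index = (I_observed − mean(I_null)) / SD(I_null),

  with |relative index| ≳ 2 marking structure beyond chance and negative
  relative nestedness the anti-nested signature.
* **Cross-forest comparison**: per-index ANOVA (covariates: plant-taxon
  count, OTU count, connectance; factors: locality, network category;
  sequential SS, Bonferroni over terms) and correlation-matrix PCA of seven
  network properties.
* **A synthetic-data generator** emulating the multi-forest sampling design
  with tunable host specificity, guild structure, nestedness and read
  noise — every statistical property of the pipeline is testable without
  external data.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(8 forests, 300 root samples collected per forest, 17–30 plant taxa per
forest, 360 fungal OTUs across the five guilds):

```bash
python analysis/01_simulate_dataset.py   # writes scratch/data/
python analysis/02_preprocess.py         # filter + rarefy + equalize
python analysis/03_network_indices.py    # observed indices per category
python analysis/04_null_models.py        # null ensembles, relative indices
python analysis/05_compare_networks.py   # ANOVA + PCA
```

Step 02 reports every forest rarefied to exactly 1000 reads per sample with
up to 240 samples retained, e.g.:

```
forest_1: 300 -> 240 samples, all at 1000 reads; expected richness at full depth 263 OTUs
```

Step 04 prints the relative indices of each forest's ALL network, e.g.:

```
forest_1 ALL: rel H2'=68.1 rel wNODF=-33.0 rel C-score=35.2
...
8/8 forests show anti-nested (rel wNODF < 0) ALL networks
```

Read: associations are far more host-specific than chance (relative H2′ ≫
2), nestedness is far *below* the label-shuffle null (anti-nested), and
fungal host ranges are more differentiated than chance (relative C-score >
2) — under the default generative regime of moderate host specialization.
Step 05 then fits the ANOVA models (locality df 7, category df 6, covariate
df 1 each) and the correlation PCA (PC1 carries 53.7% of the variance in
this run); small result tables land under `results/`, large regenerable
inputs under `scratch/`.

The library surface mirrors the scripts, e.g.:

```python
from mycorrnet import (SyntheticConfig, generate_dataset, PreprocessParams,
                       preprocess, relative_index_for)

tables, otus, plants, truth = generate_dataset(SyntheticConfig(seed=1))
t = preprocess(tables[0], PreprocessParams(seed=2))
rel = relative_index_for(t, otus, plants, "ALL", "wnodf", n_perm=1000, seed=3)
print(rel.observed, rel.null_mean, rel.z)
```

A thin CLI (`mycorrnet simulate/preprocess/build/metrics/nulls/compare`)
wraps the same functions for shell use.

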