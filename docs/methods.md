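# Methods

`mycorrnet` analyzes community-scale structure of below-ground plant–fungus
association networks inferred from root metabarcoding count tables.  This
note documents the models and procedures, the parameters that matter, the
synthetic data generator used throughout the test suite, and the numerical
choices made where the design was open.

## Data model

The pipeline moves through two matrix representations per forest:

* **Sample-level table** — samples (terminal root segments) × fungal OTUs,
  integer read counts, with one host-plant label per sample.  This is the
  unit on which quality filtering, rarefaction and the null model's label
  shuffling operate.
* **Species-level matrix** — plant species/taxa × fungal OTUs, where a cell
  counts the *samples* in which the association was observed (presence
  semantics: one read and 999 reads contribute equally).  All structural
  indices are computed here.

Annotations are exclusive categories: each OTU carries one functional guild
from {AM, ECM, SAPENDO, PATHO, UNKNOWN}; each plant one mycorrhizal type from
{AM_PLANT, ECM_PLANT, NM_PLANT, DUAL}.  Free-text guild strings are resolved
by the precedence ECM > AM > PATHO > SAPENDO (combined saprotroph/endophyte
annotations pool into SAPENDO); blank or uninformative strings map to
UNKNOWN, anything else unrecognized is rejected.

## Sample-level preprocessing

1. **Rare-entry filter** (`entry_fraction_threshold`, default 0.001): a cell
   is zeroed iff it holds strictly less than 0.1% of its sample's pre-filter
   read total.  Such rare entries typically stem from soil carry-over or
   PCR/sequencing error.  "Less than" is a strict inequality; cells exactly
   at the threshold survive.  Columns that become all-zero are retained at
   this stage — dropping them is deferred to network construction so that
   label shuffling on the sample table stays well defined.
2. **Rarefaction** (`rarefaction_depth`, default 1000 reads): each sample's
   reads are subsampled without replacement (multivariate hypergeometric) to
   the common depth; samples below depth are dropped.
3. **Sample-count equalization** (`samples_per_forest`, default 240): a
   uniform draw without replacement equalizes sampling effort across
   forests.  The pipeline wrapper retains min(240, #samples at depth) — if
   fewer samples survive rarefaction than requested, all survivors are kept
   with a warning; the bare subsampling operation, by contrast, treats a
   shortfall as an error.

Accumulation curves use the analytic expectation over equiprobable sample
subsets, E[S_k] = Σ_i [1 − C(N−n_i, k)/C(N, k)], computed with exact integer
binomials; this makes the curve deterministic (random-permutation averaging
would converge to the same values).

## Structural indices

* **Connectance** — fraction of nonzero cells of the (pruned) species
  matrix.
* **H2′ interaction specificity** — the Shannon entropy H2 of the
  interaction proportions, rescaled between the extremes achievable by
  integer matrices with the observed marginal totals:
  H2′ = (H2_max − H2)/(H2_max − H2_min), clipped to [0, 1].  0 is maximal
  generalization, 1 maximal specialization.  Entropies are in nats (H2′ is
  scale-invariant, so the base cancels).
* **Weighted NODF nestedness** (0–100) — over every ordered pair with
  strictly larger marginal total in the "richer" line, the pair score is 100
  times the fraction of the poorer line's positive cells that are positive
  and *strictly smaller* than the richer line's corresponding cells; tied
  marginal totals score 0.  The index is the mean over all row pairs and all
  column pairs.  Note that any 0/1 matrix scores 0 under the weighted rule —
  values, not just incidences, must be nested.
* **Checkerboard C-score** — on the binarized matrix, the mean over
  unordered OTU pairs of C_ij = (r_i − S_ij)(r_j − S_ij), with r the host
  counts and S the shared-host count.  The raw (un-normalized) mean is used;
  only null-standardized values are interpreted, so the normalization
  cancels.  C is zero exactly when every OTU pair has nested host sets
  (identical sets being the extreme case), and grows with host-range
  differentiation.

### Entropy extremes for H2′

The marginal-constrained extremes are found heuristically and validated in
the test suite against exhaustive enumeration of all integer matrices with
the given marginals (3×3, totals ≤ 12, agreement within 0.02):

* **Maximum**: start from the real-valued independence expectations
  r_i·c_j/m, round by largest remainder under both marginal constraints
  (stranded deficits are closed by a transportation fill), then refine by
  exact search over improving 2×2 swaps until a local maximum.  The swap
  search is quadratic in the cell count per pass and is skipped above 100
  cells,
  where integer granularity is fine relative to the totals and
  largest-remainder rounding is already entropy-tight; because observed and
  null matrices are treated identically, any residual rounding bias cancels
  in the relative index.
* **Minimum**: greedy concentration — repeatedly place
  min(remaining row total, remaining column total) at the currently largest
  marginals.

Marginals that admit a single entropy value (H2_max = H2_min) make H2′
undefined; this is reported as missing-with-reason, never coerced to a
number.

## Null model and relative indices

Null ensembles shuffle host-plant labels uniformly across samples within a
forest, leaving every sample's OTU counts untouched, then rebuild the
species matrix and recompute the index.  This preserves per-sample read
totals, per-OTU prevalence, and the number of samples per plant — the null
keeps everything except the coupling between fungal composition and host
identity.  Observed indices are standardized as

    relative index = (I_observed − mean(I_null)) / SD(I_null)

with the sample (n−1) standard deviation (fixed by a regression test).
Relative values above/below about ±2 indicate structure beyond chance;
negative relative nestedness is the "anti-nested" signature.  Ensemble sizes
default to 1000 randomizations for H2′ and weighted NODF and 100 for the
costlier checkerboard score (the analysis scripts and acceptance script use
200/200/50; see *Problem sizes* below).

For the plant-filtered categories (AM_EX, ECM_EX) the default scope shuffles
labels on the **full** table first and applies the category's plant/OTU
selection to the randomized data, so the null conditions on shuffled
identities; a `within-category` scope (restrict first, then shuffle) is
available as a switch.  Each metric draws its own ensemble; degenerate
randomized matrices are skipped and counted, and an ensemble with more than
half of its randomizations degenerate is rejected.  Every permutation index
derives its own child RNG from (seed, metric, index), so ensembles are
reproducible regardless of sample order or execution order.

## Network categories

ALL (every OTU and plant), AM / ECM / PATHO / SAPENDO (columns restricted to
one guild, all plants), AM_EX (AM fungi × AM-compatible plants: AM_PLANT and
DUAL), ECM_EX (ECM fungi × ECM_PLANT and DUAL).  DUAL plants — documented
hosts of both symbiosis types — are retained in both exclusive categories;
plants lacking an annotation are conservatively treated as non-mycorrhizal
for exclusion purposes (with a warning).  After selection, all-zero rows and
columns are pruned; a result with fewer than 2 plants or 2 OTUs is flagged
degenerate and downstream indices refuse it.

## Cross-forest comparison

For each relative index, an ANOVA linear model partitions variation among
the number of plant taxa, the number of fungal OTUs, connectance, locality
(forest, a factor) and network category (a factor).  Sums of squares are
sequential (type I) in that fixed term order; a drop-one (type II) variant
is available, and the degrees of freedom — 1 per covariate, n_forests − 1,
n_categories − 1 — are identical under both.  P-values are
Bonferroni-corrected over the five terms within each response's model.
Because formula interfaces reorder categorical terms ahead of covariates,
the design matrix is built from explicitly ordered blocks and fitted with
nested OLS models.  Rows with any missing model variable are dropped
listwise per response.

The PCA operates on the correlation matrix (all seven variables standardized
to zero mean, unit variance): relative H2′, relative wNODF, relative
C-score, plant-taxon count, OTU count, fungus/plant ratio and connectance.
Components are ordered by decreasing eigenvalue with a deterministic sign
convention (largest-magnitude loading positive).

## Synthetic data generator

The generator emulates a multi-forest root-tip survey: per forest, a fixed
number of samples is collected; each sample belongs to one host plant drawn
from a geometric rank-abundance distribution (a few dominant hosts, many
rare — matching uneven root sampling); read totals are negative-binomially
over-dispersed (mean 1500, shape 10 by default) so the rarefaction drop path
is exercised; reads follow a plant-conditional multinomial over the OTU
pool; and Poisson contamination (default 2 spurious single-read entries per
sample, drawn uniformly from the pool) exercises the 0.1% filter.  The
default pool holds 1200 OTUs (AM 150, ECM 250, SAPENDO 350, PATHO 20,
UNKNOWN 430) — saprotroph/endophyte-rich, with pathogens deliberately
scarce — and the default design is 8 forests × 383 samples with 17–55 plant
taxa per forest from a shared pool of 80.

Each forest hosts only a Bernoulli subset of the OTU pool
(`otu_occupancy`, default 0.7), so per-forest richness varies and community
composition turns over between forests — without this metacommunity
turnover, per-category OTU counts would be identical across forests and the
cross-forest ANOVA design would be degenerate (the OTU-count covariate
exactly collinear with the category factor).

The plant × OTU affinity matrix composes:

* a **guild-compatibility mask** (AM fungi ↔ AM/DUAL plants, ECM fungi ↔
  ECM/DUAL plants, other guilds ↔ all plants), softened by
  `guild_leakage_eps` (default 0.05) for out-of-guild associations;
* **OTU generalism weights**: a power law rank^(−γ) on a per-forest random
  ranking, normalized to mean 1; each plant applies its own steepness
  multiplier to the shared ranking, with heterogeneity scaling as (γ − 1) ×
  U(0.5, 1.5) — at the default γ = 1 all plants share one mild ranking,
  while steeper regimes spread plants over ordered breadths (nested partner
  sets over common generalists);
* **host-specificity draws**: Dirichlet-style gamma preferences whose
  per-OTU concentration is `specialization_alpha` × `concentration_scale`
  (default 10) × the plant's generalism weight.  Aligning concentration with
  the weights makes small α concentrate each plant on few idiosyncratic
  OTUs (specialized, anti-nested) while large α approaches the shared
  profile.  The scale of 10 places the α ∈ {0.1, 1, 10} range used in the
  recovery experiments on well-separated specialization regimes;
* an optional **block mask** (`block_structure`, 4 compartments by default,
  cross-block weight 0.02): plants and OTUs confined to compartments — the
  regime that produces anti-nested, host-differentiated networks.

An *exchangeable* variant replaces all plant rows by a single shared
affinity vector (ignoring the compatibility mask, and unaffected by α), so
fungal composition is independent of host identity and the label-shuffle
null is exactly true; it is the calibration harness for the relative
indices.

What the generator deliberately does **not** emulate: sequence-level error
and chimeras, OTU clustering artifacts, phylogenetic signal in host
affinity, spatial autocorrelation among samples, and shared community
composition across forests (each forest draws independent affinities).
Passing tests therefore demonstrate the pipeline's statistical behavior
under the stated generative assumptions, not robustness to upstream
bioinformatic error.

## Problem sizes and runtime choices

The package's experiments are sized to run comfortably on one CPU:

* Null calibration: 200 replicate exchangeable datasets, each 383 collected
  → 240 retained samples, 20 plant taxa, 300 OTUs, ensembles of 200 (H2′,
  wNODF) and 50 (C-score).
* Structure recovery: 50 replicates per regime at 240 collected → 150
  retained samples, 16 plant taxa, 200 OTUs, ensembles of 100/100/50.
* The analysis scripts and `scripts/acceptance.py` run the full 8-forest
  study at 300 collected samples per forest, 17–30 plant taxa, 360 OTUs and
  ensembles of 200/200/50.

The calibration experiment measures, under the exchangeable generator, the
fraction of replicates with |relative index| < 2 (expected ≈ 95% for each
metric) and the replicate mean (expected 0; the mean estimate carries
Monte-Carlo error of about sd/√200 ≈ 0.08, which the test accounts for via
a confidence-interval bound rather than a point assertion).

## Known limitations

* The H2′ extremes are heuristic; the exhaustive validation covers small
  matrices only, and for very large, sparse matrices the skipped swap
  refinement can leave H2_max marginally below the true integer maximum
  (consistently for observed and null matrices alike).
* The weighted NODF implementation materializes an n²·m comparison tensor
  per orientation; for matrices far larger than this study's (thousands of
  rows *and* columns) a blocked implementation would be needed.
* Network modularity and the r2dtable/vaznull fixed-marginal randomizations
  are out of scope; the label-shuffle null is the only randomization
  implemented.
* PATHO partial networks are small by design (pathogen annotations are
  scarce); their indices and relative values are reported but carry wide
  uncertainty, and degenerate cases are flagged as missing.
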