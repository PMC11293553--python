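# Methods

This note documents the models, parameter defaults and design decisions of
the `panmgas` pipeline: what each stage assumes, where the defaults come
from, and what the synthetic benchmark does and does not demonstrate.

## Quantification of MSP abundances

Input is an integer matrix of catalog-gene counts per sample, taken as
given (upstream read mapping and multi-mapping normalization are out of
scope). Samples are rarefied to a common target depth by sampling reads
without replacement (multivariate hypergeometric), which conserves totals
exactly and never increases a count; samples below the target are excluded.
The reference depth is 10,000,000 reads; the synthetic benchmark runs at
10,000–100,000 reads, which preserves every algorithmic property at desk
scale. Each sample's rarefaction stream is seeded from (global seed, sample
id), so results are independent of column order.

The abundance of an MSP is the mean count of its marker genes — the genes
that correlate the most altogether across samples, at most 100 per species.
Two declared choices where the estimator's definition is open:

- the mean includes zero-count markers (it is the mean of the full marker
  vector; sparse detection is handled by the zero rule);
- "fewer than 10% of markers seen" zeroes the MSP; a fraction exactly at
  10% is kept (the rule is a strict `<`).

`select_markers` re-derives markers from data by ranking genes on their mean
Spearman correlation to all other member genes (ties lexicographic;
constant genes contribute correlation 0). Relative abundance divides each
column by its sum; all-zero columns are preserved and flagged.

## Pan-metagenomics association

For each MSP in each disease cohort versus its country-matched healthy
controls, both one-sided Wilcoxon rank-sum tests are computed. The p-value
is exact (enumeration) when N ≤ 25 without ties, otherwise the normal
approximation with tie and continuity correction. The effect size is
ES = Φ⁻¹(1 − p)/√N, so p > 0.5 yields a negative Z and the statistic is
signed and symmetric under group exchange. Calls use ES ≥ 0.3 (the
conventional "medium" effect). Declared choices:

- only MSPs with nonzero abundance in ≥ 5 samples of the combined
  case+control group are tested (a full-tie test carries no information);
  skipped MSPs are listed;
- no multiple-testing adjustment in the calling path (the threshold is on
  ES, not p); Benjamini–Hochberg-adjusted p-values are emitted as extra
  columns for inspection;
- one healthy cohort may serve as control for several disease cohorts of
  the same country; the pairing is explicit and defaults to
  first-healthy-cohort-per-country.

Cross-cohort frequency labels: with e enriched and d depleted calls, a
species is `common_enriched` iff e + d ≥ 3 and e − d ≥ 2, `common_depleted`
iff e + d ≥ 3 and e − d ≤ −2. The predicate is tested exhaustively.

## Co-conserved functional clusters

Terms (not genes) are the unit: a species carries a term when any of its
genes is annotated with it. Pairwise Jaccard of carrier sets ≥ 0.75
(inclusive) defines the co-occurrence network; all annotation categories
share one network. Communities come from the walktrap algorithm at the
customary 4 random-walk steps; size-1 connected components are reported as
singletons. Determinism follows from canonical lexicographic node ordering.
MSP association requires carrying strictly more than 75% of a cluster's
terms; representativeness requires strictly more than 3 associated species
(the association-rule carrier count, the stricter of the two readings of
"found in more than three species").

## Cluster–disease projection

Per cluster × cohort × direction, a hypergeometric upper tail
P(X ≥ k) with population N = the MSPs actually tested in that cohort (the
sampling frame of the calls — the catalog would overstate the population),
K = the cluster's associated MSPs within it, n = the called set, k the
overlap. Only clusters with K ≥ 10 are tested; significance is strict
p < 10⁻⁴; enriched and depleted directions are tested separately. The same
frequency rule as above labels clusters across cohorts.

## Regional enrichment

z(m, g) = (mean_g − mean_all) / denom per MSP and country (or region
group). The headline definition uses only the difference of means; this
implementation standardizes by the standard error sd_all/√n_g so countries
of different sizes are comparable, with `sd` and `none` denominators
available (`--z-denominator`). Zero-variance MSPs get z = 0; countries with
fewer than 2 samples are excluded. Top-k (default 100) over-represented
MSPs per region group feed the gene-content profile: annotated genes of all
top-list species are counted per term within the chosen categories, each
group's counts are normalized to sum 1, and the 18 largest signed
differences (western − nonwestern) are reported. Including *all* genes of
the top-k species is a deliberate, transparent replacement for an
ambiguous cumulative-sum filter; k and the difference count are
configurable.

## Proportionality

ρ(a,b) = 1 − var(y_a − y_b)/(var y_a + var y_b) on y = log(x + δ), with
δ = half the smallest nonzero value of the filtered matrix (zeros must be
lifted before the log; the choice is logged and configurable). ρ is
computed on per-sample relative abundances; a centered-log-ratio option
exists but defaults off — results depend on this choice and it is recorded
in output metadata. Prevalence filter: strictly more than 50 samples with
nonzero abundance. Network edges require strictly ρ > 0.65. The permutation
FDR shuffles every species' sample order independently (destroys all
between-species association, preserves margins):
FDR(t) = mean permuted edge count at ρ ≥ t / observed count.

## Classification and biomarkers

Balanced design: equal case/control group sizes by seeded subsampling of
the larger group; features are relative abundances of all MSPs. Stratified
70/30 split; per-feature standardization is fit on the training split only
(fitting the scaler before splitting would leak test information; the
scaler choice does not affect forests but keeps the protocol clean for any
estimator). Random forest with 500 trees, unlimited depth, √p feature
subsampling, fixed seed. AUROC is reported on the untouched test split, and
optionally on an external cohort (features aligned by MSP id, absent MSPs
imputed as 0, with a repeated balanced-resampling mean ± sd variant).

Feature attributions are additive per-sample decompositions of each tree's
predicted disease probability along the sample's decision path (the change
in node value at every split is credited to the split feature), averaged
over the forest. They satisfy local accuracy exactly — base value plus
attributions equals the predicted probability — which the tests assert to
1e-6. The directional biomarker score is
D(f) = sign(Spearman(feature values, attributions)) × mean|attribution|,
with sign 0 for constant vectors. Hyperparameter tuning is deliberately
omitted; the fixed settings above define the protocol.

## Synthetic-data generator

The generator emulates a multi-cohort stool metagenome compendium:

- **Species abundances**: per sample, baseline MSP abundance ~
  LogNormal(μ = 0, σ = 1.5). σ = 1.5 spreads 30 species over roughly three
  orders of magnitude, matching the long-tailed rank-abundance profiles of
  real gut communities.
- **Planted effects**: disease effects multiply the baseline of matching
  samples by a fold-change before renormalization (so compositional closure
  is part of the simulation, exactly as in real relative-abundance data);
  region effects work the same way keyed on region class or country.
- **Reads**: total depth ~ LogNormal (default mean ≈ 100,000, truncated
  below at 10,000 so the depth-exclusion rule is exercisable), allocated
  multinomially over genes uniformly within each species — no gene-length
  bias, the simplest model consistent with the marker-mean estimator.
- **Annotations**: planted term blocks give every member species one gene
  per term (perfect within-block co-conservation, Jaccard 1); background
  terms are sprinkled independently per species at a configurable rate.

What it does **not** model: strain-level variation, gene length and GC
biases, batch/technology effects, correlated species (beyond planted
fold-changes), intervention or longitudinal structure. Passing recovery
tests therefore demonstrates algorithmic correctness and calibration under
a clean compositional noise model — not robustness to real-world batch
structure.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at desk scale:
30–210 species, 20–100 genes per species, 60–300 samples, depths of
10⁴–10⁵ reads, 10–20 replicates per property — sizes chosen so the full
chain, including a 500-tree forest and exhaustive oracles, completes in
minutes while every threshold and boundary of the reference configuration
is exercised. All randomness descends from one integer seed through
CRC-derived per-stage substreams, making every output byte-reproducible.
Ties are broken lexicographically throughout (marker ranking, community
ordering, top-k lists), degenerate inputs (all-zero columns, constant
features, zero-variance species, empty call sets) take defined, logged
values rather than NaNs, and strict-versus-inclusive threshold boundaries
follow the reference rules exactly: Jaccard ≥, ES ≥, coverage >,
representative >, prevalence >, ρ >, significance <, marker detection <.

## Known limitations

- Under the σ = 1.5 noise model, a fold-change-4 species at n = 60/60 has
  per-test power ≈ 0.9 at ES ≥ 0.3, so joint recovery of many planted
  species in a single replicate is materially below 1, and with hundreds of
  null species occasional false calls at |Z| ≥ 3.3 are expected — the
  thresholded call sets are calibrated, not infallible. Analogously,
  held-out AUROC for five fold-4 species plateaus near 0.85–0.9 at
  n = 100/100; this mirrors the moderate AUROCs typical of real
  case/control microbiome classifiers.
- The regional gene-content profile and the proportionality pseudocount are
  declared conventions (documented above), not canonical definitions;
  alternative choices change absolute values though rarely rankings.
- The walktrap partition at the chosen step length is deterministic but,
  like all modularity-style methods, can merge weakly separated blocks;
  the recovery guarantees tested here apply to well-separated carrier
  structure (within-block Jaccard 1, cross-block < 0.5).
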