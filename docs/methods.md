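# Methods

This note documents the models, numerical conventions, and design choices
behind `adrnet`, and what the synthetic-data validation does and does not
demonstrate.

## Data model

The unit of analysis is a cohort of patients genotyped on a fixed panel of
germline pharmacogenomic variants. Genotypes are collapsed to **carrier
status** (dominant coding: 1 if at least one alternate allele). This is the
simplest reproducible choice when the relative contribution of
heterozygous and homozygous genotypes is unknown; an additive 0/1/2 coding
is available (`genotype_coding="additive"`) for sensitivity analysis.
Missing calls count as non-carrier but are tracked in a parallel mask, and
patients with more than 20% missing panel sites are flagged (threshold
configurable) — at the sequencing depths typical for amplicon panels,
missingness should be rare, so a high rate indicates a sample problem
rather than a genotype.

Panel coordinates are 1-based hg19. Multi-allelic VCF records are
decomposed; only the panel's alt allele is matched. Percentages in cohort
summaries are **truncated** (not rounded) to the displayed precision,
computed in integer arithmetic; odds ratios and confidence bounds are
rounded **half-up** to two decimals at serialization only. The two
conventions are deliberate and never mixed.

## Patient-similarity network and clustering

Patients are nodes; the default edge weight is the Jaccard similarity of
carrier sets (Dice and Hamming similarity are alternatives). Edges below
`edge_threshold` are dropped, and the weighted graph is partitioned by
Louvain modularity maximization (networkx implementation, seeded), with
partitions canonicalized — clusters numbered by decreasing size, ties
broken by lexicographically smallest member — so that runs with different
seeds are directly comparable and a stability check
(`stability_check`) can assert identical partitions across seeds.

**Why a nonzero default threshold (0.2).** Two unrelated carrier profiles
still share variants by chance, so the complete similarity graph is dense
with weak background edges. Modularity optimization on such a graph
suffers from the resolution limit: small genuine groups — in particular a
single-patient group — are absorbed into larger communities, because any
node whose retained edges all lead into one community gains modularity by
joining it. Under the generator's default carrier probabilities (0.8
within a patient's own variant block, 0.05 elsewhere), the empirical
between-group Jaccard similarity stays at or below ≈0.15 while
within-group similarity stays above ≈0.17; a threshold of 0.2 sits above
the background tail, which is what isolation of very small groups hinges
on, at the cost of occasionally pruning the weakest within-group edges
(harmless while groups remain connected through their stronger edges).
With this default, community detection recovers the planted five-group
partition exactly across 40 consecutive seeds. The threshold is exposed in
configuration; for data with a different background-sharing level it
should be re-examined against the observed edge-weight distribution.

Low modularity is not treated as failure: strongly similar patients can
still split into meaningful groups with a small Q, so the pipeline warns
below Q = 0.05 and proceeds. The detected partition's Q is never negative:
if the search lands below the trivial single-cluster score (Q = 0), the
single-cluster partition is returned.

## Cluster annotation

Variants are attributed to clusters in `private` mode by default: a
variant belongs to a cluster only if carried by members of that cluster
and nobody outside it. This makes the per-cluster variant sets pairwise
disjoint, so gene "Venn" counts (exclusive genes, sharing histogram) are
exact set statistics; `union` mode (any member carries) is retained for
sensitivity analysis. Drug names are normalized to lower-case generic
names and combination regimens are split into constituents; one
(variant, drug) annotation pair is one occurrence regardless of how many
source lines repeat it, preventing annotation redundancy from skewing the
drug-proportion matrix. Each drug's proportions are normalized by its own
total occurrences, so rows sum to one by construction.

## Enrichment

Per-cluster gene sets are tested against flat GMT term maps (Biological
Process / Molecular Function namespaces) with the hypergeometric upper
tail P(X ≥ k) for k of the cluster's n genes falling in a K-gene term
within an N-gene universe, computed via the scipy survival function.
Benjamini–Hochberg FDR is applied **within each cluster** (each cluster is
its own family of term tests), terms outside the 3–500 gene size window
are skipped, and query genes outside the universe are dropped with a
warning. No ontology traversal or parent-term propagation is performed:
the stage operates on whatever flat term map is supplied, keeping it fully
testable offline. On random query sets the fraction of tests reaching
p ≤ 0.05 is ≈0.05 (slightly conservative, as expected for a discrete
statistic).

## Association

For each (treatment, cluster) pair a 2×2 table is built. The default
convention (**A**) tabulates, *among treated patients*, rows (in cluster,
out of cluster) × columns (ADR, no ADR); convention **B** (within the
cluster, treated vs untreated) is implemented as an option, since either
reading of "cluster predicts ADR under treatment" is defensible.
Convention A is the default because the integer tables that reproduce the
reference OR/CI triples have totals equal to the treated-patient counts,
which convention B's cluster-bounded totals cannot produce at the printed
interval widths. Aggregate exposures (platinum compounds;
carboplatin+pemetrexed; radiotherapy+platinum) are unions of member
treatments with each patient counted once.

The odds ratio is `ad/bc` with the Woolf (logit) 95% interval,
`exp(ln OR ± z·SE)`, `SE = √(1/a+1/b+1/c+1/d)`. When any cell is zero the
Haldane–Anscombe correction adds 0.5 to **all four** cells before both the
OR and the SE; the chi-square (Pearson, uncorrected by default; Yates not
enabled) is always computed on the raw cells. A raw zero row or column
margin is an error: no correction makes the odds ratio identified from
such a table. The normal quantile defaults to **z = 1.96**: this is the
conventional value and it reproduces the reference printed bounds exactly
under half-up rounding, which the higher-precision quantile 1.959964 does
not (it shifts one printed upper bound by 0.01). The quantile is
configurable.

`recover_table` inverts the reporting pipeline: it enumerates every
integer table with total ≤ (or =) a bound, applies the identical
OR/CI/rounding path, and returns all tables matching a printed OR and/or
CI pair. The enumeration is exhaustive over the bound, so a planted
table → printed values → recovery round trip always contains the planted
table; an empty result is meaningful (e.g. a printed OR outside its own
printed interval is unreproducible by construction). The search is
vectorized; the full total ≤ 70 enumeration (~1.1 million tables) takes
about a second.

Calibration checks: over 2000 binomial 2×2 tables (40 per arm) at true
OR 2, the Woolf interval covers the truth at ≈95%; under a zero-effect
simulation the mean log OR across 200 replicate cohorts is ≈0.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, and its
defaults are those conditions: 70 patients in five latent groups of sizes
21/16/27/5/1; a 326-variant panel with 15 design-excluded and 2 duplicate
rows (309 analyzable); each group owns a disjoint block of analyzable
variants (block sizes proportional to group size: 93/71/119/22/4), carried
with probability 0.8 by members and 0.05 by others; 176 genes partitioned
across blocks (so gene exclusivity is exact on the truth) plus five
intergenic variants, one variant on the X chromosome, one indel, and 15
radiotherapy-toxicity annotations; treatments fixed at 14 cisplatin, 30
carboplatin (44 on a platinum doublet), 17 radiotherapy, with pemetrexed
given to 80% of carboplatin patients (the published composition lists no
pemetrexed count, only that it partners carboplatin; 0.8 is the one
free choice and is configurable). ADR outcomes follow
`logit P(ADR) = logit(0.528) + Σ effect_log_odds[(cluster, treatment)]`,
so the default (all effects zero) is an exact null calibrated to the
cohort ADR prevalence of 52.8%, and planted effects are recoverable.

All randomness flows from a single seed through named per-patient
substreams (`SeedSequence((seed, tag, i))`), so adding patients never
perturbs earlier patients' draws and a fixed seed yields a byte-identical
file bundle (plain-text single-sample VCFs with an hg19 contig header,
panel TSV, clinical CSV, GMT). `make_planted_table_cohort` additionally
builds minimal deterministic cohorts whose contingency table is exactly a
requested table under either convention.

**What the generator does not emulate:** linkage disequilibrium, realistic
allele-frequency spectra, sequencing error, population structure, or
correlated treatment assignment (treatments are assigned independently of
the latent genetic groups). Passing the planted-recovery tests therefore
shows that the pipeline's machinery is correct and well calibrated under
its own model — clean block structure with independent background
carriage — not that real cohorts of this size would cluster this cleanly.
In real data the between/within similarity distributions overlap more, and
the edge threshold and the convention choice become analysis decisions.

## Numerical and degenerate-input conventions

- Truncated percentages via integer arithmetic (`100·c·10^d // n / 10^d`);
  half-up rounding via `floor(x·10^d + 0.5)/10^d` — used consistently in
  the scalar and the vectorized (search) paths.
- Jaccard between two empty carrier sets is defined as 0 with a warning.
- An edgeless patient graph yields the singleton partition with Q = 0
  rather than an error; modularity itself raises on zero total weight.
- Cluster indices are always contiguous from 0 after canonicalization.
- Empty enrichment inputs yield empty frames; an empty universe raises.
- Degenerate association rows (nobody treated, zero margins) are skipped
  with warnings in batch mode and raise in single-table mode.

## Problem sizes used in the validation suite

The test suite runs the full 70 × 309 cohort end to end (including VCF
round trips and the pipeline rerun-digest check), ten-seed planted
recovery, 500-replicate prevalence and effect-recovery calibrations,
2000-replicate interval coverage, a 200-replicate null, and exhaustive
table searches up to total 70. These sizes keep the whole suite around
ten seconds on one CPU while leaving every statistical band comfortably
narrower than the effect being checked.

## Known limitations

- The network construction (metric, threshold) and the community
  algorithm are declared choices validated on synthetic truth; other
  reasonable choices (shared-neighbor graphs, Leiden) exist and may
  behave differently near the resolution limit.
- Association estimates are univariable; no adjustment for stage, age, or
  co-treatment is attempted, and aggregate exposures are unions, not
  factorial designs.
- Per-patient reports flag OR > 1 point estimates regardless of interval
  width; with cohorts of this size most intervals cross 1, and the report
  text says so for small clusters. The output is research material, not
  clinical guidance.
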