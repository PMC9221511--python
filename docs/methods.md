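# Methods

## Model and procedure

`cardiospm` treats region specificity as a geometric property of a gene's
mean-expression vector. Within one species/platform dataset, samples are
assigned to analysis regions (LA, V, SA by default; LV and RV are merged
into V before any statistic is computed, and other labels such as RA, PV,
PA or LAA are excluded from the specificity analysis though they remain
available for sample clustering). For gene *g* the per-region arithmetic
means of log2 expression form **m**_g, and

SPM_{g,r} = m_{g,r} / ‖**m**_g‖₂.

The denominator is the Euclidean norm: this is the only reading under which
SPM is the cosine between **m**_g and the region axis, lies in [0, 1] for
non-negative means, and satisfies Σ_r SPM² = 1 — identities the test suite
asserts. Genes with an all-zero mean vector have no defined direction and
are excluded (reported in `excluded_genes`) rather than assigned 0. Negative
means are rejected: all inputs are log2(x + 1)-scale and hence non-negative;
the pipeline clips values at 0 after additive cross-sample alignment to
preserve this invariant.

A gene is called specific for region *r* when SPM_{g,r} > τ **and** its
one-way fixed-effects ANOVA across regions yields a BH-adjusted p < α
(default 0.05). The threshold τ is the 95th percentile (linear-interpolation
convention, as everywhere in the package) of the pooled null SPM values
obtained by one uniform random permutation of the sample→region labels per
gene. Pooling is across all genes *and* all regions of one dataset, giving a
single τ per species/platform. When τ < 1/√2 two regions can exceed τ
simultaneously; the call then goes to the region of maximal SPM and is
flagged `multi_region`. The permutation consumes a single seeded generator
in gene order, so a fixed seed fixes τ exactly.

Degenerate ANOVA inputs follow explicit policies: zero total variance means
no evidence of regional difference (p = 1, `degenerate` flag); zero
within-group variance with unequal means is reported as p = 0.

### Cross-species classification

Ortholog tables are directed: the x-species indexes the comparison and
multi-mapped y-side values are averaged, so the mapping is asymmetric and
the direction is exposed as a parameter (for rodent–rodent comparisons the
caller chooses the indexing species). A specific call in species *s* is
supported by species *o* when **any** ortholog of the gene is specific for
the same region in *o* — the weakest reading of "identically
region-specific" for many-to-many families; the supporting species are
recorded per gene so the stricter all-ortholog variant can be audited from
the output. Categories (common to all species / pairwise / selective)
partition each species' specific list by construction, which a test verifies
by brute-force recount.

### Clustering and enrichment

Sample clustering and SPM-profile clustering both use 1 − Spearman
correlation (range [0, 2]) with average linkage (UPGMA). Average linkage is
the package default because the upstream sample-clustering utilities this
workflow descends from default to it; the linkage is configurable in the
sense that the distance matrix and scipy linkage matrix are both exposed.
Agreement with a brute-force O(n³) agglomeration is asserted exactly on
trees of ≤ 8 leaves. Profile clustering operates on the reference-species
genes (human by default) that have at least one ortholog in every other
species, yielding |species| × |regions| = 9 labelled profiles; cutting the
tree at three clusters and scoring the majority-region fraction
(`region_purity`) quantifies whether region signal dominates platform
signal.

Enrichment is the one-sided hypergeometric upper tail (equivalent to
one-sided Fisher), BH-corrected across terms with K > 0 in the background.
The default background is the set of genes that entered the region-specific
analysis of the same dataset; the original description of the background is
ambiguous ("for the other two species"), so the choice is exposed
(`--background universe` or `custom:<file>`) rather than guessed.
Annotations are taken as given (GMT or long TSV); no GO-graph propagation is
performed. The transcription-factor filter is the intersection with the
GO:0003700 term's gene set.

### Normalisation

Cross-sample alignment is an additive shift on the log2 scale — median
alignment (every sample's median moved to the grand median of per-sample
medians) for bead-array-style data, 90-percentile normalisation (same
anchoring, 90th percentile) for Agilent-style data. Additive log-scale
shifts preserve within-sample rank order and correspond to scale-factor
normalisation in linear space. TPM is computed as length-normalised count
rates rescaled to 10⁶ per sample; all-zero samples stay all-zero with a
warning. Probe sets collapse to genes by the element-wise maximum across a
gene's probes; probes without a gene assignment are dropped. Expression
filters use strict inequality (a gene passes when it exceeds the
platform-specific threshold in at least one sample) and the filter is
applied after pseudocount and log2 transform, matching the stated processing
order of the workflow this package reimplements.

## Synthetic data: what it emulates and what it does not

The generator draws a shared ("ancestral") log2 baseline b_g ~ N(6, 2),
clipped at 0, for a universe of n orthologous genes; species expression is

value(g, sample) = shift_s + scale_s · (b_g + δ·1[g planted for sample's
region]) + N(0, σ), clipped at 0,

with per-platform location shift, multiplicative gain, and independent
per-gene dropout. Defaults: three species, regions LA/V/SA with 4 replicates
each (V emitted as 2 LV + 2 RV samples to exercise the merge rule), n = 5000
genes, σ = 0.5, δ = 4 log2 units, platform shifts of 0 / +1.5 / −1 with
gains 1.0 / 1.2 / 0.9 and dropout 3–5%. Each region carries 50 planted
specific genes per species: 20 common to all three species, 10 per species
pair, 10 selective — the conservation structure the classifier must
recover. The ortholog graph is a 1–1 backbone between index-mates plus a
configurable fraction of extra paralog-style edges.

Two deliberate simplifications keep the ground truth exact: planted genes
are exempt from dropout by default (the `dropout_planted` flag restores
marker-absent-from-platform behaviour, at the cost of removing those
plantings from the truth table), and extra many-to-many ortholog edges are
drawn only between unplanted genes, so no spurious conservation paths
exist. The generator also does **not** model probe-level microarray noise,
read-level RNA-seq sampling, correlated gene modules, or heavy-tailed human
inter-individual variability — passing tests demonstrate that the statistics
behave as designed under their stated model, not that the pipeline is robust
to every pathology of real cardiac transcriptomes. A thin count mode
(Poisson-lognormal counts with gene lengths) exists solely to exercise the
TPM path.

## Numerical choices

- Percentiles everywhere use linear interpolation between order statistics
  (numpy default) — stated because τ is a percentile and bit-reproducibility
  depends on the convention.
- BH adjustment computes q_(i) = min_{j≥i} min(1, p_(j)·m/j) with the
  products evaluated exactly in that form, vectorised via a reverse running
  minimum; it agrees with statsmodels' `fdr_bh` to 1e-12 (the two differ in
  rounding because statsmodels divides by i/m).
- Hierarchical clustering tie-breaks follow scipy's deterministic nearest-
  neighbor chain given the input column order; tests avoid exact ties, and
  topology is order-invariant for distinct distances.
- Spearman correlations use mid-ranks for ties; interspecies correlations
  require ≥ 3 mapped pairs and non-constant ranks.
- Dendrograms serialise to Newick with scikit-bio, branch lengths derived
  from merge heights.
- Per-species permutation seeds are derived deterministically from the run
  seed (seed·1000 + species index) so species fits are independent but
  reproducible; manifests record the config hash and seed but no wall-clock
  time, making reruns byte-identical.

## Problem sizes used in validation

The shipped validation runs use study-condition defaults scaled to a desk
footprint: null-calibration checks use 10,000 exchangeable-null genes × 3
regions × 4 replicates over 10–20 seeds; recovery checks use 5000 genes with
the default planting over 5–10 seeds; profile-clustering checks use 2000
genes over 10 seeds. These sizes give Monte-Carlo standard errors well below
the asserted tolerances (e.g. the 5% exceedance rate is estimated to ±0.001
per seed batch).

## Known limitations

- The permutation null uses one permutation per gene; τ is therefore a
  pooled quantile with gene-to-gene dependence ignored. It calibrates the
  marginal exceedance rate (verified empirically) but is not a family-wise
  error control.
- With τ < 1/√2 the at-most-one-region property is enforced by the argmax
  rule rather than geometry; the `multi_region` flag marks affected calls.
- The any-ortholog agreement rule is permissive for large paralog families;
  the per-gene supporting-ortholog log allows re-scoring under stricter
  rules but the package does not implement paralog-aware weighting.
- Enrichment treats annotations as flat sets; terms related through the GO
  hierarchy are tested independently and BH treats them as exchangeable.
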