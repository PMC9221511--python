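# cardiospm

Cross-platform, cross-species analysis of cardiac region-specific gene
expression with the SPM specificity statistic.

## The problem

Transcriptomes of the heart's working chambers (left atrium LA, ventricles
V = LV + RV) and its pacemaker (the sinoatrial node, SA) are measured on
whatever platform each lab has: Illumina bead arrays for mouse, Agilent
arrays for rat, RNA-seq for human. Absolute expression values are not
comparable across these platforms, and inter-individual variation often
swamps inter-region differences, so naive clustering groups samples by
platform or donor rather than by anatomy. `cardiospm` is for researchers who
want to ask, across species and platforms at once: *which genes are specific
to which cardiac region, and is that specificity conserved?*

## The statistic

For gene *g*, let **m**_g = (m_{g,LA}, m_{g,V}, m_{g,SA}) be the vector of
mean log2 expression per region. The specificity measure of region *r* is

```
SPM_{g,r} = m_{g,r} / ||m_g||_2
```

— the cosine between **m**_g and region *r*'s coordinate axis. SPM lies in
[0, 1], Σ_r SPM² = 1, and SPM is invariant to scaling of the expression
vector, which is what makes it comparable across platforms with different
units. A gene is called **region-specific** when

1. SPM_{g,r} > τ, where τ is the 95th percentile of null SPM values obtained
   by one uniform random permutation of the sample→region labels per gene
   (pooled over all genes and regions of the dataset), and
2. its one-way ANOVA across regions gives a Benjamini–Hochberg adjusted
   p-value < 0.05.

Calls are then compared across species through many-to-many ortholog tables
(Biomart-style): a call is **common** when every other species has an
ortholog specific for the same region, **pairwise** when exactly one other
species agrees, **selective** otherwise. SPM profiles of the nine
species-region pairs are clustered with 1 − Spearman distance and average
linkage; region-specific gene sets are tested for GO-term over-representation
with the one-sided hypergeometric test.

Because the original raw data live in controlled repositories, the package
ships a synthetic-data generator that emulates the study design (three
species, three platforms with location/scale shifts and gene dropout,
planted region-specific genes with known conservation categories) so every
stage is testable end to end against exact ground truth.

## Worked example

```python
import cardiospm as c

cfg = c.SyntheticConfig(n_genes=2000, seed=7)   # 50 planted genes/region/species
ds = c.generate_dataset(cfg)

model = c.RegionSpecificity.from_dataframe(
    ds.matrices["human"].values, ds.metadata["human"], tag="human"
)
res = model.fit(seed=7)
print(res.summary())
```

```
Region specificity results [human]
==================================================
genes analysed:        1952
samples / regions:     12 / LA, V, SA
SPM null threshold:    tau = 0.6219  (95th pct of 5856 null SPMs, seed 7)
ANOVA gate:            BH adj_p < 0.05  (162 genes pass)
--------------------------------------------------
specific genes per region:
  LA   54
  V    52
  SA   51
```

The model analysed 1952 genes (2000 minus platform dropout), derived the
permutation-null threshold τ = 0.622 from 1952 × 3 null SPM values, and
called ~50 specific genes per region — the generator planted exactly 50.
`res.specific_table()` lists each call with its SPM, adjusted p-value and
threshold:

```
    gene region      SPM    adj_p     tau  is_specific  multi_region
HSA00002     SA 0.636594 0.040531 0.62194         True         False
HSA00004     LA 0.779372 0.000006 0.62194         True         False
HSA00005      V 0.814183 0.000022 0.62194         True         False
```

The full pipeline — preprocessing, per-species fits, cross-species
classification, clustering and enrichment — runs from a config:

```bash
cardiospm run-all --seed 7 --out results/run
```

which writes per-species SPM/calls tables, the category table, Newick
dendrograms, the enrichment table and a manifest; rerunning with the same
config and seed reproduces every file byte for byte.

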