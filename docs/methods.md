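# Methods

## Scope and model

The package models the downstream half of a ChIP-seq target-gene study: peak
sets are given (peak calling itself, read filtering and mapping are out of
scope), and the questions are (i) which genes the peaks reproducibly
implicate, (ii) whether those genes are differentially expressed between
case and control qPCR cohorts, and (iii) which rare coding variants the
genes carry in a patient series. Each stage is a deterministic function of
its inputs and a small explicit configuration.

All genomic coordinates are 0-based half-open internally (BED convention);
GTF input is converted on read and back-converted on write, so both
round-trips are exact. Abutting half-open intervals do not overlap; a
`min_gap` parameter can relax this. Peak and gene-model chromosome
namespaces must match exactly — a mismatch ("1" vs "chr1") raises a named
error rather than silently annotating nothing.

## Peak-to-gene annotation

The original study used three external annotation tools whose internals are
not part of the record; the package replaces them with three transparent,
parameterized annotators, because the consensus logic — not any annotator's
internals — is the substance being reproduced:

* `nearest_tss` (window 100 kb): gene reported iff |anchor − TSS| ≤ window
  for some peak. Every qualifying gene is reported; no single-winner
  truncation. 100 kb is the common default of the binding-to-target family
  of tools.
* `feature` (upstream 5 kb, downstream 1 kb): each peak anchor classified
  with fixed precedence promoter > 5′UTR > 3′UTR > exon > intron >
  downstream > intergenic, so every peak lands in exactly one feature bin;
  ties at equal precedence break deterministically on gene id. Promoter and
  downstream windows are strand-aware.
* `gene_span` (same windows): gene reported iff any peak interval overlaps
  the strand-aware span [TSS − upstream, TES + downstream).

The anchor is the peak center by default; the summit is used when the
input provides one (BED3 does not). All windows are configuration, not
constants.

## Consensus voting

Route 1 operates on per-pool pooled peak sets annotated by all three
annotators: a gene is selected when ≥ `min_tools` (2) annotators report it
in each of ≥ `min_pools` (2) distinct pools. Route 2 operates on
per-replicate peak sets within each pool: overlapping replicate peaks are
merged into clusters, clusters contributed by < `cluster_min_replicates`
(2) distinct replicates are dropped as irreproducible, surviving clusters
are annotated by the union of two annotators, and a gene is selected when
its supporting clusters come from ≥ 2 distinct pools.

Two readings of route 2's "at least 2 of the clusters" rule are possible;
the default counts distinct *pools* (parallel to route 1's replication
stringency), and `VoteConfig(method2_count_pools=False)` selects the literal
"≥ 2 clusters anywhere" reading. Annotator intersection instead of union is
likewise a flag. Both voting rules are monotone: adding call records never
shrinks a selection, raising a threshold never grows it (property-tested).

Panel assembly is arithmetic over curated tables shipped as YAML: union of
the two routes (15 genes, 6 shared), plus 12 literature-curated genes
(27), mouse→human ortholog mapping (explicit entries for unnamed loci;
uppercase-symbol convention otherwise), removal of the one pseudogene
ortholog (26), plus 6 curated interactor genes (32). Curated genes enter
only through the tables, never through voting; excluded or unmapped genes
remain visible in the report rather than disappearing. The per-route
membership of the 9 single-route genes is not recorded in the curated
tables, so the packaged report attributes them to route 1 — a labeling
convention that leaves union, shared and all downstream counts unchanged.

## Expression stage

Ct semantics: more template crosses the detection threshold earlier, so
lower Ct means higher expression. ΔCt(g, s) = Ct(g, s) − Ct(control(chem(g)), s),
with 18S-type controls for probe-array chemistry and GAPDH for dye
chemistry. ΔΔCt = mean ΔCt(case) − mean ΔCt(control); fold change = 2^−ΔΔCt;
"up" means ΔΔCt < 0.

Expression calls use strict per-value ceilings (Ct < 32 probe-array,
Ct < 35 dye; a value at the ceiling is non-detection, as is a missing or
undetermined Ct). The aggregation across samples is not part of the
original record and is an explicit knob: a gene is expressed when the
detected fraction reaches `expressed_fraction` (default 0.5) in *both*
groups. Endogenous controls are reference assays and are excluded from the
expressed set. Raising a ceiling can only grow the expressed set
(property-tested).

The group test is the classical pooled-variance Student's t-test, two-sided,
on per-sample ΔCt, significant at p ≤ 0.05 — deliberately uncorrected, to
match the analysis contract being reproduced; Benjamini–Hochberg adjusted
p-values are available via `adjust="bh"`, and Welch's test via
`equal_var=False` (defensible given the unequal 14 vs 5 design). Testing on
2^−ΔCt instead of ΔCt is possible by transforming the matrix before the
call. Degenerate inputs: identical constant groups report t = 0, p = 1;
constant but different groups are the zero-variance limit and report
p = 0 with an infinite t rather than NaN; genes with < 2 values in either
group are flagged `testable=False`, never silently dropped. Missing Ct is
non-detection for expression calls but excluded (NaN) from ΔCt statistics —
censoring-aware imputation is out of scope.

Clustering uses distance 1 − Pearson r with average linkage (UPGMA) on both
genes and samples, dropping incomplete samples first. A zero-variance
profile has no defined correlation; its distances are set to the metric's
maximum (2) and logged. Results carry leaf orders and merge heights; a
red/green ΔCt heat map is available.

## Variant stage

The rare filter passes a variant when MAF < 0.01 (strict) in at least one
configured database, or when it is absent from all of them (novel) — the
curated cohort table retains fully-absent variants, so novelty must pass.
The stricter all-databases rule is a flag; its passing set is provably a
subset of the permissive rule's. Variant types derive from ref/alt lengths,
with the HGVS-style coding-change string (del/ins/dup/>) as fallback;
deletions may use "-" as the alternate allele. Summaries count types,
locations (UTR = 5′ + 3′), distinct genes and patients, multi-variant
patients with their gene lists, inheritance and phenotype; they are
permutation-invariant. TSV is the canonical format; a minimal VCF reader
maps INFO keys to database names.

## Synthetic data

Generators are pure functions of their scenario (seed included); the same
scenario yields byte-identical output files.

* Gene models: genes placed one per slot on an even grid (hence provably
  non-overlapping), truncated-normal lengths (min 2 kb), 2–8 exons, UTRs at
  the body ends, both strands. The grid placement means inter-gene spacing
  is more regular than in a real genome.
* Peaks: each replicate gets one peak per planted target centered on the
  TSS plus Gaussian jitter (300 bp), minus Bernoulli dropout, plus uniform
  background peaks; widths are truncated normal with a 50 bp floor, on the
  sonication-fragment scale. No coverage model, no enrichment statistics,
  no correlated replicate noise.
* Ct tables: expressed genes draw Ct ~ Normal(baseline, sd) with the case
  group shifted by ΔΔCt (up-regulation = negative shift); non-expressed
  genes draw uniformly above their ceiling or come back missing; endogenous
  controls are never shifted. Gaussian, homoscedastic, gene-independent
  noise — no plate effects, no amplification-efficiency variation.
* Variants: a three-way mixture (rare everywhere present / common
  everywhere present / absent everywhere) with per-database presence draws;
  the mixture class is the ground-truth label, so filter recovery is exact
  by construction.

The packaged `paper_shape` scenarios fix the study's dimensional skeleton —
3 pools × 4 ChIP replicates over 15 planted targets on a 200-gene genome;
a 32-gene panel (30 probe-array, 2 dye) in 14 case and 5 control samples
with 12 expressed genes of which 9 are planted up-regulated (shifts 2–4
cycles at sd 0.5, large enough that recovery is essentially deterministic);
a 56-patient variant screen — and carry a fixed seed so the packaged
results are reproducible run to run. The identity of the three
expressed-but-unshifted genes is a scenario choice (STAT3, DPP9, NEDD4L).
Passing recovery tests on these scenarios shows the *inference chain* is
correct at the study's scale; it says nothing about peak callers, mapping,
probe design or any upstream step the generators do not model.

## Verification and problem sizes

Every non-trivial operation is checked against an independent oracle
implemented naively in the test suite: merging and clustering against an
O(n²) union-find over all pairs (≈ 300 intervals); route-1 voting against
explicit evaluation of all 512 possible 3-tool × 3-pool presence matrices;
the annotators against all-pairs distance/overlap scans (50–80 peaks ×
20–30 genes); the t-test against the closed-form pooled-variance formula;
average linkage against a naive O(n³) agglomeration (5–7 profiles). Power
calibration uses 200 replicates of a 2-cycle shift at sd 0.5 (14 vs 5
samples; observed power ≥ 0.99) and type-I calibration 1000 replicates of
five null genes (empirical rate within the binomial band around 0.05).
These sizes keep the whole suite around ten seconds while leaving the
oracles exhaustive where enumeration is possible.

## Known limitations

* The annotators are idealized stand-ins: they reproduce the *kind* of
  assignment the original tools make, not their exact outputs.
* No multiple-testing correction by default (by design, see above); with 32
  genes the uncorrected contract inflates family-wise error.
* The rare filter treats databases as exchangeable; population-specific
  adjudication beyond the any/all rules is not modeled.
* Synthetic realism gaps listed per generator above; none of the generators
  simulate reads, coverage or mapping bias.
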