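# Methods

`chrokit` analyzes chromatin run-on sequencing (ChRO-seq) data — stranded,
single-base maps of transcriptionally engaged RNA polymerase, where each
count marks the 3′ end of a nascent RNA — across the stages of a directed
differentiation (human pluripotent stem cells → definitive endoderm →
duodenal → ileal intestinal spheroids, labelled hESC/DE/Duo/Ile). This note
documents the models, the numerical choices, and what the bundled synthetic
benchmark does and does not demonstrate.

## Signal model and quantification

All coordinates are 0-based half-open. The TSS of a minus-strand gene is
`end − 1` (the first transcribed base). Signal tracks are run-length arrays
per (chromosome, strand); minus-strand bedGraphs storing negated values (the
common PRO-seq dialect) are folded to positive counts on read (disable with
`fold_minus=False`).

Three activity matrices are computed from raw integer counts:

* **Gene bodies** — sense-strand counts over the transcription unit with the
  first 500 bp downstream of the TSS excluded, removing the promoter-proximal
  pause peak. Genes with bodies shorter than 1,000 bp are dropped (the
  exclusion would consume most of their body) and reported. Counts are
  length-normalized to TPM with effective length = body − 500 bp; each
  sample's TPM column sums to 10⁶ exactly.
* **Promoters** — sense-strand counts over a fixed window 500 bp upstream to
  200 bp downstream of the annotated TSS; the pause peak is intentionally
  included. The window is clipped at chromosome edges (logged, not an error).
* **TREs** (transcriptional regulatory elements) — both-strand raw counts
  over each element, matching the divergent eRNA signature of active
  regulatory DNA.

Gene-body and promoter quantification default to sense-strand-only signal.
The divergent eRNA transcription at promoters would otherwise contaminate
the promoter window with antisense counts; a `gene_strand_mode="both"` flag
is available. Merged per-stage tracks rescaled to a total of 10⁶ are
produced for visualization only — every statistic consumes unnormalized
counts.

## Differential activity

A deliberately transparent negative-binomial engine stands behind all
differential calls; it is not a reimplementation of any specific package
and performs no dispersion-trend fitting, empirical-Bayes shrinkage, LFC
shrinkage, independent filtering or outlier refitting.

* **Normalization**: median-of-ratios size factors over features with
  all-positive counts (a `pseudo_reference` fallback uses nonzero-only
  geometric means for sparse matrices).
* **Dispersion**: per-feature method of moments on normalized counts within
  groups, `α̂ = (s² − m)/m²`, df-weighted across groups and clipped at zero.
  The gene-wise estimate is floored at the cohort median of the estimates.
  This floor is the one piece of moderation the engine applies: at three
  replicates per group the raw per-gene estimator is so noisy that a plain
  normal Wald test rejects ~12% of true nulls at α = 0.05; the median floor
  restores ~5% while vanishing in the large-count, low-dispersion limit
  (where the cohort median itself goes to zero), so the test still agrees
  with an exact Poisson likelihood-ratio test there. Heavier-tailed
  references (a t with residual df) were rejected because they distort the
  far tail, where most biological calls live.
* **Wald contrast**: log2 fold change from group means of normalized counts
  with a +0.5 pseudocount (fold change only — the variance model sees the
  raw means); `Var[ln mean] ≈ (1/μ + α)/n` per group from the NB information;
  two-sided normal p; Benjamini–Hochberg adjustment within the tested set.
  A group with an all-zero mean yields a finite (pseudocounted) fold change,
  an infinite SE, p = 1, and a `zero_group` flag.
* **Likelihood-ratio test** across all stages: full model with one NB mean
  per stage versus a single-mean reduced model, identical dispersion in both
  fits, deviance referred to χ² with (stages − 1) df.

The BH implementation mirrors the standard step-up bit for bit (verified
against `statsmodels` in the test suite).

## Marker genes

A stage marker must pass, in the stage of interest: gene-body TPM > 50 and
RNA base mean > 100 (mean of size-factor-normalized RNA counts over the
stage's samples), and versus **each** other stage, in **both** assays:
padj < 0.2, p < 0.05, fold change > 1.5 (one-sided, elevated in the stage of
interest; threshold applied as log2FC > log2 1.5). Genes with bodies
< 1,000 bp or a biotype containing "pseudogene" are excluded. Markers shared
by both spheroid stages apply the same criteria from each spheroid stage
versus the non-spheroid stages only — no fold-change requirement between Duo
and Ile — with the activity/expression floors enforced in both spheroid
stages. Dropping the fold requirement only for the Duo↔Ile comparison (and
not versus hESC/DE) is a design choice: relaxing it everywhere would admit
constitutive genes.

Promoter-pattern groups: genes with promoter LRT padj < 0.05 and average
promoter activity > 5 (TPM-like scale over the fixed 700 bp window),
protein-coding only, are standardized per gene (z-score of stage means) and
clustered hierarchically (average linkage, correlation distance). The cut
level defaults to the silhouette-optimal k in 2..12. Any deterministic
clustering recovering planted archetype profiles would serve equally; this
one is chosen for having no tuning state.

## TRE landscape

TREs with ≥ 1 base overlap with any −1000/+200 TSS window (strand-aware) are
proximal (promoters); the rest are distal (enhancers) — an exhaustive,
exclusive partition. Stage-specific calls test the union of TREs active
(mean raw both-strand count ≥ 10) in either stage of a transition and split
them into gained (padj < 0.05, log2FC > 2.5), lost (mirror) and unchanged.
Per-gene enhancer density counts gained distal TREs overlapping (≥ 1 base)
the closed ±100 kb window around the TSS of each actively transcribed gene
(TPM > 50); a midpoint-counting mode is available since window membership of
a boundary-straddling element is a convention, not a fact. Linked genes have
density > 0, pass the activity and expression floors, and are up in both
assays (marker statistical criteria). The density-bin report (zero / low /
high, median split of the positive densities; ties collapse to high)
contrasts ChRO log2FC of high-density versus zero-density genes with a
one-sided rank-sum test.

## Enhancer hotspots

Gained distal TREs closer than 12.5 kb edge-to-edge (strict) are stitched
single-linkage into units whose signal is the sum of the members'
both-strand raw counts over the stage-of-interest samples (summing across
replicates; a per-replicate mean would only rescale the ranking). On the
ascending, unit-square-scaled rank curve (xᵢ = (i−1)/(n−1), yᵢ = sᵢ/sₙ) the
slope at each rank is the central secant, one-sided at the ends; the cutoff
is the signal at the smallest rank whose slope exceeds 1, and hotspots are
the units strictly above it. The construction is scale-invariant and the
hotspot set is always an upper set of the signal ordering; a linear or
constant curve yields no hotspots, and fewer than three units is an error.
Each stitched unit is assigned to the nearest active gene (TPM > 50) whose
TSS lies within 100 kb of either boundary — a TSS inside the unit has
distance 0 — with ties broken by genomic start, then gene id. Final
hotspot-associated genes must additionally be up in both assays. Overlap
with external acetylation peaks is classified by covered fraction of the
unit: none (0), moderate (≤ 0.5], high (> 0.5).

## Cistromes

PWMs (JASPAR 4-row text) are scanned over distal TRE sequences on both
strands with log2 odds against a uniform background, pseudocount 10⁻³,
keeping windows that reach 80% of the motif's maximum attainable score (the
threshold is a config knob; no published value exists for the empirically
tuned tools this scanner replaces). Windows containing N are skipped;
overlapping hits are retained. Motif enrichment in gained enhancers versus
the remaining distal TREs uses the one-sided hypergeometric tail on
TREs-with-≥1-hit, fold = (k/n)/(K/N), BH across motifs. A TF's candidate
cistrome consists of genes with motif density > 0 (hits inside gained distal
TREs overlapping the ±100 kb TSS window; a TRE-level counting mode exists),
TPM > 50, RNA base mean > 500, and up in both assays.

## Synthetic benchmark

The generator plants a complete, machine-readable ground truth and is fully
deterministic in (config, seed); every stochastic draw descends from one
`SeedSequence`.

Genome and annotation: 20 chromosomes × 2 Mb — enough genome for 400 genes
(log-uniform 2–50 kb bodies, random strands, rejection-sampled non-nested,
~5% pseudogenes, 8 sub-kilobase genes to exercise the length filter) at a
TSS spacing resembling real gene density, which matters because planted
enhancer clusters must have their designated target as the nearest active
TSS. Gene baseline rates are log-normal (median 500 expected reads/sample,
log-sd 1.2).

Planted effects (all on top of a gene's own baseline): 30 markers per stage
at log2FC 3; 20 shared spheroid markers elevated in both Duo and Ile; 20
enhancer-hotspot target genes at log2FC 4 and 50 singleton-enhancer target
genes at log2FC 1.5 in Duo. The singleton-target fold is chosen so that
"activated" genes are genuinely detectable by the linking criteria
(FC > 1.5) after the ~0.2 log2 compression that median-of-ratios
normalization incurs when ~30% of only 400 genes carry a planted Duo effect;
at log2FC 1 the planted truth would sit on the threshold by construction.
Designated genes are drawn from baseline rates above the 40th percentile
(markers are, in practice, well-expressed genes), and enhancer/hotspot
targets additionally from the most TSS-isolated candidates so the
nearest-gene assignment is well-defined ground truth.

TREs (1,000): 300 promoter-proximal elements centered on TSSs with a
constant intrinsic eRNA rate (they still gain signal passively at
upregulated genes through pause reads inside the element — realistic, and
it keeps the planted "gained enhancer" truth exactly the singleton + cluster
set); 490 background distal elements; 50 Duo-specific singletons (rate
10 → 160, log2FC 4); 20 clusters of 8 members at 10× the singleton signal
(100 → 1600), internal gaps drawn in [2, 12) kb so each cluster stitches
into one unit, clusters ≥ 20 kb from other planted elements so units never
merge. Distal planted elements are rejection-sampled outside TSS windows
and outside actively transcribed gene bodies — an element inside an active
body would have its eRNA signal swamped by gene-body reads, silently
diluting the planted fold change; intergenic placement is also the cleaner
model of a distal element. A 12-bp consensus motif is written into the
genome at the center of every planted enhancer (random strand); a second,
never-planted decoy motif ships alongside.

ChRO-seq tracks: per gene, total reads ~ NB(stage rate, dispersion 0.05);
40% land uniformly in the first 500 bp (the pause peak — placed there
precisely so the quantifier's exclusion window provably removes them), the
rest uniformly over the remaining body, all sense-strand. Per TRE, reads ~
NB(stage rate) split ~50/50 into a divergent pair (plus-strand downstream,
minus-strand upstream of center, uniform within a 150 bp half-width).
Uniform Poisson background of 0.01 reads/kb/strand.

RNA-seq: per gene and sample, NB around library size × rate share × a
per-gene log-normal offset (sd 0.9) modeling stable post-transcriptional
regulation. The offset is per-gene, not per-sample: a per-sample lognormal
of the size needed for realistic transcription–expression decoupling would
inflate within-group variance until no marker could meet the RNA criteria
at n = 3, which real data do not show. The sd default was calibrated once
so the genome-wide Pearson correlation of log transcription versus log
expression lands near 0.7 (typically 0.66–0.76 across seeds) — the regime
reported for matched nascent/steady-state data. The RNA denominator is the
stage-independent total baseline output, so planted fold changes carry over
to the RNA means exactly; compositional renormalization effects (global
output shifts compressing relative fold changes) are deliberately not
modeled.

### What the benchmark does not emulate

Mappability and alignment artifacts, PCR duplication, signal at repeats and
rRNA loci, transcript isoforms and overlapping antisense transcription
units beyond random placement, enhancer–promoter loops beyond linear
distance, per-gene dispersion heterogeneity (a single NB dispersion is
shared; a per-gene mode exists), and TRE discovery itself (elements are
given, as the pipeline expects them from an upstream caller). Passing the
recovery tests therefore demonstrates that the analysis logic is correct
and calibrated under the stated generative model — not that the pipeline is
robust to the full noise structure of real libraries.

## Problem sizes and runtime

The default benchmark (4 stages × 3 replicates, 400 genes, 1,000 TREs, 20
planted 8-member clusters, 40 Mb genome) runs end-to-end in well under a
minute on one CPU; the test suite adds brute-force oracle comparisons on
hundreds of random small instances per primitive and a 2,000-feature null
calibration. These sizes were chosen as the smallest at which every
statistical criterion is comfortably powered.

## Known limitations

* The Wald engine's median dispersion floor is slightly conservative for
  genuinely low-dispersion features in heterogeneous cohorts.
* Marker and linking calls inherit the thresholds' hard-edge behavior: a
  planted effect near a floor (TPM ≈ 50, base mean ≈ 100/500, FC ≈ 1.5) is
  recovered with probability near ½ by design, which is why planted effects
  sit clear of the floors.
* `tes` of a minus-strand gene is reported as `start − 1` (exclusive end in
  transcription direction), which is off the gene body by construction;
  consumers should use the interval fields for arithmetic.
* The CLI re-runs Wald contrasts inside each analysis stage rather than
  caching the `diff` stage's tables; at these problem sizes the cost is
  negligible and it keeps every stage runnable in isolation.
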