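# chrokit

Analysis of nascent transcription from chromatin run-on sequencing
(ChRO-seq) across the stages of a directed differentiation — human
pluripotent stem cells (hESC) → definitive endoderm (DE) → duodenal (Duo)
and ileal (Ile) small-intestinal spheroids. ChRO-seq maps the position of
transcriptionally engaged RNA polymerase at single-base resolution (each
read's 5′ end marks the 3′ end of a nascent RNA), so one assay reports gene
transcription, promoter activity and enhancer (eRNA) activity at once.
`chrokit` turns per-strand signal tracks plus a gene annotation, a set of
transcriptional regulatory element (TRE) intervals and a matched RNA-seq
count matrix into:

* **activity matrices** — gene bodies (pause-excluded, TPM-normalized),
  promoters and TREs;
* **differential activity** — a transparent negative-binomial engine with
  median-of-ratios normalization, pairwise Wald contrasts and an
  across-stage likelihood-ratio test, BH-corrected;
* **stage-specific markers** — genes elevated in one stage versus all
  others in both transcription and steady-state expression;
* **the TRE landscape** — proximal/distal classification, gained/lost
  elements per stage transition, per-gene enhancer density within ±100 kb
  of the TSS, and enhancer-linked gene calls;
* **enhancer hotspots** — stage-specific enhancers stitched at < 12.5 kb,
  ranked by summed raw signal and thresholded by the super-enhancer-style
  tangent-line cutoff on the scaled rank curve, each assigned to its
  nearest active gene;
* **TF cistromes** — PWM motif scanning over enhancer sequences,
  hypergeometric motif enrichment, and per-TF candidate target gene sets
  from motif density around activated genes.

It is written for computational genomicists analyzing run-on data
(ChRO-seq/PRO-seq/GRO-seq) who want the full promoter→enhancer→hotspot→TF
chain as a tested, scriptable library rather than a collection of one-off
scripts. A bundled synthetic-data generator plants markers, stage-specific
enhancers, hotspot clusters and motif instances with a machine-readable
truth manifest, so the entire pipeline is benchmarked end-to-end with no
external downloads.

## The statistics in brief

Counts K_gs for feature g in sample s are modeled as NB(s_s·q_g, α_g) with
median-of-ratios size factors s_s. Gene-body activity uses sense-strand
reads over [TSS+500, TES) (the first 500 bp remove the promoter-proximal
pause peak; bodies < 1 kb are dropped), normalized to TPM_g = 10⁶·r_g/Σr
with r_g = K_g/(len_g − 500). Pairwise contrasts use a Wald statistic
z = log2FC/SE with SE² = (1/ln²2)·Σ_groups (1/μ + α)/n and gene-wise
method-of-moments dispersion floored at the cohort median; stage-pattern
tests use the NB likelihood ratio against a single-mean model (χ², df =
stages − 1). A stage marker satisfies TPM > 50, RNA base mean > 100 and,
versus every other stage in both assays, padj < 0.2, p < 0.05, FC > 1.5.
Stage-specific TREs satisfy padj < 0.05 and log2FC > 2.5 on both-strand raw
counts. Stitched enhancers with ascending signals s₁ ≤ … ≤ s_n are
hotspots above the signal at the first rank where the scaled curve
(x = (i−1)/(n−1), y = s_i/s_n) has slope > 1. Motif hits are log2-odds
windows reaching 80% of a PWM's maximum score; enrichment is the one-sided
hypergeometric tail; a TF's cistrome requires motif density > 0, TPM > 50,
RNA base mean > 500 and up-regulation in both assays.

## Worked example

Run the whole pipeline on the bundled synthetic dataset (simulation →
quantification → differential tests → markers → TRE landscape → hotspots →
cistromes):

```bash
chrokit all --outdir run1 --seed 1
```

The log reports each stage with the thresholds in effect:

```
INFO chrokit: quantify: 392 genes (8 dropped), 400 promoters, 1000 TREs x 12 samples
INFO chrokit: markers: Duo -> 89 genes (TPM>50, baseMean>100, FC>1.5)
INFO chrokit: tres: 228 gained (210 distal), 11 lost, 78 linked genes
INFO chrokit: hotspots: 70 stitched -> 20 hotspots (cutoff 598.0); 20 final genes
INFO chrokit: cistrome: MOTIF_A -> 78 genes
INFO chrokit: cistrome: MOTIF_B -> 0 genes
```

Reading the numbers: 8 of 400 genes have sub-kilobase bodies and are
excluded from gene-body analysis; the Duo-vs-DE transition gains 228 TREs of
which 210 are distal (enhancers); those stitch into 70 units of which the
tangent cutoff flags 20 as hotspots — exactly the planted clusters — at a
signal cutoff of 598 raw reads; all 20 hotspot-assigned genes survive the
dual ChRO+RNA up-regulation filter. The planted motif's cistrome recovers
78 activated genes near motif-bearing enhancers while the decoy motif
(`MOTIF_B`, never planted) yields none. Per-unit detail lands in
`run1/hotspots/stitched.tsv`:

```
stitch_id  chrom  start    end      n_members  total_signal  rank  is_hotspot  assigned_gene  assignment_distance
SE0000     chr1   759753   760103   1          430           14    False       G0051          9204
SE0001     chr1   1240801  1241151  1          541           42    False       G0288          6948
```

Every stage writes plain TSV/BED/JSON under the run directory, and
`manifest.json` records the config, seed and SHA-256 of every output; two
runs with the same seed are byte-identical.

## Layout

```
src/chrokit/
  genome_io.py       bedGraph/GTF/BED/FASTA I/O, exact signal extraction
  quantify.py        gene-body / promoter / TRE matrices, TPM, config
  diffexpr.py        NB engine: size factors, Wald, LRT, BH
  markers.py         stage markers, differential gene sets, promoter patterns
  tre_landscape.py   TRE classes, stage-specific calls, density, linking
  hotspots.py        stitching, tangent cutoff, gene assignment
  cistrome.py        PWM scanning, enrichment, motif density, cistromes
  synthetic_data.py  planted-truth dataset generator
  pipeline.py, cli.py  orchestration and the `chrokit` command
  evaluation.py      scoring a run against the truth manifest
```
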