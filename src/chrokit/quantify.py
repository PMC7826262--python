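"""Activity matrices from nascent-transcription signal.

Three feature kinds are quantified from ChRO-seq tracks:

* gene bodies — sense-strand counts over the transcription unit with the
  first 500 bp downstream of the TSS excluded (the promoter-proximal pause
  peak), then length-normalized to TPM;
* promoters — sense-strand counts over a fixed window around the TSS
  (500 bp upstream, 200 bp downstream), pause peak deliberately included;
* TREs — both-strand raw counts over each regulatory-element interval.

All statistics downstream consume the raw integer counts; TPM is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval, StrandedSignalTrack


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, in one place.

    Defaults are the study conditions of the differentiation analysis this
    package implements; all are overridable from the CLI config file.
    """

    # quantification windows (bp)
    pause_exclusion_bp: int = 500
    min_gene_body_bp: int = 1000
    promoter_upstream_bp: int = 500
    promoter_downstream_bp: int = 200
    # proximal-TRE (promoter) classification window around the TSS
    proximal_upstream_bp: int = 1000
    proximal_downstream_bp: int = 200
    # activity floor for "actively transcribed" genes (gene-body TPM)
    active_tpm: float = 50.0
    # pairwise differential-gene volcano thresholds
    diff_avg_tpm: float = 25.0
    diff_log2fc: float = 1.0
    diff_padj: float = 0.2
    diff_p: float = 0.05
    # marker / linking statistical thresholds
    marker_fold_change: float = 1.5
    marker_padj: float = 0.2
    marker_p: float = 0.05
    # promoter-pattern clustering
    promoter_cluster_tpm: float = 5.0
    promoter_cluster_padj: float = 0.05
    # stage-specific TRE calling
    tre_padj: float = 0.05
    tre_log2fc: float = 2.5
    tre_min_mean_count: float = 10.0
    # enhancer stitching / linking geometry
    stitch_gap_bp: int = 12500
    link_window_bp: int = 100_000
    # RNA-seq expression floors (size-factor-normalized base mean)
    rna_basemean_marker: float = 100.0
    rna_basemean_cistrome: float = 500.0
    # motif scanner
    min_relative_score: float = 0.8
    # strand handling for gene-body / promoter quantification
    gene_strand_mode: str = "sense"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ActivityMatrix:
    """Feature-by-sample activity: raw counts plus optional TPM."""

    kind: str  # gene_body | promoter | tre
    counts: pd.DataFrame  # features x samples, integer raw counts
    stages: pd.Series  # sample_id -> stage label
    tpm: pd.DataFrame | None = None
    effective_lengths: pd.Series | None = None
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature_id", "reason"])
    )

    def __post_init__(self):
        if list(self.counts.columns) != list(self.stages.index):
            raise ValueError("counts columns and stage design are inconsistent")

    def stage_samples(self, stage: str) -> list[str]:
        return list(self.stages.index[self.stages == stage])

    def stage_mean_tpm(self, stage: str) -> pd.Series:
        if self.tpm is None:
            raise ValueError("TPM not computed for this matrix")
        return self.tpm[self.stage_samples(stage)].mean(axis=1)

    def subset_samples(self, samples: list[str]) -> "ActivityMatrix":
        return ActivityMatrix(
            self.kind,
            self.counts[samples],
            self.stages.loc[samples],
            None if self.tpm is None else self.tpm[samples],
            self.effective_lengths,
            self.dropped,
        )


def _stage_series(tracks: list[StrandedSignalTrack]) -> pd.Series:
    ids = [t.sample_id for t in tracks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among tracks")
    return pd.Series([t.stage for t in tracks], index=ids, name="stage")


def _gene_body_window(gene: GeneModel, pause_bp: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.start + pause_bp, gene.end
    return gene.start, gene.end - pause_bp


def _promoter_window(gene: GeneModel, up: int, down: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    # mirrored: upstream is to the right of a minus-strand TSS
    return gene.tss - down + 1, gene.tss + up + 1


def quantify_gene_bodies(
    tracks: list[StrandedSignalTrack],
    genes: list[GeneModel],
    config: PipelineConfig | None = None,
) -> ActivityMatrix:
    """Pause-excluded sense-strand gene-body counts per sample.

    Genes with a body shorter than ``min_gene_body_bp`` are dropped and
    reported, mirroring the short-gene bias of pause-peak exclusion.
    """
    config = config or PipelineConfig()
    stages = _stage_series(tracks)
    kept, dropped = [], []
    for g in genes:
        if g.body_length < config.min_gene_body_bp:
            dropped.append((g.gene_id, f"gene body {g.body_length} bp < "
                            f"{config.min_gene_body_bp} bp"))
        else:
            kept.append(g)
    data = np.zeros((len(kept), len(tracks)), dtype=np.int64)
    for i, g in enumerate(kept):
        ws, we = _gene_body_window(g, config.pause_exclusion_bp)
        iv = GenomicInterval(g.chrom, ws, we, g.strand, g.gene_id)
        for j, t in enumerate(tracks):
            data[i, j] = int(t.extract(iv, config.gene_strand_mode))
    counts = pd.DataFrame(data, index=[g.gene_id for g in kept], columns=stages.index)
    eff = pd.Series(
        {g.gene_id: g.body_length - config.pause_exclusion_bp for g in kept},
        name="effective_length", dtype=float,
    )
    drop_df = pd.DataFrame(dropped, columns=["feature_id", "reason"])
    return ActivityMatrix("gene_body", counts, stages, None, eff, drop_df)


def to_tpm(matrix: ActivityMatrix) -> ActivityMatrix:
    """Length-normalize gene-body counts to transcripts per million.

    rate_g = count_g / effective_length_g; TPM_g = 1e6 * rate_g / sum(rates),
    per sample.  Column sums are exactly 1e6 (within float tolerance).
    """
    if matrix.kind != "gene_body":
        raise ValueError("TPM is defined for gene_body matrices")
    if matrix.effective_lengths is None or (matrix.effective_lengths <= 0).any():
        raise ValueError("effective lengths must be positive for TPM")
    rates = matrix.counts.div(matrix.effective_lengths.loc[matrix.counts.index], axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) {bad} have zero total rate; TPM undefined")
    tpm = rates.div(totals, axis=1) * 1e6
    return ActivityMatrix(
        matrix.kind, matrix.counts, matrix.stages, tpm,
        matrix.effective_lengths, matrix.dropped,
    )


def quantify_promoters(
    tracks: list[StrandedSignalTrack],
    genes: list[GeneModel],
    config: PipelineConfig | None = None,
) -> ActivityMatrix:
    """Sense-strand counts over the promoter-proximal window of every gene.

    The window is fixed relative to the annotated TSS (clipped to chromosome
    bounds) and intentionally contains the pause peak.
    """
    config = config or PipelineConfig()
    stages = _stage_series(tracks)
    clipped = []
    data = np.zeros((len(genes), len(tracks)), dtype=np.int64)
    for i, g in enumerate(genes):
        ws, we = _promoter_window(
            g, config.promoter_upstream_bp, config.promoter_downstream_bp
        )
        size = tracks[0].chrom_sizes.get(g.chrom)
        if size is None:
            raise ValueError(f"gene {g.gene_id} on undeclared chromosome {g.chrom}")
        cs, ce = max(ws, 0), min(we, size)
        if (cs, ce) != (ws, we):
            clipped.append((g.gene_id, f"promoter window clipped to [{cs},{ce})"))
        if cs >= ce:
            continue
        iv = GenomicInterval(g.chrom, cs, ce, g.strand, g.gene_id)
        for j, t in enumerate(tracks):
            data[i, j] = int(t.extract(iv, config.gene_strand_mode))
    counts = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=stages.index)
    clip_df = pd.DataFrame(clipped, columns=["feature_id", "reason"])
    win_len = float(config.promoter_upstream_bp + config.promoter_downstream_bp)
    eff = pd.Series(win_len, index=counts.index, name="effective_length")
    return ActivityMatrix("promoter", counts, stages, None, eff, clip_df)


def promoter_tpm(matrix: ActivityMatrix) -> pd.DataFrame:
    """Per-sample promoter activity on a TPM-like scale (fixed window length)."""
    rates = matrix.counts.div(matrix.effective_lengths, axis=0)
    totals = rates.sum(axis=0)
    return rates.div(totals.replace(0, np.nan), axis=1) * 1e6


def quantify_tres(
    tracks: list[StrandedSignalTrack], tres: pd.DataFrame
) -> ActivityMatrix:
    """Both-strand raw counts per TRE interval per sample.

    ``tres`` columns: name (unique), chrom, start, end.
    """
    stages = _stage_series(tracks)
    if tres["name"].duplicated().any():
        dup = tres["name"][tres["name"].duplicated()].iloc[0]
        raise ValueError(f"duplicate TRE id {dup!r}")
    data = np.zeros((len(tres), len(tracks)), dtype=np.int64)
    for i, row in enumerate(tres.itertuples(index=False)):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), None, row.name)
        for j, t in enumerate(tracks):
            data[i, j] = int(t.extract(iv, "both"))
    counts = pd.DataFrame(data, index=list(tres["name"]), columns=stages.index)
    return ActivityMatrix("tre", counts, stages)
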