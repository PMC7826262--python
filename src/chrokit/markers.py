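"""Stage-specific marker genes from nascent transcription plus RNA-seq.

A marker of a stage must be both highly transcribed (gene-body TPM) and
highly expressed (RNA base mean) in that stage, and significantly elevated
relative to every other stage in both assays.  Shared spheroid markers
relax only the fold-change requirement between the two spheroid stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DesignError, base_means, lrt_test, wald_test
from .genome_io import GeneModel
from .quantify import ActivityMatrix, PipelineConfig, promoter_tpm


@dataclass
class MarkerSet:
    stage: str
    genes: list[str]
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)


def _up_criteria(res: pd.DataFrame, config: PipelineConfig) -> pd.Series:
    """One-sided 'significantly elevated' mask on a Wald result table."""
    return (
        (res["padj"] < config.marker_padj)
        & (res["pvalue"] < config.marker_p)
        & (res["log2FoldChange"] > np.log2(config.marker_fold_change))
    )


def find_differential_genes(
    chro: ActivityMatrix, stage: str, other: str,
    config: PipelineConfig | None = None,
) -> dict:
    """Volcano-style up/down gene sets for one pairwise contrast.

    Thresholds: average TPM across the two stages, |log2FC|, padj and p.
    """
    config = config or PipelineConfig()
    for s in (stage, other):
        if s not in set(chro.stages):
            raise DesignError(f"stage {s!r} absent from the design")
    res = wald_test(chro.counts, chro.stages, stage, other)
    avg_tpm = (chro.stage_mean_tpm(stage) + chro.stage_mean_tpm(other)) / 2
    passing = (
        (avg_tpm.loc[res.index] > config.diff_avg_tpm)
        & (res["padj"] < config.diff_padj)
        & (res["pvalue"] < config.diff_p)
    )
    up = sorted(res.index[passing & (res["log2FoldChange"] > config.diff_log2fc)])
    down = sorted(res.index[passing & (res["log2FoldChange"] < -config.diff_log2fc)])
    table = res.copy()
    table["avg_tpm"] = avg_tpm.loc[res.index]
    table["call"] = "ns"
    table.loc[up, "call"] = "up"
    table.loc[down, "call"] = "down"
    return {"up": up, "down": down, "table": table}


def _gene_filter(genes: list[GeneModel], config: PipelineConfig) -> set[str]:
    """Genes eligible for marker analysis: long enough, not pseudogenes."""
    return {
        g.gene_id
        for g in genes
        if g.body_length >= config.min_gene_body_bp
        and "pseudogene" not in g.biotype.lower()
    }


def find_stage_markers(
    chro: ActivityMatrix,
    rna_counts: pd.DataFrame,
    rna_stages: pd.Series,
    genes: list[GeneModel],
    stage: str,
    config: PipelineConfig | None = None,
    other_stages: list[str] | None = None,
) -> MarkerSet:
    """Markers of one stage: the intersection of ChRO-seq and RNA-seq evidence.

    ChRO-seq arm: gene-body TPM above the activity floor in the stage of
    interest and significantly elevated versus each other stage.  RNA-seq
    arm: stage base mean above the expression floor with the same
    statistical criteria.
    """
    config = config or PipelineConfig()
    if chro.tpm is None:
        raise ValueError("gene-body matrix must carry TPM")
    stage_list = list(dict.fromkeys(chro.stages))
    others = other_stages if other_stages is not None else [
        s for s in stage_list if s != stage
    ]
    if (chro.stages == stage).sum() < 2 or (rna_stages == stage).sum() < 2:
        raise DesignError(f"stage {stage!r} needs >=2 samples in both assays")
    eligible = _gene_filter(genes, config)
    candidates = pd.Index(sorted(eligible & set(chro.counts.index)
                                 & set(rna_counts.index)))

    chro_tpm_stage = chro.stage_mean_tpm(stage).reindex(candidates)
    rna_bm = base_means(rna_counts, rna_stages).reindex(candidates)
    ok = (chro_tpm_stage > config.active_tpm) & (
        rna_bm[stage] > config.rna_basemean_marker
    )
    evidence = pd.DataFrame({
        "chro_tpm": chro_tpm_stage, "rna_basemean": rna_bm[stage],
    })
    for other in others:
        cres = wald_test(chro.counts, chro.stages, stage, other).reindex(candidates)
        rres = wald_test(rna_counts, rna_stages, stage, other).reindex(candidates)
        ok &= _up_criteria(cres, config) & _up_criteria(rres, config)
        evidence[f"chro_log2fc_vs_{other}"] = cres["log2FoldChange"]
        evidence[f"chro_padj_vs_{other}"] = cres["padj"]
        evidence[f"rna_log2fc_vs_{other}"] = rres["log2FoldChange"]
        evidence[f"rna_padj_vs_{other}"] = rres["padj"]
    members = sorted(candidates[ok.fillna(False)])
    return MarkerSet(stage, members, evidence.loc[members])


def find_shared_spheroid_markers(
    chro: ActivityMatrix,
    rna_counts: pd.DataFrame,
    rna_stages: pd.Series,
    genes: list[GeneModel],
    spheroid_stages: tuple[str, str] = ("Duo", "Ile"),
    config: PipelineConfig | None = None,
) -> MarkerSet:
    """Markers shared by both spheroid stages irrespective of regional identity.

    The full criteria are applied versus every non-spheroid stage from each
    spheroid stage; no fold-change requirement is imposed between the two
    spheroid stages, but the activity and expression floors must hold in
    both.
    """
    config = config or PipelineConfig()
    non_spheroid = [s for s in dict.fromkeys(chro.stages)
                    if s not in spheroid_stages]
    member_sets = []
    evidence = None
    for stage in spheroid_stages:
        ms = find_stage_markers(
            chro, rna_counts, rna_stages, genes, stage, config,
            other_stages=non_spheroid,
        )
        member_sets.append(set(ms.genes))
        ev = ms.evidence.add_prefix(f"{stage}_")
        evidence = ev if evidence is None else evidence.join(ev, how="outer")
    members = sorted(member_sets[0] & member_sets[1])
    label = "_".join(spheroid_stages) + "_shared"
    return MarkerSet(label, members, evidence.loc[members])


def cluster_promoter_patterns(
    promoters: ActivityMatrix,
    genes: list[GeneModel],
    config: PipelineConfig | None = None,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 12),
) -> pd.DataFrame:
    """Cluster genes by their stage profile of promoter activity.

    Protein-coding genes whose promoter activity changes significantly
    across stages (likelihood-ratio test) and exceeds the average-TPM floor
    are standardized per gene (z-score of stage means) and clustered
    hierarchically with correlation distance; when ``k`` is not given it is
    chosen by silhouette score over ``k_range``.  Deterministic given inputs.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist, squareform
    from sklearn.metrics import silhouette_score

    config = config or PipelineConfig()
    coding = {g.gene_id for g in genes if g.biotype == "protein_coding"}
    ptpm = promoter_tpm(promoters)
    avg_tpm = ptpm.mean(axis=1)
    res = lrt_test(promoters.counts, promoters.stages)
    passing = sorted(
        set(res.index[(res["padj"] < config.promoter_cluster_padj)])
        & set(avg_tpm.index[avg_tpm > config.promoter_cluster_tpm])
        & coding
    )
    if len(passing) < 2:
        raise DesignError("fewer than 2 genes pass the promoter-pattern filter")
    stage_list = list(dict.fromkeys(promoters.stages))
    prof = pd.DataFrame({
        s: promoters.counts.loc[passing, promoters.stage_samples(s)].mean(axis=1)
        for s in stage_list
    })
    z = prof.sub(prof.mean(axis=1), axis=0)
    sd = prof.std(axis=1, ddof=0).replace(0, 1.0)
    z = z.div(sd, axis=0)
    dist = pdist(z.to_numpy(), metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    link = linkage(dist, method="average")
    if k is None:
        best_k, best_score = None, -np.inf
        dmat = squareform(dist)
        for kk in range(k_range[0], min(k_range[1], len(passing) - 1) + 1):
            labels = fcluster(link, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(dmat, labels, metric="precomputed")
            if score > best_score + 1e-12:
                best_k, best_score = kk, score
        k = best_k if best_k is not None else 2
    labels = fcluster(link, k, criterion="maxclust")
    out = pd.DataFrame({"gene_id": passing, "cluster": labels}).set_index(
        "gene_id", drop=False
    )
    for s in stage_list:
        out[f"z_{s}"] = z[s]
    out.attrs["k"] = int(k)
    return out
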