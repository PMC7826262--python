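"""TRE classification, stage-specific calling, density and gene linking.

TREs overlapping (by at least one base) the -1000/+200 window around any
annotated TSS are proximal elements (promoters); all others are distal
(enhancers).  Stage-specific TREs are those whose both-strand signal is
significantly higher in the stage of interest than in a comparison stage.
Per-gene enhancer density counts stage-specific TREs overlapping a window
of +/-100 kb around the TSS of each actively transcribed gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DesignError, base_means, wald_test
from .genome_io import GeneModel
from .quantify import ActivityMatrix, PipelineConfig


def tss_window(gene: GeneModel, up: int = 1000, down: int = 200) -> tuple[int, int]:
    """Strand-aware promoter-proximal window around the TSS, half-open."""
    t = gene.tss
    if gene.strand == "+":
        return t - up, t + down
    return t - down + 1, t + up + 1


def classify_tres(
    tres: pd.DataFrame, genes: list[GeneModel],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Partition TREs into proximal (promoter) and distal (enhancer) classes."""
    config = config or PipelineConfig()
    win_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        win_by_chrom.setdefault(g.chrom, []).append(
            tss_window(g, config.proximal_upstream_bp, config.proximal_downstream_bp)
        )
    starts, ends = {}, {}
    for chrom, wins in win_by_chrom.items():
        wins.sort()
        starts[chrom] = np.array([w[0] for w in wins])
        ends[chrom] = np.array([w[1] for w in wins])
    cls = []
    for row in tres.itertuples(index=False):
        chrom = row.chrom
        if chrom not in starts:
            cls.append("distal")
            continue
        i0 = np.searchsorted(ends[chrom], row.start, side="right")
        i1 = np.searchsorted(starts[chrom], row.end, side="left")
        cls.append("proximal" if i1 > i0 else "distal")
    out = tres.copy()
    out["tre_class"] = cls
    return out


def call_stage_specific_tres(
    tre_matrix: ActivityMatrix,
    stage: str,
    other: str,
    config: PipelineConfig | None = None,
) -> dict:
    """Gained / lost / unchanged TREs for one stage transition.

    Tested TREs are the union of elements active (mean raw both-strand count
    above a floor) in either stage; gained = significantly higher in the
    stage of interest (padj and log2FC thresholds), lost is the mirror image,
    unchanged the remainder of the tested set.
    """
    config = config or PipelineConfig()
    for s in (stage, other):
        if s not in set(tre_matrix.stages):
            raise DesignError(f"stage {s!r} absent from the TRE design")
    counts = tre_matrix.counts
    mean_a = counts[tre_matrix.stage_samples(stage)].mean(axis=1)
    mean_b = counts[tre_matrix.stage_samples(other)].mean(axis=1)
    tested = counts.index[
        (mean_a >= config.tre_min_mean_count) | (mean_b >= config.tre_min_mean_count)
    ]
    res = wald_test(counts.loc[tested], tre_matrix.stages, stage, other)
    gained_mask = (res["padj"] < config.tre_padj) & (
        res["log2FoldChange"] > config.tre_log2fc
    )
    lost_mask = (res["padj"] < config.tre_padj) & (
        res["log2FoldChange"] < -config.tre_log2fc
    )
    gained = sorted(res.index[gained_mask])
    lost = sorted(res.index[lost_mask])
    unchanged = sorted(res.index[~(gained_mask | lost_mask)])
    return {
        "gained": gained, "lost": lost, "unchanged": unchanged,
        "tested": list(tested), "result": res,
    }


def _window_around_tss(tss: int, window: int) -> tuple[int, int]:
    # closed +/-window around the TSS; a half-open TRE [s, e) overlaps it
    # iff s <= tss + window and e > tss - window
    return tss - window, tss + window


def compute_tre_density(
    genes: list[GeneModel],
    tre_intervals: pd.DataFrame,
    stage_tpm: pd.Series,
    config: PipelineConfig | None = None,
    mode: str = "overlap",
) -> pd.Series:
    """Count stage-specific TREs near each actively transcribed gene's TSS.

    ``mode='overlap'`` counts a TRE when it overlaps the closed window by at
    least one base; ``mode='midpoint'`` when its midpoint falls inside.
    """
    config = config or PipelineConfig()
    active = [g for g in genes if stage_tpm.get(g.gene_id, 0.0) > config.active_tpm]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in tre_intervals.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    s_arr, e_arr, mid_arr = {}, {}, {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        s_arr[chrom] = np.array([r[0] for r in rows])
        e_arr[chrom] = np.array([r[1] for r in rows])
        mid_arr[chrom] = np.sort((s_arr[chrom] + e_arr[chrom]) // 2)
    out = {}
    w = config.link_window_bp
    for g in active:
        lo, hi = _window_around_tss(g.tss, w)
        if g.chrom not in s_arr:
            out[g.gene_id] = 0
            continue
        if mode == "overlap":
            n = int(np.sum((s_arr[g.chrom] <= hi) & (e_arr[g.chrom] > lo)))
        elif mode == "midpoint":
            m = mid_arr[g.chrom]
            n = int(np.searchsorted(m, hi, "right") - np.searchsorted(m, lo, "left"))
        else:
            raise ValueError(f"unknown density mode {mode!r}")
        out[g.gene_id] = n
    return pd.Series(out, name="density", dtype=int).sort_index()


def link_density_genes(
    densities: pd.Series,
    chro: ActivityMatrix,
    rna_counts: pd.DataFrame,
    rna_stages: pd.Series,
    stage: str,
    other: str,
    config: PipelineConfig | None = None,
) -> dict:
    """Genes linked to stage-specific TREs: dense, active, expressed and up.

    Returns the link table plus a density-bin report (zero / low / high by
    median split of positive densities) with a one-sided rank-sum test of
    ChRO log2 fold change between the high and zero bins.
    """
    config = config or PipelineConfig()
    cres = wald_test(chro.counts, chro.stages, stage, other)
    rres = wald_test(rna_counts, rna_stages, stage, other)
    rna_bm = base_means(rna_counts, rna_stages)
    idx = densities.index
    thr = np.log2(config.marker_fold_change)

    def up(res):
        r = res.reindex(idx)
        return (
            (r["padj"] < config.marker_padj)
            & (r["pvalue"] < config.marker_p)
            & (r["log2FoldChange"] > thr)
        ).fillna(False)

    table = pd.DataFrame({
        "gene_id": idx,
        "density": densities,
        "passes_activity": chro.stage_mean_tpm(stage).reindex(idx) > config.active_tpm,
        "passes_expression": rna_bm[stage].reindex(idx) > config.rna_basemean_marker,
        "passes_upregulation": up(cres) & up(rres),
        "chro_log2fc": cres["log2FoldChange"].reindex(idx),
    }).set_index("gene_id", drop=False)
    table["linked"] = (
        (table["density"] > 0)
        & table["passes_activity"]
        & table["passes_expression"].fillna(False)
        & table["passes_upregulation"]
    )
    pos = table.loc[table["density"] > 0, "density"]
    if len(pos):
        med = float(pos.median())
        high = table["density"] > med
        if not high.any():  # tied positive densities: all count as high
            high = table["density"] > 0
        bins = np.where(
            table["density"] == 0, "zero", np.where(high, "high", "low")
        )
    else:
        bins = np.full(len(table), "zero")
    table["density_bin"] = bins
    hi = table.loc[table["density_bin"] == "high", "chro_log2fc"].dropna()
    zero = table.loc[table["density_bin"] == "zero", "chro_log2fc"].dropna()
    if len(hi) and len(zero):
        p = float(stats.mannwhitneyu(hi, zero, alternative="greater").pvalue)
    else:
        p = float("nan")
    return {
        "table": table,
        "linked": sorted(table.index[table["linked"]]),
        "rank_test_high_vs_zero_p": p,
    }


def union_coverage(
    start: int, end: int, peaks: list[tuple[int, int]]
) -> int:
    """Bases of [start, end) covered by the union of peak intervals."""
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in peaks if s < end and e > start
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def intersect_external(
    regions: pd.DataFrame, peaks: pd.DataFrame
) -> pd.DataFrame:
    """Overlap table of regions against an external peak set (>=1 base).

    Adds ``overlaps`` and ``covered_fraction`` (fraction of each region's
    length covered by the union of peaks).
    """
    peaks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in peaks.itertuples(index=False):
        peaks_by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    out = regions.copy()
    ov, frac = [], []
    for row in regions.itertuples(index=False):
        plist = peaks_by_chrom.get(row.chrom, [])
        cov = union_coverage(int(row.start), int(row.end), plist)
        ov.append(cov > 0)
        frac.append(cov / (int(row.end) - int(row.start)))
    out["overlaps"] = ov
    out["covered_fraction"] = frac
    return out
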