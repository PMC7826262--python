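"""PWM motif scanning, enrichment and TF cistrome construction.

A transparent log-odds scanner over TRE sequences stands in for empirically
tuned motif tools: hits are windows whose log2 odds versus a uniform
background reach a fraction of the motif's maximum attainable score, on
either strand.  Enrichment of a motif in stage-specific TREs against a
background TRE set uses the one-sided hypergeometric test; candidate
cistromes are activated genes with motif-bearing stage-specific TREs near
their TSS.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import base_means, wald_test
from .genome_io import GeneModel
from .quantify import ActivityMatrix, PipelineConfig

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T."""

    motif_id: str
    matrix: np.ndarray  # 4 x L, columns sum to 1
    background: np.ndarray | None = None  # length 4; uniform if None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: PWM must be 4 x L with L >= 4")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, pseudocount: float = 1e-3) -> np.ndarray:
        """5 x L log2-odds matrix (row 4 = N, minus infinity)."""
        bg = self.background if self.background is not None else np.full(4, 0.25)
        m = self.matrix + pseudocount
        m = m / m.sum(axis=0, keepdims=True)
        lo = np.log2(m / bg[:, None])
        return np.vstack([lo, np.full((1, self.length), -np.inf)])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def read_pwms(path: str | os.PathLike) -> list[PWM]:
    """Read JASPAR-style 4-row count/probability matrices."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        out.append(PWM(rec.name or rec.matrix_id, probs))
    return out


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN symbol {exc.args[0]!r}") from exc


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    L = lo.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo[windows, np.arange(L)].sum(axis=1)


def scan_motifs(
    sequences: dict[str, str],
    pwm: PWM,
    min_relative_score: float | None = None,
    config: PipelineConfig | None = None,
    pseudocount: float = 1e-3,
) -> pd.DataFrame:
    """Scan sequences on both strands for PWM hits.

    A hit is any window whose log2-odds score reaches
    ``min_relative_score`` x (maximum attainable score); windows containing
    N are skipped; overlapping hits are retained.  Returns columns
    tre_id, offset, strand, score, relative_score.
    """
    if min_relative_score is None:
        min_relative_score = (config or PipelineConfig()).min_relative_score
    lo = pwm.log_odds(pseudocount)
    max_score = float(lo[:4].max(axis=0).sum())
    if max_score <= 0:
        raise ValueError(f"{pwm.motif_id}: non-positive maximum log-odds score")
    thr = min_relative_score * max_score
    L = pwm.length
    recs = []
    for tre_id in sequences:
        seq = sequences[tre_id].upper()
        codes = _encode(seq)
        n = codes.size
        fwd = _scan_one_strand(codes, lo)
        hits = np.flatnonzero(fwd >= thr)
        for off in hits:
            recs.append((tre_id, int(off), "+", float(fwd[off])))
        rc = _encode(revcomp(seq))
        rev = _scan_one_strand(rc, lo)
        for off in np.flatnonzero(rev >= thr):
            recs.append((tre_id, int(n - L - off), "-", float(rev[off])))
    df = pd.DataFrame(recs, columns=["tre_id", "offset", "strand", "score"])
    df["relative_score"] = df["score"] / max_score
    df["motif_id"] = pwm.motif_id
    return df.sort_values(["tre_id", "offset", "strand"], kind="mergesort").reset_index(drop=True)


def test_motif_enrichment(
    target_tres: list[str],
    background_tres: list[str],
    hits_by_motif: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-motif enrichment of targets over background TREs.

    k of n target TREs and K of N background TREs carry >= 1 hit; p is the
    one-sided hypergeometric tail, fold = (k/n)/(K/N), BH across motifs.
    """
    from .diffexpr import bh_adjust

    target = set(target_tres)
    background = set(background_tres)
    if target & background:
        raise ValueError("target and background TRE sets must be disjoint")
    if not background:
        raise ValueError("background TRE set is empty")
    n, N = len(target), len(background)
    rows = []
    for motif_id, hits in sorted(hits_by_motif.items()):
        with_hit = set(hits["tre_id"])
        k = len(target & with_hit)
        K = len(background & with_hit)
        # population n+N with k+K marked; draw n; observe k
        p = float(stats.hypergeom.sf(k - 1, n + N, k + K, n))
        fold = (k / n) / (K / N) if K > 0 and n > 0 else np.inf if k else np.nan
        rows.append((motif_id, k, n, K, N, fold, p))
    out = pd.DataFrame(
        rows, columns=["motif_id", "k_target", "n_target", "k_background",
                       "n_background", "fold", "pvalue"],
    ).set_index("motif_id", drop=False)
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def motif_density(
    genes: list[GeneModel],
    stage_tres: pd.DataFrame,
    hits: pd.DataFrame,
    stage_tpm: pd.Series,
    config: PipelineConfig | None = None,
    count_tres: bool = False,
) -> pd.Series:
    """Motif hits in stage-specific TREs near each active gene's TSS.

    Counts individual hits inside qualifying TREs whose interval overlaps
    the closed +/- ``link_window_bp`` window around the TSS (``count_tres``
    switches to counting motif-bearing TREs instead of hits).
    """
    config = config or PipelineConfig()
    n_hits = hits.groupby("tre_id").size()
    per_tre = (n_hits > 0).astype(int) if count_tres else n_hits
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for row in stage_tres.itertuples(index=False):
        cnt = int(per_tre.get(row.name, 0))
        if cnt:
            by_chrom.setdefault(row.chrom, []).append(
                (int(row.start), int(row.end), cnt)
            )
    active = [g for g in genes if stage_tpm.get(g.gene_id, 0.0) > config.active_tpm]
    w = config.link_window_bp
    out = {}
    for g in active:
        lo, hi = g.tss - w, g.tss + w
        total = sum(
            cnt for s, e, cnt in by_chrom.get(g.chrom, []) if s <= hi and e > lo
        )
        out[g.gene_id] = total
    return pd.Series(out, name="motif_density", dtype=int).sort_index()


def cistrome_genes(
    densities: pd.Series,
    chro: ActivityMatrix,
    rna_counts: pd.DataFrame,
    rna_stages: pd.Series,
    stage: str,
    other: str,
    config: PipelineConfig | None = None,
) -> dict:
    """Candidate cistrome of one TF in one stage transition.

    Members have motif density > 0, are actively transcribed (TPM floor),
    highly expressed (cistrome RNA base-mean floor), and significantly up
    in both assays.
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
        "motif_density": densities,
        "passes_activity": chro.stage_mean_tpm(stage).reindex(idx) > config.active_tpm,
        "passes_expression": (
            rna_bm[stage].reindex(idx) > config.rna_basemean_cistrome
        ).fillna(False),
        "passes_upregulation": up(cres) & up(rres),
    }).set_index("gene_id", drop=False)
    table["member"] = (
        (table["motif_density"] > 0)
        & table["passes_activity"]
        & table["passes_expression"]
        & table["passes_upregulation"]
    )
    return {"table": table, "genes": sorted(table.index[table["member"]])}
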