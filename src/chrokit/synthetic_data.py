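"""Synthetic nascent-transcription dataset with planted ground truth.

Generates a small genome, gene annotation, TRE intervals, stranded
polymerase-position tracks, and a matched RNA-seq count matrix for a
four-stage directed-differentiation design, together with a machine-readable
truth manifest (planted markers, stage-specific enhancers, enhancer-hotspot
clusters, motif instances) so every downstream analysis can be scored
against known answers.

Signal model per ChRO-seq sample:

* each gene draws a total read count ~ NB(stage rate, dispersion); a
  ``pause_fraction`` of reads lands uniformly in the first 500 bp downstream
  of the TSS (the promoter-proximal pause peak) and the rest uniformly over
  the remaining gene body, all on the sense strand;
* each TRE draws ~ NB(stage rate) reads split evenly into a divergent eRNA
  pair: plus-strand reads downstream of the element center, minus-strand
  reads upstream, uniform within the peak half-width;
* a low uniform Poisson background is added per strand.

RNA-seq counts per gene are NB around library_size x (stage rate share) x a
per-gene log-normal offset modeling post-transcriptional regulation; the
offset standard deviation defaults to the value that puts the genome-wide
correlation between log transcription and log expression near 0.7.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_io import GeneModel, StrandedSignalTrack, write_bed, write_bed12, write_fasta, write_gtf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


class PlacementError(RuntimeError):
    """Raised when a planted element cannot be placed under the constraints."""


@dataclass
class SyntheticConfig:
    """Study conditions of the bundled synthetic dataset."""

    n_chroms: int = 20
    chrom_length: int = 2_000_000
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (2000, 50_000)  # log-uniform
    n_short_genes: int = 8           # bodies < 1 kb, exercise the length filter
    short_length_range: tuple[int, int] = (400, 900)
    pseudogene_fraction: float = 0.05
    stages: tuple[str, ...] = ("hESC", "DE", "Duo", "Ile")
    replicates: int = 3
    rna_replicates: int = 3
    baseline_rate: float = 500.0      # expected reads per gene per sample
    rate_log_sd: float = 1.2          # log-normal spread of gene baselines
    pause_fraction: float = 0.4
    dispersion: float = 0.05
    n_tres: int = 1000
    n_promoter_tres: int = 300
    tre_halfspan: int = 175           # TRE interval = center +/- halfspan
    erna_halfwidth: int = 150         # eRNA peak half-width within the TRE
    tre_baseline_rate: float = 100.0
    markers_per_stage: int = 30
    marker_log2fc: float = 3.0
    n_shared_spheroid_markers: int = 20
    n_specific_enhancers: int = 50    # singleton stage-specific enhancers
    enhancer_log2fc: float = 4.0
    enhancer_base_rate: float = 10.0
    n_hotspot_clusters: int = 20
    hotspot_members: int = 8
    hotspot_signal_mult: float = 10.0  # member signal vs singleton enhancer
    hotspot_target_log2fc: float = 4.0
    singleton_target_log2fc: float = 1.5
    cluster_gap_range: tuple[int, int] = (2000, 12_000)  # < stitch gap
    element_separation: int = 20_000  # between distinct planted units
    background_per_kb: float = 0.01
    rna_library_size: float = 5e6
    rna_coupling_sd: float = 0.9
    rna_dispersion: float = 0.05
    stage_of_interest: str = "Duo"
    comparison_stage: str = "DE"
    motifs: dict[str, str] = field(default_factory=lambda: {
        "MOTIF_A": "ACGGAAGTCCGT",   # planted in stage-specific enhancers
        "MOTIF_B": "TTGCCATAGCAA",   # decoy, never planted
    })
    designation_quantile: float = 0.4  # planted genes drawn above this baseline
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for recovery tests."""

    config: SyntheticConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    gene_table: pd.DataFrame        # gene_id, chrom, start, end, strand, biotype, baseline
    gene_rates: pd.DataFrame        # genes x stages, expected reads/sample
    rna_offsets: pd.Series          # per-gene post-transcriptional multiplier
    marker_genes: dict[str, list[str]]
    shared_spheroid_markers: list[str]
    tres: pd.DataFrame              # name, chrom, start, end, kind, cluster_id, target_gene
    tre_rates: pd.DataFrame         # tres x stages
    hotspot_clusters: pd.DataFrame  # cluster_id, member tre ids, target_gene
    motif_instances: pd.DataFrame   # motif_id, tre_id, chrom, start, strand
    genome: dict[str, np.ndarray]   # chrom -> uint8 base codes

    # -- derived -----------------------------------------------------------
    def expected_tpm(self) -> pd.DataFrame:
        """Expected gene-body TPM per stage under the placement model."""
        lens = pd.Series({g.gene_id: g.body_length for g in self.genes})
        keep = lens.index[lens >= 1000]
        eff = lens.loc[keep] - 500.0
        body = self.gene_rates.loc[keep].mul(1 - self.config.pause_fraction)
        rates = body.div(eff, axis=0)
        return rates.div(rates.sum(axis=0), axis=1) * 1e6

    def stage_specific_tres(self) -> list[str]:
        return list(self.tres.loc[self.tres["kind"].isin(
            ["singleton_enhancer", "cluster_member"]), "name"])

    def genome_sequences(self) -> dict[str, str]:
        return {c: arr.tobytes().decode("ascii") for c, arr in self.genome.items()}

    def tre_sequence(self, tre_id: str) -> str:
        row = self.tres.set_index("name").loc[tre_id]
        return self.genome[row["chrom"]][row["start"]:row["end"]].tobytes().decode()

    def manifest(self) -> dict:
        return {
            "chrom_sizes": self.chrom_sizes,
            "stages": list(self.config.stages),
            "marker_genes": self.marker_genes,
            "shared_spheroid_markers": self.shared_spheroid_markers,
            "stage_specific_tres": self.stage_specific_tres(),
            "singleton_enhancers": list(
                self.tres.loc[self.tres["kind"] == "singleton_enhancer", "name"]),
            "hotspot_clusters": [
                {"cluster_id": row.cluster_id,
                 "members": row.members.split(","),
                 "target_gene": row.target_gene}
                for row in self.hotspot_clusters.itertuples(index=False)
            ],
            "singleton_targets": sorted(set(
                self.tres.loc[self.tres["kind"] == "singleton_enhancer",
                              "target_gene"].dropna())),
            "motif_instances": self.motif_instances.to_dict(orient="records"),
            "gene_rates": {
                s: self.gene_rates[s].round(6).to_dict() for s in self.gene_rates
            },
        }


# ---------------------------------------------------------------------------
# placement helpers


def _interval_distance(tss: int, start: int, end: int) -> int:
    return max(start - tss, tss - (end - 1), 0)


class _TssIndex:
    """Per-chromosome sorted TSS-window and TSS arrays for overlap queries."""

    def __init__(self, genes: list[GeneModel], up: int = 1000, down: int = 200):
        self.win: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.tss: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list] = {}
        for g in genes:
            t = g.tss
            if g.strand == "+":
                ws, we = t - up, t + down
            else:
                ws, we = t - down + 1, t + up + 1
            by_chrom.setdefault(g.chrom, []).append((ws, we, t))
        for chrom, rows in by_chrom.items():
            rows.sort()
            s = np.array([r[0] for r in rows])
            e = np.array([r[1] for r in rows])
            self.win[chrom] = (s, e)
            self.tss[chrom] = np.sort(np.array([r[2] for r in rows]))

    def overlaps_window(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.win:
            return False
        s, e = self.win[chrom]
        i0 = np.searchsorted(e, start, side="right")
        i1 = np.searchsorted(s, end, side="left")
        return i1 > i0


# ---------------------------------------------------------------------------
# truth construction


def build_truth(config: SyntheticConfig | None = None) -> SyntheticTruth:
    """Build the full planted dataset skeleton, deterministic in the seed."""
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(cfg.seed)
    (ss_genome, ss_genes, ss_rates, ss_tres, ss_motifs) = root.spawn(5)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    sizes = {c: cfg.chrom_length for c in chroms}

    genome = _random_genome(sizes, np.random.default_rng(ss_genome))
    genes = _place_genes(cfg, chroms, sizes, np.random.default_rng(ss_genes))
    (base_s, rna_offsets, marker_genes, shared, candidates,
     partial_rates) = _assign_rates(cfg, genes, np.random.default_rng(ss_rates))
    tres, clusters, hotspot_targets, singleton_targets = _place_tres(
        cfg, genes, partial_rates, sizes, candidates, np.random.default_rng(ss_tres)
    )
    gene_rates = partial_rates.copy()
    duo = cfg.stage_of_interest
    for gid in hotspot_targets:
        gene_rates.loc[gid, duo] = base_s[gid] * 2 ** cfg.hotspot_target_log2fc
    for gid in singleton_targets:
        gene_rates.loc[gid, duo] = base_s[gid] * 2 ** cfg.singleton_target_log2fc
    tre_rates = _tre_rate_table(cfg, tres)
    motif_instances = _plant_motifs(
        cfg, tres, genome, np.random.default_rng(ss_motifs)
    )
    gene_table = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "start": [g.start for g in genes],
        "end": [g.end for g in genes],
        "strand": [g.strand for g in genes],
        "biotype": [g.biotype for g in genes],
    }).set_index("gene_id", drop=False)
    gene_table["baseline_rate"] = base_s
    return SyntheticTruth(
        cfg, sizes, genes, gene_table, gene_rates, rna_offsets, marker_genes,
        shared, tres, tre_rates, clusters, motif_instances, genome,
    )


def _expected_stage_tpm(cfg, genes, rates: pd.DataFrame, stage: str) -> pd.Series:
    lens = pd.Series({g.gene_id: g.body_length for g in genes})
    keep = lens.index[lens >= 1000]
    eff = lens.loc[keep] - 500.0
    body = rates.loc[keep, stage] * (1 - cfg.pause_fraction)
    tpm = body / eff
    return tpm / tpm.sum() * 1e6


def _random_genome(sizes: dict[str, int], rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        chrom: _BASES[rng.integers(0, 4, size=size)]
        for chrom, size in sizes.items()
    }


def _place_genes(cfg, chroms, sizes, rng) -> list[GeneModel]:
    margin = 2000
    lengths = np.exp(rng.uniform(
        np.log(cfg.gene_length_range[0]), np.log(cfg.gene_length_range[1]),
        size=cfg.n_genes - cfg.n_short_genes,
    )).astype(int)
    short = rng.integers(
        cfg.short_length_range[0], cfg.short_length_range[1] + 1,
        size=cfg.n_short_genes,
    )
    all_lengths = np.concatenate([lengths, short])
    placed: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    n_pseudo = int(round(cfg.pseudogene_fraction * cfg.n_genes))
    pseudo_idx = set(rng.choice(cfg.n_genes, size=n_pseudo, replace=False).tolist())
    for i, length in enumerate(all_lengths):
        for _ in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            hi = sizes[chrom] - margin - int(length)
            if hi <= margin:
                continue
            start = int(rng.integers(margin, hi))
            end = start + int(length)
            nested = any(
                c == chrom and ((start <= s and e <= end) or (s <= start and end <= e))
                for c, s, e in placed
            )
            if nested:
                continue
            placed.append((chrom, start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (
                "processed_pseudogene" if i in pseudo_idx else "protein_coding"
            )
            genes.append(GeneModel(f"G{i:04d}", chrom, start, end, strand, biotype))
            break
        else:
            raise PlacementError(
                f"could not place gene {i} (length {length}) after 500 attempts"
            )
    return genes


def _assign_rates(cfg, genes, rng):
    ids = [g.gene_id for g in genes]
    base = np.exp(rng.normal(np.log(cfg.baseline_rate), cfg.rate_log_sd, len(ids)))
    base_s = pd.Series(base, index=ids)
    eligible = [
        g.gene_id for g in genes
        if g.body_length >= 1000 and "pseudogene" not in g.biotype
    ]
    cut = base_s.quantile(cfg.designation_quantile)
    pool = [gid for gid in eligible if base_s[gid] >= cut]
    need = (
        cfg.markers_per_stage * len(cfg.stages)
        + cfg.n_shared_spheroid_markers
        + cfg.n_hotspot_clusters
        + cfg.n_specific_enhancers
    )
    if len(pool) < need:
        raise PlacementError(
            f"designation pool too small: need {need} genes, have {len(pool)}"
        )
    pool = list(rng.permutation(pool))
    markers: dict[str, list[str]] = {}
    for stage in cfg.stages:
        markers[stage] = sorted(pool[: cfg.markers_per_stage])
        del pool[: cfg.markers_per_stage]
    shared = sorted(pool[: cfg.n_shared_spheroid_markers])
    del pool[: cfg.n_shared_spheroid_markers]

    # enhancer/hotspot target genes must be the nearest active gene to their
    # planted element, so draw them from the pool in order of TSS isolation
    # (distance to the nearest other TSS expected to be near-active)
    partial = pd.DataFrame({s: base_s.copy() for s in cfg.stages}, index=ids)
    for stage in cfg.stages:
        for gid in markers[stage]:
            partial.loc[gid, stage] *= 2 ** cfg.marker_log2fc
    for gid in shared:
        for stage in ("Duo", "Ile"):
            partial.loc[gid, stage] *= 2 ** cfg.marker_log2fc
    proxy_tpm = _expected_stage_tpm(cfg, genes, partial, cfg.stage_of_interest)
    near_active = set(proxy_tpm.index[proxy_tpm > 25])
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        if g.gene_id in near_active:
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    gene_by_id = {g.gene_id: g for g in genes}

    def isolation(gid: str) -> float:
        g = gene_by_id[gid]
        dists = [
            abs(t - g.tss) for t, other in tss_by_chrom.get(g.chrom, [])
            if other != gid
        ]
        return min(dists) if dists else float(cfg.chrom_length)

    pool.sort(key=lambda gid: (-isolation(gid), gid))
    offsets = pd.Series(
        np.exp(rng.normal(0.0, cfg.rna_coupling_sd, len(ids))), index=ids,
        name="rna_offset",
    )
    return base_s, offsets, markers, shared, pool, partial


def _place_tres(cfg, genes, partial_rates, sizes, candidates, rng):
    gene_by_id = {g.gene_id: g for g in genes}
    tss_index = _TssIndex(genes, 1000, 200)

    # genes expected to be anywhere near "actively transcribed" in the stage
    # of interest; the margin below the TPM > 50 activity floor guards
    # against sampling noise flipping a borderline gene into the active set
    tpm_a = _expected_stage_tpm(cfg, genes, partial_rates, cfg.stage_of_interest)
    tpm_b = _expected_stage_tpm(cfg, genes, partial_rates, cfg.comparison_stage)
    active_ids = set(tpm_a.index[(tpm_a > 25) | (tpm_b > 25)])
    active_map: dict[str, list[tuple[int, str]]] = {}
    active_bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.gene_id in active_ids:
            active_map.setdefault(g.chrom, []).append((g.tss, g.gene_id))
            active_bodies.setdefault(g.chrom, []).append((g.start, g.end))
    for rows in active_map.values():
        rows.sort()

    def in_active_body(chrom, start, end):
        # distal elements inside an actively transcribed gene body would have
        # their eRNA signal swamped by gene-body reads; keep them intergenic
        return any(s < end and start < e for s, e in active_bodies.get(chrom, []))

    placed_specific: dict[str, list[tuple[int, int]]] = {}
    all_tres: dict[str, list[tuple[int, int]]] = {}
    rows = []

    def overlaps_existing(chrom, start, end):
        return any(s < end and start < e for s, e in all_tres.get(chrom, []))

    def near_specific(chrom, start, end, sep):
        return any(
            s - sep < end and start < e + sep
            for s, e in placed_specific.get(chrom, [])
        )

    def nearest_active_ok(chrom, start, end, target):
        """Target TSS must be the unique nearest active TSS to the element."""
        tgt = gene_by_id[target]
        d_t = _interval_distance(tgt.tss, start, end)
        for t, gid in active_map.get(chrom, []):
            if gid == target:
                continue
            if _interval_distance(t, start, end) <= d_t:
                return False
        return d_t <= 100_000

    width = 2 * cfg.tre_halfspan
    counter = 0

    def add(chrom, start, kind, cluster_id=None, target=None):
        nonlocal counter
        end = start + width
        rows.append({
            "name": f"TRE{counter:04d}", "chrom": chrom, "start": start,
            "end": end, "kind": kind, "cluster_id": cluster_id,
            "target_gene": target,
        })
        all_tres.setdefault(chrom, []).append((start, end))
        if kind in ("singleton_enhancer", "cluster_member"):
            placed_specific.setdefault(chrom, []).append((start, end))
        counter += 1
        return rows[-1]["name"]

    # hotspot clusters near designated target genes; candidates are walked
    # in isolation order and a target is skipped if no legal placement exists
    cluster_rows = []
    hotspot_targets: list[str] = []
    singleton_targets: list[str] = []
    remaining = list(candidates)
    while len(hotspot_targets) < cfg.n_hotspot_clusters:
        if not remaining:
            raise PlacementError(
                "exhausted target candidates while placing hotspot clusters"
            )
        target = remaining.pop(0)
        ci = len(hotspot_targets)
        tgt = gene_by_id[target]
        chrom = tgt.chrom
        done = False
        for _ in range(2000):
            gaps = rng.integers(*cfg.cluster_gap_range, size=cfg.hotspot_members - 1)
            span = cfg.hotspot_members * width + int(gaps.sum())
            # keep the cluster within 20 kb of its target so the target TSS
            # stays the nearest active TSS (checked exactly below)
            lo = max(2000, tgt.tss - span - 20_000)
            hi = min(sizes[chrom] - 2000 - span, tgt.tss + 20_000)
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + span
            starts = [start]
            for gap in gaps:
                starts.append(starts[-1] + width + int(gap))
            if any(tss_index.overlaps_window(chrom, s, s + width) for s in starts):
                continue
            if any(in_active_body(chrom, s, s + width) for s in starts):
                continue
            if near_specific(chrom, start, end, cfg.element_separation):
                continue
            if any(overlaps_existing(chrom, s, s + width) for s in starts):
                continue
            if not nearest_active_ok(chrom, start, end, target):
                continue
            member_ids = [
                add(chrom, s, "cluster_member", cluster_id=f"HC{ci:02d}",
                    target=target)
                for s in starts
            ]
            cluster_rows.append({
                "cluster_id": f"HC{ci:02d}", "members": ",".join(member_ids),
                "target_gene": target, "start": start, "end": end, "chrom": chrom,
            })
            done = True
            hotspot_targets.append(target)
            break
        # a target with no legal cluster placement is skipped, not fatal

    # singleton stage-specific enhancers
    while len(singleton_targets) < cfg.n_specific_enhancers:
        if not remaining:
            raise PlacementError(
                "exhausted target candidates while placing singleton enhancers"
            )
        target = remaining.pop(0)
        tgt = gene_by_id[target]
        chrom = tgt.chrom
        done = False
        for _ in range(2000):
            lo = max(2000, tgt.tss - 15_000)
            hi = min(sizes[chrom] - 2000 - width, tgt.tss + 15_000)
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + width
            if tss_index.overlaps_window(chrom, start, end):
                continue
            if in_active_body(chrom, start, end):
                continue
            if near_specific(chrom, start, end, cfg.element_separation):
                continue
            if overlaps_existing(chrom, start, end):
                continue
            if not nearest_active_ok(chrom, start, end, target):
                continue
            add(chrom, start, "singleton_enhancer", target=target)
            done = True
            singleton_targets.append(target)
            break
        # a target with no legal placement nearby is skipped, not fatal

    # promoter TREs at gene TSSs; their rate is held constant across stages
    # so the planted "gained enhancer" truth stays unambiguous
    flat_genes = list(genes)
    if len(flat_genes) < cfg.n_promoter_tres:
        raise PlacementError("not enough genes for promoter TREs")
    order = rng.permutation(len(flat_genes))
    n_prom = 0
    for gi in order:
        if n_prom >= cfg.n_promoter_tres:
            break
        g = flat_genes[int(gi)]
        start = g.tss - cfg.tre_halfspan
        end = start + width
        if start < 0 or end > sizes[g.chrom]:
            continue
        if overlaps_existing(g.chrom, start, end):
            continue
        add(g.chrom, start, "promoter", target=g.gene_id)
        n_prom += 1

    # background distal TREs
    n_background = cfg.n_tres - counter
    chroms = sorted(sizes)
    bg = 0
    attempts = 0
    while bg < n_background:
        attempts += 1
        if attempts > 200 * n_background:
            raise PlacementError("could not place background TREs")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(2000, sizes[chrom] - 2000 - width))
        end = start + width
        if tss_index.overlaps_window(chrom, start, end):
            continue
        if overlaps_existing(chrom, start, end):
            continue
        if near_specific(chrom, start, end, 15_000):
            continue
        add(chrom, start, "background", target=None)
        bg += 1

    tres = pd.DataFrame(rows)
    clusters = pd.DataFrame(cluster_rows)
    return tres, clusters, sorted(hotspot_targets), sorted(singleton_targets)


def _tre_rate_table(cfg, tres: pd.DataFrame) -> pd.DataFrame:
    duo = cfg.stage_of_interest
    tre_rates = pd.DataFrame(
        cfg.tre_baseline_rate, index=tres["name"], columns=list(cfg.stages)
    )
    singleton_hi = cfg.enhancer_base_rate * 2 ** cfg.enhancer_log2fc
    for row in tres.itertuples(index=False):
        if row.kind == "singleton_enhancer":
            tre_rates.loc[row.name] = cfg.enhancer_base_rate
            tre_rates.loc[row.name, duo] = singleton_hi
        elif row.kind == "cluster_member":
            base = cfg.enhancer_base_rate * cfg.hotspot_signal_mult
            tre_rates.loc[row.name] = base
            tre_rates.loc[row.name, duo] = base * 2 ** cfg.enhancer_log2fc
    return tre_rates


def _plant_motifs(cfg, tres, genome, rng) -> pd.DataFrame:
    planted = tres[tres["kind"].isin(["singleton_enhancer", "cluster_member"])]
    motif_id, consensus = next(iter(cfg.motifs.items()))
    L = len(consensus)
    recs = []
    for row in planted.itertuples(index=False):
        center = (row.start + row.end) // 2
        start = center - L // 2
        strand = "+" if rng.random() < 0.5 else "-"
        seq = consensus if strand == "+" else _revcomp(consensus)
        genome[row.chrom][start:start + L] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8
        )
        recs.append({
            "motif_id": motif_id, "tre_id": row.name, "chrom": row.chrom,
            "start": start, "strand": strand,
        })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# simulation


def _nb_draw(rng, mean, dispersion, size=None):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_chro(
    truth: SyntheticTruth, stage: str, replicate: int,
) -> StrandedSignalTrack:
    """One stranded polymerase-position track for (stage, replicate)."""
    cfg = truth.config
    ss = np.random.SeedSequence(
        [cfg.seed, 1, list(cfg.stages).index(stage), replicate]
    )
    rng = np.random.default_rng(ss)
    events: dict[tuple[str, str], list[np.ndarray]] = {}

    def emit(chrom, strand, positions):
        if positions.size:
            events.setdefault((chrom, strand), []).append(positions)

    for g in truth.genes:
        rate = float(truth.gene_rates.loc[g.gene_id, stage])
        n = int(_nb_draw(rng, rate, cfg.dispersion))
        if n == 0:
            continue
        pause_len = min(500, g.body_length)
        n_pause = int(rng.binomial(n, cfg.pause_fraction))
        n_body = n - n_pause
        if g.body_length <= pause_len:
            n_pause, n_body = n, 0
        if g.strand == "+":
            pause_lo, pause_hi = g.start, g.start + pause_len
            body_lo, body_hi = g.start + pause_len, g.end
        else:
            pause_lo, pause_hi = g.end - pause_len, g.end
            body_lo, body_hi = g.start, g.end - pause_len
        if n_body and body_hi <= body_lo:
            n_pause, n_body = n, 0
        pos = []
        if n_pause:
            pos.append(rng.integers(pause_lo, pause_hi, size=n_pause))
        if n_body:
            pos.append(rng.integers(body_lo, body_hi, size=n_body))
        emit(g.chrom, g.strand, np.concatenate(pos) if pos else np.empty(0, int))

    half = cfg.erna_halfwidth
    for row in truth.tres.itertuples(index=False):
        rate = float(truth.tre_rates.loc[row.name, stage])
        n = int(_nb_draw(rng, rate, cfg.dispersion))
        if n == 0:
            continue
        center = (row.start + row.end) // 2
        n_plus = int(rng.binomial(n, 0.5))
        emit(row.chrom, "+", rng.integers(center, center + half, size=n_plus))
        emit(row.chrom, "-", rng.integers(center - half, center, size=n - n_plus))

    lam = cfg.background_per_kb * cfg.chrom_length / 1000.0
    for chrom, size in truth.chrom_sizes.items():
        for strand in ("+", "-"):
            n_bg = int(rng.poisson(lam))
            emit(chrom, strand, rng.integers(0, size, size=n_bg))

    base_counts = {}
    for key, chunks in events.items():
        pos = np.concatenate(chunks)
        base_counts[key] = (pos, np.ones(pos.size, dtype=np.int64))
    return StrandedSignalTrack.from_base_counts(
        f"{stage}_{replicate}", stage, truth.chrom_sizes, base_counts
    )


def simulate_all_chro(truth: SyntheticTruth) -> list[StrandedSignalTrack]:
    cfg = truth.config
    return [
        simulate_chro(truth, stage, rep)
        for stage in cfg.stages
        for rep in range(1, cfg.replicates + 1)
    ]


def simulate_rna(truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.Series]:
    """RNA-seq gene count matrix coupled to the transcription rates."""
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    # stage-independent denominator: planted fold changes carry over to the
    # RNA means exactly (total sequencing output tracks cellular mRNA content)
    shares = truth.gene_rates / truth.gene_table["baseline_rate"].sum()
    cols, stage_labels = [], []
    data = {}
    for stage in cfg.stages:
        for rep in range(1, cfg.rna_replicates + 1):
            sample = f"rna_{stage}_{rep}"
            lib = cfg.rna_library_size * rng.uniform(0.7, 1.3)
            mean = lib * shares[stage] * truth.rna_offsets
            data[sample] = _nb_draw(rng, mean.to_numpy(), cfg.rna_dispersion)
            cols.append(sample)
            stage_labels.append(stage)
    counts = pd.DataFrame(data, index=truth.gene_rates.index)
    stages = pd.Series(stage_labels, index=cols, name="stage")
    return counts, stages


# ---------------------------------------------------------------------------
# dataset export


def write_pwms(motifs: dict[str, str], path: str | os.PathLike,
               major: float = 0.94) -> None:
    """Write near-deterministic consensus PWMs in JASPAR 4-row count format."""
    minor = (1.0 - major) / 3
    with open(path, "w") as fh:
        for name in sorted(motifs):
            consensus = motifs[name]
            fh.write(f">{name}\t{name}\n")
            for base in "ACGT":
                counts = [
                    int(round((major if c == base else minor) * 1000))
                    for c in consensus
                ]
                fh.write(f"{base}  [ " + " ".join(f"{c:5d}" for c in counts) + " ]\n")


def write_dataset(truth: SyntheticTruth, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the complete dataset as plain-text files; idempotent."""
    cfg = truth.config
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(p("chrom.sizes"), "w") as fh:
        for chrom in sorted(truth.chrom_sizes):
            fh.write(f"{chrom}\t{truth.chrom_sizes[chrom]}\n")
    write_fasta(truth.genome_sequences(), p("genome.fa"))
    write_gtf(truth.genes, p("genes.gtf"))
    write_bed12(truth.genes, p("genes.bed12"))
    write_bed(truth.tres, p("tres.bed"))
    write_pwms(cfg.motifs, p("pwms.jaspar"))

    design_rows = []
    for stage in cfg.stages:
        for rep in range(1, cfg.replicates + 1):
            track = simulate_chro(truth, stage, rep)
            plus = p(f"chro_{track.sample_id}_plus.bedGraph")
            minus = p(f"chro_{track.sample_id}_minus.bedGraph")
            track.to_bedgraphs(plus, minus)
            design_rows.append((track.sample_id, stage))
    pd.DataFrame(design_rows, columns=["sample_id", "stage"]).to_csv(
        p("chro_design.tsv"), sep="\t", index=False
    )

    rna_counts, rna_stages = simulate_rna(truth)
    rna_counts.to_csv(p("rna_counts.tsv"), sep="\t", index_label="gene_id")
    rna_stages.rename_axis("sample_id").reset_index().to_csv(
        p("rna_design.tsv"), sep="\t", index=False
    )

    with open(p("truth.json"), "w") as fh:
        json.dump(truth.manifest(), fh, indent=1, sort_keys=True)
    with open(p("config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
    return paths
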