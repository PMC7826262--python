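"""Pipeline orchestration: run the analysis stages over a run directory.

Each stage reads its inputs from the run directory, writes deterministic
TSV/BED/JSON outputs under a per-stage subdirectory, and records the
thresholds it applied.  ``run_all`` executes every stage in dependency
order and writes a run manifest with config hash and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import __version__
from .quantify import (
    ActivityMatrix, PipelineConfig, quantify_gene_bodies, quantify_promoters,
    quantify_tres, to_tpm,
)
from .diffexpr import lrt_test, wald_test
from .genome_io import read_annotation, read_bed, read_fasta, StrandedSignalTrack, write_bed
from .markers import (
    cluster_promoter_patterns, find_differential_genes, find_shared_spheroid_markers,
    find_stage_markers,
)
from .synthetic_data import SyntheticConfig, build_truth, write_dataset
from .tre_landscape import (
    call_stage_specific_tres, classify_tres, compute_tre_density,
    link_density_genes,
)
from .hotspots import (
    assign_genes, classify_h3k27ac_overlap, hotspot_gene_calls, stitch_enhancers,
    stitched_table, tangent_cutoff,
)
from .cistrome import cistrome_genes, motif_density, read_pwms, scan_motifs, test_motif_enrichment

log = logging.getLogger("chrokit")

SUBCOMMANDS = (
    "simulate", "quantify", "diff", "markers", "tres", "hotspots", "cistrome", "all",
)

_KNOWN_KEYS = {"seed", "synthetic", "thresholds", "contrast", "spheroid_stages"}


class PrerequisiteError(RuntimeError):
    """A stage was run before the stage that produces its inputs."""


class ConfigError(ValueError):
    """The run configuration file violates the schema."""


def load_run_config(path: str | None) -> dict:
    """Parse and validate the YAML run configuration."""
    raw = {}
    if path:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    thr = raw.get("thresholds", {}) or {}
    known_thr = set(PipelineConfig().to_dict())
    bad = set(thr) - known_thr
    if bad:
        raise ConfigError(f"unknown threshold keys: {sorted(bad)}")
    config = PipelineConfig(**thr, **({} if "seed" in thr else {"seed": seed}))
    syn_raw = raw.get("synthetic", {}) or {}
    known_syn = set(SyntheticConfig().to_dict())
    bad = set(syn_raw) - known_syn
    if bad:
        raise ConfigError(f"unknown synthetic keys: {sorted(bad)}")
    syn_raw = {
        k: tuple(v) if isinstance(v, list) and k != "stages" else v
        for k, v in syn_raw.items()
    }
    if "stages" in syn_raw:
        syn_raw["stages"] = tuple(syn_raw["stages"])
    if "motifs" in syn_raw and not isinstance(syn_raw["motifs"], dict):
        raise ConfigError("synthetic.motifs must be a mapping name -> consensus")
    synthetic = SyntheticConfig(**syn_raw, **(
        {} if "seed" in syn_raw else {"seed": seed}))
    contrast = raw.get("contrast", {}) or {}
    stage = contrast.get("stage", synthetic.stage_of_interest)
    other = contrast.get("comparison", synthetic.comparison_stage)
    spheroid = tuple(raw.get("spheroid_stages", ("Duo", "Ile")))
    return {
        "seed": seed, "config": config, "synthetic": synthetic,
        "contrast": (stage, other), "spheroid_stages": spheroid,
    }


def _need(path: str, producer: str) -> str:
    if not os.path.exists(path):
        raise PrerequisiteError(
            f"missing {path}; run the `{producer}` subcommand first"
        )
    return path


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# dataset access


def load_dataset(outdir: str) -> dict:
    data = os.path.join(outdir, "data")
    _need(os.path.join(data, "chro_design.tsv"), "simulate")
    sizes = {}
    with open(os.path.join(data, "chrom.sizes")) as fh:
        for line in fh:
            chrom, size = line.split()
            sizes[chrom] = int(size)
    design = pd.read_csv(os.path.join(data, "chro_design.tsv"), sep="\t")
    tracks = []
    for row in design.itertuples(index=False):
        tracks.append(StrandedSignalTrack.from_bedgraphs(
            os.path.join(data, f"chro_{row.sample_id}_plus.bedGraph"),
            os.path.join(data, f"chro_{row.sample_id}_minus.bedGraph"),
            sample_id=row.sample_id, stage=row.stage, chrom_sizes=sizes,
        ))
    genes = read_annotation(os.path.join(data, "genes.gtf"))
    tres = read_bed(os.path.join(data, "tres.bed"))
    rna_counts = pd.read_csv(
        os.path.join(data, "rna_counts.tsv"), sep="\t", index_col="gene_id"
    )
    rna_design = pd.read_csv(os.path.join(data, "rna_design.tsv"), sep="\t")
    rna_stages = pd.Series(
        rna_design["stage"].to_numpy(), index=rna_design["sample_id"], name="stage"
    )
    return {
        "chrom_sizes": sizes, "tracks": tracks, "genes": genes, "tres": tres,
        "rna_counts": rna_counts, "rna_stages": rna_stages,
        "fasta": os.path.join(data, "genome.fa"),
        "pwms": os.path.join(data, "pwms.jaspar"),
    }


def _load_matrix(outdir: str, stem: str, kind: str) -> ActivityMatrix:
    qdir = os.path.join(outdir, "quantify")
    counts = pd.read_csv(
        _need(os.path.join(qdir, f"{stem}_counts.tsv"), "quantify"),
        sep="\t", index_col=0,
    )
    design = pd.read_csv(os.path.join(qdir, "design.tsv"), sep="\t")
    stages = pd.Series(
        design["stage"].to_numpy(), index=design["sample_id"], name="stage"
    )
    tpm_path = os.path.join(qdir, f"{stem}_tpm.tsv")
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0) if os.path.exists(tpm_path) else None
    eff = None
    eff_path = os.path.join(qdir, f"{stem}_lengths.tsv")
    if os.path.exists(eff_path):
        eff = pd.read_csv(eff_path, sep="\t", index_col=0).iloc[:, 0]
    return ActivityMatrix(kind, counts, stages, tpm, eff)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(outdir: str, rc: dict) -> None:
    data = os.path.join(outdir, "data")
    truth = build_truth(rc["synthetic"])
    write_dataset(truth, data)
    log.info("simulate: wrote dataset under %s (seed=%d)", data, rc["synthetic"].seed)


def stage_quantify(outdir: str, rc: dict) -> None:
    cfg: PipelineConfig = rc["config"]
    ds = load_dataset(outdir)
    qdir = os.path.join(outdir, "quantify")
    os.makedirs(qdir, exist_ok=True)
    gb = to_tpm(quantify_gene_bodies(ds["tracks"], ds["genes"], cfg))
    prom = quantify_promoters(ds["tracks"], ds["genes"], cfg)
    tre = quantify_tres(ds["tracks"], ds["tres"])
    gb.counts.to_csv(os.path.join(qdir, "gene_counts.tsv"), sep="\t",
                     index_label="gene_id")
    gb.tpm.to_csv(os.path.join(qdir, "gene_tpm.tsv"), sep="\t",
                  index_label="gene_id", float_format="%.6g")
    gb.effective_lengths.to_frame().to_csv(
        os.path.join(qdir, "gene_lengths.tsv"), sep="\t", index_label="gene_id")
    _write_tsv(gb.dropped, os.path.join(qdir, "gene_dropped.tsv"))
    prom.counts.to_csv(os.path.join(qdir, "promoter_counts.tsv"), sep="\t",
                       index_label="gene_id")
    prom.effective_lengths.to_frame().to_csv(
        os.path.join(qdir, "promoter_lengths.tsv"), sep="\t", index_label="gene_id")
    tre.counts.to_csv(os.path.join(qdir, "tre_counts.tsv"), sep="\t",
                      index_label="tre_id")
    gb.stages.rename_axis("sample_id").reset_index().to_csv(
        os.path.join(qdir, "design.tsv"), sep="\t", index=False)
    log.info(
        "quantify: %d genes (%d dropped), %d promoters, %d TREs x %d samples",
        len(gb.counts), len(gb.dropped), len(prom.counts), len(tre.counts),
        len(gb.stages),
    )


def stage_diff(outdir: str, rc: dict) -> None:
    cfg: PipelineConfig = rc["config"]
    stage, other = rc["contrast"]
    ds = load_dataset(outdir)
    gb = _load_matrix(outdir, "gene", "gene_body")
    prom = _load_matrix(outdir, "promoter", "promoter")
    tre = _load_matrix(outdir, "tre", "tre")
    ddir = os.path.join(outdir, "diff")
    os.makedirs(ddir, exist_ok=True)
    for name, counts, stages in (
        ("chro", gb.counts, gb.stages),
        ("rna", ds["rna_counts"], ds["rna_stages"]),
        ("tre", tre.counts, tre.stages),
    ):
        res = wald_test(counts, stages, stage, other)
        _write_tsv(res.reset_index(drop=True),
                   os.path.join(ddir, f"{name}_wald_{stage}_vs_{other}.tsv"))
    lrt = lrt_test(prom.counts, prom.stages)
    _write_tsv(lrt.reset_index(drop=True), os.path.join(ddir, "promoter_lrt.tsv"))
    log.info("diff: Wald %s vs %s on genes/RNA/TREs; promoter LRT across stages",
             stage, other)


def stage_markers(outdir: str, rc: dict) -> None:
    cfg: PipelineConfig = rc["config"]
    ds = load_dataset(outdir)
    gb = _load_matrix(outdir, "gene", "gene_body")
    prom = _load_matrix(outdir, "promoter", "promoter")
    mdir = os.path.join(outdir, "markers")
    os.makedirs(mdir, exist_ok=True)
    stage_list = list(dict.fromkeys(gb.stages))
    all_members = {}
    for stage in stage_list:
        ms = find_stage_markers(
            gb, ds["rna_counts"], ds["rna_stages"], ds["genes"], stage, cfg
        )
        all_members[stage] = ms.genes
        ev = ms.evidence.rename_axis("gene_id").reset_index()
        _write_tsv(ev, os.path.join(mdir, f"markers_{stage}.tsv"))
        log.info("markers: %s -> %d genes (TPM>%g, baseMean>%g, FC>%g)",
                 stage, len(ms.genes), cfg.active_tpm, cfg.rna_basemean_marker,
                 cfg.marker_fold_change)
    spheroid = tuple(s for s in rc["spheroid_stages"] if s in stage_list)
    if len(spheroid) == 2:
        shared = find_shared_spheroid_markers(
            gb, ds["rna_counts"], ds["rna_stages"], ds["genes"], spheroid, cfg
        )
        _write_tsv(shared.evidence.rename_axis("gene_id").reset_index(),
                   os.path.join(mdir, "markers_shared_spheroid.tsv"))
        log.info("markers: shared spheroid -> %d genes", len(shared.genes))
    stage, other = rc["contrast"]
    diff = find_differential_genes(gb, stage, other, cfg)
    _write_tsv(diff["table"].reset_index(drop=True),
               os.path.join(mdir, f"diffgenes_{stage}_vs_{other}.tsv"))
    clusters = cluster_promoter_patterns(prom, ds["genes"], cfg)
    _write_tsv(clusters.reset_index(drop=True),
               os.path.join(mdir, "promoter_clusters.tsv"))
    log.info("markers: promoter patterns -> %d genes in %d clusters",
             len(clusters), clusters.attrs.get("k", -1))


def stage_tres(outdir: str, rc: dict) -> None:
    cfg: PipelineConfig = rc["config"]
    stage, other = rc["contrast"]
    ds = load_dataset(outdir)
    gb = _load_matrix(outdir, "gene", "gene_body")
    tre = _load_matrix(outdir, "tre", "tre")
    tdir = os.path.join(outdir, "tres")
    os.makedirs(tdir, exist_ok=True)
    classified = classify_tres(ds["tres"], ds["genes"], cfg)
    _write_tsv(classified, os.path.join(tdir, "tre_classes.tsv"))
    calls = call_stage_specific_tres(tre, stage, other, cfg)
    for key in ("gained", "lost", "unchanged"):
        sub = classified[classified["name"].isin(calls[key])]
        write_bed(sub, os.path.join(tdir, f"tres_{key}_{stage}_vs_{other}.bed"))
    _write_tsv(calls["result"].reset_index(drop=True),
               os.path.join(tdir, f"tre_wald_{stage}_vs_{other}.tsv"))
    gained_distal = classified[
        classified["name"].isin(calls["gained"])
        & (classified["tre_class"] == "distal")
    ]
    dens = compute_tre_density(
        ds["genes"], gained_distal, gb.stage_mean_tpm(stage), cfg
    )
    dens.rename_axis("gene_id").reset_index().to_csv(
        os.path.join(tdir, "tre_density.tsv"), sep="\t", index=False)
    links = link_density_genes(
        dens, gb, ds["rna_counts"], ds["rna_stages"], stage, other, cfg
    )
    _write_tsv(links["table"].reset_index(drop=True),
               os.path.join(tdir, "gene_links.tsv"))
    with open(os.path.join(tdir, "summary.json"), "w") as fh:
        json.dump({
            "contrast": [stage, other],
            "n_gained": len(calls["gained"]), "n_lost": len(calls["lost"]),
            "n_unchanged": len(calls["unchanged"]),
            "n_gained_enhancers": int(len(gained_distal)),
            "n_linked_genes": len(links["linked"]),
            "rank_test_high_vs_zero_p": links["rank_test_high_vs_zero_p"],
        }, fh, indent=1, sort_keys=True)
    log.info("tres: %d gained (%d distal), %d lost, %d linked genes",
             len(calls["gained"]), len(gained_distal), len(calls["lost"]),
             len(links["linked"]))


def stage_hotspots(outdir: str, rc: dict) -> None:
    cfg: PipelineConfig = rc["config"]
    stage, other = rc["contrast"]
    ds = load_dataset(outdir)
    gb = _load_matrix(outdir, "gene", "gene_body")
    tre = _load_matrix(outdir, "tre", "tre")
    tdir = os.path.join(outdir, "tres")
    classified = pd.read_csv(
        _need(os.path.join(tdir, "tre_classes.tsv"), "tres"), sep="\t"
    )
    gained = read_bed(
        _need(os.path.join(tdir, f"tres_gained_{stage}_vs_{other}.bed"), "tres")
    )
    hdir = os.path.join(outdir, "hotspots")
    os.makedirs(hdir, exist_ok=True)
    distal_names = set(
        classified.loc[classified["tre_class"] == "distal", "name"]
    )
    enhancers = gained[gained["name"].isin(distal_names)]
    signal = tre.counts[tre.stage_samples(stage)].sum(axis=1).astype(float)
    stitched = stitch_enhancers(enhancers, signal, cfg.stitch_gap_bp)
    if len(stitched) >= 3:
        cutoff, stitched = tangent_cutoff(stitched)
    else:
        cutoff = None
        log.warning("hotspots: only %d stitched enhancers; no cutoff applied",
                    len(stitched))
    stitched = assign_genes(stitched, ds["genes"], gb.stage_mean_tpm(stage), cfg)
    table = stitched_table(stitched)
    chro_wald = wald_test(gb.counts, gb.stages, stage, other)
    rna_wald = wald_test(ds["rna_counts"], ds["rna_stages"], stage, other)
    calls = hotspot_gene_calls(stitched, chro_wald, rna_wald, cfg)
    peaks_path = os.path.join(outdir, "data", "h3k27ac_peaks.bed")
    if os.path.exists(peaks_path):
        table = table.join(classify_h3k27ac_overlap(stitched, read_bed(peaks_path)))
    _write_tsv(table.reset_index(drop=True), os.path.join(hdir, "stitched.tsv"))
    bed = table.rename(columns={"stitch_id": "name"})[
        ["chrom", "start", "end", "name", "total_signal"]]
    write_bed(bed.assign(name=table["n_members"].astype(str)),
              os.path.join(hdir, "stitched.bed"), score_col="total_signal")
    curve = table.sort_values("rank")[["rank", "total_signal", "is_hotspot"]]
    _write_tsv(curve, os.path.join(hdir, "rank_curve.tsv"))
    with open(os.path.join(hdir, "summary.json"), "w") as fh:
        json.dump({
            "contrast": [stage, other],
            "n_stitched": len(stitched),
            "n_hotspots": int(table["is_hotspot"].sum()),
            "cutoff_signal": cutoff,
            "final_genes": calls["final_genes"],
            "hotspot_assigned": calls["hotspot_assigned"],
            "non_hotspot_assigned": calls["non_hotspot_assigned"],
            "rank_test_p": calls["rank_test_p"],
            "note": calls["note"],
        }, fh, indent=1, sort_keys=True)
    log.info("hotspots: %d stitched -> %d hotspots (cutoff %s); %d final genes",
             len(stitched), int(table["is_hotspot"].sum()), cutoff,
             len(calls["final_genes"]))


def stage_cistrome(outdir: str, rc: dict) -> None:
    cfg: PipelineConfig = rc["config"]
    stage, other = rc["contrast"]
    ds = load_dataset(outdir)
    gb = _load_matrix(outdir, "gene", "gene_body")
    tdir = os.path.join(outdir, "tres")
    classified = pd.read_csv(
        _need(os.path.join(tdir, "tre_classes.tsv"), "tres"), sep="\t"
    )
    gained = read_bed(
        _need(os.path.join(tdir, f"tres_gained_{stage}_vs_{other}.bed"), "tres")
    )
    cdir = os.path.join(outdir, "cistrome")
    os.makedirs(cdir, exist_ok=True)
    genome = read_fasta(ds["fasta"])
    distal = classified[classified["tre_class"] == "distal"]
    seqs = {
        row.name: genome[row.chrom][row.start:row.end]
        for row in distal.itertuples(index=False)
    }
    pwms = read_pwms(ds["pwms"])
    gained_distal_names = sorted(set(gained["name"]) & set(seqs))
    background_names = sorted(set(seqs) - set(gained_distal_names))
    hits_by_motif = {}
    for pwm in pwms:
        hits = scan_motifs(seqs, pwm, config=cfg)
        hits_by_motif[pwm.motif_id] = hits
        _write_tsv(hits, os.path.join(cdir, f"hits_{pwm.motif_id}.tsv"))
    enrich = test_motif_enrichment(gained_distal_names, background_names, hits_by_motif)
    _write_tsv(enrich.reset_index(drop=True), os.path.join(cdir, "enrichment.tsv"))
    gained_distal = distal[distal["name"].isin(gained_distal_names)]
    summary = {}
    for pwm in pwms:
        hits = hits_by_motif[pwm.motif_id]
        dens = motif_density(
            ds["genes"], gained_distal, hits, gb.stage_mean_tpm(stage), cfg
        )
        cis = cistrome_genes(
            dens, gb, ds["rna_counts"], ds["rna_stages"], stage, other, cfg
        )
        _write_tsv(cis["table"].reset_index(drop=True),
                   os.path.join(cdir, f"cistrome_{pwm.motif_id}.tsv"))
        summary[pwm.motif_id] = cis["genes"]
        log.info("cistrome: %s -> %d genes", pwm.motif_id, len(cis["genes"]))
    with open(os.path.join(cdir, "summary.json"), "w") as fh:
        json.dump({"contrast": [stage, other], "cistromes": summary},
                  fh, indent=1, sort_keys=True)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "diff": stage_diff,
    "markers": stage_markers,
    "tres": stage_tres,
    "hotspots": stage_hotspots,
    "cistrome": stage_cistrome,
}


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(subcommand: str, outdir: str, rc: dict) -> None:
    if subcommand not in SUBCOMMANDS:
        raise ConfigError(f"unknown subcommand {subcommand!r}")
    os.makedirs(outdir, exist_ok=True)
    order = (
        list(_STAGE_FUNCS) if subcommand == "all" else [subcommand]
    )
    log.info("thresholds in effect: %s", json.dumps(rc["config"].to_dict(),
                                                    sort_keys=True))
    for name in order:
        _STAGE_FUNCS[name](outdir, rc)
    manifest = {
        "version": __version__,
        "seed": rc["seed"],
        "config": rc["config"].to_dict(),
        "synthetic": rc["synthetic"].to_dict(),
        "contrast": list(rc["contrast"]),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }
    for root, _dirs, files in os.walk(outdir):
        for fname in sorted(files):
            if fname == "manifest.json":
                continue
            rel = os.path.relpath(os.path.join(root, fname), outdir)
            manifest["outputs"][rel] = _checksum(os.path.join(root, fname))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
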