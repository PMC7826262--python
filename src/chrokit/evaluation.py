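"""Score a pipeline run against the planted truth manifest.

Computes recovery metrics (marker recall and leakage, stage-specific
enhancer recall and false calls, hotspot-cluster recall and false hotspots,
cistrome recall) plus the hotspot/non-hotspot rank test and the global
transcription-expression correlation, for a run directory produced by
``run_pipeline('all', ...)``.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd


def load_truth(outdir: str) -> dict:
    with open(os.path.join(outdir, "data", "truth.json")) as fh:
        return json.load(fh)


def marker_recovery(outdir: str, truth: dict) -> dict:
    stages = truth["stages"]
    out = {}
    leakage = 0
    for stage in stages:
        found = set(pd.read_csv(
            os.path.join(outdir, "markers", f"markers_{stage}.tsv"), sep="\t"
        )["gene_id"])
        planted = set(truth["marker_genes"][stage])
        others = set().union(
            *(truth["marker_genes"][s] for s in stages if s != stage)
        )
        out[stage] = len(found & planted) / len(planted) if planted else float("nan")
        leakage += len(found & others)
    shared_path = os.path.join(outdir, "markers", "markers_shared_spheroid.tsv")
    shared_planted = set(truth.get("shared_spheroid_markers", []))
    if os.path.exists(shared_path) and shared_planted:
        found = set(pd.read_csv(shared_path, sep="\t")["gene_id"])
        out["shared"] = len(found & shared_planted) / len(shared_planted)
    return {"per_stage_recall": out,
            "min_recall": min(out.values()),
            "cross_stage_leakage": leakage}


def enhancer_recovery(outdir: str, truth: dict, contrast=("Duo", "DE")) -> dict:
    stage, other = contrast
    gained_bed = os.path.join(
        outdir, "tres", f"tres_gained_{stage}_vs_{other}.bed")
    gained = set(pd.read_csv(gained_bed, sep="\t", header=None)[3]) if os.path.getsize(
        gained_bed) else set()
    classes = pd.read_csv(os.path.join(outdir, "tres", "tre_classes.tsv"), sep="\t")
    distal = set(classes.loc[classes["tre_class"] == "distal", "name"])
    gained_distal = gained & distal
    planted = set(truth["stage_specific_tres"])
    return {
        "recall": len(gained_distal & planted) / len(planted),
        "false_calls": len(gained_distal - planted),
        "n_called": len(gained_distal),
        "n_planted": len(planted),
    }


def hotspot_recovery(outdir: str, truth: dict) -> dict:
    table = pd.read_csv(os.path.join(outdir, "hotspots", "stitched.tsv"), sep="\t")
    flagged = table[table["is_hotspot"].astype(bool)]
    cluster_sets = [set(c["members"]) for c in truth["hotspot_clusters"]]
    false = 0
    for row in flagged.itertuples(index=False):
        members = set(str(row.members).split(","))
        if not any(members & cs for cs in cluster_sets):
            false += 1
    recovered = sum(
        1 for cs in cluster_sets
        if any(cs & set(str(r.members).split(",")) for r in flagged.itertuples())
    )
    with open(os.path.join(outdir, "hotspots", "summary.json")) as fh:
        summary = json.load(fh)
    return {
        "recall": recovered / len(cluster_sets) if cluster_sets else float("nan"),
        "false_hotspots": false,
        "n_hotspots": len(flagged),
        "rank_test_p": summary["rank_test_p"],
    }


def cistrome_recovery(outdir: str, truth: dict, motif: str = "MOTIF_A") -> dict:
    table = pd.read_csv(
        os.path.join(outdir, "cistrome", f"cistrome_{motif}.tsv"), sep="\t")
    members = set(table.loc[table["member"].astype(bool), "gene_id"])
    targets = set(truth["singleton_targets"]) | {
        c["target_gene"] for c in truth["hotspot_clusters"]
    }
    return {
        "recall": len(members & targets) / len(targets),
        "n_members": len(members),
        "n_targets": len(targets),
    }


def transcription_expression_correlation(outdir: str) -> dict:
    """Genome-wide Pearson of log gene-body TPM vs log RNA mean, across genes."""
    tpm = pd.read_csv(os.path.join(outdir, "quantify", "gene_tpm.tsv"),
                      sep="\t", index_col=0)
    rna = pd.read_csv(os.path.join(outdir, "data", "rna_counts.tsv"),
                      sep="\t", index_col=0)
    m_tpm = tpm.mean(axis=1)
    m_rna = rna.mean(axis=1).reindex(m_tpm.index)
    ok = (m_tpm > 0) & (m_rna > 0)
    r = float(np.corrcoef(np.log(m_tpm[ok]), np.log(m_rna[ok]))[0, 1])
    return {"pearson": r, "n_genes": int(ok.sum())}


def score_run(outdir: str, contrast=("Duo", "DE")) -> dict:
    truth = load_truth(outdir)
    return {
        "markers": marker_recovery(outdir, truth),
        "enhancers": enhancer_recovery(outdir, truth, contrast),
        "hotspots": hotspot_recovery(outdir, truth),
        "cistrome": cistrome_recovery(outdir, truth),
        "correlation": transcription_expression_correlation(outdir),
    }
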