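"""Shared fixtures: tiny hand-built tracks and a session-scoped pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chrokit.genome_io import GeneModel, StrandedSignalTrack
from chrokit.quantify import PipelineConfig


CHROM_SIZES = {"chrA": 100_000, "chrB": 60_000}


def make_track(
    base_counts: dict[tuple[str, str], dict[int, int]],
    sample_id: str = "s1",
    stage: str = "X",
    chrom_sizes: dict[str, int] | None = None,
) -> StrandedSignalTrack:
    """Build a track from {(chrom, strand): {position: count}} literals."""
    enc = {
        key: (np.array(sorted(d)), np.array([d[p] for p in sorted(d)]))
        for key, d in base_counts.items()
    }
    return StrandedSignalTrack.from_base_counts(
        sample_id, stage, chrom_sizes or CHROM_SIZES, enc
    )


def random_track(
    rng: np.random.Generator,
    sample_id: str = "r1",
    stage: str = "X",
    chrom_sizes: dict[str, int] | None = None,
    n_positions: int = 400,
    max_count: int = 5,
) -> StrandedSignalTrack:
    sizes = chrom_sizes or CHROM_SIZES
    counts = {}
    for chrom, size in sizes.items():
        for strand in "+-":
            pos = rng.integers(0, size, size=n_positions)
            cnt = rng.integers(1, max_count + 1, size=n_positions)
            counts[(chrom, strand)] = (pos, cnt)
    return StrandedSignalTrack.from_base_counts(sample_id, stage, sizes, counts)


def brute_force_extract(track, chrom, start, end, strands) -> float:
    """Independent per-base oracle for signal extraction."""
    total = 0.0
    for strand in strands:
        arr = track.dense(chrom, strand)
        total += float(arr[start:end].sum())
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def simple_genes():
    return [
        GeneModel("gplus", "chrA", 10_000, 30_000, "+"),
        GeneModel("gminus", "chrA", 40_000, 52_000, "-"),
        GeneModel("gshort", "chrA", 60_000, 60_800, "+"),
        GeneModel("gB", "chrB", 5_000, 20_000, "+", "processed_pseudogene"),
    ]


# ---------------------------------------------------------------------------
# session-scoped default synthetic run, shared by recovery and CLI tests


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic dataset (seed 7)."""
    from chrokit.pipeline import load_run_config, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline_run")
    rc = load_run_config(None)
    rc["seed"] = 7
    from dataclasses import replace

    rc["config"] = replace(rc["config"], seed=7)
    rc["synthetic"] = replace(rc["synthetic"], seed=7)
    run_pipeline("all", str(outdir), rc)
    return {"outdir": str(outdir), "rc": rc}


@pytest.fixture(scope="session")
def default_truth(default_run):
    import json
    import os

    with open(os.path.join(default_run["outdir"], "data", "truth.json")) as fh:
        return json.load(fh)
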