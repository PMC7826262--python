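"""Genomic file I/O and exact signal extraction.

All coordinates are 0-based half-open internally.  GTF (1-based closed) is
shifted on read and write; BED is native.  Nascent-transcription signal is
held per sample as stranded run-length arrays mapping genomic bases to
polymerase-position counts (each count marks the 3' end of a nascent RNA).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")


class GenomeIOError(ValueError):
    """Raised for malformed input files or contract violations."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise GenomeIOError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand is not None and self.strand not in VALID_STRANDS:
            raise GenomeIOError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """An annotated transcription unit.

    ``start``/``end`` delimit the unit half-open; the TSS is the first
    transcribed base respecting strand (``start`` for '+', ``end - 1`` for
    '-').
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start >= self.end:
            raise GenomeIOError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in VALID_STRANDS:
            raise GenomeIOError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        # exclusive end of the transcription unit, walking in gene direction
        return self.end if self.strand == "+" else self.start - 1

    @property
    def body_length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.gene_id)


@dataclass
class StrandedSignalTrack:
    """Per-sample stranded single-base signal, stored as value runs.

    ``runs[(chrom, strand)] = (starts, ends, values)`` with non-overlapping,
    sorted, half-open runs of constant per-base count.
    """

    sample_id: str
    stage: str
    chrom_sizes: dict[str, int]
    runs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    integral: bool = True

    # -- construction ---------------------------------------------------
    @classmethod
    def from_bedgraphs(
        cls,
        plus_path: str | os.PathLike,
        minus_path: str | os.PathLike,
        sample_id: str,
        stage: str = "",
        chrom_sizes: dict[str, int] | None = None,
        fold_minus: bool = True,
        integer: bool = True,
    ) -> "StrandedSignalTrack":
        """Read a pair of per-strand bedGraph files.

        Minus-strand values stored as negatives (the common PRO-seq dialect)
        are folded to positive counts when ``fold_minus`` is on.
        """
        track = cls(sample_id, stage, dict(chrom_sizes or {}), {}, integer)
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            starts_by, ends_by, vals_by = _read_bedgraph(path)
            for chrom in starts_by:
                s, e, v = starts_by[chrom], ends_by[chrom], vals_by[chrom]
                if strand == "-" and fold_minus:
                    v = np.abs(v)
                if (v < 0).any():
                    raise GenomeIOError(
                        f"{path}: negative counts on {strand} strand track"
                    )
                if integer and not np.allclose(v, np.round(v), atol=1e-9):
                    bad = v[~np.isclose(v, np.round(v))][0]
                    raise GenomeIOError(
                        f"{path}: non-integer value {bad} with integer mode on"
                    )
                if chrom_sizes is None:
                    track.chrom_sizes[chrom] = max(
                        track.chrom_sizes.get(chrom, 0), int(e[-1])
                    )
                elif chrom not in track.chrom_sizes or e[-1] > track.chrom_sizes[chrom]:
                    raise GenomeIOError(
                        f"{path}: {chrom} positions exceed declared chromosome size"
                    )
                track.runs[(chrom, strand)] = (s, e, v.astype(np.float64))
        return track

    @classmethod
    def from_base_counts(
        cls,
        sample_id: str,
        stage: str,
        chrom_sizes: dict[str, int],
        base_counts: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    ) -> "StrandedSignalTrack":
        """Build from per-base sparse counts: (chrom, strand) -> (positions, counts).

        Positions may repeat; counts are aggregated.  Adjacent equal-valued
        bases are compressed into runs.
        """
        track = cls(sample_id, stage, dict(chrom_sizes), {}, True)
        for (chrom, strand), (pos, cnt) in base_counts.items():
            pos = np.asarray(pos, dtype=np.int64)
            cnt = np.asarray(cnt, dtype=np.int64)
            if pos.size == 0:
                continue
            if (pos < 0).any() or (pos >= chrom_sizes[chrom]).any():
                raise GenomeIOError(f"positions outside {chrom} bounds")
            upos, inv = np.unique(pos, return_inverse=True)
            agg = np.zeros(upos.size, dtype=np.int64)
            np.add.at(agg, inv, cnt)
            keep = agg != 0
            upos, agg = upos[keep], agg[keep]
            if upos.size == 0:
                continue
            # compress adjacent equal values into runs
            brk = np.flatnonzero((np.diff(upos) != 1) | (np.diff(agg) != 0)) + 1
            starts = upos[np.r_[0, brk]]
            ends = upos[np.r_[brk - 1, upos.size - 1]] + 1
            vals = agg[np.r_[0, brk]].astype(np.float64)
            track.runs[(chrom, strand)] = (starts, ends, vals)
        return track

    # -- queries --------------------------------------------------------
    @property
    def total_reads(self) -> float:
        tot = 0.0
        for s, e, v in self.runs.values():
            tot += float(np.sum((e - s) * v))
        return tot

    def _sum_one_strand(self, chrom: str, strand: str, start: int, end: int) -> float:
        key = (chrom, strand)
        if key not in self.runs:
            return 0.0
        s, e, v = self.runs[key]
        i0 = np.searchsorted(e, start, side="right")
        i1 = np.searchsorted(s, end, side="left")
        if i0 >= i1:
            return 0.0
        ov = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        return float(np.sum(ov * v[i0:i1]))

    def extract(self, interval: GenomicInterval, strand_mode: str = "both") -> float:
        """Exact sum of base counts in [start, end) on the requested strand(s)."""
        if interval.chrom not in self.chrom_sizes:
            raise GenomeIOError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.chrom_sizes[interval.chrom] or interval.start < 0:
            raise GenomeIOError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                "off declared chromosome"
            )
        if strand_mode == "both":
            strands = list(VALID_STRANDS)
        elif strand_mode in ("sense", "antisense"):
            if interval.strand is None:
                raise GenomeIOError(f"{strand_mode} extraction needs a stranded interval")
            flip = {"+": "-", "-": "+"}
            strands = [
                interval.strand if strand_mode == "sense" else flip[interval.strand]
            ]
        else:
            raise GenomeIOError(f"unknown strand_mode {strand_mode!r}")
        return sum(
            self._sum_one_strand(interval.chrom, st, interval.start, interval.end)
            for st in strands
        )

    def dense(self, chrom: str, strand: str) -> np.ndarray:
        """Materialize one (chrom, strand) as a dense per-base array."""
        arr = np.zeros(self.chrom_sizes[chrom], dtype=np.float64)
        if (chrom, strand) in self.runs:
            s, e, v = self.runs[(chrom, strand)]
            for a, b, val in zip(s, e, v):
                arr[a:b] += val
        return arr

    # -- output ---------------------------------------------------------
    def to_bedgraphs(
        self, plus_path: str | os.PathLike, minus_path: str | os.PathLike,
        negate_minus: bool = True,
    ) -> None:
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            sign = -1.0 if (strand == "-" and negate_minus) else 1.0
            with open(path, "w") as fh:
                for chrom in sorted({c for c, st in self.runs if st == strand}):
                    s, e, v = self.runs[(chrom, strand)]
                    for a, b, val in zip(s, e, v):
                        val = sign * val
                        txt = f"{int(val)}" if self.integral else f"{val:.6g}"
                        fh.write(f"{chrom}\t{a}\t{b}\t{txt}\n")


def _read_bedgraph(path):
    starts_by, ends_by, vals_by = {}, {}, {}
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str}, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return starts_by, ends_by, vals_by
    df = df[~df["chrom"].str.startswith("track")]
    if df.empty:
        return starts_by, ends_by, vals_by
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="mergesort")
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        v = sub["value"].to_numpy(np.float64)
        if (s >= e).any():
            raise GenomeIOError(f"{path}: {chrom} has an empty or inverted interval")
        if (s[1:] < e[:-1]).any():
            raise GenomeIOError(f"{path}: overlapping bedGraph intervals on {chrom}")
        starts_by[chrom], ends_by[chrom], vals_by[chrom] = s, e, v
    return starts_by, ends_by, vals_by


# -- annotation ---------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Read a GTF or BED12-like gene annotation into GeneModels.

    GTF ``gene`` features (1-based closed coordinates) are shifted to the
    internal 0-based half-open convention; BED is read natively.  Duplicate
    gene ids are rejected.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if path.endswith((".gtf", ".gff", ".gff3")):
        is_gtf = True
    elif path.endswith((".bed", ".bed12")):
        is_gtf = False
    else:  # sniff: GTF column 9 carries key "value"; attributes
        fields = first.rstrip("\n").split("\t")
        is_gtf = len(fields) >= 9 and "gene_id" in fields[8]
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:  # re-open from the top
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if is_gtf:
                    if len(fields) < 9:
                        raise GenomeIOError("fewer than 9 GTF columns")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                    strand = fields[6]
                    attrs = _parse_gtf_attributes(fields[8])
                    gene_id = attrs.get("gene_id")
                    if not gene_id:
                        raise GenomeIOError("gene feature without gene_id")
                    biotype = attrs.get("gene_biotype", attrs.get("gene_type", "unknown"))
                else:
                    if len(fields) < 6:
                        raise GenomeIOError("BED gene records need at least 6 columns")
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    gene_id = fields[3]
                    strand = fields[5]
                    biotype = fields[12] if len(fields) > 12 else "unknown"
                if gene_id in seen:
                    raise GenomeIOError(f"duplicate gene_id {gene_id!r}")
                seen.add(gene_id)
                genes.append(GeneModel(gene_id, chrom, start, end, strand, biotype))
            except (ValueError, IndexError) as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gtf(genes: list[GeneModel], path: str | os.PathLike) -> None:
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in ordered:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tchrokit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_bed12(genes: list[GeneModel], path: str | os.PathLike) -> None:
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in ordered:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{g.end - g.start},\t0,\t{g.biotype}\n"
            )


# -- interval BED -------------------------------------------------------

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3/BED6 intervals into a DataFrame [name, chrom, start, end, strand]."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["name", "chrom", "start", "end", "strand"])
    ncol = df.shape[1]
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
    })
    out["name"] = (
        df[3].astype(str) if ncol > 3 else [f"region_{i}" for i in range(len(df))]
    )
    out["strand"] = df[5].astype(str) if ncol > 5 else None
    if (out["start"] >= out["end"]).any():
        raise GenomeIOError(f"{path}: interval with start >= end")
    return out[["name", "chrom", "start", "end", "strand"]]


def write_bed(df: pd.DataFrame, path: str | os.PathLike,
              score_col: str | None = None) -> None:
    """Write intervals (columns chrom/start/end/name[/score]) as BED, sorted."""
    df = df.sort_values(["chrom", "start", "end", "name"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            score = getattr(row, score_col) if score_col else 0
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{score}\n")


# -- FASTA --------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# -- merging and scaling ------------------------------------------------

def scale_tracks(
    tracks: list[StrandedSignalTrack], target_total: float = 1e6
) -> StrandedSignalTrack:
    """Merge same-stage tracks and rescale to a fixed total signal.

    The scaled track is for visualization export only; all statistics in the
    pipeline consume unnormalized counts.
    """
    if not tracks:
        raise GenomeIOError("scale_tracks needs at least one track")
    chrom_sizes = dict(tracks[0].chrom_sizes)
    for t in tracks[1:]:
        if t.chrom_sizes != chrom_sizes:
            raise GenomeIOError("tracks span different genomes")
    total = sum(t.total_reads for t in tracks)
    if total == 0:
        raise GenomeIOError("zero total signal: cannot scale")
    factor = target_total / total
    merged = StrandedSignalTrack(
        sample_id=tracks[0].stage or "merged",
        stage=tracks[0].stage,
        chrom_sizes=chrom_sizes,
        integral=False,
    )
    keys = sorted({k for t in tracks for k in t.runs})
    for chrom, strand in keys:
        arr = np.zeros(chrom_sizes[chrom], dtype=np.float64)
        for t in tracks:
            if (chrom, strand) in t.runs:
                s, e, v = t.runs[(chrom, strand)]
                for a, b, val in zip(s, e, v):
                    arr[a:b] += val
        arr *= factor
        nz = arr != 0
        if not nz.any():
            continue
        # re-encode as runs of constant value
        brk = np.flatnonzero(np.diff(arr) != 0) + 1
        starts = np.r_[0, brk]
        ends = np.r_[brk, arr.size]
        vals = arr[starts]
        keep = vals != 0
        merged.runs[(chrom, strand)] = (
            starts[keep].astype(np.int64), ends[keep].astype(np.int64), vals[keep]
        )
    return merged
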