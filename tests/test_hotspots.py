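"""Enhancer stitching, tangent-line hotspot cutoff and gene assignment."""

import numpy as np
import pandas as pd
import pytest

from chrokit.genome_io import GeneModel
from chrokit.hotspots import (
    StitchedEnhancer, assign_genes, classify_h3k27ac_overlap, hotspot_gene_calls,
    stitch_enhancers, stitched_table, tangent_cutoff,
)


def _enh(rows):
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])


def _signal(df, value=10.0):
    return pd.Series(value, index=df["name"])


class TestStitch:
    def test_gap_rule_partitions(self):
        df = _enh([("a", "chr1", 0, 500), ("b", "chr1", 10_000, 10_500),
                   ("c", "chr1", 30_000, 30_500)])
        out = stitch_enhancers(df, _signal(df))
        spans = sorted((s.start, s.end, len(s.members)) for s in out)
        assert spans == [(0, 10_500, 2), (30_000, 30_500, 1)]

    def test_gap_of_exactly_12500_not_stitched(self):
        df = _enh([("a", "chr1", 0, 500), ("b", "chr1", 13_000, 13_400)])
        assert len(stitch_enhancers(df, _signal(df))) == 2
        df2 = _enh([("a", "chr1", 0, 500), ("b", "chr1", 12_999, 13_400)])
        assert len(stitch_enhancers(df2, _signal(df2))) == 1

    def test_total_signal_sums_members(self):
        df = _enh([("a", "chr1", 0, 500), ("b", "chr1", 5000, 5400)])
        sig = pd.Series({"a": 3.0, "b": 9.0})
        (st,) = stitch_enhancers(df, sig)
        assert st.total_signal == 12.0

    def test_matches_union_find_oracle(self, rng):
        starts = np.sort(rng.integers(0, 2_000_000, size=1000))
        df = _enh([(f"e{i}", "chr1", int(s), int(s) + int(rng.integers(200, 600)))
                   for i, s in enumerate(starts)])
        out = stitch_enhancers(df, _signal(df))
        # independent union-find over the same predicate
        parent = list(range(len(df)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        rows = sorted(df.itertuples(index=False), key=lambda r: r.start)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if rows[j].start - rows[i].end < 12_500:
                    a, b = find(i), find(j)
                    parent[a] = b
                else:
                    break
        groups = {}
        for i, r in enumerate(rows):
            groups.setdefault(find(i), set()).add(r.name)
        want = {frozenset(g) for g in groups.values()}
        got = {frozenset(s.members) for s in out}
        assert got == want

    def test_stitched_units_separated_by_gap(self, rng):
        starts = np.sort(rng.integers(0, 500_000, size=300))
        df = _enh([(f"e{i}", "chr1", int(s), int(s) + 300)
                   for i, s in enumerate(starts)])
        out = sorted(stitch_enhancers(df, _signal(df)), key=lambda s: s.start)
        for a, b in zip(out, out[1:]):
            assert b.start - a.end >= 12_500


def _stitched(signals):
    return [
        StitchedEnhancer(f"SE{i:04d}", "chr1", i * 100_000, i * 100_000 + 1000,
                         [f"e{i}"], float(s))
        for i, s in enumerate(signals)
    ]


def _oracle_hotspots(signals):
    """Independent slope-scan reimplementation of the tangent cutoff."""
    s = np.sort(np.asarray(signals, float))
    n = s.size
    if s[-1] <= 0:
        return set()
    x = np.arange(n) / (n - 1)
    y = s / s[-1]
    slopes = []
    for i in range(n):
        lo = max(i - 1, 0)
        hi = min(i + 1, n - 1)
        slopes.append((y[hi] - y[lo]) / (x[hi] - x[lo]))
    idx = [i for i, sl in enumerate(slopes) if sl > 1]
    if not idx:
        return set()
    cut = s[idx[0]]
    return {float(v) for v in signals if v > cut}


class TestTangentCutoff:
    def test_single_outlier_is_the_only_hotspot(self):
        st = _stitched([1, 1, 1, 1, 100])
        cutoff, st = tangent_cutoff(st)
        assert [e.is_hotspot for e in st] == [False] * 4 + [True]
        assert cutoff == 1

    def test_linear_curve_has_no_hotspots(self):
        st = _stitched([1, 2, 3, 4, 5])
        cutoff, st = tangent_cutoff(st)
        assert cutoff is None or not any(e.is_hotspot for e in st)
        assert not any(e.is_hotspot for e in st)

    def test_all_equal_signals_empty(self):
        _, st = tangent_cutoff(_stitched([5, 5, 5, 5]))
        assert not any(e.is_hotspot for e in st)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            tangent_cutoff(_stitched([1, 2]))

    def test_matches_slope_scan_oracle_on_random_vectors(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 40))
            signals = np.round(rng.lognormal(3, 1.5, size=n), 3)
            st = _stitched(signals)
            _, st = tangent_cutoff(st)
            got = {e.total_signal for e in st if e.is_hotspot}
            assert got == _oracle_hotspots(signals)

    def test_hotspots_are_an_upper_set_and_scale_invariant(self, rng):
        signals = rng.lognormal(3, 1.5, size=50)
        _, st = tangent_cutoff(_stitched(signals))
        flags = {e.total_signal: e.is_hotspot for e in st}
        hot = [s for s, f in flags.items() if f]
        if hot:
            m = min(hot)
            assert all(f for s, f in flags.items() if s > m)
        _, scaled = tangent_cutoff(_stitched(signals * 137.5))
        assert [e.is_hotspot for e in scaled] == [e.is_hotspot for e in st]

    def test_planted_clusters_dominate_singletons(self, rng):
        # 500 singleton-level units + 20 cluster-level units at ~80x signal
        singles = rng.normal(600, 80, size=500).clip(min=1)
        clusters = rng.normal(48_000, 2_000, size=20)
        st = _stitched(np.concatenate([singles, clusters]))
        _, st = tangent_cutoff(st)
        hot = {e.stitch_id for e in st if e.is_hotspot}
        planted = {f"SE{i:04d}" for i in range(500, 520)}
        assert len(hot & planted) >= 18
        assert len(hot - planted) <= 2


class TestAssignGenes:
    def test_activity_filter_and_distance(self):
        st = [StitchedEnhancer("SE0000", "chr1", 50_000, 60_000, ["e"], 5.0)]
        genes = [GeneModel("active", "chr1", 40_000, 45_000, "+"),
                 GeneModel("inactive", "chr1", 61_000, 70_000, "+")]
        tpm = pd.Series({"active": 60.0, "inactive": 10.0})
        (out,) = assign_genes(st, genes, tpm)
        assert out.assigned_gene == "active"
        assert out.assignment_distance == 10_000

    def test_tss_inside_wins_with_distance_zero(self):
        st = [StitchedEnhancer("SE0000", "chr1", 50_000, 60_000, ["e"], 5.0)]
        genes = [GeneModel("inside", "chr1", 55_000, 70_000, "+"),
                 GeneModel("near", "chr1", 49_000, 49_500, "-")]
        tpm = pd.Series({"inside": 60.0, "near": 60.0})
        (out,) = assign_genes(st, genes, tpm)
        assert out.assigned_gene == "inside" and out.assignment_distance == 0

    def test_no_candidate_left_unassigned(self):
        st = [StitchedEnhancer("SE0000", "chr1", 50_000, 60_000, ["e"], 5.0)]
        genes = [GeneModel("far", "chr1", 900_000, 950_000, "+")]
        (out,) = assign_genes(st, genes, pd.Series({"far": 60.0}))
        assert out.assigned_gene is None

    def test_matches_brute_force_nearest_search(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", int(s), int(s) + 5000, "+-"[int(rng.integers(2))])
            for i, s in enumerate(rng.integers(0, 1_900_000, size=120))
        ]
        tpm = pd.Series(rng.choice([10.0, 100.0], size=120),
                        index=[g.gene_id for g in genes])
        sts = [
            StitchedEnhancer(f"SE{i:04d}", "chr1", int(p), int(p) + 8000, ["e"], 1.0)
            for i, p in enumerate(rng.integers(0, 1_890_000, size=100))
        ]
        out = assign_genes(sts, genes, tpm)
        for st in out:
            best = None
            for g in genes:
                if tpm[g.gene_id] <= 50:
                    continue
                d = max(st.start - g.tss, g.tss - (st.end - 1), 0)
                if d > 100_000:
                    continue
                key = (d, g.start, g.gene_id)
                if best is None or key < best:
                    best = key
            assert st.assigned_gene == (best[2] if best else None)


def _wald_frame(lfc: dict, p=1e-6):
    idx = list(lfc)
    return pd.DataFrame({
        "feature_id": idx,
        "log2FoldChange": [lfc[g] for g in idx],
        "pvalue": p, "padj": p,
    }).set_index("feature_id", drop=False)


class TestHotspotGeneCalls:
    def _stitched_with_genes(self):
        st = []
        for i in range(10):
            e = StitchedEnhancer(f"SE{i:04d}", "chr1", i * 50_000, i * 50_000 + 1000,
                                 ["e"], 100.0 if i < 5 else 1.0)
            e.is_hotspot = i < 5
            e.assigned_gene = f"g{i}"
            st.append(e)
        return st

    def test_hotspot_genes_rank_above_non_hotspot(self):
        st = self._stitched_with_genes()
        lfc = {f"g{i}": (4.0 if i < 5 else 1.0) for i in range(10)}
        out = hotspot_gene_calls(st, _wald_frame(lfc), _wald_frame(lfc))
        assert out["rank_test_p"] < 0.05
        assert out["final_genes"] == [f"g{i}" for i in range(5)]

    def test_gene_flat_in_rna_excluded_from_final(self):
        st = self._stitched_with_genes()
        chro = _wald_frame({f"g{i}": 4.0 for i in range(10)})
        rna = _wald_frame({f"g{i}": (0.0 if i == 0 else 4.0) for i in range(10)})
        out = hotspot_gene_calls(st, chro, rna)
        assert "g0" not in out["final_genes"]
        assert "g1" in out["final_genes"]

    def test_no_hotspots_degenerate_note(self):
        st = self._stitched_with_genes()
        for e in st:
            e.is_hotspot = False
        out = hotspot_gene_calls(st, _wald_frame({"g0": 4.0}), _wald_frame({"g0": 4.0}))
        assert out["final_genes"] == []
        assert "degenerate" in out["note"]


class TestH3K27acOverlap:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])

    def test_three_way_classification(self):
        st = [StitchedEnhancer("SE0000", "chr1", 0, 10_000, ["e"], 1.0),
              StitchedEnhancer("SE0001", "chr1", 20_000, 30_000, ["e"], 1.0),
              StitchedEnhancer("SE0002", "chr1", 40_000, 50_000, ["e"], 1.0)]
        peaks = self._peaks([
            ("p1", "chr1", 0, 6000),          # 60% of SE0000 -> high
            ("p2", "chr1", 20_000, 25_000),   # exactly 50% -> moderate
        ])
        out = classify_h3k27ac_overlap(st, peaks)
        assert out.to_dict() == {
            "SE0000": "high", "SE0001": "moderate", "SE0002": "none"
        }


def test_stitched_table_round_trip_fields():
    st = _stitched([1, 2, 3])
    _, st = tangent_cutoff(st)
    t = stitched_table(st)
    assert list(t["total_signal"]) == [1.0, 2.0, 3.0]
    assert t.shape[0] == 3
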