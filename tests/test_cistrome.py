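"""PWM scanning, hypergeometric enrichment, motif density and cistromes."""

import math

import numpy as np
import pandas as pd
import pytest

from chrokit.cistrome import PWM, cistrome_genes, motif_density, read_pwms, revcomp, scan_motifs
from chrokit.cistrome import test_motif_enrichment as motif_enrichment
from chrokit.genome_io import GeneModel
from chrokit.quantify import ActivityMatrix, PipelineConfig
from chrokit.synthetic_data import write_pwms


def _consensus_pwm(consensus="AACG", major=0.97):
    minor = (1 - major) / 3
    mat = np.full((4, len(consensus)), minor)
    for j, c in enumerate(consensus):
        mat["ACGT".index(c), j] = major
    return PWM("M", mat)


class TestPWM:
    def test_columns_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("bad", np.full((4, 6), 0.3))

    def test_min_length(self):
        with pytest.raises(ValueError, match="L >= 4"):
            PWM("short", np.full((4, 3), 0.25))

    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        write_pwms({"TFX": "AACGGACTTG"}, path)
        (pwm,) = read_pwms(path)
        assert pwm.length == 10
        assert pwm.consensus == "AACGGACTTG"


class TestScan:
    def test_forward_consensus_hit(self):
        hits = scan_motifs({"t": "GGAACGGG"}, _consensus_pwm())
        assert len(hits) == 1
        row = hits.iloc[0]
        assert (row["offset"], row["strand"]) == (2, "+")
        assert row["relative_score"] > 0.99

    def test_reverse_complement_hit_mapped_back(self):
        seq = "TT" + revcomp("AACGGACTTGCA") + "TTT"
        hits = scan_motifs({"t": seq}, _consensus_pwm("AACGGACTTGCA"))
        assert list(hits["strand"]) == ["-"]
        assert hits["offset"].iloc[0] == 2

    def test_non_dna_symbol_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            scan_motifs({"t": "ACGTXACGT"}, _consensus_pwm())

    def test_n_windows_skipped(self):
        hits = scan_motifs({"t": "TTANGTTT"}, _consensus_pwm())
        assert hits.empty

    def test_matches_exhaustive_window_oracle(self, rng):
        pwm = _consensus_pwm("ACGGAAGTCCGT", major=0.85)
        lo = pwm.log_odds()
        thr = 0.8 * lo[:4].max(axis=0).sum()
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        # plant two exact instances
        seq = seq[:100] + "ACGGAAGTCCGT" + seq[112:480] + revcomp("ACGGAAGTCCGT") + seq[492:]
        hits = scan_motifs({"t": seq}, pwm)
        got = {(r.offset, r.strand) for r in hits.itertuples(index=False)}
        want = set()
        L = pwm.length
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for off in range(len(seq) - L + 1):
            win = seq[off:off + L]
            fwd = sum(lo[idx[c], j] for j, c in enumerate(win))
            rev = sum(lo[idx[c], j] for j, c in enumerate(revcomp(win)))
            if fwd >= thr:
                want.add((off, "+"))
            if rev >= thr:
                want.add((off, "-"))
        assert got == want
        assert {(100, "+"), (480, "-")} <= got

    def test_strand_symmetry(self, rng):
        pwm = _consensus_pwm("ACGGTAAC", major=0.8)
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(10)
        }
        fwd = scan_motifs(seqs, pwm)
        rc = scan_motifs({k: revcomp(v) for k, v in seqs.items()}, pwm)
        flip = {"+": "-", "-": "+"}
        L = pwm.length
        got = {
            (r.tre_id, len(seqs[r.tre_id]) - L - r.offset, flip[r.strand])
            for r in rc.itertuples(index=False)
        }
        want = {(r.tre_id, r.offset, r.strand) for r in fwd.itertuples(index=False)}
        assert got == want


class TestEnrichment:
    @staticmethod
    def _hits(ids):
        return pd.DataFrame({"tre_id": list(ids), "offset": 0, "strand": "+",
                             "score": 1.0})

    def test_fold_arithmetic(self):
        targets = [f"t{i}" for i in range(10)]
        background = [f"b{i}" for i in range(100)]
        hits = self._hits(targets[:8] + background[:20])
        out = motif_enrichment(targets, background, {"M": hits})
        assert out.loc["M", "fold"] == pytest.approx(4.0)
        assert out.loc["M", "pvalue"] < 0.01

    def test_non_enriched_large_p(self):
        targets = [f"t{i}" for i in range(10)]
        background = [f"b{i}" for i in range(100)]
        hits = self._hits(targets[:2] + background[:20])
        out = motif_enrichment(targets, background, {"M": hits})
        assert out.loc["M", "fold"] == pytest.approx(1.0)
        assert out.loc["M", "pvalue"] > 0.3

    def test_matches_exact_enumeration_on_small_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            N = int(rng.integers(2, 12))
            targets = [f"t{i}" for i in range(n)]
            background = [f"b{i}" for i in range(N)]
            k = int(rng.integers(0, n + 1))
            K = int(rng.integers(0, N + 1))
            hits = self._hits(targets[:k] + background[:K])
            out = motif_enrichment(targets, background, {"M": hits})
            # exact tail: P(X >= k) for X ~ Hypergeom(n+N draws=n, marked=k+K)
            M, mk = n + N, k + K
            p_exact = sum(
                math.comb(mk, x) * math.comb(M - mk, n - x) / math.comb(M, n)
                for x in range(k, min(n, mk) + 1)
            )
            assert out.loc["M", "pvalue"] == pytest.approx(p_exact, rel=1e-9)

    def test_disjointness_and_empty_background_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            motif_enrichment(["a"], ["a", "b"], {})
        with pytest.raises(ValueError, match="empty"):
            motif_enrichment(["a"], [], {})


class TestMotifDensity:
    def _setup(self):
        genes = [GeneModel("g", "chr1", 200_000, 260_000, "+")]
        tpm = pd.Series({"g": 100.0})
        tres = pd.DataFrame({
            "name": ["near", "far"], "chrom": "chr1",
            "start": [150_000, 500_000], "end": [150_350, 500_350],
        })
        return genes, tpm, tres

    def test_counts_hits_in_window(self):
        genes, tpm, tres = self._setup()
        hits = pd.DataFrame({"tre_id": ["near", "near", "far"], "offset": [1, 5, 2],
                             "strand": "+", "score": 1.0})
        assert motif_density(genes, tres, hits, tpm)["g"] == 2

    def test_tre_level_mode(self):
        genes, tpm, tres = self._setup()
        hits = pd.DataFrame({"tre_id": ["near", "near"], "offset": [1, 5],
                             "strand": "+", "score": 1.0})
        assert motif_density(genes, tres, hits, tpm, count_tres=True)["g"] == 1

    def test_raising_score_threshold_never_increases_density(self, rng):
        pwm = _consensus_pwm("ACGGAAGTCCGT", major=0.8)
        genes = [GeneModel("g", "chr1", 100_000, 160_000, "+")]
        tpm = pd.Series({"g": 100.0})
        tres = pd.DataFrame({
            "name": [f"t{i}" for i in range(5)], "chrom": "chr1",
            "start": [50_000 + 10_000 * i for i in range(5)],
        })
        tres["end"] = tres["start"] + 350
        seqs = {t: "".join(rng.choice(list("ACGT"), size=350)) for t in tres["name"]}
        prev = None
        for thr in (0.6, 0.7, 0.8, 0.9):
            hits = scan_motifs(seqs, pwm, min_relative_score=thr)
            d = motif_density(genes, tres, hits, tpm)["g"]
            if prev is not None:
                assert d <= prev
            prev = d


class TestCistromeGenes:
    def _evidence(self, rng, n=30):
        # first 10 genes activated in Duo; the rest null so that
        # median-of-ratios normalization stays anchored
        ids = [f"g{i}" for i in range(n)]
        mu = np.full(n, 2000.0)
        muB = mu.copy()
        muB[:10] *= 6
        r = 1 / 0.02
        A = rng.negative_binomial(r, r / (r + mu[:, None]), (n, 3))
        B = rng.negative_binomial(r, r / (r + muB[:, None]), (n, 3))
        counts = pd.DataFrame(np.hstack([A, B]), index=ids,
                              columns=[f"s{j}" for j in range(6)])
        stages = pd.Series(["DE"] * 3 + ["Duo"] * 3, index=counts.columns)
        from chrokit.quantify import to_tpm

        chro = to_tpm(ActivityMatrix("gene_body", counts, stages,
                                     effective_lengths=pd.Series(1500.0, index=ids)))
        rna = counts.rename(columns=lambda c: f"r{c}")
        rna_stages = pd.Series(stages.to_numpy(), index=rna.columns)
        return ids, chro, rna, rna_stages

    def test_expression_floor_is_the_cistrome_floor(self, rng):
        ids, chro, rna, rna_stages = self._evidence(rng)
        rna = rna.copy()
        rna.loc[ids[0]] = (rna.loc[ids[0]] * 200 / rna.loc[ids[0]].mean()).astype(int)
        dens = pd.Series(1, index=ids)
        out = cistrome_genes(dens, chro, rna, rna_stages, "Duo", "DE")
        # base mean ~200 passes the marker floor (100) but not the
        # cistrome floor (500)
        assert ids[0] not in out["genes"]
        assert ids[1] in out["genes"]

    def test_zero_density_excluded(self, rng):
        ids, chro, rna, rna_stages = self._evidence(rng)
        dens = pd.Series(1, index=ids)
        dens[ids[2]] = 0
        out = cistrome_genes(dens, chro, rna, rna_stages, "Duo", "DE")
        assert ids[2] not in out["genes"]
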