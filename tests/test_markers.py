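"""Marker calling criteria, planted-truth recovery and promoter clustering."""

import numpy as np
import pandas as pd
import pytest

from chrokit.diffexpr import DesignError
from chrokit.genome_io import GeneModel
from chrokit.markers import (
    cluster_promoter_patterns, find_differential_genes, find_shared_spheroid_markers,
    find_stage_markers,
)
from chrokit.quantify import ActivityMatrix, PipelineConfig


def _nb(rng, mean, disp, size):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + np.asarray(mean, float)), size=size)


def _activity(counts: pd.DataFrame, stages, eff=1500.0) -> ActivityMatrix:
    from chrokit.quantify import to_tpm

    eff_s = pd.Series(eff, index=counts.index, dtype=float)
    m = ActivityMatrix("gene_body", counts, pd.Series(stages, index=counts.columns),
                       effective_lengths=eff_s)
    return to_tpm(m)


def _gene_models(ids, length=5000):
    return [GeneModel(g, "chr1", 1000 + i * 10_000, 1000 + i * 10_000 + length, "+")
            for i, g in enumerate(ids)]


def _two_stage_sim(rng, n_up=100, n_down=100, n_null=1800, lfc=3.0):
    mean = 200.0
    ids = [f"g{i}" for i in range(n_up + n_down + n_null)]
    muA = np.full(len(ids), mean)
    muB = muA.copy()
    muB[:n_up] *= 2 ** lfc
    muB[n_up:n_up + n_down] /= 2 ** lfc
    A = _nb(rng, muA[:, None], 0.05, (len(ids), 3))
    B = _nb(rng, muB[:, None], 0.05, (len(ids), 3))
    counts = pd.DataFrame(np.hstack([A, B]), index=ids,
                          columns=[f"s{j}" for j in range(6)])
    return counts, ids[:n_up], ids[n_up:n_up + n_down]


class TestFindDifferentialGenes:
    def test_planted_two_stage_recovery(self, rng):
        counts, up_truth, down_truth = _two_stage_sim(rng)
        chro = _activity(counts, ["A"] * 3 + ["B"] * 3)
        out = find_differential_genes(chro, "B", "A")
        up, down = set(out["up"]), set(out["down"])
        assert len(up & set(up_truth)) / len(up_truth) >= 0.9
        assert len(down & set(down_truth)) / len(down_truth) >= 0.9
        assert len(up - set(up_truth)) + len(down - set(down_truth)) <= 10

    def test_tpm_floor_excludes_low_abundance(self, rng):
        counts, up_truth, _ = _two_stage_sim(rng, n_up=5, n_down=0, n_null=50)
        chro = _activity(counts, ["A"] * 3 + ["B"] * 3)
        cfg = PipelineConfig(diff_avg_tpm=1e9)  # impossible floor
        out = find_differential_genes(chro, "B", "A", cfg)
        assert out["up"] == [] and out["down"] == []

    def test_unknown_stage_rejected(self, rng):
        counts, *_ = _two_stage_sim(rng, n_up=0, n_down=0, n_null=20)
        chro = _activity(counts, ["A"] * 3 + ["B"] * 3)
        with pytest.raises(DesignError, match="absent"):
            find_differential_genes(chro, "C", "A")


def _four_stage_dataset(rng, markers_per_stage=10, shared=5, n_null=100,
                        lfc=3.0, rna_scale=30.0):
    stages = ["hESC", "DE", "Duo", "Ile"]
    n = markers_per_stage * 4 + shared + n_null
    ids = [f"g{i}" for i in range(n)]
    base = np.full(n, 300.0)
    mu = np.tile(base[:, None], (1, 4))
    truth = {}
    k = 0
    for si, st in enumerate(stages):
        truth[st] = ids[k:k + markers_per_stage]
        mu[k:k + markers_per_stage, si] *= 2 ** lfc
        k += markers_per_stage
    shared_ids = ids[k:k + shared]
    mu[k:k + shared, 2] *= 2 ** lfc
    mu[k:k + shared, 3] *= 2 ** lfc
    cols, labels, blocks = [], [], []
    for si, st in enumerate(stages):
        blocks.append(_nb(rng, mu[:, si][:, None], 0.05, (n, 3)))
        cols += [f"{st}_{r}" for r in range(3)]
        labels += [st] * 3
    counts = pd.DataFrame(np.hstack(blocks), index=ids, columns=cols)
    chro = ActivityMatrix("gene_body", counts, pd.Series(labels, index=cols),
                          effective_lengths=pd.Series(1500.0, index=ids))
    from chrokit.quantify import to_tpm

    chro = to_tpm(chro)
    rna_blocks = [
        _nb(rng, (mu[:, si] * rna_scale)[:, None], 0.05, (n, 3))
        for si in range(4)
    ]
    rna_cols = [f"rna_{c}" for c in cols]
    rna = pd.DataFrame(np.hstack(rna_blocks), index=ids, columns=rna_cols)
    rna_stages = pd.Series(labels, index=rna_cols)
    genes = _gene_models(ids)
    return chro, rna, rna_stages, genes, truth, shared_ids


class TestFindStageMarkers:
    def test_planted_recovery_no_leakage(self, rng):
        chro, rna, rna_stages, genes, truth, _ = _four_stage_dataset(rng)
        for st in ("hESC", "Duo"):
            ms = find_stage_markers(chro, rna, rna_stages, genes, st)
            planted = set(truth[st])
            others = set().union(*(truth[o] for o in truth if o != st))
            assert len(set(ms.genes) & planted) / len(planted) >= 0.85
            assert not set(ms.genes) & others

    def test_rna_floor_vetoes_chro_only_evidence(self, rng):
        chro, rna, rna_stages, genes, truth, _ = _four_stage_dataset(rng)
        gene = truth["Duo"][0]
        rna = rna.copy()
        rna.loc[gene] = 2  # expressed below the 100 base-mean floor
        ms = find_stage_markers(chro, rna, rna_stages, genes, "Duo")
        assert gene not in ms.genes

    def test_pseudogene_and_short_genes_excluded(self, rng):
        chro, rna, rna_stages, genes, truth, _ = _four_stage_dataset(rng)
        pseudo = truth["Duo"][0]
        genes = [
            GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand,
                      "unprocessed_pseudogene" if g.gene_id == pseudo else g.biotype)
            for g in genes
        ]
        ms = find_stage_markers(chro, rna, rna_stages, genes, "Duo")
        assert pseudo not in ms.genes

    def test_marker_sets_invariant_to_sample_order(self, rng):
        chro, rna, rna_stages, genes, truth, _ = _four_stage_dataset(
            rng, markers_per_stage=5, shared=0, n_null=30)
        ms1 = find_stage_markers(chro, rna, rna_stages, genes, "DE")
        perm = list(rng.permutation(chro.counts.columns))
        chro2 = chro.subset_samples(perm)
        ms2 = find_stage_markers(chro2, rna, rna_stages, genes, "DE")
        assert ms1.genes == ms2.genes

    def test_tightening_thresholds_never_grows_the_set(self, rng):
        chro, rna, rna_stages, genes, truth, _ = _four_stage_dataset(rng)
        loose = find_stage_markers(chro, rna, rna_stages, genes, "Ile")
        for cfg in (
            PipelineConfig(active_tpm=500.0),
            PipelineConfig(marker_fold_change=4.0),
            PipelineConfig(marker_padj=0.01, marker_p=0.001),
            PipelineConfig(rna_basemean_marker=5000.0),
        ):
            tight = find_stage_markers(chro, rna, rna_stages, genes, "Ile", cfg)
            assert set(tight.genes) <= set(loose.genes)


class TestSharedSpheroidMarkers:
    def test_shared_recovered_single_stage_excluded(self, rng):
        chro, rna, rna_stages, genes, truth, shared_ids = _four_stage_dataset(rng)
        ms = find_shared_spheroid_markers(chro, rna, rna_stages, genes)
        got = set(ms.genes)
        assert len(got & set(shared_ids)) / len(shared_ids) >= 0.85
        # Ile-only planted markers fail the Duo floors and stay out
        assert not got & set(truth["Ile"])
        assert not got & set(truth["hESC"])


class TestClusterPromoterPatterns:
    @staticmethod
    def _promoter_dataset(rng, n_per=50, noise=0.1):
        archetypes = np.array([
            [1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 0, 1], [0, 1, 1, 0],
        ], dtype=float)
        profiles = np.repeat(archetypes, n_per, axis=0)
        mu = 100 + 2000 * profiles
        n = mu.shape[0]
        cols, labels, blocks = [], [], []
        for si, st in enumerate(["hESC", "DE", "Duo", "Ile"]):
            blocks.append(_nb(rng, mu[:, si][:, None], noise**2, (n, 3)))
            cols += [f"{st}_{r}" for r in range(3)]
            labels += [st] * 3
        ids = [f"g{i}" for i in range(n)]
        counts = pd.DataFrame(np.hstack(blocks), index=ids, columns=cols)
        m = ActivityMatrix("promoter", counts, pd.Series(labels, index=cols),
                           effective_lengths=pd.Series(700.0, index=ids))
        truth = np.repeat(np.arange(4), n_per)
        return m, _gene_models(ids), truth

    def test_identical_profiles_cluster_together(self, rng):
        m, genes, truth = self._promoter_dataset(rng, n_per=10)
        out = cluster_promoter_patterns(m, genes, k=4)
        labels = out["cluster"].to_numpy()
        ids = list(out["gene_id"])
        same = [labels[ids.index("g0")], labels[ids.index("g1")]]
        assert same[0] == same[1]

    def test_anticorrelated_profiles_split_at_k2(self, rng):
        m, genes, truth = self._promoter_dataset(rng, n_per=10)
        out = cluster_promoter_patterns(m, genes, k=2)
        ids = list(out["gene_id"])
        labels = out["cluster"].to_numpy()
        # archetype 0 (1,1,0,0) vs archetype 1 (0,0,1,1)
        assert labels[ids.index("g0")] != labels[ids.index("g10")]

    def test_planted_archetypes_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        m, genes, truth = self._promoter_dataset(rng)
        out = cluster_promoter_patterns(m, genes)
        ids = list(out["gene_id"])
        keep = [int(g[1:]) for g in ids]
        ari = adjusted_rand_score(truth[keep], out["cluster"].to_numpy())
        assert ari >= 0.9

    def test_deterministic(self, rng):
        m, genes, _ = self._promoter_dataset(rng, n_per=15)
        a = cluster_promoter_patterns(m, genes)
        b = cluster_promoter_patterns(m, genes)
        assert a.equals(b)
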