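"""Feature catalogs, enrichment folds, ROI coverage and enzyme ranking."""

import numpy as np
import pandas as pd
import pytest

import roirrbs as rr
from roirrbs.intervals import merge_intervals, total_bp

from conftest import random_genome


class TestLoadAnnotation:
    def test_two_exon_transcript_yields_one_intron(self, toy_catalog):
        introns = toy_catalog.introns
        # gA: exons [1000,1400) and [1600,2000) -> intron [1400,1600)
        assert list(introns[["start", "end"]].itertuples(index=False, name=None)) \
            == [(1400, 1600)]

    def test_coordinates_converted_to_zero_based(self, toy_catalog):
        gA = toy_catalog.genes.set_index("gene_id").loc["gA"]
        assert (gA["start"], gA["end"], gA["tss"], gA["tes"]) == (1000, 2000, 1000, 1999)
        gB = toy_catalog.genes.set_index("gene_id").loc["gB"]
        assert (gB["tss"], gB["tes"]) == (3599, 3000)

    def test_exonless_gene_contributes_gene_body_only(self, toy_catalog):
        body = toy_catalog.merged("gene_body")
        assert ((body["chrom"] == "chr2") & (body["start"] == 500)
                & (body["end"] == 900)).any()
        exon_chroms = set(toy_catalog.merged("exon")["chrom"])
        assert "chr2" not in exon_chroms

    def test_class_bp_totals(self, toy_catalog):
        assert total_bp(toy_catalog.merged("exon")) == 400 + 400 + 600
        assert total_bp(toy_catalog.introns) == 200
        assert total_bp(toy_catalog.merged("gene_body")) == 1000 + 600 + 400


class TestDerivePromoters:
    def test_plus_strand_window(self, toy_catalog):
        prom = rr.derive_promoters(toy_catalog, upstream_bp=1000, store=False)
        pA = prom.set_index("gene_id").loc["gA"]
        assert (pA["start"], pA["end"]) == (0, 1000)

    def test_minus_strand_window(self, toy_catalog):
        prom = rr.derive_promoters(toy_catalog, upstream_bp=500, store=False)
        pB = prom.set_index("gene_id").loc["gB"]
        # gB spans [3000,3600) on -, TSS at 3599: promoter [3600, 4100)
        assert (pB["start"], pB["end"]) == (3600, 4100)

    def test_clipped_at_chromosome_start(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [400],
                              "end": [900], "strand": ["+"], "tss": [400],
                              "tes": [899]})
        cat = rr.FeatureCatalog(genes=genes)
        prom = rr.derive_promoters(cat, upstream_bp=1000, store=False)
        assert (prom["start"].iloc[0], prom["end"].iloc[0]) == (0, 400)

    def test_strand_antisymmetry(self):
        # reversing coordinates and flipping strand mirrors the promoter
        L = 10_000
        genes_f = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [4000],
                                "end": [5000], "strand": ["+"], "tss": [4000],
                                "tes": [4999]})
        genes_r = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"],
                                "start": [L - 5000], "end": [L - 4000],
                                "strand": ["-"], "tss": [L - 4001],
                                "tes": [L - 5000]})
        pf = rr.derive_promoters(rr.FeatureCatalog(genes=genes_f), 1000, store=False)
        pr = rr.derive_promoters(rr.FeatureCatalog(genes=genes_r), 1000, store=False)
        s, e = pf["start"].iloc[0], pf["end"].iloc[0]
        assert (pr["start"].iloc[0], pr["end"].iloc[0]) == (L - e, L - s)


class TestDeriveSpliceSites:
    def test_windows_around_intron_boundaries(self, toy_catalog):
        ss = rr.derive_splice_sites(toy_catalog, flank_bp=5, store=False)
        assert list(ss[["start", "end"]].itertuples(index=False, name=None)) \
            == [(1395, 1405), (1595, 1605)]

    def test_zero_flank_is_empty(self, toy_catalog):
        assert len(rr.derive_splice_sites(toy_catalog, flank_bp=0, store=False)) == 0

    def test_overlapping_windows_merged(self):
        introns = pd.DataFrame({"chrom": ["c", "c"], "start": [100, 130],
                                "end": [120, 160]})
        cat = rr.FeatureCatalog(genes=pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]),
            introns=merge_intervals(introns))
        ss = rr.derive_splice_sites(cat, flank_bp=10, store=False)
        # boundaries 100,120,130,160 with +-10 -> [90,140) and [150,170)
        assert list(ss[["start", "end"]].itertuples(index=False, name=None)) \
            == [(90, 140), (150, 170)]


class TestComputeEnrichment:
    def test_worked_fold_example(self):
        genome = {"c": "A" * 1000}
        cat = rr.FeatureCatalog(genes=pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]))
        cat.classes["promoter"] = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [100]})
        frags = rr.FragmentSet(pd.DataFrame(
            {"chrom": ["c", "c"], "start": [50, 500], "end": [100, 550]}))
        enr = rr.compute_enrichment(frags, cat, genome)
        assert enr.loc["promoter", "fold"] == pytest.approx(5.0)

    def test_whole_genome_folds_are_one(self, toy_catalog):
        genome = {"chr1": "A" * 5000, "chr2": "A" * 1000}
        frags = rr.FragmentSet(pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [5000, 1000]}))
        enr = rr.compute_enrichment(frags, toy_catalog, genome,
                                    classes=["exon", "intron", "gene_body"])
        assert np.allclose(enr["fold"].to_numpy(), 1.0)

    def test_partition_fractions_sum_to_one(self):
        genome = {"c": "A" * 1000}
        cat = rr.FeatureCatalog(genes=pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]))
        cat.classes["left"] = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [300]})
        cat.classes["right"] = pd.DataFrame({"chrom": ["c"], "start": [300], "end": [1000]})
        frags = rr.FragmentSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000]}))
        enr = rr.compute_enrichment(frags, cat, genome)
        assert enr["fraction_ref"].sum() == pytest.approx(1.0)

    def test_empty_class_fold_is_missing_not_zero(self, toy_catalog):
        genome = {"chr1": "A" * 5000, "chr2": "A" * 1000}
        frags = rr.FragmentSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100]}))
        enr = rr.compute_enrichment(frags, toy_catalog, genome, classes=["TE"])
        assert np.isnan(enr.loc["TE", "fold"])

    def test_agrees_with_quadratic_brute_force(self):
        rng = np.random.default_rng(21)
        genome = random_genome(rng, 5000)
        cat = rr.FeatureCatalog(genes=pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]))
        starts = rng.integers(0, 4900, size=30)
        feats = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(10, 100, size=30)})
        cat.classes["feat"] = merge_intervals(feats)
        frags = rr.digest_genome(genome, rr.MseI)
        kept = rr.select_fragments(frags, rr.SizeRange(20, 400))
        enr = rr.compute_enrichment(kept, cat, genome)
        # brute force: per-base membership arrays
        fmask = np.zeros(5000, dtype=bool)
        for r in cat.classes["feat"].itertuples():
            fmask[r.start:r.end] = True
        rmask = np.zeros(5000, dtype=bool)
        for r in kept.df.itertuples():
            rmask[r.start:r.end] = True
        expected_fold = ((fmask & rmask).sum() / rmask.sum()) / (fmask.sum() / 5000)
        assert enr.loc["feat", "fold"] == pytest.approx(expected_fold)


class TestROICoverage:
    def test_no_fragments_means_zero_coverage(self, toy_catalog):
        genome = {"chr1": "ACGT" * 1250, "chr2": "ACGT" * 250}
        frags = rr.FragmentSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [4900], "end": [4990]}))
        cov = rr.compute_roi_coverage(frags, toy_catalog, genome, roi="gene_body")
        assert not cov.per_gene.set_index("gene_id").loc["gB", "covered"]

    def test_fragment_spanning_promoter_covers_gene(self, toy_catalog):
        genome = {"chr1": "ACGT" * 1250, "chr2": "ACGT" * 250}
        frags = rr.FragmentSet(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000]}))
        cov = rr.compute_roi_coverage(frags, toy_catalog, genome, roi="promoter")
        assert cov.per_gene.set_index("gene_id").loc["gA", "covered"]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(31)
        genome = random_genome(rng, 4000)
        genes = pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "start": [1500, 3000], "end": [2000, 3400],
            "strand": ["+", "-"], "tss": [1500, 3399], "tes": [1999, 3000]})
        cat = rr.FeatureCatalog(genes=genes)
        frags = rr.select_fragments(rr.digest_genome(genome, rr.MseI),
                                    rr.SizeRange(20, 200))
        cov = rr.compute_roi_coverage(frags, cat, genome, roi="gene_body",
                                      chh_threshold=0)
        seq = genome["chr1"]
        rmask = np.zeros(4000, dtype=bool)
        for r in frags.df.itertuples():
            rmask[r.start:r.end] = True
        for g in genes.itertuples():
            has_c = any(rmask[i] and seq[i] in "CG"
                        for i in range(g.start, g.end))
            assert bool(cov.per_gene.set_index("gene_id").loc[g.gene_id, "covered"]) \
                == has_c

    def test_unknown_roi_rejected(self, toy_catalog):
        with pytest.raises(ValueError, match="unknown ROI"):
            rr.compute_roi_coverage(
                rr.FragmentSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                             "end": [10]})),
                toy_catalog, {"chr1": "ACGT" * 1250, "chr2": "ACGT" * 250},
                roi="intergenic")


class TestRankEnzymes:
    def test_promoter_planted_enzyme_ranks_first(self):
        from roirrbs.simulate import make_annotation, make_genome, preset

        cfg = preset("enzyme-rank", 17)
        genome, truth = make_genome(cfg)
        genes, _ = make_annotation(genome, cfg)
        cat = rr.FeatureCatalog(genes=genes)
        table = rr.rank_enzymes(genome, cat, ["MseI", "CviQI"],
                                [rr.SizeRange(40, 300)], target_roi="promoter",
                                with_coverage=False)
        assert table["enzyme"].iloc[0] == "MseI"
        assert table["roi_fold"].iloc[0] > table["roi_fold"].iloc[1]

    def test_single_pair_reproduces_enrichment(self, toy_catalog):
        genome = {"chr1": ("ACGT" * 300 + "TTAA") * 4, "chr2": "ACGT" * 250}
        rr.derive_promoters(toy_catalog,
                            chrom_sizes={c: len(s) for c, s in genome.items()})
        table = rr.rank_enzymes(genome, toy_catalog, ["MseI"],
                                [rr.SizeRange(40, 5000)], with_coverage=False)
        frags = rr.select_fragments(rr.digest_genome(genome, rr.MseI),
                                    rr.SizeRange(40, 5000))
        enr = rr.compute_enrichment(frags, toy_catalog, genome,
                                    classes=["promoter"])
        assert table["roi_fold"].iloc[0] == pytest.approx(
            float(enr.loc["promoter", "fold"]))

    def test_requires_inputs(self, toy_catalog):
        with pytest.raises(ValueError):
            rr.rank_enzymes({"c": "ACGT"}, toy_catalog, [], [rr.SizeRange(1, 2)])
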