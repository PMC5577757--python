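"""Upstream CHH binning, island calling, metrics and sequence export."""

import numpy as np
import pandas as pd
import pytest

import roirrbs as rr
from roirrbs.genome import revcomp
from roirrbs.islands import UpstreamBinTable

from conftest import methylome_from_rows


def _catalog(strand="+", tss=5000, gene_bp=500, chrom="c"):
    if strand == "+":
        start, end = tss, tss + gene_bp
        tes = end - 1
    else:
        start, end = tss - gene_bp + 1, tss + 1
        tes = start
    genes = pd.DataFrame({"gene_id": ["g"], "chrom": [chrom], "start": [start],
                          "end": [end], "strand": [strand], "tss": [tss],
                          "tes": [tes]})
    return rr.FeatureCatalog(genes=genes)


def _chh_methylome(levels_by_dist, tss=5000, strand="+", name="t", cov=20,
                   sites_per_bin=4):
    """levels_by_dist: {bin_index: level}; places sites_per_bin CHH sites
    spread through each bin at the given level."""
    rows = []
    for b, level in levels_by_dist.items():
        for k in range(sites_per_bin):
            d = b * 100 + 10 + 20 * k
            pos = (tss - 1 - d) if strand == "+" else (tss + 1 + d)
            rows.append(("c", pos, "+", "CHH", int(round(level * cov)), cov))
    return methylome_from_rows(rows, name)


class TestBinUpstreamCHH:
    def test_uniform_levels_give_zero_deltas(self):
        m1 = _chh_methylome({b: 0.3 for b in range(20)}, name="shoot")
        m2 = _chh_methylome({b: 0.3 for b in range(20)}, name="tassel")
        table = rr.bin_upstream_chh({"shoot": m1, "tassel": m2}, _catalog())
        assert np.allclose(table.bins["delta"].dropna(), 0.0)
        assert table.bins["delta"].notna().all()

    def test_empty_bins_missing_not_zero(self):
        m1 = _chh_methylome({0: 0.3, 5: 0.2}, name="shoot")
        m2 = _chh_methylome({0: 0.3, 5: 0.2}, name="tassel")
        table = rr.bin_upstream_chh({"shoot": m1, "tassel": m2}, _catalog())
        missing = table.bins[table.bins["bin"] == 3]
        assert missing["level_shoot"].isna().all()
        assert missing["delta"].isna().all()

    def test_min_sites_per_bin_enforced(self):
        m1 = _chh_methylome({0: 0.5}, sites_per_bin=1, name="shoot")
        table = rr.bin_upstream_chh({"shoot": m1}, _catalog(), min_sites_per_bin=2)
        assert table.bins["level_shoot"].isna().all()

    def test_bin_means_match_brute_force(self):
        rng = np.random.default_rng(61)
        rows = []
        for _ in range(300):
            d = int(rng.integers(0, 2000))
            cov = int(rng.integers(4, 30))
            mc = int(rng.binomial(cov, 0.2))
            rows.append(("c", 5000 - 1 - d, "+", "CHH", mc, cov))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                         "mc", "cov"]).drop_duplicates(
            subset=["chrom", "pos", "strand"])
        m = rr.Methylome(df.assign(dinuc="CA"), name="shoot")
        table = rr.bin_upstream_chh({"shoot": m}, _catalog(),
                                    min_sites_per_bin=1)
        for b in range(20):
            lo, hi = b * 100, (b + 1) * 100
            sel = df[(5000 - 1 - df["pos"] >= lo) & (5000 - 1 - df["pos"] < hi)]
            expected = (sel["mc"] / sel["cov"]).mean() if len(sel) else np.nan
            got = table.bins.loc[table.bins["bin"] == b, "level_shoot"].iloc[0]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_minus_strand_bins_run_upstream(self):
        m1 = _chh_methylome({0: 0.6}, strand="-", name="shoot")
        table = rr.bin_upstream_chh({"shoot": m1}, _catalog(strand="-"))
        b0 = table.bins[table.bins["bin"] == 0]
        assert b0["level_shoot"].iloc[0] == pytest.approx(0.6)
        assert b0["start"].iloc[0] == 5001  # just 3' of the - strand TSS


def _two_tissue_table(delta_bins, base=0.02, cutoff_delta=0.30, cov=100):
    m1 = _chh_methylome({b: (base + cutoff_delta if b in delta_bins else base)
                         for b in range(20)}, name="shoot", cov=cov)
    m2 = _chh_methylome({b: base for b in range(20)}, name="tassel", cov=cov)
    return rr.bin_upstream_chh({"shoot": m1, "tassel": m2}, _catalog())


class TestCallTissueSpecificIslands:
    def test_elevated_bin_yields_island(self):
        isl = rr.call_tissue_specific_islands(_two_tissue_table({4}))
        assert len(isl) == 1
        assert isl["tissue"].iloc[0] == "shoot"
        assert isl["gene_id"].iloc[0] == "g"

    def test_cutoff_is_inclusive(self):
        table = _two_tissue_table({4}, cutoff_delta=0.25)
        isl = rr.call_tissue_specific_islands(table, cutoff=0.25)
        assert len(isl) == 1
        below = _two_tissue_table({4}, cutoff_delta=0.249, cov=1000)
        assert len(rr.call_tissue_specific_islands(below, cutoff=0.25)) == 0

    def test_adjacent_bins_merge(self):
        isl = rr.call_tissue_specific_islands(_two_tissue_table({3, 4, 5, 9}))
        assert len(isl) == 2
        assert sorted(isl["n_bins"]) == [1, 3]

    def test_extent_trimmed_to_outermost_sites(self):
        isl = rr.call_tissue_specific_islands(_two_tissue_table({4}))
        # sites within bin 4 sit at distances 410..470 -> extent 61 bp
        assert isl["size"].iloc[0] == 61
        assert isl["distance_to_tss"].iloc[0] == 410

    def test_extent_within_upstream_window(self):
        isl = rr.call_tissue_specific_islands(_two_tissue_table({0, 19}))
        assert (isl["distance_to_tss"] >= 0).all()
        assert (isl["distance_to_tss"] <= 2000).all()

    def test_swapping_tissues_swaps_labels(self):
        table = _two_tissue_table({6})
        isl = rr.call_tissue_specific_islands(table)
        swapped = UpstreamBinTable(
            bins=table.bins.assign(delta=-table.bins["delta"]).rename(
                columns={"level_shoot": "level_tassel",
                         "level_tassel": "level_shoot",
                         "n_shoot": "n_tassel", "n_tassel": "n_shoot"}),
            sites=table.sites.rename(columns={"level_shoot": "level_tassel",
                                              "level_tassel": "level_shoot"}),
            tissues=("tassel", "shoot"),
            upstream_bp=table.upstream_bp, bin_bp=table.bin_bp)
        isl2 = rr.call_tissue_specific_islands(swapped)
        assert isl["tissue"].tolist() == ["shoot"]
        assert isl2["tissue"].tolist() == ["shoot"]
        pd.testing.assert_frame_equal(isl.drop(columns="tissue"),
                                      isl2.drop(columns="tissue"))

    def test_opposite_directions_give_both(self):
        m1 = _chh_methylome({2: 0.4, 10: 0.02}, cov=100, name="shoot")
        m2 = _chh_methylome({2: 0.02, 10: 0.4}, cov=100, name="tassel")
        table = rr.bin_upstream_chh({"shoot": m1, "tassel": m2}, _catalog())
        isl = rr.call_tissue_specific_islands(table)
        spec = rr.gene_specificity(isl, ("shoot", "tassel"))
        assert spec["specificity"].tolist() == ["both"]


class TestStaticIslands:
    def test_level_boundary_inclusive(self):
        m_at = _chh_methylome({3: 0.25}, cov=100, name="s")
        t = rr.bin_upstream_chh({"s": m_at}, _catalog())
        assert len(rr.call_static_islands(t, "s", level_cutoff=0.25)) == 1
        m_below = _chh_methylome({3: 0.249}, cov=1000, name="s")
        t2 = rr.bin_upstream_chh({"s": m_below}, _catalog())
        assert len(rr.call_static_islands(t2, "s", level_cutoff=0.25)) == 0

    def test_tile_islands_match_threshold_scan(self):
        rng = np.random.default_rng(71)
        rows = []
        for tile in range(30):
            level = float(rng.choice([0.05, 0.3]))
            for k in range(3):
                rows.append(("c", tile * 100 + 20 + k * 25, "+", "CHH",
                             int(level * 100), 100))
        m = methylome_from_rows(rows, "s")
        isl = rr.tile_static_islands(m, {"c": "A" * 3000}, level_cutoff=0.25)
        df = m.df
        hot = {int(p // 100) for p, mc, cov in
               zip(df["pos"], df["mc"], df["cov"]) if mc / cov >= 0.25}
        got_tiles = set()
        for r in isl.itertuples():
            got_tiles |= set(range(r.start // 100, (r.end - 1) // 100 + 1))
        assert got_tiles == hot


class TestIslandMetricsAndRegions:
    def test_metrics_match_direct_medians(self):
        isl = pd.DataFrame({
            "gene_id": list("abcd"), "tissue": ["shoot", "shoot", "tassel", "tassel"],
            "chrom": "c", "start": [0, 0, 0, 0], "end": [10, 30, 5, 13],
            "size": [10, 30, 5, 13], "distance_to_tss": [100, 700, 600, 800],
            "n_bins": 1, "peak_value": 0.3, "n_sites": 2})
        met = rr.island_metrics(isl).set_index("tissue")
        assert met.loc["shoot", "median_size"] == 20
        assert met.loc["tassel", "median_distance_to_tss"] == 700

    def test_single_site_island_size_one(self):
        m1 = _chh_methylome({4: 0.4}, cov=100, sites_per_bin=1, name="shoot")
        m2 = _chh_methylome({4: 0.02}, cov=100, sites_per_bin=1, name="tassel")
        table = rr.bin_upstream_chh({"shoot": m1, "tassel": m2}, _catalog(),
                                    min_sites_per_bin=1)
        isl = rr.call_tissue_specific_islands(table)
        assert isl["size"].iloc[0] == 1

    def test_regulatory_region_plus_strand(self):
        rng = np.random.default_rng(81)
        seq = "".join(rng.choice(list("ACGT"), size=8000))
        genome = {"c": seq}
        cat = _catalog(strand="+", tss=5000)
        isl = pd.DataFrame({"gene_id": ["g"], "tissue": ["shoot"], "chrom": ["c"],
                            "start": [4400], "end": [4500], "size": [100],
                            "distance_to_tss": [500], "n_bins": [1],
                            "peak_value": [0.4], "n_sites": [3]})
        recs = rr.extract_regulatory_regions(isl, cat, genome)
        assert len(recs) == 1
        header, s = recs[0]
        assert s == seq[4500:5000]
        assert len(s) == 500

    def test_regulatory_region_minus_strand_revcomp(self):
        rng = np.random.default_rng(82)
        seq = "".join(rng.choice(list("ACGT"), size=8000))
        genome = {"c": seq}
        cat = _catalog(strand="-", tss=5000)
        isl = pd.DataFrame({"gene_id": ["g"], "tissue": ["shoot"], "chrom": ["c"],
                            "start": [5400], "end": [5500], "size": [100],
                            "distance_to_tss": [399], "n_bins": [1],
                            "peak_value": [0.4], "n_sites": [3]})
        recs = rr.extract_regulatory_regions(isl, cat, genome)
        assert recs[0][1] == revcomp(seq[5001:5400])

    def test_island_abutting_tss_skipped(self):
        genome = {"c": "ACGT" * 2000}
        cat = _catalog(strand="+", tss=5000)
        isl = pd.DataFrame({"gene_id": ["g"], "tissue": ["shoot"], "chrom": ["c"],
                            "start": [4900], "end": [5000], "size": [100],
                            "distance_to_tss": [0], "n_bins": [1],
                            "peak_value": [0.4], "n_sites": [3]})
        assert rr.extract_regulatory_regions(isl, cat, genome) == []
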