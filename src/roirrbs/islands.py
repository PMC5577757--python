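"""mCHH islands: elevated CHH methylation upstream of TSSs.

The 2 kb region upstream of each TSS is dissected into 100-bp bins
(bin 0 is TSS-proximal) and the mean CHH level per bin is computed per
tissue. A tissue-specific island is a run of adjacent bins whose
between-tissue difference meets the cutoff (default 25%, inclusive); a
static island is a run of bins (or genome-wide tiles) whose single-tissue
mean level meets the cutoff. Island extents are trimmed to the outermost
CHH sites with data inside the qualifying bins — the bins locate the
island, the sites delimit it — which is why island sizes can be far
smaller than the 100-bp bin width.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureCatalog
from .genome import GenomeLike, load_genome, revcomp
from .methylome import Methylome


@dataclass
class UpstreamBinTable:
    """Per-gene upstream CHH bins plus the site-level records behind them.

    ``bins`` columns: gene_id, bin (0 = TSS-proximal), chrom, start, end,
    partial flag, then per tissue ``level_<t>`` / ``n_<t>``, and ``delta``
    (first tissue minus second) where both tissues have data.
    ``sites`` columns: gene_id, bin, chrom, pos, dist (bp upstream of the
    TSS) and per tissue ``level_<t>``.
    """

    bins: pd.DataFrame
    sites: pd.DataFrame
    tissues: tuple[str, ...]
    upstream_bp: int
    bin_bp: int


def bin_upstream_chh(methylomes: Mapping[str, Methylome],
                     catalog: FeatureCatalog,
                     upstream_bp: int = 2000, bin_bp: int = 100,
                     min_sites_per_bin: int = 2) -> UpstreamBinTable:
    """Mean CHH level per 100-bp upstream bin, per tissue.

    Bins are strand-aware: distance is measured 5' from the TSS along the
    gene's own orientation, so bin i covers upstream distances
    [i*bin_bp, (i+1)*bin_bp). Bins with fewer than ``min_sites_per_bin``
    covered CHH sites in a tissue are missing (NaN) for that tissue, and
    deltas are only computed where both tissues are present. Genes whose
    upstream window is clipped by the chromosome start are flagged
    ``partial``.
    """
    tissues = tuple(methylomes)
    if not 1 <= len(tissues) <= 2:
        raise ValueError("provide one or two tissues")
    n_bins = upstream_bp // bin_bp
    chh = {}
    for t, m in methylomes.items():
        df = m.subset_context("CHH").df
        df = df[df["cov"] > 0]
        chh[t] = {c: s for c, s in df.groupby("chrom")}

    bin_rows, site_rows = [], []
    for gene in catalog.genes.itertuples():
        if gene.strand == "+":
            win_lo, win_hi = gene.tss - upstream_bp, gene.tss
            partial = win_lo < 0
        else:
            win_lo, win_hi = gene.tss + 1, gene.tss + 1 + upstream_bp
            partial = False  # clipping at chromosome end handled by data absence
        tissue_levels: dict[str, np.ndarray] = {}
        tissue_counts: dict[str, np.ndarray] = {}
        for t in tissues:
            sub = chh[t].get(gene.chrom)
            sums = np.zeros(n_bins)
            counts = np.zeros(n_bins, dtype=np.int64)
            if sub is not None:
                pos = sub["pos"].to_numpy()
                i0, i1 = np.searchsorted(pos, [max(win_lo, 0), win_hi])
                p = pos[i0:i1]
                lev = (sub["mc"].to_numpy()[i0:i1]
                       / sub["cov"].to_numpy()[i0:i1])
                dist = (gene.tss - 1 - p) if gene.strand == "+" else (p - gene.tss - 1)
                ok = (dist >= 0) & (dist < upstream_bp)
                p, lev, dist = p[ok], lev[ok], dist[ok]
                b = dist // bin_bp
                np.add.at(sums, b, lev)
                np.add.at(counts, b, 1)
                for pp, ll, dd, bb in zip(p, lev, dist, b):
                    site_rows.append((gene.gene_id, int(bb), gene.chrom, int(pp),
                                      int(dd), t, ll))
            tissue_levels[t] = np.where(counts >= min_sites_per_bin,
                                        sums / np.maximum(counts, 1), np.nan)
            tissue_counts[t] = counts
        for i in range(n_bins):
            if gene.strand == "+":
                b_start, b_end = gene.tss - (i + 1) * bin_bp, gene.tss - i * bin_bp
            else:
                b_start, b_end = gene.tss + 1 + i * bin_bp, gene.tss + 1 + (i + 1) * bin_bp
            row = [gene.gene_id, i, gene.chrom, max(b_start, 0), max(b_end, 0),
                   bool(partial and b_start < 0)]
            for t in tissues:
                row += [tissue_levels[t][i], int(tissue_counts[t][i])]
            bin_rows.append(row)

    cols = ["gene_id", "bin", "chrom", "start", "end", "partial"]
    for t in tissues:
        cols += [f"level_{t}", f"n_{t}"]
    bins = pd.DataFrame(bin_rows, columns=cols)
    if len(tissues) == 2:
        t1, t2 = tissues
        bins["delta"] = bins[f"level_{t1}"] - bins[f"level_{t2}"]
    sites = pd.DataFrame(site_rows, columns=["gene_id", "bin", "chrom", "pos",
                                             "dist", "tissue", "level"])
    if len(sites):
        sites = sites.pivot_table(index=["gene_id", "bin", "chrom", "pos", "dist"],
                                  columns="tissue", values="level").reset_index()
        sites.columns.name = None
        sites = sites.rename(columns={t: f"level_{t}" for t in tissues})
    else:
        sites = pd.DataFrame(columns=["gene_id", "bin", "chrom", "pos", "dist"]
                             + [f"level_{t}" for t in tissues])
    return UpstreamBinTable(bins=bins, sites=sites, tissues=tissues,
                            upstream_bp=upstream_bp, bin_bp=bin_bp)


def _runs(sorted_bins: Sequence[int]) -> list[list[int]]:
    runs, cur = [], []
    for b in sorted(sorted_bins):
        if cur and b == cur[-1] + 1:
            cur.append(b)
        else:
            if cur:
                runs.append(cur)
            cur = [b]
    if cur:
        runs.append(cur)
    return runs


def _island_rows(gsites: pd.DataFrame, gene_id: str, tissue_label: str,
                 qualifying: pd.DataFrame, value_col: str,
                 site_level_col: str) -> list[dict]:
    """Merge adjacent qualifying bins into islands and trim each to its
    outermost CHH sites with data."""
    rows = []
    for run in _runs(qualifying["bin"].tolist()):
        in_run = gsites[gsites["bin"].isin(run)
                        & gsites[site_level_col].notna()]
        if len(in_run) == 0:
            continue
        start = int(in_run["pos"].min())
        end = int(in_run["pos"].max()) + 1
        dist = int(in_run["dist"].min())
        sub = qualifying[qualifying["bin"].isin(run)]
        rows.append({
            "gene_id": gene_id, "tissue": tissue_label,
            "chrom": in_run["chrom"].iloc[0], "start": start, "end": end,
            "size": end - start, "distance_to_tss": dist,
            "n_bins": len(run), "peak_value": float(sub[value_col].abs().max()),
            "n_sites": len(in_run),
        })
    return rows


def call_tissue_specific_islands(table: UpstreamBinTable,
                                 cutoff: float = 0.25) -> pd.DataFrame:
    """Islands where the between-tissue CHH difference meets ``cutoff``.

    A gene has a first-tissue island when >= 1 upstream bin has
    delta >= cutoff (inclusive), a second-tissue island symmetrically at
    delta <= -cutoff, and counts as 'both' when it carries qualifying
    bins in the two opposite directions. Adjacent qualifying bins merge.
    """
    if len(table.tissues) != 2:
        raise ValueError("tissue-specific islands need exactly two tissues")
    t1, t2 = table.tissues
    bins = table.bins[table.bins["delta"].notna()]
    sites_by_gene = dict(iter(table.sites.groupby("gene_id", sort=False)))
    empty_sites = table.sites.iloc[0:0]
    rows: list[dict] = []
    for gene_id, gbins in bins.groupby("gene_id", sort=True):
        up1 = gbins[gbins["delta"] >= cutoff]
        up2 = gbins[gbins["delta"] <= -cutoff]
        gsites = sites_by_gene.get(gene_id, empty_sites)
        if len(up1):
            rows += _island_rows(gsites, gene_id, t1, up1, "delta", f"level_{t1}")
        if len(up2):
            rows += _island_rows(gsites, gene_id, t2, up2, "delta", f"level_{t2}")
    out = pd.DataFrame(rows, columns=["gene_id", "tissue", "chrom", "start", "end",
                                      "size", "distance_to_tss", "n_bins",
                                      "peak_value", "n_sites"])
    return out


def gene_specificity(islands: pd.DataFrame,
                     tissues: Sequence[str]) -> pd.DataFrame:
    """Per-gene label: which tissue(s) hold its islands ('both' when the
    gene has islands elevated in each direction)."""
    t1, t2 = tissues
    g1 = set(islands.loc[islands["tissue"] == t1, "gene_id"])
    g2 = set(islands.loc[islands["tissue"] == t2, "gene_id"])
    rows = [(g, "both" if g in g1 and g in g2 else (t1 if g in g1 else t2))
            for g in sorted(g1 | g2)]
    return pd.DataFrame(rows, columns=["gene_id", "specificity"])


def call_static_islands(table: UpstreamBinTable, tissue: str,
                        level_cutoff: float = 0.25) -> pd.DataFrame:
    """Single-tissue islands: upstream bins whose mean CHH level is at or
    above ``level_cutoff`` (inclusive), merged and trimmed as for
    tissue-specific islands."""
    col = f"level_{tissue}"
    if col not in table.bins.columns:
        raise KeyError(f"tissue {tissue!r} not in bin table")
    bins = table.bins[table.bins[col].notna()]
    sites_by_gene = dict(iter(table.sites.groupby("gene_id", sort=False)))
    empty_sites = table.sites.iloc[0:0]
    rows: list[dict] = []
    for gene_id, gbins in bins.groupby("gene_id", sort=True):
        qual = gbins[gbins[col] >= level_cutoff]
        if len(qual):
            rows += _island_rows(sites_by_gene.get(gene_id, empty_sites),
                                 gene_id, tissue, qual, col, col)
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "chrom", "start", "end",
                                       "size", "distance_to_tss", "n_bins",
                                       "peak_value", "n_sites"])


def tile_static_islands(methylome: Methylome, genome: GenomeLike,
                        tile_bp: int = 100,
                        level_cutoff: float = 0.25) -> pd.DataFrame:
    """Genome-wide static islands: fixed 100-bp tiles whose mean CHH
    level meets the cutoff, adjacent qualifying tiles merged, extents
    trimmed to outermost covered CHH sites."""
    df = methylome.subset_context("CHH").df
    df = df[df["cov"] > 0]
    sizes = {c: len(s) for c, s in load_genome(genome).items()}
    rows = []
    for chrom, sub in df.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        lev = sub["mc"].to_numpy() / sub["cov"].to_numpy()
        tiles = pos // tile_bp
        means = pd.Series(lev).groupby(tiles).mean()
        qual = means[means >= level_cutoff].index.to_numpy()
        for run in _runs(qual.tolist()):
            in_run = np.isin(tiles, run)
            start = int(pos[in_run].min())
            end = int(pos[in_run].max()) + 1
            rows.append({"chrom": chrom, "start": start, "end": min(end, sizes.get(chrom, end)),
                         "size": end - start, "n_tiles": len(run),
                         "mean_level": float(lev[in_run].mean())})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "size",
                                       "n_tiles", "mean_level"])


def island_metrics(islands: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue median island size (bp) and median distance to the TSS."""
    if len(islands) == 0:
        return pd.DataFrame(columns=["tissue", "n_islands", "median_size",
                                     "median_distance_to_tss"])
    out = (islands.groupby("tissue")
           .agg(n_islands=("size", "size"), median_size=("size", "median"),
                median_distance_to_tss=("distance_to_tss", "median"))
           .reset_index())
    return out


def extract_regulatory_regions(islands: pd.DataFrame, catalog: FeatureCatalog,
                               genome: GenomeLike,
                               fasta_path: str | Path | None = None) -> list[tuple[str, str]]:
    """5' regulatory sequences spanning island-to-TSS, oriented 5'->3'
    along the gene (reverse-complemented for minus-strand genes).

    Returns (header, sequence) pairs; islands abutting the TSS
    (zero-length region) are skipped. Optionally writes FASTA.
    """
    g = load_genome(genome)
    genes = catalog.genes.set_index("gene_id")
    records = []
    for isl in islands.itertuples():
        gene = genes.loc[isl.gene_id]
        if gene["strand"] == "+":
            lo, hi = isl.end, gene["tss"]
        else:
            lo, hi = gene["tss"] + 1, isl.start
        if hi <= lo:
            continue  # island abuts the TSS; nothing between
        seq = g[isl.chrom][lo:hi]
        if gene["strand"] == "-":
            seq = revcomp(seq)
        header = (f"{isl.gene_id}|{isl.tissue}|{isl.chrom}:{lo}-{hi}"
                  f"({gene['strand']})")
        records.append((header, seq))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
    return records
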