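"""Feature catalogs and RR-genome enrichment.

Enzyme selection for ROI-directed RRBS asks, for each candidate enzyme
and size window: what fraction of the genome is retained, and how
over-represented is the region of interest in that retained set? The
fold enrichment of a feature class is

    fold = (feature bp in RR genome / RR bp) / (feature bp / genome bp)

computed on merged (non-overlapping) class intervals. Classes are not
made mutually exclusive: a base can be both promoter and TE, and each
class is scored independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .digest import FragmentSet, SizeRange, digest_genome, select_fragments
from .enzymes import RestrictionEnzyme, get_enzyme
from .genome import GenomeLike, load_genome
from .intervals import (empty_intervals, merge_intervals, overlap_bp,
                        points_in_intervals, total_bp)
from .methylome import assign_contexts

FEATURE_CLASSES = ("promoter", "exon", "intron", "five_prime_UTR",
                   "three_prime_UTR", "splice_site", "TE", "gene_body")


@dataclass
class FeatureCatalog:
    """Gene table plus merged interval sets per feature class.

    ``genes`` columns: gene_id, chrom, start, end, strand, tss, tes
    (tss/tes are 0-based positions of the first/last transcribed base).
    ``classes`` maps a label to a merged (chrom, start, end) frame;
    promoter and splice_site are added by their derive functions.
    """

    genes: pd.DataFrame
    classes: dict[str, pd.DataFrame] = field(default_factory=dict)
    introns: pd.DataFrame = field(default_factory=empty_intervals)

    def merged(self, label: str) -> pd.DataFrame:
        if label not in self.classes:
            if label == "gene_body" and len(self.genes):
                self.classes["gene_body"] = merge_intervals(
                    self.genes[["chrom", "start", "end"]])
                return self.classes["gene_body"]
            raise KeyError(f"feature class {label!r} not in catalog "
                           f"(have {sorted(self.classes)})")
        return self.classes[label]


def _gene_tss_tes(start: int, end: int, strand: str) -> tuple[int, int]:
    return (start, end - 1) if strand == "+" else (end - 1, start)


def load_annotation(gff3: str | Path, te_gff3: str | Path | None = None,
                    te_types: Sequence[str] = ("transposable_element",
                                               "transposon_fragment",
                                               "repeat_region")) -> FeatureCatalog:
    """Build a feature catalog from GFF3 (1-based inclusive, converted to
    0-based half-open).

    Introns are derived as within-transcript gaps between exons; the gene
    body is the TSS..TES span. The TSS of a multi-transcript gene is the
    5'-most transcript start on the gene's strand (one promoter per gene).
    TEs come from ``te_gff3`` if given (any of ``te_types``, else every
    record in that file).
    """
    try:
        db = gffutils.create_db(str(gff3), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {gff3}: {exc}") from exc

    gene_rows = []
    exons, introns, utr5, utr3 = [], [], [], []
    for gene in db.features_of_type("gene"):
        g_start, g_end = gene.start - 1, gene.end
        strand = gene.strand if gene.strand in "+-" else "+"
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"),
                                       level=1))
        span_start, span_end = g_start, g_end
        any_exons = False
        for tx in transcripts:
            tx_exons = sorted((e.start - 1, e.end)
                              for e in db.children(tx, featuretype="exon"))
            if not tx_exons:
                warnings.warn(f"transcript {tx.id} has no exons; skipped")
                continue
            any_exons = True
            span_start = min(span_start, tx_exons[0][0])
            span_end = max(span_end, tx_exons[-1][1])
            for s, e in tx_exons:
                exons.append((gene.seqid, s, e))
            for (s1, e1), (s2, e2) in zip(tx_exons[:-1], tx_exons[1:]):
                if s2 > e1:
                    introns.append((gene.seqid, e1, s2))
            for u in db.children(tx, featuretype="five_prime_UTR"):
                utr5.append((gene.seqid, u.start - 1, u.end))
            for u in db.children(tx, featuretype="three_prime_UTR"):
                utr3.append((gene.seqid, u.start - 1, u.end))
        if transcripts and not any_exons:
            warnings.warn(f"gene {gene.id}: no transcript with exons; "
                          "contributes gene_body only")
        tss, tes = _gene_tss_tes(span_start, span_end, strand)
        gene_rows.append((gene.id, gene.seqid, span_start, span_end, strand, tss, tes))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end",
                                             "strand", "tss", "tes"])
    def _mk(rows):
        if not rows:
            return empty_intervals()
        return merge_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    classes = {
        "exon": _mk(exons),
        "intron": _mk(introns),
        "five_prime_UTR": _mk(utr5),
        "three_prime_UTR": _mk(utr3),
        "gene_body": _mk(list(genes[["chrom", "start", "end"]].itertuples(index=False))),
    }

    te_rows = []
    if te_gff3 is not None:
        te_db = gffutils.create_db(str(te_gff3), ":memory:",
                                   merge_strategy="create_unique", keep_order=True)
        feats = list(te_db.all_features())
        typed = [f for f in feats if f.featuretype in te_types]
        for f in (typed or feats):
            te_rows.append((f.seqid, f.start - 1, f.end))
    classes["TE"] = _mk(te_rows)

    introns_df = _mk(introns)
    return FeatureCatalog(genes=genes, classes=classes, introns=introns_df)


def derive_promoters(catalog: FeatureCatalog, upstream_bp: int = 1000,
                     chrom_sizes: Mapping[str, int] | None = None,
                     store: bool = True) -> pd.DataFrame:
    """Promoter = ``upstream_bp`` immediately 5' of each gene's TSS
    (default 1 kb), strand-aware and clipped at chromosome bounds.

    Returns per-gene intervals (gene_id retained); the merged union is
    stored on the catalog as class 'promoter' when ``store``.
    """
    g = catalog.genes
    plus = g["strand"] == "+"
    start = np.where(plus, g["start"] - upstream_bp, g["end"])
    end = np.where(plus, g["start"], g["end"] + upstream_bp)
    out = pd.DataFrame({"gene_id": g["gene_id"], "chrom": g["chrom"],
                        "start": start, "end": end, "strand": g["strand"]})
    out["start"] = out["start"].clip(lower=0)
    if chrom_sizes:
        out["end"] = np.minimum(out["end"],
                                out["chrom"].map(chrom_sizes).astype(np.int64))
    out = out[out["end"] > out["start"]].reset_index(drop=True)
    if store:
        catalog.classes["promoter"] = merge_intervals(out[["chrom", "start", "end"]])
    return out


def derive_splice_sites(catalog: FeatureCatalog, flank_bp: int = 20,
                        store: bool = True) -> pd.DataFrame:
    """+-``flank_bp`` windows around every exon-intron boundary, merged.
    The boundary flank is unstandardised in the field; 20 bp is the
    package default and is configurable."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    introns = catalog.introns
    if flank_bp == 0 or len(introns) == 0:
        out = empty_intervals()
    else:
        bounds = pd.concat([
            pd.DataFrame({"chrom": introns["chrom"], "b": introns["start"]}),
            pd.DataFrame({"chrom": introns["chrom"], "b": introns["end"]}),
        ])
        out = merge_intervals(pd.DataFrame({
            "chrom": bounds["chrom"],
            "start": (bounds["b"] - flank_bp).clip(lower=0),
            "end": bounds["b"] + flank_bp,
        }))
    if store:
        catalog.classes["splice_site"] = out
    return out


def compute_enrichment(fragments: FragmentSet, catalog: FeatureCatalog,
                       genome: GenomeLike,
                       classes: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-class fold enrichment of the RR genome (see module docstring).

    Folds are NaN (reported missing, never 0) when the RR genome or the
    feature class is empty.
    """
    sizes = {c: len(s) for c, s in load_genome(genome).items()}
    genome_bp = sum(sizes.values())
    rr = merge_intervals(fragments.intervals())
    rr_bp = total_bp(rr)
    labels = list(classes) if classes is not None else sorted(catalog.classes)
    rows = []
    for label in labels:
        feat = catalog.merged(label)
        feat_bp = total_bp(feat)
        bp_in_rr = overlap_bp(feat, rr)
        frac_rr = bp_in_rr / rr_bp if rr_bp else np.nan
        frac_ref = feat_bp / genome_bp if genome_bp else np.nan
        fold = (frac_rr / frac_ref
                if rr_bp and feat_bp and frac_ref > 0 else np.nan)
        rows.append((label, feat_bp, bp_in_rr, frac_rr, frac_ref, fold))
    return pd.DataFrame(rows, columns=["feature", "feature_bp", "bp_in_rr",
                                       "fraction_rr", "fraction_ref", "fold"]
                        ).set_index("feature")


@dataclass(frozen=True)
class ROICoverage:
    """Per-gene coverage of an ROI class by retained fragments."""

    per_gene: pd.DataFrame  # gene_id, covered, n_chh_covered
    fraction_covered: float
    fraction_chh_above_threshold: float
    roi: str
    chh_threshold: int


def compute_roi_coverage(fragments: FragmentSet, catalog: FeatureCatalog,
                         genome: GenomeLike, roi: str = "promoter",
                         chh_threshold: int = 50,
                         upstream_bp: int = 1000) -> ROICoverage:
    """Which genes have >=1 cytosine of their ROI inside a retained
    fragment, and how many CHH sites are covered per gene.

    ``roi`` is 'promoter' (``upstream_bp`` 5' of the TSS) or 'gene_body'.
    Cytosines on both strands count.
    """
    if roi == "promoter":
        regions = derive_promoters(catalog, upstream_bp=upstream_bp,
                                   chrom_sizes={c: len(s) for c, s in
                                                load_genome(genome).items()},
                                   store=False)
    elif roi == "gene_body":
        regions = catalog.genes[["gene_id", "chrom", "start", "end"]].copy()
    else:
        raise ValueError(f"unknown ROI {roi!r} (promoter or gene_body)")
    sites = assign_contexts(genome)
    rr = merge_intervals(fragments.intervals())
    in_rr = points_in_intervals(sites["chrom"].to_numpy(), sites["pos"].to_numpy(), rr)
    sites = sites.assign(in_rr=in_rr)
    is_chh = (sites["context"] == "CHH").to_numpy()
    by_chrom = {c: s for c, s in sites.groupby("chrom")}
    rows = []
    for r in regions.itertuples():
        sub = by_chrom.get(r.chrom)
        if sub is None:
            rows.append((r.gene_id, False, 0))
            continue
        pos = sub["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [r.start, r.end])
        cov = sub["in_rr"].to_numpy()[i0:i1]
        chh = (sub["context"] == "CHH").to_numpy()[i0:i1]
        rows.append((r.gene_id, bool(cov.any()), int((cov & chh).sum())))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "covered", "n_chh_covered"])
    n = len(per_gene)
    return ROICoverage(
        per_gene=per_gene,
        fraction_covered=per_gene["covered"].mean() if n else float("nan"),
        fraction_chh_above_threshold=(per_gene["n_chh_covered"] > chh_threshold).mean()
        if n else float("nan"),
        roi=roi,
        chh_threshold=chh_threshold,
    )


def rank_enzymes(genome: GenomeLike, catalog: FeatureCatalog,
                 enzymes: Sequence[str | RestrictionEnzyme],
                 size_ranges: Sequence[SizeRange | tuple[int, int]],
                 target_roi: str = "promoter",
                 with_coverage: bool = True) -> pd.DataFrame:
    """Score every (enzyme, size range) pair for one target ROI.

    Rows are sorted by ROI fold enrichment descending, ties broken by
    smaller RR fraction (less sequencing for the same enrichment).
    """
    if not enzymes or not size_ranges:
        raise ValueError("need at least one enzyme and one size range")
    if target_roi not in catalog.classes:
        if target_roi == "promoter":
            derive_promoters(catalog, chrom_sizes={c: len(s) for c, s in
                                                   load_genome(genome).items()})
        else:
            raise KeyError(f"target ROI {target_roi!r} not in catalog")
    g = load_genome(genome)
    genome_bp = sum(len(s) for s in g.values())
    rows = []
    for enz in enzymes:
        enz = get_enzyme(enz)
        all_frags = digest_genome(g, enz)
        for rng in size_ranges:
            rng = rng if isinstance(rng, SizeRange) else SizeRange(*rng)
            retained = select_fragments(all_frags, rng)
            rr_fraction = retained.total_bp / genome_bp
            enr = compute_enrichment(retained, catalog, g, classes=[target_roi])
            fold = float(enr.loc[target_roi, "fold"])
            cov = np.nan
            if with_coverage and len(retained):
                cov = compute_roi_coverage(
                    retained, catalog, g,
                    roi=target_roi if target_roi in ("promoter", "gene_body")
                    else "promoter").fraction_covered
            rows.append((enz.name, str(rng), rr_fraction, fold, cov))
    out = pd.DataFrame(rows, columns=["enzyme", "size_range", "rr_fraction",
                                      "roi_fold", "roi_coverage"])
    return out.sort_values(["roi_fold", "rr_fraction"],
                           ascending=[False, True], kind="stable",
                           na_position="last").reset_index(drop=True)
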