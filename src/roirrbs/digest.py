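"""In silico restriction digestion and fragment size selection.

Digesting a genome with a 4-cutter and retaining a size window defines
the reduced-representation (RR) genome: the subset of the genome an
RRBS library actually sequences. The ops here produce the fragment set,
apply the size window, summarise the RR genome, project sequencing
cost, and check observed read starts against the residual cut site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .enzymes import RestrictionEnzyme, get_enzyme
from .genome import GenomeLike, load_genome


@dataclass(frozen=True)
class SizeRange:
    """Inclusive fragment-length window, e.g. SizeRange(40, 300)."""

    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.min_bp <= self.max_bp:
            raise ValueError(f"invalid size range [{self.min_bp}, {self.max_bp}]")

    def __str__(self) -> str:
        return f"{self.min_bp}-{self.max_bp}"


class FragmentSet:
    """Genomic fragments as a sorted (chrom, start, end) table.

    Fragments straight out of :func:`digest_genome` tile each chromosome
    exactly; after :func:`select_fragments` they are a sorted subset.
    """

    def __init__(self, df: pd.DataFrame):
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"fragment frame missing column {col!r}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("fragment with non-positive length")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def intervals(self) -> pd.DataFrame:
        return self.df[["chrom", "start", "end"]].copy()

    def to_bed(self, path: str | Path, lengths: bool = False) -> None:
        out = self.df[["chrom", "start", "end"]].copy()
        if lengths:
            out["length"] = self.lengths
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "FragmentSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        return cls(df)


@dataclass(frozen=True)
class RRGenomeSummary:
    """Size of the reduced-representation genome relative to the assembly."""

    total_bp: int
    fraction_of_genome: float
    n_fragments: int
    per_chromosome: pd.DataFrame  # chrom, n_fragments, total_bp, chrom_bp

    def to_tsv(self, path: str | Path) -> None:
        self.per_chromosome.to_csv(path, sep="\t", index=False)


def digest_genome(genome: GenomeLike, enzyme: str | RestrictionEnzyme) -> FragmentSet:
    """Cut every chromosome at every recognition-site occurrence.

    Cut coordinates are ``site_start + cut_offset`` for each forward-strand
    occurrence (overlaps included); chromosome ends act as cut sites, so
    fragments tile each chromosome with no gaps or overlaps. Only
    palindromic-site enzymes are accepted: for those, forward-strand
    scanning reproduces double-strand digestion.
    """
    enzyme = get_enzyme(enzyme)
    if not enzyme.is_palindromic:
        raise ValueError(
            f"{enzyme.name}: recognition site {enzyme.recognition_site} is not "
            "palindromic; forward-strand digestion would miss bottom-strand sites"
        )
    g = load_genome(genome)
    if not g:
        raise ValueError("empty genome")
    rows = []
    for chrom, seq in g.items():
        if len(seq) == 0:
            warnings.warn(f"chromosome {chrom!r} is empty; no fragments produced")
            continue
        bounds = [0] + sorted(set(enzyme.cut_positions(seq))) + [len(seq)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, s, e))
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def select_fragments(fragments: FragmentSet, size_range: SizeRange) -> FragmentSet:
    """Retain fragments with min_bp <= length <= max_bp (both inclusive)."""
    if not isinstance(size_range, SizeRange):
        size_range = SizeRange(*size_range)
    lengths = fragments.lengths
    keep = (lengths >= size_range.min_bp) & (lengths <= size_range.max_bp)
    return FragmentSet(fragments.df[keep])


def summarize_rr_genome(fragments: FragmentSet, genome: GenomeLike) -> RRGenomeSummary:
    """RR-genome totals; the fraction denominator is the full assembled
    length including N bases."""
    sizes = {c: len(s) for c, s in load_genome(genome).items()}
    df = fragments.df
    unknown = set(df["chrom"]) - set(sizes)
    if unknown:
        raise ValueError(f"fragments on chromosomes absent from genome: {sorted(unknown)}")
    for chrom, sub in df.groupby("chrom"):
        if (sub["end"] > sizes[chrom]).any():
            raise ValueError(f"fragment beyond end of chromosome {chrom!r}")
    per = (
        df.assign(length=fragments.lengths)
        .groupby("chrom")
        .agg(n_fragments=("length", "size"), total_bp=("length", "sum"))
        .reindex(sorted(sizes))
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    per["chrom_bp"] = per["chrom"].map(sizes)
    genome_bp = sum(sizes.values())
    total = int(per["total_bp"].sum())
    return RRGenomeSummary(
        total_bp=total,
        fraction_of_genome=total / genome_bp if genome_bp else 0.0,
        n_fragments=len(df),
        per_chromosome=per,
    )


def estimate_cost(summary: RRGenomeSummary, target_depth: float,
                  price_per_gb: float) -> float:
    """Sequencing cost = retained bp x depth x unit price (price per 1e9
    sequenced bases). Linear in the RR fraction, so halving the RR genome
    halves the cost."""
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    if price_per_gb <= 0:
        raise ValueError("price_per_gb must be positive")
    return summary.total_bp * target_depth * price_per_gb / 1e9


def read_start_qc(
    reads: str | Path | Mapping[str, str | Path],
    enzyme: str | RestrictionEnzyme | None = None,
    expected_prefixes: Iterable[str] | None = None,
) -> dict[str, float]:
    """Fraction of reads per mate beginning with an expected residual-site
    prefix (matched literally at position 0).

    ``reads`` is one FASTQ path or a mapping mate-label -> path. Prefixes
    default to the enzyme's residual site plus its bisulfite-converted
    variant (MseI -> TAA; CviQI -> TAC/TAT).
    """
    if expected_prefixes is None:
        if enzyme is None:
            raise ValueError("provide expected_prefixes or an enzyme")
        expected_prefixes = get_enzyme(enzyme).expected_read_prefixes()
    prefixes = tuple(p.upper() for p in expected_prefixes)
    if not prefixes:
        raise ValueError("no expected prefixes")
    if not isinstance(reads, Mapping):
        reads = {"R1": reads}
    out: dict[str, float] = {}
    for mate, path in reads.items():
        n = hit = 0
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            if str(rec.seq).upper().startswith(prefixes):
                hit += 1
        if n == 0:
            raise ValueError(f"FASTQ {path} contains no reads")
        out[mate] = hit / n
    return out
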