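"""Genome sequence access helpers.

A genome is represented in memory as a plain ``dict`` mapping chromosome
name to an upper-case sequence string; helpers here load that dict from
FASTA (plain via pyfaidx, gzipped via Biopython) and write it back out.
All coordinates in this package are 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GenomeLike = Union[Mapping[str, str], str, Path]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def load_genome(source: GenomeLike) -> dict[str, str]:
    """Return ``{chrom: sequence}`` with upper-case sequences.

    ``source`` may already be such a mapping (returned normalised), or a
    path to a FASTA file (optionally gzip-compressed).
    """
    if isinstance(source, Mapping):
        return {str(k): str(v).upper() for k, v in source.items()}
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def chrom_sizes(genome: GenomeLike) -> dict[str, int]:
    g = load_genome(genome)
    return {c: len(s) for c, s in g.items()}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
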