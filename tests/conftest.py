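"""Shared fixtures: toy sequences, a small annotated genome, and the
session-scoped simulation benches reused by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import roirrbs as rr
from roirrbs.simulate import make_genome, preset, simulate_methylomes

GFF3_TOY = """\
##gff-version 3
chr1\ttest\tgene\t1001\t2000\t.\t+\t.\tID=gA
chr1\ttest\tmRNA\t1001\t2000\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\ttest\texon\t1001\t1400\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chr1\ttest\texon\t1601\t2000\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
chr1\ttest\tgene\t3001\t3600\t.\t-\t.\tID=gB
chr1\ttest\tmRNA\t3001\t3600\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\ttest\texon\t3001\t3600\t.\t-\t.\tID=gB.t1.e1;Parent=gB.t1
chr2\ttest\tgene\t501\t900\t.\t+\t.\tID=gC
chr2\ttest\tmRNA\t501\t900\t.\t+\t.\tID=gC.t1;Parent=gC
"""


@pytest.fixture(scope="session")
def toy_gff3(tmp_path_factory):
    path = tmp_path_factory.mktemp("ann") / "toy.gff3"
    path.write_text(GFF3_TOY)
    return path


@pytest.fixture(scope="session")
def toy_catalog(toy_gff3):
    with pytest.warns(UserWarning):
        return rr.load_annotation(toy_gff3)


def random_genome(rng: np.random.Generator, length: int,
                  gc: float = 0.5, n_chroms: int = 1) -> dict[str, str]:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        f"chr{i + 1}": rng.choice(bases, size=length, p=p).tobytes().decode()
        for i in range(n_chroms)
    }


def brute_force_cuts(seq: str, enzyme: rr.RestrictionEnzyme) -> list[int]:
    """Independent digestion oracle: test every position of the sequence
    against the IUPAC-expanded site, character by character."""
    from roirrbs.enzymes import IUPAC

    seq = seq.upper()
    site = enzyme.recognition_site
    cuts = []
    for i in range(len(seq) - len(site) + 1):
        if all(seq[i + j] in IUPAC[site[j]] for j in range(len(site))):
            c = i + enzyme.cut_offset
            if 0 < c < len(seq):
                cuts.append(c)
    return sorted(set(cuts))


def fragments_from_cuts(seq: str, cuts: list[int], chrom: str) -> pd.DataFrame:
    bounds = [0] + cuts + [len(seq)]
    return pd.DataFrame({"chrom": chrom,
                         "start": bounds[:-1], "end": bounds[1:]})


def methylome_from_rows(rows, name="m") -> rr.Methylome:
    """rows: (chrom, pos, strand, context, mc, cov)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "mc", "cov"])
    df["dinuc"] = "CA"
    return rr.Methylome(df, name=name)


@pytest.fixture(scope="session")
def null_bench():
    cfg = preset("null", 20260926)
    genome, truth = make_genome(cfg)
    sim = simulate_methylomes(genome, truth["genes"], cfg)
    return genome, sim


@pytest.fixture(scope="session")
def dmr_bench():
    cfg = preset("dmr-bench", 20260927)
    genome, truth = make_genome(cfg)
    sim = simulate_methylomes(genome, truth["genes"], cfg)
    return genome, sim


@pytest.fixture(scope="session")
def island_bench():
    cfg = preset("island-bench", 20260928)
    genome, truth = make_genome(cfg)
    sim = simulate_methylomes(genome, truth["genes"], cfg)
    return genome, sim
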