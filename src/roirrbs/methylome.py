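"""Per-cytosine methylation: contexts, CGmap I/O, levels and profiles.

The unit of data is one cytosine on one strand with methylated (#C) and
unmethylated (#T) read counts; its methylation level is #C/(#C+#T), an
estimate of the fraction of cells methylated at that position. Plant
methylomes distinguish the symmetric CG and CHG contexts from the
asymmetric CHH context (H = A, T or C); all three are carried here.

A :class:`Methylome` wraps a pandas DataFrame with columns
``chrom, pos, strand, context, dinuc, mc, cov`` (pos 0-based; ``mc`` =
methylated reads, ``cov`` = total reads). CGmap files (the per-cytosine
table emitted by bisulfite aligners such as BS Seeker 2) are the on-disk
interchange format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomeLike, load_genome

CONTEXTS = ("CG", "CHG", "CHH")
_KEY = ["chrom", "pos", "strand"]
_COLS = ["chrom", "pos", "strand", "context", "dinuc", "mc", "cov"]


@dataclass
class Methylome:
    """A set of per-cytosine records keyed by (chrom, pos, strand)."""

    df: pd.DataFrame
    name: str = "methylome"
    tissue: str | None = None
    enzyme: str | None = None
    min_coverage: int = 0  # coverage filter already applied, 0 = none

    def __post_init__(self) -> None:
        missing = [c for c in _COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"methylome frame missing columns {missing}")
        df = self.df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["mc"] = df["mc"].astype(np.int64)
        df["cov"] = df["cov"].astype(np.int64)
        if (df["mc"] < 0).any() or (df["cov"] < df["mc"]).any():
            raise ValueError("counts must satisfy 0 <= mc <= cov")
        bad = ~df["context"].isin(CONTEXTS)
        if bad.any():
            raise ValueError(f"unknown contexts: {sorted(df.loc[bad, 'context'].unique())}")
        if df.duplicated(_KEY).any():
            raise ValueError("duplicate (chrom, pos, strand) records")
        self.df = df.sort_values(_KEY, kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def levels(self) -> np.ndarray:
        """Per-site #C/(#C+#T); NaN where coverage is 0."""
        cov = self.df["cov"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.df["mc"].to_numpy() / cov, np.nan)

    def keys(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.df[_KEY])

    def subset_context(self, context: str) -> "Methylome":
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return replace(self, df=self.df[self.df["context"] == context])


def assign_contexts(genome: GenomeLike,
                    contexts: Iterable[str] | None = None) -> pd.DataFrame:
    """Map every genomic cytosine (both strands) to CG/CHG/CHH.

    A + strand C at i is CG when base(i+1) = G, CHG when base(i+2) = G
    with base(i+1) = H, else CHH when both following bases are in
    {A, T, C}; the - strand is the mirror image evaluated on the reverse
    complement. Cytosines whose two downstream bases run off the
    chromosome or touch an N are excluded (context undefined).

    Returns a DataFrame with chrom, pos (0-based), strand, context, dinuc
    (the C plus its next base on the C's strand).
    """
    g = load_genome(genome)
    wanted = set(contexts) if contexts is not None else set(CONTEXTS)
    comp = np.zeros(256, dtype=np.uint8)  # A<->T, C<->G on byte codes
    for x, y in ((65, 84), (67, 71)):
        comp[x], comp[y] = y, x
    frames = []
    for chrom, seq in g.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        if n < 3:
            continue
        A, C, G, T = 65, 67, 71, 84
        valid = np.isin(arr, (A, C, G, T))
        for strand in "+-":
            if strand == "+":
                pos = np.flatnonzero(arr[: n - 2] == C)
                b1 = arr[pos + 1]
                b2 = arr[pos + 2]
                ok = valid[pos + 1] & valid[pos + 2]
            else:
                pos = np.flatnonzero(arr[2:] == G) + 2
                # read 5'->3' on the - strand: complement of i-1, i-2
                b1 = comp[arr[pos - 1]]
                b2 = comp[arr[pos - 2]]
                ok = valid[pos - 1] & valid[pos - 2]
            pos, b1, b2 = pos[ok], b1[ok], b2[ok]
            ctx = np.where(b1 == G, "CG", np.where(b2 == G, "CHG", "CHH"))
            dinuc = np.char.add("C", np.frombuffer(b1.tobytes(), dtype="S1").astype("U1"))
            sub = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand,
                                "context": ctx, "dinuc": dinuc})
            frames.append(sub[sub["context"].isin(wanted)])
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "dinuc"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(_KEY, kind="stable").reset_index(drop=True)


def load_cgmap(path: str | Path, name: str | None = None, **meta) -> Methylome:
    """Read a CGmap file (tab-separated, 1-based positions; gzip ok).

    Columns: chrom, nucleotide (C for + strand, G for -), position,
    context, dinucleotide, level, methylated count, total count. Levels
    are recomputed from the counts, not trusted from the file (a
    mismatch beyond 1e-6 raises a warning).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "nuc", "pos1", "context", "dinuc", "level", "mc", "cov"],
            dtype={"chrom": str, "nuc": str, "context": str, "dinuc": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed CGmap {path}: {exc}") from exc
    if len(df) == 0:
        warnings.warn(f"CGmap {path} is empty")
        empty = pd.DataFrame(columns=_COLS)
        return Methylome(empty, name=name or path.stem, **meta)
    bad_nuc = ~df["nuc"].isin(["C", "G"])
    if bad_nuc.any():
        lineno = int(df.index[bad_nuc][0]) + 1
        raise ValueError(f"{path}:{lineno}: nucleotide column must be C or G")
    if df[["pos1", "mc", "cov"]].isna().any().any():
        lineno = int(df.index[df[["pos1", "mc", "cov"]].isna().any(axis=1)][0]) + 1
        raise ValueError(f"{path}:{lineno}: missing numeric field")
    cov = df["cov"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recomputed = np.where(cov > 0, df["mc"].to_numpy() / cov, np.nan)
    stated = df["level"].to_numpy(dtype=float)
    mismatch = np.isfinite(stated) & np.isfinite(recomputed) & \
        (np.abs(stated - recomputed) > 1e-6)
    if mismatch.any():
        warnings.warn(
            f"{path}: {int(mismatch.sum())} rows where the stated level disagrees "
            "with mc/cov; counts take precedence"
        )
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos1"].astype(np.int64) - 1,
        "strand": np.where(df["nuc"] == "C", "+", "-"),
        "context": df["context"],
        "dinuc": df["dinuc"],
        "mc": df["mc"].astype(np.int64),
        "cov": df["cov"].astype(np.int64),
    })
    return Methylome(out, name=name or path.stem, **meta)


def write_cgmap(methylome: Methylome, path: str | Path) -> None:
    """Write the CGmap dialect read by :func:`load_cgmap` (bit-exact
    round trip of counts, positions and contexts)."""
    df = methylome.df
    cov = df["cov"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(cov > 0, df["mc"] / cov, np.nan)
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "nuc": np.where(df["strand"] == "+", "C", "G"),
        "pos1": df["pos"] + 1,
        "context": df["context"],
        "dinuc": df["dinuc"],
        "level": np.round(level, 6),
        "mc": df["mc"],
        "cov": df["cov"],
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def filter_coverage(methylome: Methylome, min_reads: int = 4) -> Methylome:
    """Retain cytosines covered by at least ``min_reads`` reads (the
    standard call-quality filter; default 4)."""
    keep = methylome.df["cov"] >= min_reads
    return replace(methylome, df=methylome.df[keep],
                   min_coverage=max(min_reads, methylome.min_coverage))


def bulk_level(methylome: Methylome, context: str | None = None) -> float:
    """Unweighted mean of per-site levels (optionally one context);
    NaN when no site qualifies."""
    df = methylome.df if context is None else methylome.subset_context(context).df
    cov = df["cov"].to_numpy(dtype=float)
    ok = cov > 0
    if not ok.any():
        return float("nan")
    return float((df["mc"].to_numpy()[ok] / cov[ok]).mean())


def conversion_rate(control: Methylome) -> float:
    """Bisulfite conversion rate from an unmethylated spike-in control
    (e.g. lambda phage): total #T / total (#C + #T)."""
    cov = int(control.df["cov"].sum())
    if cov == 0:
        raise ValueError("control methylome has zero coverage")
    return (cov - int(control.df["mc"].sum())) / cov


def methylome_overlap(a: Methylome, b: Methylome,
                      denominator: str = "union") -> float:
    """Fraction of cytosine site keys shared by two methylomes.

    ``denominator='union'`` gives the Jaccard index; ``'a'``/``'b'``
    normalise by one methylome's site count instead.
    """
    ka, kb = a.keys(), b.keys()
    inter = len(ka.intersection(kb))
    if denominator == "union":
        denom = len(ka.union(kb))
    elif denominator == "a":
        denom = len(ka)
    elif denominator == "b":
        denom = len(kb)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return inter / denom if denom else float("nan")


def metagene_profile(
    methylome: Methylome,
    genes: pd.DataFrame,
    context: str,
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    n_body_bins: int = 100,
    flank_bin_bp: int = 100,
) -> pd.DataFrame:
    """Mean methylation across genes: fixed-width flank bins around a
    proportionally binned gene body, 5'->3' (minus-strand genes flipped).

    ``genes`` needs chrom, start, end, strand (the features catalog's
    gene table). Bins with no sites are NaN, never 0. Genes shorter than
    ``n_body_bins`` bp are skipped with a warning.

    Returns a DataFrame with segment (upstream/body/downstream), bin,
    mean_level and n_sites.
    """
    sub = methylome.subset_context(context).df
    n_up = upstream_bp // flank_bin_bp
    n_down = downstream_bp // flank_bin_bp
    total_bins = n_up + n_body_bins + n_down
    sums = np.zeros(total_bins)
    counts = np.zeros(total_bins, dtype=np.int64)
    by_chrom = {c: s for c, s in sub.groupby("chrom")}
    n_skipped = 0
    for gene in genes.itertuples():
        length = gene.end - gene.start
        if length < n_body_bins:
            n_skipped += 1
            continue
        sites = by_chrom.get(gene.chrom)
        if sites is None:
            continue
        lo = gene.start - (upstream_bp if gene.strand == "+" else downstream_bp)
        hi = gene.end + (downstream_bp if gene.strand == "+" else upstream_bp)
        pos = sites["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi])
        if i0 == i1:
            continue
        pos = pos[i0:i1]
        lev = sites["mc"].to_numpy()[i0:i1] / sites["cov"].to_numpy()[i0:i1]
        ok = sites["cov"].to_numpy()[i0:i1] > 0
        pos, lev = pos[ok], lev[ok]
        if gene.strand == "+":
            rel = pos - gene.start  # 0 at TSS, grows 5'->3'
        else:
            rel = gene.end - 1 - pos
        bins = np.full(len(pos), -1, dtype=np.int64)
        up = rel < 0
        bins[up] = n_up + (rel[up] // flank_bin_bp)  # rel=-1 -> last upstream bin
        body = (rel >= 0) & (rel < length)
        bins[body] = n_up + (rel[body] * n_body_bins // length)
        down = rel >= length
        bins[down] = n_up + n_body_bins + ((rel[down] - length) // flank_bin_bp)
        ok = (bins >= 0) & (bins < total_bins)
        np.add.at(sums, bins[ok], lev[ok])
        np.add.at(counts, bins[ok], 1)
    if n_skipped:
        warnings.warn(f"{n_skipped} genes shorter than {n_body_bins} bp skipped")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    segment = (["upstream"] * n_up + ["body"] * n_body_bins + ["downstream"] * n_down)
    bin_idx = list(range(n_up)) + list(range(n_body_bins)) + list(range(n_down))
    return pd.DataFrame({"segment": segment, "bin": bin_idx,
                         "mean_level": means, "n_sites": counts})
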