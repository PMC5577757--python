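"""Synthetic genomes, annotations and two-tissue methylomes.

The generator emulates the study conditions of a plant ROI-directed
RRBS experiment at desk scale: a random genome with restriction sites
planted at controllable densities inside and outside promoters,
non-overlapping genes with exon/intron structure and TEs near a
configurable fraction of genes, and two tissues whose per-cytosine read
counts follow the same binomial read model the null-FDR machinery
assumes (mc ~ Binomial(coverage, level), plus a small per-read
non-conversion error). Differential signal is planted explicitly — DMR
fragments shifted by a methylation delta, mCHH-island bins elevated in
one tissue — and every planted effect is returned in truth tables so
recovery can be scored.

Site-level true methylation is drawn per context: CG and CHG from a
two-component (hypo/hyper) Beta mixture reproducing the bimodal levels
seen in plant methylomes, CHH from a low-mean Beta. Defaults put the
context means near CG 0.8 / CHG 0.6 / CHH 0.02, the magnitudes typical
of maize RRBS; both tissues share each site's base level so that, absent
planted effects, the comparison is an exact null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import FragmentSet, SizeRange, digest_genome, select_fragments
from .enzymes import get_enzyme, site_pattern
from .genome import write_fasta
from .methylome import Methylome, assign_contexts, write_cgmap


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; ``seed`` is mandatory."""

    seed: int
    genome_bp: int = 200_000
    n_chroms: int = 2
    gc: float = 0.46
    n_genes: int = 40
    gene_bp: int = 600
    n_exons: int = 2
    upstream_bp: int = 2000  # promoter/upstream window kept free of overlap
    te_fraction_near_genes: float = 0.85
    te_bp: int = 300
    # enzyme name -> (sites per kb inside promoters, sites per kb elsewhere)
    site_density: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"MseI": (6.0, 6.0)})
    promoter_bp: int = 1000
    enzyme: str = "MseI"
    size_range: tuple[int, int] = (40, 300)
    # methylation model
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH")
    baselines: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.6, "CHH": 0.02})
    coverage: tuple[int, int] = (4, 40)  # uniform inclusive
    non_conversion: float = 0.005  # per-read false-methylation probability
    tissues: tuple[str, str] = ("shoot", "tassel")
    # planted differential methylation
    dmr_fraction: float = 0.0
    dmr_delta: float = 0.3
    dmr_context: str = "CG"
    island_genes: int = 0
    island_delta: float = 0.4
    island_coverage: int | None = None  # fixed coverage override for islands

    def __post_init__(self) -> None:
        for p in (self.gc, self.te_fraction_near_genes, self.non_conversion,
                  self.dmr_fraction, self.dmr_delta, self.island_delta):
            if not 0 <= p <= 1:
                raise ValueError(f"probability/level {p} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def preset(name: str, seed: int) -> SimConfig:
    """Named study conditions: 'null' (no planted effects, ~2000 retained
    CG fragments, coverage 4-40x), 'dmr-bench' (10% of fragments planted
    at delta 0.3, coverage 10-30x), 'island-bench' (100 of 1000 genes
    with a planted delta-0.4 mCHH island at 20x), and 'enzyme-rank'
    (promoter-planted TTAA at 5x background density)."""
    if name == "null":
        return SimConfig(seed=seed, genome_bp=600_000, n_chroms=2, n_genes=60,
                         contexts=("CG",), coverage=(4, 40),
                         site_density={"MseI": (6.0, 6.0)})
    if name == "dmr-bench":
        return SimConfig(seed=seed, genome_bp=600_000, n_chroms=2, n_genes=60,
                         contexts=("CG",), coverage=(10, 30),
                         dmr_fraction=0.10, dmr_delta=0.3, dmr_context="CG",
                         site_density={"MseI": (6.0, 6.0)})
    if name == "island-bench":
        return SimConfig(seed=seed, genome_bp=5_000_000, n_chroms=4,
                         n_genes=1000, contexts=("CHH",), coverage=(20, 20),
                         island_genes=100, island_delta=0.4,
                         site_density={"MseI": (6.0, 6.0)})
    if name == "enzyme-rank":
        return SimConfig(seed=seed, genome_bp=300_000, n_chroms=2, n_genes=60,
                         site_density={"MseI": (10.0, 2.0), "CviQI": (2.0, 2.0)})
    raise ValueError(f"unknown preset {name!r} "
                     "(null, dmr-bench, island-bench, enzyme-rank)")


# ---------------------------------------------------------------------------
# genome + annotation layout

def _gene_layout(config: SimConfig) -> pd.DataFrame:
    """Deterministic non-overlapping gene placement shared by genome and
    annotation generation.

    Each gene gets a private slot on its chromosome large enough for the
    gene body plus a full upstream window on either side, so no gene's
    2-kb upstream region (or planted island within it) can reach a
    neighbouring gene's.
    """
    rng = np.random.default_rng([config.seed, 1])
    chrom_bp = config.genome_bp // config.n_chroms
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    slot_need = config.gene_bp + 2 * config.upstream_bp + 200
    rows = []
    gid = 0
    for ci in range(config.n_chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = chrom_bp // n
        if slot < slot_need:
            raise ValueError(f"{n} genes do not fit on a {chrom_bp} bp chromosome "
                             f"(need {slot_need} bp per gene)")
        for k in range(n):
            jitter = int(rng.integers(0, max(slot - slot_need, 1)))
            start = k * slot + config.upstream_bp + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{gid:05d}", f"chr{ci + 1}", start,
                         start + config.gene_bp, strand))
            gid += 1
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["tes"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    return df


def _promoter_intervals(genes: pd.DataFrame, promoter_bp: int) -> pd.DataFrame:
    plus = genes["strand"] == "+"
    return pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.where(plus, genes["start"] - promoter_bp, genes["end"]),
        "end": np.where(plus, genes["start"], genes["end"] + promoter_bp),
    })


def _scrub_sites(arr: np.ndarray, sites: list[str], rng: np.random.Generator) -> None:
    """Destroy every occurrence of the given recognition sites in place by
    rewriting one base, repeating until the sequence is clean."""
    seq_bases = np.frombuffer(b"ACGT", dtype="S1")
    patterns = [site_pattern(s) for s in sites]
    for _ in range(50):
        seq = arr.tobytes().decode("ascii")
        hits = sorted({m.start() for p in patterns for m in p.finditer(seq)})
        if not hits:
            return
        for h in hits:
            site_len = 4
            j = h + int(rng.integers(0, site_len))
            old = arr[j]
            choices = seq_bases[seq_bases != old]
            arr[j] = choices[int(rng.integers(0, len(choices)))]
    raise RuntimeError("failed to scrub recognition sites")


def make_genome(config: SimConfig) -> tuple[dict[str, str], dict[str, pd.DataFrame]]:
    """Random genome with planted recognition sites.

    Background sequence is i.i.d. with the configured GC fraction,
    scrubbed of every configured enzyme's site, then sites are planted
    uniformly at the configured per-kb densities inside promoters and
    elsewhere (plantings that would create or destroy another site are
    re-drawn). Returns the genome plus truth tables: 'genes' (the layout)
    and 'sites' (BED-like planted site positions per enzyme).
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = _gene_layout(config)
    promoters = _promoter_intervals(genes, config.promoter_bp)
    chrom_bp = config.genome_bp // config.n_chroms
    site_strings = {name: get_enzyme(name).recognition_site
                    for name in config.site_density}
    for name, s in site_strings.items():
        if len(s) != 4 or any(c not in "ACGT" for c in s):
            raise ValueError(f"site planting supports literal 4-base sites, got {s}")
    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")

    genome: dict[str, str] = {}
    site_rows = []
    all_sites = list(site_strings.values())
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = rng.choice(bases, size=chrom_bp, p=p)
        _scrub_sites(arr, all_sites, rng)
        prom = promoters[promoters["chrom"] == chrom]
        prom_mask = np.zeros(chrom_bp, dtype=bool)
        for r in prom.itertuples():
            prom_mask[max(r.start, 0): r.end] = True
        prom_bp = int(prom_mask.sum())
        occupied = np.zeros(chrom_bp, dtype=bool)
        patterns = [site_pattern(s) for s in all_sites]
        for name, (d_in, d_out) in config.site_density.items():
            site = site_strings[name]
            site_b = np.frombuffer(site.encode(), dtype="S1")
            n_in = rng.poisson(d_in * prom_bp / 1000)
            n_out = rng.poisson(d_out * (chrom_bp - prom_bp) / 1000)
            cand_in = np.flatnonzero(prom_mask[: chrom_bp - 4])
            cand_out = np.flatnonzero(~prom_mask[: chrom_bp - 4])
            for n_want, cand in ((n_in, cand_in), (n_out, cand_out)):
                if len(cand) == 0:
                    if n_want:
                        raise ValueError("no room to plant requested sites")
                    continue
                placed = 0
                attempts = 0
                while placed < n_want and attempts < 20 * n_want + 100:
                    attempts += 1
                    pos = int(cand[rng.integers(0, len(cand))])
                    if occupied[max(pos - 4, 0): pos + 8].any():
                        continue
                    window_old = arr[max(pos - 3, 0): pos + 7].copy()
                    arr[pos: pos + 4] = site_b
                    window = arr[max(pos - 3, 0): pos + 7].tobytes().decode()
                    n_hits = sum(1 for p in patterns for _ in p.finditer(window))
                    if n_hits != 1:
                        arr[max(pos - 3, 0): pos + 7] = window_old
                        continue
                    occupied[max(pos - 4, 0): pos + 8] = True
                    site_rows.append((chrom, pos, pos + 4, name))
                    placed += 1
                if placed < n_want:
                    raise ValueError(
                        f"could not plant {n_want} {name} sites on {chrom} "
                        "(density too high for the available space)")
        genome[chrom] = arr.tobytes().decode("ascii")

    sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "enzyme"])
    sites = sites.sort_values(["chrom", "start"]).reset_index(drop=True)
    return genome, {"genes": genes, "sites": sites}


def make_annotation(genome: dict[str, str], config: SimConfig,
                    gff3_path: str | Path | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models (with exons/UTRs) and TE intervals for the layout.

    Exon boundaries split each gene evenly with short introns; a TE of
    ``te_bp`` is placed just upstream of the promoter for the configured
    fraction of genes. Returns (genes, tes) and optionally writes GFF3.
    """
    rng = np.random.default_rng([config.seed, 3])
    genes = _gene_layout(config)
    te_rows = []
    for g in genes.itertuples():
        if rng.random() < config.te_fraction_near_genes:
            if g.strand == "+":
                s = g.start - config.promoter_bp - config.te_bp - 10
            else:
                s = g.end + config.promoter_bp + 10
            if s >= 0 and s + config.te_bp <= len(genome[g.chrom]):
                te_rows.append((g.chrom, s, s + config.te_bp))
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end"])
    if gff3_path is not None:
        write_gff3(genes, config, gff3_path, tes=tes)
    return genes, tes


def write_gff3(genes: pd.DataFrame, config: SimConfig, path: str | Path,
               tes: pd.DataFrame | None = None) -> None:
    """Emit the gene models as GFF3 (1-based inclusive): gene, mRNA,
    evenly split exons with introns implied, terminal UTR stubs."""
    n_exons = max(config.n_exons, 1)
    intron_bp = 60 if n_exons > 1 else 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            gid, chrom = g.gene_id, g.chrom
            fh.write(f"{chrom}\troirrbs_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            mid = f"{gid}.t1"
            fh.write(f"{chrom}\troirrbs_sim\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mid};Parent={gid}\n")
            length = g.end - g.start
            exon_bp = (length - intron_bp * (n_exons - 1)) // n_exons
            cursor = g.start
            exon_bounds = []
            for i in range(n_exons):
                e_end = g.end if i == n_exons - 1 else cursor + exon_bp
                exon_bounds.append((cursor, e_end))
                cursor = e_end + intron_bp
            for i, (s, e) in enumerate(exon_bounds, start=1):
                fh.write(f"{chrom}\troirrbs_sim\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mid}.exon{i};Parent={mid}\n")
            utr5 = (g.start, g.start + 30) if g.strand == "+" else (g.end - 30, g.end)
            utr3 = (g.end - 30, g.end) if g.strand == "+" else (g.start, g.start + 30)
            fh.write(f"{chrom}\troirrbs_sim\tfive_prime_UTR\t{utr5[0] + 1}\t{utr5[1]}"
                     f"\t.\t{g.strand}\t.\tID={mid}.utr5;Parent={mid}\n")
            fh.write(f"{chrom}\troirrbs_sim\tthree_prime_UTR\t{utr3[0] + 1}\t{utr3[1]}"
                     f"\t.\t{g.strand}\t.\tID={mid}.utr3;Parent={mid}\n")
        if tes is not None:
            for i, t in enumerate(tes.itertuples()):
                fh.write(f"{t.chrom}\troirrbs_sim\ttransposable_element\t"
                         f"{t.start + 1}\t{t.end}\t.\t+\t.\tID=te{i:05d}\n")


# ---------------------------------------------------------------------------
# methylomes

def _base_levels(context: np.ndarray, baselines: dict[str, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Per-site true methylation level around the context baselines;
    CG/CHG are hypo/hyper Beta mixtures, CHH a low-mean Beta."""
    level = np.zeros(len(context))
    for ctx in np.unique(context):
        sel = context == ctx
        n = int(sel.sum())
        mean = baselines.get(ctx, 0.02)
        if ctx in ("CG", "CHG"):
            hi_mean, lo_mean = 0.92, 0.04
            w = np.clip((mean - lo_mean) / (hi_mean - lo_mean), 0, 1)
            hyper = rng.random(n) < w
            draws = np.where(hyper,
                             rng.beta(23, 2, size=n),   # mean 0.92
                             rng.beta(1, 24, size=n))   # mean 0.04
        else:
            a = 0.5
            b = a * (1 - mean) / max(mean, 1e-6)
            draws = rng.beta(a, b, size=n)
        level[sel] = draws
    return level


@dataclass
class SimulatedMethylomes:
    """Two tissues plus the planted truth."""

    methylomes: dict[str, Methylome]
    fragments: FragmentSet            # retained (size-selected) fragments
    all_fragments: FragmentSet
    truth_dmrs: pd.DataFrame          # chrom, start, end, context, delta, hyper_tissue
    truth_islands: pd.DataFrame       # gene_id, bins, delta, tissue
    genes: pd.DataFrame
    config: SimConfig


def simulate_methylomes(genome: dict[str, str], genes: pd.DataFrame,
                        config: SimConfig) -> SimulatedMethylomes:
    """Draw two-tissue per-cytosine counts over the whole genome.

    Both tissues share every site's base level; planted DMR fragments
    shift one tissue by ``dmr_delta`` (direction randomised per
    fragment, base levels re-drawn mid-range so the shift survives
    clipping), planted island genes elevate the first tissue's CHH sites
    in 1-3 adjacent upstream bins by ``island_delta``. Observed counts
    are mc ~ Binomial(cov, level + (1-level) * non_conversion).
    """
    rng = np.random.default_rng([config.seed, 4])
    all_frags = digest_genome(genome, config.enzyme)
    retained = select_fragments(all_frags, SizeRange(*config.size_range))
    sites = assign_contexts(genome, contexts=config.contexts)
    ctx = sites["context"].to_numpy()
    level = _base_levels(ctx, config.baselines, rng)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    t1, t2 = config.tissues
    shift = {t1: np.zeros(len(sites)), t2: np.zeros(len(sites))}

    # --- planted DMRs on retained fragments
    truth_dmr_rows = []
    if config.dmr_fraction > 0:
        fdf = retained.df
        is_ctx = ctx == config.dmr_context
        ctx_idx_by_chrom = {}  # chrom -> global indices of dmr-context sites
        for chrom in fdf["chrom"].unique():
            ctx_idx_by_chrom[chrom] = np.flatnonzero((chrom_arr == chrom) & is_ctx)
        eligible = []  # (frag row, slice of global site indices)
        for i, fr in enumerate(fdf.itertuples()):
            idx = ctx_idx_by_chrom.get(fr.chrom)
            if idx is None or len(idx) == 0:
                continue
            i0, i1 = np.searchsorted(pos_arr[idx], [fr.start, fr.end])
            if i1 - i0 >= 3:
                eligible.append((i, idx[i0:i1]))
        n_plant = int(round(config.dmr_fraction * len(fdf)))
        n_plant = min(n_plant, len(eligible))
        chosen = rng.choice(len(eligible), size=n_plant, replace=False)
        for j in chosen:
            i, site_idx = eligible[j]
            fr = fdf.iloc[i]
            level[site_idx] = rng.uniform(0.15, 0.55, size=len(site_idx))
            hyper = t1 if rng.random() < 0.5 else t2
            shift[hyper][site_idx] += config.dmr_delta
            truth_dmr_rows.append((fr["chrom"], int(fr["start"]), int(fr["end"]),
                                   config.dmr_context, config.dmr_delta, hyper))
    truth_dmrs = pd.DataFrame(
        truth_dmr_rows,
        columns=["chrom", "start", "end", "context", "delta", "hyper_tissue"])

    # --- planted mCHH islands (elevated in the first tissue)
    truth_island_rows = []
    if config.island_genes > 0:
        if "CHH" not in config.contexts:
            raise ValueError("island planting needs the CHH context simulated")
        chh_idx_by_chrom = {
            chrom: np.flatnonzero((chrom_arr == chrom) & (ctx == "CHH"))
            for chrom in genes["chrom"].unique()}
        idx = rng.choice(len(genes), size=min(config.island_genes, len(genes)),
                         replace=False)
        for gi in idx:
            g = genes.iloc[gi]
            first = int(rng.integers(1, 18))
            width = int(rng.integers(1, 4))
            bins = list(range(first, min(first + width, 20)))
            if g["strand"] == "+":
                lo = g["tss"] - (bins[-1] + 1) * 100
                hi = g["tss"] - bins[0] * 100
            else:
                lo = g["tss"] + 1 + bins[0] * 100
                hi = g["tss"] + 1 + (bins[-1] + 1) * 100
            if lo < 0:
                raise ValueError("planted island outside genome")
            cidx = chh_idx_by_chrom[g["chrom"]]
            i0, i1 = np.searchsorted(pos_arr[cidx], [lo, hi])
            site_idx = cidx[i0:i1]
            level[site_idx] = np.minimum(level[site_idx], 1 - config.island_delta)
            shift[t1][site_idx] += config.island_delta
            truth_island_rows.append((g["gene_id"], bins[0], bins[-1],
                                      config.island_delta, t1))
    truth_islands = pd.DataFrame(
        truth_island_rows,
        columns=["gene_id", "first_bin", "last_bin", "delta", "tissue"])

    # --- observed counts per tissue
    methylomes = {}
    cov_lo, cov_hi = config.coverage
    for t in config.tissues:
        true_level = np.clip(level + shift[t], 0, 1)
        obs_p = true_level + (1 - true_level) * config.non_conversion
        cov = rng.integers(cov_lo, cov_hi + 1, size=len(sites))
        mc = rng.binomial(cov, obs_p)
        df = sites[["chrom", "pos", "strand", "context", "dinuc"]].copy()
        df["mc"] = mc
        df["cov"] = cov
        methylomes[t] = Methylome(df, name=t, tissue=t, enzyme=config.enzyme)

    return SimulatedMethylomes(
        methylomes=methylomes, fragments=retained, all_fragments=all_frags,
        truth_dmrs=truth_dmrs, truth_islands=truth_islands, genes=genes,
        config=config)


def simulate_control(n_sites: int = 2000, coverage: int = 20,
                     non_conversion: float = 0.005, seed: int = 0) -> Methylome:
    """An unmethylated spike-in control (lambda-phage-like): every read of
    a truly unmethylated C reports methylated with probability
    ``non_conversion``."""
    rng = np.random.default_rng(seed)
    cov = np.full(n_sites, coverage)
    mc = rng.binomial(cov, non_conversion)
    df = pd.DataFrame({
        "chrom": "lambda", "pos": np.arange(n_sites) * 3, "strand": "+",
        "context": "CHH", "dinuc": "CA", "mc": mc, "cov": cov,
    })
    return Methylome(df, name="lambda_control")


def make_qc_reads(genome: dict[str, str], enzyme: str, n_reads: int,
                  read_bp: int = 50, random_start_fraction: float = 0.0,
                  seed: int = 0, fastq_path: str | Path | None = None) -> list[str]:
    """Reads beginning at enzyme cut sites (residual site at position 0),
    a configurable fraction starting at random positions instead — the
    fixture for read-start QC."""
    rng = np.random.default_rng(seed)
    enz = get_enzyme(enzyme)
    cuts = []
    for chrom, seq in genome.items():
        cuts += [(chrom, c) for c in enz.cut_positions(seq)]
    if not cuts:
        raise ValueError("genome contains no cut sites")
    reads = []
    for i in range(n_reads):
        if rng.random() < random_start_fraction:
            chrom = list(genome)[int(rng.integers(0, len(genome)))]
            start = int(rng.integers(0, max(len(genome[chrom]) - read_bp, 1)))
        else:
            chrom, start = cuts[int(rng.integers(0, len(cuts)))]
        reads.append(genome[chrom][start: start + read_bp])
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")
    return reads


def write_outputs(sim: SimulatedMethylomes, genome: dict[str, str],
                  outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, two CGmaps, fragment BED and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    paths["gff3"] = outdir / "annotation.gff3"
    _, tes = make_annotation(genome, sim.config, gff3_path=paths["gff3"])
    for t, m in sim.methylomes.items():
        paths[f"cgmap_{t}"] = outdir / f"{t}.cgmap"
        write_cgmap(m, paths[f"cgmap_{t}"])
    paths["fragments"] = outdir / "fragments.bed"
    sim.fragments.to_bed(paths["fragments"], lengths=True)
    paths["truth_dmrs"] = outdir / "truth_dmrs.tsv"
    sim.truth_dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    paths["truth_islands"] = outdir / "truth_islands.tsv"
    sim.truth_islands.to_csv(paths["truth_islands"], sep="\t", index=False)
    return paths
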