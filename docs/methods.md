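# Methods

This note documents the models and procedures implemented in `roirrbs`,
the defaults they ship with, and the choices made where the underlying
methodology leaves room.

## The problem

Whole-genome bisulfite sequencing of a multi-gigabase plant genome is
expensive; reduced representation bisulfite sequencing (RRBS) sequences
only the size-selected fragments of a restriction digest. In genomes
without CpG islands — maize being the motivating case — the mammalian
default enzyme (MspI, C^CGG) does not enrich promoters, so the enzyme
and size window must be chosen per genome and per region of interest
(ROI). `roirrbs` covers that design step in silico and the downstream
statistics that the resulting two-tissue methylomes support: bulk
levels, metagene profiles, fragment-level differentially methylated
regions (DMRs), and tissue-specific mCHH islands.

## In silico digestion (`digest`)

A restriction enzyme is its IUPAC recognition site plus the top-strand
cut offset (MseI = T^TAA, CviQI = G^TAC, MspI = C^CGG). Digestion scans
the forward strand at every position, so overlapping site occurrences
(TTAATTAA) all cut, as they do physically. Only palindromic-site
enzymes are accepted: for those the forward scan reproduces
double-strand cutting, and the package refuses non-palindromic sites
rather than silently missing bottom-strand cuts. IUPAC `N` in the
genome matches no site letter, so assembly gaps never produce phantom
cuts. Chromosome ends count as cut sites; a digest therefore tiles each
chromosome exactly (the suite asserts this, together with equality to an
exhaustive per-position oracle scan).

Coordinates are 0-based half-open everywhere internally; BED output
matches; GFF3 input is converted from 1-based inclusive on load. The
filled-in overhang bases belong to the downstream fragment, consistent
with MseI-RRBS reads beginning with the residual `TAA`. Size selection
is inclusive on both ends (a "40–300 bp" window keeps 40 and 300), and
models the naked fragment length, not the ligated insert. The
RR-genome fraction uses the full assembled length (N bases included) as
its denominator.

Read-start QC counts reads whose first bases literally match the
enzyme's residual site or its bisulfite-converted variant (C→T), giving
TAA for MseI and TAC/TAT for CviQI.

Sequencing cost is projected as retained bp × target depth × price per
sequenced Gb — linear in the RR fraction by construction.

## Feature catalogs and enrichment (`features`)

Gene models come from GFF3 via `gffutils`; introns are the
within-transcript gaps between exons, the gene body is the TSS–TES
span, and a gene with several transcripts gets one TSS (the 5′-most
transcript start on its strand) and hence one promoter. Promoters
default to 1000 bp immediately upstream of the TSS, strand-aware and
clipped at chromosome bounds. Splice sites are ±20 bp windows around
exon–intron boundaries; the flank size is not standardised in the
field, so it is exposed as a parameter with that documented default.

Fold enrichment of a class is
`(class bp ∩ RR bp / RR bp) / (class bp / genome bp)` on merged
intervals. Classes are deliberately not made mutually exclusive — a
base can be both promoter and TE — and each fold is computed
independently. Folds with an empty numerator or denominator are
reported as missing (NaN), never as 0. No significance test is attached
to folds; they are descriptive, and ranking candidate (enzyme, size
window) pairs sorts by target-ROI fold with ties broken toward the
smaller RR fraction (less sequencing for the same enrichment).

## Methylome representation (`methylome`)

A cytosine's methylation level is #C/(#C+#T) over its aligned reads, an
estimate of the fraction of cells methylated there. Contexts are CG,
CHG, CHH (H ∈ {A,T,C}), assigned from the genome on both strands;
cytosines whose two downstream bases are truncated or touch an N have
undefined context and are excluded. A CG dinucleotide contributes two
records, one per strand (collapsing is available but off by default).

CGmap (the per-cytosine table of bisulfite aligners) is the interchange
format; on load, levels are recomputed from the counts rather than
trusted from the file. The default coverage filter keeps sites with at
least 4 reads. Bulk levels are unweighted means over site levels — a
deliberate choice over read-weighted means, so deep sites do not
dominate. The bisulfite conversion rate is ΣT/Σ(C+T) over an
unmethylated spike-in (lambda phage in practice).

Metagene profiles use 100-bp fixed flank bins over 2 kb on either side
and 100 proportional gene-body bins by default (bin counts are
configurable; the flank extent is the common convention, the bin counts
are package defaults). Genes shorter than the body bin count are
skipped rather than padded, and empty bins are NaN, never 0 — 0 is a
valid methylation level.

Methylome overlap defaults to the Jaccard index over site keys; since
the natural denominator is debatable, `denominator="a"|"b"` variants
are exposed.

## Fragment-level DMR calling (`dmr`)

The testing unit is the retained restriction fragment. At each context
cytosine with data in every sample, a two-sample t statistic compares
the groups; a fragment's z score is the mean of its member sites' t
scores. A fragment is a DMR when it simultaneously (1) differs by ≥10%
in mean methylation level between groups, (2) has ≥3 member cytosines,
and (3) has |z| at or above the calibrated threshold.

Two observation models are supported, because the typical design — one
library per tissue — has no between-replicate variance to feed a t
test:

- **read-level mode** (default for 1-vs-1): the observations at a site
  are the per-read 0/1 methylation calls, so a sample with k methylated
  of n reads is a binary vector with mean k/n and sample variance
  n·p(1−p)/(n−1); the Welch t then has a closed form in the counts and
  behaves like a two-proportion test.
- **replicate mode** (default for ≥2 samples per group): observations
  are per-sample site levels; Welch by default, pooled-variance
  available.

The calling rule is two-sided on |z| with the direction taken from the
sign, since differential methylation is reported in both directions.
Zero-variance sites give t = 0 at equal means; with unequal means the
infinite t is capped at the largest finite |t| in the comparison and
flagged — this keeps fragment z scores finite without discarding
exactly the most extreme sites.

**FDR calibration.** Simulated null methylomes share the real data's
coverage and methylation landscape but carry no group difference: per
site, Pm is the pooled (read-weighted) level across all real samples,
and each simulated sample redraws its methylated count as
Binomial(n, Pm) at its own real coverage n. Every DMR found in the
simulation is a false positive by construction, so
FDR(τ) = n_sim(τ)/n_real(τ), and the operating threshold is the loosest
τ with FDR below the target (default 10%). When the comparison is
itself null, n_sim ≈ n_real at every τ and no threshold qualifies; the
calibration reports that honestly instead of picking one. The simulated
null is the only multiple-testing control — no BH correction is
stacked on top. The procedure is run per context (CG, CHG, CHH)
separately.

Genes are associated with DMRs by promoter/gene-body overlap, yielding
compartment labels `promoter`, `gene_body` or `both`.

## mCHH islands (`islands`)

The 2-kb region upstream of each TSS is dissected into 100-bp bins
(bin 0 TSS-proximal, strand-aware). Per tissue, a bin's level is the
mean of its covered CHH sites; bins with fewer than 2 covered sites
(configurable) are missing, and missing bins are excluded from Δ
calling, never imputed. A tissue-specific island is a run of adjacent
bins with Δ ≥ 25% (inclusive) in one direction; a gene with qualifying
bins in both directions carries islands "in both tissues". Static
islands use the same machinery with a single-tissue level cutoff of
25%, and a genome-wide 100-bp-tile variant is also provided.

Island extents are trimmed to the outermost covered CHH sites inside
the qualifying bins rather than the full bin span: the bins locate the
island, the sites delimit it, which is why island sizes can be a single
base pair while bins are 100 bp. Distance to the TSS is measured from
the TSS-proximal island edge along the gene's 5′ direction. The 5′
regulatory region exported for motif analysis runs from that edge to
the TSS, oriented 5′→3′ along the gene (reverse-complemented for minus
strand genes); islands abutting the TSS yield no sequence and are
skipped.

## The synthetic-data generator (`simulate`)

The generator exists so every stage is testable without external
downloads, and its defaults are the study conditions of the test suite
and acceptance script:

- **Genome**: i.i.d. sequence at GC 0.46, scrubbed of all configured
  enzyme sites, then sites planted uniformly at per-kb densities inside
  promoters vs elsewhere (default 6/kb uniform; the `enzyme-rank`
  preset plants TTAA at 5× background density in promoters). Plantings
  that would create or destroy another site occurrence are re-drawn, so
  the planted-site truth table and a digestion agree exactly.
- **Annotation**: non-overlapping genes (600 bp, 2 exons, mixed
  strands) in private slots wide enough that no gene's 2-kb upstream
  window reaches a neighbour's, with a TE placed just upstream of the
  promoter for 85% of genes.
- **Methylomes**: per-site true levels shared between tissues — CG/CHG
  from a hypo/hyper Beta mixture whose weights hit the configured means
  (defaults CG 0.8, CHG 0.6, magnitudes typical of maize), CHH from a
  low-mean Beta (default 0.02). Observed counts are
  mc ~ Binomial(cov, level + (1−level)·0.005), i.e. the same binomial
  read model the null-FDR machinery assumes plus a 0.5% per-read
  non-conversion error (matching >99% conversion controls). Coverage is
  uniform on a configured range (null preset 4–40×, DMR bench 10–30×,
  island bench fixed 20×).
- **Planted signal**: DMR fragments (10% of retained fragments in the
  bench) re-draw their sites' base levels mid-range (0.15–0.55) and
  shift one tissue by Δ = 0.3 so the shift survives clipping, with
  random direction; island genes (100 of 1000) elevate the first
  tissue's CHH level by Δ = 0.4 in 1–3 adjacent upstream bins. Truth
  tables record every planted effect.

What the generator does *not* emulate: spatial autocorrelation of
methylation beyond the planted regions, mapping bias and coverage
heterogeneity along fragments, partial digestion, methylation-sensitive
cutting, and sequence-composition effects on conversion. Passing the
benches therefore demonstrates that the statistics behave as designed
under their own model assumptions — error control under the binomial
null and recovery of planted effects — not that those assumptions hold
for any particular real library.

## Problem sizes and numerical choices

The null and DMR benches use 600-kb two-chromosome genomes (~2,500
retained fragments, ~60k CG sites); the island bench uses a 5-Mb
four-chromosome genome with 1,000 genes. These sizes make every bench
statistically meaningful while keeping the whole suite and the
acceptance script fast. The z-threshold grid is 0.2–5.0 in steps of
0.2. All randomness flows through `numpy.random.default_rng` seeded
from a single user seed; identical seeds give byte-identical outputs
(asserted in the suite). Ties and degenerate cases — zero-variance
sites, empty bins, empty classes, zero-coverage sites — are handled as
described above, always preferring an explicit missing value or a
capped flag over a silent 0.

## Known limitations

- Enrichment folds carry no significance test.
- The read-level t test treats reads as independent Bernoulli draws;
  clonal (PCR-duplicate) reads violate that.
- Static genome-wide tile islands are thresholded per tile without
  smoothing across tile boundaries.
- The external-genome workflow (a multi-Gb assembly through `pyfaidx`)
  is supported but not exercised by the test suite, which is entirely
  synthetic.
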