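"""Fragment-level differential methylation with simulated-null FDR.

The testing unit is the RRBS restriction fragment. At every cytosine of
the chosen context with data in all samples, a two-sample t statistic is
computed between the groups; the t scores of a fragment's member sites
are averaged into the fragment's z score. A fragment is called a DMR
when it (1) differs by >= ``min_delta`` (default 10%) in mean
methylation level, (2) has >= ``min_sites`` (default 3) member
cytosines, and (3) has |z| at or above a threshold.

The threshold is calibrated against simulated null methylomes: per site,
the pooled level Pm across all real samples drives a Binomial(n, Pm)
redraw of methylated-read counts at the real per-sample coverage n, so
the simulated samples keep the real methylation landscape and power but
carry no group difference. DMRs found in the simulation are false
positives by construction; FDR(threshold) = n_sim / n_real, and the
chosen threshold is the loosest one with FDR below the target (default
10%). No additional multiple-testing correction is applied.

With one library per group (the common RRBS design) there is no
between-replicate variance, so the default observation unit is the
individual read: each site contributes 0/1 methylation calls of length =
coverage per group, and the t test becomes a two-proportion-style test
with a closed form in the counts. With >= 2 samples per group,
``mode='replicate'`` tests per-sample site levels instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .digest import FragmentSet
from .methylome import Methylome

_KEY = ["chrom", "pos", "strand"]


# ---------------------------------------------------------------------------
# site-level t statistics

def welch_t_from_counts(mc_a, cov_a, mc_b, cov_b):
    """Vectorised Welch t on read-level 0/1 observations given counts.

    A sample with k methylated of n reads is the binary vector with mean
    p = k/n and sample variance n p (1-p) / (n-1). Requires n >= 2 on
    both sides. Zero pooled variance gives t = 0 at equal means and
    +-inf otherwise (capped later at the comparison level).
    """
    mc_a = np.asarray(mc_a, dtype=float)
    cov_a = np.asarray(cov_a, dtype=float)
    mc_b = np.asarray(mc_b, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if np.any(cov_a < 2) or np.any(cov_b < 2):
        raise ValueError("read-level t requires coverage >= 2 in both groups")
    pa, pb = mc_a / cov_a, mc_b / cov_b
    var_a = cov_a * pa * (1 - pa) / (cov_a - 1)
    var_b = cov_b * pb * (1 - pb) / (cov_b - 1)
    se2 = var_a / cov_a + var_b / cov_b
    diff = pa - pb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        t = np.where(se2 == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t


def site_t_test(obs_a: Sequence[float], obs_b: Sequence[float],
                equal_var: bool = False) -> float:
    """Two-sample t statistic between the observation vectors at one site
    (replicate levels, or read-level 0/1 calls). Sign follows
    mean(A) - mean(B); degenerate zero-variance cases give 0 at equal
    means and +-inf otherwise.
    """
    a = np.asarray(obs_a, dtype=float)
    b = np.asarray(obs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    diff = a.mean() - b.mean()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(stats.ttest_ind(a, b, equal_var=equal_var).statistic)


def _cap_infinite(t: np.ndarray) -> np.ndarray:
    """Replace +-inf t scores by the largest finite |t| observed in the
    comparison (keeps fragment z scores finite without dropping the most
    extreme sites)."""
    inf = ~np.isfinite(t)
    if not inf.any():
        return t
    finite = np.abs(t[~inf])
    cap = finite.max() if len(finite) else 1.0
    out = t.copy()
    out[inf] = np.sign(out[inf]) * cap
    return out


# ---------------------------------------------------------------------------
# fragment scores and DMR calls

def _aligned_counts(methylomes: Sequence[Methylome], context: str) -> pd.DataFrame:
    """Inner-join per-sample counts on the site key, one (mc_i, cov_i)
    column pair per sample; only context sites with data in every sample
    survive."""
    if not methylomes:
        raise ValueError("need at least one methylome")
    joined = None
    for i, m in enumerate(methylomes):
        df = m.subset_context(context).df[_KEY + ["mc", "cov"]]
        df = df.rename(columns={"mc": f"mc_{i}", "cov": f"cov_{i}"})
        joined = df if joined is None else joined.merge(df, on=_KEY, how="inner")
    return joined


def fragment_scores(methylomes_a: Sequence[Methylome],
                    methylomes_b: Sequence[Methylome],
                    fragments: FragmentSet, context: str,
                    mode: str = "auto",
                    equal_var: bool = False) -> pd.DataFrame:
    """Per-fragment statistics feeding the DMR criteria.

    Returns one row per fragment containing >= 1 usable site: chrom,
    start, end, n_sites, mean_a, mean_b, delta (= mean_a - mean_b) and z
    (mean of member-site t scores).
    """
    if mode == "auto":
        mode = "replicate" if min(len(methylomes_a), len(methylomes_b)) >= 2 \
            else "read"
    if mode not in ("read", "replicate"):
        raise ValueError(f"unknown mode {mode!r}")

    na, nb = len(methylomes_a), len(methylomes_b)
    joined = _aligned_counts(list(methylomes_a) + list(methylomes_b), context)
    if joined is None or len(joined) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "mean_a", "mean_b", "delta", "z"])
    mc = joined[[f"mc_{i}" for i in range(na + nb)]].to_numpy(dtype=float)
    cov = joined[[f"cov_{i}" for i in range(na + nb)]].to_numpy(dtype=float)
    lev = mc / cov
    mean_a = lev[:, :na].mean(axis=1)
    mean_b = lev[:, na:].mean(axis=1)

    if mode == "read":
        # pool reads within each group; observations are 0/1 calls
        t = welch_t_from_counts(mc[:, :na].sum(axis=1), cov[:, :na].sum(axis=1),
                                mc[:, na:].sum(axis=1), cov[:, na:].sum(axis=1))
    else:
        if na < 2 or nb < 2:
            raise ValueError("replicate mode needs >= 2 samples per group")
        a, b = lev[:, :na], lev[:, na:]
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1 / na + 1 / nb)
        else:
            se2 = va / na + vb / nb
        diff = mean_a - mean_b
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(se2)
            t = np.where(se2 == 0, np.where(diff == 0, 0.0,
                                            np.sign(diff) * np.inf), t)
    t = _cap_infinite(np.asarray(t, dtype=float))

    # assign sites to fragments (fragments sorted; sites outside dropped)
    frag = fragments.df
    frag_idx = np.full(len(joined), -1, dtype=np.int64)
    chrom_groups = {c: s for c, s in frag.groupby("chrom")}
    order = joined.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    joined_sorted = joined.loc[order]
    t_sorted = t[order]
    mean_a_s, mean_b_s = mean_a[order], mean_b[order]
    for chrom, sub in joined_sorted.groupby("chrom", sort=False):
        fsub = chrom_groups.get(chrom)
        if fsub is None:
            continue
        starts = fsub["start"].to_numpy()
        ends = fsub["end"].to_numpy()
        rowpos = fsub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        sel = np.flatnonzero(joined_sorted["chrom"].to_numpy() == chrom)
        frag_idx[sel[ok]] = rowpos[k[ok]]

    used = frag_idx >= 0
    agg = pd.DataFrame({
        "frag": frag_idx[used],
        "t": t_sorted[used],
        "mean_a": mean_a_s[used],
        "mean_b": mean_b_s[used],
    })
    grouped = agg.groupby("frag").agg(
        n_sites=("t", "size"), z=("t", "mean"),
        mean_a=("mean_a", "mean"), mean_b=("mean_b", "mean"))
    out = frag.loc[grouped.index, ["chrom", "start", "end"]].copy()
    out[["n_sites", "z", "mean_a", "mean_b"]] = grouped[
        ["n_sites", "z", "mean_a", "mean_b"]].to_numpy()
    out["n_sites"] = out["n_sites"].astype(int)
    out["delta"] = out["mean_a"] - out["mean_b"]
    out["context"] = context
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def call_dmrs(methylomes_a: Sequence[Methylome], methylomes_b: Sequence[Methylome],
              fragments: FragmentSet, context: str, z_threshold: float,
              min_delta: float = 0.10, min_sites: int = 3,
              mode: str = "auto", scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fragments passing all three DMR criteria (see module docstring).

    ``scores`` short-circuits recomputation when :func:`fragment_scores`
    output is already at hand (as during calibration). The returned
    frame adds ``direction`` ('hyper_in_a' / 'hyper_in_b').
    """
    if scores is None:
        scores = fragment_scores(methylomes_a, methylomes_b, fragments, context,
                                 mode=mode)
    if len(scores) == 0 or (scores["n_sites"] >= min_sites).sum() == 0:
        warnings.warn("no fragment has enough informative sites; no DMRs callable")
    calls = apply_criteria(scores, z_threshold, min_delta, min_sites)
    return calls


def apply_criteria(scores: pd.DataFrame, z_threshold: float,
                   min_delta: float = 0.10, min_sites: int = 3) -> pd.DataFrame:
    keep = ((scores["n_sites"] >= min_sites)
            & (scores["delta"].abs() >= min_delta)
            & (scores["z"].abs() >= z_threshold))
    out = scores[keep].copy()
    out["direction"] = np.where(out["delta"] > 0, "hyper_in_a", "hyper_in_b")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# simulated-null FDR calibration

def simulate_null_methylome(methylomes: Sequence[Methylome],
                            seed: int | np.random.Generator) -> list[Methylome]:
    """One simulated methylome per real sample under the pooled null.

    At each site shared by all samples, Pm = pooled methylated reads /
    pooled coverage across every real sample; each simulated sample keeps
    its real coverage n and redraws mc ~ Binomial(n, Pm).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    joined = None
    metas = []
    for i, m in enumerate(methylomes):
        df = m.df[_KEY + ["context", "dinuc", "mc", "cov"]].rename(
            columns={"mc": f"mc_{i}", "cov": f"cov_{i}",
                     "context": f"ctx_{i}", "dinuc": f"din_{i}"})
        joined = df if joined is None else joined.merge(
            df, on=_KEY, how="inner", suffixes=(None, None))
        metas.append(m)
    k = len(metas)
    mc = joined[[f"mc_{i}" for i in range(k)]].to_numpy(dtype=np.int64)
    cov = joined[[f"cov_{i}" for i in range(k)]].to_numpy(dtype=np.int64)
    pooled_cov = cov.sum(axis=1)
    pm = np.where(pooled_cov > 0, mc.sum(axis=1) / np.maximum(pooled_cov, 1), 0.0)
    out = []
    for i, m in enumerate(metas):
        sim_mc = rng.binomial(cov[:, i], pm)
        df = pd.DataFrame({
            "chrom": joined["chrom"], "pos": joined["pos"],
            "strand": joined["strand"],
            "context": joined["ctx_0"], "dinuc": joined["din_0"],
            "mc": sim_mc, "cov": cov[:, i],
        })
        out.append(Methylome(df, name=f"sim_{m.name}", tissue=m.tissue,
                             min_coverage=m.min_coverage))
    return out


@dataclass(frozen=True)
class NullCalibration:
    """FDR per z threshold and the chosen operating point."""

    table: pd.DataFrame  # threshold, n_real, n_sim, fdr
    chosen_threshold: float | None
    target_fdr: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def calibrate_fdr(methylomes_a: Sequence[Methylome],
                  methylomes_b: Sequence[Methylome],
                  fragments: FragmentSet, context: str,
                  thresholds: Sequence[float],
                  target_fdr: float = 0.10,
                  min_delta: float = 0.10, min_sites: int = 3,
                  mode: str = "auto", seed: int = 0) -> NullCalibration:
    """Sweep z thresholds on real vs simulated-null data.

    FDR(threshold) = DMRs in simulation / DMRs in real data (NaN when no
    real DMR). The chosen threshold is the loosest (smallest) one with
    FDR < ``target_fdr``; None when no threshold qualifies.
    """
    thresholds = sorted(thresholds)
    if not thresholds:
        raise ValueError("empty threshold grid")
    rng = np.random.default_rng(seed)
    real = fragment_scores(methylomes_a, methylomes_b, fragments, context, mode=mode)
    sims = simulate_null_methylome(list(methylomes_a) + list(methylomes_b), rng)
    sim_a, sim_b = sims[:len(methylomes_a)], sims[len(methylomes_a):]
    sim = fragment_scores(sim_a, sim_b, fragments, context, mode=mode)
    rows = []
    for thr in thresholds:
        n_real = len(apply_criteria(real, thr, min_delta, min_sites))
        n_sim = len(apply_criteria(sim, thr, min_delta, min_sites))
        fdr = n_sim / n_real if n_real > 0 else np.nan
        rows.append((thr, n_real, n_sim, fdr))
    table = pd.DataFrame(rows, columns=["threshold", "n_real", "n_sim", "fdr"])
    ok = table[table["fdr"] < target_fdr]
    chosen = float(ok["threshold"].iloc[0]) if len(ok) else None
    if chosen is None:
        warnings.warn(f"no z threshold reaches FDR < {target_fdr}; "
                      "no operating point chosen")
    return NullCalibration(table=table, chosen_threshold=chosen,
                           target_fdr=target_fdr)


# ---------------------------------------------------------------------------
# gene association

def associate_genes(dmrs: pd.DataFrame, catalog, upstream_bp: int = 1000,
                    chrom_sizes=None) -> pd.DataFrame:
    """Label genes whose promoter and/or gene body overlaps a DMR.

    Returns one row per differentially methylated gene: gene_id,
    compartment ('promoter', 'gene_body' or 'both') and DMR counts per
    compartment. A gene may aggregate several DMRs.
    """
    from .features import derive_promoters

    promoters = derive_promoters(catalog, upstream_bp=upstream_bp,
                                 chrom_sizes=chrom_sizes, store=False)
    bodies = catalog.genes[["gene_id", "chrom", "start", "end"]]

    def _hits(regions: pd.DataFrame) -> dict[str, int]:
        counts: dict[str, int] = {}
        if len(dmrs) == 0:
            return counts
        by_chrom = {c: s for c, s in regions.groupby("chrom")}
        for d in dmrs.itertuples():
            sub = by_chrom.get(d.chrom)
            if sub is None:
                continue
            hit = (sub["start"] < d.end) & (sub["end"] > d.start)
            for gid in sub.loc[hit, "gene_id"]:
                counts[gid] = counts.get(gid, 0) + 1
        return counts

    prom_hits = _hits(promoters)
    body_hits = _hits(bodies)
    rows = []
    for gid in sorted(set(prom_hits) | set(body_hits)):
        p, b = prom_hits.get(gid, 0), body_hits.get(gid, 0)
        compartment = "both" if p and b else ("promoter" if p else "gene_body")
        rows.append((gid, compartment, p, b))
    return pd.DataFrame(rows, columns=["gene_id", "compartment",
                                       "n_promoter_dmrs", "n_gene_body_dmrs"])
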