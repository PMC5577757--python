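"""Sorted-interval arithmetic on (chrom, start, end) DataFrames.

All intervals are 0-based half-open. These are the only interval
primitives the package needs: merge, total length, pairwise overlap bp,
and point-in-set membership via searchsorted on merged sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLUMNS = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalise an interval frame (extra columns preserved)."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["end"] < out["start"]).any():
        raise ValueError("interval with end < start")
    return out


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=object),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, non-overlapping (touching runs joined)."""
    if len(df) == 0:
        return empty_intervals()
    df = as_intervals(df[COLUMNS])
    pieces = []
    for chrom, sub in df.groupby("chrom", sort=True):
        arr = sub[["start", "end"]].to_numpy()
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        starts, ends = [], []
        cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
        for s, e in arr[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        starts.append(cur_s)
        ends.append(cur_e)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    out = pd.concat(pieces, ignore_index=True)
    return out[out["end"] > out["start"]].reset_index(drop=True)


def total_bp(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def overlap_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Base pairs in the intersection of two interval sets (each merged
    internally first, so duplicated bases are not double-counted)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return 0
    total = 0
    bg = {c: sub[["start", "end"]].to_numpy() for c, sub in b.groupby("chrom")}
    for chrom, sub in a.groupby("chrom"):
        if chrom not in bg:
            continue
        xa = sub[["start", "end"]].to_numpy()
        xb = bg[chrom]
        i = j = 0
        while i < len(xa) and j < len(xb):
            lo = max(xa[i, 0], xb[j, 0])
            hi = min(xa[i, 1], xb[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if xa[i, 1] <= xb[j, 1]:
                i += 1
            else:
                j += 1
    return total


def points_in_intervals(chroms: np.ndarray, positions: np.ndarray,
                        merged: pd.DataFrame) -> np.ndarray:
    """Boolean mask: which (chrom, position) points fall inside a merged
    interval set."""
    mask = np.zeros(len(positions), dtype=bool)
    if len(merged) == 0 or len(positions) == 0:
        return mask
    idx = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
           for c, sub in merged.groupby("chrom")}
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    for chrom, (starts, ends) in idx.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        pos = positions[sel]
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        mask[sel] = ok
    return mask
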