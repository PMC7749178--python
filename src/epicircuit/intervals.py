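"""Base-pair interval arithmetic on BED-like tables.

All interval sets are pandas DataFrames with at least ``chrom`` (str),
``start`` and ``end`` (int) columns, 0-based half-open. These primitives —
merge, intersection, per-base coverage counting, base-pair Jaccard — are the
building blocks of the consensus-region and enrichment machinery and are kept
dependency-free (plain numpy) so that every test can check them against a
per-base bitset oracle.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an interval table (copy, int coords, sorted)."""
    missing = [c for c in BED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"interval table lacks columns {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        bad = out[out["start"] >= out["end"]].iloc[0]
        raise ValueError(
            f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    return out.sort_values(BED_COLS, kind="mergesort").reset_index(drop=True)


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted, possibly overlapping intervals on one chromosome."""
    if len(starts) == 0:
        return starts, ends
    # book-ended intervals ([0,10) + [10,20)) merge too
    keep = np.ones(len(starts), dtype=bool)
    run_end = ends[0]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= run_end:
            run_end = max(run_end, e)
            out_e[-1] = run_end
        else:
            out_s.append(s)
            out_e.append(e)
            run_end = e
    del keep
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping/book-ended intervals per chromosome."""
    df = as_intervals(df)
    pieces = []
    for chrom, grp in df.groupby("chrom", sort=True):
        s, e = _merge_arrays(grp["start"].to_numpy(), grp["end"].to_numpy())
        pieces.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not pieces:
        return pd.DataFrame(columns=BED_COLS)
    return pd.concat(pieces, ignore_index=True)


def total_bp(df: pd.DataFrame) -> int:
    """Total covered base pairs of a (merged) interval set."""
    if len(df) == 0:
        return 0
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merged intersection of two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    pieces = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a.loc[a["chrom"] == chrom]
        sb = b.loc[b["chrom"] == chrom]
        s1, e1 = sa["start"].to_numpy(), sa["end"].to_numpy()
        s2, e2 = sb["start"].to_numpy(), sb["end"].to_numpy()
        i = j = 0
        out_s, out_e = [], []
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if lo < hi:
                out_s.append(lo)
                out_e.append(hi)
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
        if out_s:
            pieces.append(pd.DataFrame({"chrom": chrom, "start": out_s, "end": out_e}))
    if not pieces:
        return pd.DataFrame(columns=BED_COLS)
    return pd.concat(pieces, ignore_index=True)


def coverage_runs(intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-base support of a stack of intervals, as maximal constant runs.

    Returns columns chrom, start, end, count where ``count`` is the number of
    input intervals covering every base of the run (genomecov-style). Runs with
    zero count are omitted.
    """
    intervals = as_intervals(intervals)
    pieces = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        pos = np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()])
        delta = np.concatenate(
            [np.ones(len(grp), dtype=np.int64), -np.ones(len(grp), dtype=np.int64)]
        )
        order = np.argsort(pos, kind="mergesort")
        pos, delta = pos[order], delta[order]
        # collapse identical breakpoints
        uniq, idx = np.unique(pos, return_index=True)
        sums = np.add.reduceat(delta, idx)
        counts = np.cumsum(sums)[:-1]
        starts, ends = uniq[:-1], uniq[1:]
        keep = counts > 0
        pieces.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts[keep], "end": ends[keep],
                 "count": counts[keep]}
            )
        )
    if not pieces:
        return pd.DataFrame(columns=BED_COLS + ["count"])
    return pd.concat(pieces, ignore_index=True)


def threshold_runs(runs: pd.DataFrame, min_count: int) -> pd.DataFrame:
    """Merge maximal runs whose support meets ``min_count``.

    ``runs`` is coverage_runs output; the result carries the maximum support
    observed inside each merged interval as ``support``.
    """
    kept = runs[runs["count"] >= min_count]
    if len(kept) == 0:
        return pd.DataFrame(columns=BED_COLS + ["support"])
    merged = merge_intervals(kept[BED_COLS])
    support = []
    for _, row in merged.iterrows():
        sub = kept[
            (kept["chrom"] == row["chrom"])
            & (kept["start"] < row["end"])
            & (kept["end"] > row["start"])
        ]
        support.append(int(sub["count"].max()))
    merged["support"] = support
    return merged


def overlap_bp_per_query(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Overlapping base pairs of each query interval with a merged subject set."""
    subject = merge_intervals(subject)
    out = np.zeros(len(query), dtype=np.int64)
    for chrom, sub in subject.groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        # cumulative covered bp up to the start of each subject interval
        cum = np.concatenate([[0], np.cumsum(e - s)])

        sel = np.flatnonzero((query["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            continue
        qs = query["start"].to_numpy()[sel]
        qe = query["end"].to_numpy()[sel]
        # covered bp in [0, x): full intervals before + partial current one
        def covered_upto(x: np.ndarray) -> np.ndarray:
            i = np.searchsorted(s, x, side="right") - 1
            base = cum[np.maximum(i, 0) + 1]
            partial = np.where(
                (i >= 0) & (x < e[np.maximum(i, 0)]),
                e[np.maximum(i, 0)] - x,
                0,
            )
            return np.where(i >= 0, base - partial, 0)

        out[sel] = covered_upto(qe) - covered_upto(qs)
    return out


def jaccard_bp(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-pair Jaccard: bp(a ∩ b) / bp(a ∪ b).

    Both sets are merged first. Undefined (ValueError) when both are empty.
    """
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    inter = total_bp(intersect_intervals(a, b)) if len(a) and len(b) else 0
    union = total_bp(pd.concat([a[BED_COLS], b[BED_COLS]], ignore_index=True)
                     if len(a) and len(b) else (a if len(a) else b))
    return inter / union


def fractional_overlap(
    query: pd.DataFrame, subject: pd.DataFrame, min_frac: float = 0.5
) -> tuple[np.ndarray, float]:
    """Flag query intervals with ≥ min_frac of their width inside the subject.

    Returns (per-query boolean flags, fraction of queries flagged). With an
    empty query the fraction is nan.
    """
    query = as_intervals(query)
    if len(query) == 0:
        return np.zeros(0, dtype=bool), float("nan")
    ov = overlap_bp_per_query(query, subject) if len(subject) else np.zeros(len(query))
    widths = (query["end"] - query["start"]).to_numpy()
    flags = ov >= min_frac * widths
    return flags, float(flags.mean())


def tile_genome(chrom_lengths: Mapping[str, int], width: int) -> pd.DataFrame:
    """Tile each chromosome into consecutive windows of ``width`` bp.

    The final partial window (if any) is kept.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)
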