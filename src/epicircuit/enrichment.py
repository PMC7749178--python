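"""Chromatin-state enrichment of interval sets by matched-background permutation.

The overlap of two region sets is summarised by the base-pair Jaccard
coefficient s = bp(intersection) / bp(union). Its significance is assessed
against a null built by relocating the query features, width-preserved, into a
background whose CpG content matches the features themselves:

1. a window size w is set to the 25th percentile of feature widths, rounded to
   the nearest 1,000 bp and clipped to [1 kb, 10 kb];
2. the features are split into w-sized windows (fragments narrower than w/4
   dropped) and each window's CpG content p (CpG sites per kb) recorded;
3. the genome is tiled into w windows and those with p between the 5th and
   95th percentile of the feature windows' p form the background;
4. features are shuffled uniformly into the merged background 1,000 times and
   the enrichment reported as z = (s - mu) / sigma over the permuted Jaccards,
   with an empirical p of (1 + #{perm >= s}) / (n_perm + 1).

Also here: the 18-state ChromHMM conveniences — collapsing states to
TSS/Enh/other, largest-overlap peak annotation, and the >= 50 % modal
consensus state across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    BED_COLS,
    as_intervals,
    jaccard_bp,
    merge_intervals,
    overlap_bp_per_query,
    tile_genome,
)

STATE_ALPHABET = tuple(f"E{i:02d}" for i in range(1, 19))
TSS_STATES = frozenset(f"E{i:02d}" for i in range(1, 5))     # E01-E04
ENH_STATES = frozenset(f"E{i:02d}" for i in range(7, 12))    # E07-E11


@dataclass(frozen=True)
class BackgroundSpec:
    """CpG-content-matched shuffle background.

    w        : window size in bp (in [1,000, 10,000])
    windows  : qualifying genome windows (BED-like frame)
    p_lo/p_hi: CpG-content bounds (CpG sites per kb) that windows satisfy
    """

    w: int
    windows: pd.DataFrame
    p_lo: float
    p_hi: float


@dataclass(frozen=True)
class EnrichmentResult:
    s: float        # observed Jaccard
    mu: float       # permutation mean
    sigma: float    # permutation SD
    z: float        # (s - mu) / sigma; nan when sigma == 0
    p_emp: float    # (1 + #{perm >= s}) / (n_perm + 1)
    n_perm: int


def _cpg_count_per_window(windows: pd.DataFrame, cpg_sites: pd.DataFrame) -> np.ndarray:
    """CpG sites falling in each window (sites given as chrom/pos)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in cpg_sites.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        sel = np.flatnonzero((windows["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            continue
        s = windows["start"].to_numpy()[sel]
        e = windows["end"].to_numpy()[sel]
        counts[sel] = np.searchsorted(pos, e) - np.searchsorted(pos, s)
    return counts


def _round_to_thousand(x: float) -> int:
    """Round half away from zero to the nearest multiple of 1,000."""
    return int(np.floor(x / 1000.0 + 0.5) * 1000)


def build_matched_background(
    features: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    cpg_sites: pd.DataFrame,
) -> BackgroundSpec:
    """Select genome windows whose CpG content matches the query features."""
    features = as_intervals(features)
    if len(features) == 0:
        raise ValueError("cannot build a background for an empty feature set")
    widths = (features["end"] - features["start"]).to_numpy()
    w = _round_to_thousand(float(np.percentile(widths, 25)))
    w = min(max(w, 1_000), 10_000)

    # split features into w windows, drop fragments below w/4
    rows = []
    for row in features.itertuples():
        starts = np.arange(row.start, row.end, w, dtype=np.int64)
        ends = np.minimum(starts + w, row.end)
        rows.append(pd.DataFrame({"chrom": row.chrom, "start": starts, "end": ends}))
    fwin = pd.concat(rows, ignore_index=True)
    fwin = fwin[(fwin["end"] - fwin["start"]) >= w / 4].reset_index(drop=True)
    if len(fwin) == 0:
        raise ValueError("all feature windows narrower than w/4; cannot match CpG content")
    p_feat = _cpg_count_per_window(fwin, cpg_sites) / (
        (fwin["end"] - fwin["start"]).to_numpy() / 1000.0
    )
    p_lo, p_hi = (float(np.percentile(p_feat, q)) for q in (5, 95))

    gwin = tile_genome(chrom_lengths, w)
    p_gen = _cpg_count_per_window(gwin, cpg_sites) / (
        (gwin["end"] - gwin["start"]).to_numpy() / 1000.0
    )
    keep = (p_gen >= p_lo) & (p_gen <= p_hi)
    windows = gwin.loc[keep].reset_index(drop=True)
    if len(windows) == 0:
        raise ValueError(
            "no genome window matches the feature CpG content "
            f"(bounds [{p_lo:.2f}, {p_hi:.2f}] CpG/kb; genome windows span "
            f"[{p_gen.min():.2f}, {p_gen.max():.2f}])"
        )
    return BackgroundSpec(w=w, windows=windows, p_lo=p_lo, p_hi=p_hi)


class _ShuffleArena:
    """Pre-digested background runs and state regions for fast shuffling.

    The background is merged into maximal runs; state regions are merged per
    chromosome with cumulative-coverage arrays so that the intersected bp of
    any interval batch is a pair of searchsorted lookups.
    """

    def __init__(self, background: pd.DataFrame, state_regions: pd.DataFrame):
        runs = merge_intervals(background)
        self.run_chrom = runs["chrom"].to_numpy()
        self.run_start = runs["start"].to_numpy(dtype=np.int64)
        self.run_len = (runs["end"] - runs["start"]).to_numpy(dtype=np.int64)
        self.states: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.state_bp = 0
        if len(state_regions):
            merged = merge_intervals(state_regions)
            for chrom, grp in merged.groupby("chrom"):
                s = grp["start"].to_numpy(dtype=np.int64)
                e = grp["end"].to_numpy(dtype=np.int64)
                cum = np.concatenate([[0], np.cumsum(e - s)])
                self.states[chrom] = (s, e, cum)
                self.state_bp += int((e - s).sum())

    def covered_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> int:
        if chrom not in self.states:
            return 0
        s, e, cum = self.states[chrom]

        def upto(x: np.ndarray) -> np.ndarray:
            i = np.searchsorted(s, x, side="right") - 1
            base = cum[np.maximum(i, 0) + 1]
            partial = np.where((i >= 0) & (x < e[np.maximum(i, 0)]),
                               e[np.maximum(i, 0)] - x, 0)
            return np.where(i >= 0, base - partial, 0)

        return int((upto(ends) - upto(starts)).sum())

    def place(self, widths: np.ndarray, rng: np.random.Generator) -> tuple:
        """Uniform placement of each width inside the background runs.

        Features land uniformly over every position keeping them inside one
        merged run (they may overlap each other, as in a genome-arithmetic
        shuffle restricted to an inclusion set). Returns (chroms, starts, ends).
        """
        chroms = np.empty(len(widths), dtype=object)
        starts = np.empty(len(widths), dtype=np.int64)
        for width in np.unique(widths):
            cap = self.run_len - width + 1
            valid = cap > 0
            if not valid.any():
                raise ValueError(
                    f"feature of width {width} exceeds every background run "
                    f"(longest run {int(self.run_len.max())} bp)"
                )
            weights = np.where(valid, cap, 0).astype(float)
            cdf = np.cumsum(weights)
            sel = np.flatnonzero(widths == width)
            u = rng.uniform(0, cdf[-1], size=len(sel))
            run_idx = np.searchsorted(cdf, u, side="right")
            offsets = rng.integers(0, cap[run_idx])
            chroms[sel] = self.run_chrom[run_idx]
            starts[sel] = self.run_start[run_idx] + offsets
        return chroms, starts, starts + widths

    def jaccard(self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> float:
        """Base-pair Jaccard of a placed interval batch against the states."""
        feat_bp = 0
        inter = 0
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            s, e = starts[sel], ends[sel]
            order = np.argsort(s, kind="mergesort")
            s, e = s[order], e[order]
            cm = np.maximum.accumulate(e)
            new = np.concatenate([[True], s[1:] > cm[:-1]])
            ms = s[new]
            me = np.maximum.reduceat(e, np.flatnonzero(new))
            feat_bp += int((me - ms).sum())
            inter += self.covered_bp(chrom, ms, me)
        union = feat_bp + self.state_bp - inter
        return inter / union if union else float("nan")


def place_features(
    widths: Sequence[int], background: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Place intervals of the given widths uniformly inside a background.

    Convenience wrapper around the shuffle arena; used both by the
    permutation null and to draw calibration features from the background.
    """
    arena = _ShuffleArena(background, pd.DataFrame(columns=BED_COLS))
    c, s, e = arena.place(np.asarray(widths, dtype=np.int64), rng)
    return pd.DataFrame({"chrom": c, "start": s, "end": e})


def permutation_enrichment(
    features: pd.DataFrame,
    state_regions: pd.DataFrame,
    background: BackgroundSpec | pd.DataFrame,
    n_perm: int = 1_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Matched-background permutation test of the base-pair Jaccard overlap."""
    bg = background.windows if isinstance(background, BackgroundSpec) else background
    features = as_intervals(features)
    if len(bg) == 0:
        raise ValueError("background is empty")
    rng = np.random.default_rng(seed)
    widths = (features["end"] - features["start"]).to_numpy(dtype=np.int64)

    arena = _ShuffleArena(bg, state_regions)
    if len(state_regions) == 0:
        s = 0.0
        perms = np.zeros(n_perm)
    else:
        s = jaccard_bp(features, state_regions)
        perms = np.empty(n_perm)
        for k in range(n_perm):
            perms[k] = arena.jaccard(*arena.place(widths, rng))
    mu = float(perms.mean())
    sigma = float(perms.std(ddof=0))
    z = (s - mu) / sigma if sigma > 0 else float("nan")
    p_emp = (1 + int((perms >= s).sum())) / (n_perm + 1)
    return EnrichmentResult(s=float(s), mu=mu, sigma=sigma, z=z, p_emp=p_emp,
                            n_perm=n_perm)


# ---------------------------------------------------------------------------
# ChromHMM-state utilities

def collapse_states(state: str) -> str:
    """Collapse an 18-state label: E01-E04 → TSS, E07-E11 → Enh, else other."""
    if state not in STATE_ALPHABET:
        raise ValueError(f"unknown chromatin state {state!r}")
    if state in TSS_STATES:
        return "TSS"
    if state in ENH_STATES:
        return "Enh"
    return "other"


def annotate_by_largest_overlap(
    peaks: pd.DataFrame, state_segments: pd.DataFrame
) -> pd.Series:
    """Label each peak with the state contributing the most overlapping bp.

    Ties break to the lowest state index; peaks overlapping no segment get
    "unannotated". ``state_segments`` needs a ``state`` column.
    """
    peaks = as_intervals(peaks)
    states = sorted(state_segments["state"].unique())
    best_bp = np.zeros(len(peaks), dtype=np.int64)
    label = np.array(["unannotated"] * len(peaks), dtype=object)
    for state in states:  # ascending order makes the tie-break "first wins"
        seg = state_segments[state_segments["state"] == state]
        ov = overlap_bp_per_query(peaks, seg)
        better = ov > best_bp
        best_bp[better] = ov[better]
        label[better] = state
    return pd.Series(label, index=peaks.index, name="state")


def consensus_state(
    per_sample: Mapping[str, pd.DataFrame], min_frequency: float = 0.5
) -> pd.DataFrame:
    """Modal chromatin state per grid cell, requiring ≥ min_frequency support.

    All samples' segmentations are re-cut on the union grid of their
    breakpoints; a cell gets the modal state when that state's frequency is at
    least ``min_frequency`` of all samples, else None.
    """
    n_samples = len(per_sample)
    chroms = sorted({c for df in per_sample.values() for c in df["chrom"].unique()})
    rows = []
    for chrom in chroms:
        cuts = np.unique(
            np.concatenate(
                [
                    df.loc[df["chrom"] == chrom, ["start", "end"]].to_numpy().ravel()
                    for df in per_sample.values()
                ]
            )
        )
        starts, ends = cuts[:-1], cuts[1:]
        cell_states = []
        for df in per_sample.values():
            sub = df[df["chrom"] == chrom].sort_values("start")
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            st = sub["state"].to_numpy()
            i = np.searchsorted(s, starts, side="right") - 1
            covered = (i >= 0) & (starts < e[np.maximum(i, 0)])
            states = np.where(covered, st[np.maximum(i, 0)], None)
            cell_states.append(states)
        grid_states = np.vstack(cell_states)  # samples × cells
        for j, (cs, ce) in enumerate(zip(starts, ends)):
            col = [x for x in grid_states[:, j] if x is not None]
            consensus = None
            if col:
                vals, counts = np.unique(col, return_counts=True)
                top = counts.max()
                if top / n_samples >= min_frequency:
                    consensus = sorted(vals[counts == top])[0]
            rows.append((chrom, int(cs), int(ce), consensus))
    return pd.DataFrame(rows, columns=BED_COLS + ["state"])
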