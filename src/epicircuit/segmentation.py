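"""Per-sample methylome segmentation and DMV/LMR/PMD feature calling.

The segmentation is a two-stage rule. Chromosomes are first split into blocks
wherever the inter-CpG distance exceeds ``gap_max``. Within each block, every
CpG is assigned a methylation class (low / intermediate / high) from a
median-filtered beta signal — the running median is edge-preserving, so a
single noisy CpG neither splits a hypomethylated run nor shifts its
boundaries — and maximal same-class runs become the final blocks. Feature
calls are then made on runs of same-class blocks:

* DMV  — a low run at least ``dmv_min_width`` wide with mean beta at most
  ``dmv_max_mean`` (long, near-unmethylated valleys over developmental genes);
* LMR  — a shorter low run with at least ``lmr_min_cpgs`` CpGs and mean beta
  at most ``lmr_max_mean`` (distal regulatory hypomethylation); LMRs less than
  1 kb apart are merged;
* PMD  — an intermediate run at least 10 kb wide whose pooled beta mean falls
  in ``pmd_beta_range`` with pooled SD at least ``pmd_min_sd`` (disordered,
  partially methylated domains).

Consensus regions across a cohort are produced genomecov-style: per-base
support counting followed by run thresholding, either with an absolute
cross-sample coverage (default 4) or, per subtype, with support in strictly
more than half of that subtype's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import (
    BED_COLS,
    coverage_runs,
    merge_intervals,
    threshold_runs,
)

FEATURE_CLASSES = ("DMV", "LMR", "PMD")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the block segmentation and feature-calling rules.

    ``pmd_min_width`` (10 kb) and ``lmr_merge_gap`` (1 kb, strict) are fixed
    by the method; the remaining defaults follow the hypomethylated-region
    literature and are configurable.
    """

    gap_max: int = 1_000            # bp; new block when inter-CpG gap exceeds this
    low_max: float = 0.3            # mean beta ≤ low_max → low
    high_min: float = 0.7           # mean beta ≥ high_min → high
    smooth_window: int = 5          # CpGs; running-median window for CpG classes
    feature_merge_gap: int = 2_000  # bp; same-class runs bridge CpG deserts up to this
    dmv_min_width: int = 5_000      # bp
    dmv_max_mean: float = 0.15
    lmr_max_mean: float = 0.5
    lmr_min_cpgs: int = 4
    lmr_max_width: int | None = None  # defaults to dmv_min_width
    pmd_min_width: int = 10_000     # bp
    pmd_beta_range: tuple[float, float] = (0.3, 0.7)
    pmd_min_sd: float = 0.1
    lmr_merge_gap: int = 1_000      # bp; LMRs strictly closer than this merge
    consensus_min_coverage: int = 4
    subtype_min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.low_max < self.high_min < 1):
            raise ValueError("need 0 < low_max < high_min < 1")
        for name in ("gap_max", "dmv_min_width", "pmd_min_width", "lmr_merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


BLOCK_COLS = ["chrom", "start", "end", "n_cpgs", "mean_beta", "sd_beta", "cls"]
FEATURE_COLS = ["chrom", "start", "end", "cls", "mean_beta", "n_cpgs"]


def _classify(mean: float, params: SegmentationParams) -> str:
    if mean <= params.low_max:
        return "low"
    if mean >= params.high_min:
        return "high"
    return "intermediate"


def segment_methylome(
    sites: pd.DataFrame, params: SegmentationParams = SegmentationParams()
) -> pd.DataFrame:
    """Segment one sample's CpGs into classified methylation blocks.

    ``sites`` needs columns chrom, pos (or start) and beta; CpGs with missing
    beta are ignored. Returns a BLOCK_COLS frame; blocks partition the covered
    CpGs, each block spanning its first to its last CpG + 1.
    """
    df = sites.rename(columns={"start": "pos"}) if "pos" not in sites.columns else sites
    df = df.loc[~df["beta"].isna(), ["chrom", "pos", "beta"]]
    df = df.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    rows: list[tuple] = []
    h = params.smooth_window
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        beta = grp["beta"].to_numpy(dtype=float)
        gap_breaks = np.flatnonzero(np.diff(pos) > params.gap_max) + 1
        for seg_pos, seg_beta in zip(np.split(pos, gap_breaks), np.split(beta, gap_breaks)):
            smoothed = (
                pd.Series(seg_beta)
                .rolling(window=h, center=True, min_periods=1)
                .median()
                .to_numpy()
            )
            cls_codes = np.where(
                smoothed <= params.low_max, 0, np.where(smoothed >= params.high_min, 2, 1)
            )
            cls_breaks = np.flatnonzero(np.diff(cls_codes) != 0) + 1
            for p, b in zip(np.split(seg_pos, cls_breaks), np.split(seg_beta, cls_breaks)):
                mean = float(b.mean())
                sd = float(b.std(ddof=1)) if len(b) > 1 else 0.0
                rows.append(
                    (chrom, int(p[0]), int(p[-1]) + 1, len(p), mean, sd,
                     _classify(mean, params))
                )
    return pd.DataFrame(rows, columns=BLOCK_COLS)


def _pooled_stats(blocks: pd.DataFrame) -> tuple[float, float, int]:
    """Pooled mean and sample SD of CpG betas across a run of blocks."""
    n = blocks["n_cpgs"].to_numpy(dtype=float)
    mean = blocks["mean_beta"].to_numpy()
    sd = blocks["sd_beta"].to_numpy()
    total = n.sum()
    grand = float((n * mean).sum() / total)
    ss = float(((n - 1) * sd**2 + n * mean**2).sum() - total * grand**2)
    pooled_sd = float(np.sqrt(max(ss, 0.0) / (total - 1))) if total > 1 else 0.0
    return grand, pooled_sd, int(total)


def _runs_of_class(
    blocks: pd.DataFrame, cls: str, merge_gap: int
) -> list[pd.DataFrame]:
    """Maximal runs of same-class blocks, bridging CpG-free gaps ≤ merge_gap.

    A run is broken by any intervening block of another class, or by a gap
    larger than merge_gap.
    """
    order = blocks.sort_values(["chrom", "start"]).reset_index(drop=True)
    runs: list[list[int]] = []
    current: list[int] = []
    prev_chrom, prev_end = None, None
    for row in order.itertuples():
        if row.cls == cls:
            extend = (
                current
                and row.chrom == prev_chrom
                and row.start - prev_end <= merge_gap
            )
            if extend:
                current.append(row.Index)
            else:
                if current:
                    runs.append(current)
                current = [row.Index]
        elif current:
            runs.append(current)
            current = []
        prev_chrom, prev_end = row.chrom, row.end
    if current:
        runs.append(current)
    return [order.loc[idx] for idx in runs]


def call_features(
    blocks: pd.DataFrame, params: SegmentationParams = SegmentationParams()
) -> pd.DataFrame:
    """Call DMVs, LMRs and PMDs from one sample's classified blocks."""
    if len(blocks) == 0:
        return pd.DataFrame(columns=FEATURE_COLS)
    lmr_max_width = params.lmr_max_width or params.dmv_min_width
    feats: list[tuple] = []

    for run in _runs_of_class(blocks, "low", params.feature_merge_gap):
        chrom = run["chrom"].iloc[0]
        start, end = int(run["start"].min()), int(run["end"].max())
        width = end - start
        mean, _, n = _pooled_stats(run)
        if width >= params.dmv_min_width and mean <= params.dmv_max_mean:
            feats.append((chrom, start, end, "DMV", mean, n))
        elif (
            width < lmr_max_width
            and mean <= params.lmr_max_mean
            and n >= params.lmr_min_cpgs
        ):
            feats.append((chrom, start, end, "LMR", mean, n))

    for run in _runs_of_class(blocks, "intermediate", params.feature_merge_gap):
        chrom = run["chrom"].iloc[0]
        start, end = int(run["start"].min()), int(run["end"].max())
        mean, sd, n = _pooled_stats(run)
        lo, hi = params.pmd_beta_range
        if end - start >= params.pmd_min_width and lo <= mean <= hi and sd >= params.pmd_min_sd:
            feats.append((chrom, start, end, "PMD", mean, n))

    out = pd.DataFrame(feats, columns=FEATURE_COLS)
    out = _merge_close_lmrs(out, params)
    return out.sort_values(["chrom", "start", "cls"]).reset_index(drop=True)


def _merge_close_lmrs(features: pd.DataFrame, params: SegmentationParams) -> pd.DataFrame:
    """Merge LMRs whose gap is strictly below ``lmr_merge_gap``."""
    lmrs = features[features["cls"] == "LMR"].sort_values(["chrom", "start"])
    if len(lmrs) <= 1:
        return features
    rows, current = [], None
    for row in lmrs.itertuples():
        if (
            current is not None
            and row.chrom == current["chrom"]
            and row.start - current["end"] < params.lmr_merge_gap
        ):
            w_old = current["n_cpgs"]
            current["mean_beta"] = (
                current["mean_beta"] * w_old + row.mean_beta * row.n_cpgs
            ) / (w_old + row.n_cpgs)
            current["n_cpgs"] = w_old + row.n_cpgs
            current["end"] = max(current["end"], row.end)
        else:
            if current is not None:
                rows.append(current)
            current = {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "cls": "LMR", "mean_beta": row.mean_beta, "n_cpgs": row.n_cpgs,
            }
    rows.append(current)
    merged = pd.DataFrame(rows, columns=FEATURE_COLS)
    return pd.concat([features[features["cls"] != "LMR"], merged], ignore_index=True)


def consensus_features(
    per_sample: Mapping[str, pd.DataFrame],
    mode: str = "cohort_coverage",
    params: SegmentationParams = SegmentationParams(),
    subtype_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Consensus intervals per feature class across samples.

    mode = "cohort_coverage": per-base support ≥ ``consensus_min_coverage``
    samples. mode = "subtype_fraction": per subtype, support in strictly more
    than ``subtype_min_fraction`` of that subtype's samples (output carries a
    ``subtype`` column). Each interval reports its maximum support.
    """
    if mode not in ("cohort_coverage", "subtype_fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "subtype_fraction":
        if subtype_labels is None:
            raise ValueError("subtype_fraction mode needs subtype labels")
        unknown = [s for s in per_sample if s not in subtype_labels]
        if unknown:
            raise ValueError(f"samples without subtype label: {unknown}")

    out = []
    for cls in FEATURE_CLASSES:
        stacks: dict[str, list[pd.DataFrame]] = {}
        for sample, feats in per_sample.items():
            sub = feats[feats["cls"] == cls][BED_COLS]
            if len(sub) == 0:
                sub = pd.DataFrame(columns=BED_COLS)
            group = (
                "cohort" if mode == "cohort_coverage" else subtype_labels[sample]
            )
            stacks.setdefault(group, []).append(merge_intervals(sub) if len(sub) else sub)
        for group, dfs in sorted(stacks.items()):
            stacked = pd.concat([d for d in dfs if len(d)], ignore_index=True) \
                if any(len(d) for d in dfs) else pd.DataFrame(columns=BED_COLS)
            if len(stacked) == 0:
                continue
            runs = coverage_runs(stacked)
            if mode == "cohort_coverage":
                min_count = params.consensus_min_coverage
            else:
                n = len(dfs)
                # strictly more than the fraction
                min_count = int(np.floor(params.subtype_min_fraction * n)) + 1
            cons = threshold_runs(runs, min_count)
            cons["cls"] = cls
            if mode == "subtype_fraction":
                cons["subtype"] = group
            out.append(cons)
    cols = BED_COLS + ["support", "cls"] + (
        ["subtype"] if mode == "subtype_fraction" else []
    )
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)[cols]


def sharing_fractions(per_subtype: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Fraction of the union width covered by exactly k subtypes, k = 1..n.

    Each subtype's interval set is merged first so a subtype contributes at
    most one layer of support per base. Fractions sum to 1 over the union.
    """
    if len(per_subtype) < 2:
        raise ValueError("sharing requires at least two subtypes")
    merged = {st: merge_intervals(df) for st, df in per_subtype.items() if len(df)}
    n = len(per_subtype)
    if not merged:
        raise ValueError("sharing undefined: union of subtype features is empty")
    stacked = pd.concat(list(merged.values()), ignore_index=True)
    runs = coverage_runs(stacked)
    widths = runs["end"] - runs["start"]
    union_bp = widths.sum()
    frac = pd.Series(0.0, index=pd.RangeIndex(1, n + 1, name="n_subtypes"))
    for k, grp in runs.groupby("count"):
        frac.loc[int(k)] = float((grp["end"] - grp["start"]).sum() / union_bp)
    return frac


def recovery_jaccard(truth: pd.DataFrame, calls: pd.DataFrame) -> pd.Series:
    """Per planted feature, Jaccard with the union of overlapping calls.

    Evaluation helper for cohorts with planted ground truth: for each truth
    interval, the called intervals of the same class that intersect it are
    unioned and the base-pair Jaccard against the truth interval reported
    (0 when nothing overlaps).
    """
    from .intervals import intersect_intervals, total_bp

    scores = []
    for row in truth.itertuples():
        sub = calls[
            (calls["cls"] == row.cls)
            & (calls["chrom"] == row.chrom)
            & (calls["start"] < row.end)
            & (calls["end"] > row.start)
        ][BED_COLS]
        if len(sub) == 0:
            scores.append(0.0)
            continue
        t = pd.DataFrame({"chrom": [row.chrom], "start": [row.start], "end": [row.end]})
        inter = total_bp(intersect_intervals(t, sub))
        union = total_bp(pd.concat([t, sub], ignore_index=True))
        scores.append(inter / union)
    return pd.Series(scores, index=truth.index, name="jaccard")
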