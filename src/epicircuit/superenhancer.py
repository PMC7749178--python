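"""Superenhancer calling, subtype testing, TAD-constrained target assignment
and core-regulatory-circuit cliques.

Enhancer peaks within 12.5 kb of each other are stitched into candidate
regions; ranking the stitched regions by H3K27ac signal yields the familiar
hockey-stick curve, and superenhancers (SEs) are the regions above the point
where the slope of the min-max-scaled curve reaches 1 (the geometric tangent
rule). Subtype SEs are found by one-way ANOVA on signal across subtypes with
BH correction and a minimum log2 fold change. Each SE is assigned a target
gene: the gene with the highest Spearman correlation between SE signal and
expression across samples, among genes with a TSS within 500 kb of the SE and
in the same topologically associating domain (TAD). Core regulatory circuits
are maximal cliques of autoregulatory transcription factors whose SEs contain
binding motifs for every member of the clique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import BED_COLS, as_intervals, overlap_bp_per_query

LOGFC_PSEUDOCOUNT = 1e-6


def stitch_enhancers(
    peaks: pd.DataFrame,
    signal: pd.DataFrame | None = None,
    stitch_dist: int = 12_500,
) -> pd.DataFrame:
    """Chain peaks with gaps ≤ stitch_dist into stitched enhancer regions.

    ``signal`` (rows aligned with peaks, one column per sample) is summed over
    the constituents of each stitched region. Returns chrom/start/end plus
    ``n_peaks`` and any signal columns.
    """
    peaks = as_intervals(peaks)
    if signal is not None and len(signal) != len(peaks):
        raise ValueError("signal rows must align with peaks")
    sig = signal.reset_index(drop=True) if signal is not None else None
    rows = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        run = [0]
        run_end = ends[0]
        for i in range(1, len(idx)):
            if starts[i] - run_end <= stitch_dist:
                run.append(i)
                run_end = max(run_end, ends[i])
            else:
                rows.append((chrom, starts[run[0]], run_end, idx[run]))
                run = [i]
                run_end = ends[i]
        rows.append((chrom, starts[run[0]], run_end, idx[run]))
    out = pd.DataFrame(
        [(c, s, e, len(m)) for c, s, e, m in rows],
        columns=BED_COLS + ["n_peaks"],
    )
    if sig is not None:
        sums = pd.DataFrame(
            [sig.loc[m].sum(axis=0) for _, _, _, m in rows]
        ).reset_index(drop=True)
        out = pd.concat([out, sums], axis=1)
    return out


@dataclass(frozen=True)
class SECallResult:
    order: np.ndarray       # indices of enhancers, ascending signal
    cutoff: float           # signal value at the tangent point
    is_super: np.ndarray    # aligned with the input signal vector


def call_superenhancers(signal: np.ndarray | pd.Series) -> SECallResult:
    """Rank-curve superenhancer call on one signal vector.

    Enhancers are sorted ascending; both axes are min-max scaled to [0, 1];
    the cutoff is the signal at the point minimising y - x on the scaled curve
    (where a slope-1 line is tangent from below). Enhancers with signal
    strictly above the cutoff are superenhancers. A flat curve has no elbow
    and yields no superenhancers. Invariant to positive rescaling.
    """
    sig = np.asarray(signal, dtype=float)
    if len(sig) < 3:
        raise ValueError("superenhancer calling needs at least 3 enhancers")
    if (sig < 0).any():
        raise ValueError("signal must be non-negative")
    order = np.argsort(sig, kind="mergesort")
    y = sig[order]
    if y[-1] == y[0]:
        return SECallResult(order=order, cutoff=float(y[-1]),
                            is_super=np.zeros(len(sig), dtype=bool))
    x = np.linspace(0.0, 1.0, len(sig))
    y_scaled = (y - y[0]) / (y[-1] - y[0])
    tangent = int(np.argmin(y_scaled - x))
    cutoff = float(y[tangent])
    return SECallResult(order=order, cutoff=cutoff, is_super=sig > cutoff)


def subtype_se_test(
    signal: pd.DataFrame,
    subtype_labels: Mapping[str, str],
    min_lfc: float = 1.0,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """One-way ANOVA of SE signal across subtypes with BH and logFC gating.

    ``signal`` is SEs × samples (linear scale). Per SE and subtype the log2
    fold change is log2(mean in subtype / mean of all other samples); the SE
    is assigned to its argmax-logFC subtype iff the BH-adjusted ANOVA p ≤
    ``alpha`` and that logFC ≥ ``min_lfc``. SEs with zero variance in every
    group are flagged and left untested.
    """
    labels = pd.Series({s: subtype_labels[s] for s in signal.columns})
    subtypes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every subtype needs at least 2 samples")
    groups = {st: signal.loc[:, labels[labels == st].index].to_numpy() for st in subtypes}

    n = len(signal)
    pvals = np.full(n, np.nan)
    fstat = np.full(n, np.nan)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        gs = [g[i] for g in groups.values()]
        if all(np.ptp(g) == 0 for g in gs) and len({g[0] for g in gs}) == 1:
            degenerate[i] = True
            continue
        f, p = stats.f_oneway(*gs)
        fstat[i], pvals[i] = f, p

    adj = np.full(n, np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    lfc = pd.DataFrame(index=signal.index, columns=subtypes, dtype=float)
    for st in subtypes:
        inside = groups[st].mean(axis=1)
        others = signal.loc[:, labels[labels != st].index].to_numpy().mean(axis=1)
        lfc[st] = np.log2((inside + LOGFC_PSEUDOCOUNT) / (others + LOGFC_PSEUDOCOUNT))

    best = lfc.idxmax(axis=1)
    best_lfc = lfc.max(axis=1)
    assigned = np.where(
        tested & (adj <= alpha) & (best_lfc.to_numpy() >= min_lfc), best, None
    )
    out = pd.DataFrame(
        {
            "F": fstat,
            "p": pvals,
            "adj_p": adj,
            "assigned_subtype": assigned,
            "degenerate": degenerate,
        },
        index=signal.index,
    )
    return pd.concat([out, lfc.add_prefix("lfc_")], axis=1)


def subtype_specific_ses(
    per_subtype: Mapping[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """SEs of each subtype with zero bp overlap against every other subtype."""
    out = {}
    for st, ses in per_subtype.items():
        ses = as_intervals(ses)
        keep = np.ones(len(ses), dtype=bool)
        for other, other_ses in per_subtype.items():
            if other == st or len(other_ses) == 0:
                continue
            keep &= overlap_bp_per_query(ses, other_ses) == 0
        out[st] = ses.loc[keep].reset_index(drop=True)
    return out


def se_gene_score(
    expression: pd.DataFrame, target_genes: Sequence[str]
) -> pd.Series:
    """Per-sample score: mean expression of the subtype-specific SE targets."""
    targets = [g for g in target_genes if g in expression.index]
    if not targets:
        raise ValueError("none of the target genes is in the expression matrix")
    return expression.loc[targets].mean(axis=0)


def _tad_of_point(tads: pd.DataFrame, chrom: str, pos: int) -> str | None:
    sub = tads[(tads["chrom"] == chrom) & (tads["start"] <= pos) & (pos < tads["end"])]
    if len(sub) == 0:
        return None
    return str(sub.iloc[0]["tad_id"]) if "tad_id" in sub.columns else (
        f"{sub.iloc[0]['chrom']}:{sub.iloc[0]['start']}-{sub.iloc[0]['end']}"
    )


def assign_se_target(
    se: pd.Series,
    se_signal: pd.Series,
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    tads: pd.DataFrame,
    max_dist: int = 500_000,
) -> dict | None:
    """Assign one SE its target gene by Spearman correlation within the TAD.

    ``se`` carries chrom/start/end; ``se_signal`` is its per-sample signal;
    ``genes`` has gene_id, chrom, tss (and optionally tad_id); ``tads`` is a
    BED-like frame (optionally with tad_id). Candidates are genes with a TSS
    within ``max_dist`` of the SE boundary and in the same TAD as the SE
    midpoint. The highest-rho gene wins; ties break by TSS distance, then
    lexicographic gene id. Returns None (no candidates) or a dict with
    gene_id, rho, distance and n_samples.
    """
    shared = [s for s in se_signal.index if s in expression.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 paired samples for target assignment")
    mid = (int(se["start"]) + int(se["end"])) // 2
    se_tad = _tad_of_point(tads, se["chrom"], mid)
    if se_tad is None:
        return None

    cand = genes[genes["chrom"] == se["chrom"]].copy()
    dist = np.maximum.reduce(
        [cand["tss"] - int(se["end"]) + 1, int(se["start"]) - cand["tss"],
         np.zeros(len(cand), dtype=np.int64)]
    )
    cand["distance"] = dist
    cand = cand[cand["distance"] <= max_dist]
    if "tad_id" in cand.columns:
        gene_tads = cand["tad_id"]
    else:
        gene_tads = cand.apply(lambda r: _tad_of_point(tads, r["chrom"], r["tss"]), axis=1)
    cand = cand[gene_tads == se_tad]
    cand = cand[cand["gene_id"].isin(expression.index)]
    if len(cand) == 0:
        return None

    x = se_signal[shared].to_numpy(dtype=float)
    best = None
    for row in cand.sort_values(["gene_id"]).itertuples():
        y = expression.loc[row.gene_id, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # rho undefined for constant vectors
        rho = stats.spearmanr(x, y).statistic
        key = (-rho, row.distance, row.gene_id)
        if best is None or key < best[0]:
            best = (key, row.gene_id, float(rho), int(row.distance))
    if best is None:
        return None
    return {
        "gene_id": best[1],
        "rho": best[2],
        "distance": best[3],
        "n_samples": len(shared),
    }


def crc_cliques(
    tf_to_se: Mapping[str, str], motif_hits: pd.DataFrame
) -> list[dict]:
    """Maximal cliques of autoregulatory TFs with fully mutual motif support.

    ``tf_to_se`` maps each TF to the SE whose target it is; ``motif_hits`` is
    a boolean TF × SE matrix (motif of the row-TF present in the column-SE).
    A TF is autoregulatory when its own SE contains its own motif; a clique is
    a maximal TF set in which every member's SE contains the motifs of all
    members. Output sorted by decreasing size, then lexicographic members.
    """
    missing = [tf for tf in tf_to_se if tf_to_se[tf] not in motif_hits.columns]
    if missing:
        raise ValueError(f"motif matrix lacks the SEs of TFs {missing}")
    auto = [
        tf for tf, se in tf_to_se.items()
        if tf in motif_hits.index and bool(motif_hits.loc[tf, se])
    ]
    g = nx.Graph()
    g.add_nodes_from(auto)
    for a in auto:
        for b in auto:
            if a < b and bool(motif_hits.loc[a, tf_to_se[b]]) and bool(
                motif_hits.loc[b, tf_to_se[a]]
            ):
                g.add_edge(a, b)
    cliques = [sorted(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    return [
        {"tfs": c, "ses": sorted({tf_to_se[tf] for tf in c})} for c in cliques
    ]


def se_signal_tstat(signal_a: np.ndarray, signal_b: np.ndarray) -> float:
    """Welch t-statistic comparing one sample's signal over two SE sets."""
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both SE sets need at least 2 regions")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return float("nan")  # no variance, no difference: undefined
        raise ValueError("zero variance in both SE sets with unequal means")
    return float(stats.ttest_ind(a, b, equal_var=False).statistic)
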