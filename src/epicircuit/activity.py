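"""Master-regulator activity: subtype assignment, cross-network consensus,
single-cell scoring and the copy-number threshold classifier.

A master regulator (MR) is a transcription factor whose regulon activity — a
normalised enrichment score (NES) per sample or cell, computed upstream by a
regulon-enrichment tool and consumed here as a matrix — defines a cellular
state. An MR is assigned to the subtype in which its mean activity is
maximal. Consensus MRs are those significant in two independently inferred
regulatory networks for the same subtype with the same direction of activity.
Per-cell subtype calls z-score each MR's activity across cells and take the
subtype with the maximum mean z. Signature scores for single cells subtract a
matched background (the 100 non-signature genes closest in dataset-mean
expression to each signature gene) before summing over the signature.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def assign_mr_subtype(
    activity: pd.DataFrame, sample_subtypes: Mapping[str, str]
) -> pd.DataFrame:
    """Assign each MR (row) the subtype with the maximal mean activity.

    Ties break to the lexicographically first subtype (flagged). MRs with no
    finite activity are left unassigned (flagged).
    """
    missing = [s for s in activity.columns if s not in sample_subtypes]
    if missing:
        raise ValueError(f"samples without subtype label: {missing}")
    labels = pd.Series({s: sample_subtypes[s] for s in activity.columns})
    means = activity.T.groupby(labels).mean().T  # MR × subtype
    means = means[sorted(means.columns)]
    arr = means.to_numpy()
    all_nan = np.isnan(arr).all(axis=1)
    best = np.where(all_nan, None, means.columns[np.nanargmax(
        np.where(np.isnan(arr), -np.inf, arr), axis=1)])
    with np.errstate(invalid="ignore"):
        tie = (
            (arr == np.nanmax(np.where(np.isnan(arr), -np.inf, arr),
                              axis=1, keepdims=True)).sum(axis=1) > 1
        ) & ~all_nan
    out = means.copy()
    out["subtype"] = best
    out["tie"] = tie
    out["unassigned"] = all_nan
    return out


def consensus_mrs(
    records_a: pd.DataFrame, records_b: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """MRs significant in both networks, same subtype, same activity direction.

    Each records frame has columns mr, subtype, score (signed dES/NES) and
    adj_p; one row per MR per network. Retention needs adj_p < alpha in both
    networks with matching subtype and sign(score).
    """
    for name, rec in (("A", records_a), ("B", records_b)):
        if rec.duplicated(["mr", "subtype"]).any():
            dups = rec.loc[rec.duplicated(["mr", "subtype"]), "mr"].tolist()
            raise ValueError(f"network {name} has conflicting duplicate records: {dups}")
    merged = records_a.merge(records_b, on=["mr", "subtype"], suffixes=("_a", "_b"))
    keep = (
        (merged["adj_p_a"] < alpha)
        & (merged["adj_p_b"] < alpha)
        & (np.sign(merged["score_a"]) == np.sign(merged["score_b"]))
    )
    out = merged.loc[keep, ["mr", "subtype", "score_a", "score_b"]]
    return out.sort_values("mr").reset_index(drop=True)


def cell_subtype_score(
    activity: pd.DataFrame, mr_subtype: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cell subtype call from MR activity.

    Each MR row is z-scored across cells (population SD; constant rows are
    dropped with a flag); per cell the mean z over each subtype's MRs is
    computed and the call is the argmax subtype.
    """
    if activity.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    unmapped = [m for m in activity.index if m not in mr_subtype]
    if unmapped:
        raise ValueError(f"MRs without subtype mapping: {unmapped}")
    sd = activity.std(axis=1, ddof=0)
    kept = activity.loc[sd > 0]
    dropped = sorted(set(activity.index) - set(kept.index))
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[kept.index], axis=0)
    groups = pd.Series({m: mr_subtype[m] for m in kept.index})
    mean_z = z.groupby(groups).mean().T  # cells × subtype
    mean_z = mean_z[sorted(mean_z.columns)]
    calls = mean_z.idxmax(axis=1)
    out = mean_z.add_prefix("z_")
    out["call"] = calls
    out.attrs["dropped_constant_mrs"] = dropped
    return out


def match_background_genes(
    gene_means: pd.Series, signature: Sequence[str], n_background: int = 100
) -> dict[str, list[str]]:
    """For each signature gene, the non-signature genes nearest in mean expression.

    Matching uses the dataset-wide mean per gene; with fewer than
    ``n_background`` candidates all are used.
    """
    sig = list(signature)
    missing = [g for g in sig if g not in gene_means.index]
    if missing:
        raise ValueError(f"signature genes absent from the matrix: {missing}")
    pool = gene_means.drop(index=sig)
    out = {}
    for g in sig:
        diff = (pool - gene_means[g]).abs().sort_values(kind="mergesort")
        out[g] = diff.index[: min(n_background, len(diff))].tolist()
    return out


def signature_score(
    expression: pd.DataFrame,
    signature: Sequence[str],
    n_background: int = 100,
) -> pd.Series:
    """Background-corrected signature score per cell.

    ``expression`` is genes × cells. Per signature gene the mean expression of
    its matched background genes is subtracted cell-wise; the score is the sum
    of corrected values over the signature. Invariant to adding a constant to
    the whole matrix.
    """
    gene_means = expression.mean(axis=1)
    backgrounds = match_background_genes(gene_means, signature, n_background)
    score = pd.Series(0.0, index=expression.columns, name="score")
    for g, bg in backgrounds.items():
        score += expression.loc[g] - expression.loc[bg].mean(axis=0)
    return score


CNA_CATEGORIES = ("deletion", "loss", "no_change", "gain", "amplification")


def classify_cna(x: float) -> str:
    """Copy-number category from a processed log-ratio value.

    deletion: x < -1; loss: -1 ≤ x < -0.2; no change: -0.2 ≤ x ≤ 0.2;
    gain: 0.2 < x ≤ 1; amplification: x > 1. The printed thresholds are open
    intervals; boundary values go to the lower-magnitude class.
    """
    if not np.isfinite(x):
        raise ValueError(f"copy-number value must be finite, got {x!r}")
    if x < -1:
        return "deletion"
    if x < -0.2:
        return "loss"
    if x <= 0.2:
        return "no_change"
    if x <= 1:
        return "gain"
    return "amplification"
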