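"""Canonical synthetic scenarios and their evaluation routines.

Each scenario fixes the simulated study conditions — cohort sizes, planted
effect sizes, noise levels — at the values the pipeline is expected to work
under, runs the corresponding pipeline stage and measures recovery of the
planted truth. They back both the recovery test suite and the reproduction
script; the parameters here are the scenario definitions and are not meant to
be tuned per run (only the seed varies).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import enrichment as enr
from . import segmentation as seg
from . import simulate as sim
from . import superenhancer as se_mod
from .activity import assign_mr_subtype, cell_subtype_score, signature_score
from .simulate import SUBTYPES


def methylome_scenario(seed: int) -> sim.SimMethylomeConfig:
    """A 2 Mb four-subtype WGBS cohort (~20,000 CpGs) with a sharing design.

    Per feature class, 60 % of the planted width is present in all four
    subtypes, 20 % in two and 20 % in one, so both feature recovery and
    subtype-sharing fractions have known truth. 3 samples per subtype, beta
    noise SD 0.05, mean coverage 10.
    """
    two = tuple(SUBTYPES[:2])
    one = (SUBTYPES[0],)
    rows = []
    pos = 30_000

    def add(cls, width, mean, subtypes, count):
        nonlocal pos
        for _ in range(count):
            rows.append(("chr1", pos, pos + width, cls, mean, subtypes))
            pos += width + 30_000

    add("DMV", 8_000, 0.05, "all", 3)
    add("DMV", 8_000, 0.05, two, 1)
    add("DMV", 8_000, 0.05, one, 1)
    add("LMR", 2_000, 0.10, "all", 6)
    add("LMR", 2_000, 0.10, two, 2)
    add("LMR", 2_000, 0.10, one, 2)
    add("PMD", 60_000, 0.50, "all", 3)
    add("PMD", 60_000, 0.50, two, 1)
    add("PMD", 60_000, 0.50, one, 1)
    planted = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cls", "mean_beta", "subtypes"]
    )
    return sim.SimMethylomeConfig(
        chrom_lengths={"chr1": 2_000_000},
        planted_features=planted,
        cpg_spacing_mean=100,
        n_subtypes=4,
        samples_per_subtype=3,
        baseline_beta=0.8,
        beta_noise_sd=0.05,
        coverage_mean=10.0,
        seed=seed,
    )


SHARING_TRUTH = {1: 0.2, 2: 0.2, 3: 0.0, 4: 0.6}


def run_methylome_recovery(seed: int) -> dict:
    """Segment the canonical cohort; per-class recovery Jaccard and sharing."""
    cfg = methylome_scenario(seed)
    tables, truth = sim.gen_methylome_cohort(cfg)
    params = seg.SegmentationParams()
    calls = {
        s: seg.call_features(seg.segment_methylome(t, params), params)
        for s, t in tables.items()
    }
    jac = []
    for sample, feats in calls.items():
        t = truth.features[truth.features["sample"] == sample]
        scores = seg.recovery_jaccard(t, feats)
        jac.append(pd.DataFrame({"cls": t["cls"].to_numpy(), "jaccard": scores.to_numpy()}))
    per_class = pd.concat(jac).groupby("cls")["jaccard"].mean()

    labels = {s: s.rsplit("_", 1)[0] for s in tables}
    consensus = seg.consensus_features(calls, "subtype_fraction", params, labels)
    sharing = {}
    for cls in ("DMV", "LMR", "PMD"):
        per_subtype = {
            st: consensus[(consensus["cls"] == cls) & (consensus["subtype"] == st)]
            for st in SUBTYPES
        }
        sharing[cls] = seg.sharing_fractions(per_subtype)
    return {"recovery": per_class, "sharing": sharing}


def enrichment_genome(seed: int, length: int = 1_000_000):
    """A toy genome: CpG sites, a two-state annotation and its enhancer state."""
    rng = np.random.default_rng(seed)
    gaps = rng.geometric(1 / 100, size=int(length / 100 * 1.3))
    pos = np.cumsum(gaps)
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos[pos < length]})
    states = sim.gen_state_annotation(
        {"chr1": length}, {"E09": 0.3, "E18": 0.7}, segment_mean_len=3_000, seed=seed
    )
    e09 = states.loc[states["state"] == "E09", ["chrom", "start", "end"]]
    return sites, states, e09


def run_null_calibration(
    seed: int, n_replicates: int = 100, n_perm: int = 200, n_features: int = 30
) -> dict:
    """Features drawn from the matched background: z and empirical p nulls."""
    sites, _, e09 = enrichment_genome(seed)
    rng = np.random.default_rng(seed + 1)
    anchor = enr.place_features(
        np.full(n_features, 1_500), pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [1_000_000]}
        ), rng,
    )
    bg = enr.build_matched_background(anchor, {"chr1": 1_000_000}, sites)
    zs, ps = [], []
    for rep in range(n_replicates):
        feats = enr.place_features(np.full(n_features, 1_500), bg.windows, rng)
        res = enr.permutation_enrichment(
            feats, e09, bg, n_perm=n_perm, seed=seed + 10_000 + rep
        )
        zs.append(res.z)
        ps.append(res.p_emp)
    ks = stats.kstest(ps, "uniform")
    return {"mean_z": float(np.mean(zs)), "ks_p": float(ks.pvalue),
            "z": np.array(zs), "p": np.array(ps)}


def run_enrichment_power(seed: int, n_perm: int = 1_000) -> enr.EnrichmentResult:
    """Features planted inside the enhancer state: large positive enrichment."""
    sites, _, e09 = enrichment_genome(seed)
    wide = e09[(e09["end"] - e09["start"]) >= 2_000]
    feats = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": wide["start"].to_numpy()[:40],
            "end": wide["start"].to_numpy()[:40] + 1_500,
        }
    )
    bg = enr.build_matched_background(feats, {"chr1": 1_000_000}, sites)
    return enr.permutation_enrichment(feats, e09, bg, n_perm=n_perm, seed=seed + 2)


def run_se_target_recovery(seed: int) -> dict:
    """Planted SE→gene links at rho 0.9, 40 samples, 10 candidates per SE."""
    data, truth = sim.gen_se_cohort(
        n_ses=20, n_genes=200, samples_per_subtype=10, tad_count=10,
        effect_logfc=1.5, rho_target=0.9, seed=seed,
    )
    hits = 0
    for _, row in data["ses"].iterrows():
        res = se_mod.assign_se_target(
            row, data["signal"].loc[row["se_id"]], data["expression"],
            data["genes"], data["tads"],
        )
        hits += res is not None and res["gene_id"] == truth.se_targets[row["se_id"]]
    return {"recovered": hits, "total": len(data["ses"]),
            "fraction": hits / len(data["ses"])}


def run_mr_assignment(seed: int, effect_sd: float = 1.5) -> dict:
    """MR subtype assignment accuracy on a 500-sample activity matrix."""
    mat, truth = sim.gen_activity_matrix(
        mrs_per_subtype=25, samples_per_subtype=125, effect_sd=effect_sd, seed=seed
    )
    labels = {s: s.rsplit("_", 1)[0] for s in mat.columns}
    out = assign_mr_subtype(mat, labels)
    correct = sum(out.loc[m, "subtype"] == st for m, st in truth.mr_subtype.items())
    counts = out["subtype"].value_counts()
    return {
        "accuracy": correct / len(truth.mr_subtype),
        "n_mrs": len(truth.mr_subtype),
        "assignment_counts": counts,
    }


def run_cell_calls(seed: int, effect_sd: float = 1.5) -> dict:
    """Per-cell subtype call accuracy from a planted activity matrix."""
    mat, truth = sim.gen_activity_matrix(
        mrs_per_subtype=10, samples_per_subtype=125, effect_sd=effect_sd, seed=seed
    )
    out = cell_subtype_score(mat, truth.mr_subtype)
    true_labels = pd.Series({c: c.rsplit("_", 1)[0] for c in mat.columns})
    return {"accuracy": float((out["call"] == true_labels).mean()), "n_cells": mat.shape[1]}


def run_signature_scoring(seed: int) -> dict:
    """AUROC of the matched-background signature score at a 1 SD planted shift."""
    expr, truth = sim.gen_sc_expression(
        n_cells=500, n_genes=2_000, signature_size=30, shift=1.0,
        positive_fraction=0.5, seed=seed,
    )
    score = signature_score(expr, truth.signature_genes)
    pos = score.index.isin(truth.signature_positive_cells)
    u = stats.mannwhitneyu(score[pos], score[~pos], alternative="greater")
    auroc = u.statistic / (pos.sum() * (~pos).sum())
    shifted = signature_score(expr + 7.25, truth.signature_genes)
    return {
        "auroc": float(auroc),
        "n_cells": len(score),
        "max_shift_effect": float(np.abs(score - shifted).max()),
    }
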