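"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generators emulate the shapes of the real inputs — per-subtype WGBS
methylomes, ChromHMM-style state annotations, an H3K27ac superenhancer cohort
with TADs and expression, MR activity matrices and single-cell expression —
with effects planted where the downstream detectors should find them. No
published noise model exists for any of these data types, so the
distributional choices (censored-Gaussian beta noise, negative-binomial
coverage, geometric CpG spacing, log-normal H3K27ac signal) are deliberately
simple and configurable; see the methods note for what they do and do not
emulate.

Determinism: every generator consumes a single numpy Generator seeded from
its config, so identical configuration and seed reproduce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("IDH", "MES", "RTK_I", "RTK_II")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside synthetic data.

    Only the fields relevant to the emitting generator are populated.
    """

    features: pd.DataFrame | None = None          # sample, chrom, start, end, cls
    se_targets: dict[str, str] = field(default_factory=dict)
    subtype_se: dict[str, str] = field(default_factory=dict)
    mr_subtype: dict[str, str] = field(default_factory=dict)
    signature_genes: list[str] = field(default_factory=list)
    signature_positive_cells: set[str] = field(default_factory=set)


def _subtype_names(n: int) -> list[str]:
    if n <= len(SUBTYPES):
        return list(SUBTYPES[:n])
    return list(SUBTYPES) + [f"ST{i}" for i in range(len(SUBTYPES), n)]


# ---------------------------------------------------------------------------
# methylome cohort

@dataclass
class SimMethylomeConfig:
    """Configuration of the WGBS cohort generator.

    planted_features rows need chrom, start, end, cls (DMV/LMR/PMD),
    mean_beta and subtypes (iterable of subtype names, or "all").
    """

    chrom_lengths: Mapping[str, int]
    planted_features: pd.DataFrame
    cpg_spacing_mean: int = 100
    n_subtypes: int = 4
    samples_per_subtype: int = 3
    baseline_beta: float = 0.8
    beta_noise_sd: float = 0.05
    coverage_mean: float = 10.0
    coverage_dispersion: float = 0.3
    pmd_within_sd: float = 0.12   # per-CpG spread of planted PMD means
    noise_model: str = "truncnorm"  # or "beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.noise_model not in ("truncnorm", "beta"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        pf = self.planted_features
        for row in pf.itertuples():
            if row.chrom not in self.chrom_lengths:
                raise ValueError(f"planted interval on unknown chromosome {row.chrom}")
            if row.start < 0 or row.end > self.chrom_lengths[row.chrom]:
                raise ValueError(
                    f"planted {row.cls} {row.chrom}:{row.start}-{row.end} lies "
                    f"outside the chromosome (length {self.chrom_lengths[row.chrom]})"
                )
        # same-class planted intervals sharing a subtype must not overlap
        for cls, grp in pf.groupby("cls"):
            g = grp.sort_values(["chrom", "start"])
            prev = None
            for row in g.itertuples():
                if (
                    prev is not None
                    and row.chrom == prev.chrom
                    and row.start < prev.end
                    and _subtype_overlap(row.subtypes, prev.subtypes, self.n_subtypes)
                ):
                    raise ValueError(
                        f"overlapping planted {cls} intervals "
                        f"{prev.chrom}:{prev.start}-{prev.end} and "
                        f"{row.chrom}:{row.start}-{row.end}"
                    )
                prev = row


def _subtype_overlap(a, b, n: int) -> bool:
    names = set(_subtype_names(n))
    sa = names if (isinstance(a, str) and a == "all") else set(a)
    sb = names if (isinstance(b, str) and b == "all") else set(b)
    return bool(sa & sb)


def _place_cpgs(length: int, spacing_mean: int, rng: np.random.Generator) -> np.ndarray:
    # geometric inter-CpG gaps; draw a safety margin then trim to the chromosome
    n_draw = int(length / spacing_mean * 1.5) + 50
    gaps = rng.geometric(1.0 / spacing_mean, size=n_draw)
    pos = np.cumsum(gaps)
    while pos[-1] < length:
        extra = rng.geometric(1.0 / spacing_mean, size=n_draw)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos < length].astype(np.int64)


def _beta_noise(
    target: np.ndarray, sd: float, model: str, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return target.copy()
    if model == "truncnorm":
        return np.clip(target + rng.normal(0.0, sd, size=target.shape), 0.0, 1.0)
    # beta noise: match mean and (approximately) sd via the method of moments
    t = np.clip(target, 1e-3, 1 - 1e-3)
    var = min(sd**2, 0.24)
    k = np.maximum(t * (1 - t) / var - 1, 1e-2)
    return rng.beta(t * k, (1 - t) * k)


def gen_methylome_cohort(
    cfg: SimMethylomeConfig,
) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Per-sample CpG methylation tables with planted DMV/LMR/PMD features.

    CpG positions are shared across the cohort (they are positions in one
    genome); betas and coverage are per sample. Returns bedGraph-like frames
    (chrom, start, end, beta, coverage) keyed by sample id, plus the truth
    table listing every planted feature in every sample of its subtypes.
    """
    rng = np.random.default_rng(cfg.seed)
    subtypes = _subtype_names(cfg.n_subtypes)
    samples = {
        f"{st}_{i + 1}": st
        for st in subtypes
        for i in range(cfg.samples_per_subtype)
    }
    positions = {
        chrom: _place_cpgs(int(length), cfg.cpg_spacing_mean, rng)
        for chrom, length in sorted(cfg.chrom_lengths.items())
    }

    r = 1.0 / cfg.coverage_dispersion if cfg.coverage_dispersion > 0 else None
    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for sample, st in samples.items():
        chrom_frames = []
        for chrom, pos in positions.items():
            target = np.full(len(pos), cfg.baseline_beta)
            for feat in cfg.planted_features.itertuples():
                if feat.chrom != chrom:
                    continue
                applies = (
                    isinstance(feat.subtypes, str) and feat.subtypes == "all"
                ) or st in feat.subtypes
                if not applies:
                    continue
                inside = (pos >= feat.start) & (pos < feat.end)
                if feat.cls == "PMD":
                    # PMDs are disordered: per-CpG means scatter around the target
                    target[inside] = np.clip(
                        rng.normal(feat.mean_beta, cfg.pmd_within_sd, inside.sum()),
                        0.02, 0.98,
                    )
                else:
                    target[inside] = feat.mean_beta
            beta = _beta_noise(target, cfg.beta_noise_sd, cfg.noise_model, rng)
            if r is not None:
                cov = rng.negative_binomial(r, r / (r + cfg.coverage_mean), len(pos))
            else:
                cov = rng.poisson(cfg.coverage_mean, len(pos))
            chrom_frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": pos, "end": pos + 1,
                     "beta": beta, "coverage": cov}
                )
            )
        tables[sample] = pd.concat(chrom_frames, ignore_index=True)
        for feat in cfg.planted_features.itertuples():
            applies = (
                isinstance(feat.subtypes, str) and feat.subtypes == "all"
            ) or st in feat.subtypes
            if applies:
                truth_rows.append(
                    (sample, st, feat.chrom, feat.start, feat.end, feat.cls)
                )
    truth = PlantedTruth(
        features=pd.DataFrame(
            truth_rows, columns=["sample", "subtype", "chrom", "start", "end", "cls"]
        )
    )
    return tables, truth


# ---------------------------------------------------------------------------
# chromatin-state annotation

def gen_state_annotation(
    chrom_lengths: Mapping[str, int],
    state_proportions: Mapping[str, float],
    segment_mean_len: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile each chromosome with state segments at the requested proportions.

    Segment lengths are geometric with the given mean; states are drawn iid
    with the given probabilities, so realised bp fractions converge on the
    requested proportions for long chromosomes.
    """
    states = sorted(state_proportions)
    probs = np.array([state_proportions[s] for s in states], dtype=float)
    if (probs < 0).any():
        raise ValueError("state proportions must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"state proportions sum to {probs.sum()}, not 1")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        pos = 0
        while pos < length:
            seg = int(rng.geometric(1.0 / segment_mean_len))
            end = min(pos + seg, int(length))
            state = states[rng.choice(len(states), p=probs)]
            rows.append((chrom, pos, end, state))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


# ---------------------------------------------------------------------------
# superenhancer cohort

def gen_se_cohort(
    n_ses: int = 40,
    n_genes: int = 400,
    samples_per_subtype: int = 10,
    tad_count: int = 10,
    effect_logfc: float = 1.5,
    rho_target: float = 0.9,
    seed: int = 0,
    se_width: int = 20_000,
    tad_width: int = 1_000_000,
    signal_log_sd: float = 1.0,
) -> tuple[dict, PlantedTruth]:
    """SE intervals + signal, TAD-resident gene models, expression, truth.

    Each SE sits in one TAD with its planted target gene within 500 kb; the
    remaining genes are decoy candidates in the same windows. H3K27ac signal
    is log-normal; when ``effect_logfc`` > 0, SEs are assigned subtypes
    round-robin and shifted by that log2 fold change in their subtype's
    samples. Target-gene expression follows the SE's (standardised) log
    signal with latent correlation ``rho_target``; decoys are independent.
    """
    if tad_count < 1:
        raise ValueError("tad_count must be at least 1")
    if n_genes < n_ses:
        raise ValueError("need at least one gene per SE")
    rng = np.random.default_rng(seed)
    subtypes = _subtype_names(4)
    samples = [f"{st}_{i + 1}" for st in subtypes for i in range(samples_per_subtype)]
    labels = {s: s.rsplit("_", 1)[0] for s in samples}

    tads = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(tad_count) * tad_width,
            "end": (np.arange(tad_count) + 1) * tad_width,
            "tad_id": [f"TAD{i:03d}" for i in range(tad_count)],
        }
    )
    # geometry: each SE owns a block holding itself plus its gene neighbourhood
    decoys_per_se = (n_genes - n_ses) // n_ses
    leftover = (n_genes - n_ses) % n_ses
    max_gene_offset = 60_000 + max(decoys_per_se + (1 if leftover else 0) - 1, 0) * 9_000
    if max_gene_offset > 450_000:
        raise ValueError("too many candidate genes per SE to stay within 500 kb")
    block = se_width + max_gene_offset + 20_000
    slots_per_tad = -(-n_ses // tad_count)  # ceil
    if 20_000 + slots_per_tad * block > tad_width:
        raise ValueError("too many SEs per TAD for the chosen widths")
    se_rows, gene_rows = [], []
    per_tad: dict[int, int] = {}
    for i in range(n_ses):
        tad = i % tad_count
        slot = per_tad.get(tad, 0)
        per_tad[tad] = slot + 1
        start = tad * tad_width + 20_000 + slot * block
        se_rows.append(("chr1", start, start + se_width, f"SE{i:03d}", f"TAD{tad:03d}"))
    ses = pd.DataFrame(se_rows, columns=["chrom", "start", "end", "se_id", "tad_id"])
    gid = 0
    se_targets: dict[str, str] = {}
    for i, se in enumerate(ses.itertuples()):
        tss = se.end + 40_000
        gene_rows.append((f"G{gid:04d}", "chr1", tss, se.tad_id, False))
        se_targets[se.se_id] = f"G{gid:04d}"
        gid += 1
        n_dec = decoys_per_se + (1 if i < leftover else 0)
        for j in range(n_dec):
            gene_rows.append(
                (f"G{gid:04d}", "chr1", se.end + 60_000 + j * 9_000, se.tad_id, False)
            )
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "tad_id", "is_tf"])

    subtype_se: dict[str, str] = {}
    if effect_logfc > 0:
        subtype_se = {
            se_id: subtypes[i % len(subtypes)] for i, se_id in enumerate(ses["se_id"])
        }

    label_arr = np.array([labels[s] for s in samples])
    base = rng.normal(5.0, 1.0, n_ses)
    log_sig = base[:, None] + rng.normal(0.0, signal_log_sd, (n_ses, len(samples)))
    for i, se_id in enumerate(ses["se_id"]):
        if se_id in subtype_se:
            log_sig[i, label_arr == subtype_se[se_id]] += effect_logfc
    signal = pd.DataFrame(2.0**log_sig, index=ses["se_id"], columns=samples)

    gene_base = rng.uniform(2.0, 8.0, len(genes))
    expr = gene_base[:, None] + rng.normal(0.0, 1.0, (len(genes), len(samples)))
    gene_index = {g: k for k, g in enumerate(genes["gene_id"])}
    for i, se_id in enumerate(ses["se_id"]):
        t = log_sig[i]
        t_std = (t - t.mean()) / t.std()
        eps = rng.normal(0.0, 1.0, len(samples))
        k = gene_index[se_targets[se_id]]
        expr[k] = gene_base[k] + rho_target * t_std + np.sqrt(
            max(1.0 - rho_target**2, 0.0)
        ) * eps
    expression = pd.DataFrame(expr, index=genes["gene_id"], columns=samples)

    data = {
        "ses": ses,
        "signal": signal,
        "genes": genes,
        "tads": tads,
        "expression": expression,
        "sample_subtypes": labels,
    }
    truth = PlantedTruth(se_targets=se_targets, subtype_se=subtype_se)
    return data, truth


# ---------------------------------------------------------------------------
# MR activity

def gen_activity_matrix(
    mrs_per_subtype: int = 10,
    samples_per_subtype: int = 25,
    effect_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """MR × sample activity with a planted subtype shift per MR.

    Background is standard normal; each MR's activity is raised by
    ``effect_sd`` (in SD units) in the samples of its planted subtype.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be non-negative")
    rng = np.random.default_rng(seed)
    subtypes = _subtype_names(4)
    samples = [f"{st}_{i + 1}" for st in subtypes for i in range(samples_per_subtype)]
    label_arr = np.array([s.rsplit("_", 1)[0] for s in samples])
    mrs = [f"MR_{st}_{i + 1}" for st in subtypes for i in range(mrs_per_subtype)]
    planted = {mr: mr.split("_", 1)[1].rsplit("_", 1)[0] for mr in mrs}

    mat = rng.normal(0.0, 1.0, (len(mrs), len(samples)))
    for i, mr in enumerate(mrs):
        mat[i, label_arr == planted[mr]] += effect_sd
    activity = pd.DataFrame(mat, index=mrs, columns=samples)
    return activity, PlantedTruth(mr_subtype=planted)


# ---------------------------------------------------------------------------
# single-cell expression

def gen_sc_expression(
    n_cells: int = 500,
    n_genes: int = 2_000,
    signature_size: int = 30,
    shift: float = 1.0,
    positive_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Log-scale single-cell expression with a planted signature shift.

    Gene baselines are uniform on [2, 8]; per-cell noise is standard normal;
    signature genes gain ``shift`` in the truth-positive cells.
    """
    if signature_size > n_genes:
        raise ValueError("signature_size cannot exceed n_genes")
    if not (0 < positive_fraction < 1):
        raise ValueError("positive_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    baseline = rng.uniform(2.0, 8.0, n_genes)
    expr = baseline[:, None] + rng.normal(0.0, 1.0, (n_genes, n_cells))
    sig_idx = rng.choice(n_genes, size=signature_size, replace=False)
    n_pos = int(round(positive_fraction * n_cells))
    pos_idx = rng.choice(n_cells, size=n_pos, replace=False)
    expr[np.ix_(sig_idx, pos_idx)] += shift
    truth = PlantedTruth(
        signature_genes=[genes[i] for i in sorted(sig_idx)],
        signature_positive_cells={cells[i] for i in sorted(pos_idx)},
    )
    return pd.DataFrame(expr, index=genes, columns=cells), truth
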