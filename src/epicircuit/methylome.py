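"""CpG methylation tables: strand merging, cohort assembly and site filters.

A WGBS caller reports the two cytosines of a CpG dinucleotide separately (one
per strand). Downstream segmentation works on the merged dinucleotide unit,
with the methylation level combined as a coverage-weighted mean

    m = (m1*c1 + m2*c2) / (c1 + c2)

and the merged coverage as the self-weighted mean

    c = (c1^2 + c2^2) / (c1 + c2).

Cohort-level filters drop CpGs overlapping common variants (minor allele
frequency above 0.25) and CpGs with 2 or fewer reads in more than half of the
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BEDGRAPH_COLS = ["chrom", "start", "end", "beta", "coverage"]


@dataclass(frozen=True)
class StrandedCpGPair:
    """The two cytosines of one CpG dinucleotide; either strand may be absent."""

    chrom: str
    pos: int  # 0-based position of the forward-strand C
    m1: float | None = None  # forward methylation level in [0, 1]
    c1: int = 0
    m2: float | None = None  # reverse methylation level in [0, 1]
    c2: int = 0


@dataclass(frozen=True)
class CpGDinucleotide:
    chrom: str
    pos: int
    m: float  # nan when no covered strand
    c: float  # merged coverage; may be non-integer


def merge_strand_cpgs(pairs: Sequence[StrandedCpGPair]) -> list[CpGDinucleotide]:
    """Merge per-strand CpG records into dinucleotide units.

    Single-strand records pass through unchanged; records with zero total
    coverage are emitted with c = 0 and m = nan (missing).
    """
    out: list[CpGDinucleotide] = []
    for p in pairs:
        for label, m, c in (("forward", p.m1, p.c1), ("reverse", p.m2, p.c2)):
            if c < 0 or int(c) != c:
                raise ValueError(f"{p.chrom}:{p.pos}: {label} coverage {c} invalid")
            if m is not None and not (0.0 <= m <= 1.0):
                raise ValueError(
                    f"{p.chrom}:{p.pos}: {label} methylation level {m} outside [0, 1]"
                )
        c1 = p.c1 if p.m1 is not None else 0
        c2 = p.c2 if p.m2 is not None else 0
        total = c1 + c2
        if total == 0:
            out.append(CpGDinucleotide(p.chrom, p.pos, float("nan"), 0.0))
            continue
        if c1 == 0 or c2 == 0:
            m, c = (p.m1, c1) if c1 > 0 else (p.m2, c2)
            out.append(CpGDinucleotide(p.chrom, p.pos, float(m), float(c)))
            continue
        m = (p.m1 * c1 + p.m2 * c2) / total
        c = (c1 * c1 + c2 * c2) / total
        out.append(CpGDinucleotide(p.chrom, p.pos, m, c))
    return out


@dataclass
class CohortMethylome:
    """Merged CpG methylation for a labelled sample cohort.

    sites    : DataFrame (chrom, pos) — the shared, ordered CpG site list
    beta     : array samples × sites, nan where missing
    coverage : array samples × sites
    samples  : sample ids (rows of the matrices)
    subtypes : per-sample subtype label, aligned with samples
    """

    sites: pd.DataFrame
    beta: np.ndarray
    coverage: np.ndarray
    samples: list[str]
    subtypes: list[str]

    def __post_init__(self) -> None:
        n_s, n_c = self.beta.shape
        if self.coverage.shape != (n_s, n_c):
            raise ValueError("beta and coverage matrices are not congruent")
        if len(self.sites) != n_c:
            raise ValueError("site list does not match matrix columns")
        if len(self.samples) != n_s or len(self.subtypes) != n_s:
            raise ValueError("sample/subtype labels do not match matrix rows")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.beta)

    def subset_sites(self, keep: np.ndarray) -> "CohortMethylome":
        return CohortMethylome(
            sites=self.sites.loc[keep].reset_index(drop=True),
            beta=self.beta[:, keep],
            coverage=self.coverage[:, keep],
            samples=list(self.samples),
            subtypes=list(self.subtypes),
        )

    def sample_table(self, sample: str) -> pd.DataFrame:
        """One sample's sites as a bedGraph-style table (covered sites only)."""
        i = self.samples.index(sample)
        keep = ~np.isnan(self.beta[i])
        df = self.sites.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "beta": self.beta[i, keep],
                "coverage": self.coverage[i, keep],
            }
        )


def cohort_from_tables(
    tables: Mapping[str, pd.DataFrame], subtypes: Mapping[str, str]
) -> CohortMethylome:
    """Assemble a cohort from per-sample bedGraph-like tables.

    Sites absent from a sample are recorded as missing (beta nan, coverage 0).
    """
    samples = sorted(tables)
    unknown = [s for s in samples if s not in subtypes]
    if unknown:
        raise ValueError(f"samples without subtype label: {unknown}")
    all_sites = (
        pd.concat(
            [t[["chrom", "start"]].rename(columns={"start": "pos"}) for t in tables.values()]
        )
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    key = {(c, p): i for i, (c, p) in enumerate(zip(all_sites["chrom"], all_sites["pos"]))}
    beta = np.full((len(samples), len(all_sites)), np.nan)
    cov = np.zeros((len(samples), len(all_sites)))
    for si, s in enumerate(samples):
        t = tables[s]
        idx = np.fromiter((key[(c, p)] for c, p in zip(t["chrom"], t["start"])), dtype=int)
        beta[si, idx] = t["beta"].to_numpy(dtype=float)
        cov[si, idx] = t["coverage"].to_numpy(dtype=float)
    return CohortMethylome(all_sites, beta, cov, samples, [subtypes[s] for s in samples])


def filter_variant_cpgs(
    cohort: CohortMethylome, mask: pd.DataFrame, maf_threshold: float = 0.25
) -> CohortMethylome:
    """Remove CpGs overlapping variant intervals with MAF strictly above threshold.

    ``mask`` has columns chrom, start, end, maf (0-based half-open).
    """
    if len(mask) == 0:
        return cohort.subset_sites(np.ones(len(cohort.sites), dtype=bool))
    bad = mask[mask["maf"] > maf_threshold]
    keep = np.ones(len(cohort.sites), dtype=bool)
    for chrom, grp in bad.groupby("chrom"):
        s = np.sort(grp["start"].to_numpy())
        e_sorted = grp.sort_values("start")["end"].to_numpy()
        sel = cohort.sites["chrom"] == chrom
        pos = cohort.sites.loc[sel, "pos"].to_numpy()
        i = np.searchsorted(s, pos, side="right") - 1
        inside = (i >= 0) & (pos < e_sorted[np.maximum(i, 0)])
        keep[np.flatnonzero(sel.to_numpy())[inside]] = False
    return cohort.subset_sites(keep)


def filter_low_coverage(
    cohort: CohortMethylome, min_reads: int = 3, max_low_fraction: float = 0.5
) -> CohortMethylome:
    """Drop sites under-covered in most of the cohort.

    A site is removed when its coverage is below ``min_reads`` (i.e. 2 or fewer
    reads at the default) in strictly more than ``max_low_fraction`` of samples.
    """
    low = cohort.coverage < min_reads
    frac_low = low.mean(axis=0)
    return cohort.subset_sites(frac_low <= max_low_fraction)


# ---------------------------------------------------------------------------
# file round-trip

def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BEDGRAPH_COLS)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=BEDGRAPH_COLS, float_format="%.6f")


def read_stranded_report(path, one_based: bool = False) -> list[StrandedCpGPair]:
    """Read a cytosine-report style TSV: chrom, pos, strand, level, coverage.

    Forward/reverse records at pos/pos+1 are paired into StrandedCpGPair units.
    ``one_based`` shifts input positions down by one.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "strand", "level", "coverage"])
    if one_based:
        df["pos"] = df["pos"] - 1
    pairs: dict[tuple[str, int], dict] = {}
    for row in df.itertuples(index=False):
        if row.strand == "+":
            key = (row.chrom, int(row.pos))
            pairs.setdefault(key, {})["fwd"] = (float(row.level), int(row.coverage))
        elif row.strand == "-":
            key = (row.chrom, int(row.pos) - 1)
            pairs.setdefault(key, {})["rev"] = (float(row.level), int(row.coverage))
        else:
            raise ValueError(f"unknown strand {row.strand!r} at {row.chrom}:{row.pos}")
    out = []
    for (chrom, pos), d in sorted(pairs.items()):
        fwd = d.get("fwd")
        rev = d.get("rev")
        out.append(
            StrandedCpGPair(
                chrom, pos,
                m1=fwd[0] if fwd else None, c1=fwd[1] if fwd else 0,
                m2=rev[0] if rev else None, c2=rev[1] if rev else 0,
            )
        )
    return out
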