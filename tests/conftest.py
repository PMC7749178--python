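"""Shared fixtures and per-base bitset oracles.

The oracles realise interval sets as boolean arrays over a toy chromosome and
compute overlap statistics by direct counting; they are deliberately naive and
independent of the package's interval arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def bitset(df: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    """Per-base occupancy of one chromosome as a boolean array."""
    mask = np.zeros(length, dtype=bool)
    for row in df[df["chrom"] == chrom].itertuples():
        mask[row.start:row.end] = True
    return mask


def bitset_counts(dfs: list[pd.DataFrame], chrom: str, length: int) -> np.ndarray:
    """Per-base support counts over a stack of interval sets."""
    counts = np.zeros(length, dtype=int)
    for df in dfs:
        counts += bitset(df, chrom, length)
    return counts


def oracle_jaccard(a: pd.DataFrame, b: pd.DataFrame, chroms: dict[str, int]) -> float:
    inter = union = 0
    for chrom, length in chroms.items():
        ma, mb = bitset(a, chrom, length), bitset(b, chrom, length)
        inter += int((ma & mb).sum())
        union += int((ma | mb).sum())
    return inter / union


def random_intervals(
    rng: np.random.Generator, n: int, length: int, max_width: int, chrom: str = "chr1"
) -> pd.DataFrame:
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + widths})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)
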