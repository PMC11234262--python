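"""Mendelian segregation tests on phenotype/abortion counts.

A cross segregating a fully recessive embryo-lethal combination is
expected to abort ~25% of seeds; observed counts are tested against the
expected fraction with the exact two-sided binomial test
(minimum-likelihood summation convention).  Reported class frequencies
use half-up integer rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = ["CrossCounts", "SegregationResult", "class_frequency",
           "segregation_test", "segregation_table"]


@dataclass(frozen=True)
class CrossCounts:
    label: str
    n_affected: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= self.n_affected <= self.n_total):
            raise ValueError("n_affected must be in [0, n_total]")


@dataclass(frozen=True)
class SegregationResult:
    label: str
    n_affected: int
    n_total: int
    observed_frac: float
    expected_frac: float
    p_value: float


def class_frequency(k: int, n: int) -> int:
    """Percentage k/n rounded half-up to an integer (e.g. 20/29 -> 69)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must be in [0, n]")
    return int(math.floor(100.0 * k / n + 0.5))


def segregation_test(c: CrossCounts, expected_frac: float = 0.25) -> SegregationResult:
    """Exact two-sided binomial test of the observed affected fraction.

    The p-value sums all outcomes at most as probable as the observed count
    under Binomial(n_total, expected_frac)."""
    if not (0 < expected_frac < 1):
        raise ValueError("expected_frac must be in (0, 1)")
    p = stats.binomtest(
        c.n_affected, c.n_total, expected_frac, alternative="two-sided"
    ).pvalue
    return SegregationResult(
        label=c.label,
        n_affected=c.n_affected,
        n_total=c.n_total,
        observed_frac=c.n_affected / c.n_total,
        expected_frac=expected_frac,
        p_value=float(min(1.0, p)),
    )


def segregation_table(
    counts: list[CrossCounts], expected_frac: float = 0.25
) -> pd.DataFrame:
    return pd.DataFrame(
        [segregation_test(c, expected_frac).__dict__ for c in counts]
    )


def read_cross_counts(path: str | Path) -> list[CrossCounts]:
    """Read a TSV with columns label, n_affected, n_total."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "n_affected", "n_total"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return [
        CrossCounts(str(r.label), int(r.n_affected), int(r.n_total))
        for r in df.itertuples(index=False)
    ]
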