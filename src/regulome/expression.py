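"""Expression matrices, replicate averaging and expressed-gene flagging.

Datasets arrive pre-normalized (TPM for bulk, TP10k or probabilistically
normalized counts for single cells).  A gene is flagged *expressed* in a
sample when its linear-scale value strictly exceeds the unit's threshold;
thresholding in linear space is identical to the log-space statement of the
rule (log10 TPM > 0.75 etc.) but needs no pseudocount for zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "ExpressedFlagConfig",
    "average_replicates",
    "flag_expressed",
    "union_expressed",
    "cumulative_expression",
    "expressed_genes",
]


class Unit(str, Enum):
    TPM = "TPM"
    TP10K = "TP10K"
    NORMALIZED_COUNT = "NORMALIZED_COUNT"
    OTHER = "OTHER"


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of non-negative linear-scale values.

    ``replicate_groups`` optionally maps sample -> condition label for
    replicate averaging.
    """

    values: pd.DataFrame
    unit: Unit | str = Unit.OTHER
    replicate_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def value(self, gene: str, sample: str) -> float:
        return float(self.values.at[gene, sample])


# default thresholds, stated in linear scale: log10(TPM) > 0.75,
# log10(TP10k) > 0.1, normalized counts > 5
DEFAULT_THRESHOLDS: dict[Unit, float] = {
    Unit.TPM: 10.0**0.75,
    Unit.TP10K: 10.0**0.1,
    Unit.NORMALIZED_COUNT: 5.0,
}


@dataclass
class ExpressedFlagConfig:
    """Per-unit linear-scale expressed thresholds (strict inequality)."""

    thresholds: dict[Unit, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        self.thresholds = {Unit(k): float(v) for k, v in self.thresholds.items()}
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be strictly positive")

    def threshold_for(self, unit: Unit | str) -> float:
        unit = Unit(unit)
        if unit not in self.thresholds:
            raise ValueError(f"no expressed threshold configured for unit {unit.value}")
        return self.thresholds[unit]


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean of linear-scale values within each replicate group."""
    if m.replicate_groups is None:
        raise ValueError("replicate_groups not defined")
    missing = set(m.replicate_groups) - set(m.samples)
    if missing:
        raise ValueError(f"replicate map names unknown samples: {sorted(missing)}")
    conditions: dict[str, list[str]] = {}
    for sample in m.samples:
        cond = m.replicate_groups.get(sample, sample)
        conditions.setdefault(cond, []).append(sample)
    for cond, samples in conditions.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
    out = pd.DataFrame(
        {cond: m.values[samples].mean(axis=1) for cond, samples in conditions.items()}
    )
    return ExpressionMatrix(out, unit=m.unit)


def flag_expressed(
    m: ExpressionMatrix, cfg: ExpressedFlagConfig | None = None
) -> pd.DataFrame:
    """Boolean genes x samples table: value strictly above the unit threshold."""
    cfg = cfg or ExpressedFlagConfig()
    thr = cfg.threshold_for(m.unit)
    return m.values > thr


def union_expressed(sets: list[set[str]]) -> set[str]:
    """Union of expressed-gene sets (e.g. plants of several ages, concatenated)."""
    if not sets:
        raise ValueError("need at least one gene set")
    return set().union(*sets)


def cumulative_expression(m: ExpressionMatrix, gene_set) -> pd.Series:
    """Per-sample sum of linear-scale expression over the set's genes.

    Genes absent from the matrix are dropped with a logged warning; an empty
    intersection is an error.
    """
    present = [g for g in m.genes if g in set(gene_set)]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    absent = set(gene_set) - set(present)
    if absent:
        logger.warning(
            "%d gene(s) of the set absent from the matrix", len(absent)
        )
    return m.values.loc[present].sum(axis=0)


def expressed_genes(flags: pd.DataFrame, sample: str | None = None) -> set[str]:
    """Genes flagged in the given sample (or in any sample if None)."""
    if sample is None:
        mask = flags.any(axis=1)
    else:
        mask = flags[sample]
    return set(flags.index[mask])
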