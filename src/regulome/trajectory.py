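"""Gene-set expression along single-cell pseudotime.

For a set of genes (e.g. direct TF targets) and its control set, the
per-cell *expressed fraction* is the percentage of the set's genes flagged
in that cell.  Fractions are summarized as binned curves over pseudotime
and contrasted between the k earliest ("stem-like") and k latest
("differentiated") cells with a one-tailed Welch t-test on the same cells'
target vs non-target fractions.  Genes not expressed in at least a minimum
fraction of the early or late reference cells can be removed first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellAnnotation",
    "TrajectoryConfig",
    "ContrastResult",
    "EnrichmentResult",
    "fraction_expressed_per_cell",
    "fraction_expressed",
    "filter_genes_by_group_expression",
    "bin_curve",
    "select_extreme_cells",
    "welch_t_one_tailed",
    "enrichment_over_pseudotime",
    "cells_expressing_fraction",
    "loess_smooth",
]


@dataclass(frozen=True)
class CellAnnotation:
    """One cell's trajectory coordinates: a continuous pseudotime and/or an
    ordinal pseudotime group (e.g. T0..T9), plus an optional lineage label."""

    cell_id: str
    lineage: str | None = None
    pseudotime: float | None = None
    time_group: str | None = None

    def __post_init__(self) -> None:
        if self.pseudotime is None and self.time_group is None:
            raise ValueError(
                f"cell {self.cell_id}: needs pseudotime or time_group"
            )
        if self.pseudotime is not None and self.pseudotime < 0:
            raise ValueError(f"cell {self.cell_id}: negative pseudotime")


@dataclass
class TrajectoryConfig:
    """Parameters of the trajectory analysis.

    The early/late rules serve two purposes: defining the reference cells of
    the minimum-expression gene prefilter, and labelling curve panels.  On
    the group-annotated datasets the rules are group memberships instead of
    pseudotime cutoffs.  Setting both pseudotime cutoffs to None disables
    the prefilter.
    """

    bin_width: float = 0.1
    min_cells_per_bin: int = 2
    early_max_pseudotime: float | None = 1.0
    late_min_pseudotime: float | None = 86.0
    early_groups: frozenset[str] = frozenset({"T0", "T1"})
    late_groups: frozenset[str] = frozenset({"T8", "T9"})
    min_cell_frac: float = 0.10
    k_extreme: int = 10
    loess_span: float = 0.75

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not (0 <= self.min_cell_frac <= 1):
            raise ValueError("min_cell_frac must be in [0, 1]")
        if self.k_extreme < 2:
            raise ValueError("k_extreme must be >= 2")

    def early_cells(self, cells: list[CellAnnotation]) -> list[str]:
        out = [
            c.cell_id
            for c in cells
            if (
                self.early_max_pseudotime is not None
                and c.pseudotime is not None
                and c.pseudotime <= self.early_max_pseudotime
            )
            or (c.time_group is not None and c.time_group in self.early_groups)
        ]
        return out

    def late_cells(self, cells: list[CellAnnotation]) -> list[str]:
        out = [
            c.cell_id
            for c in cells
            if (
                self.late_min_pseudotime is not None
                and c.pseudotime is not None
                and c.pseudotime >= self.late_min_pseudotime
            )
            or (c.time_group is not None and c.time_group in self.late_groups)
        ]
        return out


@dataclass(frozen=True)
class ContrastResult:
    """One-tailed Welch contrast between target and non-target per-cell
    fractions measured on the same k extreme cells."""

    t: float
    df: float
    p: float
    fold: float
    n: int


@dataclass
class EnrichmentResult:
    """Binned expressed-fraction curves plus early/late contrasts."""

    curves: pd.DataFrame  # columns: set_label, bin_mid, mean_pct, n_cells
    per_cell: pd.DataFrame  # columns: cell_id, pseudotime, target_pct, non_target_pct
    early: ContrastResult
    late: ContrastResult | None
    n_targets: int
    n_non_targets: int


def fraction_expressed(flags: pd.DataFrame, gene_set) -> pd.Series:
    """Per-cell percentage of the set's genes flagged (denominator = set
    genes present in the flag table)."""
    present = flags.index.intersection(sorted(set(gene_set)))
    if len(present) == 0:
        raise ValueError("no gene of the set is present in the flag table")
    return 100.0 * flags.loc[present].mean(axis=0)


def fraction_expressed_per_cell(flags: pd.DataFrame, gene_set, cell: str) -> float:
    return float(fraction_expressed(flags, gene_set)[cell])


def filter_genes_by_group_expression(
    flags: pd.DataFrame,
    early_cells: list[str],
    late_cells: list[str],
    min_frac: float = 0.10,
) -> set[str]:
    """Keep genes flagged in at least ``min_frac`` of early OR late cells."""
    if not early_cells or not late_cells:
        raise ValueError("early and late cell groups must both be non-empty")
    early_frac = flags[list(early_cells)].mean(axis=1)
    late_frac = flags[list(late_cells)].mean(axis=1)
    keep = (early_frac >= min_frac) | (late_frac >= min_frac)
    return set(flags.index[keep])


def bin_curve(
    pseudotimes: pd.Series,
    values: pd.Series,
    bin_width: float = 0.1,
    min_cells_per_bin: int = 2,
) -> pd.DataFrame:
    """Mean of ``values`` in half-open pseudotime bins [k*w, (k+1)*w).

    Bins with fewer than ``min_cells_per_bin`` cells are dropped; each
    surviving bin is reported at its midpoint.
    """
    common = pseudotimes.index.intersection(values.index)
    pt = pseudotimes[common].astype(float)
    v = values[common].astype(float)
    if len(common) == 0:
        raise ValueError("no cells shared between pseudotimes and values")
    idx = np.floor(pt.to_numpy() / bin_width).astype(int)
    df = pd.DataFrame({"bin": idx, "value": v.to_numpy()})
    grouped = df.groupby("bin")["value"].agg(["mean", "count"]).reset_index()
    grouped = grouped[grouped["count"] >= min_cells_per_bin]
    if grouped.empty:
        raise ValueError("no pseudotime bin satisfies the minimum cell count")
    out = pd.DataFrame(
        {
            "bin_mid": (grouped["bin"] + 0.5) * bin_width,
            "mean": grouped["mean"],
            "n_cells": grouped["count"].astype(int),
        }
    )
    return out.reset_index(drop=True)


def select_extreme_cells(
    cells: list[CellAnnotation], k: int, end: str = "earliest"
) -> list[str]:
    """The k cells with smallest ("earliest") or largest ("latest")
    pseudotime; ties at the cutoff go to the lexicographically smaller
    cell_id, making the selection input-order invariant."""
    if end not in ("earliest", "latest"):
        raise ValueError("end must be 'earliest' or 'latest'")
    with_pt = [c for c in cells if c.pseudotime is not None]
    if len(with_pt) < k:
        raise ValueError(f"need at least {k} cells with pseudotime, have {len(with_pt)}")
    if end == "earliest":
        ordered = sorted(with_pt, key=lambda c: (c.pseudotime, c.cell_id))
    else:
        ordered = sorted(with_pt, key=lambda c: (-c.pseudotime, c.cell_id))
    return [c.cell_id for c in ordered[:k]]


def welch_t_one_tailed(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, one-tailed with alternative a > b.

    Returns (t, Welch-Satterthwaite df, upper-tail p).  Raises when both
    samples have zero variance (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; t undefined")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(stats.t.sf(t, df))
    return float(t), float(df), p


def enrichment_over_pseudotime(
    flags: pd.DataFrame,
    cells: list[CellAnnotation],
    targets,
    non_targets,
    cfg: TrajectoryConfig | None = None,
    apply_filter: bool = True,
) -> EnrichmentResult:
    """Full target vs non-target enrichment analysis along pseudotime.

    Steps: optional minimum-expression prefilter against the config's early
    and late reference cells; per-cell expressed fractions for both sets;
    binned curves; one-tailed Welch contrasts (target > non-target) on the
    k earliest and, when enough cells remain, the k latest cells.
    """
    cfg = cfg or TrajectoryConfig()
    targets = set(targets) & set(flags.index)
    non_targets = set(non_targets) & set(flags.index)
    if not targets or not non_targets:
        raise ValueError("target and non-target sets must be non-empty in the matrix")
    if targets & non_targets:
        raise ValueError("target and non-target sets overlap")

    if apply_filter and cfg.min_cell_frac > 0:
        early_ref = cfg.early_cells(cells)
        late_ref = cfg.late_cells(cells)
        kept = filter_genes_by_group_expression(
            flags, early_ref, late_ref, cfg.min_cell_frac
        )
        targets &= kept
        non_targets &= kept
        if not targets or not non_targets:
            raise ValueError("minimum-expression prefilter removed an entire set")

    pt = pd.Series(
        {c.cell_id: c.pseudotime for c in cells if c.pseudotime is not None},
        dtype=float,
    )
    target_pct = fraction_expressed(flags, targets)
    non_target_pct = fraction_expressed(flags, non_targets)

    curves = []
    for label, series in (("target", target_pct), ("non_target", non_target_pct)):
        c = bin_curve(pt, series, cfg.bin_width, cfg.min_cells_per_bin)
        c.insert(0, "set_label", label)
        c = c.rename(columns={"mean": "mean_pct"})
        curves.append(c)
    curves = pd.concat(curves, ignore_index=True)

    def contrast(end: str) -> ContrastResult:
        chosen = select_extreme_cells(cells, cfg.k_extreme, end)
        a = target_pct[chosen].to_numpy()
        b = non_target_pct[chosen].to_numpy()
        t, df, p = welch_t_one_tailed(a, b)
        fold = float(a.mean() / b.mean()) if b.mean() > 0 else float("nan")
        return ContrastResult(t=t, df=df, p=p, fold=fold, n=cfg.k_extreme)

    early = contrast("earliest")
    late = contrast("latest") if len(pt) >= 2 * cfg.k_extreme else None

    per_cell = pd.DataFrame(
        {
            "cell_id": pt.index,
            "pseudotime": pt.to_numpy(),
            "target_pct": target_pct[pt.index].to_numpy(),
            "non_target_pct": non_target_pct[pt.index].to_numpy(),
        }
    ).sort_values("pseudotime", kind="stable").reset_index(drop=True)

    return EnrichmentResult(
        curves=curves,
        per_cell=per_cell,
        early=early,
        late=late,
        n_targets=len(targets),
        n_non_targets=len(non_targets),
    )


def cells_expressing_fraction(
    flags: pd.DataFrame, gene_set, cell_groups: dict[str, list[str]]
) -> dict[str, float]:
    """Per group, the percentage of cells with at least one set gene flagged."""
    present = flags.index.intersection(sorted(set(gene_set)))
    if len(present) == 0:
        raise ValueError("no gene of the set is present in the flag table")
    out: dict[str, float] = {}
    for group, members in cell_groups.items():
        if not members:
            raise ValueError(f"cell group {group!r} is empty")
        any_expr = flags.loc[present, list(members)].any(axis=0)
        out[group] = 100.0 * float(any_expr.mean())
    return out


def loess_smooth(x, y, span: float = 0.75) -> np.ndarray:
    """Locally weighted regression smooth for curve presentation only."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return lowess(y, x, frac=span, return_sorted=False)
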