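"""Synthetic-data generators with planted ground truth.

Every pipeline stage can be exercised end to end without external data:
a random gene annotation, multi-dataset peak sets sharing planted binding
sites with positional jitter, a single-cell expression matrix whose target
set has elevated early expression probability decaying toward the shared
baseline (the ~40% -> 10% vs ~20% -> 10% shape of the real trajectory),
multi-tissue expressed-gene sets containing a planted core, and binomial
seed-abortion counts from a recessive cross.  All generators are
deterministic under their seed, and noiseless parameterizations are
recovered exactly by the corresponding stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, Unit, DEFAULT_THRESHOLDS
from .io import GeneModel, GenomicInterval, Peak
from .segregation import CrossCounts
from .trajectory import CellAnnotation

__all__ = [
    "SimTruth",
    "gen_genome",
    "gen_peak_sets",
    "gen_expression_trajectory",
    "gen_multi_tissue_expression",
    "gen_segregation",
]


@dataclass
class SimTruth:
    """Planted ground truth of a synthetic scenario."""

    seed: int
    planted_sites: list[dict] = field(default_factory=list)
    planted_targets: list[str] = field(default_factory=list)
    planted_core: list[str] = field(default_factory=list)
    expression_model: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def gen_genome(
    n_genes: int,
    n_chroms: int = 1,
    chrom_len: int = 1_000_000,
    min_spacing: int = 5000,
    gene_len: int = 1000,
    seed: int = 0,
) -> list[GeneModel]:
    """Non-overlapping genes of fixed length with random strand.

    Start positions are spaced by at least ``min_spacing + gene_len`` so
    that TSS positions (either gene end) are pairwise at least
    ``min_spacing`` apart on each chromosome.
    """
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    spacing = min_spacing + gene_len
    genes: list[GeneModel] = []
    idx = 0
    for ci, k in enumerate(per_chrom):
        if k == 0:
            continue
        slack = chrom_len - k * spacing - gene_len
        if slack < 0:
            raise ValueError(
                f"cannot place {k} genes with spacing {min_spacing} on a "
                f"{chrom_len} bp chromosome"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        chrom = f"chr{ci + 1}"
        for j in range(k):
            start = int(offsets[j] + j * spacing)
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel(f"g{idx:05d}", chrom, strand, tss))
            idx += 1
    return genes


def write_gene_table(genes: list[GeneModel], path: str | Path,
                     gene_len: int = 1000) -> None:
    """Serialize a generated annotation as the TSV the readers accept."""
    rows = []
    for g in genes:
        start = g.tss if g.strand == "+" else g.tss + 1 - gene_len
        rows.append((g.gene_id, g.chrom, start, start + gene_len, g.strand))
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def gen_peak_sets(
    genes: list[GeneModel],
    n_datasets: int = 4,
    n_shared: int = 20,
    n_unique_per_dataset: int = 5,
    jitter_sd: float = 0.0,
    peak_len: int = 200,
    flank: int = 150,
    chrom_len: int = 1_000_000,
    seed: int = 0,
) -> tuple[dict[str, list[Peak]], SimTruth]:
    """Peak sets sharing planted binding sites plus per-dataset decoys.

    Each shared site is emitted once per dataset with an independent
    Normal(0, jitter_sd) start jitter rounded to bp.  Decoys (and shared
    sites) are mutually separated by at least ``2 * (peak_len + 2*flank)``
    so decoys can never qualify against anything.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sep = 2 * (peak_len + 2 * flank)
    n_slots_needed = n_shared + n_datasets * n_unique_per_dataset
    chroms = sorted({g.chrom for g in genes}) or ["chr1"]
    slots_per_chrom = chrom_len // sep - 1
    if n_slots_needed > slots_per_chrom * len(chroms):
        raise ValueError("cannot place peaks with the required separation")
    all_slots = [(c, s) for c in chroms for s in range(1, slots_per_chrom + 1)]
    chosen = rng.choice(len(all_slots), size=n_slots_needed, replace=False)
    positions = [(all_slots[i][0], all_slots[i][1] * sep) for i in chosen]

    dataset_ids = [f"ds{i + 1}" for i in range(n_datasets)]
    shared = positions[:n_shared]
    peaks: dict[str, list[Peak]] = {d: [] for d in dataset_ids}
    truth_sites = []
    for chrom, pos in shared:
        for d in dataset_ids:
            jitter = int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0
            start = max(0, pos + jitter)
            peaks[d].append(
                Peak(GenomicInterval(chrom, start, start + peak_len), d)
            )
        truth_sites.append(
            {"chrom": chrom, "start": pos, "end": pos + peak_len,
             "datasets": dataset_ids}
        )
    decoys = positions[n_shared:]
    for i, d in enumerate(dataset_ids):
        for chrom, pos in decoys[i * n_unique_per_dataset:(i + 1) * n_unique_per_dataset]:
            peaks[d].append(Peak(GenomicInterval(chrom, pos, pos + peak_len), d))
    for d in dataset_ids:
        peaks[d].sort(key=lambda p: (p.interval.chrom, p.interval.start))
    truth = SimTruth(seed=seed, planted_sites=truth_sites)
    return peaks, truth


def _interp_prob(t: np.ndarray, p_early: float, p_late: float,
                 t_max: float) -> np.ndarray:
    return p_early + (p_late - p_early) * (t / t_max)


def gen_expression_trajectory(
    genes: list[str],
    n_cells: int,
    target_set,
    p_target_early: float = 0.40,
    p_shared_late: float = 0.10,
    p_bg_early: float = 0.20,
    t_max: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[CellAnnotation], SimTruth]:
    """Single-cell TPM matrix over pseudotime with a planted target set.

    Target genes start at probability ``p_target_early`` of being expressed
    and decay linearly to the shared late baseline ``p_shared_late``;
    background genes start at ``p_bg_early``.  Values are drawn
    threshold-consistently: an expressed gene gets a TPM uniformly above
    the TPM threshold, a silent one uniformly below, so flagging inverts
    the planted Bernoulli draws exactly.
    """
    for p in (p_target_early, p_shared_late, p_bg_early):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must be in [0, 1]")
    target_set = set(target_set)
    if not target_set <= set(genes):
        raise ValueError("target_set must be a subset of genes")
    rng = np.random.default_rng(seed)
    pt = np.sort(rng.uniform(0, t_max, size=n_cells))
    cell_ids = [f"c{i:04d}" for i in range(n_cells)]
    thr = DEFAULT_THRESHOLDS[Unit.TPM]

    is_target = np.array([g in target_set for g in genes])
    p_early = np.where(is_target, p_target_early, p_bg_early)
    # genes x cells planted expression probability
    probs = p_early[:, None] + (p_shared_late - p_early)[:, None] * (pt[None, :] / t_max)
    flags = rng.random((len(genes), n_cells)) < probs
    values = np.where(
        flags,
        rng.uniform(thr * 1.001, thr * 20, size=flags.shape),
        rng.uniform(0, thr, size=flags.shape),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(genes), columns=cell_ids), unit=Unit.TPM
    )
    cells = [
        CellAnnotation(cell_id=cid, lineage="sim", pseudotime=float(t))
        for cid, t in zip(cell_ids, pt)
    ]
    truth = SimTruth(
        seed=seed,
        planted_targets=sorted(target_set),
        expression_model={
            "p_target_early": p_target_early,
            "p_shared_late": p_shared_late,
            "p_bg_early": p_bg_early,
            "t_max": t_max,
            "interpolation": "linear",
        },
    )
    return matrix, cells, truth


def planted_probability(
    truth: SimTruth, t: float, is_target: bool
) -> float:
    """The generator's planted expression probability at pseudotime ``t``."""
    m = truth.expression_model
    p_early = m["p_target_early"] if is_target else m["p_bg_early"]
    return p_early + (m["p_shared_late"] - p_early) * (t / m["t_max"])


def gen_multi_tissue_expression(
    genes: list[str],
    tissue_labels: list[str],
    core_set,
    p_core: float = 0.75,
    p_other: float = 0.35,
    seed: int = 0,
) -> tuple[dict[str, set[str]], SimTruth]:
    """Per-tissue expressed-gene sets with a planted core.

    Each core gene is expressed in each tissue with probability ``p_core``,
    every other gene with ``p_other``; with p_core=1 and p_other=0 the
    intersection recovers the core exactly.
    """
    core_set = set(core_set)
    if not core_set <= set(genes):
        raise ValueError("core_set must be a subset of genes")
    rng = np.random.default_rng(seed)
    is_core = np.array([g in core_set for g in genes])
    p = np.where(is_core, p_core, p_other)
    sets: dict[str, set[str]] = {}
    for tissue in tissue_labels:
        draw = rng.random(len(genes)) < p
        sets[tissue] = {g for g, d in zip(genes, draw) if d}
    truth = SimTruth(
        seed=seed,
        planted_core=sorted(core_set),
        expression_model={"p_core": p_core, "p_other": p_other},
    )
    return sets, truth


def gen_segregation(n_seeds: int, p_abort: float = 0.25, seed: int = 0,
                    label: str = "sim_cross") -> CrossCounts:
    """Binomial seed-abortion count from a segregating cross."""
    if not (0 <= p_abort <= 1):
        raise ValueError("p_abort must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n_seeds, p_abort))
    return CrossCounts(label=label, n_affected=k, n_total=n_seeds)
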