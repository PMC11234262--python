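"""TSS-window assignment of consensus sites to genes and target-set definition.

A site is assigned to a gene when the site midpoint falls within a fixed
window around the gene's TSS ([-4 kb, +4 kb] by default, closed on both
ends), with the signed distance measured 5'->3' relative to the gene.
Direct targets are bound genes that are also upregulated on overexpression
of at least one family member; non-targets have no peak from ANY input
dataset in the window and appear in no upregulated set.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .consensus import ConsensusSite
from .io import GeneModel, Peak

__all__ = [
    "TargetConfig",
    "GeneSetCatalog",
    "assign_genes",
    "define_targets",
    "define_non_targets",
    "build_catalog",
]


@dataclass(frozen=True)
class TargetConfig:
    """TSS window: ``upstream`` bp before and ``downstream`` bp after the TSS,
    both boundaries inclusive.  Sites are anchored at their midpoint."""

    upstream: int = 4000
    downstream: int = 4000

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")


@dataclass
class GeneSetCatalog:
    """Named gene-id sets produced by the target-definition stage."""

    universe: set[str]
    bound: set[str]
    upregulated_by: dict[str, set[str]]
    targets: set[str]
    non_targets: set[str]

    def __post_init__(self) -> None:
        if not self.bound <= self.universe:
            raise ValueError("bound genes outside universe")
        if not self.targets <= self.bound:
            raise ValueError("targets must be a subset of bound")
        if self.targets & self.non_targets:
            raise ValueError("targets and non_targets overlap")
        if not self.non_targets <= self.universe:
            raise ValueError("non_targets outside universe")


def _signed_distance(anchor: int, gene: GeneModel) -> int:
    # distance measured along the gene: positive downstream of the TSS
    return anchor - gene.tss if gene.strand == "+" else gene.tss - anchor


def _gene_index(genes: list[GeneModel]) -> dict[str, tuple[list[int], list[GeneModel]]]:
    index: dict[str, list[GeneModel]] = {}
    for g in genes:
        index.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, gs in index.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        out[chrom] = ([g.tss for g in gs], gs)
    return out


def _anchor_hits(anchor: int, tss_list, gs, cfg: TargetConfig):
    # a '+' gene at tss is hit iff tss in [anchor-down, anchor+up];
    # a '-' gene iff tss in [anchor-up, anchor+down]; scan the widest span
    lo = anchor - max(cfg.upstream, cfg.downstream)
    hi = anchor + max(cfg.upstream, cfg.downstream)
    for k in range(bisect_left(tss_list, lo), bisect_right(tss_list, hi)):
        g = gs[k]
        d = _signed_distance(anchor, g)
        if -cfg.upstream <= d <= cfg.downstream:
            yield g, d


def assign_genes(
    sites: list[ConsensusSite],
    genes: list[GeneModel],
    cfg: TargetConfig | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Assign consensus sites to genes by midpoint-to-TSS distance.

    Returns the association table (site_id, gene_id, signed_distance) sorted
    by (site_id, gene_id), and the set of bound genes.  A site may hit
    several genes and a gene several sites.
    """
    cfg = cfg or TargetConfig()
    if not genes:
        raise ValueError("empty gene annotation")
    index = _gene_index(genes)
    rows = []
    for site in sites:
        if site.interval.chrom not in index:
            continue
        tss_list, gs = index[site.interval.chrom]
        for g, d in _anchor_hits(site.interval.midpoint, tss_list, gs, cfg):
            rows.append((site.site_id, g.gene_id, d))
    table = pd.DataFrame(rows, columns=["site_id", "gene_id", "signed_distance"])
    table = table.sort_values(["site_id", "gene_id"]).reset_index(drop=True)
    return table, set(table["gene_id"])


def define_targets(
    bound: set[str], upregulated_by: dict[str, set[str]]
) -> set[str]:
    """Bound genes upregulated by at least one family member."""
    if not upregulated_by:
        raise ValueError("no upregulated gene sets given; target filter undefined")
    up_union: set[str] = set().union(*upregulated_by.values())
    return bound & up_union


def define_non_targets(
    genes: list[GeneModel],
    peak_sets: list[list[Peak]],
    upregulated_by: dict[str, set[str]],
    cfg: TargetConfig | None = None,
) -> set[str]:
    """Genes with no peak from ANY dataset in the TSS window and no
    upregulation on overexpression.

    Note this uses the raw per-dataset peaks, not only >=2-support consensus
    sites, so single-dataset evidence is enough to disqualify a gene.
    """
    cfg = cfg or TargetConfig()
    index = _gene_index(genes)
    with_peak: set[str] = set()
    for ps in peak_sets:
        for p in ps:
            if p.interval.chrom not in index:
                continue
            tss_list, gs = index[p.interval.chrom]
            for g, _ in _anchor_hits(p.interval.midpoint, tss_list, gs, cfg):
                with_peak.add(g.gene_id)
    up_union: set[str] = set()
    for s in upregulated_by.values():
        up_union |= s
    return {g.gene_id for g in genes} - with_peak - up_union


def build_catalog(
    genes: list[GeneModel],
    sites: list[ConsensusSite],
    peak_sets: list[list[Peak]],
    upregulated_by: dict[str, set[str]],
    cfg: TargetConfig | None = None,
) -> tuple[GeneSetCatalog, pd.DataFrame]:
    """Run the full target-definition stage and return the catalog plus the
    site-gene association table."""
    cfg = cfg or TargetConfig()
    table, bound = assign_genes(sites, genes, cfg)
    targets = define_targets(bound, upregulated_by)
    non_targets = define_non_targets(genes, peak_sets, upregulated_by, cfg)
    catalog = GeneSetCatalog(
        universe={g.gene_id for g in genes},
        bound=bound,
        upregulated_by={k: set(v) for k, v in upregulated_by.items()},
        targets=targets,
        non_targets=non_targets,
    )
    return catalog, table
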