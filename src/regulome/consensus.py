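"""Consensus binding-site calling across multiple peak datasets.

Each called peak is extended by a fixed flank on both sides; two peaks from
different datasets *qualify* as mutual evidence when their extended
intervals overlap reciprocally by at least a configured fraction of each.
A consensus site is a connected component of the qualifying-overlap graph
spanning a minimum number of distinct datasets, reported on the union span
of the members' ORIGINAL (unextended) coordinates.  Pairs of datasets can
be excluded so that their mutual overlaps never qualify (e.g. two ChIP
experiments on the same factor with an order of magnitude more peaks than
the rest); exclusion removes edges, not peaks, so chains through a third
dataset still connect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .io import GenomicInterval, Peak

__all__ = [
    "ConsensusConfig",
    "ConsensusSite",
    "extend_interval",
    "reciprocal_fraction",
    "qualifies",
    "call_consensus",
    "write_sites_bed",
    "write_manifest",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Parameters of the consensus procedure.

    flank
        bp added to each side of every peak before overlap testing (150 by
        default, a tolerance device only — sites are reported on original
        coordinates).
    min_reciprocal_frac
        qualifying overlap fraction of BOTH extended intervals (0.75).
    min_support
        minimum distinct datasets a component must span (2).
    excluded_pairs
        unordered dataset-id pairs whose mutual overlaps never qualify.
    strict
        if True, require strictly greater than ``min_reciprocal_frac``
        instead of >= (the default mirrors the behaviour of the standard
        interval tools despite ">75%" phrasing in common usage).
    """

    flank: int = 150
    min_reciprocal_frac: float = 0.75
    min_support: int = 2
    excluded_pairs: frozenset[frozenset[str]] = frozenset()
    strict: bool = False

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not (0 < self.min_reciprocal_frac <= 1):
            raise ValueError("min_reciprocal_frac must be in (0, 1]")
        if self.min_support < 2:
            raise ValueError("min_support must be >= 2")
        object.__setattr__(
            self,
            "excluded_pairs",
            frozenset(frozenset(p) for p in self.excluded_pairs),
        )

    def pair_excluded(self, ds_a: str, ds_b: str) -> bool:
        return frozenset((ds_a, ds_b)) in self.excluded_pairs


@dataclass(frozen=True)
class ConsensusSite:
    """Merged multi-dataset binding evidence.

    ``interval`` is the union span of member peaks' original intervals;
    ``support_datasets`` the distinct dataset ids among members.
    """

    site_id: str
    interval: GenomicInterval
    support_datasets: frozenset[str]
    members: tuple[Peak, ...]

    @property
    def n_support(self) -> int:
        return len(self.support_datasets)


def extend_interval(iv: GenomicInterval, flank: int) -> GenomicInterval:
    """Symmetric extension by ``flank`` bp, clamped at the chromosome origin."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank)


def reciprocal_fraction(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """Overlap of ``a`` and ``b`` as a fraction of each interval's length.

    Intervals on different chromosomes overlap by 0.
    """
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return (ov / a.length, ov / b.length)


def qualifies(a: Peak, b: Peak, cfg: ConsensusConfig) -> bool:
    """True iff the two peaks count as mutual cross-dataset evidence."""
    if a.dataset_id == b.dataset_id:
        return False
    if cfg.pair_excluded(a.dataset_id, b.dataset_id):
        return False
    fa, fb = reciprocal_fraction(
        extend_interval(a.interval, cfg.flank),
        extend_interval(b.interval, cfg.flank),
    )
    if cfg.strict:
        return fa > cfg.min_reciprocal_frac and fb > cfg.min_reciprocal_frac
    return fa >= cfg.min_reciprocal_frac and fb >= cfg.min_reciprocal_frac


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def call_consensus(
    peak_sets: list[list[Peak]], cfg: ConsensusConfig | None = None
) -> list[ConsensusSite]:
    """Call consensus sites over >=2 peak datasets.

    Builds the qualifying-overlap graph with a per-chromosome sweep over
    flank-extended intervals and merges connected components; components
    spanning fewer than ``cfg.min_support`` distinct datasets are dropped.
    Output is sorted by (chrom, start, end) with deterministic site ids.
    """
    cfg = cfg or ConsensusConfig()
    if len(peak_sets) < 2:
        raise ValueError("consensus is undefined for fewer than two peak datasets")
    peaks = [p for ps in peak_sets for p in ps]
    n = len(peaks)
    uf = _UnionFind(n)

    # sweep: per chromosome, in order of extended start, compare each peak
    # with the still-active (extended-end > current start) predecessors
    by_chrom: dict[str, list[int]] = {}
    ext = [extend_interval(p.interval, cfg.flank) for p in peaks]
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.interval.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (ext[i].start, ext[i].end))
        active: list[int] = []
        for i in idxs:
            active = [j for j in active if ext[j].end > ext[i].start]
            for j in active:
                if qualifies(peaks[i], peaks[j], cfg):
                    uf.union(i, j)
            active.append(i)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    raw_sites = []
    for members in comps.values():
        datasets = {peaks[i].dataset_id for i in members}
        if len(datasets) < cfg.min_support:
            continue
        chrom = peaks[members[0]].interval.chrom
        start = min(peaks[i].interval.start for i in members)
        end = max(peaks[i].interval.end for i in members)
        member_peaks = tuple(
            sorted(
                (peaks[i] for i in members),
                key=lambda p: (p.dataset_id, p.interval.start, p.interval.end),
            )
        )
        raw_sites.append(
            (GenomicInterval(chrom, start, end), frozenset(datasets), member_peaks)
        )
    raw_sites.sort(key=lambda s: (s[0].chrom, s[0].start, s[0].end))
    width = max(4, len(str(len(raw_sites))))
    return [
        ConsensusSite(f"site_{i + 1:0{width}d}", iv, ds, members)
        for i, (iv, ds, members) in enumerate(raw_sites)
    ]


def write_sites_bed(sites: list[ConsensusSite], path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, site_id, n_support, dataset ids."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.interval.chrom,
                        str(s.interval.start),
                        str(s.interval.end),
                        s.site_id,
                        str(s.n_support),
                        ",".join(sorted(s.support_datasets)),
                    ]
                )
                + "\n"
            )


def write_manifest(
    path: str | Path,
    cfg: ConsensusConfig,
    peak_sets: list[list[Peak]],
    sites: list[ConsensusSite],
) -> None:
    per_dataset: dict[str, int] = {}
    for ps in peak_sets:
        for p in ps:
            per_dataset[p.dataset_id] = per_dataset.get(p.dataset_id, 0) + 1
    manifest = {
        "config": {
            "flank": cfg.flank,
            "min_reciprocal_frac": cfg.min_reciprocal_frac,
            "min_support": cfg.min_support,
            "excluded_pairs": sorted(sorted(p) for p in cfg.excluded_pairs),
            "strict": cfg.strict,
        },
        "peaks_per_dataset": dict(sorted(per_dataset.items())),
        "n_sites": len(sites),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
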