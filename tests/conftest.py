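"""Shared fixtures and independent oracles for the test suite.

The consensus oracle here is a deliberately naive O(n^2) all-pairs +
breadth-first connected-components routine with its own inline overlap
arithmetic, kept independent of the package's sweep/union-find
implementation so the two can be compared on randomized instances.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest
from hypothesis import settings

from regulome.io import GenomicInterval, Peak

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def brute_force_consensus(peak_sets, flank, min_frac, min_support,
                          excluded_pairs, strict=False):
    """All-pairs qualifying graph + BFS components; returns comparable
    site tuples (chrom, start, end, support frozenset, member tuples)."""
    peaks = [p for ps in peak_sets for p in ps]
    n = len(peaks)

    def ext(p):
        return (p.interval.chrom,
                max(0, p.interval.start - flank),
                p.interval.end + flank)

    def pair_qualifies(a, b):
        if a.dataset_id == b.dataset_id:
            return False
        if frozenset((a.dataset_id, b.dataset_id)) in excluded_pairs:
            return False
        ca, sa, ea = ext(a)
        cb, sb, eb = ext(b)
        if ca != cb:
            return False
        ov = min(ea, eb) - max(sa, sb)
        if ov <= 0:
            return False
        fa, fb = ov / (ea - sa), ov / (eb - sb)
        if strict:
            return fa > min_frac and fb > min_frac
        return fa >= min_frac and fb >= min_frac

    adj = [[] for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if pair_qualifies(peaks[i], peaks[j]):
            adj[i].append(j)
            adj[j].append(i)

    seen = [False] * n
    sites = []
    for s in range(n):
        if seen[s]:
            continue
        comp = []
        queue = deque([s])
        seen[s] = True
        while queue:
            i = queue.popleft()
            comp.append(i)
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    queue.append(j)
        datasets = frozenset(peaks[i].dataset_id for i in comp)
        if len(datasets) < min_support:
            continue
        chrom = peaks[comp[0]].interval.chrom
        start = min(peaks[i].interval.start for i in comp)
        end = max(peaks[i].interval.end for i in comp)
        members = tuple(sorted(
            (peaks[i].dataset_id, peaks[i].interval.start, peaks[i].interval.end)
            for i in comp
        ))
        sites.append((chrom, start, end, datasets, members))
    sites.sort(key=lambda s: (s[0], s[1], s[2]))
    return sites


def site_tuples(sites):
    """Project package ConsensusSites onto the oracle's comparable tuples."""
    return [
        (
            s.interval.chrom,
            s.interval.start,
            s.interval.end,
            frozenset(s.support_datasets),
            tuple(sorted(
                (m.dataset_id, m.interval.start, m.interval.end)
                for m in s.members
            )),
        )
        for s in sites
    ]


def random_peak_instance(rng, max_peaks=50, span=3000):
    """A small random multi-dataset peak instance with random exclusions."""
    n_datasets = int(rng.integers(3, 6))
    datasets = [f"ds{i}" for i in range(n_datasets)]
    n_peaks = int(rng.integers(n_datasets, max_peaks + 1))
    peak_sets = [[] for _ in range(n_datasets)]
    for _ in range(n_peaks):
        d = int(rng.integers(0, n_datasets))
        chrom = f"chr{int(rng.integers(1, 3))}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(50, 400))
        peak_sets[d].append(
            Peak(GenomicInterval(chrom, start, start + length), datasets[d])
        )
    excluded = set()
    if rng.random() < 0.5:
        a, b = rng.choice(n_datasets, size=2, replace=False)
        excluded.add(frozenset((datasets[a], datasets[b])))
    flank = int(rng.choice([0, 50, 150]))
    return peak_sets, flank, frozenset(excluded)


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)
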