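"""Core regulome: target genes expressed in every queried tissue, and their
enrichment over a complement set across cell states.

The core is the intersection of the direct-target set with each tissue's
expressed-gene set (e.g. root meristem, quiescent center, shoot stem
cells).  Per evaluation dataset the enrichment is the log2 ratio of the
percentage of core genes expressed to the percentage of complement genes
expressed, each computed over the genes actually measured in that dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CoreEnrichmentRow", "core_targets", "core_enrichment", "core_table"]


@dataclass(frozen=True)
class CoreEnrichmentRow:
    """Per-dataset core enrichment.

    ``log2_ratio`` is NaN (with a logged warning) when no complement gene is
    expressed, rather than a silent infinity.
    """

    dataset: str
    pct_core_expressed: float
    pct_complement_expressed: float
    log2_ratio: float
    n_core_measured: int
    n_complement_measured: int


def core_targets(targets, expressed_sets: list[set[str]]) -> set[str]:
    """Targets expressed in EVERY given tissue set."""
    if not expressed_sets:
        raise ValueError("need at least one expressed-gene set")
    core = set(targets)
    for s in expressed_sets:
        core &= set(s)
    return core


def core_enrichment(
    core,
    complement,
    expressed: set[str],
    dataset: str = "",
    measured: set[str] | None = None,
) -> CoreEnrichmentRow:
    """Expressed percentage of core vs complement in one dataset.

    ``measured`` restricts both sets to genes observed in the dataset, so
    genes absent from the assay do not deflate the percentages; it defaults
    to no restriction.
    """
    core = set(core)
    complement = set(complement)
    if core & complement:
        raise ValueError("core and complement sets overlap")
    if measured is not None:
        core &= measured
        complement &= measured
    if not core or not complement:
        raise ValueError("core and complement must be non-empty after restriction")
    f_core = 100.0 * len(core & expressed) / len(core)
    f_comp = 100.0 * len(complement & expressed) / len(complement)
    if f_comp == 0:
        logger.warning(
            "dataset %s: no complement gene expressed; log2 ratio undefined", dataset
        )
        ratio = float("nan")
    elif f_core == 0:
        ratio = float("-inf")
    else:
        ratio = math.log2(f_core / f_comp)
    return CoreEnrichmentRow(
        dataset=dataset,
        pct_core_expressed=f_core,
        pct_complement_expressed=f_comp,
        log2_ratio=ratio,
        n_core_measured=len(core),
        n_complement_measured=len(complement),
    )


def core_table(
    core,
    complement,
    datasets: dict[str, set[str]],
    measured: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Core enrichment across several evaluation datasets as a tidy table."""
    rows = []
    for name, expressed in datasets.items():
        m = measured.get(name) if measured else None
        rows.append(core_enrichment(core, complement, expressed, name, m))
    return pd.DataFrame([r.__dict__ for r in rows])
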