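"""End-to-end orchestration: consensus -> targets -> flags -> trajectory -> core.

Every intermediate is a flat file (BED-like TSV, gene lists, tidy TSV,
JSON) so each stage is independently inspectable and testable, and a run
manifest records the config hash, input checksums and per-stage record
counts; reruns on identical inputs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consensus as cns
from . import core_regulome as core
from . import expression as expr
from . import io as gio
from . import targets as tg
from . import trajectory as traj

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and per-stage parameters of a full run."""

    peaks: list[str]
    genes: str
    upregulated: dict[str, str]
    expression: str
    cell_metadata: str
    out_dir: str
    gene_format: str = "tsv"
    expression_unit: str = "TPM"
    tissue_expressed: dict[str, str] = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    target: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "peaks": list(self.peaks),
            "genes": self.genes,
            "upregulated": dict(self.upregulated),
            "expression": self.expression,
            "cell_metadata": self.cell_metadata,
            "out_dir": self.out_dir,
            "gene_format": self.gene_format,
            "expression_unit": self.expression_unit,
            "tissue_expressed": dict(self.tissue_expressed),
            "consensus": dict(self.consensus),
            "target": dict(self.target),
            "trajectory": dict(self.trajectory),
            "seed": self.seed,
        }

    def input_paths(self) -> list[Path]:
        paths = [Path(p) for p in self.peaks]
        paths.append(Path(self.genes))
        paths.extend(Path(p) for p in self.upregulated.values())
        paths.extend([Path(self.expression), Path(self.cell_metadata)])
        paths.extend(Path(p) for p in self.tissue_expressed.values())
        return paths

    def validate(self) -> None:
        missing = [str(p) for p in self.input_paths() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _consensus_config(d: dict) -> cns.ConsensusConfig:
    d = dict(d)
    if "excluded_pairs" in d:
        d["excluded_pairs"] = frozenset(
            frozenset(p) for p in d["excluded_pairs"]
        )
    return cns.ConsensusConfig(**d)


def _trajectory_config(d: dict) -> traj.TrajectoryConfig:
    d = dict(d)
    for key in ("early_groups", "late_groups"):
        if key in d:
            d[key] = frozenset(d[key])
    return traj.TrajectoryConfig(**d)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest (also written
    to ``<out_dir>/manifest.json``)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "consensus"
    try:
        peak_sets = [gio.read_narrowpeak(p) for p in cfg.peaks]
        ccfg = _consensus_config(cfg.consensus)
        sites = cns.call_consensus(peak_sets, ccfg)
        cns.write_sites_bed(sites, out / "sites.bed")

        stage = "targets"
        genes = gio.read_gene_table(cfg.genes, format=cfg.gene_format)
        upregulated = {k: gio.read_gene_list(v) for k, v in cfg.upregulated.items()}
        tcfg = tg.TargetConfig(**cfg.target)
        catalog, assoc = tg.build_catalog(genes, sites, peak_sets, upregulated, tcfg)
        assoc.to_csv(out / "site_gene_associations.tsv", sep="\t", index=False)
        gio.write_gene_list(catalog.bound, out / "bound.txt")
        gio.write_gene_list(catalog.targets, out / "targets.txt")
        gio.write_gene_list(catalog.non_targets, out / "non_targets.txt")

        stage = "flags"
        matrix = gio.read_expression(cfg.expression, unit=cfg.expression_unit)
        cells = gio.read_cell_metadata(cfg.cell_metadata, matrix=matrix)
        flags = expr.flag_expressed(matrix)
        flags.to_csv(out / "expressed_flags.tsv", sep="\t")

        stage = "trajectory"
        jcfg = _trajectory_config(cfg.trajectory)
        enrich = traj.enrichment_over_pseudotime(
            flags, cells, catalog.targets, catalog.non_targets, jcfg
        )
        enrich.curves.to_csv(out / "enrichment_curves.tsv", sep="\t", index=False)
        contrasts = {"early": enrich.early.__dict__}
        if enrich.late is not None:
            contrasts["late"] = enrich.late.__dict__
        with open(out / "contrasts.json", "w") as fh:
            json.dump(contrasts, fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "core"
        core_set: set[str] = set()
        core_rows = 0
        if cfg.tissue_expressed:
            tissue_sets = {
                k: gio.read_gene_list(v) for k, v in cfg.tissue_expressed.items()
            }
            core_set = core.core_targets(
                catalog.targets, list(tissue_sets.values())
            )
            gio.write_gene_list(core_set, out / "core_targets.txt")
            table = core.core_table(core_set, catalog.non_targets, tissue_sets)
            table.to_csv(out / "core_enrichment.tsv", sep="\t", index=False)
            core_rows = len(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_dict = cfg.to_dict()
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": {str(p): _sha256(p) for p in cfg.input_paths()},
        "counts": {
            "peaks_per_dataset": {
                ps[0].dataset_id if ps else f"dataset_{i}": len(ps)
                for i, ps in enumerate(peak_sets)
            },
            "consensus_sites": len(sites),
            "genes": len(genes),
            "bound": len(catalog.bound),
            "targets": len(catalog.targets),
            "non_targets": len(catalog.non_targets),
            "cells": len(cells),
            "core": len(core_set),
            "core_datasets": core_rows,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
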