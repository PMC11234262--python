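"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are held internally as 0-based, half-open intervals
(the narrowPeak/BED native convention).  1-based formats (GTF/GFF3) are
converted on read, so no other module ever needs to think about origin
conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "read_narrowpeak",
    "write_peaks_bed",
    "read_gene_table",
    "read_expression",
    "read_cell_metadata",
    "read_gene_list",
    "write_gene_list",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Anchor point used for TSS-distance assignment (floor of the mean)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called peak carrying its source-dataset label.

    ``score`` is the caller's significance column and ``summit_offset`` the
    bp offset of the summit from ``interval.start``; both are optional.
    ``name`` and ``strand`` are retained verbatim so that BED6 round-trips.
    """

    interval: GenomicInterval
    dataset_id: str
    score: float | None = None
    summit_offset: int | None = None
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the single anchor the pipeline needs: its TSS.

    The TSS is the biological 5' end: ``start`` for '+' genes and
    ``end - 1`` (0-based last base) for '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_narrowpeak(path: str | Path, dataset_id: str | None = None) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) or plain BED (>=3 column) file.

    ``dataset_id`` defaults to the file stem.  Malformed records raise
    :class:`ValueError` naming the offending line number.
    """
    path = Path(path)
    ds = dataset_id if dataset_id is not None else path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                interval = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 else "."
            summit: int | None = None
            if len(fields) >= 10:
                raw = int(fields[9])
                summit = raw if raw >= 0 else None
            try:
                peaks.append(
                    Peak(interval, ds, score=score, summit_offset=summit,
                         name=name, strand=strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        _fmt_score(p.score),
                        p.strand,
                    ]
                )
                + "\n"
            )


def _genes_from_gff(path: Path, fmt: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    id_attr = "gene_id" if fmt == "gtf" else "ID"
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if id_attr in feat.attributes:
            gene_id = feat.attributes[id_attr][0]
        else:
            gene_id = feat.id
        if feat.strand == "+":
            tss = feat.start - 1  # gffutils is 1-based inclusive
        elif feat.strand == "-":
            tss = feat.end - 1
        else:
            raise ValueError(f"unknown strand {feat.strand!r} for {gene_id}")
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, tss))
    return genes


def read_gene_table(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read a gene annotation as a list of :class:`GeneModel`.

    ``format`` is one of ``tsv``, ``gtf``, ``gff3``.  TSV needs columns
    ``gene_id, chrom, start, end, strand`` with 0-based half-open
    coordinates; GTF/GFF3 coordinates are converted from 1-based on read.
    Duplicate gene ids are rejected.
    """
    path = Path(path)
    if format in ("gtf", "gff3"):
        genes = _genes_from_gff(path, format)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        genes = []
        for row in df.itertuples(index=False):
            tss = int(row.start) if row.strand == "+" else int(row.end) - 1
            genes.append(GeneModel(str(row.gene_id), str(row.chrom), row.strand, tss))
    else:
        raise ValueError(f"unknown gene table format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def read_expression(
    path: str | Path,
    unit: str = "OTHER",
    rownames: str | Path | None = None,
    colnames: str | Path | None = None,
    replicate_groups: dict[str, str] | None = None,
):
    """Read a genes x samples expression matrix (TSV or matrix-market).

    For matrix-market (``.mtx``) input, row/column name files default to
    ``<stem>.rownames.txt`` / ``<stem>.colnames.txt`` next to the matrix.
    Missing values are rejected.
    """
    from .expression import ExpressionMatrix

    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(path)).toarray()
        rownames = Path(rownames) if rownames else path.with_suffix(".rownames.txt")
        colnames = Path(colnames) if colnames else path.with_suffix(".colnames.txt")
        rows = [ln.strip() for ln in open(rownames) if ln.strip()]
        cols = [ln.strip() for ln in open(colnames) if ln.strip()]
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    return ExpressionMatrix(df.astype(float), unit=unit,
                            replicate_groups=replicate_groups)


def read_cell_metadata(path: str | Path, matrix=None):
    """Read a cell-metadata TSV into a list of :class:`~regulome.trajectory.CellAnnotation`.

    The file needs a ``cell_id`` column plus ``pseudotime`` and/or
    ``time_group``; ``lineage`` is optional.  If ``matrix`` (an
    :class:`~regulome.expression.ExpressionMatrix`) is given, every cell must
    be a matrix sample; offenders are listed in the error.
    """
    from .trajectory import CellAnnotation

    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: missing cell_id column")
    cells = []
    for row in df.to_dict("records"):
        pt = row.get("pseudotime")
        pt = None if pt is None or (isinstance(pt, float) and np.isnan(pt)) else float(pt)
        group = row.get("time_group")
        group = None if group is None or (isinstance(group, float) and np.isnan(group)) else str(group)
        cells.append(
            CellAnnotation(
                cell_id=str(row["cell_id"]),
                lineage=str(row["lineage"]) if "lineage" in row else None,
                pseudotime=pt,
                time_group=group,
            )
        )
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate cell ids")
    if matrix is not None:
        unknown = sorted(set(ids) - set(matrix.samples))
        if unknown:
            raise ValueError(
                f"{path}: cells absent from expression matrix: {unknown}"
            )
    return cells


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one id per line) into a set.

    Duplicates are deduplicated with a logged warning.
    """
    ids = [ln.strip() for ln in open(path) if ln.strip()]
    out = set(ids)
    if len(out) != len(ids):
        logger.warning("%s: %d duplicate gene ids collapsed", path, len(ids) - len(out))
    return out


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
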