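"""Readers and writers for the tabular study formats.

All expression matrices are tab-separated: first column ``transcript_id``,
remaining columns sample ids. Annotation is a TSV with the
:data:`~circstab.model.ANNOTATION_COLUMNS` fields (a GTF with
``transcript_id`` / ``gene_id`` / ``gene_biotype`` attributes is accepted
as a convenience; coordinates are converted to 0-based half-open on read).
The design is a TSV with ``sample_id``, ``donor``, ``time_h``.
"""

from __future__ import annotations

import os
import re
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ANNOTATION_COLUMNS,
    DEFAULT_TIME_GRID,
    ExpressionStudy,
)

__all__ = [
    "read_matrix",
    "read_annotation",
    "read_design",
    "read_expression_study",
    "write_results_table",
    "write_expression_study",
    "read_circ_bed",
]

NA_TOKEN = "NA"


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a transcripts x samples TSV matrix (first column = transcript_id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            )
    return frame


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _read_annotation_gtf(path: str | os.PathLike) -> pd.DataFrame:
    cols = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    rows: dict[str, dict] = {}
    exon_counts: dict[str, int] = {}
    exon_lengths: dict[str, int] = {}
    for rec in raw.itertuples(index=False):
        attrs = dict(_GTF_ATTR.findall(rec.attributes))
        tid = attrs.get("transcript_id")
        if tid is None:
            continue
        if rec.feature == "transcript":
            rows[tid] = {
                "transcript_id": tid,
                "gene_id": attrs.get("gene_id", tid),
                "rna_class": attrs.get("rna_class", "mRNA"),
                "gene_biotype": attrs.get("gene_biotype", "protein_coding"),
                "chrom": str(rec.chrom),
                "start": int(rec.start) - 1,  # GTF is 1-based inclusive
                "end": int(rec.end),
                "strand": rec.strand,
            }
        elif rec.feature == "exon":
            exon_counts[tid] = exon_counts.get(tid, 0) + 1
            exon_lengths[tid] = exon_lengths.get(tid, 0) + (
                int(rec.end) - int(rec.start) + 1
            )
    frame = pd.DataFrame(list(rows.values()))
    frame["exon_count"] = [max(exon_counts.get(t, 1), 1) for t in frame["transcript_id"]]
    frame["length_nt"] = [
        exon_lengths.get(t, row_end - row_start)
        for t, row_start, row_end in zip(
            frame["transcript_id"], frame["start"], frame["end"]
        )
    ]
    return frame[ANNOTATION_COLUMNS].set_index("transcript_id", drop=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read transcript annotation from TSV (canonical) or GTF."""
    spath = str(path)
    if spath.endswith((".gtf", ".gff")):
        return _read_annotation_gtf(path)
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return frame.set_index("transcript_id", drop=False)


def read_circ_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read circRNA back-splice spans from BED6 (0-based half-open)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return frame.set_index("name", drop=False)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "donor", "time_h"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"design missing columns: {sorted(missing)}")
    frame["time_h"] = frame["time_h"].astype(float)
    if "library_size" not in frame.columns:
        frame["library_size"] = np.nan
    return frame.set_index("sample_id", drop=False)


def read_expression_study(
    counts_path: str | os.PathLike,
    tpm_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    design_path: str | os.PathLike,
    *,
    renormalize_tpm: bool = False,
    time_grid: Sequence[float] | None = DEFAULT_TIME_GRID,
) -> ExpressionStudy:
    """Assemble and validate an :class:`ExpressionStudy` from TSV inputs.

    Matrix rows not present in the annotation are rejected with a report
    in the raised error. TPM columns whose sum is off 1e6 by more than
    0.1% raise unless ``renormalize_tpm`` is set, in which case they are
    rescaled with a warning.
    """
    counts = read_matrix(counts_path)
    tpm = read_matrix(tpm_path)
    annotation = read_annotation(annotation_path)
    design = read_design(design_path)

    missing_samples = set(counts.columns) - set(design.index)
    if missing_samples:
        raise ValueError(
            f"samples absent from design: {sorted(missing_samples)}"
        )
    design = design.loc[list(counts.columns)]

    unannotated = counts.index.difference(annotation.index)
    if len(unannotated):
        raise ValueError(
            f"{len(unannotated)} matrix rows missing from annotation: "
            f"{list(unannotated[:10])}"
        )
    annotation = annotation.loc[counts.index]

    colsums = tpm.sum(axis=0).to_numpy(dtype=float)
    off = ~np.isclose(colsums, 1e6, rtol=1e-3)
    if off.any():
        if renormalize_tpm:
            warnings.warn(
                f"renormalizing {int(off.sum())} TPM columns to 1e6",
                stacklevel=2,
            )
            tpm = tpm * (1e6 / tpm.sum(axis=0))
        # else leave it to ExpressionStudy.validate to raise

    return ExpressionStudy(
        annotation, design, counts, tpm,
        validate=True,
    ) if time_grid is None else _validated_study(
        annotation, design, counts, tpm, time_grid
    )


def _validated_study(annotation, design, counts, tpm, time_grid) -> ExpressionStudy:
    study = ExpressionStudy(annotation, design, counts, tpm, validate=False)
    study.validate(time_grid=time_grid)
    return study


def write_results_table(
    records: pd.DataFrame,
    path: str | os.PathLike,
    *,
    allow_empty: bool = False,
) -> None:
    """Write a result table as TSV with stable column order and "NA" cells.

    Round-trip via :func:`pandas.read_csv` returns equal values (floats to
    representation precision).
    """
    if len(records) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table (pass allow_empty=True)")
    records.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def write_expression_study(study: ExpressionStudy, outdir: str | os.PathLike) -> dict:
    """Write counts/tpm/annotation/design TSVs; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "tpm": os.path.join(outdir, "tpm.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
    }
    study.counts.rename_axis("transcript_id").to_csv(paths["counts"], sep="\t")
    study.tpm.rename_axis("transcript_id").to_csv(
        paths["tpm"], sep="\t", float_format="%.10g"
    )
    study.transcripts.to_csv(paths["annotation"], sep="\t", index=False)
    study.samples.to_csv(paths["design"], sep="\t", index=False)
    return paths
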