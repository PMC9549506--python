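"""Core domain types for the PBMC time-course stability analysis.

The analysis operates on a transcript-level expression study: a set of
annotated transcripts (mRNA / lncRNA / circRNA), a paired sample design
(donors crossed with blood incubation times), and matched raw-count and
TPM matrices. Everything downstream — low-expression filtering,
differential expression, dynamic gain/loss classification, circRNA
origin calls — consumes the :class:`ExpressionStudy` container defined
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RNA_CLASSES",
    "DEFAULT_TIME_GRID",
    "TranscriptRecord",
    "SampleInfo",
    "ExpressionStudy",
    "DesignReport",
    "validate_design",
]

#: Recognised transcript classes.
RNA_CLASSES = ("circRNA", "mRNA", "lncRNA")

#: Incubation time grid of the blood-processing-delay design (hours at 4°C).
DEFAULT_TIME_GRID = (0.0, 2.0, 6.0, 12.0, 24.0, 48.0)

#: Columns of the tabular transcript annotation, in canonical order.
ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_id",
    "rna_class",
    "gene_biotype",
    "chrom",
    "start",
    "end",
    "strand",
    "exon_count",
    "length_nt",
]


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript, the unit of all per-transcript analysis.

    Coordinates are 0-based half-open (BED convention). For circRNAs the
    (start, end) span is the back-splice junction acceptor/donor span.
    """

    transcript_id: str
    gene_id: str
    rna_class: str
    gene_biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    length_nt: int

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(
                f"unknown rna_class {self.rna_class!r} for {self.transcript_id}"
            )
        if not self.start < self.end:
            raise ValueError(
                f"{self.transcript_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.exon_count < 1:
            raise ValueError(f"{self.transcript_id}: exon_count must be >= 1")
        if self.length_nt < 1:
            raise ValueError(f"{self.transcript_id}: length_nt must be >= 1")


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq library: donor identity and incubation time point."""

    sample_id: str
    donor: str
    time_h: float
    library_size: float = float("nan")


def _records_to_frame(records: Iterable[TranscriptRecord]) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in ANNOTATION_COLUMNS} for r in records
    ]
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return frame.set_index("transcript_id", drop=False)


def _samples_to_frame(samples: Iterable[SampleInfo]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "donor": s.donor,
            "time_h": float(s.time_h),
            "library_size": float(s.library_size),
        }
        for s in samples
    ]
    frame = pd.DataFrame(
        rows, columns=["sample_id", "donor", "time_h", "library_size"]
    )
    return frame.set_index("sample_id", drop=False)


class ExpressionStudy:
    """Counts + TPM matrices with annotation and sample design.

    Parameters
    ----------
    transcripts
        Annotation table indexed by ``transcript_id`` with the
        :data:`ANNOTATION_COLUMNS` columns, or an iterable of
        :class:`TranscriptRecord`.
    samples
        Design table indexed by ``sample_id`` with columns
        ``donor``, ``time_h`` (and optionally ``library_size``), or an
        iterable of :class:`SampleInfo`.
    counts, tpm
        transcripts x samples matrices (DataFrames). ``counts`` holds
        non-negative integers, ``tpm`` non-negative reals with each
        column summing to 1e6.
    validate
        Run consistency checks on construction (default True).
    """

    def __init__(
        self,
        transcripts,
        samples,
        counts: pd.DataFrame,
        tpm: pd.DataFrame,
        *,
        validate: bool = True,
    ) -> None:
        if not isinstance(transcripts, pd.DataFrame):
            transcripts = _records_to_frame(transcripts)
        if not isinstance(samples, pd.DataFrame):
            samples = _samples_to_frame(samples)
        if "sample_id" not in samples.columns:
            samples = samples.assign(sample_id=samples.index)
        if "library_size" not in samples.columns:
            samples = samples.assign(library_size=np.nan)
        self.transcripts = transcripts
        self.samples = samples
        self.counts = counts
        self.tpm = tpm
        if validate:
            self.validate()

    # -- basic protocol ------------------------------------------------

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.samples["time_h"].unique())

    def rna_class_of(self) -> pd.Series:
        """Per-transcript RNA class aligned to the count matrix rows."""
        return self.transcripts.loc[self.counts.index, "rna_class"]

    def samples_at(self, time_h: float) -> list[str]:
        sel = self.samples["time_h"] == float(time_h)
        return list(self.samples.index[sel])

    def subset_transcripts(self, ids: Sequence[str]) -> "ExpressionStudy":
        ids = list(ids)
        return ExpressionStudy(
            self.transcripts.loc[ids],
            self.samples,
            self.counts.loc[ids],
            self.tpm.loc[ids],
            validate=False,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ExpressionStudy {self.n_transcripts} transcripts x "
            f"{self.n_samples} samples, times={list(self.time_points)}>"
        )

    # -- validation ----------------------------------------------------

    def validate(self, *, time_grid: Sequence[float] | None = DEFAULT_TIME_GRID) -> None:
        """Check matrix/annotation/design consistency and invariants.

        Raises ``ValueError`` on the first violation found.
        """
        if list(self.counts.columns) != list(self.tpm.columns):
            raise ValueError("counts and tpm have different sample columns")
        if list(self.counts.index) != list(self.tpm.index):
            raise ValueError("counts and tpm have different transcript rows")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        unannotated = self.counts.index.difference(self.transcripts.index)
        if len(unannotated):
            raise ValueError(
                f"{len(unannotated)} matrix rows missing from annotation, "
                f"e.g. {list(unannotated[:5])}"
            )
        cvals = self.counts.to_numpy()
        if not np.issubdtype(cvals.dtype, np.number):
            raise ValueError("non-numeric values in counts matrix")
        if np.any(cvals < 0):
            raise ValueError("negative values in counts matrix")
        if np.any(cvals != np.floor(cvals)):
            raise ValueError("non-integer values in counts matrix")
        tvals = self.tpm.to_numpy(dtype=float)
        if np.any(tvals < 0):
            raise ValueError("negative values in TPM matrix")
        colsums = tvals.sum(axis=0)
        ok = np.isclose(colsums, 1e6, rtol=1e-3)
        if not np.all(ok):
            bad = list(self.tpm.columns[~ok])
            raise ValueError(
                f"TPM columns do not sum to 1e6 within 0.1%: {bad[:5]}"
            )
        if time_grid is not None:
            grid = set(float(t) for t in time_grid)
            off = set(float(t) for t in self.samples["time_h"]) - grid
            if off:
                raise ValueError(
                    f"time point outside design grid: {sorted(off)}"
                )
        dup = self.samples.duplicated(subset=["donor", "time_h"])
        if dup.any():
            raise ValueError(
                "duplicate (donor, time_h) pairs: "
                f"{list(self.samples.index[dup])}"
            )


@dataclass
class DesignReport:
    """Report of :func:`validate_design`: missing/duplicate design cells."""

    missing: list[tuple[str, float]] = field(default_factory=list)
    duplicates: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing and not self.duplicates


def validate_design(
    samples,
    expected_donors: int | Sequence[str] | None = None,
    expected_times: Sequence[float] = DEFAULT_TIME_GRID,
) -> DesignReport:
    """Check a sample design against the full donor x time factorial.

    ``expected_donors`` may be an explicit donor list or a count (in which
    case the donors observed in ``samples`` are used, and the count only
    determines whether donors are missing entirely).
    A complete 3 donors x 6 times design yields an empty report.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = _samples_to_frame(samples)
    donors_seen = list(pd.unique(samples["donor"]))
    if expected_donors is None or isinstance(expected_donors, int):
        donors = donors_seen
        n_expected = expected_donors if isinstance(expected_donors, int) else None
        if n_expected is not None and len(donors) < n_expected:
            # unknown donor labels are unrecoverable; report by placeholder
            donors = donors + [
                f"<missing donor {i + 1}>" for i in range(n_expected - len(donors))
            ]
    else:
        donors = list(expected_donors)
    report = DesignReport()
    have = set(zip(samples["donor"], samples["time_h"].astype(float)))
    for donor in donors:
        for t in expected_times:
            if (donor, float(t)) not in have:
                report.missing.append((donor, float(t)))
    dup_mask = samples.duplicated(subset=["donor", "time_h"], keep=False)
    if dup_mask.any():
        seen = set()
        for donor, t in zip(
            samples.loc[dup_mask, "donor"],
            samples.loc[dup_mask, "time_h"].astype(float),
        ):
            if (donor, t) not in seen:
                seen.add((donor, t))
                report.duplicates.append((donor, t))
    return report
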