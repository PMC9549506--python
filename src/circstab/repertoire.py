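"""Expressed-transcript repertoire construction and QC.

Two filters build the repertoire: a low-expression filter (a transcript
with TPM < 1 in more than four samples is excluded — the count is
absolute, not proportional) and a circRNA parental-gene biotype filter
(circRNAs are kept only when the host-gene biotype is protein_coding or
lncRNA). Composition statistics summarise the surviving repertoire by
RNA class; an mtRNA-content one-way ANOVA across time points serves as
a sample-viability QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionStudy

__all__ = [
    "filter_low_expression",
    "filter_circ_biotype",
    "composition_stats",
    "class_fractions",
    "mt_content_test",
    "RepertoireSummary",
    "MT_CHROMS",
]

ALLOWED_CIRC_BIOTYPES = {"protein_coding", "lncRNA"}
KNOWN_BIOTYPES = {
    "protein_coding", "lncRNA", "pseudogene", "misc_RNA", "snoRNA",
    "TR_gene", "miRNA", "rRNA",
}
MT_CHROMS = {"MT", "chrM", "chrMT", "M"}


def filter_low_expression(
    study: ExpressionStudy,
    *,
    tpm_threshold: float = 1.0,
    max_below: int = 4,
    proportional: bool = False,
) -> tuple[ExpressionStudy, list[str]]:
    """Remove lowly expressed transcripts.

    A transcript is removed iff the number of samples with TPM strictly
    below ``tpm_threshold`` is strictly greater than ``max_below``
    (i.e. TPM < 1 in more than four samples, at the defaults). With
    ``proportional=True`` the cutoff is ``max_below / 18`` of the actual
    sample count instead of the absolute number (off by default).

    Returns the filtered study (all samples preserved) and the removed
    transcript ids.
    """
    cutoff = max_below
    if proportional:
        cutoff = max_below / 18.0 * study.n_samples
    n_below = (study.tpm < tpm_threshold).sum(axis=1)
    removed = list(study.tpm.index[n_below > cutoff])
    kept = [t for t in study.tpm.index if t not in set(removed)]
    return study.subset_transcripts(kept), removed


def filter_circ_biotype(
    transcripts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Filter circRNAs by parental-gene biotype.

    circRNAs are kept iff ``gene_biotype`` is protein_coding or lncRNA;
    non-circ transcripts always pass. Returns (kept, excluded,
    per-biotype exclusion tally); unknown biotype strings are excluded
    and tallied under "other".
    """
    is_circ = transcripts["rna_class"] == "circRNA"
    bad = is_circ & ~transcripts["gene_biotype"].isin(ALLOWED_CIRC_BIOTYPES)
    excluded = transcripts[bad]
    kept = transcripts[~bad]
    tally: dict[str, int] = {}
    for bt in excluded["gene_biotype"]:
        key = bt if bt in KNOWN_BIOTYPES else "other"
        tally[key] = tally.get(key, 0) + 1
    return kept, excluded, tally


@dataclass
class RepertoireSummary:
    """Per-class composition of the expressed repertoire."""

    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    tpm_shares: dict[str, float]
    mean_tpm: dict[str, float]
    circ_exon_histogram: pd.DataFrame = field(default=None, repr=False)
    circ_length_histogram: pd.DataFrame = field(default=None, repr=False)
    aggregate: str = "mean TPM across samples"

    def as_table(self) -> pd.DataFrame:
        rows = []
        for cls in self.class_counts:
            rows.append({
                "rna_class": cls,
                "n_transcripts": self.class_counts[cls],
                "fraction_pct": round(100.0 * self.class_fractions[cls], 1),
                "tpm_share_pct": round(100.0 * self.tpm_shares[cls], 1),
                "mean_tpm": self.mean_tpm[cls],
            })
        return pd.DataFrame(rows)


def class_fractions(counts: dict[str, int]) -> dict[str, float]:
    """Fractions of the repertoire per class (sum to 1)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty repertoire")
    return {k: v / total for k, v in counts.items()}


def composition_stats(
    study: ExpressionStudy,
    *,
    length_bins: np.ndarray | None = None,
) -> RepertoireSummary:
    """Composition statistics of a (filtered) study.

    Counts and count-fractions per class, per-class share of total
    expression (on mean TPM across samples), mean TPM per class, and
    exon-count / length histograms for circRNAs.
    """
    if study.n_transcripts == 0:
        raise ValueError("empty study")
    classes = study.rna_class_of()
    counts = {str(k): int(v) for k, v in classes.value_counts().items()}
    fractions = class_fractions(counts)
    mean_tpm = study.tpm.mean(axis=1)
    total = float(mean_tpm.sum())
    shares = {
        cls: float(mean_tpm[classes == cls].sum()) / total for cls in counts
    }
    means = {
        cls: float(mean_tpm[classes == cls].mean()) for cls in counts
    }
    circ = study.transcripts[classes == "circRNA"]
    if len(circ):
        exon_hist = (
            circ["exon_count"].value_counts().sort_index()
            .rename_axis("exon_count").reset_index(name="count")
        )
        if length_bins is None:
            length_bins = np.arange(0, 2201, 200)
            length_bins = np.append(length_bins, np.inf)
        binned = pd.cut(circ["length_nt"], bins=length_bins, right=False)
        length_hist = (
            binned.value_counts().sort_index()
            .rename_axis("length_bin").reset_index(name="count")
        )
        length_hist["length_bin"] = length_hist["length_bin"].astype(str)
    else:
        exon_hist = pd.DataFrame(columns=["exon_count", "count"])
        length_hist = pd.DataFrame(columns=["length_bin", "count"])
    return RepertoireSummary(
        class_counts=counts,
        class_fractions=fractions,
        tpm_shares=shares,
        mean_tpm=means,
        circ_exon_histogram=exon_hist,
        circ_length_histogram=length_hist,
    )


def mt_content_test(
    study: ExpressionStudy,
    mt_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Per-sample mtRNA TPM totals and one-way ANOVA across time points.

    mtRNA membership comes from an explicit id set or, by default, from
    annotation chromosome names in :data:`MT_CHROMS`. Returns
    (per-sample totals frame, F, p). Degenerate inputs: identical group
    means give F = 0, p = 1; zero within-group variance with differing
    means gives F = inf, p = 0.
    """
    if mt_ids is None:
        chrom = study.transcripts["chrom"].astype(str)
        mt_ids = set(study.transcripts.index[chrom.isin(MT_CHROMS)])
    mt_ids = mt_ids & set(study.tpm.index)
    if not mt_ids:
        raise ValueError("empty mtRNA set")
    totals = study.tpm.loc[sorted(mt_ids)].sum(axis=0)
    frame = pd.DataFrame({
        "sample_id": totals.index,
        "time_h": study.samples.loc[totals.index, "time_h"].to_numpy(),
        "mt_tpm_total": totals.to_numpy(),
    })
    groups = [g["mt_tpm_total"].to_numpy() for _, g in frame.groupby("time_h")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 time points with >= 2 samples each")
    grand = np.concatenate(groups)
    ss_between = sum(
        len(g) * (g.mean() - grand.mean()) ** 2 for g in groups
    )
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_between <= 1e-12 * max(grand.var(), 1.0):
        return frame, 0.0, 1.0
    if ss_within == 0.0:
        return frame, math.inf, 0.0
    f_stat, p = stats.f_oneway(*groups)
    return frame, float(f_stat), float(p)
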