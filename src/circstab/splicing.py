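"""Percent-spliced-in (Ψ) computation and paired ΔΨ testing.

Ψ for an alternative-splicing event is the effective-length-normalised
inclusion ratio

    Ψ = (I / l_I) / (I / l_I + S / l_S)

with I/S the inclusion/skipping junction read counts and l_I/l_S the
effective lengths of the two forms (rMATS convention; setting both
lengths to 1 recovers the raw junction ratio). ΔΨ at time t is the
within-donor difference Ψ(t) − Ψ(0), tested with a paired t-test across
donors. An event is significantly differentially spliced when
p < .05 and |mean ΔΨ| ≥ .05.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ASEventTable",
    "compute_psi",
    "psi_matrix",
    "identify_events",
    "test_delta_psi",
    "normalized_as_rate",
    "DeltaPsiModel",
    "DeltaPsiResults",
]


@dataclass
class ASEventTable:
    """AS events with per-sample inclusion/skipping junction counts.

    ``events``: event_id-indexed frame with gene_id, rna_class,
    event_type (SE/A5SS/A3SS/RI) and effective lengths.
    ``inclusion``/``skipping``: events x samples count matrices.
    ``design``: sample_id-indexed frame with donor and time_h.
    """

    events: pd.DataFrame
    inclusion: pd.DataFrame
    skipping: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.inclusion.index) != list(self.skipping.index):
            raise ValueError("inclusion/skipping row mismatch")
        if list(self.inclusion.columns) != list(self.skipping.columns):
            raise ValueError("inclusion/skipping column mismatch")
        if (self.inclusion.to_numpy() < 0).any() or (
            self.skipping.to_numpy() < 0
        ).any():
            raise ValueError("negative junction counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.inclusion.columns)

    def samples_at(self, time_h: float) -> list[str]:
        sel = self.design["time_h"] == float(time_h)
        return list(self.design.index[sel])

    def write(self, path: str | os.PathLike) -> None:
        """Single-TSV export: metadata plus inc_/skip_ count columns."""
        out = self.events.copy()
        for sid in self.sample_ids:
            out[f"inc_{sid}"] = self.inclusion[sid]
            out[f"skip_{sid}"] = self.skipping[sid]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | os.PathLike, design: pd.DataFrame) -> "ASEventTable":
        frame = pd.read_csv(path, sep="\t").set_index("event_id", drop=False)
        inc_cols = [c for c in frame.columns if c.startswith("inc_")]
        sids = [c[len("inc_"):] for c in inc_cols]
        inclusion = frame[inc_cols].copy()
        inclusion.columns = sids
        skipping = frame[[f"skip_{s}" for s in sids]].copy()
        skipping.columns = sids
        meta = frame[["event_id", "gene_id", "rna_class", "event_type",
                      "eff_len_inclusion", "eff_len_skipping"]]
        return cls(meta, inclusion, skipping, design.loc[sids])


def compute_psi(
    inclusion: float,
    skipping: float,
    eff_len_inc: float = 1.0,
    eff_len_skip: float = 1.0,
) -> float:
    """Ψ for one event in one sample; NaN when no supporting reads."""
    if inclusion < 0 or skipping < 0:
        raise ValueError("junction counts must be non-negative")
    if eff_len_inc < 1 or eff_len_skip < 1:
        raise ValueError("effective lengths must be >= 1")
    if inclusion + skipping == 0:
        return math.nan
    i = inclusion / eff_len_inc
    s = skipping / eff_len_skip
    return i / (i + s)


def psi_matrix(table: ASEventTable, *, length_normalized: bool = True) -> pd.DataFrame:
    """Events x samples Ψ matrix (NaN where no reads support the event)."""
    inc = table.inclusion.to_numpy(dtype=float)
    skip = table.skipping.to_numpy(dtype=float)
    if length_normalized:
        l_i = table.events["eff_len_inclusion"].to_numpy(dtype=float)[:, None]
        l_s = table.events["eff_len_skipping"].to_numpy(dtype=float)[:, None]
    else:
        l_i = l_s = 1.0
    i = inc / l_i
    s = skip / l_s
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(inc + skip > 0, i / (i + s), np.nan)
    return pd.DataFrame(psi, index=table.inclusion.index,
                        columns=table.inclusion.columns)


def identify_events(
    table: ASEventTable,
    *,
    min_total_reads: int = 10,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Events with >= min_total_reads junction support in every sample.

    Returns the identified event ids and per-RNA-class identified totals
    (the normalisation denominators for differential-AS rates).
    """
    cols = list(sample_ids) if sample_ids is not None else table.sample_ids
    total = table.inclusion[cols].to_numpy() + table.skipping[cols].to_numpy()
    ok = (total >= min_total_reads).all(axis=1)
    ids = list(table.inclusion.index[ok])
    tallies = (
        table.events.loc[ids, "rna_class"].value_counts().to_dict()
    )
    return ids, {str(k): int(v) for k, v in tallies.items()}


def _paired_t(diffs: np.ndarray) -> tuple[float, float, str]:
    """Two-sided paired t-test on a vector of per-donor differences.

    Returns (mean, p, flag). Degenerate cases: zero variance with
    nonzero mean -> p = 0; zero variance and zero mean -> p = 1.
    """
    n = len(diffs)
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return mean, 1.0, "zero_variance"
        return mean, 0.0, "zero_variance"
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return mean, p, ""


def test_delta_psi(
    event_psi_t: dict[str, float] | pd.Series,
    event_psi_0: dict[str, float] | pd.Series,
    *,
    alpha: float = 0.05,
    min_delta: float = 0.05,
) -> dict:
    """Paired ΔΨ test for one event given per-donor Ψ at t and at 0 h.

    Donors with an undefined Ψ at either time are dropped; fewer than two
    complete pairs yields an "untestable" NA result. Significance
    requires p < alpha and |mean ΔΨ| >= min_delta.
    """
    psi_t = pd.Series(event_psi_t, dtype=float)
    psi_0 = pd.Series(event_psi_0, dtype=float)
    donors = psi_t.index.intersection(psi_0.index)
    d = (psi_t[donors] - psi_0[donors]).dropna()
    if len(d) < 2:
        return {"mean_delta_psi": math.nan, "p_value": math.nan,
                "significant": False, "n_pairs": int(len(d)),
                "flag": "untestable"}
    mean, p, flag = _paired_t(d.to_numpy())
    return {
        "mean_delta_psi": mean,
        "p_value": p,
        "significant": bool(p < alpha and abs(mean) >= min_delta),
        "n_pairs": int(len(d)),
        "flag": flag,
    }


def normalized_as_rate(
    results: pd.DataFrame,
    identified_totals: dict[str, int],
) -> pd.DataFrame:
    """Differential-AS rate per class and time point.

    rate(class, t) = #significant(class, t) / identified_total(class);
    NaN with a warning column when the denominator is zero/absent.
    """
    rows = []
    for (cls, t), grp in results.groupby(["rna_class", "contrast_time_h"]):
        denom = identified_totals.get(cls, 0)
        n_sig = int(grp["significant"].sum())
        rate = n_sig / denom if denom > 0 else math.nan
        rows.append({"rna_class": cls, "contrast_time_h": t,
                     "n_significant": n_sig, "n_identified": denom,
                     "rate": rate})
    return pd.DataFrame(rows)


class DeltaPsiModel:
    """Paired differential-splicing model over an AS event table.

    Computes per-sample Ψ, restricts to events identified in the
    contrast samples, and tests within-donor ΔΨ against the 0 h baseline
    at each requested time point.

    Parameters
    ----------
    table
        The :class:`ASEventTable` with junction counts and design.
    length_normalized
        Use effective-length-normalised Ψ (default). ``False`` falls back
        to the raw junction ratio.
    min_total_reads
        Identification support threshold (total junction reads required
        in every contrast sample).
    """

    def __init__(
        self,
        table: ASEventTable,
        *,
        length_normalized: bool = True,
        min_total_reads: int = 10,
    ) -> None:
        self.table = table
        self.length_normalized = length_normalized
        self.min_total_reads = min_total_reads
        self.psi = psi_matrix(table, length_normalized=length_normalized)
        if table.design["donor"].nunique() < 4:
            self._low_df_warning = (
                "paired t-test has "
                f"{table.design['donor'].nunique() - 1} degrees of freedom; "
                "calibration is approximate at such small donor numbers"
            )
        else:
            self._low_df_warning = None

    def fit(
        self,
        times: Sequence[float] | None = None,
        *,
        alpha: float = 0.05,
        min_delta: float = 0.05,
        adjust: bool = False,
    ) -> "DeltaPsiResults":
        """Test ΔΨ at each non-zero time point against 0 h.

        ``adjust=True`` applies BH across events within a contrast before
        the significance call (off by default: the significance rule is
        defined on raw p-values).
        """
        design = self.table.design
        all_times = sorted(design["time_h"].unique())
        if times is None:
            times = [t for t in all_times if t > 0]
        rows = []
        identified: dict[float, dict[str, int]] = {}
        base_samples = self.table.samples_at(0.0)
        for t in times:
            t_samples = self.table.samples_at(t)
            contrast_samples = base_samples + t_samples
            ids, tallies = identify_events(
                self.table, min_total_reads=self.min_total_reads,
                sample_ids=contrast_samples,
            )
            identified[float(t)] = tallies
            donor_of = design["donor"]
            psi0 = self.psi.loc[ids, base_samples]
            psit = self.psi.loc[ids, t_samples]
            psi0.columns = [donor_of[s] for s in base_samples]
            psit.columns = [donor_of[s] for s in t_samples]
            donors = psi0.columns.intersection(psit.columns)
            d = psit[donors].to_numpy() - psi0[donors].to_numpy()
            n_ok = np.sum(~np.isnan(d), axis=1)
            mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
            sd = np.nanstd(d, axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                tstat = mean / (sd / np.sqrt(n_ok))
            p = 2.0 * stats.t.sf(np.abs(tstat), df=np.maximum(n_ok - 1, 1))
            p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
            p = np.where(n_ok < 2, np.nan, p)
            mean = np.where(n_ok < 1, np.nan, mean)
            frame = pd.DataFrame({
                "event_id": ids,
                "gene_id": self.table.events.loc[ids, "gene_id"].to_numpy(),
                "rna_class": self.table.events.loc[ids, "rna_class"].to_numpy(),
                "event_type": self.table.events.loc[ids, "event_type"].to_numpy(),
                "contrast_time_h": float(t),
                "mean_delta_psi": mean,
                "p_value": p,
                "n_pairs": n_ok,
            })
            rows.append(frame)
        result = pd.concat(rows, ignore_index=True)
        if adjust:
            from .diffexpr import adjust_bh
            result["p_effective"] = np.concatenate([
                adjust_bh(grp["p_value"].to_numpy())
                for _, grp in result.groupby("contrast_time_h", sort=True)
            ])
        else:
            result["p_effective"] = result["p_value"]
        result["significant"] = (
            (result["p_effective"] < alpha)
            & (result["mean_delta_psi"].abs() >= min_delta)
        )
        return DeltaPsiResults(
            table=result, identified=identified, alpha=alpha,
            min_delta=min_delta, model=self,
        )


@dataclass
class DeltaPsiResults:
    """Per-event ΔΨ tests plus identification denominators."""

    table: pd.DataFrame
    identified: dict[float, dict[str, int]]
    alpha: float
    min_delta: float
    model: DeltaPsiModel = field(repr=False, default=None)

    def rates(self, time_h: float | None = None) -> pd.DataFrame:
        """Class-normalised differential-AS rates (per contrast)."""
        frames = []
        for t, tallies in self.identified.items():
            if time_h is not None and float(t) != float(time_h):
                continue
            sub = self.table[self.table["contrast_time_h"] == float(t)]
            frames.append(normalized_as_rate(sub, tallies))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Significant-event counts and rates per class and time."""
        return self.rates().sort_values(
            ["contrast_time_h", "rna_class"]
        ).reset_index(drop=True)
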