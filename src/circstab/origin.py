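"""Transcription- vs splice-derived classification of dysregulated circRNAs.

circRNA abundance is the product of host-gene transcription and
back-splicing efficiency, so a dysregulated circRNA can be explained by
either factor. The classification is a truth table over the DE calls of
the circRNA and its host gene at the same contrast and thresholds:

=============  ============  ====================
circRNA call   host call     category
=============  ============  ====================
up             up            transcription_up
down           down          transcription_down
up             none          splice_up
down           none          splice_down
up/down        opposite      discordant
none           any           none
=============  ============  ====================

Host-gene DE is evaluated at gene level (transcript counts summed per
gene before fitting) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_origin",
    "correlate_fold_changes",
    "ORIGIN_CATEGORIES",
]

ORIGIN_CATEGORIES = (
    "transcription_up", "transcription_down",
    "splice_up", "splice_down", "discordant", "none",
)


def _category(circ_call: str, host_call: str) -> str:
    if circ_call == "none":
        return "none"
    if host_call == circ_call:
        return f"transcription_{circ_call}"
    if host_call == "none":
        return f"splice_{circ_call}"
    return "discordant"


def _host_lookup(host_de: pd.DataFrame, contrast_time_h: float) -> pd.DataFrame:
    sub = host_de[host_de["contrast_time_h"] == float(contrast_time_h)]
    key = "gene_id" if "gene_id" in sub.columns else sub.columns[0]
    return sub.set_index(key)


def classify_origin(
    circ_de: pd.DataFrame,
    host_de: pd.DataFrame,
    contrast_time_h: float,
    *,
    circ_host_map: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify each circRNA DE record at one contrast.

    ``circ_de`` rows need transcript_id, gene_id (host), log2fc and
    de_call; ``host_de`` is a gene-level DE table with gene_id, log2fc
    and de_call. ``circ_host_map`` optionally overrides the circ ->
    host-gene mapping. circRNAs without a resolvable host record are
    skipped with a warning and tallied under "unmapped".

    Returns (per-circRNA origin calls, category tallies).
    """
    circ = circ_de[circ_de["contrast_time_h"] == float(contrast_time_h)]
    hosts = _host_lookup(host_de, contrast_time_h)
    rows = []
    tallies = {c: 0 for c in ORIGIN_CATEGORIES}
    tallies["unmapped"] = 0
    for rec in circ.itertuples(index=False):
        circ_id = rec.transcript_id
        host_gene = (
            circ_host_map[circ_id] if circ_host_map is not None
            else rec.gene_id
        )
        if host_gene not in hosts.index:
            tallies["unmapped"] += 1
            continue
        host = hosts.loc[host_gene]
        cat = _category(rec.de_call, host["de_call"])
        tallies[cat] += 1
        rows.append({
            "circ_id": circ_id,
            "host_gene_id": host_gene,
            "contrast_time_h": float(contrast_time_h),
            "circ_log2fc": rec.log2fc,
            "host_log2fc": host["log2fc"],
            "circ_call": rec.de_call,
            "host_call": host["de_call"],
            "category": cat,
        })
    if tallies["unmapped"]:
        warnings.warn(
            f"{tallies['unmapped']} circRNAs without host DE record skipped",
            stacklevel=2,
        )
    calls = pd.DataFrame(rows, columns=[
        "circ_id", "host_gene_id", "contrast_time_h", "circ_log2fc",
        "host_log2fc", "circ_call", "host_call", "category",
    ])
    return calls, tallies


def correlate_fold_changes(
    circ_de: pd.DataFrame,
    host_de: pd.DataFrame,
    contrast_time_h: float,
    *,
    method: str = "pearson",
    circ_host_map: pd.Series | None = None,
) -> tuple[float, float, int]:
    """Correlation of circRNA vs host-gene log2 fold changes.

    Pairs with an NA fold change on either side are dropped; fewer than
    three complete pairs is an error. Returns (r, p, n).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    circ = circ_de[circ_de["contrast_time_h"] == float(contrast_time_h)]
    hosts = _host_lookup(host_de, contrast_time_h)
    x, y = [], []
    for rec in circ.itertuples(index=False):
        host_gene = (
            circ_host_map[rec.transcript_id] if circ_host_map is not None
            else rec.gene_id
        )
        if host_gene not in hosts.index:
            continue
        cx, hy = rec.log2fc, hosts.loc[host_gene, "log2fc"]
        if np.isfinite(cx) and np.isfinite(hy):
            x.append(cx)
            y.append(hy)
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p), len(x)
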