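import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from circstab.model import ExpressionStudy
from circstab.simulate import SimulationConfig, simulate_expression

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_study(
    tpm_rows: dict[str, list[float]],
    times: list[float],
    donors: list[str],
    *,
    rna_class: dict[str, str] | None = None,
    counts_rows: dict[str, list[int]] | None = None,
    chrom: dict[str, str] | None = None,
) -> ExpressionStudy:
    """Small hand-built study; one column per (donor, time) in given order.

    Column order is donor-major: for donors [a, b] and times [0, 24] the
    columns are a_T0, a_T24, b_T0, b_T24.
    """
    sample_ids, rows = [], []
    for d in donors:
        for t in times:
            sid = f"{d}_T{int(t)}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "donor": d, "time_h": float(t),
                         "library_size": 1e6})
    design = pd.DataFrame(rows).set_index("sample_id", drop=False)
    tids = list(tpm_rows)
    tpm = pd.DataFrame(
        [tpm_rows[t] for t in tids], index=tids, columns=sample_ids,
        dtype=float,
    )
    if counts_rows is None:
        counts = (tpm * 10).round().astype(int)
    else:
        counts = pd.DataFrame(
            [counts_rows[t] for t in tids], index=tids, columns=sample_ids
        )
    ann = pd.DataFrame({
        "transcript_id": tids,
        "gene_id": [f"G_{t}" for t in tids],
        "rna_class": [
            (rna_class or {}).get(t, "mRNA") for t in tids
        ],
        "gene_biotype": "protein_coding",
        "chrom": [(chrom or {}).get(t, "1") for t in tids],
        "start": 0,
        "end": 1000,
        "strand": "+",
        "exon_count": 3,
        "length_nt": 1000,
    }).set_index("transcript_id", drop=False)
    return ExpressionStudy(ann, design, counts, tpm, validate=False)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulated study shared across tests."""
    cfg = SimulationConfig(seed=0)
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """No-dynamics (null) simulation used by calibration tests."""
    cfg = SimulationConfig(
        n_mrna=1600, n_lncrna=200, n_circ=200,
        frac_decaying=0.0, frac_newborn=0.0,
        donor_sd=0.1, nb_dispersion=0.1, seed=0,
    )
    return simulate_expression(cfg)
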