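import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circstab.simulate import SimulationConfig, simulate_junctions
from circstab.splicing import (
    ASEventTable,
    DeltaPsiModel,
    compute_psi,
    identify_events,
    normalized_as_rate,
    psi_matrix,
    test_delta_psi as paired_delta_psi,
)


def _toy_table(inc, skip, rna_class=None, types=None, lens=None,
               times=(0.0, 48.0), donors=("D1", "D2", "D3")):
    """Build an ASEventTable from events x samples count arrays."""
    inc = np.asarray(inc)
    m = inc.shape[0]
    sample_ids, rows = [], []
    for d in donors:
        for t in times:
            sid = f"{d}_T{int(t)}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "donor": d, "time_h": float(t)})
    design = pd.DataFrame(rows).set_index("sample_id", drop=False)
    eid = [f"e{i}" for i in range(m)]
    lens = lens or [(1, 1)] * m
    events = pd.DataFrame({
        "event_id": eid,
        "gene_id": [f"g{i}" for i in range(m)],
        "rna_class": rna_class or ["mRNA"] * m,
        "event_type": types or ["SE"] * m,
        "eff_len_inclusion": [a for a, _ in lens],
        "eff_len_skipping": [b for _, b in lens],
    }).set_index("event_id", drop=False)
    return ASEventTable(
        events,
        pd.DataFrame(inc, index=eid, columns=sample_ids),
        pd.DataFrame(np.asarray(skip), index=eid, columns=sample_ids),
        design,
    )


class TestComputePsi:
    def test_symmetric_counts_give_half(self):
        assert compute_psi(10, 10, 1, 1) == pytest.approx(0.5)

    def test_boundaries(self):
        assert compute_psi(5, 0) == 1.0
        assert compute_psi(0, 5) == 0.0
        assert math.isnan(compute_psi(0, 0))

    def test_length_normalised_formula(self):
        """I=30, S=10 with lengths 2 and 1: Ψ = 15 / (15 + 10) = 0.6."""
        assert compute_psi(30, 10, 2, 1) == pytest.approx(0.6)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 5)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=1, max_value=10),
        st.integers(min_value=1, max_value=10),
    )
    def test_in_unit_interval_and_scale_invariant(self, i, s, li, ls):
        psi = compute_psi(i, s, li, ls)
        if i + s == 0:
            assert math.isnan(psi)
        else:
            assert 0.0 <= psi <= 1.0
            assert compute_psi(3 * i, 3 * s, li, ls) == pytest.approx(psi)

    def test_matrix_agrees_with_scalar(self):
        table = _toy_table(
            [[3, 5, 0, 2, 7, 1]], [[1, 5, 0, 8, 3, 9]], lens=[(2, 1)]
        )
        mat = psi_matrix(table)
        for j, sid in enumerate(table.sample_ids):
            expected = compute_psi(
                table.inclusion.iloc[0, j], table.skipping.iloc[0, j], 2, 1
            )
            got = mat.iloc[0, j]
            assert (math.isnan(got) and math.isnan(expected)) or (
                got == pytest.approx(expected)
            )


class TestIdentifyEvents:
    def test_zero_support_sample_excludes(self):
        inc = [[5, 5, 5, 5, 5, 0]]
        skip = [[5, 5, 5, 5, 5, 0]]
        ids, tallies = identify_events(_toy_table(inc, skip))
        assert ids == []

    def test_zero_threshold_keeps_all(self):
        inc = [[0] * 6, [1] * 6]
        skip = [[0] * 6, [0] * 6]
        ids, _ = identify_events(_toy_table(inc, skip), min_total_reads=0)
        assert len(ids) == 2

    def test_hand_enumerated_mixed_set(self):
        """6 events, threshold 10: only those with >=10 reads everywhere."""
        inc = [
            [10] * 6,          # total 10 everywhere -> identified
            [4] * 6,           # total 8 everywhere -> no
            [20, 20, 20, 20, 20, 3],  # one weak sample -> no
            [6] * 6,           # total 12 everywhere -> yes
            [0] * 6,           # -> no
            [100] * 6,         # -> yes
        ]
        skip = [
            [0] * 6, [4] * 6, [0] * 6, [6] * 6, [5] * 6, [0] * 6,
        ]
        classes = ["mRNA", "mRNA", "circRNA", "circRNA", "mRNA", "circRNA"]
        ids, tallies = identify_events(
            _toy_table(inc, skip, rna_class=classes), min_total_reads=10
        )
        assert ids == ["e0", "e3", "e5"]
        assert tallies == {"mRNA": 1, "circRNA": 2}


class TestPairedDeltaPsi:
    def test_null_identity(self):
        res = paired_delta_psi(
            {"D1": 0.5, "D2": 0.6, "D3": 0.4},
            {"D1": 0.5, "D2": 0.6, "D3": 0.4},
        )
        assert res["mean_delta_psi"] == 0.0
        assert not res["significant"]

    def test_closed_form_t_on_three_donors(self):
        """d = (0.10, 0.12, 0.08): t = mean / (sd/√3) with 2 df."""
        d = np.array([0.10, 0.12, 0.08])
        res = paired_delta_psi(
            {"D1": 0.60, "D2": 0.62, "D3": 0.58},
            {"D1": 0.50, "D2": 0.50, "D3": 0.50},
        )
        t = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        p_expected = 2 * stats.t.sf(abs(t), df=2)
        assert res["p_value"] == pytest.approx(p_expected, abs=1e-9)
        assert res["mean_delta_psi"] == pytest.approx(0.10)

    def test_effect_size_gate(self):
        """Cancelling shifts: mean ΔΨ = 0 is never significant."""
        res = paired_delta_psi(
            {"D1": 0.7, "D2": 0.3, "D3": 0.5},
            {"D1": 0.5, "D2": 0.5, "D3": 0.5},
        )
        assert res["mean_delta_psi"] == pytest.approx(0.0)
        assert not res["significant"]

    def test_untestable_with_one_pair(self):
        res = paired_delta_psi({"D1": 0.5, "D2": np.nan}, {"D1": 0.4})
        assert res["flag"] == "untestable"
        assert math.isnan(res["p_value"])

    def test_zero_variance_edge_cases(self):
        same_shift = paired_delta_psi(
            {"D1": 0.6, "D2": 0.6}, {"D1": 0.4, "D2": 0.4}
        )
        assert same_shift["p_value"] == 0.0
        no_shift = paired_delta_psi(
            {"D1": 0.4, "D2": 0.4}, {"D1": 0.4, "D2": 0.4}
        )
        assert no_shift["p_value"] == 1.0
        assert not no_shift["significant"]

    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=0, max_value=2 ** 31 - 1),
    )
    @settings(max_examples=100)
    def test_matches_scipy_paired_t(self, n_donors, seed):
        """Random small instances agree with scipy's paired t-test."""
        rng = np.random.default_rng(seed)
        psi_t = rng.uniform(0, 1, n_donors)
        psi_0 = rng.uniform(0, 1, n_donors)
        donors = {f"D{k}": v for k, v in enumerate(psi_t)}
        base = {f"D{k}": v for k, v in enumerate(psi_0)}
        res = paired_delta_psi(donors, base)
        d = psi_t - psi_0
        if np.std(d, ddof=1) == 0:
            return  # covered by the zero-variance edge-case test
        ref = stats.ttest_rel(psi_t, psi_0)
        assert res["p_value"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestRates:
    def _results(self, sig_flags, classes, time=48.0):
        return pd.DataFrame({
            "event_id": [f"e{i}" for i in range(len(sig_flags))],
            "rna_class": classes,
            "contrast_time_h": [time] * len(sig_flags),
            "significant": sig_flags,
        })

    def test_rate_arithmetic(self):
        res = self._results([True] * 5 + [False] * 15, ["mRNA"] * 20)
        rates = normalized_as_rate(res, {"mRNA": 100})
        assert rates["rate"].iloc[0] == pytest.approx(0.05)

    def test_zero_significant(self):
        res = self._results([False] * 4, ["circRNA"] * 4)
        rates = normalized_as_rate(res, {"circRNA": 10})
        assert rates["rate"].iloc[0] == 0.0

    def test_class_relabelling_equivariance(self):
        res = self._results(
            [True, False, True, True], ["mRNA", "mRNA", "circRNA", "circRNA"]
        )
        r1 = normalized_as_rate(res, {"mRNA": 10, "circRNA": 20})
        swapped = res.replace({"mRNA": "circRNA", "circRNA": "mRNA"})
        r2 = normalized_as_rate(swapped, {"circRNA": 10, "mRNA": 20})
        a = r1.set_index("rna_class")["rate"]
        b = r2.set_index("rna_class")["rate"]
        assert a["mRNA"] == b["circRNA"]
        assert a["circRNA"] == b["mRNA"]

    def test_zero_denominator_is_na(self):
        res = self._results([True], ["mRNA"])
        rates = normalized_as_rate(res, {})
        assert math.isnan(rates["rate"].iloc[0])


class TestDeltaPsiModel:
    def test_power_on_planted_shifts(self):
        """ΔΨ=0.3 planted at 48 h, depth 200: most shifts are recovered
        and the circRNA rate stays below the mRNA rate (shifts planted
        in mRNAs only)."""
        recovered = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_as_events=600, frac_as_shifted=0.5,
                delta_psi_effect=0.3, event_read_depth=200, seed=seed,
            )
            table, truth = simulate_junctions(cfg)
            res = DeltaPsiModel(table).fit(times=[48.0])
            t48 = res.table.set_index("event_id")
            shifted = [
                e for e in truth.events.index[truth.events["shifted"]]
                if e in t48.index
            ]
            recovered.append(t48.loc[shifted, "significant"].mean())
            rates = res.rates(48.0).set_index("rna_class")["rate"]
            assert rates["circRNA"] < rates["mRNA"]
        assert min(recovered) >= 0.6

    def test_gate_only_shrinks_significant_set(self):
        cfg = SimulationConfig(n_as_events=500, frac_as_shifted=0.3, seed=4)
        table, _ = simulate_junctions(cfg)
        res = DeltaPsiModel(table).fit(times=[48.0])
        by_p = res.table["p_value"] < 0.05
        gated = res.table["significant"]
        assert gated.sum() <= by_p.sum()
        assert not (gated & ~by_p).any()
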