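import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from circstab.diffexpr import (
    DifferentialExpressionModel,
    adjust_bh,
    call_de,
    classify_dynamics,
    estimate_size_factors,
    fit_nb_glm,
    fit_nb_lrt,
    shrink_lfc,
)

from conftest import make_study


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        y = np.tile([[10], [20], [5]], (1, 2))
        np.testing.assert_allclose(estimate_size_factors(y), [1.0, 1.0])

    def test_doubled_sample_scaling(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, size=30)
        y = np.column_stack([a, 2 * a])
        sf = estimate_size_factors(y)
        assert sf[1] / sf[0] == pytest.approx(2.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_matches_brute_force_median_of_ratios(self):
        y = np.array([
            [10, 20, 15],
            [100, 80, 120],
            [5, 5, 5],
            [50, 60, 40],
            [7, 9, 8],
        ], dtype=float)
        # brute-force oracle
        logs = np.log(y)
        ref = logs.mean(axis=1)
        expected = np.exp(np.median(logs - ref[:, None], axis=0))
        expected /= np.exp(np.log(expected).mean())
        np.testing.assert_allclose(estimate_size_factors(y), expected)

    def test_fallback_to_totals_with_warning(self):
        y = np.array([[0, 5], [3, 0]], dtype=float)
        with pytest.warns(UserWarning, match="total-count"):
            sf = estimate_size_factors(y)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)


class TestNBGLM:
    def test_matches_statsmodels_negative_binomial(self):
        rng = np.random.default_rng(4)
        n_s = 6
        X = np.column_stack([
            np.ones(n_s), [0, 0, 1, 1, 0, 1], [0, 0, 0, 1, 1, 1],
        ])
        y = rng.poisson([40, 50, 90, 110, 45, 100], size=(5, n_s)).astype(float)
        alpha = np.full(5, 0.05)
        offset = np.zeros(n_s)
        beta, ll, cov = fit_nb_glm(y, X, alpha, offset)
        for i in range(5):
            ref = sm.GLM(
                y[i], X, family=sm.families.NegativeBinomial(alpha=0.05)
            ).fit()
            np.testing.assert_allclose(beta[i], ref.params, atol=1e-5)

    def test_poisson_limit_lrt_matches_poisson_glm(self):
        """At dispersion→0 the NB LRT equals the Poisson GLM deviance test."""
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson([30, 35, 28, 60, 70, 65], size=(20, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        donors = ["a", "b", "c", "a", "b", "c"]
        cond = np.array([0, 0, 0, 1, 1, 1])
        res = fit_nb_lrt(
            counts, donors, cond,
            size_factors=np.ones(6),
            dispersions=np.full(20, 1e-8),
        )
        X_full = np.column_stack([
            np.ones(6), [0, 1, 0, 0, 1, 0], [0, 0, 1, 0, 0, 1], cond,
        ])
        for i in range(20):
            full = sm.GLM(counts.iloc[i].to_numpy(), X_full,
                          family=sm.families.Poisson()).fit()
            red = sm.GLM(counts.iloc[i].to_numpy(), X_full[:, :3],
                         family=sm.families.Poisson()).fit()
            lrt = 2 * (full.llf - red.llf)
            from scipy.stats import chi2
            p_ref = chi2.sf(lrt, df=1)
            assert res["p_value"].iloc[i] == pytest.approx(p_ref, abs=1e-3)

    def test_null_identity_rows(self):
        """Identical counts per donor across conditions give log2fc 0, p ~ 1."""
        counts = pd.DataFrame(
            [[50, 80, 60, 50, 80, 60]] * 3,
            columns=[f"s{i}" for i in range(6)],
        )
        res = fit_nb_lrt(
            counts, ["a", "b", "c", "a", "b", "c"],
            np.array([0, 0, 0, 1, 1, 1]),
            size_factors=np.ones(6),
            dispersions=np.full(3, 0.1),
        )
        np.testing.assert_allclose(res["log2fc_raw"], 0.0, atol=1e-6)
        np.testing.assert_allclose(res["lrt_stat"], 0.0, atol=1e-6)
        np.testing.assert_allclose(res["p_value"], 1.0, atol=1e-4)

    def test_all_zero_row_is_na(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 0, 0], [10, 12, 9, 30, 33, 28]],
            columns=[f"s{i}" for i in range(6)],
        )
        res = fit_nb_lrt(
            counts, ["a", "b", "c", "a", "b", "c"],
            np.array([0, 0, 0, 1, 1, 1]),
            size_factors=np.ones(6),
            dispersions=np.full(2, 0.1),
        )
        assert res["status"].iloc[0] == "all_zero"
        assert np.isnan(res["p_value"].iloc[0])
        assert res["status"].iloc[1] == "ok"

    def test_lrt_stat_nonnegative(self, null_sim):
        study, _ = null_sim
        sub = study.subset_transcripts(list(study.counts.index[:300]))
        res = DifferentialExpressionModel(sub).fit(times=[24.0])
        ok = res.table[res.table["status"] == "ok"]
        assert (ok["lrt_stat"] >= 0).all()


class TestShrinkLfc:
    def test_zero_stays_zero(self):
        assert shrink_lfc(0.0, 1.0, 1.0) == 0.0

    def test_small_se_approaches_raw(self):
        assert shrink_lfc(2.0, 1e-8, 1.0) == pytest.approx(2.0, rel=1e-6)

    def test_matches_grid_search_map(self):
        """raw=2, se=1, prior 1: numeric MAP of the penalised objective."""
        grid = np.linspace(-5, 5, 200001)
        post = -((grid - 2.0) ** 2) / (2 * 1.0) - grid ** 2 / 2.0
        expected = grid[np.argmax(post)]
        assert shrink_lfc(2.0, 1.0, 1.0) == pytest.approx(expected, abs=1e-4)

    def test_magnitude_never_grows_and_monotone(self):
        raws = np.linspace(-4, 4, 41)
        shr = shrink_lfc(raws, np.full_like(raws, 0.7), 1.0)
        assert (np.abs(shr) <= np.abs(raws) + 1e-12).all()
        assert (np.diff(shr) > 0).all()

    def test_bad_se_passes_through(self):
        assert shrink_lfc(1.5, 0.0, 1.0) == 1.5
        assert shrink_lfc(1.5, np.nan, 1.0) == 1.5


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_ties(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])
        np.testing.assert_allclose(adjust_bh([0.1, 0.1, 0.1]), [0.1] * 3)

    def test_na_excluded_from_m(self):
        out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m=2: padj = min(0.01*2/1, ...) etc.
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=200)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        mine = adjust_bh(p)
        # brute-force step-up oracle
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(mine, expected, rtol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        from statsmodels.stats.multitest import multipletests
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_bh(p), ref, rtol=1e-12)


class TestCallDE:
    def _frame(self, lfc, padj):
        return pd.DataFrame({
            "rna_class": ["mRNA"] * len(lfc),
            "contrast_time_h": [24.0] * len(lfc),
            "log2fc": lfc, "padj": padj,
        })

    def test_strict_boundaries(self):
        res = call_de(self._frame([0.5, 0.51, -0.51], [0.04, 0.04, 0.05]))
        assert list(res["de_call"]) == ["none", "up", "none"]

    def test_na_never_called(self):
        res = call_de(self._frame([3.0], [np.nan]))
        assert list(res["de_call"]) == ["none"]

    def test_proportion_arithmetic(self):
        from circstab.diffexpr import de_proportions
        lfc = [1.0] * 10 + [0.0] * 90
        padj = [0.001] * 10 + [0.9] * 90
        frame = self._frame(lfc, padj)
        frame["rna_class"] = "circRNA"
        res = call_de(frame)
        prop = de_proportions(res, {"circRNA": 100})
        assert prop["proportion"].iloc[0] == pytest.approx(0.10)


class TestDynamics:
    def _study(self, tpm_0, tpm_24):
        """3 donors x 2 times, one test transcript plus a stable one."""
        vals = {}
        vals["x"] = [tpm_0[0], tpm_24[0], tpm_0[1], tpm_24[1],
                     tpm_0[2], tpm_24[2]]
        vals["stable"] = [50.0] * 6
        return make_study(vals, times=[0.0, 24.0], donors=["D1", "D2", "D3"])

    def test_newborn_rule(self):
        dyn = classify_dynamics(self._study([0.5, 0.9, 0.8], [2.0, 3.0, 0.4]))
        assert dyn.newborn[24.0] == {"x"}
        assert dyn.degraded[24.0] == set()

    def test_tpm_exactly_one_not_expressed(self):
        """TPM must be strictly greater than 1 to count as expressed."""
        dyn = classify_dynamics(self._study([0.5, 0.5, 0.5], [1.0, 1.0, 1.0]))
        assert dyn.newborn[24.0] == set()

    def test_stable_high_expresser_neither(self):
        dyn = classify_dynamics(self._study([5.0, 6.0, 7.0], [6.0, 5.0, 8.0]))
        assert dyn.newborn[24.0] == set()
        assert dyn.degraded[24.0] == set()

    def test_degraded_rule_and_disjointness(self):
        dyn = classify_dynamics(self._study([4.0, 5.0, 3.0], [0.2, 0.3, 2.0]))
        assert dyn.degraded[24.0] == {"x"}
        assert not (dyn.newborn[24.0] & dyn.degraded[24.0])


class TestNullCalibration:
    def test_pvalue_uniformity_under_null(self, null_sim):
        """No-dynamics simulation: raw LRT p-values are near-uniform."""
        from scipy.stats import kstest
        study, _ = null_sim
        res = DifferentialExpressionModel(study).fit(times=[48.0])
        p = res.table["p_value"].dropna()
        assert len(p) >= 1900
        assert kstest(p, "uniform").statistic < 0.05
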