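"""Rank correlation, normality gate, OLS and hierarchical R²-change."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import brute_hierarchical, brute_ranks, brute_spearman
from aimm.analysis import (
    AnalysisError, average_ranks, correlation_table, hierarchical_r2_change,
    normality_check, ols_fit, residual_diagnostics, spearman_rho,
)
from aimm.profiles import MissScore
from aimm.workforce import StateVitalRecord


class TestAverageRanks:
    @pytest.mark.parametrize("x, expected", [
        ([3, 1, 2], [3, 1, 2]),
        ([5, 5, 1], [2.5, 2.5, 1]),
        ([2, 2, 2, 2], [2.5, 2.5, 2.5, 2.5]),
    ])
    def test_values(self, x, expected):
        assert average_ranks(x).tolist() == expected

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            average_ranks([])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(-100, 100), min_size=1, max_size=30))
    def test_matches_counting_oracle_and_sums(self, x):
        ranks = average_ranks(x)
        assert ranks.tolist() == [float(r) for r in brute_ranks(x)]
        n = len(x)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)


class TestSpearman:
    def test_monotone_transform_gives_rho_1(self):
        x = np.arange(1.0, 9.0)
        r = spearman_rho(x, x ** 2)
        assert r.rho == 1.0 and r.p_two_tailed == 0.0

    def test_hand_example(self):
        r = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.rho == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert spearman_rho(x, y).rho == spearman_rho(y, x).rho

    def test_constant_vector_rejected(self):
        with pytest.raises(AnalysisError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.integers(0, 6, size=15).astype(float)
            y = rng.integers(0, 6, size=15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            mine = spearman_rho(x, y)
            ref = stats.spearmanr(x, y)
            assert mine.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exhaustive_permutations_match_oracle_exactly(self):
        x = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        for perm in itertools.permutations([1.0, 2.5, 4.0, 7.0, 11.0, 13.0]):
            assert spearman_rho(x, perm).rho == brute_spearman(x, perm)

    def test_exact_permutation_p_small_n(self):
        # perfectly concordant n = 4: only reversal ties |rho|; p = 2/24
        r = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40], method="exact")
        assert r.p_two_tailed == pytest.approx(2 / 24)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = spearman_rho(x, y).rho
        assert spearman_rho(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_rho(x, 3 * y + 1).rho == pytest.approx(base)


class TestNormalityCheck:
    def test_constant_rejected(self):
        with pytest.raises(AnalysisError):
            normality_check([2.0] * 10)

    def test_gaussian_passes_most_seeds(self):
        passes = sum(
            normality_check(np.random.default_rng(s).normal(size=500))[2]
            for s in range(40)
        )
        assert passes >= 36  # >= 90%

    def test_skewed_fails_most_seeds(self):
        fails = sum(
            not normality_check(
                np.random.default_rng(s).normal(size=500) ** 2
            )[2]
            for s in range(40)
        )
        assert fails >= 36


class TestOls:
    def test_exact_linear_r2_1(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        _, r2, resid = ols_fit(X, 3 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert np.allclose(resid, 0)

    def test_orthogonal_response_r2_0(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x and constant
        X = np.column_stack([np.ones(4), x])
        beta, r2, _ = ols_fit(X, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert beta[1] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_normal_equations_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        y = np.array([1.0, 2.0, 1.5, 3.5, 5.0])
        X = np.column_stack([np.ones(5), x])
        beta, _, _ = ols_fit(X, y)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(beta - ref)) < 1e-10

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(AnalysisError, match="rank"):
            ols_fit(X, np.arange(6.0))


class TestHierarchical:
    def test_duplicated_predictor_adds_nothing(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        fit = hierarchical_r2_change(y, x, x)
        assert fit.delta_r2 == 0.0
        assert fit.f_change == 0.0
        assert fit.p_change == 1.0

    def test_noiseless_two_predictor_r2_1(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=15), rng.normal(size=15)
        fit = hierarchical_r2_change(2 * x1 + 3 * x2, x1, x2)
        assert fit.r2_total == pytest.approx(1.0)

    def test_six_point_ss_decomposition_oracle(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.5])
        b1 = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        b2 = np.array([1.0, 0.0, 2.0, 1.0, 3.0, 2.0])
        fit = hierarchical_r2_change(y, b1, b2)
        r2_1, r2_2, delta, f = brute_hierarchical(y, b1, b2)
        assert abs(fit.r2_block1 - r2_1) < 1e-10
        assert abs(fit.delta_r2 - delta) < 1e-10
        assert abs(fit.f_change - f) < 1e-10

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        b1 = rng.normal(size=(40, 2))
        b2 = rng.normal(size=(40, 1))
        y = b1 @ [1.0, -0.5] + 0.8 * b2[:, 0] + rng.normal(size=40)
        fit = hierarchical_r2_change(y, b1, b2)
        full = sm.OLS(y, sm.add_constant(np.hstack([b1, b2]))).fit()
        restricted = sm.OLS(y, sm.add_constant(b1)).fit()
        assert fit.r2_total == pytest.approx(full.rsquared, abs=1e-10)
        assert fit.r2_block1 == pytest.approx(restricted.rsquared, abs=1e-10)
        cmp = full.compare_f_test(restricted)
        assert fit.f_change == pytest.approx(cmp[0], abs=1e-8)
        assert fit.p_change == pytest.approx(cmp[1], abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_r2_never_decreases_with_predictors(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        b1 = rng.normal(size=(n, 1))
        b2 = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        fit = hierarchical_r2_change(y, b1, b2)
        assert 0 <= fit.r2_block1 <= fit.r2_total <= 1
        assert fit.delta_r2 >= 0
        assert fit.delta_r2 == pytest.approx(
            fit.r2_total - fit.r2_block1, abs=1e-12
        )


class TestResidualDiagnostics:
    def test_fitted_residual_orthogonality(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        fit = hierarchical_r2_change(y, x, rng.normal(size=30))
        report = residual_diagnostics(fit)
        assert abs(report["fitted_residual_corr"]) < 1e-8
        assert report["linearity_ok"]

    def test_normal_noise_passes_most_seeds(self):
        passes = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            x1, x2 = rng.normal(size=80), rng.normal(size=80)
            y = x1 + 0.5 * x2 + rng.normal(size=80)
            fit = hierarchical_r2_change(y, x1, x2)
            passes += residual_diagnostics(fit)["residuals_normal"]
        assert passes >= 27

    def test_cauchy_noise_fails_most_seeds(self):
        fails = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            x1, x2 = rng.normal(size=200), rng.normal(size=200)
            y = x1 + 0.5 * x2 + rng.standard_cauchy(size=200)
            fit = hierarchical_r2_change(y, x1, x2)
            fails += not residual_diagnostics(fit)["residuals_normal"]
        assert fails >= 27


class TestCorrelationTable:
    @staticmethod
    def _panel(n=30, seed=0, plant=True):
        rng = np.random.default_rng(seed)
        scores, records = [], []
        for j in range(n):
            total = float(rng.uniform(10, 90))
            scores.append(MissScore(f"S{j:03d}", total, {}))
            bf = (0.4 * total if plant else 0.0) + rng.normal(0, 5)
            records.append(StateVitalRecord(
                jurisdiction=f"S{j:03d}", year=2014, births_total=1000,
                midwife_counts={"CNM_CM": 3, "CPM_other": 1},
                births_by_attendant_setting={
                    ("CNM_CM", "hospital"): int(rng.uniform(0, 200)),
                    ("CPM_other", "home"): int(rng.uniform(0, 20)),
                },
                pct_black_births=10.0,
                outcomes={"breastfeeding_at_birth": 40 + bf},
                community_birth_rate=1.0,
            ))
        return scores, records

    def test_shape_is_exposures_by_outcomes(self):
        scores, records = self._panel()
        table = correlation_table(scores, records,
                                  outcomes=("breastfeeding_at_birth",))
        assert len(table) == 3  # 3 exposures x 1 outcome
        assert {t.label_x for t in table} == {
            "miss_total", "pct_midwife_hospital", "pct_midwife_community"
        }

    def test_planted_effect_detected(self):
        scores, records = self._panel(n=200, seed=1, plant=True)
        table = correlation_table(scores, records,
                                  outcomes=("breastfeeding_at_birth",))
        cell = next(t for t in table if t.label_x == "miss_total")
        assert cell.rho > 0 and cell.sig_flag == "p<0.01"

    def test_null_correlation_false_positive_rate(self):
        """With an outcome independent of the exposure at n = 51, the
        0.05-level star fires in about 5% (±2%) of 1000 replicates."""
        hits = 0
        for rep in range(1000):
            rng = np.random.default_rng(rep)
            r = spearman_rho(rng.normal(size=51), rng.normal(size=51))
            hits += r.p_two_tailed < 0.05
        assert 0.03 <= hits / 1000 <= 0.07

    def test_small_join_rejected_naming_cell(self):
        scores, records = self._panel(n=2)
        with pytest.raises(AnalysisError, match="jurisdictions"):
            correlation_table(scores, records,
                              outcomes=("breastfeeding_at_birth",))
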