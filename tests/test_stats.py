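"""Repeated-measures statistics against independent oracles.

Each statistic is checked two ways: against a from-scratch brute-force
implementation written here (explicit loops / alternative formulas), and --
for the conventional quantities -- against pingouin as an independently
developed reference.
"""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from tostab.errors import (ConfigError, DegenerateDataError,
                           InsufficientDataError)
from tostab.features import build_window_grid
from tostab.stats import (PairwiseTestMatrix, analyze_variable, gg_epsilon,
                          mauchly_sphericity, pairwise_paired_tests, rm_anova,
                          stabilization_time)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def anova_f_oracle(X):
    """Explicit-loop sums-of-squares decomposition."""
    n, k = X.shape
    grand = sum(X[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_f = sum(n * (sum(X[i, j] for i in range(n)) / n - grand) ** 2
               for j in range(k))
    ss_s = sum(k * (sum(X[i, j] for j in range(k)) / k - grand) ** 2
               for i in range(n))
    ss_t = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_e = ss_t - ss_f - ss_s
    return (ss_f / (k - 1)) / (ss_e / ((k - 1) * (n - 1)))


def gg_epsilon_trace_oracle(S):
    """Eigenvalue-free trace formula on the double-centered covariance."""
    k = S.shape[0]
    J = np.eye(k) - 1.0 / k
    Sc = J @ S @ J
    return np.trace(Sc) ** 2 / ((k - 1) * np.trace(Sc @ Sc))


def paired_t_oracle(x, y):
    d = x - y
    n = len(d)
    mean = d.sum() / n
    sd = np.sqrt(((d - mean) ** 2).sum() / (n - 1))
    t = mean / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


def mauchly_oracle(X):
    """W via a different (random orthonormal) contrast basis; W is basis
    invariant."""
    n, k = X.shape
    rng = np.random.default_rng(99)
    raw = np.column_stack([np.ones(k), rng.standard_normal((k, k - 1))])
    q, _ = np.linalg.qr(raw)
    C = q[:, 1:]
    Sc = C.T @ np.cov(X.T, ddof=1) @ C
    return np.linalg.det(Sc) / (np.trace(Sc) / (k - 1)) ** (k - 1)


# ---------------------------------------------------------------------------
# oracle equivalence on random matrices
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    def test_rm_anova_and_epsilon_match_bruteforce_on_100_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(6, 15))
            k = int(rng.integers(3, 7))
            X = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
            res = rm_anova(X)
            assert res.f == pytest.approx(anova_f_oracle(X), abs=1e-8, rel=1e-8)
            S = np.cov(X.T, ddof=1)
            eps_oracle = np.clip(gg_epsilon_trace_oracle(S), 1 / (k - 1), 1.0)
            assert gg_epsilon(S) == pytest.approx(eps_oracle, abs=1e-10)
            if n > k:
                w, _ = mauchly_sphericity(X)
                assert w == pytest.approx(mauchly_oracle(X), abs=1e-8, rel=1e-8)

    def test_paired_t_matches_formula_on_100_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x, y = rng.standard_normal((2, n))
            tests = pairwise_paired_tests(np.column_stack([x, y]))
            t_o, p_o = paired_t_oracle(x, y)
            assert tests.t[0, 1] == pytest.approx(t_o, abs=1e-8, rel=1e-8)
            assert tests.p_raw[0, 1] == pytest.approx(p_o, abs=1e-10)

    def test_f_equals_squared_paired_t_for_two_windows(self, rng):
        X = rng.standard_normal((12, 2))
        res = rm_anova(X)
        t, _ = paired_t_oracle(X[:, 0], X[:, 1])
        assert res.f == pytest.approx(t**2, rel=1e-10)

    def test_fixed_integer_matrix_against_loop_oracle(self):
        X = np.array([[3, 5, 7], [1, 4, 6], [2, 2, 5], [4, 6, 9], [0, 3, 4]],
                     dtype=float)
        res = rm_anova(X)
        assert res.f == pytest.approx(anova_f_oracle(X), rel=1e-12)

    def test_matches_pingouin_reference(self):
        rng = np.random.default_rng(3)
        n, k = 25, 5
        X = rng.standard_normal((n, k)) + 0.5 * np.arange(k) \
            + rng.standard_normal((n, 1))
        import pandas as pd
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "window": np.tile(np.arange(k), n),
            "y": X.ravel(),
        })
        ref = pg.rm_anova(data=long, dv="y", within="window",
                          subject="subject", correction=True)
        res = rm_anova(X)
        assert res.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p_uncorrected == pytest.approx(float(ref["p_unc"].iloc[0]),
                                                  abs=1e-10)
        assert res.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]),
                                         abs=1e-10)
        assert res.epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        spher, w, _chi, _dof, w_p = pg.sphericity(long, dv="y", within="window",
                                                  subject="subject")
        assert res.mauchly_w == pytest.approx(w, rel=1e-6)
        assert res.mauchly_p == pytest.approx(w_p, abs=1e-8)


# ---------------------------------------------------------------------------
# analytic special cases
# ---------------------------------------------------------------------------


class TestSpecialCases:
    def test_identical_columns_give_f_zero_p_one(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 4))
        res = rm_anova(X)
        assert res.f == 0.0 and res.p == 1.0

    def test_mauchly_trivial_for_two_levels(self, rng):
        w, p = mauchly_sphericity(rng.standard_normal((10, 2)))
        assert (w, p) == (1.0, 1.0)

    def test_mauchly_singular_covariance_errors(self):
        X = np.tile(np.arange(8.0)[:, None], (1, 4))  # rank-deficient
        with pytest.raises(DegenerateDataError):
            mauchly_sphericity(X)

    def test_epsilon_bounds(self, rng):
        k = 7
        # compound symmetry -> sphericity holds -> eps = 1
        S = 0.6 * np.ones((k, k)) + 0.4 * np.eye(k)
        assert gg_epsilon(S) == pytest.approx(1.0)
        # rank-1 double-centered covariance -> lower bound 1/(k-1)
        v = np.arange(1.0, k + 1.0)
        S1 = np.outer(v, v)
        assert gg_epsilon(S1) == pytest.approx(1.0 / (k - 1))
        # random SPD stays inside [1/(k-1), 1]
        A = rng.standard_normal((k, k))
        eps = gg_epsilon(A @ A.T)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_epsilon_rejects_asymmetric(self):
        with pytest.raises(ConfigError):
            gg_epsilon(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_insufficient_units(self):
        with pytest.raises(InsufficientDataError):
            rm_anova(np.ones((2, 4)))

    def test_bonferroni_m_is_21_for_seven_windows(self, rng):
        tests = pairwise_paired_tests(rng.standard_normal((10, 7)))
        assert tests.m == 21

    def test_identical_pair_not_significant(self):
        x = np.arange(8.0)
        tests = pairwise_paired_tests(np.column_stack([x, x]))
        assert tests.t[0, 1] == 0.0
        assert tests.p_adj[0, 1] == 1.0
        assert not tests.significant.any()

    def test_untestable_pair_flagged(self):
        X = np.full((5, 3), np.nan)
        X[:, 0] = X[:, 1] = 1.0
        X[0, 2] = 1.0  # only one complete pair against column 2
        tests = pairwise_paired_tests(X)
        assert tests.untestable[0, 2] and tests.untestable[1, 2]
        assert not tests.untestable[0, 1]


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


class TestProperties:
    @given(st.integers(0, 10_000))
    def test_bonferroni_dominance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 4))
        tests = pairwise_paired_tests(X, alpha=0.05)
        iu = np.triu_indices(4, 1)
        assert (tests.p_adj[iu] >= tests.p_raw[iu] - 1e-15).all()
        raw_sig = tests.p_raw[iu] < 0.05
        assert (tests.significant[iu] <= raw_sig).all()

    @given(st.integers(0, 10_000))
    def test_correction_never_increases_df(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((9, 5)) * np.array([1, 1, 1, 1, 4.0])
        res = rm_anova(X)
        n, k = X.shape
        assert res.df1 <= k - 1 + 1e-12
        assert res.df2 <= (k - 1) * (n - 1) + 1e-12
        assert 1.0 / (k - 1) - 1e-12 <= res.epsilon <= 1.0 + 1e-12

    @given(st.integers(0, 500))
    def test_removing_evidence_never_delays_stabilization(self, seed):
        """Flipping any significant pair to non-significant can only move
        the stabilization window earlier."""
        rng = np.random.default_rng(seed)
        k = 7
        grid = build_window_grid(2.0)
        sig = np.zeros((k, k), dtype=bool)
        iu = np.triu_indices(k, 1)
        mask = rng.random(len(iu[0])) < 0.4
        sig[iu] = mask
        sig |= sig.T
        base = _stab_from_mask(sig, grid)
        on = np.argwhere(np.triu(sig, 1))
        if len(on) == 0:
            return
        i, j = on[rng.integers(len(on))]
        weaker = sig.copy()
        weaker[i, j] = weaker[j, i] = False
        new = _stab_from_mask(weaker, grid)
        assert _key(new) <= _key(base)


def _fake_tests(sig):
    k = sig.shape[0]
    p_adj = np.where(sig, 0.001, 1.0)
    return PairwiseTestMatrix(
        t=np.zeros((k, k)), p_raw=p_adj, p_adj=p_adj,
        n_pairs=np.full((k, k), 10), significant=sig,
        untestable=np.zeros((k, k), bool), m=k * (k - 1) // 2, alpha=0.05)


def _fake_anova(p=0.001):
    from tostab.stats import AnovaResult
    return AnovaResult(10.0, 6, 60, p, p, p, 1.0, 0.9, 0.5, False, 11, 7)


def _stab_from_mask(sig, grid):
    return stabilization_time(_fake_tests(sig), grid, _fake_anova()).stabilized_at


def _key(s):
    return np.inf if s is None else s


# ---------------------------------------------------------------------------
# stabilization rule
# ---------------------------------------------------------------------------


class TestStabilizationRule:
    def setup_method(self):
        self.grid = build_window_grid(2.0)

    def test_no_significant_pair_stabilizes_at_zero(self):
        sig = np.zeros((7, 7), bool)
        res = stabilization_time(_fake_tests(sig), self.grid, _fake_anova())
        assert res.stabilized_at == 0.0

    def test_every_pair_significant_never_stabilizes(self):
        sig = ~np.eye(7, dtype=bool)
        res = stabilization_time(_fake_tests(sig), self.grid, _fake_anova())
        assert res.stabilized_at is None
        assert res.plateaus == ()

    def test_constructed_mask_stabilizes_at_eight_seconds(self):
        # windows {8,10,12} mutually quiet; every (w<=6, w') significant
        sig = np.zeros((7, 7), bool)
        for i in range(4):       # starts 0,2,4,6
            for j in range(i + 1, 7):
                sig[i, j] = sig[j, i] = True
        res = stabilization_time(_fake_tests(sig), self.grid, _fake_anova())
        assert res.stabilized_at == 8.0

    def test_anova_gate_short_circuits(self):
        res = stabilization_time(None, self.grid, _fake_anova(p=0.4))
        assert res.stabilized_at == 0.0

    def test_dip_and_recover_reports_transient_plateau(self):
        # quiet {2,4}, differences elsewhere, quiet again {8,10,12}
        sig = np.zeros((7, 7), bool)
        quiet = {(1, 2), (4, 5), (4, 6), (5, 6)}
        for i in range(7):
            for j in range(i + 1, 7):
                if (i, j) not in quiet:
                    sig[i, j] = sig[j, i] = True
        res = stabilization_time(_fake_tests(sig), self.grid, _fake_anova())
        assert res.stabilized_at == 8.0
        assert (2.0, 4.0) in res.plateaus and (8.0, 12.0) in res.plateaus


# ---------------------------------------------------------------------------
# Mauchly calibration (simulation)
# ---------------------------------------------------------------------------


class TestMauchlyCalibration:
    def test_type_i_error_near_nominal_under_sphericity(self):
        rng = np.random.default_rng(2024)
        reps, n, k = 400, 120, 4
        rejections = sum(
            mauchly_sphericity(rng.standard_normal((n, k)))[1] < 0.05
            for _ in range(reps)
        )
        rate = rejections / reps
        assert 0.02 <= rate <= 0.09  # binomial 95% band around 0.05

    def test_power_against_strong_autocorrelation(self):
        rng = np.random.default_rng(2025)
        reps, n, k, rho = 100, 60, 4, 0.9
        L = np.linalg.cholesky(rho ** np.abs(np.subtract.outer(range(k), range(k))))
        hits = 0
        w_sum = 0.0
        for _ in range(reps):
            X = rng.standard_normal((n, k)) @ L.T
            w, p = mauchly_sphericity(X)
            hits += p < 0.05
            w_sum += w
        assert hits / reps > 0.8
        assert w_sum / reps < 0.9


# ---------------------------------------------------------------------------
# analyze_variable plumbing
# ---------------------------------------------------------------------------


class TestAnalyzeVariable:
    def _features(self, X, variable="pd", length=2.0):
        import pandas as pd
        n, k = X.shape
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append((f"e{i:03d}", f"d{i % 5}", variable, 2.0 * j,
                             length, X[i, j], np.isnan(X[i, j])))
        return pd.DataFrame(rows, columns=[
            "event_id", "driver_id", "variable", "window_start_s",
            "window_len_s", "value", "is_missing"])

    def test_missing_variable_errors(self, rng):
        feats = self._features(rng.standard_normal((10, 7)))
        with pytest.raises(InsufficientDataError):
            analyze_variable(feats, "hr", 2.0)

    def test_too_few_complete_cases_errors(self, rng):
        X = rng.standard_normal((10, 7))
        X[:8, 3] = np.nan
        feats = self._features(X)
        with pytest.raises(InsufficientDataError):
            analyze_variable(feats, "pd", 2.0)

    def test_complete_case_count_reported(self, rng):
        X = rng.standard_normal((30, 7))
        X[:5, 2] = np.nan
        res = analyze_variable(self._features(X), "pd", 2.0)
        assert res.n_total == 30 and res.n_complete == 25

    def test_driver_level_aggregation(self, rng):
        X = rng.standard_normal((30, 7))
        res = analyze_variable(self._features(X), "pd", 2.0, unit="driver")
        assert res.n_complete == 5
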