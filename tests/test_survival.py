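"""Survival machinery: KM, log-rank, Cox partial likelihood, RCS splines."""

import math

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
import pandas as pd
from scipy.optimize import minimize_scalar

from btmbkit.errors import ConvergenceError, EmptyInputError, ValidationError
from btmbkit.survival import (cox_derivatives, cox_fit, interaction_analysis,
                              km_estimate, logrank_test, median_survival,
                              rcs_basis, rcs_cox_curve)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2.0

    def test_censored_middle_observation(self):
        # risk set at t=3 is a single patient, so S drops to 0 there
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        s = dict(zip(curve.event_times, curve.survival))
        assert s[1] == pytest.approx(2 / 3)
        assert s[2] == pytest.approx(2 / 3)
        assert s[3] == pytest.approx(0.0)

    def test_all_censored(self):
        curve = km_estimate([5, 7, 9], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert math.isnan(curve.median)
        assert math.isnan(median_survival(curve))

    def test_median_at_exact_half(self):
        # S(2) = 0.5 exactly: the step-function convention takes t=2
        curve = km_estimate([1, 2, 3, 4], [1, 1, 0, 0])
        assert curve.median == 2.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=50)  # continuous: ties a.s. absent
        curve = km_estimate(t, np.ones(50))
        np.testing.assert_allclose(curve.survival, 1.0 - np.arange(1, 51) / 50,
                                   atol=1e-12)

    def test_matches_lifelines(self, rng):
        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        e[0] = 1
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(curve.event_times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_six_patients(self):
        # alternating deaths at t=1..6: O-E = 23/30, V = 1091/900,
        # chi2 = (23/30)^2 / (1091/900) = 529/1091
        chi2, _ = logrank_test([1, 2, 3, 4, 5, 6], [1] * 6, [0, 1, 0, 1, 0, 1])
        assert chi2 == pytest.approx(529 / 1091, abs=1e-10)

    def test_matches_lifelines_multigroup(self, rng):
        t = rng.exponential(10, size=90)
        e = rng.integers(0, 2, size=90)
        e[:3] = 1
        g = rng.integers(0, 3, size=90)
        chi2, p = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_equals_squared_cox_score_statistic(self, rng):
        """Two-group log-rank == score test of a binary-covariate Cox model
        at beta=0 (Breslow). Exact for untied event times; under ties the
        conventional hypergeometric log-rank variance carries a finite-
        population correction the Cox score variance does not."""
        for _ in range(10):
            n = 40
            t = rng.exponential(10, size=n)
            e = rng.integers(0, 2, size=n)
            e[:2] = 1
            g = rng.integers(0, 2, size=n)
            if g.min() == g.max():
                g[0] = 1 - g[0]
            chi2, _ = logrank_test(t, e, g)
            _, score, info = cox_derivatives(g.astype(float), t, e, [0.0], "breslow")
            score_chi2 = float(score @ np.linalg.solve(info, score))
            assert chi2 == pytest.approx(score_chi2, abs=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], [0, 0])


def partial_likelihood_1d(beta, x, t, e, ties="efron"):
    ll, _, _ = cox_derivatives(x, t, e, [beta], ties)
    return ll


class TestCox:
    def test_coefficient_matches_grid_oracle(self, rng):
        """NR estimate equals direct 1-d maximization of the exact likelihood."""
        for _ in range(8):
            n = 8
            t = np.round(rng.exponential(10, size=n), 2)
            e = np.ones(n, dtype=int)
            x = rng.integers(0, 2, size=n).astype(float)
            if x.min() == x.max() or abs(np.corrcoef(x, t)[0, 1]) > 0.95:
                continue
            try:
                fit = cox_fit(x, t, e)
            except ConvergenceError:
                continue
            res = minimize_scalar(lambda b: -partial_likelihood_1d(b, x, t, e),
                                  bounds=(-8, 8), method="bounded",
                                  options={"xatol": 1e-8})
            assert fit.coef[0] == pytest.approx(res.x, abs=1e-3)

    def test_matches_lifelines_multivariate(self, rng):
        n = 150
        x = rng.normal(size=(n, 3))
        lp = x @ [0.5, -0.3, 0.0]
        t = rng.exponential(np.exp(-lp))
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(x, t, e, "efron")
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_[["a", "b", "c"]], atol=1e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_[["a", "b", "c"]], atol=1e-4)

    def test_affine_shift_invariance(self, rng):
        n = 80
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-x[:, 0] * 0.4))
        e = np.ones(n)
        a = cox_fit(x, t, e).coef
        b = cox_fit(x + [5.0, -3.0], t, e).coef
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_doubling_invariance_breslow(self, rng):
        n = 40
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(n)
        single = cox_fit(x, t, e, "breslow").coef[0]
        doubled = cox_fit(np.tile(x, 2), np.tile(t, 2), np.tile(e, 2), "breslow").coef[0]
        assert doubled == pytest.approx(single, abs=1e-6)

    def test_hazard_ratio_and_ci_consistency(self, rng):
        x = rng.normal(size=100)
        t = rng.exponential(np.exp(-0.3 * x))
        fit = cox_fit(x, t, np.ones(100))
        assert fit.hazard_ratios[0] == pytest.approx(math.exp(fit.coef[0]))
        assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]
        assert fit.score_norm < 1e-6

    def test_perfect_separation_raises(self):
        # the x=1 patients all die first: monotone likelihood
        t = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        e = np.ones(6)
        x = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        with pytest.raises(ConvergenceError):
            cox_fit(x, t, e)

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=(30, 2))
        X = np.column_stack([x[:, 0], x[:, 1], x[:, 0] + x[:, 1]])
        t = rng.exponential(size=30)
        with pytest.raises(ValidationError, match="rank deficient"):
            cox_fit(X, t, np.ones(30), names=("a", "b", "a_plus_b"))

    def test_null_covariate_consistency(self, rng):
        """A covariate independent of survival estimates near zero at large n."""
        n = 5000
        x = rng.normal(size=n)
        t = rng.exponential(size=n)
        fit = cox_fit(x, t, np.ones(n))
        assert abs(fit.coef[0]) < 0.07


class TestInteraction:
    @staticmethod
    def _frame(rng, n=240, b_tx=math.log(0.5)):
        treat = rng.integers(0, 2, size=n)
        marker = rng.integers(0, 2, size=n)
        lp = math.log(0.85) * treat + b_tx * treat * marker
        t = rng.exponential(np.exp(-lp) * 12)
        cens = rng.uniform(12, 36, size=n)
        df = pd.DataFrame({
            "arm": np.where(treat == 1, "ICI", "comparator"),
            "os_months": np.minimum(t, cens),
            "os_event": (t <= cens).astype(int),
        })
        df["pfs_months"], df["pfs_event"] = df["os_months"], df["os_event"]
        return df, marker

    def test_marker_swap_flips_interaction_sign(self, rng):
        df, marker = self._frame(rng)
        fit, p, _ = interaction_analysis(df, marker, "os")
        fit2, p2, _ = interaction_analysis(df, 1 - marker, "os")
        assert fit2.term("treatment_x_marker")["coef"] == pytest.approx(
            -fit.term("treatment_x_marker")["coef"], abs=1e-6)
        assert p2 == pytest.approx(p, abs=1e-9)

    def test_empty_stratum_reported(self, rng):
        df, marker = self._frame(rng, n=60)
        marker = np.where(df["arm"] == "ICI", 1, marker)  # no ICI/low cell
        with pytest.raises(ValidationError, match="empty stratum"):
            interaction_analysis(df, marker, "os")

    def test_stratified_hrs_bracket_truth(self, rng):
        df, marker = self._frame(rng, n=4000)
        _, _, strat = interaction_analysis(df, marker, "os")
        assert strat["high"].term("treatment")["hr"] == pytest.approx(0.85 * 0.5, rel=0.15)
        assert strat["low"].term("treatment")["hr"] == pytest.approx(0.85, rel=0.15)


class TestRCS:
    KNOTS = np.array([0.0, 1.0, 2.5, 4.0])

    def test_zero_below_first_knot(self):
        basis = rcs_basis([-2.0, -0.5, 0.0], self.KNOTS)
        np.testing.assert_allclose(basis[:, 1:], 0.0)

    def test_linear_tail_above_last_knot(self):
        # numerical second difference vanishes above the last knot
        x = np.array([5.0, 5.01, 5.02])
        basis = rcs_basis(x, self.KNOTS)
        second_diff = basis[0] - 2 * basis[1] + basis[2]
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-6)

    def test_matches_symbolic_construction(self):
        """Evaluate the truncated-power formula with sympy as an exact oracle."""
        import sympy as sp

        t = [sp.Rational(0), sp.Rational(1), sp.Rational(5, 2), sp.Rational(4)]
        xs = sp.Symbol("x")

        def plus3(v):
            return sp.Piecewise((v ** 3, v > 0), (0, True))

        norm = (t[3] - t[0]) ** 2
        exact_cols = []
        for j in range(2):
            expr = (plus3(xs - t[j])
                    - plus3(xs - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
                    + plus3(xs - t[3]) * (t[2] - t[j]) / (t[3] - t[2])) / norm
            exact_cols.append(expr)
        eval_at = [0.0, 1.0, 2.5, 4.0, 1.7, 3.3]
        basis = rcs_basis(eval_at, self.KNOTS)
        for j, expr in enumerate(exact_cols):
            vals = [float(expr.subs(xs, sp.Float(v, 30))) for v in eval_at]
            np.testing.assert_allclose(basis[:, 1 + j], vals, atol=1e-12)

    def test_continuity_of_derivatives_at_knots(self):
        for knot in self.KNOTS:
            h = 1e-5
            x = np.array([knot - 2 * h, knot - h, knot, knot + h, knot + 2 * h])
            b = rcs_basis(x, self.KNOTS)
            for col in range(b.shape[1]):
                d2_left = (b[0, col] - 2 * b[1, col] + b[2, col]) / h ** 2
                d2_right = (b[2, col] - 2 * b[3, col] + b[4, col]) / h ** 2
                assert d2_left == pytest.approx(d2_right, abs=1e-3)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValidationError):
            rcs_basis([1.0], [0.0, 1.0, 1.0, 2.0])

    def test_hr_at_reference_is_one(self, rng):
        n = 300
        x = rng.lognormal(1.0, 0.6, size=n)
        t = rng.exponential(np.exp(-0.2 * np.log(x)) * 10)
        fit = rcs_cox_curve(x, t, np.ones(n))
        assert fit.hr_at(fit.reference_value) == 1.0

    def test_detects_u_shaped_hazard(self, rng):
        """Quadratic log-hazard: the nonlinearity test must fire at n=2000."""
        n = 2000
        x = rng.normal(size=n)
        lp = 0.6 * (x ** 2 - 1)
        t = rng.exponential(np.exp(-lp) * 10)
        fit = rcs_cox_curve(x, t, np.ones(n))
        assert fit.nonlinearity_p < 0.01
        # fitted minimum lies in the central knot span
        xmin = fit.curve.loc[fit.curve["hr"].idxmin(), "x"]
        assert fit.knots[0] < xmin < fit.knots[-1]

    def test_linear_basis_only_reproduces_plain_cox(self, rng):
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * x))
        e = np.ones(n)
        plain = cox_fit(x, t, e).coef[0]
        via_basis = cox_fit(rcs_basis(x, np.percentile(x, [5, 35, 65, 95]))[:, :1],
                            t, e).coef[0]
        assert via_basis == pytest.approx(plain, abs=1e-9)
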