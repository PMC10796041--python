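"""Partial likelihood, penalized path, scoring and categorization."""

import numpy as np
import pandas as pd
import pytest

from mdci.model import (
    categorize_index,
    cox_loglik_and_gradient,
    cox_partial_loglik,
    fit_cox_newton,
    fit_penalized_cox,
    horizon_censor,
    kkt_residuals,
    mdci_score,
    _column_scales,
)


class TestPartialLoglik:
    def test_null_value_is_log_riskset_sizes(self):
        """At beta = 0 the Breslow partial log-likelihood is
        -sum over events of log(risk-set size)."""
        time = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        event = np.array([0, 1, 0, 1, 1])
        X = np.zeros((5, 2))
        ll = cox_partial_loglik(X, np.zeros(2), time, event)
        # risk sets: t=4 -> {5,4}, t=2 -> {5,4,3,2}, t=1 -> all 5
        assert ll == pytest.approx(-(np.log(2) + np.log(4) + np.log(5)))

    def test_two_subject_closed_form(self):
        """times (1 event, 2 censored), x = (1, 0):
        ll(b) = b - log(e^b + 1)."""
        X = np.array([[1.0], [0.0]])
        time = np.array([1.0, 2.0])
        event = np.array([1, 0])
        for b in (-1.0, 0.0, 0.7, 2.5):
            ll = cox_partial_loglik(X, np.array([b]), time, event)
            assert ll == pytest.approx(b - np.log(np.exp(b) + 1))

    def test_order_invariance(self, toy_survival):
        X, time, event = toy_survival
        beta = np.array([0.5, -0.2, 0.1])
        ll = cox_partial_loglik(X, beta, time, event)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(time))
        ll_p = cox_partial_loglik(X[perm], beta, time[perm], event[perm])
        assert ll_p == pytest.approx(ll, rel=1e-12)

    def test_gradient_matches_finite_differences(self, toy_survival):
        X, time, event = toy_survival
        beta = np.array([0.3, -0.4, 0.2])
        ll, g = cox_loglik_and_gradient(X, beta, time, event)
        eps = 1e-6
        for j in range(3):
            bp = beta.copy(); bp[j] += eps
            num = (cox_partial_loglik(X, bp, time, event) - ll) / eps
            assert g[j] == pytest.approx(num, abs=1e-4)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            cox_partial_loglik(np.zeros((3, 1)), np.zeros(1),
                               np.arange(1, 4), np.zeros(3))


class TestPenalizedPath:
    def test_lambda_max_gives_all_zero(self, toy_survival):
        X, time, event = toy_survival
        fit = fit_penalized_cox(X, time, event, n_lambda=20, n_folds=4, seed=0)
        # the grid starts at lambda_max: refit at the first grid point is zero
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        s = _column_scales(X)
        m = CoxnetSurvivalAnalysis(alphas=fit.lambda_grid, l1_ratio=0.5,
                                   normalize=False, tol=1e-7)
        m.fit(X / s, Surv.from_arrays(event.astype(bool), time))
        assert np.all(m.coef_[:, 0] == 0)
        assert np.any(m.coef_[:, -1] != 0)

    def test_small_lambda_matches_newton_oracle(self, toy_survival):
        """As lambda -> 0 (vanishing L1, small ridge) the elastic-net
        solution agrees with an independent Newton-Raphson ridge fit to
        1e-4, which itself sits next to the unpenalized fit."""
        from mdci.model import lambda_grid_from_data
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        X, time, event = toy_survival
        grid = lambda_grid_from_data(X, time, event, 0.05, 60, 1e-5)
        lam = grid[-1]  # lambda_max * 1e-5
        m = CoxnetSurvivalAnalysis(alphas=[lam], l1_ratio=0.05,
                                   normalize=False, tol=1e-9, max_iter=10**6)
        m.fit(X, Surv.from_arrays(event.astype(bool), time))
        beta = m.coef_[:, 0]
        beta_newton = fit_cox_newton(X, time, event, ridge=lam * (1 - 0.05))
        assert np.abs(beta - beta_newton).max() < 1e-4
        beta_unpen = fit_cox_newton(X, time, event)
        assert np.abs(beta - beta_unpen).max() < 1e-3

    def test_duplicated_columns_share_coefficient(self):
        rng = np.random.default_rng(3)
        n = 150
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.2 * np.exp(0.9 * x)))
        event = np.ones(n, dtype=int)
        X = np.column_stack([x, x])
        fit = fit_penalized_cox(X, t, event, alpha_mix=0.5, n_lambda=30,
                                n_folds=5, seed=1)
        b = fit.coefficients
        assert b[0] != 0 and b[1] != 0
        # exact symmetry holds at the optimum; coordinate descent leaves a
        # small tolerance-level asymmetry
        assert b[0] == pytest.approx(b[1], rel=0.05)

    def test_kkt_conditions_along_grid(self, toy_survival):
        """Subgradient optimality holds at every grid solution."""
        X, time, event = toy_survival
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        fit = fit_penalized_cox(X, time, event, n_lambda=25, n_folds=4, seed=0)
        s = _column_scales(X)
        m = CoxnetSurvivalAnalysis(alphas=fit.lambda_grid, l1_ratio=0.5,
                                   normalize=False, tol=1e-9)
        m.fit(X / s, Surv.from_arrays(event.astype(bool), time))
        for j, lam in enumerate(fit.lambda_grid):
            beta = m.coef_[:, j] / s
            stat, viol = kkt_residuals(X, time, event, beta, lam, 0.5, s)
            assert stat < 5e-4, (j, lam)
            assert viol < 5e-4, (j, lam)

    def test_tie_on_cv_criterion_prefers_larger_lambda(self, toy_survival):
        X, time, event = toy_survival
        fit = fit_penalized_cox(X, time, event, n_lambda=15, n_folds=4, seed=2)
        best = fit.cv_cindex.max()
        first = int(np.flatnonzero(fit.cv_cindex == best)[0])
        assert fit.chosen_lambda == fit.lambda_grid[first]
        # grid is descending, so the first maximizer is the largest penalty
        assert np.all(np.diff(fit.lambda_grid) < 0)

    def test_all_censored_rejected(self):
        X = np.zeros((20, 2))
        with pytest.raises(ValueError, match="censored"):
            fit_penalized_cox(X, np.arange(1, 21), np.zeros(20), n_folds=2)

    def test_roundtrip_serialization(self, toy_survival, tmp_path):
        X, time, event = toy_survival
        fit = fit_penalized_cox(X, time, event, n_lambda=10, n_folds=4, seed=0)
        fit.save(tmp_path / "index")
        back = type(fit).load(tmp_path / "index")
        assert np.array_equal(back.coefficients, fit.coefficients)
        assert back.chosen_lambda == fit.chosen_lambda
        assert np.array_equal(back.cutoffs, fit.cutoffs)


class TestScoring:
    def _make_index(self, coefs):
        from mdci.model import FittedIndex

        p = len(coefs)
        cols = pd.DataFrame({"variant": [f"V{i}" for i in range(p)],
                             "dimension": ["occ_any"] * p})
        return FittedIndex(cols, np.asarray(coefs, float), 0.5,
                           np.array([1.0]), np.array([0.5]), 1.0,
                           np.array([0.0, 0.0, 0.0]))

    def test_all_zero_features_score_zero(self):
        idx = self._make_index([0.5, -0.2, 0.0])
        assert mdci_score(idx, np.zeros(3)) == 0.0

    def test_single_indicator_returns_its_coefficient(self):
        idx = self._make_index([0.5, -0.2, 0.3])
        assert mdci_score(idx, np.array([0, 1, 0])) == pytest.approx(-0.2)

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(8)
        coefs = rng.normal(size=12)
        idx = self._make_index(coefs)
        F = rng.binomial(1, 0.4, size=(30, 12))
        scores = mdci_score(idx, F.astype(float))
        brute = np.array([sum(c for c, f in zip(coefs, row) if f) for row in F])
        assert np.allclose(scores, brute)

    def test_misaligned_vector_rejected(self):
        idx = self._make_index([0.5, -0.2])
        with pytest.raises(ValueError, match="columns"):
            mdci_score(idx, np.zeros(5))


class TestCategorize:
    def test_basic_quartiles(self):
        cats = categorize_index([1, 2, 3, 4], (1.5, 2.5, 3.5))
        assert list(cats) == ["Q1", "Q2", "Q3", "Q4"]

    def test_boundary_falls_low(self):
        assert categorize_index([2.5], (1.5, 2.5, 3.5))[0] == "Q2"
        assert categorize_index([1.5], (1.5, 2.5, 3.5))[0] == "Q1"

    def test_continuous_scores_quarter_shares(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20_000)
        cuts = np.quantile(scores, [0.25, 0.5, 0.75])
        cats = categorize_index(scores, cuts)
        _, counts = np.unique(cats, return_counts=True)
        assert np.allclose(counts / 20_000, 0.25, atol=0.01)

    def test_decreasing_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            categorize_index([1.0], (2.0, 1.0, 3.0))


class TestHorizonCensor:
    @pytest.mark.parametrize(
        "t,e,h,expect",
        [
            (int(7 * 365.25) + 1, 1, 5, (1826, 0)),  # death after horizon -> censored
            (183, 1, 1, (183, 1)),                   # death within horizon kept
            (4000, 0, 10, (3653, 0)),
        ],
    )
    def test_rules(self, t, e, h, expect):
        tt, ee = horizon_censor(np.array([t]), np.array([e]), h)
        assert (tt[0], ee[0]) == expect

    def test_idempotent(self):
        t = np.array([100, 2000, 4000])
        e = np.array([1, 1, 0])
        once = horizon_censor(*horizon_censor(t, e, 5), 5)
        twice = horizon_censor(t, e, 5)
        assert np.array_equal(once[0], twice[0])
        assert np.array_equal(once[1], twice[1])
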