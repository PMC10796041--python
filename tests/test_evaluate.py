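"""Concordance, bootstrap, Kaplan-Meier, calibration, HRs, correlation."""

import numpy as np
import pandas as pd
import pytest

from mdci.evaluate import (
    bootstrap_ci,
    breslow_cumhaz,
    calibration_curve,
    harrell_cindex,
    index_correlation,
    kaplan_meier,
    stratified_hazard_ratios,
)


def brute_force_cindex(scores, time, event):
    """O(n^2) pair enumeration oracle for Harrell's c."""
    conc = disc = ties = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable: i dies strictly before j's observed time, or i dies at
            # the moment j is censored (the censored subject outlives i);
            # pairs of tied event times are not usable
            usable = event[i] and (
                time[i] < time[j] or (time[i] == time[j] and not event[j])
            )
            if usable:
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] < scores[j]:
                    disc += 1
                else:
                    ties += 1
    denom = conc + disc + ties
    if denom == 0:
        raise ValueError("no usable pairs")
    return (conc + 0.5 * ties) / denom


class TestCindex:
    def test_perfect_inverse_ordering(self):
        time = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert harrell_cindex(scores, time, np.ones(5)) == 1.0

    def test_constant_scores_give_half(self):
        time = np.arange(1.0, 11.0)
        assert harrell_cindex(np.ones(10), time, np.ones(10)) == 0.5

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_censored_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
        time = rng.integers(1, 20, n).astype(float)
        event = rng.binomial(1, 0.6, n)
        if event.sum() == 0:
            event[0] = 1
        assert harrell_cindex(scores, time, event) == pytest.approx(
            brute_force_cindex(scores, time, event))

    def test_reversal_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)  # continuous: no score ties
        time = rng.exponential(1, 30)
        event = rng.binomial(1, 0.7, 30)
        event[0] = 1
        c = harrell_cindex(scores, time, event)
        assert c + harrell_cindex(-scores, time, event) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=50)
        time = rng.exponential(1, 50)
        event = rng.binomial(1, 0.5, 50)
        event[:2] = 1
        c1 = harrell_cindex(scores, time, event)
        c2 = harrell_cindex(np.exp(3 * scores), time, event)
        assert c1 == c2

    def test_no_usable_pairs(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_cindex(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                           np.array([0, 0]))


class TestBootstrap:
    def test_normal_mean_interval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        lo, hi = bootstrap_ci(lambda a: a.mean(), (x,), n_boot=400, seed=1)
        assert lo < 0 < hi
        assert hi - lo == pytest.approx(2 * 1.96 / 100, rel=0.2)

    def test_degenerate_data_zero_width(self):
        x = np.full(50, 3.14)
        lo, hi = bootstrap_ci(lambda a: a.mean(), (x,), n_boot=50, seed=2)
        assert lo == hi == pytest.approx(3.14)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        a = bootstrap_ci(lambda v: v.mean(), (x,), n_boot=100, seed=7)
        b = bootstrap_ci(lambda v: v.mean(), (x,), n_boot=100, seed=7)
        assert a == b

    def test_undefined_resamples_redrawn(self):
        # statistic undefined when the resample lacks both classes
        x = np.array([0.0] * 18 + [1.0, 1.0])

        def stat(v):
            if v.sum() == 0:
                raise ValueError("undefined")
            return v.mean()

        lo, hi = bootstrap_ci(stat, (x,), n_boot=50, seed=3)
        assert lo > 0


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(1 / 3)
        assert km(3) == pytest.approx(0.0)
        assert km(0.5) == 1.0

    def test_all_censored_flat_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert km(10) == 1.0

    def test_no_censoring_matches_ecdf_complement(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 50, 200).astype(float)
        km = kaplan_meier(t, np.ones(200))
        for q in (5, 20, 40):
            assert km(q) == pytest.approx((t > q).mean())

    def test_censoring_before_horizon_is_handled(self):
        # KM at horizon equals 1 - event fraction only without censoring
        km = kaplan_meier([1.0, 2.0, 4.0, 5.0], [1, 0, 1, 0])
        assert km(4) == pytest.approx((3 / 4) * (1 / 2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestCalibration:
    def test_constant_scores_single_bin_matches_marginal_km(self):
        rng = np.random.default_rng(5)
        n = 2000
        t = np.minimum(rng.exponential(8 * 365, n), 3653)
        e = (t < 3653).astype(int)
        rep = calibration_curve(np.zeros(n), t, e, 10.0)
        assert len(rep.bins) == 1
        km = kaplan_meier(t, e)
        # observed is exactly the marginal KM; predicted is exp(-Nelson-Aalen),
        # which agrees with KM to first order
        assert rep.bins["observed_km"].iloc[0] == pytest.approx(km(3653), abs=1e-9)
        assert rep.bins["mean_predicted"].iloc[0] == pytest.approx(km(3653), abs=0.01)

    def test_degenerate_two_bin_edges_partition_cohort(self):
        rng = np.random.default_rng(6)
        n = 3000
        score = rng.binomial(1, 0.5, n).astype(float)
        t = np.minimum(rng.exponential(1 / (0.0003 * np.exp(score)), n), 3653)
        e = (t < 3653).astype(int)
        rep = calibration_curve(score, t, e, 10.0, bin_edges=(0.0, 0.5, 1.0))
        assert rep.bins["n"].sum() == n
        assert len(rep.bins) <= 2

    def test_breslow_baseline_matches_km_at_null(self):
        """With eta = 0 the Breslow cumulative hazard is the Nelson-Aalen
        estimator, close to -log KM."""
        rng = np.random.default_rng(7)
        t = rng.integers(1, 100, 500).astype(float)
        e = rng.binomial(1, 0.7, 500)
        H = breslow_cumhaz(np.zeros(500), t, e)
        km = kaplan_meier(t, e)
        assert H(50) == pytest.approx(-np.log(km(50)), rel=0.02)


class TestStratifiedHR:
    def _simulate_groups(self, hr, n, seed):
        rng = np.random.default_rng(seed)
        cat = np.where(rng.random(n) < 0.5, "Q1", "Q4")
        h = 0.4 * np.where(cat == "Q4", hr, 1.0)
        t = rng.exponential(365.25 / h, n)
        time = np.minimum(t, 3653)
        event = (t < 3653).astype(int)
        return cat, time, event

    def test_recovers_known_hr(self):
        cat, time, event = self._simulate_groups(2.0, 20_000, 0)
        tab = stratified_hazard_ratios(cat, np.full(20_000, "all"), time, event,
                                       followup_years=1.0, contrasts=("Q4",))
        row = tab.iloc[0]
        assert row["status"] == "estimated"
        assert row["hr"] == pytest.approx(2.0, abs=0.15)
        assert row["ci_low"] < 2.0 < row["ci_high"]

    def test_null_case_hr_near_one(self):
        cat, time, event = self._simulate_groups(1.0, 10_000, 1)
        tab = stratified_hazard_ratios(cat, np.full(10_000, "all"), time, event,
                                       followup_years=1.0, contrasts=("Q4",))
        assert tab.iloc[0]["hr"] == pytest.approx(1.0, abs=0.1)

    def test_zero_event_stratum_is_na(self):
        cat = np.array(["Q1"] * 50 + ["Q4"] * 50)
        time = np.full(100, 300.0)
        event = np.array([0] * 50 + [1] * 50)  # no events in reference arm
        tab = stratified_hazard_ratios(cat, np.full(100, "s"), time, event,
                                       contrasts=("Q4",))
        assert tab.iloc[0]["status"] == "NA"
        assert np.isnan(tab.iloc[0]["hr"])


class TestCorrelation:
    def test_identity_and_reversal(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.3])
        assert index_correlation(x, x) == pytest.approx(1.0)
        assert index_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_hand_rank_formula(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        b = np.array([2.0, 0.5, 2.5, 3.0, 4.0])
        # Spearman = Pearson on ranks
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        expected = np.corrcoef(ra, rb)[0, 1]
        assert index_correlation(a, b) == pytest.approx(expected)

    def test_constant_input_flagged(self):
        with pytest.warns(RuntimeWarning):
            out = index_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(out)

    def test_pearson_option(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(2, 40))
        assert index_correlation(a, b, method="pearson") == pytest.approx(
            np.corrcoef(a, b)[0, 1])
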