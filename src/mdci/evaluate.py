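"""Validation suite: discrimination, calibration, survival stratification.

Discrimination uses Harrell's concordance index over usable pairs (ties in
the risk score count one half), with percentile bootstrap confidence
intervals from subject-level resampling.  Calibration follows the
one-covariate recalibration procedure: a Cox model with the index score as
its only predictor supplies, via the Breslow baseline, a predicted
survival probability at the horizon for every subject; subjects are binned
on predicted survival at fixed cutoffs and the bin-wise mean prediction is
compared with the Kaplan-Meier estimate inside the bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.metrics import concordance_index_censored
from sksurv.nonparametric import kaplan_meier_estimator

from .model import QUARTILE_LABELS, horizon_censor

__all__ = [
    "harrell_cindex",
    "bootstrap_ci",
    "KaplanMeierCurve",
    "kaplan_meier",
    "CalibrationReport",
    "calibration_curve",
    "stratified_hazard_ratios",
    "index_correlation",
]

logger = logging.getLogger(__name__)

#: Predicted-survival bin cutoffs used for calibration reporting.
DEFAULT_BIN_EDGES = (0.0, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 1.00)


def harrell_cindex(scores, time, event) -> float:
    """Harrell's c-index: higher score should mean earlier death.

    Usable pairs are those whose ordering is determinable under right
    censoring; tied scores contribute 1/2.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if len(scores) != len(time):
        raise ValueError("scores and outcome must have equal length")
    try:
        c, *_ = concordance_index_censored(event, time, scores)
    except Exception as exc:  # no comparable pairs
        raise ValueError("no usable pairs for the c-index") from exc
    return float(c)


def bootstrap_ci(
    statistic_fn,
    data: tuple,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI over subject-level resamples.

    ``data`` is a tuple of equal-length arrays; ``statistic_fn`` receives
    the resampled arrays positionally and returns a scalar.  Resamples on
    which the statistic is undefined (raises or returns NaN) are redrawn;
    the redraw count is logged.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    if max_redraws is None:
        max_redraws = 10 * n_boot
    out = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            try:
                val = statistic_fn(*(a[idx] for a in arrays))
            except Exception:
                val = np.nan
            if np.isfinite(val):
                out[b] = val
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("statistic undefined on too many bootstrap resamples")
    if redraws:
        logger.info("bootstrap: %d resamples redrawn", redraws)
    alpha = (1 - level) / 2
    return float(np.quantile(out, alpha)), float(np.quantile(out, 1 - alpha))


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit estimate with S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.times) - 1)])
        return float(s) if s.ndim == 0 else s

    @property
    def last_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Product-limit survival estimator."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if len(time) == 0:
        raise ValueError("empty input")
    t, s = kaplan_meier_estimator(event, time)
    return KaplanMeierCurve(np.asarray(t, float), np.asarray(s, float))


@dataclass
class CalibrationReport:
    """Per-bin predicted vs observed survival at a horizon."""

    bin_edges: tuple
    horizon_years: float
    bins: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: bin_low, bin_high, n, mean_predicted, observed_km

    def max_abs_gap(self) -> float:
        ok = self.bins.dropna(subset=["observed_km"])
        return float((ok["mean_predicted"] - ok["observed_km"]).abs().max())


def breslow_cumhaz(eta, time, event) -> KaplanMeierCurve:
    """Breslow baseline cumulative hazard for linear predictor ``eta``.

    Returned as a step function of time (same container as the KM curve);
    the baseline corresponds to eta = 0.
    """
    eta = np.asarray(eta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    w_s = np.exp(eta[order] - eta.max())
    # risk set at t = subjects with time >= t  -> reverse cumulative sum
    rev = np.cumsum(w_s[::-1])[::-1]
    ut, first = np.unique(t_s, return_index=True)
    s0 = rev[first] * np.exp(eta.max())
    d = np.zeros(len(ut))
    np.add.at(d, np.searchsorted(ut, t_s[e_s]), 1.0)
    return KaplanMeierCurve(ut, np.cumsum(d / s0))


def _fit_scalar_cox(scores, time, event) -> float:
    """One-covariate Breslow Cox fit by safeguarded Newton iteration."""
    from .model import cox_loglik_and_gradient

    x = np.asarray(scores, float)[:, None]
    beta = 0.0
    for _ in range(50):
        ll, g = cox_loglik_and_gradient(x, np.array([beta]), time, event)
        eps = 1e-4 * max(1.0, abs(beta))
        _, g2 = cox_loglik_and_gradient(x, np.array([beta + eps]), time, event)
        h = (g2[0] - g[0]) / eps
        if h >= -1e-12:
            break
        step = -g[0] / h
        step = np.clip(step, -2.0, 2.0)
        beta += step
        if abs(step) < 1e-9:
            break
    return float(beta)


def calibration_curve(
    index_scores,
    time,
    event,
    horizon_years: float = 10.0,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
) -> CalibrationReport:
    """Calibration of an index against observed survival at a horizon.

    A Cox model with the score as single predictor is fit on the
    evaluation cohort; each subject's predicted survival at the horizon is
    ``exp(-H0(h) * exp(b * score))`` with Breslow baseline ``H0``.  Subjects
    are binned by predicted survival at the stated cutoffs (bins are
    ``(low, high]``); empty bins are omitted.  Observed survival inside a
    bin is the Kaplan-Meier estimate at the horizon, NaN-flagged when the
    horizon exceeds the bin's last observed time.
    """
    scores = np.asarray(index_scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    hd = int(365.25 * horizon_years + 0.5)

    if np.all(scores == scores[0]):
        b = 0.0
    else:
        b = _fit_scalar_cox(scores, time, event)
    eta = b * scores
    H0 = breslow_cumhaz(eta, time, event)
    pred = np.exp(-H0(hd) * np.exp(eta))

    edges = np.asarray(bin_edges, float)
    rows = []
    which = np.digitize(pred, edges[1:-1], right=True)  # bin i: (e_i, e_{i+1}]
    for i in range(len(edges) - 1):
        mask = which == i
        if not mask.any():
            continue
        km = kaplan_meier(time[mask], event[mask])
        # horizon beyond the bin's follow-up -> observed value undefined
        obs = km(hd) if time[mask].max() >= hd else np.nan
        rows.append({
            "bin_low": edges[i], "bin_high": edges[i + 1], "n": int(mask.sum()),
            "mean_predicted": float(pred[mask].mean()), "observed_km": obs,
        })
    return CalibrationReport(tuple(edges), horizon_years, pd.DataFrame(rows))


def stratified_hazard_ratios(
    categories,
    strata,
    time,
    event,
    followup_years: float = 1.0,
    contrasts: tuple = ("Q2", "Q3", "Q4"),
    min_events: int = 5,
) -> pd.DataFrame:
    """Within-stratum Cox hazard ratios of index categories vs Q1.

    The outcome is horizon-censored to ``followup_years``.  A contrast is
    estimated only if both arms hold at least ``min_events`` events;
    otherwise the row carries ``status='NA'`` (mirroring small-cell
    suppression in register reports).  Wald 95% CIs.
    """
    from lifelines import CoxPHFitter

    categories = np.asarray(categories)
    strata = np.asarray(strata)
    t, e = horizon_censor(np.asarray(time), np.asarray(event, int), followup_years)

    rows = []
    for st in pd.unique(strata):
        in_st = strata == st
        for q in contrasts:
            arm = in_st & np.isin(categories, ["Q1", q])
            n = int(arm.sum())
            ev_ref = int(e[in_st & (categories == "Q1")].sum())
            ev_q = int(e[in_st & (categories == q)].sum())
            base = {"stratum": st, "contrast": f"{q}-vs-Q1", "n": n,
                    "events": ev_ref + ev_q}
            if min(ev_ref, ev_q) < min_events:
                rows.append({**base, "hr": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "status": "NA"})
                continue
            df = pd.DataFrame({
                "time": t[arm], "event": e[arm],
                "x": (categories[arm] == q).astype(float),
            })
            try:
                cph = CoxPHFitter()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
                hr = float(np.exp(cph.params_["x"]))
                lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy()
                rows.append({**base, "hr": hr, "ci_low": float(lo),
                             "ci_high": float(hi), "status": "estimated"})
            except Exception:
                rows.append({**base, "hr": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "status": "NA"})
    return pd.DataFrame(rows)


def index_correlation(scores_a, scores_b, method: str = "spearman") -> float:
    """Correlation between two index scores (rank-based by default)."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("correlation undefined for constant scores", RuntimeWarning)
        return np.nan
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def km_by_category(categories, time, event) -> dict[str, KaplanMeierCurve]:
    """Kaplan-Meier curve per index category (for quartile survival plots)."""
    categories = np.asarray(categories)
    out = {}
    for q in QUARTILE_LABELS:
        mask = categories == q
        if mask.any():
            out[q] = kaplan_meier(np.asarray(time)[mask], np.asarray(event)[mask])
    return out
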