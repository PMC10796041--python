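"""Synthetic hospital-register simulator.

Generates cohorts with the structure of a national patient register: each
subject has an index date, a pre-index diagnosis history of inpatient
admissions and specialist outpatient visits coded with ICD-10-shaped codes,
and all-cause survival over a post-index horizon.

The generative model is deliberately built on the same feature space the
comorbidity index uses.  Each subject carries a random subset of chronic
conditions; each active condition emits a Poisson process of care episodes
over the lookback window.  A per-subject-per-condition severity draw
inflates both the length of inpatient stays and the intensity of extra
episodes close to the index date ("flares"), so duration and recency carry
correlated -- but not collinear -- prognostic signal.  The true log-hazard
is a linear combination of realized occurrence/frequency/recency/duration
indicators specified by ``effect_spec``, and death times are drawn from a
proportional-hazards model on that linear predictor.  Parameter-recovery
experiments against this known truth are therefore meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import DIMENSIONS, dimension_flags, lookback_days

__all__ = [
    "Effect",
    "SimulationConfig",
    "SimulatedCohort",
    "default_effects",
    "synthetic_code_table",
    "simulate_cohort",
    "simulate_survival",
]

#: Age-band mix typical of an elderly male register cohort:
#: (low, high, probability).
AGE_BANDS = ((45, 59, 0.10), (60, 69, 0.38), (70, 79, 0.35), (80, 95, 0.17))

_CHAPTERS = "ABCDEFGHIJKLMNRSTZ"
_CODE_TABLE_SEED = 744101  # fixed: the code table is not part of cohort randomness

#: Common chronic-disease ICD-10 stems (heart disease, COPD, diabetes,
#: renal failure, cancers, dementia, liver disease ...).  A share of the
#: synthetic conditions is coded with these so that comorbidity mappings
#: keyed on real prefixes (e.g. Charlson) engage with simulated cohorts.
_CHRONIC_STEMS = (
    "I21", "I50", "I48", "I63", "I70", "I739", "J44", "J45", "E119", "E112",
    "N18", "C34", "C18", "C90", "K703", "K74", "F03", "G30", "G81", "M05",
    "B18", "K25", "C77",
)


@dataclass(frozen=True)
class Effect:
    """One (condition, predictor-dimension, log-hazard-ratio) truth triple."""

    condition: int
    dimension: str
    log_hr: float


def default_effects() -> list[Effect]:
    """Twelve true effects spread across all four predictor dimensions.

    Placed on the most prevalent conditions so each indicator has enough
    positive subjects for its effect to be estimable.  Plain occurrence of
    a chronic code carries moderate hazard (log-HR 0.5-0.6); repeated
    coding, recent contact and long hospital stays mark severe or
    decompensating disease and carry the strongest weights (log-HR up to
    1.3, hazard ratios ~2.5-3.7), so a substantial share of the prognostic
    signal genuinely lives outside simple occurrence.  One negative
    occurrence effect represents a contact-with-care code carried by
    healthier subjects.
    """
    return [
        Effect(0, "occ_any", 0.6),
        Effect(1, "occ_primary", 0.5),
        Effect(2, "occ_any", -0.5),
        Effect(3, "freq_ge2", 0.7),
        Effect(4, "freq_ge3", 0.8),
        Effect(5, "freq_ge2", 0.6),
        Effect(6, "rec_90", 1.2),
        Effect(7, "rec_180", 1.0),
        Effect(8, "rec_365", 0.7),
        Effect(9, "dur_gt7", 1.0),
        Effect(10, "dur_gt14", 1.3),
        Effect(11, "occ_primary", 0.5),
    ]


@dataclass(kw_only=True)
class SimulationConfig:
    """All knobs of the register simulator.

    Rates are per condition per year; probabilities are shared across
    conditions.  ``baseline_hazard`` is the yearly scale of the baseline
    (Weibull shape 1 = exponential); its default is set so that the default
    cohort shows roughly 30% ten-year all-cause mortality.
    """

    n_subjects: int
    n_conditions: int = 50
    condition_prevalence: np.ndarray | None = None  # default: geomspace 0.30 -> 0.005
    episode_rate: float | np.ndarray = 0.2
    p_inpatient: float = 0.30
    mean_los: float = 3.0  # severity-scaled mean extra days beyond the first
    p_secondary: float = 0.20
    effect_spec: list[Effect] | None = None  # None -> default_effects()
    baseline_hazard: float = 0.020
    weibull_shape: float = 1.0
    admin_censor_years: float = 10.0
    dropout_rate: float = 0.01
    lookback_years: float = 10.0
    flare_factor: float = 1.0
    flare_window_days: int = 365
    severity_shape: float = 2.0
    index_year_range: tuple[int, int] = (2008, 2014)
    seed: int = 0

    def prevalences(self) -> np.ndarray:
        if self.condition_prevalence is not None:
            return np.broadcast_to(
                np.asarray(self.condition_prevalence, float), (self.n_conditions,)
            )
        return np.geomspace(0.30, 0.005, self.n_conditions)

    def rates(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.episode_rate, float), (self.n_conditions,))

    def effects(self) -> list[Effect]:
        if self.effect_spec is not None:
            return list(self.effect_spec)
        # default truth, restricted to conditions that exist
        return [e for e in default_effects() if e.condition < self.n_conditions]

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_conditions <= 0:
            raise ValueError("n_conditions must be positive")
        prev = self.prevalences()
        if np.any((prev <= 0) | (prev >= 1)):
            raise ValueError("condition prevalences must lie in (0, 1)")
        for p in (self.p_inpatient, self.p_secondary):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if np.any(self.rates() < 0) or self.dropout_rate < 0 or self.flare_factor < 0:
            raise ValueError("rates must be nonnegative")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline hazard and Weibull shape must be positive")
        for eff in self.effects():
            if not 0 <= eff.condition < self.n_conditions:
                raise ValueError(f"effect references unknown condition {eff.condition}")
            if eff.dimension not in DIMENSIONS:
                raise ValueError(f"unknown predictor dimension {eff.dimension!r}")


@dataclass
class SimulatedCohort:
    subjects: pd.DataFrame  # subject_id, index_date, age, time_days, event
    events: pd.DataFrame    # io.EVENT_COLUMNS
    true_eta: np.ndarray
    truth: list[Effect]
    code_table: pd.DataFrame  # condition, code


def synthetic_code_table(n_conditions: int) -> pd.DataFrame:
    """Deterministic table of ICD-10-shaped condition codes.

    Codes have one chapter letter and 2-4 digits (lengths 3-5) spread
    across chapters, so granularity expansion produces overlapping
    prefixes without being degenerate.  Roughly a third of the conditions
    are coded under common chronic-disease stems so that prefix-based
    comorbidity mappings (Charlson) engage with simulated histories.  The
    table depends only on ``n_conditions``, never on the cohort seed.
    """
    rng = np.random.default_rng(_CODE_TABLE_SEED)
    codes: list[str] = []
    seen = set()
    while len(codes) < n_conditions:
        if rng.random() < 0.35:
            stem = _CHRONIC_STEMS[rng.integers(len(_CHRONIC_STEMS))]
            code = stem if len(stem) >= 4 or rng.random() < 0.5 \
                else stem + str(rng.integers(10))
        else:
            letter = _CHAPTERS[rng.integers(len(_CHAPTERS))]
            length = rng.choice([3, 4, 5], p=[0.35, 0.45, 0.20])
            code = letter + "".join(str(rng.integers(10)) for _ in range(length - 1))
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return pd.DataFrame({"condition": np.arange(n_conditions), "code": codes})


def _draw_index_dates(n: int, year_range: tuple[int, int], rng) -> np.ndarray:
    years = rng.integers(year_range[0], year_range[1] + 1, n)
    day = rng.integers(0, 365, n)
    base = np.array([np.datetime64(f"{y}-01-01") for y in years])
    return base + day.astype("timedelta64[D]")


def _draw_ages(n: int, rng) -> np.ndarray:
    lows, highs, probs = (np.array(x) for x in zip(*AGE_BANDS))
    band = rng.choice(len(AGE_BANDS), n, p=probs / probs.sum())
    return rng.integers(lows[band], highs[band] + 1)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort: history, truth and survival.

    Deterministic given ``config.seed``: history, calendar placement and
    survival use independent child streams of the seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_hist, rng_surv = (np.random.default_rng(s) for s in ss.spawn(2))

    n, c = config.n_subjects, config.n_conditions
    prev, rates = config.prevalences(), config.rates()
    lb = lookback_days(config.lookback_years)
    code_table = synthetic_code_table(c)
    codes = code_table["code"].to_numpy()

    # -- active (subject, condition) pairs, ordered by subject -------------
    active = rng_hist.random((n, c)) < prev[None, :]
    subj_of_pair, cond_of_pair = np.nonzero(active)
    m = len(subj_of_pair)
    severity = rng_hist.gamma(config.severity_shape, 1.0 / config.severity_shape, m)

    # -- episodes ----------------------------------------------------------
    base_n = rng_hist.poisson(rates[cond_of_pair] * config.lookback_years)
    flare_window = min(config.flare_window_days, lb)
    flare_mean = (
        rates[cond_of_pair] * config.flare_factor
        * np.maximum(severity - 1.0, 0.0) * flare_window / 365.25
    )
    flare_n = rng_hist.poisson(flare_mean)

    pair_idx = np.concatenate([np.repeat(np.arange(m), base_n),
                               np.repeat(np.arange(m), flare_n)])
    days_before = np.concatenate([
        rng_hist.integers(1, lb + 1, int(base_n.sum())),
        rng_hist.integers(1, flare_window + 1, int(flare_n.sum())),
    ]) if len(pair_idx) else np.array([], dtype=int)

    k = len(pair_idx)
    inpat = rng_hist.random(k) < config.p_inpatient
    los = np.ones(k, dtype=int)
    los[inpat] = 1 + rng_hist.poisson(config.mean_los * severity[pair_idx[inpat]])

    # -- secondary codes: another active condition of the same subject -----
    n_active = np.bincount(subj_of_pair, minlength=n)
    pair_start = np.concatenate([[0], np.cumsum(n_active)])  # CSR offsets
    sec_flag = rng_hist.random(k) < config.p_secondary
    ep_subj = subj_of_pair[pair_idx]
    pick = rng_hist.integers(0, np.maximum(n_active[ep_subj], 1))
    sec_pair = pair_start[ep_subj] + pick
    sec_cond = cond_of_pair[sec_pair] if k else np.array([], dtype=int)
    sec_flag &= (n_active[ep_subj] > 1) & (sec_cond != cond_of_pair[pair_idx])

    # -- internal day-resolved event frame ---------------------------------
    ep = pd.DataFrame({
        "subject_row": ep_subj,
        "code": codes[cond_of_pair[pair_idx]] if k else np.array([], dtype=object),
        "days_before": days_before,
        "setting": np.where(inpat, "IN", "OUT"),
        "position": "PRIMARY",
        "adm_before": np.where(inpat, days_before, np.nan),
        "dis_before": np.where(inpat, days_before - los, np.nan),
    })
    sec = ep[sec_flag].copy()
    if len(sec):
        sec["code"] = codes[sec_cond[sec_flag]]
        sec["position"] = "SECONDARY"
    events_day = pd.concat([ep, sec], ignore_index=True)

    # -- true linear predictor --------------------------------------------
    true_eta = _true_eta(events_day, config, code_table, n)

    # -- subjects, calendar dates, survival --------------------------------
    subject_ids = np.array([f"S{i:06d}" for i in range(n)])
    index_dates = _draw_index_dates(n, config.index_year_range, rng_hist)
    ages = _draw_ages(n, rng_hist)
    time_days, event = simulate_survival(true_eta, config, rng=rng_surv)

    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "index_date": pd.to_datetime(index_dates),
        "age": ages,
        "time_days": time_days,
        "event": event,
    })

    ed = events_day.sort_values(["subject_row", "days_before", "code", "position"],
                                ascending=[True, False, True, True], kind="stable")
    idx_of = index_dates[ed["subject_row"].to_numpy()]
    dd = ed["days_before"].to_numpy().astype("timedelta64[D]")
    events = pd.DataFrame({
        "subject_id": subject_ids[ed["subject_row"].to_numpy()],
        "code": ed["code"].to_numpy(),
        "event_date": pd.to_datetime(idx_of - dd),
        "setting": ed["setting"].to_numpy(),
        "position": ed["position"].to_numpy(),
        "admission_date": pd.to_datetime(
            idx_of - np.nan_to_num(ed["adm_before"].to_numpy(), nan=0).astype("timedelta64[D]")
        ).where(ed["setting"].to_numpy() == "IN"),
        "discharge_date": pd.to_datetime(
            idx_of - np.nan_to_num(ed["dis_before"].to_numpy(), nan=0).astype("timedelta64[D]")
        ).where(ed["setting"].to_numpy() == "IN"),
    }).reset_index(drop=True)

    return SimulatedCohort(subjects, events, true_eta, config.effects(), code_table)


def _true_eta(events_day: pd.DataFrame, config: SimulationConfig,
              code_table: pd.DataFrame, n: int) -> np.ndarray:
    """Evaluate the effect specification on realized per-condition features."""
    eta = np.zeros(n)
    effects = config.effects()
    if events_day.empty or not effects:
        return eta
    eff_codes = {code_table["code"].iloc[e.condition] for e in effects}
    sub = events_day[events_day["code"].isin(eff_codes)].rename(columns={"code": "key"})
    sub = sub.assign(subject_id=sub["subject_row"])
    flags = dimension_flags(sub, config.lookback_years)
    if flags.empty:
        return eta
    for eff in effects:
        code = code_table["code"].iloc[eff.condition]
        col = flags[eff.dimension].xs(code, level="key")
        rows = col.index.to_numpy(int)
        eta[rows] += eff.log_hr * col.to_numpy()
    return eta


def simulate_survival(
    true_eta: np.ndarray,
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time_days, event) from the proportional-hazards truth.

    Death times follow a Weibull baseline ``H0(t) = h0 * t^k`` (years)
    scaled by ``exp(eta)``; observed time is the minimum of death, random
    dropout and administrative censoring at the horizon.
    """
    true_eta = np.asarray(true_eta, float)
    if not np.all(np.isfinite(true_eta)):
        raise ValueError("true_eta must be finite")
    if config.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(true_eta)
    e = rng.exponential(1.0, n)
    t_death = (e / (config.baseline_hazard * np.exp(true_eta))) ** (1.0 / config.weibull_shape)
    t_drop = (rng.exponential(1.0 / config.dropout_rate, n)
              if config.dropout_rate > 0 else np.full(n, np.inf))
    t_admin = config.admin_censor_years
    t = np.minimum(np.minimum(t_death, t_drop), t_admin)
    event = (t_death <= np.minimum(t_drop, t_admin)).astype(int)
    time_days = np.maximum(np.ceil(t * 365.25), 1).astype(int)
    return time_days, event


def with_lookback(config: SimulationConfig, lookback_years: float) -> SimulationConfig:
    """Copy of a config with a different lookback window."""
    return replace(config, lookback_years=lookback_years)
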