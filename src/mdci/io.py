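"""Fixed file schemas for cohort tables.

Two delimited (tab-separated) tables move between pipeline stages:

``events``   one row per registered diagnosis:
             subject_id, code, event_date, setting (IN/OUT),
             position (PRIMARY/SECONDARY), admission_date, discharge_date
``subjects`` one row per subject:
             subject_id, index_date, age, time_days, event

Dates are ISO-8601; inpatient stay dates are empty for outpatient rows.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "subject_id", "code", "event_date", "setting", "position",
    "admission_date", "discharge_date",
]
SUBJECT_COLUMNS = ["subject_id", "index_date", "age", "time_days", "event"]

SETTINGS = ("IN", "OUT")
POSITIONS = ("PRIMARY", "SECONDARY")

_DATE_COLS = ("event_date", "admission_date", "discharge_date")


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "code": str})
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    for c in _DATE_COLS:
        ev[c] = pd.to_datetime(ev[c], format="%Y-%m-%d", errors="coerce")
    return ev[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    for c in _DATE_COLS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_subjects(path) -> pd.DataFrame:
    subj = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in subj.columns or "index_date" not in subj.columns:
        raise ValueError("subjects table needs subject_id and index_date columns")
    subj["index_date"] = pd.to_datetime(subj["index_date"], format="%Y-%m-%d")
    return subj


def write_subjects(subjects: pd.DataFrame, path) -> None:
    out = subjects.copy()
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


def validate_events(events: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Schema checks applied when events enter the pipeline.

    Rejects events dated on/after the subject's index date, events for
    unknown subjects, inpatient rows violating
    ``admission_date <= event_date <= discharge_date`` and outpatient rows
    carrying stay dates.  Raises ``ValueError`` describing the first class
    of violation found.
    """
    unknown = ~events["subject_id"].isin(set(subjects["subject_id"]))
    if unknown.any():
        raise ValueError(
            f"{int(unknown.sum())} events reference subjects absent from the subject table"
        )
    idx = subjects.set_index("subject_id")["index_date"]
    index_dates = events["subject_id"].map(idx)
    late = events["event_date"] >= index_dates
    if late.any():
        raise ValueError(
            f"{int(late.sum())} events dated on/after the index date; "
            "history must precede the index date"
        )
    inpat = events["setting"] == "IN"
    bad_stay = inpat & ~(
        (events["admission_date"] <= events["event_date"])
        & (events["event_date"] <= events["discharge_date"])
    )
    if bad_stay.any():
        raise ValueError(f"{int(bad_stay.sum())} inpatient events violate stay-date ordering")
    outpat_dates = ~inpat & (
        events["admission_date"].notna() | events["discharge_date"].notna()
    )
    if outpat_dates.any():
        raise ValueError(f"{int(outpat_dates.sum())} outpatient events carry stay dates")
    return events


def clean_event_codes(events: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Normalize the ``code`` column, dropping malformed codes.

    Returns the cleaned frame and the count of dropped events; the count is
    also logged so pipeline runs account for every record.
    """
    from .codes import MalformedCodeError, clean_code

    cleaned: dict[str, str | None] = {}
    for raw in events["code"].unique():
        try:
            cleaned[raw] = clean_code(raw)
        except MalformedCodeError:
            cleaned[raw] = None
    mapped = events["code"].map(cleaned)
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.warning("dropped %d events with malformed codes", n_dropped)
    out = events[mapped.notna()].copy()
    out["code"] = mapped[mapped.notna()]
    return out.reset_index(drop=True), n_dropped
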