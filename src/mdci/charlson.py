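"""Charlson comorbidity index from ICD-10 diagnosis histories.

The default mapping is the widely used Quan et al. (2005) ICD-10 coding
algorithm for the 17 Charlson conditions with the original Charlson
weights (1/2/3/6).  It is shipped as an editable table so register-specific
adaptations can be substituted.  Codes registered as primary or secondary
diagnosis within the lookback window both count; each condition counts
once.  Standard severity hierarchies apply: moderate/severe liver disease
supersedes mild, diabetes with complications supersedes diabetes without,
and metastatic solid tumour supersedes non-metastatic malignancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .codes import apply_outcome_exclusion
from .features import lookback_days

__all__ = ["CharlsonMapping", "default_charlson_mapping", "charlson_index"]


def _span(letter: str, lo: int, hi: int) -> list[str]:
    return [f"{letter}{i:02d}" for i in range(lo, hi + 1)]


@dataclass
class CharlsonMapping:
    """condition -> (ICD-10 prefixes, integer weight), plus hierarchy rules."""

    conditions: dict[str, tuple[list[str], int]]
    hierarchy: list[tuple[str, str]] = field(default_factory=list)  # (superseded, dominant)
    lookback_years: float = 10.0
    position_rule: str = "primary-or-secondary"

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, p, w) for name, (pref, w) in self.conditions.items() for p in pref]
        return pd.DataFrame(rows, columns=["condition", "prefix", "weight"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kw) -> "CharlsonMapping":
        conditions = {}
        for name, grp in frame.groupby("condition", sort=False):
            conditions[name] = (list(grp["prefix"]), int(grp["weight"].iloc[0]))
        return cls(conditions, **kw)


def default_charlson_mapping(lookback_years: float = 10.0) -> CharlsonMapping:
    """Quan 2005 ICD-10 prefixes, original Charlson weights."""
    c = {
        "myocardial_infarction": (["I21", "I22", "I252"], 1),
        "congestive_heart_failure": (
            ["I099", "I110", "I130", "I132", "I255", "I420", "I425", "I426",
             "I427", "I428", "I429", "I43", "I50", "P290"], 1),
        "peripheral_vascular_disease": (
            ["I70", "I71", "I731", "I738", "I739", "I771", "I790", "I792",
             "K551", "K558", "K559", "Z958", "Z959"], 1),
        "cerebrovascular_disease": (
            ["G45", "G46", "H340"] + _span("I", 60, 69), 1),
        "dementia": (["F00", "F01", "F02", "F03", "F051", "G30", "G311"], 1),
        "chronic_pulmonary_disease": (
            ["I278", "I279", "J684", "J701", "J703"]
            + _span("J", 40, 47) + _span("J", 60, 67), 1),
        "rheumatic_disease": (
            ["M05", "M06", "M315", "M32", "M33", "M34", "M351", "M353", "M360"], 1),
        "peptic_ulcer_disease": (_span("K", 25, 28), 1),
        "mild_liver_disease": (
            ["B18", "K700", "K701", "K702", "K703", "K709", "K713", "K714",
             "K715", "K717", "K73", "K74", "K760", "K762", "K763", "K764",
             "K768", "K769", "Z944"], 1),
        "diabetes_without_complication": (
            [f"E{b}{d}" for b in (10, 11, 12, 13, 14) for d in (0, 1, 6, 8, 9)], 1),
        "diabetes_with_complication": (
            [f"E{b}{d}" for b in (10, 11, 12, 13, 14) for d in (2, 3, 4, 5, 7)], 2),
        "hemiplegia_paraplegia": (
            ["G041", "G114", "G801", "G802", "G81", "G82", "G830", "G831",
             "G832", "G833", "G834", "G839"], 2),
        "renal_disease": (
            ["I120", "I131", "N032", "N033", "N034", "N035", "N036", "N037",
             "N052", "N053", "N054", "N055", "N056", "N057", "N18", "N19",
             "N250", "Z490", "Z491", "Z492", "Z940", "Z992"], 2),
        "any_malignancy": (
            _span("C", 0, 26) + _span("C", 30, 34) + _span("C", 37, 41)
            + ["C43"] + _span("C", 45, 58) + _span("C", 60, 76)
            + _span("C", 81, 85) + ["C88"] + _span("C", 90, 97), 2),
        "moderate_severe_liver_disease": (
            ["I850", "I859", "I864", "I982", "K704", "K711", "K721", "K729",
             "K765", "K766", "K767"], 3),
        "metastatic_solid_tumor": (["C77", "C78", "C79", "C80"], 6),
        "aids_hiv": (["B20", "B21", "B22", "B24"], 6),
    }
    hierarchy = [
        ("mild_liver_disease", "moderate_severe_liver_disease"),
        ("diabetes_without_complication", "diabetes_with_complication"),
        ("any_malignancy", "metastatic_solid_tumor"),
    ]
    return CharlsonMapping(c, hierarchy, lookback_years=lookback_years)


def charlson_index(
    events: pd.DataFrame,
    subjects: pd.DataFrame,
    mapping: CharlsonMapping | None = None,
    lookback_years: float | None = None,
    cancer_exclusion: tuple[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """Per-subject Charlson score over the lookback window.

    Parameters
    ----------
    events, subjects : cohort tables (normalized codes).
    cancer_exclusion : optional ``(target_code, companion_prefixes)``; when
        set, outcome-related codes are stripped first (e.g.
        ``("C61", ("C77", "C78", "C79", "C80"))`` for a prostate-cancer
        cohort).

    Returns an integer Series indexed like ``subjects`` (0 for subjects
    with no mapped condition).
    """
    if mapping is None:
        mapping = default_charlson_mapping()
    lb_years = mapping.lookback_years if lookback_years is None else lookback_years

    sid = subjects["subject_id"]
    out = pd.Series(0, index=subjects.index, dtype=int)
    if events.empty:
        return out
    if cancer_exclusion is not None:
        target, companions = cancer_exclusion
        events = apply_outcome_exclusion(events, target, companions)
        if events.empty:
            return out

    idx = subjects.set_index("subject_id")["index_date"]
    days_before = (events["subject_id"].map(idx) - events["event_date"]).dt.days
    lb = lookback_days(lb_years)
    ev = events[(days_before >= 1) & (days_before <= lb)]
    if ev.empty:
        return out

    frame = mapping.to_frame()
    per_subject: dict[str, set] = {}
    codes = ev["code"]
    for cond, grp in frame.groupby("condition", sort=False):
        hit = codes.str.startswith(tuple(grp["prefix"]))
        for s in ev.loc[hit, "subject_id"].unique():
            per_subject.setdefault(s, set()).add(cond)

    dominated = {sup: dom for sup, dom in mapping.hierarchy}
    weights = {name: w for name, (_, w) in mapping.conditions.items()}
    scores = {}
    for s, conds in per_subject.items():
        keep = {c for c in conds if not (c in dominated and dominated[c] in conds)}
        scores[s] = sum(weights[c] for c in keep)

    out[:] = sid.map(scores).fillna(0).astype(int)
    return out
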