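"""ICD-10 code normalization, granularity expansion and vocabulary building.

ICD-10 codes are hierarchical: ``I731`` (thromboangiitis obliterans) sits
under ``I73`` (other peripheral vascular diseases) which sits under the
two-character block ``I7``.  Registers record codes at varying depth, and a
trailing ``9`` conventionally means "unspecified".  To let every recorded
code contribute information at four depths, each cleaned code is expanded to
variants of length 2, 3, 4 and 5: prefixes below its recorded length,
``9``-padding above it (``I731`` -> ``I7, I73, I731, I7319``; ``I5`` ->
``I5, I59, I599, I5999``).

The vocabulary is the set of variants observed in at least a minimum
fraction of cohort subjects (default 0.01%), counted as distinct subjects
with at least one crediting event in any position and any setting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MalformedCodeError",
    "CodeVariantSet",
    "CodeVocabulary",
    "clean_code",
    "expand_granularity",
    "variant_table",
    "build_vocabulary",
    "apply_outcome_exclusion",
]

#: A normalized code: one uppercase chapter letter followed by 1-4 digits.
CODE_PATTERN = re.compile(r"^[A-Z][0-9]{1,4}$")

GRANULARITY_LEVELS = (2, 3, 4, 5)

_PUNCT = re.compile(r"[.\-\s]")
_TRAILING_JUNK = re.compile(r"[^A-Z0-9]+$")


class MalformedCodeError(ValueError):
    """Raised when a raw string cannot be reduced to a valid ICD-10 code."""


def clean_code(raw: str) -> str:
    """Normalize a raw ICD-10 string to ``letter + 1-4 digits``.

    Uppercases, strips dots/hyphens/whitespace and trailing
    non-alphanumerics, and truncates sub-classification codes longer than
    five characters to five.

    Raises
    ------
    MalformedCodeError
        If the result does not match ``^[A-Z][0-9]{1,4}$``.
    """
    if not raw:
        raise MalformedCodeError("empty code")
    code = _PUNCT.sub("", str(raw).strip().upper())
    code = _TRAILING_JUNK.sub("", code)
    if len(code) > 5:
        code = code[:5]
    if not CODE_PATTERN.match(code):
        raise MalformedCodeError(f"cannot normalize {raw!r} to an ICD-10 code")
    return code


@dataclass(frozen=True)
class CodeVariantSet:
    """The four granularity variants of one normalized code."""

    raw_code: str
    variants: tuple[str, str, str, str]

    def __iter__(self):
        return iter(self.variants)


def expand_granularity(code: str) -> CodeVariantSet:
    """Expand a normalized code to its length-2..5 variants.

    Variants shorter than the recorded code are prefixes; variants longer
    are padded with trailing ``9`` ("unspecified").
    """
    if not CODE_PATTERN.match(code):
        raise MalformedCodeError(f"{code!r} is not a normalized code")
    padded = code + "9" * (5 - len(code))
    return CodeVariantSet(code, tuple(padded[:n] for n in GRANULARITY_LEVELS))


def variant_table(codes: Iterable[str]) -> pd.DataFrame:
    """Long table mapping each distinct code to its four variants.

    Columns: ``code``, ``variant``, ``level`` (2-5).
    """
    rows = []
    for code in dict.fromkeys(codes):  # preserve order, dedupe
        for level, v in zip(GRANULARITY_LEVELS, expand_granularity(code)):
            rows.append((code, v, level))
    return pd.DataFrame(rows, columns=["code", "variant", "level"])


@dataclass
class CodeVocabulary:
    """Prevalence-filtered, lexicographically ordered set of code variants."""

    variants: list[str]
    prevalence: "pd.Series"  # indexed by variant, fraction of subjects
    min_prevalence: float = 1e-4
    exclusions: list[str] = field(default_factory=list)
    excluded_variants: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.variants = sorted(self.variants)
        self._index = {v: i for i, v in enumerate(self.variants)}

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant: str) -> bool:
        return variant in self._index

    def index_of(self, variant: str) -> int:
        return self._index[variant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant": self.variants,
             "prevalence": self.prevalence.reindex(self.variants).to_numpy()}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, min_prevalence: float = 1e-4) -> "CodeVocabulary":
        prev = pd.Series(frame["prevalence"].to_numpy(), index=frame["variant"])
        return cls(list(frame["variant"]), prev, min_prevalence)


def build_vocabulary(
    events: pd.DataFrame,
    n_subjects: int,
    min_prevalence: float = 1e-4,
    exclusions: Sequence[str] = (),
    prune_redundant: bool = False,
) -> CodeVocabulary:
    """Build the filtered variant vocabulary from normalized events.

    Every event credits its subject with all four granularity variants of
    its code, in any position and any setting.  A variant is retained iff
    the fraction of distinct subjects credited is at least
    ``min_prevalence`` (inclusive boundary) and no exclusion prefix matches.

    Parameters
    ----------
    events : DataFrame with columns ``subject_id`` and ``code`` (normalized).
    n_subjects : size of the cohort the prevalence is relative to.
    min_prevalence : retention threshold, default 0.0001 (0.01%).
    exclusions : code prefixes whose variants are removed by rule.
    prune_redundant : if True, drop a child variant whose supporting
        subject set is identical to its parent's (the child can carry no
        independent occurrence information).  Off by default.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if events.empty:
        return CodeVocabulary([], pd.Series(dtype=float), min_prevalence, list(exclusions))

    vmap = variant_table(events["code"])
    long = events[["subject_id", "code"]].merge(vmap[["code", "variant"]], on="code")
    support = long.groupby("variant")["subject_id"].nunique()
    prevalence = support / float(n_subjects)

    keep = prevalence[prevalence >= min_prevalence]
    excluded = []
    if exclusions:
        mask = keep.index.to_series().apply(
            lambda v: any(v.startswith(p) for p in exclusions)
        )
        excluded = sorted(keep.index[mask])
        keep = keep[~mask]

    if prune_redundant and not keep.empty:
        subject_sets = long.groupby("variant")["subject_id"].agg(frozenset)
        drop = set()
        for v in keep.index:
            if len(v) == 2:
                continue
            parent = v[:-1]
            if parent in keep.index and subject_sets[v] == subject_sets[parent]:
                drop.add(v)
        keep = keep.drop(labels=list(drop))

    return CodeVocabulary(
        list(keep.index), keep.sort_index(), min_prevalence, list(exclusions), excluded
    )


def apply_outcome_exclusion(
    events: pd.DataFrame,
    target_code: str = "C61",
    companion_prefixes: Sequence[str] = ("C77", "C78", "C79", "C80"),
) -> pd.DataFrame:
    """Remove outcome-related codes from a cohort's event history.

    Events whose granularity expansion falls under ``target_code`` are
    always removed.  Events under a companion prefix (by default the
    secondary-malignancy block C77-C80) are removed only for subjects who
    also have a target event on any date; for all other subjects they are
    kept untouched.  Used to strip prostate cancer (C61) and its metastases
    from the comorbidity history of a cancer cohort.
    """
    if events.empty:
        return events

    codes = events["code"]
    distinct = codes.unique()
    under_target = {
        c for c in distinct
        if any(v.startswith(target_code) for v in expand_granularity(c))
    }
    under_companion = {
        c for c in distinct
        if any(
            v.startswith(p)
            for p in companion_prefixes
            for v in expand_granularity(c)
        )
    }

    is_target = codes.isin(under_target)
    target_subjects = set(events.loc[is_target, "subject_id"])
    is_companion = codes.isin(under_companion) & events["subject_id"].isin(target_subjects)
    return events[~(is_target | is_companion)].reset_index(drop=True)
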