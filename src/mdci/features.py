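"""Ten-dimensional binary predictors per code variant.

For every vocabulary variant, a subject contributes ten dummy predictors
summarizing the lookback window before the index date:

====================  ====================================================
``occ_primary``       >=1 event with the variant as primary diagnosis
``occ_any``           >=1 event in any position (primary or secondary)
``freq_ge2/3/4``      primary events on >=2/3/4 distinct dates
``rec_90/180/365``    >=1 primary event within 90/180/365 days of index
``dur_gt7/gt14``      total inpatient days with the variant primary >7/>14
====================  ====================================================

Frequency, recency and duration are based on primary-position events only;
occurrence-any is the single predictor that also credits secondary codes.
Duration counts each distinct inpatient stay once, with a one-day minimum
for same-day admission/discharge and clipping of stays that straddle the
window boundaries.  The lookback window is measured in whole days
(``round(365.25 * lookback_years)``), half-open: events dated on the index
date are outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .codes import CodeVocabulary, variant_table
from .io import validate_events

__all__ = [
    "DIMENSIONS",
    "DesignMatrix",
    "lookback_days",
    "dimension_flags",
    "subject_features",
    "build_design_matrix",
    "save_design_matrix",
    "load_design_matrix",
]

DIMENSIONS = (
    "occ_primary", "occ_any",
    "freq_ge2", "freq_ge3", "freq_ge4",
    "rec_90", "rec_180", "rec_365",
    "dur_gt7", "dur_gt14",
)

_FREQ_CUTS = {"freq_ge2": 2, "freq_ge3": 3, "freq_ge4": 4}
_REC_CUTS = {"rec_90": 90, "rec_180": 180, "rec_365": 365}
_DUR_CUTS = {"dur_gt7": 7, "dur_gt14": 14}


def lookback_days(lookback_years: float) -> int:
    return int(365.25 * lookback_years + 0.5)


def dimension_flags(ev: pd.DataFrame, lookback_years: float) -> pd.DataFrame:
    """Per-(subject, key) binary flags for the ten predictor dimensions.

    ``ev`` is a long frame with columns ``subject_id``, ``key`` (a code or
    code variant), ``days_before`` (integer days between event and index,
    >=1), ``position``, ``setting``, and for inpatient rows
    ``adm_before``/``dis_before`` (days between admission/discharge and the
    index date; discharge after the index gives a negative value).  Only
    rows with ``1 <= days_before <= lookback`` contribute.  Returns a frame
    indexed by (subject_id, key) with one uint8 column per dimension.

    This is the single implementation of the predictor semantics: both the
    design-matrix builder (keyed by variant) and the cohort simulator's
    true linear predictor (keyed by raw condition code) evaluate through it.
    """
    lb = lookback_days(lookback_years)
    ev = ev[(ev["days_before"] >= 1) & (ev["days_before"] <= lb)]
    if ev.empty:
        return pd.DataFrame(
            columns=list(DIMENSIONS),
            index=pd.MultiIndex.from_arrays([[], []], names=["subject_id", "key"]),
            dtype=np.uint8,
        )

    keys = ["subject_id", "key"]
    out = pd.DataFrame(index=pd.MultiIndex.from_frame(
        ev[keys].drop_duplicates().sort_values(keys)))
    out.index.names = keys

    def put(name, series):
        out[name] = series.reindex(out.index, fill_value=False)

    prim = ev[ev["position"] == "PRIMARY"]
    g_prim = prim.groupby(keys)

    put("occ_primary", g_prim.size() >= 1)
    out["occ_any"] = True  # every row in `out` has >=1 event in some position

    ndates = g_prim["days_before"].nunique()
    for name, k in _FREQ_CUTS.items():
        put(name, ndates >= k)
    latest = g_prim["days_before"].min()
    for name, d in _REC_CUTS.items():
        put(name, latest <= d)

    stays = prim[prim["setting"] == "IN"].drop_duplicates(
        keys + ["adm_before", "dis_before"]
    )
    if stays.empty:
        total = pd.Series(dtype=float)
    else:
        days = (
            np.minimum(stays["adm_before"], lb) - np.maximum(stays["dis_before"], 0)
        ).clip(lower=1)
        total = days.groupby([stays["subject_id"], stays["key"]]).sum()
    for name, t in _DUR_CUTS.items():
        put(name, total > t)

    return out.astype(np.uint8)[list(DIMENSIONS)]


@dataclass
class DesignMatrix:
    """Sparse binary subjects x predictors matrix with column metadata."""

    X: sp.csr_matrix
    subject_ids: np.ndarray
    columns: pd.DataFrame  # columns: variant, dimension
    lookback_years: float

    @property
    def shape(self):
        return self.X.shape

    def column_names(self) -> list[str]:
        return [f"{v}:{d}" for v, d in
                zip(self.columns["variant"], self.columns["dimension"])]


def _event_day_frame(events: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    idx = subjects.set_index("subject_id")["index_date"]
    ev = events.copy()
    index_dates = ev["subject_id"].map(idx)
    ev["days_before"] = (index_dates - ev["event_date"]).dt.days
    ev["adm_before"] = (index_dates - ev["admission_date"]).dt.days
    ev["dis_before"] = (index_dates - ev["discharge_date"]).dt.days
    return ev


def build_design_matrix(
    events: pd.DataFrame,
    subjects: pd.DataFrame,
    vocabulary: CodeVocabulary,
    lookback_years: float = 10.0,
) -> DesignMatrix:
    """Assemble the full sparse design matrix for a cohort.

    One row per subject (in subject-table order), ten columns per
    vocabulary variant in lexicographic variant order; always exactly
    ``10 * len(vocabulary)`` columns.  Events are exploded to their four
    granularity variants and variants outside the vocabulary are ignored.
    """
    columns = pd.DataFrame(
        [(v, d) for v in vocabulary.variants for d in DIMENSIONS],
        columns=["variant", "dimension"],
    )
    sid = subjects["subject_id"].to_numpy()
    n, p = len(sid), len(columns)
    if events.empty or n == 0 or len(vocabulary) == 0:
        return DesignMatrix(sp.csr_matrix((n, p), dtype=np.uint8), sid, columns, lookback_years)

    validate_events(events, subjects)
    ev = _event_day_frame(events, subjects)
    vmap = variant_table(ev["code"].unique())
    vmap = vmap[vmap["variant"].isin(set(vocabulary.variants))]
    long = ev.merge(vmap[["code", "variant"]], on="code").rename(columns={"variant": "key"})

    flags = dimension_flags(long, lookback_years)
    if flags.empty:
        return DesignMatrix(sp.csr_matrix((n, p), dtype=np.uint8), sid, columns, lookback_years)

    row_of = {s: i for i, s in enumerate(sid)}
    subj_idx = flags.index.get_level_values("subject_id").map(row_of).to_numpy(int)
    var_idx = np.array([vocabulary.index_of(v)
                        for v in flags.index.get_level_values("key")])
    vals = flags.to_numpy()  # (m, 10)
    mask = vals.astype(bool)
    rows = np.repeat(subj_idx, 10)[mask.ravel()]
    cols = (var_idx[:, None] * 10 + np.arange(10)[None, :])[mask]
    X = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.uint8), (rows, cols)), shape=(n, p)
    ).tocsr()
    return DesignMatrix(X, sid, columns, lookback_years)


def subject_features(
    events: pd.DataFrame,
    vocabulary: CodeVocabulary,
    index_date,
    lookback_years: float = 10.0,
    subject_id: str | None = None,
) -> np.ndarray:
    """Dense binary feature vector for a single subject."""
    if subject_id is None:
        subject_id = events["subject_id"].iloc[0] if len(events) else "s0"
    subjects = pd.DataFrame(
        {"subject_id": [subject_id], "index_date": [pd.Timestamp(index_date)]}
    )
    dm = build_design_matrix(events, subjects, vocabulary, lookback_years)
    return np.asarray(dm.X.todense()).ravel()


def save_design_matrix(dm: DesignMatrix, out_dir) -> None:
    """Persist as MatrixMarket plus sidecar row/column tables."""
    import os
    from scipy.io import mmwrite

    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, "matrix.mtx"), dm.X.tocoo())
    dm.columns.to_csv(os.path.join(out_dir, "columns.tsv"), sep="\t", index=False)
    pd.DataFrame({"subject_id": dm.subject_ids}).to_csv(
        os.path.join(out_dir, "rows.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "meta.txt"), "w") as fh:
        fh.write(f"lookback_years\t{dm.lookback_years}\n")


def load_design_matrix(out_dir) -> DesignMatrix:
    import os
    from scipy.io import mmread

    X = sp.csr_matrix(mmread(os.path.join(out_dir, "matrix.mtx")))
    columns = pd.read_csv(os.path.join(out_dir, "columns.tsv"), sep="\t")
    rows = pd.read_csv(os.path.join(out_dir, "rows.tsv"), sep="\t", dtype={"subject_id": str})
    with open(os.path.join(out_dir, "meta.txt")) as fh:
        lookback = float(fh.read().split("\t")[1])
    return DesignMatrix(X, rows["subject_id"].to_numpy(), columns, lookback)
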