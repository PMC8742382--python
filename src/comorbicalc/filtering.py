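"""Claims qualification: lookback window and repeat-occurrence filter.

Comorbidities in administrative data are usually ascertained from dated
hospital and outpatient claims around an index event (here, an index
hospitalization). Two rules raise the validity of that ascertainment:

* only claims at the index date or during the preceding lookback period
  (default four years, both endpoints inclusive) are considered;
* a diagnosis code counts only if it appears on at least two distinct dates
  at least seven days apart — one-off codes are often rule-out or
  miscoded diagnoses.

Both rules are tunable and the whole filter is optional: the calculator
itself consumes any code list.
"""

from __future__ import annotations

import pandas as pd

from .codec import QCReport, normalize_code

__all__ = [
    "window_filter",
    "qualify_codes",
    "qualified_wide_table",
    "LOOKBACK_YEARS",
    "MIN_OCCURRENCES",
    "MIN_GAP_DAYS",
]

LOOKBACK_YEARS = 4
MIN_OCCURRENCES = 2
MIN_GAP_DAYS = 7


def _as_datetime(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="ISO8601")


def window_filter(
    claims: pd.DataFrame,
    index_events: pd.DataFrame,
    lookback_years: int = LOOKBACK_YEARS,
    id_col: str = "patient_id",
    date_col: str = "date",
    index_date_col: str = "index_date",
    qc: QCReport | None = None,
) -> pd.DataFrame:
    """Keep claims inside the inclusive lookback window of each patient.

    A claim is retained when ``index_date - lookback_years <= date <=
    index_date`` (calendar years, both ends inclusive: a claim exactly four
    years before the index event still counts, one a day earlier does not).
    Claims dated after the index event are dropped with a QC note. Patients
    without an index event contribute no claims.
    """
    required = {id_col, date_col}
    if not required <= set(claims.columns):
        raise KeyError(f"claims table missing columns {sorted(required - set(claims.columns))}")
    merged = claims.merge(
        index_events[[id_col, index_date_col]], on=id_col, how="inner"
    )
    dates = _as_datetime(merged[date_col])
    index_dates = _as_datetime(merged[index_date_col])
    window_start = index_dates - pd.DateOffset(years=lookback_years)
    after = dates > index_dates
    if qc is not None and int(after.sum()):
        qc.dropped_claims += int(after.sum())
        qc.note(f"{int(after.sum())} claims dated after the index event were dropped")
    keep = (dates >= window_start) & ~after
    return merged.loc[keep, list(claims.columns)].reset_index(drop=True)


def qualify_codes(
    claims: pd.DataFrame,
    min_occurrences: int = MIN_OCCURRENCES,
    min_gap_days: int = MIN_GAP_DAYS,
    id_col: str = "patient_id",
    date_col: str = "date",
    code_col: str = "code",
) -> dict[str, set[str]]:
    """Per patient, the set of normalized codes passing the repeat rule.

    A code qualifies when it occurs on at least ``min_occurrences`` distinct
    dates and at least one pair of those dates is ``min_gap_days`` or more
    apart (equivalently: its date span reaches the gap). With
    ``min_occurrences=1`` and ``min_gap_days=0`` this degenerates to the
    distinct normalized code set.
    """
    if claims.empty:
        return {}
    work = pd.DataFrame(
        {
            "pid": claims[id_col].astype(str),
            "date": _as_datetime(claims[date_col]),
            "code": [normalize_code(c) for c in claims[code_col]],
        }
    )
    grouped = work.drop_duplicates(["pid", "code", "date"]).groupby(
        ["pid", "code"], sort=False
    )["date"]
    stats = grouped.agg(n="nunique", span=lambda d: (d.max() - d.min()).days)
    ok = stats[(stats["n"] >= min_occurrences) & (stats["span"] >= min_gap_days)]
    out: dict[str, set[str]] = {pid: set() for pid in work["pid"].unique()}
    for pid, code in ok.index:
        out[pid].add(code)
    return out


def qualified_wide_table(
    claims: pd.DataFrame,
    index_events: pd.DataFrame | None = None,
    lookback_years: int = LOOKBACK_YEARS,
    min_occurrences: int = MIN_OCCURRENCES,
    min_gap_days: int = MIN_GAP_DAYS,
    id_col: str = "patient_id",
    date_col: str = "date",
    code_col: str = "code",
    separator: str = ";",
    qc: QCReport | None = None,
) -> pd.DataFrame:
    """Window-filter, qualify, and emit a wide table ready for scoring.

    Every patient present in the input claims (or, when ``index_events`` is
    given, every patient with an index event) gets a row, including patients
    whose every code failed qualification — they legitimately score 0.
    Codes are emitted in sorted order for byte-stable output.
    """
    windowed = (
        window_filter(claims, index_events, lookback_years, id_col, date_col, qc=qc)
        if index_events is not None
        else claims
    )
    qualified = qualify_codes(
        windowed, min_occurrences, min_gap_days, id_col, date_col, code_col
    )
    if index_events is not None:
        pids = [str(p) for p in index_events[id_col]]
    else:
        pids = [str(p) for p in claims[id_col].unique()]
    return pd.DataFrame(
        {
            "patient_id": pids,
            "icd10": [separator.join(sorted(qualified.get(p, set()))) for p in pids],
        }
    )
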