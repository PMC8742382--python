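"""Table I/O and long/wide reshaping for patient diagnosis data.

Wide format carries one subject per row with all diagnosis codes in a single
cell; long format carries one diagnosis per row (optionally dated). Both are
plain delimited text (CSV or TSV, UTF-8, header row); dates are ISO-8601.
"""

from __future__ import annotations

import os

import pandas as pd

from .codec import QCReport, tokenize_codes
from .maps import SCHEME_INDEX, load_map
from .scoring import PatientResult

__all__ = [
    "MissingColumnError",
    "TableReadError",
    "long_to_wide",
    "wide_to_long",
    "read_table",
    "write_table",
    "results_to_frame",
    "write_results",
]


class MissingColumnError(KeyError):
    """A mandatory column is absent; the message names it."""


class TableReadError(RuntimeError):
    """The file could not be read or decoded."""


def long_to_wide(
    long: pd.DataFrame,
    id_col: str = "patient_id",
    code_col: str = "code",
    separator: str = ";",
    dedupe: bool = False,
) -> pd.DataFrame:
    """Collapse one-diagnosis-per-row data to one subject per row.

    Codes are joined with ``separator`` in first-appearance order; repeated
    (patient, code) pairs are kept unless ``dedupe`` is set. Output columns
    are ``patient_id`` and ``icd10``.
    """
    _require(long, [id_col, code_col])
    rows: dict[str, list[str]] = {}
    for pid, code in zip(long[id_col].astype(str), long[code_col].astype(str)):
        bucket = rows.setdefault(pid, [])
        if dedupe and code in bucket:
            continue
        bucket.append(code)
    return pd.DataFrame(
        {"patient_id": list(rows), "icd10": [separator.join(v) for v in rows.values()]}
    )


def wide_to_long(
    wide: pd.DataFrame,
    id_col: str = "patient_id",
    code_col: str = "icd10",
    qc: QCReport | None = None,
) -> pd.DataFrame:
    """Explode one-subject-per-row data to one diagnosis per row.

    The code cell is tokenized with full separator tolerance; token order is
    preserved. A patient with an empty cell contributes no rows. Output
    columns are ``patient_id`` and ``code``.
    """
    _require(wide, [id_col])
    pids, codes = [], []
    cells = wide[code_col] if code_col in wide.columns else [""] * len(wide)
    for pid, cell in zip(wide[id_col].astype(str), cells):
        for token in tokenize_codes(cell, qc):
            pids.append(pid)
            codes.append(token)
    return pd.DataFrame({"patient_id": pids, "code": codes})


def read_table(path: str, delimiter: str | None = None, required: list[str] | None = None) -> pd.DataFrame:
    """Read a delimited text table with a header row.

    The delimiter defaults by extension (``.tsv`` -> tab, otherwise comma).
    ``required`` columns are checked and a missing one raises
    ``MissingColumnError`` naming it.
    """
    if delimiter is None:
        delimiter = "\t" if os.fspath(path).lower().endswith(".tsv") else ","
    try:
        table = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise TableReadError(f"cannot read {path}: {exc}") from exc
    except UnicodeDecodeError as exc:
        raise TableReadError(f"{path} is not valid UTF-8: {exc}") from exc
    if required:
        _require(table, required, where=str(path))
    return table


def write_table(table: pd.DataFrame, path: str, delimiter: str | None = None) -> None:
    if delimiter is None:
        delimiter = "\t" if os.fspath(path).lower().endswith(".tsv") else ","
    table.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def results_to_frame(results: list[PatientResult]) -> pd.DataFrame:
    """One row per patient: scores, then raw and adjusted flags per index.

    Column layout is fixed (schemes in canonical order, categories in map
    order, raw before adjusted) so repeated runs are bit-stable.
    """
    scheme_names = [s for s in SCHEME_INDEX if any(s in r.scores for r in results)]
    index_names = sorted(
        {i for r in results for i in r.flags}, key=["charlson", "elixhauser"].index
    )
    records = []
    for r in results:
        rec: dict[str, object] = {"patient_id": r.patient_id}
        for s in scheme_names:
            rec[s] = r.scores[s]
        for index_name in index_names:
            flags = r.flags[index_name]
            for cat in load_map(index_name).category_names:
                rec[f"{index_name}_raw_{cat}"] = flags.raw[cat]
            for cat in load_map(index_name).category_names:
                rec[f"{index_name}_adj_{cat}"] = flags.adjusted[cat]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_results(results: list[PatientResult], path: str, delimiter: str | None = None) -> None:
    write_table(results_to_frame(results), path, delimiter)


def _require(table: pd.DataFrame, columns: list[str], where: str = "input table") -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise MissingColumnError(
            f"{where} is missing required column(s): {', '.join(missing)}"
        )
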