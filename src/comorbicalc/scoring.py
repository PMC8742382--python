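"""Category flagging and weighted comorbidity scores.

The calculation runs in two steps, mirroring the classical spreadsheet
formulation: step one flags each comorbidity category when any of the
patient's normalized ICD-10 codes starts with one of the category's prefixes;
step two computes the weighted sum, suppressing a mild category whenever its
severe hierarchy partner is present (uncomplicated diabetes yields no points
when complicated diabetes is coded, a non-metastatic malignancy yields none
when metastases are coded, and so on).

Both the raw flags and the hierarchy-adjusted flags are kept on every result:
published cohort tables differ on which of the two they tabulate, and keeping
both makes either reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .codec import QCReport, is_wellformed, tokenize_codes
from .maps import (
    INDEX_NAMES,
    SCHEME_INDEX,
    SCHEME_NAMES,
    ComorbidityMap,
    WeightScheme,
    load_map,
    load_weights,
)

__all__ = [
    "CategoryFlags",
    "PatientResult",
    "DuplicatePatientError",
    "flag_categories",
    "apply_hierarchy",
    "score",
    "compute_cohort",
]


class DuplicatePatientError(ValueError):
    """A wide table contains the same patient id on more than one row."""


@dataclass
class CategoryFlags:
    """Raw and hierarchy-adjusted 0/1 flags for one patient and one index."""

    patient_id: str
    index_name: str
    raw: dict[str, int]
    adjusted: dict[str, int]


@dataclass
class PatientResult:
    """Per-patient flags for both indices plus the four scheme scores."""

    patient_id: str
    flags: dict[str, CategoryFlags] = field(default_factory=dict)
    scores: dict[str, int] = field(default_factory=dict)


@lru_cache(maxsize=None)
def _prefix_lookup(index_name: str) -> tuple[tuple[int, ...], dict[str, tuple[str, ...]]]:
    # prefix -> categories containing it, bucketed by prefix length, so each
    # code is matched with a handful of dict lookups instead of scanning every
    # prefix of every category
    table: dict[str, list[str]] = {}
    for cat in load_map(index_name).categories:
        for p in cat.prefixes:
            table.setdefault(p, []).append(cat.name)
    lengths = tuple(sorted({len(p) for p in table}))
    return lengths, {p: tuple(v) for p, v in table.items()}


def flag_categories(
    codes: list[str],
    comorbidity_map: ComorbidityMap,
    qc: QCReport | None = None,
) -> dict[str, int]:
    """Step one: 0/1 raw flag per category from a patient's normalized codes.

    A category is flagged when any code prefix-matches any of its prefixes.
    Duplicated codes change nothing; codes matching no category are counted in
    the QC report (most real claims are not comorbidity codes).
    """
    lengths, table = _prefix_lookup(comorbidity_map.index_name)
    flags = dict.fromkeys(comorbidity_map.category_names, 0)
    for code in set(codes):
        hit = False
        for n in lengths:
            if len(code) < n:
                break
            for cat in table.get(code[:n], ()):
                flags[cat] = 1
                hit = True
        if not hit and qc is not None and is_wellformed(code):
            qc.unmatched_codes.append(code)
    return flags


def apply_hierarchy(raw_flags: dict[str, int], scheme: WeightScheme) -> dict[str, int]:
    """Step two, part one: zero each mild flag whose severe partner is set."""
    adjusted = dict(raw_flags)
    for mild, severe in scheme.hierarchy:
        if adjusted.get(severe):
            adjusted[mild] = 0
    return adjusted


def score(adjusted_flags: dict[str, int], scheme: WeightScheme) -> int:
    """Step two, part two: dot product of adjusted flags and scheme weights.

    Elixhauser schemes carry negative weights, so the total may be negative.
    """
    return sum(scheme.weights[c] * adjusted_flags[c] for c in scheme.weights)


def compute_cohort(
    wide: pd.DataFrame,
    id_col: str = "patient_id",
    code_col: str = "icd10",
    schemes: tuple[str, ...] = SCHEME_NAMES,
    merge_duplicates: bool = False,
    qc: QCReport | None = None,
) -> list[PatientResult]:
    """Score every row of a wide table (one subject per row).

    Codes are tokenized from the code cell with full format tolerance and
    deduplicated before flagging. Rows with an empty or missing code cell are
    valid and score 0 everywhere. Duplicate patient ids raise
    ``DuplicatePatientError`` unless ``merge_duplicates`` pools their codes.
    Row order (first appearance, when merging) is preserved.
    """
    unknown = [s for s in schemes if s not in SCHEME_NAMES]
    if unknown:
        raise ValueError(f"unknown schemes {unknown}")
    if id_col not in wide.columns:
        raise KeyError(f"missing required column {id_col!r}")
    codes_series = (
        wide[code_col] if code_col in wide.columns else pd.Series("", index=wide.index)
    )

    per_patient: dict[str, list[str]] = {}
    for pid, cell in zip(wide[id_col].astype(str), codes_series):
        if pid in per_patient:
            if not merge_duplicates:
                raise DuplicatePatientError(
                    f"patient id {pid!r} appears on more than one row"
                )
            per_patient[pid].extend(tokenize_codes(cell, qc))
        else:
            per_patient[pid] = tokenize_codes(cell, qc)

    indices = sorted({SCHEME_INDEX[s] for s in schemes}, key=INDEX_NAMES.index)
    results = []
    for pid, codes in per_patient.items():
        result = PatientResult(patient_id=pid)
        for index_name in indices:
            raw = flag_categories(codes, load_map(index_name), qc)
            # hierarchy pairs are a property of the index, identical across
            # its schemes, so adjusted flags are computed once per index
            any_scheme = next(s for s in schemes if SCHEME_INDEX[s] == index_name)
            adjusted = apply_hierarchy(raw, load_weights(any_scheme))
            result.flags[index_name] = CategoryFlags(pid, index_name, raw, adjusted)
        for scheme_name in schemes:
            scheme = load_weights(scheme_name)
            adjusted = result.flags[scheme.index_name].adjusted
            result.scores[scheme_name] = score(adjusted, scheme)
        results.append(result)
    return results
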