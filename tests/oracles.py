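"""Independent reference implementations used only as test oracles.

The flagging oracle mimics the spreadsheet formulation directly: normalize
the whole diagnosis cell, then flag a category iff any of its prefixes occurs
as a *substring* of the cell text. Hierarchy and scoring are re-stated as
plain loops. The weight tables below are typed here independently from the
packaged data files (double entry from the published tables) so a typo in
either copy surfaces as a disagreement.
"""

from __future__ import annotations

ORACLE_HIERARCHY = {
    "charlson": [
        ("mild_liver_disease", "moderate_severe_liver_disease"),
        ("diabetes_without_complications", "diabetes_with_complications"),
        ("any_malignancy", "metastatic_solid_tumor"),
    ],
    "elixhauser": [
        ("hypertension_uncomplicated", "hypertension_complicated"),
        ("diabetes_uncomplicated", "diabetes_complicated"),
        ("solid_tumour_without_metastasis", "metastatic_cancer"),
    ],
}

# Charlson ME et al. 1987 (ICD-10 17-category adaptation)
ORACLE_WEIGHTS_CHARLSON_ORIGINAL = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes_without_complications": 1,
    "diabetes_with_complications": 2,
    "hemiplegia_paraplegia": 2,
    "renal_disease": 2,
    "any_malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids_hiv": 6,
}

# Quan H et al. 2011 updated Charlson weights
ORACLE_WEIGHTS_CHARLSON_UPDATED = {
    "myocardial_infarction": 0,
    "congestive_heart_failure": 2,
    "peripheral_vascular_disease": 0,
    "cerebrovascular_disease": 0,
    "dementia": 2,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 0,
    "mild_liver_disease": 2,
    "diabetes_without_complications": 0,
    "diabetes_with_complications": 1,
    "hemiplegia_paraplegia": 2,
    "renal_disease": 1,
    "any_malignancy": 2,
    "moderate_severe_liver_disease": 4,
    "metastatic_solid_tumor": 6,
    "aids_hiv": 4,
}

# van Walraven C et al. 2009
ORACLE_WEIGHTS_VANWALRAVEN = {
    "congestive_heart_failure": 7,
    "cardiac_arrhythmias": 5,
    "valvular_disease": -1,
    "pulmonary_circulation_disorders": 4,
    "peripheral_vascular_disorders": 2,
    "hypertension_uncomplicated": 0,
    "hypertension_complicated": 0,
    "paralysis": 7,
    "other_neurological_disorders": 6,
    "chronic_pulmonary_disease": 3,
    "diabetes_uncomplicated": 0,
    "diabetes_complicated": 0,
    "hypothyroidism": 0,
    "renal_failure": 5,
    "liver_disease": 11,
    "peptic_ulcer_disease_excluding_bleeding": 0,
    "aids_hiv": 0,
    "lymphoma": 9,
    "metastatic_cancer": 12,
    "solid_tumour_without_metastasis": 4,
    "rheumatoid_arthritis_collagen_vascular": 0,
    "coagulopathy": 3,
    "obesity": -4,
    "weight_loss": 6,
    "fluid_electrolyte_disorders": 5,
    "blood_loss_anaemia": -2,
    "deficiency_anaemia": -2,
    "alcohol_abuse": 0,
    "drug_abuse": -7,
    "psychoses": 0,
    "depression": -3,
}

# Moore BJ et al. 2017 AHRQ in-hospital mortality index (arrhythmias not in
# the model -> 0; combined hypertension weight -1 on both categories)
ORACLE_WEIGHTS_AHRQ = {
    "congestive_heart_failure": 9,
    "cardiac_arrhythmias": 0,
    "valvular_disease": 0,
    "pulmonary_circulation_disorders": 6,
    "peripheral_vascular_disorders": 3,
    "hypertension_uncomplicated": -1,
    "hypertension_complicated": -1,
    "paralysis": 4,
    "other_neurological_disorders": 5,
    "chronic_pulmonary_disease": 3,
    "diabetes_uncomplicated": 0,
    "diabetes_complicated": -1,
    "hypothyroidism": 0,
    "renal_failure": 6,
    "liver_disease": 4,
    "peptic_ulcer_disease_excluding_bleeding": 0,
    "aids_hiv": 0,
    "lymphoma": 6,
    "metastatic_cancer": 14,
    "solid_tumour_without_metastasis": 7,
    "rheumatoid_arthritis_collagen_vascular": 0,
    "coagulopathy": 11,
    "obesity": -5,
    "weight_loss": 9,
    "fluid_electrolyte_disorders": 11,
    "blood_loss_anaemia": -3,
    "deficiency_anaemia": -2,
    "alcohol_abuse": -1,
    "drug_abuse": -7,
    "psychoses": -6,
    "depression": -5,
}

ORACLE_WEIGHTS = {
    "charlson_original": ORACLE_WEIGHTS_CHARLSON_ORIGINAL,
    "charlson_updated": ORACLE_WEIGHTS_CHARLSON_UPDATED,
    "elixhauser_vanwalraven": ORACLE_WEIGHTS_VANWALRAVEN,
    "elixhauser_ahrq": ORACLE_WEIGHTS_AHRQ,
}
ORACLE_SCHEME_INDEX = {
    "charlson_original": "charlson",
    "charlson_updated": "charlson",
    "elixhauser_vanwalraven": "elixhauser",
    "elixhauser_ahrq": "elixhauser",
}


def oracle_normalize_cell(raw_codes: list[str], sep: str = ";") -> str:
    """Uppercase, punctuation-free cell text, codes joined by ``sep``."""
    tokens = []
    for raw in raw_codes:
        token = "".join(ch for ch in str(raw).upper() if ch.isalnum())
        if token:
            tokens.append(token)
    return sep.join(tokens)


def oracle_flags(raw_codes: list[str], categories) -> dict[str, int]:
    """Substring-search flagging over the whole normalized cell.

    ``categories`` is an iterable of objects with ``name`` and ``prefixes``
    (the packaged map); a category is flagged iff any prefix occurs anywhere
    in the cell text — the spreadsheet SUBSTITUTE/LEN trick.
    """
    cell = oracle_normalize_cell(raw_codes)
    return {
        cat.name: int(any(p in cell for p in cat.prefixes)) for cat in categories
    }


def oracle_adjust(flags: dict[str, int], index_name: str) -> dict[str, int]:
    adjusted = dict(flags)
    for mild, severe in ORACLE_HIERARCHY[index_name]:
        if adjusted[severe] == 1:
            adjusted[mild] = 0
    return adjusted


def oracle_score(raw_flags: dict[str, int], scheme_name: str) -> int:
    """Brute-force score: independent hierarchy + term-by-term summation."""
    adjusted = oracle_adjust(raw_flags, ORACLE_SCHEME_INDEX[scheme_name])
    total = 0
    for category, weight in ORACLE_WEIGHTS[scheme_name].items():
        if adjusted[category] == 1:
            total += weight
    return total


def oracle_qualify(records: list[tuple], min_occurrences: int = 2, min_gap_days: int = 7):
    """O(n^2) pairwise-date qualification over (patient, date, code) tuples.

    Dates are ``datetime.date``. A code qualifies for a patient when it
    occurs on at least ``min_occurrences`` distinct dates and some pair of
    occurrence dates (a single date pairs with itself) differs by at least
    ``min_gap_days``.
    """
    by_patient: dict[str, dict[str, set]] = {}
    for pid, date, code in records:
        norm = "".join(ch for ch in str(code).upper() if ch.isalnum())
        by_patient.setdefault(str(pid), {}).setdefault(norm, set()).add(date)
    out: dict[str, set[str]] = {}
    for pid, codes in by_patient.items():
        out[pid] = set()
        for code, dates in codes.items():
            if len(dates) < min_occurrences:
                continue
            ordered = sorted(dates)
            ok = False
            for a in ordered:
                for b in ordered:
                    if abs((a - b).days) >= min_gap_days:
                        ok = True
            if ok:
                out[pid].add(code)
    return out
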