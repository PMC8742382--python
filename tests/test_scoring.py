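"""Flagging, hierarchy suppression, scoring, and cohort orchestration."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbicalc import (
    DuplicatePatientError,
    QCReport,
    apply_hierarchy,
    compute_cohort,
    flag_categories,
    load_map,
    load_weights,
    score,
)
from conftest import unique_code
from oracles import oracle_flags, oracle_score

valid_codes = st.from_regex(r"[A-Z][0-9]{2,4}", fullmatch=True)


def test_single_code_flags_single_category(charlson_map):
    flags = flag_categories(["I21"], charlson_map)
    assert flags["myocardial_infarction"] == 1
    assert sum(flags.values()) == 1


def test_empty_codes_flag_nothing(charlson_map):
    assert sum(flag_categories([], charlson_map).values()) == 0


def test_duplicates_do_not_change_flags(charlson_map):
    once = flag_categories(["I210", "I509"], charlson_map)
    thrice = flag_categories(["I210", "I509", "I509", "I509"], charlson_map)
    assert once == thrice
    assert once["myocardial_infarction"] == 1
    assert once["congestive_heart_failure"] == 1


def test_unmatched_codes_land_in_qc_report(charlson_map):
    qc = QCReport()
    flags = flag_categories(["S7210", "I21"], charlson_map, qc)
    assert flags["myocardial_infarction"] == 1
    assert qc.unmatched_codes == ["S7210"]


@pytest.mark.parametrize(
    "scheme_name",
    ["charlson_original", "charlson_updated", "elixhauser_vanwalraven", "elixhauser_ahrq"],
)
def test_hierarchy_suppresses_only_mild_with_severe_present(scheme_name):
    scheme = load_weights(scheme_name)
    cmap = load_map(scheme.index_name)
    for mild, severe in scheme.hierarchy:
        raw = dict.fromkeys(cmap.category_names, 0)
        raw[mild] = raw[severe] = 1
        adjusted = apply_hierarchy(raw, scheme)
        assert adjusted[mild] == 0 and adjusted[severe] == 1
        only_mild = dict.fromkeys(cmap.category_names, 0)
        only_mild[mild] = 1
        assert apply_hierarchy(only_mild, scheme) == only_mild


def test_hierarchy_is_identity_without_severe_flags(charlson_map):
    scheme = load_weights("charlson_original")
    raw = dict.fromkeys(charlson_map.category_names, 0)
    raw["dementia"] = raw["mild_liver_disease"] = 1
    assert apply_hierarchy(raw, scheme) == raw


def test_score_zero_for_empty_flags(charlson_map):
    scheme = load_weights("charlson_original")
    assert score(dict.fromkeys(charlson_map.category_names, 0), scheme) == 0


def test_malignancy_with_metastasis_scores_6_not_8(charlson_map):
    scheme = load_weights("charlson_original")
    raw = dict.fromkeys(charlson_map.category_names, 0)
    raw["any_malignancy"] = raw["metastatic_solid_tumor"] = 1
    assert score(apply_hierarchy(raw, scheme), scheme) == 6


def test_scores_may_be_negative_for_elixhauser(elixhauser_map):
    scheme = load_weights("elixhauser_vanwalraven")
    raw = dict.fromkeys(elixhauser_map.category_names, 0)
    raw["obesity"] = 1
    assert score(apply_hierarchy(raw, scheme), scheme) == -4


@given(codes=st.lists(valid_codes, min_size=0, max_size=10), extra=valid_codes)
@settings(derandomize=True, max_examples=150)
def test_adding_a_code_never_decreases_raw_flags(codes, extra):
    cmap = load_map("elixhauser")
    before = flag_categories(codes, cmap)
    after = flag_categories(codes + [extra], cmap)
    assert all(after[c] >= before[c] for c in before)


@given(codes=st.lists(valid_codes, min_size=0, max_size=12))
@settings(derandomize=True, max_examples=150)
def test_flags_and_scores_agree_with_substring_oracle(codes):
    """Randomized dual-route check: prefix-match engine vs whole-cell
    substring oracle plus brute-force summation."""
    for index_name in ("charlson", "elixhauser"):
        cmap = load_map(index_name)
        engine = flag_categories(codes, cmap)
        assert engine == oracle_flags(codes, cmap.categories)
    table = pd.DataFrame({"patient_id": ["P1"], "icd10": [";".join(codes)]})
    result = compute_cohort(table)[0]
    for scheme_name, value in result.scores.items():
        index_name = load_weights(scheme_name).index_name
        assert value == oracle_score(result.flags[index_name].raw, scheme_name)


def test_compute_cohort_one_row():
    table = pd.DataFrame({"patient_id": ["P1"], "icd10": ["i21.0"]})
    result = compute_cohort(table)[0]
    assert result.scores["charlson_original"] == 1
    assert result.flags["charlson"].raw["myocardial_infarction"] == 1


def test_compute_cohort_empty_table():
    assert compute_cohort(pd.DataFrame({"patient_id": [], "icd10": []})) == []


def test_compute_cohort_junk_codes_score_zero_with_qc():
    qc = QCReport()
    table = pd.DataFrame({"patient_id": ["P1"], "icd10": ["???, 99ZZZZZZ"]})
    result = compute_cohort(table, qc=qc)[0]
    assert all(v == 0 for v in result.scores.values())
    assert "99ZZZZZZ" in qc.odd_tokens


def test_duplicate_ids_error_unless_merged():
    table = pd.DataFrame({"patient_id": ["P1", "P1"], "icd10": ["I21", "I50"]})
    with pytest.raises(DuplicatePatientError):
        compute_cohort(table)
    merged = compute_cohort(table, merge_duplicates=True)
    assert len(merged) == 1
    assert merged[0].scores["charlson_original"] == 2  # MI + CHF


def test_missing_code_column_treated_as_empty():
    table = pd.DataFrame({"patient_id": ["P1"]})
    result = compute_cohort(table)[0]
    assert all(v == 0 for v in result.scores.values())


def test_adjusted_flags_never_exceed_raw(charlson_map):
    table = pd.DataFrame({"patient_id": ["P1"], "icd10": ["C18;C77;K70.0;K70.4"]})
    flags = compute_cohort(table)[0].flags["charlson"]
    assert all(flags.adjusted[c] <= flags.raw[c] for c in flags.raw)
    assert flags.raw["any_malignancy"] == 1 and flags.adjusted["any_malignancy"] == 0


def test_unique_code_helper_produces_single_flags(charlson_map):
    code = unique_code(charlson_map, "mild_liver_disease")
    flags = flag_categories([code], charlson_map)
    assert sum(flags.values()) == 1
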