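"""Synthetic cohort generator: determinism, ground-truth consistency, noise
disjointness, and the degradation operator."""

import pandas as pd
import pytest

from comorbicalc import (
    CohortSpec,
    compute_cohort,
    degrade,
    flag_categories,
    generate,
    list_all_codes,
    load_map,
    prefix_match,
    qualified_wide_table,
)
from comorbicalc.synthetic import SpecError, _noise_pool


def small_spec(**kw):
    defaults = dict(n_patients=40, seed=123)
    defaults.update(kw)
    return CohortSpec(**defaults)


def test_empty_cohort():
    claims, truth, index_events = generate(CohortSpec(n_patients=0, seed=1))
    assert claims.empty and index_events.empty and truth.patient_ids == []


def test_same_seed_gives_identical_output():
    a = generate(small_spec())
    b = generate(small_spec())
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[2], b[2])
    for name in ("charlson", "elixhauser"):
        pd.testing.assert_frame_equal(a[1].flags[name], b[1].flags[name])


def test_different_seed_changes_output():
    a = generate(small_spec())
    b = generate(small_spec(seed=124))
    assert not a[0].equals(b[0])


def test_unknown_category_in_prevalence_rejected():
    with pytest.raises(SpecError):
        generate(small_spec(charlson_prevalence={"gout": 0.5}))
    with pytest.raises(SpecError):
        generate(small_spec(charlson_prevalence={"dementia": 1.5}))


def test_forced_single_category_scores_one_everywhere():
    spec = small_spec(
        n_patients=25,
        charlson_prevalence={"myocardial_infarction": 1.0},
        elixhauser_prevalence={},
        noise_code_rate=0.0,
    )
    claims, truth, index_events = generate(spec)
    wide = qualified_wide_table(claims, index_events)
    for result in compute_cohort(wide):
        assert result.scores["charlson_original"] == 1


def test_ground_truth_consistent_with_emitted_codes():
    claims, truth, _ = generate(small_spec())
    by_patient = claims.groupby("patient_id")["code"].apply(set)
    for index_name in ("charlson", "elixhauser"):
        cmap = load_map(index_name)
        for pid in truth.patient_ids:
            flags = flag_categories(sorted(by_patient.get(pid, set())), cmap)
            assert flags == truth.flags[index_name].loc[pid].to_dict()


def test_noise_pool_disjoint_from_both_maps():
    pool = _noise_pool()
    for index_name in ("charlson", "elixhauser"):
        prefixes = list_all_codes(load_map(index_name))
        assert not any(prefix_match(code, prefixes) for code in pool)


def test_claims_respect_window_and_spacing():
    claims, _, index_events = generate(small_spec())
    merged = claims.merge(index_events, on="patient_id")
    dates = pd.to_datetime(merged["date"])
    index_dates = pd.to_datetime(merged["index_date"])
    delta = (index_dates - dates).dt.days
    assert (delta >= 0).all() and (delta <= 1461).all()
    spans = (
        claims.assign(date=pd.to_datetime(claims["date"]))
        .groupby(["patient_id", "code"])["date"]
        .agg(lambda d: (d.max() - d.min()).days)
    )
    assert (spans >= 7).all()  # every code survives the qualification rule


def test_degrade_identity_at_zero_rates():
    claims, truth, _ = generate(small_spec())
    degraded, new_truth = degrade(claims, truth, drop_rate=0.0)
    assert sorted(map(tuple, degraded.values)) == sorted(map(tuple, claims.values))
    for name in ("charlson", "elixhauser"):
        pd.testing.assert_frame_equal(
            new_truth.flags[name], truth.flags[name], check_dtype=False
        )


def test_degrade_collapse_fails_qualification():
    claims, truth, index_events = generate(small_spec(n_patients=15))
    degraded, new_truth = degrade(claims, truth, same_day_collapse=1.0)
    assert (new_truth.flags["charlson"].to_numpy() == 0).all()
    wide = qualified_wide_table(degraded, index_events)
    assert (wide["icd10"] == "").all()


def test_degrade_drop_all_repeats_empties_qualified_set():
    claims, truth, index_events = generate(small_spec(n_patients=15))
    degraded, new_truth = degrade(claims, truth, drop_rate=1.0)
    assert degraded.groupby(["patient_id", "code"]).size().max() == 1
    assert (new_truth.flags["elixhauser"].to_numpy() == 0).all()
    wide = qualified_wide_table(degraded, index_events)
    results = compute_cohort(wide)
    assert all(v == 0 for r in results for v in r.scores.values())
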