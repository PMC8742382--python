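"""Synthetic dated ICD-10 claim streams with known comorbidity structure.

The generator emulates the kind of administrative data the calculator is
built for: each patient has an index hospitalization date, and dated hospital
or outpatient claims carrying ICD-10 codes during the preceding four years.
Comorbidity categories are sampled independently per patient with known
prevalences (the defaults are the category prevalences observed in a
population-wide elderly hip-fracture cohort, n = 11,491); a present category
contributes one full code drawn from the category's prefix list, repeated on
two distinct dates at least seven days apart so it survives the
qualification filter. Injury-chapter (S) noise codes, verified disjoint from
both comorbidity maps, are sprinkled on top.

Deliberately not modelled: disease co-occurrence correlations, mortality,
seasonality, or coding drift — synthetic cohorts exercise the calculator's
correctness, not the epidemiology.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import load_map
from .scoring import flag_categories

__all__ = [
    "CHARLSON_PREVALENCE",
    "ELIXHAUSER_PREVALENCE",
    "CohortSpec",
    "GroundTruth",
    "generate",
    "degrade",
]

# Default per-category prevalences (fractions) mirroring a real elderly
# hip-fracture cohort's published comorbidity profile.
CHARLSON_PREVALENCE: dict[str, float] = {
    "myocardial_infarction": 0.069,
    "congestive_heart_failure": 0.437,
    "peripheral_vascular_disease": 0.104,
    "cerebrovascular_disease": 0.216,
    "dementia": 0.096,
    "chronic_pulmonary_disease": 0.108,
    "rheumatic_disease": 0.033,
    "peptic_ulcer_disease": 0.047,
    "mild_liver_disease": 0.015,
    "diabetes_without_complications": 0.108,
    "diabetes_with_complications": 0.059,
    "hemiplegia_paraplegia": 0.046,
    "renal_disease": 0.040,
    "any_malignancy": 0.103,
    "moderate_severe_liver_disease": 0.003,
    "metastatic_solid_tumor": 0.004,
    "aids_hiv": 0.0001,
}

ELIXHAUSER_PREVALENCE: dict[str, float] = {
    "congestive_heart_failure": 0.437,
    "cardiac_arrhythmias": 0.207,
    "valvular_disease": 0.031,
    "pulmonary_circulation_disorders": 0.013,
    "peripheral_vascular_disorders": 0.104,
    "hypertension_uncomplicated": 0.259,
    "hypertension_complicated": 0.542,
    "paralysis": 0.046,
    "other_neurological_disorders": 0.092,
    "chronic_pulmonary_disease": 0.108,
    "diabetes_uncomplicated": 0.084,
    "diabetes_complicated": 0.093,
    "hypothyroidism": 0.051,
    "renal_failure": 0.040,
    "liver_disease": 0.016,
    "peptic_ulcer_disease_excluding_bleeding": 0.023,
    "aids_hiv": 0.0001,
    "lymphoma": 0.006,
    "metastatic_cancer": 0.004,
    "solid_tumour_without_metastasis": 0.094,
    "rheumatoid_arthritis_collagen_vascular": 0.036,
    "coagulopathy": 0.003,
    "obesity": 0.016,
    "weight_loss": 0.002,
    "fluid_electrolyte_disorders": 0.004,
    "blood_loss_anaemia": 0.011,
    "deficiency_anaemia": 0.067,
    "alcohol_abuse": 0.032,
    "drug_abuse": 0.001,
    "psychoses": 0.022,
    "depression": 0.098,
}

_MIN_GAP_DAYS = 7


class SpecError(ValueError):
    """The cohort spec references an unknown category or bad probability."""


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort; fully reproducible from ``seed``."""

    n_patients: int = 1000
    charlson_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(CHARLSON_PREVALENCE)
    )
    elixhauser_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(ELIXHAUSER_PREVALENCE)
    )
    noise_code_rate: float = 2.0  # expected injury-chapter codes per patient
    claims_per_code: int = 2
    date_span_days: int = 1461  # 4-year lookback window
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SpecError("n_patients must be non-negative")
        for index_name, prev in (
            ("charlson", self.charlson_prevalence),
            ("elixhauser", self.elixhauser_prevalence),
        ):
            known = set(load_map(index_name).category_names)
            for cat, p in prev.items():
                if cat not in known:
                    raise SpecError(f"unknown {index_name} category {cat!r}")
                if not 0.0 <= p <= 1.0:
                    raise SpecError(f"prevalence for {cat} out of [0, 1]: {p}")
        if self.claims_per_code < 1:
            raise SpecError("claims_per_code must be >= 1")
        if self.date_span_days < 1:
            raise SpecError("date_span_days must be positive")


@dataclass
class GroundTruth:
    """Intended category draws and the flags implied by the emitted codes.

    ``intended`` holds the raw Bernoulli draws per index (patients x
    categories); ``flags`` holds their closure — the flags obtained by
    pushing each patient's emitted comorbidity codes through both maps. The
    two differ where a code drawn for one index's category also belongs to a
    category of the other index (e.g. any congestive-heart-failure code flags
    the category in both indices).
    """

    patient_ids: list[str]
    intended: dict[str, pd.DataFrame]
    flags: dict[str, pd.DataFrame]


def _noise_pool() -> list[str]:
    # S-chapter injury codes; the maps draw on other chapters, but
    # disjointness is asserted rather than assumed
    pool = [f"S{i:02d}{d}" for i in range(0, 70) for d in range(10)]
    for index_name in ("charlson", "elixhauser"):
        cmap = load_map(index_name)
        bad = [c for c in pool if any(flag_categories([c], cmap).values())]
        if bad:
            raise AssertionError(f"noise codes collide with {index_name} map: {bad[:5]}")
    return pool


def _expand_prefix(prefix: str, rng: np.random.Generator) -> str:
    # 3-character map prefixes are padded with a random digit so prefix
    # matching on longer recorded codes is exercised
    if len(prefix) == 3:
        return prefix + str(rng.integers(0, 10))
    return prefix


def _claim_offsets(k: int, span: int, rng: np.random.Generator) -> list[int]:
    # days before the index date; for k >= 2 the first two are >= 7 apart
    if k == 1:
        return [int(rng.integers(0, span + 1))]
    far = int(rng.integers(_MIN_GAP_DAYS, span + 1))
    near = int(rng.integers(0, far - _MIN_GAP_DAYS + 1))
    extras = [int(x) for x in rng.integers(0, span + 1, size=k - 2)]
    return [far, near, *extras]


def generate(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Draw one synthetic cohort: (claims, ground truth, index events).

    Claims come back as a long table (``patient_id``, ``date`` ISO-8601,
    ``code``), index events as (``patient_id``, ``index_date``). Identical
    specs (including seed) produce byte-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    maps = {name: load_map(name) for name in ("charlson", "elixhauser")}
    prevalence = {
        "charlson": spec.charlson_prevalence,
        "elixhauser": spec.elixhauser_prevalence,
    }
    noise_pool = _noise_pool()
    base_date = dt.date(2016, 9, 30)

    n = spec.n_patients
    patient_ids = [f"P{i + 1:05d}" for i in range(n)]
    draws = {}
    for index_name, cmap in maps.items():
        cats = cmap.category_names
        p = np.array([prevalence[index_name].get(c, 0.0) for c in cats])
        draws[index_name] = pd.DataFrame(
            (rng.random((n, len(cats))) < p).astype(int),
            index=patient_ids,
            columns=list(cats),
        )

    # A disease present in both indices (same prefix set, same prevalence) is
    # one disease, not two: couple its draws so its codes are emitted once and
    # its observed prevalence stays at the spec value instead of inflating.
    coupled: dict[str, str] = {}
    for ecat in maps["elixhauser"].categories:
        for ccat in maps["charlson"].categories:
            if ecat.prefixes == ccat.prefixes and prevalence["elixhauser"].get(
                ecat.name, 0.0
            ) == prevalence["charlson"].get(ccat.name, 0.0):
                coupled[ecat.name] = ccat.name
                draws["elixhauser"][ecat.name] = draws["charlson"][ccat.name]
                break

    index_offsets = rng.integers(0, 366, size=n)
    noise_counts = rng.poisson(spec.noise_code_rate, size=n)

    claim_rows: list[tuple[str, str, str]] = []
    truth_flags = {name: [] for name in maps}
    index_rows = []
    for i, pid in enumerate(patient_ids):
        index_date = base_date + dt.timedelta(days=int(index_offsets[i]))
        index_rows.append((pid, index_date.isoformat()))
        comorbidity_codes: list[str] = []
        for index_name, cmap in maps.items():
            row = draws[index_name].iloc[i]
            for cat in cmap.categories:
                if index_name == "elixhauser" and cat.name in coupled:
                    continue  # codes already emitted via the coupled draw
                if row[cat.name]:
                    prefix = sorted(cat.prefixes)[rng.integers(0, len(cat.prefixes))]
                    comorbidity_codes.append(_expand_prefix(prefix, rng))
        noise_codes = [
            noise_pool[j] for j in rng.integers(0, len(noise_pool), size=noise_counts[i])
        ]
        for code in comorbidity_codes + noise_codes:
            for off in _claim_offsets(spec.claims_per_code, spec.date_span_days, rng):
                claim_date = index_date - dt.timedelta(days=off)
                claim_rows.append((pid, claim_date.isoformat(), code))
        for index_name, cmap in maps.items():
            truth_flags[index_name].append(flag_categories(comorbidity_codes, cmap))

    claims = pd.DataFrame(claim_rows, columns=["patient_id", "date", "code"])
    index_events = pd.DataFrame(index_rows, columns=["patient_id", "index_date"])
    truth = GroundTruth(
        patient_ids=patient_ids,
        intended=draws,
        flags={
            name: pd.DataFrame(rows, index=patient_ids)
            for name, rows in truth_flags.items()
        },
    )
    return claims, truth, index_events


def degrade(
    claims: pd.DataFrame,
    truth: GroundTruth,
    drop_rate: float = 0.0,
    same_day_collapse: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Stress the qualification filter by thinning or collapsing claims.

    Per (patient, code) group: each repeat claim after the first is dropped
    with probability ``drop_rate``; with probability ``same_day_collapse``
    all of the group's dates are collapsed onto the first date. Ground-truth
    flags are recomputed as the expected *post-filter* truth — flags implied
    by codes that still occur on >= 2 distinct dates >= 7 days apart.
    """
    rng = np.random.default_rng(seed)
    kept_rows = []
    surviving: dict[str, set[str]] = {pid: set() for pid in truth.patient_ids}
    for (pid, code), group in claims.groupby(["patient_id", "code"], sort=False):
        group = group.sort_values("date")
        rows = [group.iloc[0]]
        for _, row in group.iloc[1:].iterrows():
            if drop_rate == 0.0 or rng.random() >= drop_rate:
                rows.append(row)
        if same_day_collapse > 0.0 and rng.random() < same_day_collapse:
            first = rows[0]["date"]
            rows = [row.copy() for row in rows]
            for row in rows:
                row["date"] = first
        kept_rows.extend(rows)
        dates = sorted({pd.Timestamp(r["date"]) for r in rows})
        if len(dates) >= 2 and (dates[-1] - dates[0]).days >= _MIN_GAP_DAYS:
            surviving.setdefault(str(pid), set()).add(str(code))
    degraded = (
        pd.DataFrame(kept_rows).reset_index(drop=True)
        if kept_rows
        else claims.iloc[0:0].copy()
    )
    new_flags = {}
    for index_name in truth.flags:
        cmap = load_map(index_name)
        new_flags[index_name] = pd.DataFrame(
            [flag_categories(sorted(surviving.get(pid, set())), cmap) for pid in truth.patient_ids],
            index=truth.patient_ids,
        )
    return degraded, GroundTruth(truth.patient_ids, truth.intended, new_flags)
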