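# comorbicalc

Charlson and Elixhauser comorbidity indices from per-patient ICD-10
diagnosis data.

Comorbidity burden is the standard confounder in clinical and health-services
research, and two weighted scores dominate: the Charlson Comorbidity Index
(CCI, 17 ICD-coded disease categories) and the Elixhauser Comorbidity Index
(ECI, 31 categories). `comorbicalc` computes both from administrative claims
or any patient–code table, for epidemiologists and outcomes researchers who
need reproducible, auditable risk-adjustment scores.

## The calculation

For patient *i* with normalized ICD-10 code set *C_i*, each category *k* of an
index is flagged by prefix matching against the Quan et al. (2005) ICD-10
coding algorithm:

    x_ik = 1  iff  some c in C_i starts with a prefix of category k

A hierarchy then zeroes each mild category whose severe partner is present
(uncomplicated vs. complicated diabetes, any malignancy vs. metastatic solid
tumour, mild vs. moderate/severe liver disease; analogously for ECI), and the
score is the weighted sum

    S_i = sum_k  w_k * x~_ik

where *x~* are the hierarchy-adjusted flags and *w* one of four weighting
schemes: original Charlson (1987), updated Charlson (Quan 2011), van Walraven
(2009), or AHRQ (Moore 2017). ECI scores can be negative (some weights are
protective). Code matching is tolerant to case, punctuation and arbitrary
separators — `"i21.0; e11,K70"` parses as `I210`, `E11`, `K70`.

An optional claims-qualification filter restricts ascertainment the way
registry studies do: only codes dated within a 4-year lookback window ending
at the patient's index event, appearing on at least two distinct dates at
least 7 days apart.

The category→prefix maps, the four weight tables and the hierarchy ship as
commented TSV files under `src/comorbicalc/data/` so they can be audited or
adapted.

## Worked example

```sh
$ printf 'patient_id,icd10\nP1,"i21.0; C18, C77"\nP2,K70.4;B18\n' > demo.csv
$ comorbicalc score --input demo.csv --output scores.csv
$ cut -d, -f1-5 scores.csv
patient_id,charlson_original,charlson_updated,elixhauser_vanwalraven,elixhauser_ahrq
P1,7,6,12,14
P2,3,4,11,4
```

P1 has a myocardial infarction (1 point, original CCI), a colon cancer code
(`C18`, any malignancy, 2) and a metastasis code (`C77`, 6): the hierarchy
suppresses the 2-point malignancy flag, so the original CCI is 1 + 6 = 7, not
9. Under the van Walraven ECI the metastasis weighs 12 and `C18` (solid
tumour without metastasis, 4) is likewise suppressed. P2 carries `K70.4`
(moderate/severe liver disease, 3) and `B18`, chronic viral hepatitis (mild
liver disease, 1) — the mild flag is suppressed, so the original CCI is 3;
the same single liver-disease category gives the van Walraven ECI 11. The
remaining columns of `scores.csv` hold every raw and hierarchy-adjusted
category flag.

The full pipeline on synthetic claims:

```sh
comorbicalc simulate --seed 7 --n 1000 --out-prefix cohort
comorbicalc qualify  --input cohort_claims.csv --index-dates cohort_index_events.csv --output wide.csv
comorbicalc score    --input wide.csv --output results.csv
comorbicalc summarize --input wide.csv
```

`summarize` prints median (25th–75th percentile) per scheme, binned score
counts (CCI bins 0, 1–2, 3–4, ≥5; ECI bins ≤0, 1–4, 5–9, ≥10) and per-category
n (%) rows.

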