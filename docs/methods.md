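# Methods

## Scope and model

`comorbicalc` computes the two standard comorbidity summary scores used for
risk adjustment in administrative-data research — the Charlson Comorbidity
Index (CCI) and the Elixhauser Comorbidity Index (ECI) — from per-patient
ICD-10 diagnosis codes. The computation is deliberately simple and fully
deterministic, in two steps per patient:

1. **Category flagging.** Each of the CCI's 17 and the ECI's 31 comorbidity
   categories is defined by a set of ICD-10 code prefixes (the Quan et al.
   2005 coding algorithm). A category is flagged when any of the patient's
   normalized codes starts with one of its prefixes. Flagging is
   presence-based: repeating a code changes nothing.
2. **Weighted score with hierarchy.** For each weighting scheme, a mild
   category is zeroed when its severe partner is flagged (three pairs per
   index: liver disease, diabetes, and malignancy for the CCI; hypertension,
   diabetes, and solid tumour for the ECI), then the score is the integer dot
   product of the adjusted flags and the scheme's weights.

Both raw and adjusted flags are retained on every result because published
cohort tables do not always state which of the two their category counts use;
keeping both makes either reproducible.

### Code matching semantics

Codes are normalized to uppercase alphanumeric tokens before any comparison,
so `i21.0`, `I21,0` and `I210` are the same code. Diagnosis cells may use any
separator; the one subtlety is the ICD-10 dot, which is intra-code
punctuation when digits follow (`I21.0` is one code) and a separator
otherwise. Matching is per-token prefix matching, which is provably
equivalent (property-tested over randomized cells) to the spreadsheet idiom
of searching each pattern as a substring of the whole cell text — the
equivalence holds because ICD-10 tokens start with a letter followed by
digits, so a pattern can never begin mid-token. A recorded code shorter than
a pattern (e.g. a bare `E11` against the four-character diabetes prefixes)
never matches; this follows the substring behaviour and errs toward
under-flagging at coarse coding granularity.

A few prefixes of the published Elixhauser algorithm legitimately belong to
two categories (e.g. `I426` to congestive heart failure and alcohol abuse,
`I120` to complicated hypertension and renal failure); such cross-category
overlaps are reported by `prefix_overlap_report` at audit time, never
rejected.

### Weight schemes

| scheme | source | notes |
|---|---|---|
| `charlson_original` | Charlson 1987 | weights 1–6, 17-category ICD-10 adaptation |
| `charlson_updated` | Quan 2011 | five categories drop to weight 0 |
| `elixhauser_vanwalraven` | van Walraven 2009 | weights −7…12 |
| `elixhauser_ahrq` | Moore 2017 (AHRQ v2017, in-hospital mortality) | see below |

Published "AHRQ" weights exist in several revisions; this package pins the
Moore et al. 2017 in-hospital mortality index. Two consequences are worth
stating: cardiac arrhythmias is not part of that model and carries weight 0,
and the single published combined-hypertension weight (−1) is assigned to
both hypertension categories — the hierarchy makes them mutually exclusive at
scoring time, so a patient contributes the weight exactly once. All weight
tables are double-entered: the packaged TSVs are compared category-by-category
in the test suite against an independently typed copy.

## Claims qualification filter

When input is dated claims rather than a curated code list, two optional
rules (on by default in the `qualify` command, defaults chosen to match
common registry practice) restrict ascertainment:

* **Lookback window** — claims from the index date back `lookback_years`
  (default 4) calendar years, both endpoints inclusive; later claims are
  dropped with a QC note.
* **Repeat rule** — a code qualifies only if it occurs on at least
  `min_occurrences` (default 2) distinct dates with at least one pair of
  dates `min_gap_days` (default 7) apart. "Apart" is read as calendar-day
  difference ≥ 7 between some pair of occurrence dates — the weakest reading
  of the rule, equivalent to requiring the date span to reach the gap, and
  monotone in both parameters (verified by property tests and an O(n²)
  pairwise-date oracle). Occurrences are counted on distinct dates, not
  distinct claims, and qualification operates on codes at recorded precision
  (no truncation — downstream prefix matching already absorbs granularity).

With `min_occurrences=1, min_gap_days=0` the filter degenerates to the
distinct code set.

## Synthetic cohort generator

The generator emulates dated ICD-10 claim streams around an index
hospitalization. Per patient, each category of each index is drawn
independently with a specified prevalence; the defaults are the comorbidity
profile of a population-wide elderly hip-fracture cohort (e.g. congestive
heart failure 43.7%, complicated hypertension 54.2%). A present category
emits one full code drawn uniformly from its prefix list (three-character
prefixes are padded with a random digit so longer-than-prefix matching is
exercised), repeated on `claims_per_code` (default 2) distinct dates at least
7 days apart inside the 4-year window — the minimum that survives the
qualification filter. Poisson-distributed injury-chapter (S) noise codes
(rate 2/patient) are added; their disjointness from both maps is asserted at
generation time rather than assumed from the chapter rule.

Two ground-truth views are stored. The *intended* draws are the raw Bernoulli
samples; the *flag* truth is their closure — the flags implied by pushing the
emitted codes through both maps. The two differ because indices share
diseases: a congestive-heart-failure code flags the category in both indices.
Where a category pair has identical prefix sets and equal prevalence across
indices (heart failure, peripheral vascular disease, chronic pulmonary
disease, paralysis, metastatic cancer, AIDS/HIV), the draws are coupled and
the codes emitted once, so observed prevalence stays at the spec value
instead of inflating. Pipeline-recovery tests compare against the closure;
prevalence-recovery tests (within 3 binomial standard errors at n = 10,000)
against the intended draws.

What the generator does **not** model — and therefore what passing tests do
not establish about real data: disease co-occurrence correlation, coding
drift over time, miscoding, mortality, or any relationship between
comorbidity and the index event. Synthetic cohorts certify the calculator's
mechanics, not the epidemiology; score distributions of synthetic cohorts are
accordingly close to, but not identical with, those of the real cohort whose
marginal prevalences they borrow. A `degrade` operator thins repeat claims or
collapses dates to stress the qualification filter, updating ground truth to
the expected post-filter state.

## Summaries

Cohort summaries report, per scheme, the median with 25th/75th percentiles
(linear interpolation between order statistics — the common software default;
on large integer-score cohorts the median is an order statistic regardless),
binned counts (CCI: 0, 1–2, 3–4, ≥5; ECI: ≤0 labelled "0", 1–4, 5–9, ≥10 —
the first ECI bin absorbs negative totals so bins partition the cohort), and
per-category n (%). Percentages are printed to one decimal; a nonzero count
that rounds to 0.0 prints as `< 0.0`.

## Verification design

Every numerical path has an independent route in the test suite:

* flagging and scoring vs. a whole-cell substring oracle plus brute-force
  hierarchy and summation, on randomized inputs and on a 2,000-patient
  synthetic cohort (104,000 compared values, zero tolerated mismatches);
* full coverage: every mapped prefix, fed as a code, flags exactly its
  contributing categories;
* the six hierarchy pairs in isolation and jointly;
* the qualification filter vs. an O(n²) pairwise-date oracle across parameter
  settings;
* exact ground-truth recovery of noise-free synthetic cohorts through the
  full qualify-and-score pipeline.

`scripts/acceptance.py` re-runs all of these from scratch at fixed problem
sizes (2,000-patient oracle cohort, 1,000-patient recovery cohort, 50-patient
filter fixture — sizes chosen to keep the whole run under a few seconds while
exceeding 10⁵ compared values) and writes the resulting counts and medians as
JSON.

## Known limitations

* ICD-10 only: no ICD-9(-CM), ICD-10-CM or ICD-11 mappings, and no validation
  against the official WHO registry — a syntactically valid but nonexistent
  code simply matches or misses prefixes.
* The deposited real-cohort reproduction check requires downloading the
  published dataset and is therefore optional; the corresponding test runs
  only when the file is present locally.
* Scores are risk-adjustment covariates; the package makes no mortality or
  survival predictions from them.
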