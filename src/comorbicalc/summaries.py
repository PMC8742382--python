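"""Cohort-level summaries: score quartiles, binned distributions, prevalences.

The conventional presentation for a comorbidity-scored cohort is a table of
"median (25th–75th percentile)" per weighting scheme, binned score counts,
and per-category n (%) rows. Charlson scores are binned {0, 1–2, 3–4, ≥5};
Elixhauser scores {≤0 (labelled "0"), 1–4, 5–9, ≥10} — the first Elixhauser
bin absorbs negative totals (van Walraven weights admit them) so the bins
partition the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import SCHEME_INDEX, load_map
from .scoring import PatientResult

__all__ = [
    "ScoreSummary",
    "CohortSummary",
    "summarize_scores",
    "summarize_categories",
    "summarize_cohort",
    "format_percent",
    "summary_frame",
    "render_text",
]

_BINS = {
    "charlson": (
        ("0", lambda s: s == 0),
        ("1-2", lambda s: (1 <= s) & (s <= 2)),
        ("3-4", lambda s: (3 <= s) & (s <= 4)),
        (">=5", lambda s: s >= 5),
    ),
    "elixhauser": (
        ("0", lambda s: s <= 0),  # "<= 0": negative totals land here
        ("1-4", lambda s: (1 <= s) & (s <= 4)),
        ("5-9", lambda s: (5 <= s) & (s <= 9)),
        (">=10", lambda s: s >= 10),
    ),
}


@dataclass
class ScoreSummary:
    scheme_name: str
    n: int
    median: float
    p25: float
    p75: float
    bins: list[tuple[str, int, float]]  # (label, count, percent)


@dataclass
class CohortSummary:
    n: int
    scores: dict[str, ScoreSummary]
    category_counts: dict[str, dict[str, tuple[int, float]]]  # index -> cat -> (n, %)


def format_percent(count: int, total: int) -> str:
    """Percent to one decimal; a nonzero count that rounds to 0.0 prints "< 0.0"."""
    pct = round(100.0 * count / total, 1)
    if count > 0 and pct == 0.0:
        return "< 0.0"
    return f"{pct:.1f}"


def summarize_scores(scores: list[int], scheme_name: str) -> ScoreSummary:
    """Median, quartiles and binned counts for one scheme's scores.

    Quartiles use linear interpolation between order statistics (the default
    of mainstream statistical software). Raises on an empty cohort.
    """
    if len(scores) == 0:
        raise ValueError("cannot summarize an empty cohort")
    arr = np.asarray(scores)
    p25, median, p75 = np.percentile(arr, [25, 50, 75])
    bins = []
    for label, rule in _BINS[SCHEME_INDEX[scheme_name]]:
        count = int(rule(arr).sum())
        bins.append((label, count, round(100.0 * count / len(arr), 1)))
    return ScoreSummary(scheme_name, len(arr), float(median), float(p25), float(p75), bins)


def summarize_categories(
    results: list[PatientResult],
    index_name: str,
    which_flags: str = "raw",
) -> dict[str, tuple[int, float]]:
    """Per category: count of flagged patients and percent of cohort.

    ``which_flags`` selects raw (pre-hierarchy) or adjusted (post-hierarchy)
    flags; cohort tables in the literature may use either.
    """
    if not results:
        raise ValueError("cannot summarize an empty cohort")
    if which_flags not in ("raw", "adjusted"):
        raise ValueError("which_flags must be 'raw' or 'adjusted'")
    n = len(results)
    out = {}
    for cat in load_map(index_name).category_names:
        count = sum(
            getattr(r.flags[index_name], which_flags)[cat] for r in results
        )
        out[cat] = (count, round(100.0 * count / n, 1))
    return out


def summarize_cohort(
    results: list[PatientResult], which_flags: str = "raw"
) -> CohortSummary:
    """Full Table-style summary over every scheme and index present."""
    scheme_names = [s for s in SCHEME_INDEX if s in results[0].scores]
    scores = {
        s: summarize_scores([r.scores[s] for r in results], s) for s in scheme_names
    }
    categories = {
        index_name: summarize_categories(results, index_name, which_flags)
        for index_name in results[0].flags
    }
    return CohortSummary(len(results), scores, categories)


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Flatten a CohortSummary to a tidy frame (section, variable, value...)."""
    rows = []
    for s in summary.scores.values():
        rows.append((s.scheme_name, "median (p25-p75)",
                     f"{s.median:g} ({s.p25:g}-{s.p75:g})", "", ""))
        for label, count, _pct in s.bins:
            rows.append((s.scheme_name, f"score {label}", "", count,
                         format_percent(count, summary.n)))
    for index_name, counts in summary.category_counts.items():
        cmap = load_map(index_name)
        for cat, (count, _pct) in counts.items():
            rows.append((f"{index_name} categories", cmap.display_name(cat), "",
                         count, format_percent(count, summary.n)))
    return pd.DataFrame(rows, columns=["section", "variable", "value", "n", "percent"])


def render_text(summary: CohortSummary) -> str:
    """Aligned plain-text rendering of the cohort summary."""
    frame = summary_frame(summary)
    lines = [f"Cohort summary (n = {summary.n})"]
    section = None
    for _, row in frame.iterrows():
        if row["section"] != section:
            section = row["section"]
            lines.append(f"\n{section}")
        if row["value"]:
            lines.append(f"  {row['variable']:<42} {row['value']}")
        else:
            lines.append(f"  {row['variable']:<42} {row['n']:>6} ({row['percent']})")
    return "\n".join(lines) + "\n"
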