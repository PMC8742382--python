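"""Packaged comorbidity maps and weight schemes.

The ICD-10 coding algorithms (category -> code-prefix sets) for the Charlson
(17 categories) and Elixhauser (31 categories) indices, and the four weighting
schemes — original Charlson (1987), updated Charlson (Quan 2011), van Walraven
(2009) and AHRQ (Moore 2017) — ship as plain TSV files under
``comorbicalc/data/`` so users can audit or adapt them. Each file carries its
source citation in its comment header. A schema check runs at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "MAP_VERSION",
    "INDEX_NAMES",
    "SCHEME_NAMES",
    "SCHEME_INDEX",
    "Category",
    "ComorbidityMap",
    "WeightScheme",
    "ConfigurationError",
    "DataIntegrityError",
    "load_map",
    "load_weights",
    "list_all_codes",
    "prefix_overlap_report",
]

MAP_VERSION = "2025.1"

INDEX_NAMES = ("charlson", "elixhauser")
SCHEME_NAMES = (
    "charlson_original",
    "charlson_updated",
    "elixhauser_vanwalraven",
    "elixhauser_ahrq",
)
SCHEME_INDEX = {
    "charlson_original": "charlson",
    "charlson_updated": "charlson",
    "elixhauser_vanwalraven": "elixhauser",
    "elixhauser_ahrq": "elixhauser",
}

_EXPECTED_N_CATEGORIES = {"charlson": 17, "elixhauser": 31}


class ConfigurationError(ValueError):
    """Unknown index or scheme name."""


class DataIntegrityError(ValueError):
    """A packaged data file violates its schema or invariants."""


@dataclass(frozen=True)
class Category:
    name: str
    display_name: str
    prefixes: frozenset[str]


@dataclass(frozen=True)
class ComorbidityMap:
    """Ordered categories of one index, each with its ICD-10 prefix set."""

    index_name: str
    categories: tuple[Category, ...]

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def display_name(self, category: str) -> str:
        for c in self.categories:
            if c.name == category:
                return c.display_name
        raise KeyError(category)


@dataclass(frozen=True)
class WeightScheme:
    """Integer weights plus mild->severe suppression pairs for one scheme."""

    scheme_name: str
    index_name: str
    weights: dict[str, int]
    hierarchy: tuple[tuple[str, str], ...]


def _read_data_lines(filename: str) -> list[list[str]]:
    text = resources.files("comorbicalc.data").joinpath(filename).read_text("utf-8")
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    if not rows:
        raise DataIntegrityError(f"{filename}: no data rows")
    return rows


@lru_cache(maxsize=None)
def load_map(index_name: str) -> ComorbidityMap:
    """Load and validate the packaged coding algorithm for one index.

    Raises ``ConfigurationError`` for an unknown index name and
    ``DataIntegrityError`` if the packaged file fails validation.
    """
    if index_name not in INDEX_NAMES:
        raise ConfigurationError(
            f"unknown index {index_name!r}; expected one of {INDEX_NAMES}"
        )
    rows = _read_data_lines(f"{index_name}_map.tsv")
    header, body = rows[0], rows[1:]
    if header != ["category", "display_name", "prefixes"]:
        raise DataIntegrityError(f"{index_name}_map.tsv: bad header {header}")
    categories = []
    for row in body:
        if len(row) != 3:
            raise DataIntegrityError(f"{index_name}_map.tsv: bad row {row}")
        name, display, prefixes = row
        prefix_set = frozenset(p for p in prefixes.split(";") if p)
        if not prefix_set:
            raise DataIntegrityError(f"{index_name}_map.tsv: {name} has no prefixes")
        if any(not p.isalnum() or not p[0].isalpha() or p != p.upper() for p in prefix_set):
            raise DataIntegrityError(f"{index_name}_map.tsv: malformed prefix in {name}")
        categories.append(Category(name, display, prefix_set))
    n_expected = _EXPECTED_N_CATEGORIES[index_name]
    if len(categories) != n_expected:
        raise DataIntegrityError(
            f"{index_name} map has {len(categories)} categories, expected {n_expected}"
        )
    if len({c.name for c in categories}) != len(categories):
        raise DataIntegrityError(f"{index_name} map has duplicate category names")
    return ComorbidityMap(index_name, tuple(categories))


@lru_cache(maxsize=None)
def _load_hierarchy(index_name: str) -> tuple[tuple[str, str], ...]:
    rows = _read_data_lines("hierarchy.tsv")
    if rows[0] != ["index", "mild", "severe"]:
        raise DataIntegrityError(f"hierarchy.tsv: bad header {rows[0]}")
    pairs = tuple((m, s) for idx, m, s in rows[1:] if idx == index_name)
    names = set(load_map(index_name).category_names)
    for mild, severe in pairs:
        if mild not in names or severe not in names:
            raise DataIntegrityError(f"hierarchy pair ({mild}, {severe}) unknown")
        if any(p[0] == severe for p in pairs):
            # severe side may not be the mild side of another pair (no chains)
            if severe in {m for m, _ in pairs}:
                raise DataIntegrityError(f"hierarchy chain through {severe}")
    return pairs


@lru_cache(maxsize=None)
def load_weights(scheme_name: str) -> WeightScheme:
    """Load and validate one of the four packaged weighting schemes."""
    if scheme_name not in SCHEME_NAMES:
        raise ConfigurationError(
            f"unknown scheme {scheme_name!r}; expected one of {SCHEME_NAMES}"
        )
    index_name = SCHEME_INDEX[scheme_name]
    rows = _read_data_lines("weights.tsv")
    if rows[0] != ["scheme", "index", "category", "weight"]:
        raise DataIntegrityError(f"weights.tsv: bad header {rows[0]}")
    weights: dict[str, int] = {}
    for scheme, index, category, weight in rows[1:]:
        if scheme != scheme_name:
            continue
        if index != index_name:
            raise DataIntegrityError(f"weights.tsv: {scheme} bound to wrong index {index}")
        if category in weights:
            raise DataIntegrityError(f"weights.tsv: duplicate weight for {category}")
        weights[category] = int(weight)
    expected = set(load_map(index_name).category_names)
    if set(weights) != expected:
        missing = expected - set(weights)
        extra = set(weights) - expected
        raise DataIntegrityError(
            f"weights.tsv: {scheme_name} category mismatch "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )
    return WeightScheme(scheme_name, index_name, weights, _load_hierarchy(index_name))


def list_all_codes(comorbidity_map: ComorbidityMap) -> set[str]:
    """Union of every category's prefix set (the full-coverage test input)."""
    out: set[str] = set()
    for c in comorbidity_map.categories:
        out |= c.prefixes
    return out


def prefix_overlap_report(comorbidity_map: ComorbidityMap) -> list[str]:
    """Report prefixes of one category that are strict prefixes of another's.

    The published coding algorithm contains a handful of deliberate overlaps
    (e.g. the Elixhauser complicated-hypertension prefix ``I12`` covers the
    renal-failure code ``I120``); they are reported, not rejected, so map
    editors can see exactly where a single code feeds two categories. Declared
    hierarchy pairs are excluded.
    """
    hierarchy = set(_load_hierarchy(comorbidity_map.index_name))
    hierarchy |= {(s, m) for m, s in hierarchy}
    report = []
    for a in comorbidity_map.categories:
        for b in comorbidity_map.categories:
            if a.name == b.name or (a.name, b.name) in hierarchy:
                continue
            for p in sorted(a.prefixes):
                hits = [q for q in b.prefixes if q != p and q.startswith(p)]
                if hits:
                    report.append(
                        f"{comorbidity_map.index_name}: prefix {p} of {a.name} "
                        f"covers {sorted(hits)} of {b.name}"
                    )
    return report
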