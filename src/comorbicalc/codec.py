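"""ICD-10 code normalization, tokenization and prefix matching.

ICD-10 diagnosis codes are alphanumeric tokens — one letter followed by two
to five alphanumeric characters (``I21.0``, ``S72.1``). Administrative data
arrives in every imaginable surface form: lowercase, with or without the dot,
and with arbitrary separators between codes in a single cell. Everything in
this module is tolerant to that variation: codes are reduced to a canonical
uppercase, punctuation-free token before any comparison, and category
membership is decided by prefix matching on those tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "MalformedCodeError",
    "QCReport",
    "normalize_code",
    "tokenize_codes",
    "prefix_match",
    "is_wellformed",
]

# A token is an alphanumeric run, optionally continued by ".<digits>" — the
# dot is ICD-10's intra-code punctuation ("I21.0" is one code), whereas a dot
# followed by a letter separates two codes.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:\.[0-9]+)*")

# Canonical token: letter + 2-5 alphanumerics. Tokens outside this shape are
# kept (the calculator accepts any input) but flagged in the QC report.
_WELLFORMED_RE = re.compile(r"^[A-Z][A-Z0-9]{2,5}$")


class MalformedCodeError(ValueError):
    """Raised when a code is empty after stripping punctuation and whitespace."""


@dataclass
class QCReport:
    """Accumulates non-fatal data-quality observations across a run.

    Nothing here stops a computation: odd tokens are scored as-is (they simply
    match no category) and post-index claims are dropped, but a user auditing
    a cohort should be able to see both.
    """

    odd_tokens: list[str] = field(default_factory=list)
    unmatched_codes: list[str] = field(default_factory=list)
    dropped_claims: int = 0
    notes: list[str] = field(default_factory=list)

    def note(self, message: str) -> None:
        self.notes.append(message)

    def merge(self, other: "QCReport") -> None:
        self.odd_tokens.extend(other.odd_tokens)
        self.unmatched_codes.extend(other.unmatched_codes)
        self.dropped_claims += other.dropped_claims
        self.notes.extend(other.notes)

    def summary(self) -> str:
        return (
            f"QC: {len(self.odd_tokens)} odd tokens, "
            f"{len(self.unmatched_codes)} unmatched codes, "
            f"{self.dropped_claims} dropped claims, {len(self.notes)} notes"
        )


def normalize_code(raw: str, qc: QCReport | None = None) -> str:
    """Return the canonical form of one ICD-10 code.

    Uppercases and strips every non-alphanumeric character, so ``"i21.0"``,
    ``" I21,0 "`` and ``"I210"`` all normalize to ``"I210"``.

    Raises
    ------
    MalformedCodeError
        If nothing alphanumeric remains.
    """
    token = "".join(ch for ch in str(raw) if ch.isalnum()).upper()
    if not token:
        raise MalformedCodeError(f"code {raw!r} is empty after normalization")
    if qc is not None and not is_wellformed(token):
        qc.odd_tokens.append(token)
    return token


def tokenize_codes(cell: str | None, qc: QCReport | None = None) -> list[str]:
    """Split one diagnosis cell into normalized code tokens.

    Any run of non-alphanumeric characters acts as a separator, so ``";"``,
    ``", "``, ``" | "`` and mixtures thereof all work — except the ICD-10
    dot, which stays inside a code when digits follow it (``"I21.0"`` is the
    single code ``I210``). Order is preserved and duplicates are kept —
    deduplication is a downstream decision (the claims qualification filter
    needs occurrence counts).
    """
    if cell is None:
        return []
    text = str(cell)
    if text != text:  # NaN from pandas
        return []
    tokens = [m.group(0).replace(".", "").upper() for m in _TOKEN_RE.finditer(text)]
    if qc is not None:
        qc.odd_tokens.extend(t for t in tokens if not is_wellformed(t))
    return tokens


def prefix_match(code: str, patterns: Iterable[str]) -> bool:
    """True iff some pattern is a leading substring of ``code``.

    A code strictly shorter than every pattern never matches: a recorded
    three-character diagnosis ``I5`` does not match the pattern ``I50``,
    mirroring the substring semantics of searching the pattern inside the
    cell text.
    """
    return any(code.startswith(p) for p in patterns)


def is_wellformed(token: str) -> bool:
    """Whether a normalized token has the canonical ICD-10 shape."""
    return bool(_WELLFORMED_RE.match(token))
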