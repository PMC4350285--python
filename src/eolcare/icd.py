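"""ICD-10 code normalization and range-expression matching.

Administrative cancer-ascertainment rules are written as mixed lists of
3-character category ranges (``C00-C43``), single categories (``D03``),
single one-decimal subcodes (``D46.7``) and one-decimal subcode ranges
(``D46.0-D46.4``, ``D47.4-D48.9``).  :class:`CodeSet` parses such a list
once and provides a total membership test over well-formed ICD-10 codes.

Matching semantics
------------------
* A category range matches any code whose 3-character category sorts
  within the range, inclusive.
* A decimal range matches a code whose category plus *first* decimal
  digit sorts within the range.  A bare 3-character code matches a
  decimal range only when its entire ``.0``-``.9`` span is contained in
  the range (so ``D48`` is inside ``D47.4-D48.9`` but ``D46`` is not
  inside ``D46.0-D46.4``).
* A single decimal entry matches on category plus first decimal digit;
  deeper digits are ignored (``D46.71`` matches ``D46.7``).

Codes are normalized by uppercasing and stripping whitespace; the
decimal point is retained.  Malformed codes always raise — membership is
never silently ``False`` for garbage input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ICDValidationError",
    "normalize_icd10",
    "CodeSet",
    "NOTIFIABLE_CANCER",
    "NON_NOTIFIABLE_CANCER_COD",
    "is_notifiable",
]

_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.([0-9]{1,4}))?$")
# Range separators seen in code lists: ASCII hyphen, en-dash, em-dash.
_DASH_RE = re.compile(r"[–—-]")


class ICDValidationError(ValueError):
    """Raised for a string that is not a well-formed ICD-10 code."""


def normalize_icd10(code: str) -> str:
    """Return the canonical form of *code* (uppercase, no whitespace).

    Raises :class:`ICDValidationError` if the result is not a letter,
    two digits and an optional decimal part.
    """
    if not isinstance(code, str):
        raise ICDValidationError(f"ICD-10 code must be a string, got {type(code).__name__}")
    cleaned = re.sub(r"\s+", "", code).upper()
    if not _CODE_RE.match(cleaned):
        raise ICDValidationError(f"malformed ICD-10 code: {code!r}")
    return cleaned


def _split(code: str) -> tuple[str, str | None]:
    """Normalized code -> (3-char category, first decimal digit or None)."""
    m = _CODE_RE.match(code)
    assert m is not None
    cat = m.group(1) + m.group(2)
    dec = m.group(3)
    return cat, (dec[0] if dec else None)


@dataclass(frozen=True)
class _Range:
    lo_cat: str
    hi_cat: str
    lo_dec: str | None  # first decimal digit of the low endpoint, or None
    hi_dec: str | None

    @property
    def decimal(self) -> bool:
        return self.lo_dec is not None

    def contains(self, cat: str, dec: str | None) -> bool:
        if not self.decimal:
            return self.lo_cat <= cat <= self.hi_cat
        lo = self.lo_cat + self.lo_dec
        hi = self.hi_cat + self.hi_dec
        if dec is None:
            # bare category: inside only if its whole .0-.9 span is covered
            return lo <= cat + "0" and cat + "9" <= hi
        return lo <= cat + dec <= hi


@dataclass
class CodeSet:
    """A named set of ICD-10 range expressions with a total membership test."""

    name: str
    expressions: tuple[str, ...]
    _ranges: list[_Range] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.expressions = tuple(self.expressions)
        for expr in self.expressions:
            self._ranges.append(self._parse(expr))

    @staticmethod
    def _parse(expr: str) -> _Range:
        parts = [p for p in _DASH_RE.split(expr.strip()) if p]
        if len(parts) == 1:
            lo = hi = normalize_icd10(parts[0])
        elif len(parts) == 2:
            lo, hi = (normalize_icd10(p) for p in parts)
        else:
            raise ValueError(f"cannot parse ICD-10 range expression: {expr!r}")
        lo_cat, lo_dec = _split(lo)
        hi_cat, hi_dec = _split(hi)
        if (lo_dec is None) != (hi_dec is None):
            raise ValueError(f"mixed category/decimal endpoints in range: {expr!r}")
        if (lo_cat, lo_dec or "") > (hi_cat, hi_dec or ""):
            raise ValueError(f"inverted range: {expr!r}")
        return _Range(lo_cat, hi_cat, lo_dec, hi_dec)

    def __contains__(self, code: str) -> bool:
        cat, dec = _split(normalize_icd10(code))
        return any(r.contains(cat, dec) for r in self._ranges)

    def any_member(self, codes) -> str | None:
        """First code in *codes* that belongs to the set, else None."""
        for code in codes:
            if code in self:
                return code
        return None


#: Cancers notifiable by law to the state registry.
NOTIFIABLE_CANCER = CodeSet(
    "notifiable_cancer",
    (
        "C00-C43", "C45-C97", "D03", "D05", "D45",
        "D46.0-D46.4", "D46.7", "D46.9", "D47.1", "D47.3",
    ),
)

#: Non-notifiable cancer causes of death (screening step 4 of the
#: non-cancer cohort hierarchy).
NON_NOTIFIABLE_CANCER_COD = CodeSet(
    "non_notifiable_cancer_cod",
    (
        "C44", "D01-D02", "D04", "D06-D09", "D10-D44",
        "D46.5", "D47.0", "D47.2", "D47.4-D48.9",
    ),
)


def is_notifiable(code: str) -> bool:
    """True iff *code* (or its category) is a notifiable cancer.

    ``C44`` and its subcodes are excluded — the notifiable ranges skip
    from C43 to C45.  Raises on malformed input.
    """
    return code in NOTIFIABLE_CANCER
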