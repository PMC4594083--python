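"""Patent identifier parsing, normalization and coverage windows.

Patent numbers arrive in many spellings (``WO2008/129280A1``, ``EP-1481667``,
``US4231938``).  For cross-database matching they are reduced to a
*comparison key*: the two-letter office code concatenated with the bare
serial, kind code stripped.  The SCPN rendering (``PO-n-KK``) is the
canonical hyphenated form used by SureChEMBL-style databases and requires a
kind code.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

__all__ = [
    "PatentId",
    "PatentIdError",
    "SourceCoverage",
    "parse_patent_number",
    "to_scpn",
    "comparison_key",
    "in_coverage",
    "COVERAGE_PRESETS",
]

#: Office-name synonyms normalized to two-letter codes on input.
_OFFICE_SYNONYMS = {"EPO": "EP", "USPTO": "US", "WIPO": "WO"}

# Kind code = trailing uppercase letter plus optional single digit, but only
# when what precedes it still ends in a digit (so a serial is never truncated).
_KIND_RE = re.compile(r"^(?P<serial>.*\d)(?P<kind>[A-Z]\d?)$")
_AUTH_RE = re.compile(r"^(?P<auth>[A-Z]{2})(?P<rest>\d.*)$")


class PatentIdError(ValueError):
    """Raised when a raw patent identifier cannot be parsed."""


@dataclass(frozen=True)
class PatentId:
    """A parsed patent identifier.

    ``year`` is publication-year metadata used for coverage-window checks;
    it is recovered from an explicit hint or from a four-digit year prefix
    of WO/EP-style serials, and is ``None`` when unknown.
    """

    authority: str
    serial: str
    kind_code: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]{2}", self.authority):
            raise PatentIdError(f"invalid authority {self.authority!r}")
        if not (self.serial and self.serial.isdigit()):
            raise PatentIdError(f"invalid serial {self.serial!r}")
        if self.kind_code and not re.fullmatch(r"[A-Z]\d?", self.kind_code):
            raise PatentIdError(f"invalid kind code {self.kind_code!r}")


@dataclass(frozen=True)
class SourceCoverage:
    """The slice of the patent corpus a database claims to cover.

    ``image_year_min`` marks the year from which structures are also mined
    from images; before it, image-only disclosures are invisible to the
    source even though the patent itself is covered.
    """

    authorities: frozenset[str] = frozenset({"EP", "US", "WO"})
    year_min: int = 1976
    year_max: int | None = None
    image_year_min: int | None = None

    def __post_init__(self) -> None:
        if self.year_max is not None and self.year_min > self.year_max:
            raise ValueError("year_min must not exceed year_max")
        object.__setattr__(self, "authorities", frozenset(self.authorities))


#: Named coverage windows for the sources studied; keys usable on the CLI.
COVERAGE_PRESETS: dict[str, SourceCoverage] = {
    "surechembl": SourceCoverage(year_min=1976, year_max=None, image_year_min=2007),
    "ibm": SourceCoverage(year_min=1976, year_max=2010),
    "both": SourceCoverage(year_min=1976, year_max=2010),
}


def parse_patent_number(raw: str, year_hint: int | None = None) -> PatentId:
    """Parse a raw patent-number string into a :class:`PatentId`.

    Separators (``/``, ``-``, whitespace) are removed, the leading
    two-letter authority (or an office-name synonym) is split off, and a
    trailing kind code — one uppercase letter plus an optional digit,
    anchored so it never consumes serial digits — is stripped from the
    serial but retained in the ``kind_code`` field.
    """
    if not raw or not raw.strip():
        raise PatentIdError("empty patent number")
    s = re.sub(r"[/\-\s]+", "", raw.strip().upper())
    for name, code in _OFFICE_SYNONYMS.items():
        if s.startswith(name) and len(s) > len(name) and s[len(name)].isdigit():
            s = code + s[len(name):]
            break
    m = _AUTH_RE.match(s)
    if not m:
        raise PatentIdError(f"no leading 2-letter authority in {raw!r}")
    authority, rest = m.group("auth"), m.group("rest")
    kind = ""
    km = _KIND_RE.match(rest)
    if km:
        rest, kind = km.group("serial"), km.group("kind")
    if not rest.isdigit():
        raise PatentIdError(f"non-digit residue {rest!r} in {raw!r}")
    year = year_hint
    if year is None and len(rest) >= 8:
        prefix = int(rest[:4])
        if 1900 <= prefix <= 2099:
            year = prefix
    return PatentId(authority=authority, serial=rest, kind_code=kind, year=year)


def to_scpn(p: PatentId) -> str:
    """Render ``PO-n-KK`` (authority, serial, kind code, hyphenated)."""
    if not p.kind_code:
        raise PatentIdError(
            "SCPN rendering requires a kind code; use comparison_key() for "
            "kind-code-free matching"
        )
    return f"{p.authority}-{p.serial}-{p.kind_code}"


def comparison_key(p: PatentId) -> str:
    """Matching key: two-letter office code + serial, kind code dropped."""
    return f"{p.authority}{p.serial}"


def in_coverage(
    p: PatentId, cov: SourceCoverage, *, unknown_year_included: bool = False
) -> bool:
    """Whether patent ``p`` falls inside coverage window ``cov``.

    A patent with unknown publication year cannot be placed in the window;
    by default it is excluded with a warning (set ``unknown_year_included``
    to keep it instead).
    """
    if p.authority not in cov.authorities:
        return False
    if p.year is None:
        warnings.warn(
            f"patent {comparison_key(p)} has unknown year; "
            f"{'included' if unknown_year_included else 'excluded'} from coverage",
            stacklevel=2,
        )
        return unknown_year_included
    if p.year < cov.year_min:
        return False
    if cov.year_max is not None and p.year > cov.year_max:
        return False
    return True
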