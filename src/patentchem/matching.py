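"""Coverage statistics for database-against-database comparison.

Two questions are answered here.  Patent->compounds: of the compounds a
curated source attributes to a patent, which fraction appears under the
same patent in an automatically mined source (per patent, aggregate, and
binned into a coverage histogram), with a three-way attribution when two
mined sources are compared.  Compound->patents: of a reference list of
(compound key, patent key) pairs, which are found in a mined source,
directly or — with family expansion enabled — in any retained family
member of the patent.

All percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CompoundPatentPair",
    "PatentOverlap",
    "OverlapReport",
    "SourceAttribution",
    "PairMatch",
    "PairMatchResult",
    "FamilyTable",
    "round_half_up",
    "coverage_percent",
    "relative_increase",
    "patent_to_compound_overlap",
    "bin_distribution",
    "three_way_attribution",
    "match_pairs",
    "per_authority_breakdown",
]

DECILE_EDGES: tuple[float, ...] = tuple(float(x) for x in range(0, 101, 10))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half-up (2.05 -> 2.1), the convention used for every reported
    percentage; banker's rounding would understate exact .x5 cases."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def coverage_percent(n_found: int, n_total: int) -> float:
    """100 * n_found / n_total, half-up to one decimal; NaN when the
    denominator is empty (reported as NA downstream)."""
    if n_total == 0:
        return math.nan
    if not 0 <= n_found <= n_total:
        raise ValueError("need 0 <= n_found <= n_total")
    return round_half_up(100.0 * n_found / n_total)


def relative_increase(before: int, after: int) -> float:
    """Percent increase from ``before`` to ``after`` (e.g. the gain from
    family expansion), half-up to one decimal; NaN when before == 0."""
    if before == 0:
        return math.nan
    if after < before:
        raise ValueError("after must be >= before")
    return round_half_up(100.0 * (after - before) / before)


# ---------------------------------------------------------------------------
# patent -> compounds


@dataclass(frozen=True)
class CompoundPatentPair:
    """The atomic claim that a compound appears in a patent document."""

    compound_key: str
    patent_key: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.compound_key or not self.patent_key:
            raise ValueError("compound_key and patent_key must be non-empty")


@dataclass(frozen=True)
class PatentOverlap:
    patent_key: str
    n_reference: int
    n_matched: int
    percent: float
    unmatched: tuple[str, ...] = ()


@dataclass
class OverlapReport:
    """Per-patent and aggregate patent->compounds coverage."""

    per_patent: list[PatentOverlap]
    total_reference: int
    total_matched: int
    percent: float
    bins: "pd.Series" = field(repr=False, default=None)

    @property
    def per_patent_percents(self) -> list[float]:
        return [p.percent for p in self.per_patent]

    def mean_per_patent_percent(self) -> float:
        """Unweighted mean of per-patent percentages (secondary statistic;
        the headline number pools compounds across patents)."""
        return round_half_up(
            sum(self.per_patent_percents) / len(self.per_patent)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patent_key": p.patent_key,
                    "n_reference": p.n_reference,
                    "n_matched": p.n_matched,
                    "percent": p.percent,
                    "unmatched_keys": ";".join(p.unmatched),
                }
                for p in self.per_patent
            ]
        )


def patent_to_compound_overlap(
    reference: Mapping[str, Iterable[str]],
    test: Mapping[str, Iterable[str]],
    *,
    bin_edges: Sequence[float] = DECILE_EDGES,
) -> OverlapReport:
    """Per-patent intersection of reference and test compound-key sets.

    Both sides must be keyed with the same key mode.  A patent present in
    the reference but absent from the test source counts with zero matched.
    The aggregate pools compounds over all patents.
    """
    per_patent: list[PatentOverlap] = []
    total_ref = total_matched = 0
    for patent_key in sorted(reference):
        ref_keys = set(reference[patent_key])
        test_keys = set(test.get(patent_key, ()))
        matched = ref_keys & test_keys
        per_patent.append(
            PatentOverlap(
                patent_key=patent_key,
                n_reference=len(ref_keys),
                n_matched=len(matched),
                percent=coverage_percent(len(matched), len(ref_keys)),
                unmatched=tuple(sorted(ref_keys - test_keys)),
            )
        )
        total_ref += len(ref_keys)
        total_matched += len(matched)
    report = OverlapReport(
        per_patent=per_patent,
        total_reference=total_ref,
        total_matched=total_matched,
        percent=coverage_percent(total_matched, total_ref),
    )
    report.bins = bin_distribution(
        [p for p in report.per_patent_percents if not math.isnan(p)],
        edges=bin_edges,
    )
    return report


def bin_distribution(
    percents: Iterable[float], edges: Sequence[float] = DECILE_EDGES
) -> pd.Series:
    """Histogram of per-patent percentages over half-open bins [lo, hi),
    last bin closed; counts sum to the number of patents."""
    edges = list(edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("edges must be strictly increasing")
    labels = [
        f"[{edges[i]:g},{edges[i+1]:g}{']' if i == len(edges) - 2 else ')'}"
        for i in range(len(edges) - 1)
    ]
    counts = dict.fromkeys(labels, 0)
    for p in percents:
        if not edges[0] <= p <= edges[-1]:
            raise ValueError(f"percent {p} outside bin range")
        for i in range(len(edges) - 1):
            if p < edges[i + 1] or i == len(edges) - 2:
                counts[labels[i]] += 1
                break
    return pd.Series(counts, name="n_patents")


@dataclass(frozen=True)
class SourceAttribution:
    """Partition of a reference compound set by which mined source found
    each member; only_a + only_b + both + neither == total."""

    only_a: int
    only_b: int
    both: int
    neither: int

    @property
    def total(self) -> int:
        return self.only_a + self.only_b + self.both + self.neither

    @property
    def found_a(self) -> int:
        return self.only_a + self.both

    @property
    def found_b(self) -> int:
        return self.only_b + self.both

    @property
    def found_any(self) -> int:
        return self.only_a + self.only_b + self.both

    def percent_a(self) -> float:
        return coverage_percent(self.found_a, self.total)

    def percent_b(self) -> float:
        return coverage_percent(self.found_b, self.total)


def three_way_attribution(
    reference: Iterable[str], db_a: Iterable[str], db_b: Iterable[str]
) -> SourceAttribution:
    """Partition reference keys into found-only-in-A / only-in-B / both /
    neither."""
    ref, a, b = set(reference), set(db_a), set(db_b)
    return SourceAttribution(
        only_a=len(ref & a - b),
        only_b=len(ref & b - a),
        both=len(ref & a & b),
        neither=len(ref - a - b),
    )


# ---------------------------------------------------------------------------
# compound -> patents (pair matching)


class FamilyTable:
    """Patent family membership, symmetric-transitively closed.

    Built from (patent_key, family_member_key) rows; members outside the
    retained authorities are dropped.  ``members(k)`` always contains ``k``
    itself.
    """

    def __init__(
        self,
        rows: Iterable[tuple[str, str]],
        authorities: Iterable[str] = ("EP", "US", "WO"),
    ) -> None:
        self.authorities = frozenset(authorities)
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_dropped = 0
        for a, b in rows:
            if a[:2] not in self.authorities or b[:2] not in self.authorities:
                n_dropped += 1
                continue
            parent[find(a)] = find(b)
        if n_dropped:
            warnings.warn(
                f"family table: {n_dropped} rows outside retained authorities "
                f"{sorted(self.authorities)} ignored",
                stacklevel=2,
            )
        self._groups: dict[str, frozenset[str]] = {}
        by_root: dict[str, set[str]] = defaultdict(set)
        for k in parent:
            by_root[find(k)].add(k)
        for group in by_root.values():
            fg = frozenset(group)
            for k in group:
                self._groups[k] = fg

    def members(self, patent_key: str) -> frozenset[str]:
        return self._groups.get(patent_key, frozenset({patent_key}))


@dataclass(frozen=True)
class PairMatch:
    """Outcome for one reference pair against one test source."""

    compound_key: str
    patent_key: str
    source_tag: str
    matched: bool
    match_route: str = ""  # direct | family | ""
    reason: str = ""  # compound_absent | patent_absent | pair_absent | ""


@dataclass
class PairMatchResult:
    """Pair-matching outcome across one or more test sources."""

    sources: list[str]
    matches: list[PairMatch]  # len == n_pairs * n_sources
    family_enabled: bool = False

    @property
    def reference_pairs(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for m in self.matches:
            seen.setdefault((m.compound_key, m.patent_key))
        return list(seen)

    def matched_pairs(self, source: str) -> set[tuple[str, str]]:
        return {
            (m.compound_key, m.patent_key)
            for m in self.matches
            if m.source_tag == source and m.matched
        }

    def n_found_any(self) -> int:
        found: set[tuple[str, str]] = set()
        for s in self.sources:
            found |= self.matched_pairs(s)
        return len(found)

    def n_found(self, source: str) -> int:
        return len(self.matched_pairs(source))

    def percent_found_any(self) -> float:
        return coverage_percent(self.n_found_any(), len(self.reference_pairs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound_key": m.compound_key,
                    "patent_key": m.patent_key,
                    "source": m.source_tag,
                    "matched": m.matched,
                    "match_route": m.match_route,
                    "reason": m.reason,
                }
                for m in self.matches
            ]
        )


def _dedupe(pairs: Iterable[CompoundPatentPair]) -> list[CompoundPatentPair]:
    seen: dict[tuple[str, str], CompoundPatentPair] = {}
    for p in pairs:
        seen.setdefault((p.compound_key, p.patent_key), p)
    return list(seen.values())


def match_pairs(
    reference_pairs: Iterable[CompoundPatentPair],
    test_pairs: Mapping[str, Iterable[CompoundPatentPair]]
    | Iterable[CompoundPatentPair],
    family: FamilyTable | None = None,
    family_authorities: Iterable[str] = ("EP", "US", "WO"),
) -> PairMatchResult:
    """Match unique reference (compound, patent) pairs against test sources.

    A pair matches directly when the test source holds the identical pair,
    and — with a family table — when it holds the compound under any
    retained family member of the patent.  A reference compound matched in
    several family members counts once.  Unmatched reasons are assigned in
    priority order: compound absent from the source entirely, then patent
    absent, then pair absent.
    """
    if not isinstance(test_pairs, Mapping):
        test_pairs = {"test": test_pairs}
    if family is not None and not isinstance(family, FamilyTable):
        family = FamilyTable(family, authorities=family_authorities)
    reference = _dedupe(reference_pairs)
    sources = list(test_pairs)
    matches: list[PairMatch] = []
    for source in sources:
        pairs = {
            (p.compound_key, p.patent_key) for p in _dedupe(test_pairs[source])
        }
        compounds = {c for c, _ in pairs}
        patents = {p for _, p in pairs}
        for ref in reference:
            route = reason = ""
            matched = (ref.compound_key, ref.patent_key) in pairs
            if matched:
                route = "direct"
            elif family is not None:
                for member in family.members(ref.patent_key):
                    if member != ref.patent_key and (ref.compound_key, member) in pairs:
                        matched, route = True, "family"
                        break
            if not matched:
                if ref.compound_key not in compounds:
                    reason = "compound_absent"
                elif ref.patent_key not in patents:
                    reason = "patent_absent"
                else:
                    reason = "pair_absent"
            matches.append(
                PairMatch(
                    compound_key=ref.compound_key,
                    patent_key=ref.patent_key,
                    source_tag=source,
                    matched=matched,
                    match_route=route,
                    reason=reason,
                )
            )
    return PairMatchResult(
        sources=sources, matches=matches, family_enabled=family is not None
    )


def per_authority_breakdown(result: PairMatchResult) -> pd.DataFrame:
    """Table of pair-matching outcomes per patent authority plus an All row.

    Columns: total, not_found, found, percent_found, and — when the result
    covers two sources — only_<a>, only_<b>, both.  The All row equals the
    column sums of the authority rows.
    """
    pairs = result.reference_pairs
    by_auth: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for c, p in pairs:
        by_auth[p[:2]].append((c, p))
    matched = {s: result.matched_pairs(s) for s in result.sources}
    two = result.sources[:2] if len(result.sources) >= 2 else None

    def row(subset: list[tuple[str, str]]) -> dict:
        found = {pr for pr in subset if any(pr in matched[s] for s in result.sources)}
        r = {
            "total": len(subset),
            "not_found": len(subset) - len(found),
            "found": len(found),
            "percent_found": coverage_percent(len(found), len(subset)),
        }
        if two:
            a, b = two
            r[f"only_{a}"] = len([p for p in subset if p in matched[a] and p not in matched[b]])
            r[f"only_{b}"] = len([p for p in subset if p in matched[b] and p not in matched[a]])
            r["both"] = len([p for p in subset if p in matched[a] and p in matched[b]])
        return r

    rows = {auth: row(subset) for auth, subset in sorted(by_auth.items())}
    rows["All"] = row(pairs)
    return pd.DataFrame.from_dict(rows, orient="index")
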