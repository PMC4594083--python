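"""Tabular interchange formats: pair tables, family tables, corpus counts.

All tables are plain CSV.  Pair tables carry raw patent numbers plus an
optional publication year and source label; reading one normalizes every
patent number to its comparison key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .matching import CompoundPatentPair
from .patents import PatentId, comparison_key, parse_patent_number

__all__ = [
    "read_pair_table",
    "write_pair_table",
    "read_family_table",
    "write_family_table",
    "read_corpus_counts",
    "write_corpus_counts",
]


def read_pair_table(
    path: str | Path, *, default_source: str = ""
) -> tuple[list[CompoundPatentPair], dict[str, PatentId]]:
    """Read a pair CSV (compound_key, patent_raw[, year][, source]).

    Returns the pairs with patent numbers normalized to comparison keys,
    plus a map from comparison key to the parsed :class:`PatentId` (which
    retains year metadata for coverage checks).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"compound_key", "patent_raw"}
    if not required <= set(df.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    pairs: list[CompoundPatentPair] = []
    ids: dict[str, PatentId] = {}
    for row in df.itertuples(index=False):
        year = getattr(row, "year", None)
        year_hint = int(year) if year is not None and not pd.isna(year) else None
        pid = parse_patent_number(row.patent_raw, year_hint=year_hint)
        key = comparison_key(pid)
        ids.setdefault(key, pid)
        source = getattr(row, "source", None)
        pairs.append(
            CompoundPatentPair(
                compound_key=row.compound_key,
                patent_key=key,
                source_tag=(
                    source
                    if source is not None and not pd.isna(source)
                    else default_source
                ),
            )
        )
    return pairs, ids


def write_pair_table(
    pairs: Iterable[CompoundPatentPair],
    path: str | Path,
    *,
    years: Mapping[str, int] | None = None,
) -> None:
    rows = [
        {
            "compound_key": p.compound_key,
            "patent_raw": p.patent_key,
            "year": (years or {}).get(p.patent_key, ""),
            "source": p.source_tag,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=["compound_key", "patent_raw", "year", "source"]).to_csv(
        path, index=False
    )


def read_family_table(path: str | Path) -> list[tuple[str, str]]:
    """Read family CSV rows (patent_key, family_member_key)."""
    df = pd.read_csv(path, dtype=str)
    required = {"patent_key", "family_member_key"}
    if not required <= set(df.columns):
        raise ValueError(f"family table needs columns {sorted(required)}")
    return [
        (row.patent_key, row.family_member_key) for row in df.itertuples(index=False)
    ]


def write_family_table(rows: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["patent_key", "family_member_key"]).to_csv(
        path, index=False
    )


def read_corpus_counts(path: str | Path) -> dict[str, int]:
    """Read corpus-count CSV (compound_key, corpus_count)."""
    df = pd.read_csv(path, dtype={"compound_key": str, "corpus_count": int})
    required = {"compound_key", "corpus_count"}
    if not required <= set(df.columns):
        raise ValueError(f"corpus-count table needs columns {sorted(required)}")
    return dict(zip(df["compound_key"], df["corpus_count"]))


def write_corpus_counts(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(counts.items()), columns=["compound_key", "corpus_count"]
    ).to_csv(path, index=False)
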