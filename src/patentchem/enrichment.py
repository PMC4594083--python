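"""Corpus-count filtering and enrichment statistics.

A mined patent-chemistry source attributes far more compounds to a patent
than a curated one — reagents, solvents, intermediates and marketed drugs
drown out the claimed chemistry.  The *chemical corpus count* (how often a
structure occurs across the whole patent corpus) separates the two
regimes: patent-specific compounds are rare corpus-wide, while noise
compounds recur everywhere.  Filtering at corpus count <= 30 keeps most
relevant compounds while discarding most noise; the enrichment factor
quantifies the gain.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .standardize import StandardizedCompound

__all__ = [
    "DEFAULT_CORPUS_THRESHOLD",
    "DEFAULT_CORPUS_BIN_EDGES",
    "apply_corpus_filter",
    "enrichment_factor",
    "bin_corpus_counts",
    "property_filters",
]

DEFAULT_CORPUS_THRESHOLD = 30

#: Eight corpus-count ranges spanning the relevant (<=30) and noise regimes.
DEFAULT_CORPUS_BIN_EDGES: tuple[int, ...] = (1, 6, 11, 21, 31, 101, 1001, 10001)


def _pass_fraction(
    keys: Iterable[str], counts: Mapping[str, int], threshold: int
) -> tuple[int, int]:
    """(n passing, n with a count) under corpus_count <= threshold."""
    n_pass = n_known = 0
    for k in keys:
        c = counts.get(k)
        if c is None:
            continue
        n_known += 1
        if c <= threshold:
            n_pass += 1
    return n_pass, n_known


def apply_corpus_filter(
    compound_keys: Iterable[str],
    counts: Mapping[str, int],
    threshold: int = DEFAULT_CORPUS_THRESHOLD,
    *,
    missing: str = "keep",
) -> list[str]:
    """Keep compounds whose corpus count is <= ``threshold`` (inclusive).

    ``missing`` decides the fate of compounds with no count: ``keep``
    (default, warn — unobserved is not infinite), ``drop``, or ``error``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if missing not in {"keep", "drop", "error"}:
        raise ValueError(f"unknown missing-count policy {missing!r}")
    kept: list[str] = []
    n_missing = 0
    for k in compound_keys:
        c = counts.get(k)
        if c is None:
            n_missing += 1
            if missing == "error":
                raise KeyError(f"no corpus count for {k!r}")
            if missing == "keep":
                kept.append(k)
            continue
        if c <= threshold:
            kept.append(k)
    if n_missing and missing == "keep":
        warnings.warn(
            f"{n_missing} compounds had no corpus count; kept", stacklevel=2
        )
    return kept


def enrichment_factor(
    relevant: Iterable[str],
    background: Iterable[str],
    counts: Mapping[str, int],
    threshold: int = DEFAULT_CORPUS_THRESHOLD,
) -> float:
    """Ratio of pass fractions: relevant vs background at the threshold.

    A factor of ~5 means the corpus-count filter concentrates the
    compounds of interest five-fold relative to everything the mined
    source returned.  NaN when the background pass fraction is zero.
    Fractions are computed over unique compounds with known counts.
    """
    rel_pass, rel_n = _pass_fraction(set(relevant), counts, threshold)
    bg_pass, bg_n = _pass_fraction(set(background), counts, threshold)
    if rel_n == 0 or bg_n == 0 or bg_pass == 0:
        return math.nan
    return (rel_pass / rel_n) / (bg_pass / bg_n)


def bin_corpus_counts(
    compound_keys: Iterable[str],
    counts: Mapping[str, int],
    edges: Sequence[int] = DEFAULT_CORPUS_BIN_EDGES,
) -> pd.Series:
    """Histogram of corpus counts over the configured ranges.

    ``edges`` are lower bounds of consecutive ranges; the last range is
    open-ended.  Compounds without a count are reported under ``unknown``.
    Counts sum to the number of compounds.
    """
    edges = list(edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("edges must be strictly increasing")
    labels = [
        f"{edges[i]}-{edges[i + 1] - 1}" for i in range(len(edges) - 1)
    ] + [f">={edges[-1]}"]
    out = dict.fromkeys(labels, 0)
    out["unknown"] = 0
    for k in compound_keys:
        c = counts.get(k)
        if c is None:
            out["unknown"] += 1
            continue
        if c < edges[0]:
            raise ValueError(f"corpus count {c} below first edge {edges[0]}")
        idx = len(edges) - 1
        for i in range(len(edges) - 1):
            if c < edges[i + 1]:
                idx = i
                break
        out[labels[idx]] += 1
    if out["unknown"] == 0:
        del out["unknown"]
    return pd.Series(out, name="n_compounds")


_FILTER_FIELDS = {
    "min_ring_count",
    "max_ring_count",
    "min_mol_weight",
    "max_mol_weight",
    "min_logp",
    "max_logp",
    "exclude_radicals",
}


def property_filters(
    compounds: Iterable[StandardizedCompound], spec: Mapping[str, object]
) -> list[StandardizedCompound]:
    """Conjunctive descriptor filters (ring count, MW, logP, radical flag).

    Ring count, logP and the radical flag are computed from the retained
    fragment with RDKit; every clause is optional and an empty spec is the
    identity.
    """
    unknown = set(spec) - _FILTER_FIELDS
    if unknown:
        raise ValueError(f"unknown filter fields: {sorted(unknown)}")
    from rdkit import Chem
    from rdkit.Chem import Crippen, rdMolDescriptors

    kept: list[StandardizedCompound] = []
    for c in compounds:
        if "min_mol_weight" in spec and c.mol_weight < float(spec["min_mol_weight"]):
            continue
        if "max_mol_weight" in spec and c.mol_weight >= float(spec["max_mol_weight"]):
            continue
        needs_mol = bool(
            {"min_ring_count", "max_ring_count", "min_logp", "max_logp",
             "exclude_radicals"} & set(spec)
        )
        if needs_mol:
            mol = Chem.MolFromSmiles(c.key_smiles)
            if mol is None:  # pragma: no cover - keys are canonical
                continue
            nrings = rdMolDescriptors.CalcNumRings(mol)
            if "min_ring_count" in spec and nrings < int(spec["min_ring_count"]):
                continue
            if "max_ring_count" in spec and nrings > int(spec["max_ring_count"]):
                continue
            if "min_logp" in spec or "max_logp" in spec:
                logp = Crippen.MolLogP(mol)
                if "min_logp" in spec and logp < float(spec["min_logp"]):
                    continue
                if "max_logp" in spec and logp > float(spec["max_logp"]):
                    continue
            if spec.get("exclude_radicals") and any(
                a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()
            ):
                continue
        kept.append(c)
    return kept
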