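"""End-to-end workflows tying the pipeline stages together.

Use case 1 (patent -> compounds): standardize a gold SDF and one or more
mined SMILES-TSV extracts, compute per-patent overlap, the coverage
histogram and — with two sources — the three-way attribution.

Use case 2 (compound -> patents): take a reference pair table, apply the
coverage-window exclusion, match pairs against the mined sources with
optional family expansion, and break results down by authority, by
per-compound patent count and by component count.

Both runs are fully determined by their configuration; when an output
directory is given, machine-readable artifacts plus a run manifest
(config, package version, seed) are written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .enrichment import (
    DEFAULT_CORPUS_THRESHOLD,
    bin_corpus_counts,
    enrichment_factor,
)
from .io import read_family_table, read_pair_table
from .matching import (
    CompoundPatentPair,
    FamilyTable,
    OverlapReport,
    PairMatchResult,
    SourceAttribution,
    coverage_percent,
    match_pairs,
    patent_to_compound_overlap,
    per_authority_breakdown,
    three_way_attribution,
)
from .patents import (
    COVERAGE_PRESETS,
    SourceCoverage,
    comparison_key,
    in_coverage,
    parse_patent_number,
)
from .standardize import (
    KEY_MODES,
    Reject,
    StandardizeOptions,
    StandardizedCompound,
    read_structures,
    standardize_all,
    write_rejects,
)

__all__ = [
    "RunConfig",
    "UseCase1Result",
    "UseCase2Result",
    "load_source",
    "run_use_case_1",
    "run_use_case_2",
    "run_enrichment",
    "emit_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the workflow runners."""

    key_mode: str = "inchi_strict"
    normalize_nitro: bool = False
    family: bool = False
    corpus_threshold: int = DEFAULT_CORPUS_THRESHOLD
    family_authorities: tuple[str, ...] = ("EP", "US", "WO")
    coverage: str | None = None  # preset name or "name:YYYY-YYYY"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.key_mode not in KEY_MODES:
            raise ValueError(f"key_mode must be one of {KEY_MODES}")


def parse_coverage_spec(spec: str) -> SourceCoverage:
    """``both:1976-2010`` / ``surechembl:1976-`` / bare preset name."""
    name, _, window = spec.partition(":")
    base = COVERAGE_PRESETS.get(name.lower())
    if base is None:
        raise ValueError(f"unknown coverage preset {name!r}")
    if not window:
        return base
    lo, _, hi = window.partition("-")
    return SourceCoverage(
        authorities=base.authorities,
        year_min=int(lo),
        year_max=int(hi) if hi else None,
        image_year_min=base.image_year_min,
    )


# ---------------------------------------------------------------------------
# source loading


@dataclass
class LoadedSource:
    source_tag: str
    compounds: list[StandardizedCompound]
    rejects: list[Reject]

    def per_patent_keys(self, key_mode: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for c in self.compounds:
            if not c.patent_ref:
                continue
            pkey = comparison_key(parse_patent_number(c.patent_ref))
            out.setdefault(pkey, set()).add(c.key(key_mode))
        return out

    def pairs(self, key_mode: str) -> list[CompoundPatentPair]:
        return [
            CompoundPatentPair(
                c.key(key_mode),
                comparison_key(parse_patent_number(c.patent_ref)),
                self.source_tag,
            )
            for c in self.compounds
            if c.patent_ref
        ]

    def corpus_counts(self, key_mode: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.compounds:
            raw = c.annotations.get("corpus_count")
            if raw is not None:
                out.setdefault(c.key(key_mode), int(raw))
        return out


def load_source(
    path: str | Path,
    format: str,
    *,
    source_tag: str = "",
    config: RunConfig = RunConfig(),
    patent_field: str = "PATENT_ID",
) -> LoadedSource:
    """Read and standardize one structure file into a queryable source."""
    tag = source_tag or Path(path).stem
    read = read_structures(path, format, patent_field=patent_field, source_tag=tag)
    opts = StandardizeOptions(
        strip_stereo=config.key_mode.endswith("nostereo"),
        normalize_nitro=config.normalize_nitro,
    )
    compounds, std_rejects = standardize_all(read.records, opts)
    return LoadedSource(tag, compounds, read.rejects + std_rejects)


# ---------------------------------------------------------------------------
# use case 1: patent -> compounds


@dataclass
class UseCase1Result:
    key_mode: str
    overlaps: dict[str, OverlapReport]
    attribution: SourceAttribution | None = None
    attribution_per_patent: pd.DataFrame | None = None
    rejects: dict[str, list[Reject]] = field(default_factory=dict)

    def summary(self) -> dict:
        s: dict = {"key_mode": self.key_mode, "sources": {}}
        for tag, rep in self.overlaps.items():
            s["sources"][tag] = {
                "total_reference": rep.total_reference,
                "total_matched": rep.total_matched,
                "percent": rep.percent,
                "n_patents": len(rep.per_patent),
                "bins": rep.bins.to_dict(),
            }
        if self.attribution is not None:
            a = self.attribution
            s["attribution"] = {
                "only_a": a.only_a,
                "only_b": a.only_b,
                "both": a.both,
                "neither": a.neither,
                "percent_a": a.percent_a(),
                "percent_b": a.percent_b(),
            }
        return s


def run_use_case_1(
    reference_sdf: str | Path,
    test_sources: Mapping[str, str | Path],
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
    *,
    patent_field: str = "PATENT_ID",
) -> UseCase1Result:
    """Patent->compounds overlap of a gold SDF against mined TSV extracts.

    ``test_sources`` maps source tag to SMILES-TSV path; with exactly two
    sources the three-way attribution is computed as well.  All sources
    are keyed under ``config.key_mode``.
    """
    reference = load_source(
        reference_sdf, "sdf", source_tag="reference", config=config,
        patent_field=patent_field,
    )
    ref_sets = reference.per_patent_keys(config.key_mode)
    result = UseCase1Result(key_mode=config.key_mode, overlaps={})
    result.rejects["reference"] = reference.rejects
    test_sets: dict[str, dict[str, set[str]]] = {}
    for tag, path in test_sources.items():
        src = load_source(path, "smiles_tsv", source_tag=tag, config=config)
        test_sets[tag] = src.per_patent_keys(config.key_mode)
        result.overlaps[tag] = patent_to_compound_overlap(ref_sets, test_sets[tag])
        result.rejects[tag] = src.rejects

    if len(test_sets) == 2:
        (tag_a, sets_a), (tag_b, sets_b) = test_sets.items()
        rows = []
        agg = dict.fromkeys(("only_a", "only_b", "both", "neither"), 0)
        for pkey, ref_keys in sorted(ref_sets.items()):
            part = three_way_attribution(
                ref_keys, sets_a.get(pkey, ()), sets_b.get(pkey, ())
            )
            rows.append(
                {
                    "patent_key": pkey,
                    f"only_{tag_a}": part.only_a,
                    f"only_{tag_b}": part.only_b,
                    "both": part.both,
                    "neither": part.neither,
                }
            )
            agg["only_a"] += part.only_a
            agg["only_b"] += part.only_b
            agg["both"] += part.both
            agg["neither"] += part.neither
        result.attribution = SourceAttribution(**agg)
        result.attribution_per_patent = pd.DataFrame(rows)

    if out_dir is not None:
        emit_report(result, out_dir, config)
    return result


# ---------------------------------------------------------------------------
# use case 2: compound -> patents


@dataclass
class UseCase2Result:
    config: RunConfig
    direct: PairMatchResult
    with_family: PairMatchResult | None
    breakdown: pd.DataFrame
    excluded_out_of_coverage: list[tuple[str, str]]
    by_patent_count: pd.DataFrame | None = None
    by_components: pd.DataFrame | None = None

    def summary(self) -> dict:
        n_ref = len(self.direct.reference_pairs)
        s: dict = {
            "n_reference_pairs": n_ref,
            "n_excluded_out_of_coverage": len(self.excluded_out_of_coverage),
            "percent_found_any": self.direct.percent_found_any(),
            "per_source": {
                tag: {
                    "found": self.direct.n_found(tag),
                    "percent": coverage_percent(self.direct.n_found(tag), n_ref),
                }
                for tag in self.direct.sources
            },
        }
        if self.with_family is not None:
            s["per_source_family"] = {
                tag: {
                    "found": self.with_family.n_found(tag),
                    "percent": coverage_percent(self.with_family.n_found(tag), n_ref),
                }
                for tag in self.with_family.sources
            }
        return s


def _found_fraction_by(
    pairs: Sequence[CompoundPatentPair],
    found: set[tuple[str, str]],
    group_of: Mapping[str, object],
    label: str,
) -> pd.DataFrame:
    """Found/not-found compounds grouped by a per-compound attribute."""
    by_compound: dict[str, bool] = {}
    for p in pairs:
        by_compound[p.compound_key] = by_compound.get(p.compound_key, False) or (
            (p.compound_key, p.patent_key) in found
        )
    rows: dict[object, list[int]] = {}
    for ck, was_found in by_compound.items():
        g = group_of.get(ck)
        if g is None:
            continue
        rows.setdefault(g, [0, 0])[0 if was_found else 1] += 1
    return pd.DataFrame(
        [
            {
                label: g,
                "found": f,
                "not_found": nf,
                "percent_found": coverage_percent(f, f + nf),
            }
            for g, (f, nf) in sorted(rows.items(), key=lambda kv: str(kv[0]))
        ]
    )


def run_use_case_2(
    reference_pairs_csv: str | Path,
    test_sources: Mapping[str, str | Path],
    config: RunConfig = RunConfig(),
    family_csv: str | Path | None = None,
    out_dir: str | Path | None = None,
    *,
    compound_components: Mapping[str, int] | None = None,
) -> UseCase2Result:
    """Compound->patents pair matching against mined sources.

    Reference pairs whose patent falls outside the configured coverage
    window are excluded from the denominator (and logged).  With
    ``config.family`` a family CSV is required and matching is repeated
    with family expansion; direct results are always reported so the gain
    is visible.
    """
    if config.family and family_csv is None:
        raise ValueError("family expansion requested but no family table given")
    ref_pairs, patent_ids = read_pair_table(reference_pairs_csv, default_source="reference")

    excluded: list[tuple[str, str]] = []
    if config.coverage is not None:
        cov = parse_coverage_spec(config.coverage)
        kept = []
        for p in ref_pairs:
            if in_coverage(patent_ids[p.patent_key], cov):
                kept.append(p)
            else:
                excluded.append((p.compound_key, p.patent_key))
        ref_pairs = kept

    test_pairs: dict[str, list[CompoundPatentPair]] = {}
    for tag, path in test_sources.items():
        src = load_source(path, "smiles_tsv", source_tag=tag, config=config)
        test_pairs[tag] = src.pairs(config.key_mode)

    direct = match_pairs(ref_pairs, test_pairs, family=None)
    with_family = None
    if config.family:
        family = FamilyTable(
            read_family_table(family_csv), authorities=config.family_authorities
        )
        with_family = match_pairs(
            ref_pairs, test_pairs, family=family,
            family_authorities=config.family_authorities,
        )
    best = with_family if with_family is not None else direct
    breakdown = per_authority_breakdown(best)

    found_any: set[tuple[str, str]] = set()
    for s in best.sources:
        found_any |= best.matched_pairs(s)
    n_patents_of: dict[str, int] = {}
    for p in ref_pairs:
        n_patents_of[p.compound_key] = n_patents_of.get(p.compound_key, 0) + 1
    by_patent_count = _found_fraction_by(
        ref_pairs, found_any,
        {k: (v if v <= 5 else ">5") for k, v in n_patents_of.items()},
        "n_patents",
    )
    by_components = None
    if compound_components is not None:
        by_components = _found_fraction_by(
            ref_pairs, found_any, compound_components, "n_components"
        )

    result = UseCase2Result(
        config=config,
        direct=direct,
        with_family=with_family,
        breakdown=breakdown,
        excluded_out_of_coverage=excluded,
        by_patent_count=by_patent_count,
        by_components=by_components,
    )
    if out_dir is not None:
        emit_report(result, out_dir, config)
    return result


# ---------------------------------------------------------------------------
# enrichment workflow


def run_enrichment(
    relevant_keys: Sequence[str],
    background_keys: Sequence[str],
    counts: Mapping[str, int],
    config: RunConfig = RunConfig(),
) -> dict:
    """Corpus-count filter statistics for a relevant set against the full
    mined background."""
    factor = enrichment_factor(
        relevant_keys, background_keys, counts, config.corpus_threshold
    )
    return {
        "threshold": config.corpus_threshold,
        "enrichment_factor": factor,
        "relevant_histogram": bin_corpus_counts(set(relevant_keys), counts).to_dict(),
        "background_histogram": bin_corpus_counts(set(background_keys), counts).to_dict(),
    }


# ---------------------------------------------------------------------------
# reporting


def _json_default(obj):
    import math

    if isinstance(obj, float) and math.isnan(obj):  # pragma: no cover
        return None
    raise TypeError(f"not JSON serializable: {obj!r}")


def emit_report(
    result: UseCase1Result | UseCase2Result,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
) -> dict[str, Path]:
    """Write machine-readable artifacts plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = result.summary()
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=_json_default))
    paths["summary"] = spath

    if isinstance(result, UseCase1Result):
        for tag, rep in result.overlaps.items():
            p = out / f"overlap_{tag}.csv"
            rep.to_frame().to_csv(p, index=False)
            paths[f"overlap_{tag}"] = p
            b = out / f"bins_{tag}.csv"
            rep.bins.rename_axis("bin").to_csv(b)
            paths[f"bins_{tag}"] = b
        if result.attribution_per_patent is not None:
            p = out / "attribution_per_patent.csv"
            result.attribution_per_patent.to_csv(p, index=False)
            paths["attribution_per_patent"] = p
        for tag, rejects in result.rejects.items():
            if rejects:
                p = out / f"rejects_{tag}.csv"
                write_rejects(rejects, p)
                paths[f"rejects_{tag}"] = p
    else:
        p = out / "pair_matches.csv"
        (result.with_family or result.direct).to_frame().to_csv(p, index=False)
        paths["pair_matches"] = p
        b = out / "authority_breakdown.csv"
        result.breakdown.rename_axis("authority").to_csv(b)
        paths["authority_breakdown"] = b
        for name, df in (
            ("by_patent_count", result.by_patent_count),
            ("by_components", result.by_components),
        ):
            if df is not None and len(df):
                fp = out / f"{name}.csv"
                df.to_csv(fp, index=False)
                paths[name] = fp
        if result.excluded_out_of_coverage:
            fp = out / "excluded_pairs.csv"
            pd.DataFrame(
                result.excluded_out_of_coverage,
                columns=["compound_key", "patent_key"],
            ).to_csv(fp, index=False)
            paths["excluded_pairs"] = fp

    cfg = asdict(config)
    manifest = {
        "package": "patentchem",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mpath
    return paths
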