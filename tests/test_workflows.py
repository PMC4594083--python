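"""End-to-end workflow runs over the synthetic database fixtures."""

import json

import pytest

from patentchem.workflows import (
    RunConfig,
    load_source,
    parse_coverage_spec,
    run_enrichment,
    run_use_case_1,
    run_use_case_2,
)


def test_coverage_spec_parsing():
    cov = parse_coverage_spec("both:1976-2010")
    assert (cov.year_min, cov.year_max) == (1976, 2010)
    open_ended = parse_coverage_spec("surechembl:1976-")
    assert open_ended.year_max is None
    with pytest.raises(ValueError):
        parse_coverage_spec("nosuchdb:1976-")


def test_use_case_1_recovers_planted_coverage(fixture_dir, small_sources):
    """The pipeline's per-source coverage equals the truth log exactly for
    both InChI key modes — the central planted-recovery property."""
    for key_mode in ("inchi_strict", "inchi_nostereo"):
        r1 = run_use_case_1(
            fixture_dir["gold_sdf"],
            {tag: fixture_dir[tag] for tag in small_sources},
            RunConfig(key_mode=key_mode),
        )
        for tag, (_, truth) in small_sources.items():
            expected = truth.expected_coverage(key_mode)
            rep = r1.overlaps[tag]
            assert (rep.total_matched, rep.total_reference) == expected


def test_use_case_1_attribution_conserves_reference(fixture_dir, small_sources):
    r1 = run_use_case_1(
        fixture_dir["gold_sdf"],
        {tag: fixture_dir[tag] for tag in small_sources},
        RunConfig(),
    )
    att = r1.attribution
    total_ref = sum(
        len(keys)
        for keys in load_source(fixture_dir["gold_sdf"], "sdf", config=RunConfig())
        .per_patent_keys("inchi_strict")
        .values()
    )
    assert att.total == total_ref


def test_stereo_mode_coverage_ordering(fixture_dir, small_sources):
    """Stereo-stripped keys can only match more: coverage(no-stereo) >=
    coverage(strict), strictly greater for the source with stereo loss."""
    strict = run_use_case_1(
        fixture_dir["gold_sdf"],
        {tag: fixture_dir[tag] for tag in small_sources},
        RunConfig(key_mode="inchi_strict"),
    )
    nostereo = run_use_case_1(
        fixture_dir["gold_sdf"],
        {tag: fixture_dir[tag] for tag in small_sources},
        RunConfig(key_mode="inchi_nostereo"),
    )
    for tag, (_, truth) in small_sources.items():
        assert nostereo.overlaps[tag].total_matched >= strict.overlaps[tag].total_matched
        if (truth.df.failure_mode == "stereo_loss").any():
            assert (
                nostereo.overlaps[tag].total_matched
                > strict.overlaps[tag].total_matched
            )


def test_use_case_2_direct_and_family_recovery(fixture_dir, small_sources):
    config = RunConfig(family=True)
    r2 = run_use_case_2(
        fixture_dir["gold_pairs"],
        {tag: fixture_dir[tag] for tag in small_sources},
        config,
        family_csv=fixture_dir["family"],
    )
    for tag, (_, truth) in small_sources.items():
        assert r2.direct.n_found(tag) == truth.expected_pair_matches()
        assert r2.with_family.n_found(tag) == truth.expected_pair_matches(family=True)
        # family monotonicity
        assert r2.with_family.n_found(tag) >= r2.direct.n_found(tag)


def test_use_case_2_requires_family_table():
    with pytest.raises(ValueError, match="family"):
        run_use_case_2("nonexistent.csv", {}, RunConfig(family=True))


def test_use_case_2_coverage_exclusion(fixture_dir, small_gold):
    """Patents outside the coverage window leave the denominator and are
    logged."""
    r_all = run_use_case_2(
        fixture_dir["gold_pairs"], {"src_a": fixture_dir["src_a"]}, RunConfig()
    )
    r_win = run_use_case_2(
        fixture_dir["gold_pairs"],
        {"src_a": fixture_dir["src_a"]},
        RunConfig(coverage="both:1976-2005"),
    )
    outside = {p.key for p in small_gold.patents if p.year > 2005}
    excluded_patents = {pk for _, pk in r_win.excluded_out_of_coverage}
    assert excluded_patents == outside
    assert len(r_win.direct.reference_pairs) == len(r_all.direct.reference_pairs) - len(
        r_win.excluded_out_of_coverage
    )


def test_reports_deterministic_and_round_trip(fixture_dir, small_sources, tmp_path):
    config = RunConfig()
    sources = {tag: fixture_dir[tag] for tag in small_sources}
    r1 = run_use_case_1(fixture_dir["gold_sdf"], sources, config, out_dir=tmp_path / "a")
    run_use_case_1(fixture_dir["gold_sdf"], sources, config, out_dir=tmp_path / "b")
    sa = (tmp_path / "a" / "summary.json").read_bytes()
    sb = (tmp_path / "b" / "summary.json").read_bytes()
    assert sa == sb
    assert json.loads(sa) == r1.summary()
    manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
    assert manifest["config"]["key_mode"] == "inchi_strict"
    assert "config_sha256" in manifest


def test_enrichment_workflow_on_synthetic(fixture_dir, small_gold, small_sources):
    """Planted relevant compounds are enriched by the corpus-count filter
    against the noisy mined background."""
    from patentchem.io import read_corpus_counts

    src = load_source(fixture_dir["src_a"], "smiles_tsv", config=RunConfig())
    counts = src.corpus_counts("inchi_strict")
    counts.update(read_corpus_counts(fixture_dir["corpus_counts"]))
    relevant = {c.key_strict for p in small_gold.patents for c in p.compounds}
    background = {c.key("inchi_strict") for c in src.compounds}
    stats = run_enrichment(sorted(relevant), sorted(background), counts, RunConfig())
    assert stats["enrichment_factor"] > 2.0
    assert stats["threshold"] == 30
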