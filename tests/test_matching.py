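"""Overlap, attribution and pair matching, checked against brute-force
oracles on small random instances."""

import math
import random

import pytest

from patentchem.matching import (
    CompoundPatentPair,
    FamilyTable,
    bin_distribution,
    coverage_percent,
    match_pairs,
    patent_to_compound_overlap,
    per_authority_breakdown,
    relative_increase,
    three_way_attribution,
)


@pytest.mark.parametrize(
    "found,total,expected",
    [
        (1588, 2692, 59.0),
        (1362, 2692, 50.6),
        (651, 873, 74.6),
        (1233, 1740, 70.9),
        (0, 5, 0.0),
        (1, 2000, 0.1),  # 0.05% rounds half-up to 0.1, not banker's 0.0
    ],
)
def test_coverage_percent(found, total, expected):
    assert coverage_percent(found, total) == expected


def test_coverage_percent_degenerate():
    assert math.isnan(coverage_percent(0, 0))
    with pytest.raises(ValueError):
        coverage_percent(5, 3)


@pytest.mark.parametrize(
    "before,after,expected",
    [(1072, 1156, 7.8), (1032, 1132, 9.7), (100, 100, 0.0)],
)
def test_relative_increase(before, after, expected):
    assert relative_increase(before, after) == expected


# ---------------------------------------------------------------------------
# patent -> compounds overlap


def test_overlap_trivial_cases():
    ref = {"US1": {"a", "b"}, "US2": {"c"}}
    full = patent_to_compound_overlap(ref, ref)
    assert full.percent == 100.0
    assert all(p.percent == 100.0 for p in full.per_patent)
    empty = patent_to_compound_overlap(ref, {})
    assert empty.percent == 0.0
    assert empty.total_reference == 3 and empty.total_matched == 0


def test_overlap_matches_brute_force_oracle():
    rng = random.Random(5)
    compounds = [f"k{i}" for i in range(40)]
    ref = {
        f"US{p}": set(rng.sample(compounds, rng.randint(1, 15))) for p in range(20)
    }
    test = {
        f"US{p}": set(rng.sample(compounds, rng.randint(0, 20)))
        for p in range(20)
        if rng.random() > 0.2
    }
    report = patent_to_compound_overlap(ref, test)
    # oracle: nested loop over every (patent, compound) combination
    total = matched = 0
    for pk, ref_keys in ref.items():
        n = sum(1 for c in ref_keys for t in test.get(pk, set()) if c == t)
        row = next(r for r in report.per_patent if r.patent_key == pk)
        assert row.n_matched == n and row.n_reference == len(ref_keys)
        total += len(ref_keys)
        matched += n
    assert (report.total_matched, report.total_reference) == (matched, total)
    assert report.percent == coverage_percent(matched, total)
    assert report.bins.sum() == len(ref)


def test_bin_distribution():
    assert bin_distribution([100.0] * 5).iloc[-1] == 5
    hand = [0.0, 5.0, 10.0, 15.0, 55.0, 59.9, 60.0, 99.9, 100.0, 100.0]
    bins = bin_distribution(hand)
    assert bins["[0,10)"] == 2
    assert bins["[10,20)"] == 2
    assert bins["[50,60)"] == 2
    assert bins["[60,70)"] == 1
    assert bins["[90,100]"] == 3
    assert bins.sum() == len(hand)
    with pytest.raises(ValueError):
        bin_distribution([50.0], edges=[0, 0, 100])


def test_planted_low_coverage_count():
    percents = [20.0] * 7 + [80.0] * 39  # 7 of 46 patents at <= 30%
    assert sum(1 for p in percents if p <= 30.0) == 7
    bins = bin_distribution(percents, edges=[0, 30, 100])
    assert bins["[0,30)"] == 7 and bins.sum() == 46


# ---------------------------------------------------------------------------
# three-way attribution


def test_attribution_printed_partition():
    """231 both + 13 only-B + 50 only-A of 438 gives 281 (64.2%) in A,
    244 (55.7%) in B, 294 in at least one."""
    ref = [f"c{i}" for i in range(438)]
    a = set(ref[:231] + ref[244:294])  # both + only_a
    b = set(ref[:244])  # both + only_b
    att = three_way_attribution(ref, a, b)
    assert (att.both, att.only_b, att.only_a) == (231, 13, 50)
    assert att.found_any == 294
    assert (att.found_a, att.found_b) == (281, 244)
    assert att.percent_a() == 64.2
    assert att.percent_b() == 55.7


def test_attribution_identical_sources():
    att = three_way_attribution({"x", "y"}, {"x"}, {"x"})
    assert att.only_a == att.only_b == 0
    assert att.both == 1 and att.neither == 1


def test_attribution_oracle_and_symmetry():
    rng = random.Random(9)
    universe = [f"c{i}" for i in range(60)]
    ref = set(rng.sample(universe, 40))
    a = set(rng.sample(universe, 25))
    b = set(rng.sample(universe, 30))
    att = three_way_attribution(ref, a, b)
    assert att.only_a == len({x for x in ref if x in a and x not in b})
    assert att.only_b == len({x for x in ref if x in b and x not in a})
    assert att.both == len(ref & a & b)
    assert att.neither == len(ref - a - b)
    assert att.total == len(ref)  # conservation
    swapped = three_way_attribution(ref, b, a)
    assert (swapped.only_a, swapped.only_b) == (att.only_b, att.only_a)
    assert (swapped.both, swapped.neither) == (att.both, att.neither)


# ---------------------------------------------------------------------------
# pair matching


def _pairs(tuples, tag=""):
    return [CompoundPatentPair(c, p, tag) for c, p in tuples]


def test_family_expansion_recovers_member_pair():
    ref = _pairs([("c1", "EP100"), ("c2", "EP100")])
    test = _pairs([("c1", "EP100"), ("c2", "WO200")])
    fam = FamilyTable([("EP100", "WO200")])
    off = match_pairs(ref, test)
    on = match_pairs(ref, test, family=fam)
    assert off.n_found("test") == 1
    assert on.n_found("test") == 2
    routes = {m.compound_key: m.match_route for m in on.matches if m.matched}
    assert routes == {"c1": "direct", "c2": "family"}


def test_empty_test_source_assigns_reasons():
    ref = _pairs([("c1", "EP100"), ("c2", "US200")])
    res = match_pairs(ref, [])
    assert res.n_found("test") == 0
    assert all(m.reason == "compound_absent" for m in res.matches)


def test_unmatched_reason_priority():
    ref = _pairs([("c1", "EP100"), ("c2", "EP100"), ("c3", "WO300")])
    test = _pairs([("c2", "US200"), ("x9", "EP100"), ("c3", "WO300x")])
    res = match_pairs(ref, test)
    reasons = {m.compound_key: m.reason for m in res.matches}
    assert reasons == {
        "c1": "compound_absent",  # c1 nowhere in the source
        "c2": "pair_absent",  # compound and patent known, pair missing
        "c3": "patent_absent",
    }


def test_duplicate_pairs_collapse():
    ref = _pairs([("c1", "EP100")] * 3)
    res = match_pairs(ref, _pairs([("c1", "EP100")] * 2))
    assert len(res.reference_pairs) == 1
    assert res.n_found("test") == 1


def test_family_outside_authorities_ignored_with_warning():
    ref = _pairs([("c1", "EP100")])
    test = _pairs([("c1", "JP900")])
    with pytest.warns(UserWarning, match="outside retained authorities"):
        fam = FamilyTable([("EP100", "JP900")])
    assert match_pairs(ref, test, family=fam).n_found("test") == 0


def _brute_force_pair_match(ref, test, families):
    """Oracle: double loop with explicit family closure."""
    test_set = {(p.compound_key, p.patent_key) for p in test}
    found = set()
    for r in ref:
        group = families.get(r.patent_key, {r.patent_key})
        for member in group:
            if (r.compound_key, member) in test_set:
                found.add((r.compound_key, r.patent_key))
                break
    return found


def test_match_pairs_against_brute_force_oracle():
    rng = random.Random(17)
    auths = ["EP", "US", "WO"]
    patents = [f"{rng.choice(auths)}{1000 + i}" for i in range(40)]
    compounds = [f"c{i}" for i in range(50)]
    ref = _pairs(
        {(rng.choice(compounds), rng.choice(patents)) for _ in range(200)}
    )
    test = _pairs(
        {(rng.choice(compounds), rng.choice(patents)) for _ in range(150)}
    )
    fam_rows = [(patents[i], patents[i + 1]) for i in range(0, 30, 2)]
    fam = FamilyTable(fam_rows)
    closure = {}
    for a, b in fam_rows:
        group = closure.get(a, {a}) | closure.get(b, {b})
        for k in group:
            closure[k] = group
    res = match_pairs(ref, test, family=fam)
    assert res.matched_pairs("test") == _brute_force_pair_match(ref, test, closure)
    # monotonicity: family expansion never loses matches
    res_off = match_pairs(ref, test)
    assert res_off.matched_pairs("test") <= res.matched_pairs("test")


def test_per_authority_breakdown_sums():
    rng = random.Random(3)
    patents = [f"{a}{n}" for a in ("EP", "US", "WO") for n in range(100, 110)]
    compounds = [f"c{i}" for i in range(20)]
    ref = _pairs({(rng.choice(compounds), rng.choice(patents)) for _ in range(80)})
    test_a = _pairs({(rng.choice(compounds), rng.choice(patents)) for _ in range(50)})
    test_b = _pairs({(rng.choice(compounds), rng.choice(patents)) for _ in range(50)})
    res = match_pairs(ref, {"a": test_a, "b": test_b})
    table = per_authority_breakdown(res)
    body = table.drop(index="All")
    for col in ("total", "not_found", "found", "only_a", "only_b", "both"):
        assert body[col].sum() == table.loc["All", col]
    assert (table["found"] + table["not_found"] == table["total"]).all()


def test_per_authority_single_authority_equals_all():
    ref = _pairs([("c1", "US100"), ("c2", "US101")])
    res = match_pairs(ref, _pairs([("c1", "US100")]))
    table = per_authority_breakdown(res)
    assert table.loc["US"].equals(table.loc["All"])
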