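"""Use case 2: are known (compound, patent) pairs present in a mined source?

A mined source sometimes books a compound under a different member of the
same patent family (an EP filing instead of the WO application, say).
Family expansion counts such pairs as found.  The gain from expansion is
reported as a relative increase.
"""

from patentchem import ErrorRates, GeneratorConfig, RunConfig, relative_increase, run_use_case_2
from patentchem.synthetic import corrupt_to_automated, generate_gold_standard, write_fixtures

gold = generate_gold_standard(GeneratorConfig(n_patents=8, compounds_per_patent_mean=25, seed=4))
extract, truth = corrupt_to_automated(
    gold, ErrorRates(family_shift=0.15), seed=5, source_tag="mined"
)
paths = write_fixtures(gold, [extract], "scratch/example_uc2", truths=[truth])

r = run_use_case_2(
    paths["gold_pairs"],
    {"mined": paths["mined"]},
    RunConfig(family=True, coverage="surechembl"),
    family_csv=paths["family"],
)
n = len(r.direct.reference_pairs)
direct = r.direct.n_found("mined")
fam = r.with_family.n_found("mined")
print(f"reference pairs: {n}")
print(f"found directly: {direct} ({r.direct.percent_found_any()}%)")
print(f"found with family expansion: {fam} (+{relative_increase(direct, fam)}%)")
print("\nper-authority breakdown (family expansion on):")
print(r.breakdown)
print("\nfound fraction by number of patents per compound:")
print(r.by_patent_count.to_string(index=False))
# compounds appearing in more patents are more likely to be found at least
# once — the same pattern the per-authority table shows in aggregate
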