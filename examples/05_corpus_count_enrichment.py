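"""Find the needles in the haystack with the chemical corpus count.

A mined source attributes several times more compounds to a patent than a
curated one — reagents, solvents and marketed drugs drown out the claimed
chemistry.  Compounds that are rare across the whole corpus (corpus count
<= 30) are enriched for the patent-specific chemistry of interest.
"""

from patentchem import ErrorRates, GeneratorConfig, RunConfig
from patentchem.enrichment import bin_corpus_counts, enrichment_factor
from patentchem.io import read_corpus_counts
from patentchem.synthetic import corrupt_to_automated, generate_gold_standard, write_fixtures
from patentchem.workflows import load_source

gold = generate_gold_standard(GeneratorConfig(n_patents=10, compounds_per_patent_mean=30, seed=6))
extract, _ = corrupt_to_automated(gold, ErrorRates(), seed=7, source_tag="mined")
paths = write_fixtures(gold, [extract], "scratch/example_enrich")

mined = load_source(paths["mined"], "smiles_tsv", config=RunConfig())
counts = mined.corpus_counts("inchi_strict")
counts.update(read_corpus_counts(paths["corpus_counts"]))

relevant = {c.key_strict for p in gold.patents for c in p.compounds}
background = {c.key("inchi_strict") for c in mined.compounds}
print(f"relevant (curated) compounds: {len(relevant)}")
print(f"mined background compounds:   {len(background)} "
      f"({len(background) / len(relevant):.1f}x more)")

for label, keys in (("relevant", relevant), ("background", background)):
    frac = sum(counts.get(k, 0) <= 30 for k in keys) / len(keys)
    print(f"fraction of {label} at corpus count <= 30: {frac:.2f}")

factor = enrichment_factor(relevant, background, counts, threshold=30)
print(f"enrichment factor of the <=30 filter: {factor:.2f}")
print("\ncorpus-count histogram of the mined background:")
print(bin_corpus_counts(background, counts).to_string())
# the filter keeps most of the curated chemistry while discarding the bulk
# of the mined noise, concentrating the compounds of interest several-fold
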