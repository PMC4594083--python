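# patentchem

Benchmarking automatically generated patent-chemistry databases against
gold-standard extracts.

Large patent-chemistry databases built by text- and image-mining (the
SureChEMBL / IBM SIIP kind) promise free access to the compounds disclosed
in patents, but how much of the *curated* record (SciFinder, Reaxys) do
they actually contain?  `patentchem` implements the assessment workflow
for that question, for two complementary views:

- **patent → compounds**: of the compounds a curated source attributes to
  a patent, what fraction appears under the same patent in the mined
  source (per patent, pooled, and as a coverage histogram), with a
  three-way attribution when two mined sources are compared;
- **compound → patents**: of a reference list of (compound, patent)
  pairs, which are found in the mined source — directly, or in any
  EP/US/WO member of the same patent family.

Because compound identity is the crux, every record is reduced to match
keys first: canonical SMILES and standard InChI (version 1) of the
**largest fragment** (identical disconnected copies grouped, so a 2:1
salt reduces to its parent drug), in strict and stereo-stripped variants,
with nitro groups rewritten to a single convention.  Tautomers are *not*
canonicalized beyond standard InChI: an imine and its enamine keep
distinct keys.  Patent numbers are normalized to office code + serial
(kind code stripped; `PO-n-KK` SCPN rendering supported), and coverage
windows (authority + publication-year range, image mining from 2007)
decide which patents a source can be expected to know at all.

Two further components make the package self-contained:

- **corpus-count enrichment** (`patentchem.enrichment`): mined sources
  attribute several times more compounds to a patent than curated ones
  (reagents, solvents, marketed drugs).  Filtering at chemical corpus
  count ≤ 30 — how often a structure occurs across the whole corpus —
  concentrates the patent-specific chemistry; the enrichment factor is
  (pass fraction of relevant) / (pass fraction of background).
- **a synthetic benchmark generator** (`patentchem.synthetic`): gold
  standards and corrupted "mined" extracts with a planted truth log,
  emulating the documented extraction-failure taxonomy (image-only
  disclosures before 2007, Markush-only claims, amino-acid name codes,
  name truncation, ambiguous names, salt loss, stereo loss/error,
  tautomer shift) plus per-patent noise injection with heavy-tailed
  corpus counts.  Every pipeline stage can therefore be verified against
  known truth without any commercial database export.

## Worked example

```python
from patentchem import RawStructureRecord, standardize, coverage_percent

metoprolol = "COCCc1ccc(OCC(O)CNC(C)C)cc1"
tartaric = "OC(=O)C(O)C(O)C(=O)O"
salt = f"{metoprolol}.{metoprolol}.{tartaric}"     # 2:1 tartrate salt

sc = standardize(RawStructureRecord(record_id="metoprolol tartrate", structure=salt))
print(sc.n_components, sc.heavy_atom_count)        # -> 2 38
print(coverage_percent(1588, 2692))                # -> 59.0
```

The salt record has two distinct components; the retained metoprolol part
has 38 heavy atoms (two copies of 19) against the tartaric acid's 10, and
its match key is the InChI of a single metoprolol copy — so the salt and
the free base match.  `coverage_percent` is the pooled coverage statistic
(half-up, one decimal): 1588 of 2692 reference compounds found is 59.0%.

A full synthetic run, end to end (`examples/03_patent_to_compound_overlap.py`):

```text
key mode: inchi_strict
  source_a: 123/173 = 71.1% (truth log: 123/173)
  source_b: 120/173 = 69.4% (truth log: 120/173)
  attribution of 173 reference compounds: both=110, only source_a=13,
  only source_b=10, neither=40

key mode: inchi_nostereo
  source_a: 127/173 = 73.4% (truth log: 127/173)
```

The pipeline's coverage equals the planted truth exactly, and
stereo-stripped keys recover the compounds lost to stereo errors — which
is why the no-stereo coverage is higher.

The `examples/` directory has one short script per capability
(standardization, patent numbers, overlap, pair matching with families,
enrichment).  A thin CLI mirrors the stages:

```bash
patentchem simulate --seed 1 --out db/
patentchem match-patents --reference db/gold.sdf --test a db/source_a.smi --out out/
patentchem match-pairs --reference db/gold_pairs.csv --test a db/source_a.smi \
    --family db/family.csv --coverage both:1976-2010 --out out2/
```

## Layout

- `src/patentchem/standardize.py` — structure reading, largest-fragment
  reduction, match keys
- `src/patentchem/patents.py` — patent-number parsing, SCPN, coverage
  windows
- `src/patentchem/matching.py` — overlap, attribution, pair matching,
  family expansion
- `src/patentchem/enrichment.py` — corpus-count filter and statistics
- `src/patentchem/synthetic.py` — benchmark generator with planted truth
- `src/patentchem/workflows.py` — the two use-case runners and reporting
- `src/patentchem/cli.py` — thin command-line front end
- `docs/methods.md` — models, parameters, design choices, limitations
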