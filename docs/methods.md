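# Methods

## The comparison model

Two databases are compared on *match keys*, never on raw records.  A
compound's key is computed by a fixed pipeline:

1. **parse** (SMILES or V2000 molblock; unparseable records go to a
   rejects report with their position — they are never dropped silently,
   because they sit in the denominator of every coverage number);
2. **nitro normalization** (optional): the pentavalent drawing
   `N(=O)=O` is rewritten to the charge-separated convention
   `[N+](=O)[O-]`.  The choice of convention is arbitrary; only key
   equality matters.  The rewrite runs before sanitization so hypervalent
   input notations survive parsing, and it is idempotent;
3. **largest-fragment reduction**: disconnected components are grouped by
   canonical structure; the group whose member has the most heavy atoms is
   retained (ties: higher molecular weight, then lexicographically
   smallest canonical SMILES — deterministic and order-independent).
   Grouping identical copies is what makes a 2:1 salt behave sensibly:
   metoprolol tartrate counts as two components, its drug part as 38 heavy
   atoms (2 × 19) against tartaric acid's 10, and its key is the InChI of
   a single metoprolol copy, so salt and free base match.  No charge
   neutralization or salt-to-parent lookup is applied beyond this;
4. **stereo stripping** (optional): all atom- and bond-stereo descriptors
   are removed before key computation, collapsing enantiomers and
   diastereomers.  Keys are computed in both variants so strict and
   no-stereo comparisons come from one standardization pass;
5. **keys**: canonical SMILES, standard InChI (version 1) and InChIKey of
   the retained component.  Keys are invariant under atom reordering and
   input format; conformers are discarded after parsing because InChI
   would otherwise re-derive double-bond stereo from drawing coordinates
   and make file-format an accidental part of the key.

Tautomers are deliberately **not** canonicalized beyond what standard
InChI's mobile-H layer already merges: an imine and its enamine (or a
ketone and its enol) keep distinct keys.  Layering aggressive tautomer
canonicalization onto the keys would hide a real failure mode of mined
databases behind the metric.

Patent identifiers reduce to a comparison key of two-letter office code +
bare serial.  Kind codes (one uppercase letter plus an optional digit) are
stripped only when what precedes them still ends in a digit, so a serial
can never be truncated.  Office-name synonyms (EPO/USPTO/WIPO) normalize
to two-letter codes.  Publication years come from an explicit metadata
column or from a four-digit year prefix of WO/EP-style serials; a patent
with unknown year fails coverage checks by default (with a warning),
because year-window filtering is meaningless without one.

## Statistics

- Pooled coverage: `100 · n_found / n_total`, rounded half-up to one
  decimal (half-up rather than banker's so exact .x5 cases are not
  understated).  Pooling compounds across patents is the headline
  statistic; the unweighted per-patent mean is available as a secondary
  number.
- Per-patent percentages are binned into half-open deciles `[lo, hi)`
  with the last bin closed; counts sum to the number of patents.
- Three-way attribution partitions the reference set into
  only-A / only-B / both / neither; the partition sums to the reference
  total by construction and swapping the sources swaps only the
  `only_*` counts.
- Pair matching deduplicates (compound, patent) pairs per source before
  counting.  With family expansion, a pair is found if the compound
  appears under any retained family member (EP/US/WO by default); a pair
  matched in several members counts once, so expansion is monotone.
  Unmatched pairs carry a reason, assigned in priority order: compound
  absent from the source entirely, then patent absent, then pair absent —
  mirroring the two-stage question (is the compound there at all? is it
  attributed to this patent?).
- Enrichment factor: (fraction of relevant compounds with corpus count ≤
  threshold) / (same fraction of the background), both over unique
  compounds with known counts.  The threshold comparison is inclusive
  (≤ 30 by default).  Missing counts are kept with a warning by default
  (unobserved is not infinite), droppable by policy.
- Corpus-count histograms use eight default ranges (1–5, 6–10, 11–20,
  21–30, 31–100, 101–1000, 1001–10000, > 10000), spanning the two regimes
  the filter separates; fully configurable.

## The synthetic benchmark

The generator emulates the *shape* of a real assessment corpus so that
every stage can be verified against planted truth.

**Gold standard.**  Defaults: 46 patents; compounds per patent drawn from
a gamma distribution (shape 1.6) with mean 59, clipped to [2, 277];
authority mix EP 10% / US 50% / WO 40%; publication years uniform
1976–2015; 60% of patents get one or two EP/US/WO family members.
Compounds are sampled per patent (without replacement within a patent;
recurrence across patents is allowed, as in real corpora) from a packaged
pool of ~620 RDKit-validated drug-like structures that includes
stereo-bearing members, tautomer-prone pairs (with the alternative
tautomer stored), and nitro compounds.  15% of records are turned into
salts by attaching a counterion with fewer heavy atoms than the parent.
Per-record disclosure flags (image-only 5%, Markush-only 10%, amino-acid
code 3%) and a "biological studies" annotation (35%) are drawn once at
generation.

**Corpus counts.**  Relevant compounds draw from a geometric distribution
(p = 0.074, so ~90% of mass at ≤ 30); noise compounds from a discretized
lognormal (μ = 5.4, σ = 1.2, ~5% at ≤ 30).  The noise pool is the
packaged staples (solvents, reagents, common drugs, fragments including a
methyl radical) extended by a deterministic combinatorial enumeration of
small esters/amides/ethers/sulfones, giving a unique-noise corpus several
times larger than the relevant pool — the regime in which the published
~90% vs ~16% pass fractions, and hence a ~5× enrichment, arise.  These
conditions were fixed from the documented regime, not tuned to any test.

**Corruption.**  Per (patent, compound) and per source, failure modes are
checked in a fixed order, first hit wins: image-only disclosure in a
patent published before image mining (year < 2007, rate 1.0 given the
flag); Markush-only (1.0 given the flag); amino-acid code (1.0 given the
flag); name truncation (3%, emits a wrong structure with one terminal
atom removed); ambiguous name (2%, emits nothing); salt loss (80% of
multi-component records — the extractor emits the *counterion*, which can
never match the largest-fragment key, realizing the multi-component
penalty); stereo loss (15% of stereo-bearing, emits the stereo-stripped
structure — recoverable under no-stereo keys); stereo error (5%, emits an
inverted stereocenter — likewise); tautomer shift (30% of tautomer-prone,
emits the alternative tautomer — never recoverable under standard keys).
Surviving records may be booked under a family member's patent number
(5%), invisible to direct pair matching but recovered by family
expansion.  Noise records are then injected at 4× the per-patent compound
count.  The default rates are a calibration chosen to land aggregate
strict-key coverage in the ~60–70% regime that motivates the assessment;
real per-mode failure rates are not empirically known, so these defaults
should be read as plausible, not measured.

**Truth log.**  One row per (source, patent, reference compound) with the
failure mode and four planted match flags (strict/no-stereo ×
direct/family).  The flags are computed against the *full* set of emitted
records per patent — including noise and wrong-structure emissions — so
coincidental key collisions are booked exactly as the pipeline will see
them.  This makes the central property exact, not statistical: for any
seed, the pipeline's per-source coverage under InChI keys equals the
truth log's retention identically.  SMILES keys partition a handful of
mobile-H tautomers differently from InChI, so SMILES-mode coverage is
checked within three binomial standard errors instead.

One seeded NumPy generator drives each stage (documented draw order:
patent sizes, authorities, years, per-patent samples and flags, family
structure, corpus counts; corruption takes its own seed), so a fixed seed
gives byte-identical fixture files.

## What the synthetic data does not show

The generator plants *which* records fail and *how*, not the messy
upstream causes: there is no OCR or character-level noise, no Markush
grammar (Markush-only is a binary failure flag), no name-to-structure
conversion, and patent full text does not exist at all.  Passing tests
therefore demonstrate that the measurement pipeline is correct and
self-consistent — that standardization, key matching, family expansion
and the statistics recover planted truth exactly — not that any
particular mined database achieves any particular coverage of real
curated content.  Real-scale headline numbers require commercial exports
that cannot be redistributed; the published worked-example arithmetic is
reproduced from its printed counts instead.

## Numerical and interface choices

- Fragment tie-breaks, the nitro convention, half-up rounding and the
  unmatched-reason priority are fixed as above so results are
  deterministic and order-independent.
- Compound deduplication for overlap statistics is per (patent, key);
  whether the original workflows deduplicated within a patent is not
  documented, but pooled counts reproduce the published arithmetic under
  this choice.
- Aggregate coverage pools compounds across patents (this reproduces the
  published 1588/2692 → 59.0% arithmetic); the per-patent mean is
  exposed separately.
- The 16%-style background pass fraction is computed over unique
  compounds, not compound-occurrences.
- SDF field conventions vary between exporters; the patent-ID field name
  is configurable (default `PATENT_ID`).
- Kind codes `A` and `A1` on the same document are stripped identically;
  no ST.16 semantics are implemented.
- `#` starts a comment in SMILES-TSV input only at the start of a line —
  `#` is a triple bond inside a SMILES string.
- Test and acceptance runs use scaled-down synthetic corpora (6–10
  patents, 15–25 compounds each) for the property suites and the default
  46-patent scale for the acceptance script's end-to-end run; these sizes
  are stated in the respective configurations.

## Known limitations

- Year recovery from serials only works for WO/EP-style numbers with an
  embedded four-digit year; US serials need a metadata year column.
- Largest-fragment grouping reports the *stoichiometric* heavy-atom count
  of the retained part (38 for the 2:1 salt), which is the convention the
  assessment's worked example uses; callers wanting per-copy descriptors
  can recompute from the key SMILES.
- The family table is an input; no live family retrieval is performed,
  and families are closed symmetric-transitively over the retained
  authorities only.
- Enrichment treats corpus counts as given annotations; the package does
  not compute corpus counts from a corpus.
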