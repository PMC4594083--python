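"""Synthetic patent-chemistry databases with planted ground truth.

Real assessments of mined patent-chemistry sources run against commercial
exports that cannot be redistributed.  This module generates the same
*shape* of data with known truth: a gold standard of patents with curated
compound lists (drug-like structures, constructed salts, stereoisomers,
tautomer-prone and nitro-containing members), and per-source "automated"
extracts produced by corrupting the gold standard with the documented
extraction-failure taxonomy:

- ``image_pre2007`` — structure disclosed only as an image in a patent
  published before image mining began;
- ``markush_only`` — compound claimed only generically (Markush);
- ``aa_code`` — peptide-like name using three-letter amino-acid codes;
- ``name_truncation`` — a truncated name converted to a wrong structure;
- ``ambiguous_name`` — name too ambiguous to convert;
- ``salt_loss`` — only the named counterion of a multi-component record is
  extracted;
- ``stereo_loss`` / ``stereo_error`` — stereochemistry dropped or
  mis-assigned (recoverable under stereo-stripped keys);
- ``tautomer_shift`` — the alternative tautomer is extracted (never
  matches under standard keys).

Noise compounds (reagents, solvents, common drugs, small fragments) are
injected per patent with heavy-tailed corpus counts, while relevant
compounds carry low corpus counts, reproducing the regime in which a
corpus-count filter is informative.

Everything is driven by one seeded generator with a documented draw order,
so a fixed seed yields byte-identical fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from . import io as pcio
from .matching import CompoundPatentPair
from .patents import PatentId, comparison_key
from .standardize import (
    RawStructureRecord,
    StandardizeOptions,
    standardize,
)

__all__ = [
    "ErrorRates",
    "GeneratorConfig",
    "GoldCompound",
    "GoldPatent",
    "GoldStandard",
    "AutomatedExtract",
    "SyntheticTruth",
    "FAILURE_MODES",
    "load_pool",
    "generate_gold_standard",
    "corrupt_to_automated",
    "write_fixtures",
]

FAILURE_MODES = (
    "image_pre2007",
    "markush_only",
    "aa_code",
    "name_truncation",
    "ambiguous_name",
    "salt_loss",
    "stereo_loss",
    "stereo_error",
    "tautomer_shift",
    "none",
)

_DATA = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ErrorRates:
    """Per-mode extraction-failure rates applied during corruption.

    Disclosure-driven modes (image/Markush/amino-acid code) fire only for
    compounds carrying the corresponding susceptibility flag; structural
    modes (salt/stereo/tautomer) only for structurally susceptible
    compounds.  ``family_shift`` books an otherwise-correct record under a
    family member's patent number, so it is invisible to direct pair
    matching but recovered by family expansion.
    """

    image_pre2007: float = 1.0
    markush_only: float = 1.0
    aa_code: float = 1.0
    name_truncation: float = 0.03
    ambiguous_name: float = 0.02
    salt_loss: float = 0.8
    stereo_loss: float = 0.15
    stereo_error: float = 0.05
    tautomer_shift: float = 0.3
    family_shift: float = 0.05
    image_year_min: int = 2007
    noise_multiplier: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "image_pre2007", "markush_only", "aa_code", "name_truncation",
            "ambiguous_name", "salt_loss", "stereo_loss", "stereo_error",
            "tautomer_shift", "family_shift",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {name}={v} outside [0, 1]")

    @classmethod
    def zero(cls) -> "ErrorRates":
        """Error-free extraction (extract equals gold)."""
        return cls(
            image_pre2007=0.0, markush_only=0.0, aa_code=0.0,
            name_truncation=0.0, ambiguous_name=0.0, salt_loss=0.0,
            stereo_loss=0.0, stereo_error=0.0, tautomer_shift=0.0,
            family_shift=0.0, noise_multiplier=0.0,
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the gold-standard generator.

    Defaults emulate the assessed corpus: 46 patents averaging 59
    compounds each (range 2-277), a mix of EP/US/WO authorities, salts on
    a minority of records, and corpus counts drawn from a low-mean
    distribution for relevant compounds (~90% of mass at <= 30) versus a
    heavy-tailed one for noise.
    """

    n_patents: int = 46
    compounds_per_patent_mean: float = 59.0
    compounds_per_patent_min: int = 2
    compounds_per_patent_max: int = 277
    compounds_per_patent_shape: float = 1.6  # gamma shape; scale from mean
    relevant_fraction: float = 1.0  # gold compounds that are relevant (rest noise-class)
    multi_component_fraction: float = 0.15
    image_only_fraction: float = 0.05
    markush_only_fraction: float = 0.10
    aa_code_fraction: float = 0.03
    bio_studies_fraction: float = 0.35
    authority_mix: tuple[tuple[str, float], ...] = (("EP", 0.1), ("US", 0.5), ("WO", 0.4))
    year_min: int = 1976
    year_max: int = 2015
    family_fraction: float = 0.6
    family_extra_members_max: int = 2
    relevant_count_p: float = 0.074  # geometric; P(count<=30) ~ 0.90
    noise_count_mu: float = 5.4  # lognormal; P(count<=30) ~ 0.05
    noise_count_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "relevant_fraction", "multi_component_fraction",
            "image_only_fraction", "markush_only_fraction",
            "aa_code_fraction", "bio_studies_fraction", "family_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {name}={v} outside [0, 1]")
        if self.n_patents < 1:
            raise ValueError("n_patents must be positive")


# ---------------------------------------------------------------------------
# the packaged compound pool


@dataclass(frozen=True)
class PoolMember:
    smiles: str  # canonical
    role: str  # relevant | noise | counterion
    tautomer_alt: str = ""
    has_stereo: bool = False
    heavy_atoms: int = 0


def _mol_has_stereo(mol: Chem.Mol) -> bool:
    if any(a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()):
        return True
    return any(
        b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds()
    )


def load_pool() -> list[PoolMember]:
    """The packaged curated pool (drug-like relevant structures, noise
    staples, counterions), RDKit-revalidated on load."""
    members: list[PoolMember] = []
    with open(_DATA / "pool.tsv") as fh:
        header = fh.readline()
        assert header.startswith("smiles")
        for line in fh:
            smi, role, alt = line.rstrip("\n").split("\t")
            mol = Chem.MolFromSmiles(smi)
            if mol is None:  # pragma: no cover - pool is pre-validated
                continue
            members.append(
                PoolMember(
                    smiles=smi,
                    role=role,
                    tautomer_alt=alt,
                    has_stereo=_mol_has_stereo(mol),
                    heavy_atoms=mol.GetNumHeavyAtoms(),
                )
            )
    return members


def _expanded_noise_pool() -> list[str]:
    """Combinatorial small-molecule noise (esters, amides, ethers,
    sulfones over simple radicals), enumerated deterministically in code so
    the unique-noise corpus is several times larger than the relevant pool
    — the regime that makes the corpus-count filter informative."""
    left = [
        "C", "CC", "CCC", "CCCC", "CC(C)", "CC(C)C", "CCCCC", "C1CCCCC1",
        "c1ccccc1", "Cc1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccncc1",
        "COc1ccccc1", "c1ccc(Br)cc1", "CCOC(=O)C", "OCC", "NCC", "C1CCOC1C",
        "CC(F)(F)", "c1csc(c1)", "c1ccc2ccccc2c1",
    ]
    linkers = ["C(=O)O", "C(=O)N", "O", "N", "C(=O)", "S", "S(=O)(=O)", "OC(=O)"]
    right = [
        "C", "CC", "CCC", "C(C)C", "CCCC", "CCO", "CCN", "c1ccccc1",
        "Cc1ccccc1", "c1ccc(C)cc1", "C1CCCCC1", "CC(C)C", "CCOC", "CC#N",
        "c1ccc(O)cc1", "CCc1ccccc1", "C1CCNCC1", "CC(=O)C", "CCCl",
    ]
    seen: set[str] = set()
    out: list[str] = []
    for a, lk, b in itertools.product(left, linkers, right):
        mol = Chem.MolFromSmiles(a + lk + b)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
    return out


# ---------------------------------------------------------------------------
# gold standard


@dataclass
class GoldCompound:
    compound_id: str
    smiles: str  # full record, counterion included for salts
    parent_smiles: str
    counterion_smiles: str = ""
    tautomer_alt: str = ""
    has_stereo: bool = False
    is_multi_component: bool = False
    image_only: bool = False
    markush_only: bool = False
    aa_code: bool = False
    bio_studies: bool = False
    key_strict: str = ""
    key_nostereo: str = ""


@dataclass
class GoldPatent:
    patent_id: PatentId
    compounds: list[GoldCompound]
    family_members: tuple[str, ...] = ()  # comparison keys, self excluded

    @property
    def key(self) -> str:
        return comparison_key(self.patent_id)

    @property
    def year(self) -> int:
        return self.patent_id.year


@dataclass
class GoldStandard:
    config: GeneratorConfig
    patents: list[GoldPatent]
    corpus_counts: dict[str, int]  # canonical parent SMILES -> corpus count
    noise_pool: list[str] = field(repr=False, default_factory=list)

    @property
    def n_compounds(self) -> int:
        return sum(len(p.compounds) for p in self.patents)

    def reference_sets(self, key_mode: str = "inchi_strict") -> dict[str, set[str]]:
        """Per-patent compound-key sets (deduplicated per patent)."""
        attr = {"inchi_strict": "key_strict", "inchi_nostereo": "key_nostereo"}[key_mode]
        return {
            p.key: {getattr(c, attr) for c in p.compounds} for p in self.patents
        }

    def reference_pairs(self) -> list[CompoundPatentPair]:
        return [
            CompoundPatentPair(c.key_strict, p.key, "gold")
            for p in self.patents
            for c in p.compounds
        ]

    def family_rows(self) -> list[tuple[str, str]]:
        return [
            (p.key, m) for p in self.patents for m in p.family_members
        ]

    def corpus_counts_by_key(self) -> dict[str, int]:
        """Corpus counts re-keyed by strict match key (largest-fragment
        standard InChI) for the compounds appearing in the gold standard."""
        out: dict[str, int] = {}
        for p in self.patents:
            for c in p.compounds:
                cnt = self.corpus_counts.get(c.parent_smiles)
                if cnt is not None:
                    out.setdefault(c.key_strict, cnt)
        return out


def _strict_and_nostereo_keys(smiles: str) -> tuple[str, str]:
    sc = standardize(
        RawStructureRecord(record_id="x", structure=smiles), StandardizeOptions()
    )
    return sc.key_inchi, sc.key_nostereo


def generate_gold_standard(config: GeneratorConfig = GeneratorConfig()) -> GoldStandard:
    """Generate the gold-standard database for the configured conditions.

    Draw order per run: patent sizes, authorities, years, family structure,
    then per patent the compound sample and per-compound flags, then corpus
    counts for every pool member.  A patent never demands more compounds
    than the relevant pool holds (error otherwise); across patents,
    compounds may recur, as they do in real corpora.
    """
    rng = np.random.default_rng(config.seed)
    pool = load_pool()
    relevant = [m for m in pool if m.role == "relevant"]
    noise = [m for m in pool if m.role == "noise"]
    counterions = [m for m in pool if m.role == "counterion"]
    noise_pool = sorted(
        {m.smiles for m in noise} | set(_expanded_noise_pool())
    )

    scale = config.compounds_per_patent_mean / config.compounds_per_patent_shape
    sizes = np.clip(
        np.round(rng.gamma(config.compounds_per_patent_shape, scale, config.n_patents)),
        config.compounds_per_patent_min,
        config.compounds_per_patent_max,
    ).astype(int)
    if sizes.max() > len(relevant):
        raise ValueError(
            f"compound pool ({len(relevant)} relevant members) smaller than "
            f"the largest per-patent demand ({sizes.max()})"
        )

    auths, weights = zip(*config.authority_mix)
    authorities = rng.choice(auths, size=config.n_patents, p=np.asarray(weights))
    years = rng.integers(config.year_min, config.year_max + 1, config.n_patents)

    # serials: authority-embedded year prefix for WO/EP-style numbers
    patents: list[GoldPatent] = []
    key_cache: dict[str, tuple[str, str]] = {}
    serial_counter = itertools.count(100001)
    for i in range(config.n_patents):
        auth, year = str(authorities[i]), int(years[i])
        if auth in {"WO", "EP"} and auth == "WO":
            serial = f"{year}{next(serial_counter):06d}"
        else:
            serial = f"{next(serial_counter)}"
        pid = PatentId(authority=auth, serial=serial, kind_code="A1", year=year)

        idx = rng.choice(len(relevant), size=sizes[i], replace=False)
        compounds: list[GoldCompound] = []
        for j, k in enumerate(idx):
            m = relevant[int(k)]
            is_salt = (
                not m.has_stereo  # keep failure modes separable per compound
                and rng.random() < config.multi_component_fraction
            )
            counter = ""
            smiles = m.smiles
            if is_salt:
                cand = counterions[int(rng.integers(len(counterions)))]
                if cand.heavy_atoms < m.heavy_atoms:
                    counter = cand.smiles
                    smiles = f"{m.smiles}.{counter}"
                else:
                    is_salt = False
            if m.smiles not in key_cache:
                key_cache[m.smiles] = _strict_and_nostereo_keys(m.smiles)
            ks, kn = key_cache[m.smiles]
            compounds.append(
                GoldCompound(
                    compound_id=f"{comparison_key(pid)}:{j:04d}",
                    smiles=smiles,
                    parent_smiles=m.smiles,
                    counterion_smiles=counter,
                    tautomer_alt=m.tautomer_alt,
                    has_stereo=m.has_stereo,
                    is_multi_component=is_salt,
                    image_only=rng.random() < config.image_only_fraction,
                    markush_only=rng.random() < config.markush_only_fraction,
                    aa_code=rng.random() < config.aa_code_fraction,
                    bio_studies=rng.random() < config.bio_studies_fraction,
                    key_strict=ks,
                    key_nostereo=kn,
                )
            )
        patents.append(GoldPatent(patent_id=pid, compounds=compounds))

    # family clusters over EP/US/WO
    fam_serial = itertools.count(900001)
    for p in patents:
        if rng.random() >= config.family_fraction:
            continue
        n_extra = int(rng.integers(1, config.family_extra_members_max + 1))
        others = [a for a in ("EP", "US", "WO") if a != p.patent_id.authority]
        members = []
        for _ in range(n_extra):
            a = others[int(rng.integers(len(others)))]
            members.append(f"{a}{next(fam_serial)}")
        p.family_members = tuple(dict.fromkeys(members))

    # corpus counts: relevant ~ geometric (low), noise ~ discretized lognormal
    corpus_counts: dict[str, int] = {}
    for m in relevant:
        corpus_counts[m.smiles] = int(rng.geometric(config.relevant_count_p))
    for smi in noise_pool:
        corpus_counts[smi] = max(
            31,
            int(np.round(rng.lognormal(config.noise_count_mu, config.noise_count_sigma))),
        ) if rng.random() < 0.95 else int(rng.integers(1, 31))
    for m in counterions:
        corpus_counts[m.smiles] = int(
            np.round(rng.lognormal(config.noise_count_mu, config.noise_count_sigma))
        ) or 1

    if config.relevant_fraction < 1.0:
        # a slice of gold compounds re-labelled as noise-class (high counts)
        for p in patents:
            for c in p.compounds:
                if rng.random() > config.relevant_fraction:
                    corpus_counts[c.parent_smiles] = int(
                        max(31, np.round(rng.lognormal(config.noise_count_mu,
                                                       config.noise_count_sigma)))
                    )

    return GoldStandard(
        config=config,
        patents=patents,
        corpus_counts=corpus_counts,
        noise_pool=noise_pool,
    )


# ---------------------------------------------------------------------------
# corruption


@dataclass
class AutomatedExtract:
    """One simulated mined source: SMILES records with patent attribution
    and corpus counts, as a SMILES-TSV-shaped table."""

    source_tag: str
    records: pd.DataFrame  # columns: smiles, patent_raw, corpus_count

    def pairs(self) -> list[tuple[str, str, int]]:
        return list(
            self.records[["smiles", "patent_raw", "corpus_count"]].itertuples(
                index=False, name=None
            )
        )


@dataclass
class SyntheticTruth:
    """Planted per-(patent, compound) outcome for one simulated source.

    ``df`` has one row per gold reference compound with its failure mode
    and whether the emitted record matches the gold keys directly or via a
    family member, under strict and stereo-stripped keys; ``noise_df``
    logs the injected noise records.
    """

    source_tag: str
    df: pd.DataFrame
    noise_df: pd.DataFrame

    def expected_coverage(self, key_mode: str = "inchi_strict") -> tuple[int, int]:
        """(n matched, n reference) for direct per-patent matching.

        Deduplicated per (patent, key) exactly as the pipeline counts: a
        gold key in a patent is covered if any emitted record in that
        patent carries it.
        """
        col = {
            "inchi_strict": "match_strict_direct",
            "inchi_nostereo": "match_nostereo_direct",
        }[key_mode]
        kcol = {"inchi_strict": "key_strict", "inchi_nostereo": "key_nostereo"}[key_mode]
        g = self.df.groupby(["patent_key", kcol])[col].any()
        return int(g.sum()), int(len(g))

    def expected_pair_matches(self, *, family: bool = False) -> int:
        col = "match_strict_family" if family else "match_strict_direct"
        g = self.df.groupby(["patent_key", "key_strict"])[col].any()
        return int(g.sum())


def _invert_first_stereocenter(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            return Chem.MolToSmiles(mol)
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            return Chem.MolToSmiles(mol)
    for bond in mol.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREOE:
            bond.SetStereo(Chem.BondStereo.STEREOZ)
            return Chem.MolToSmiles(mol)
        if bond.GetStereo() == Chem.BondStereo.STEREOZ:
            bond.SetStereo(Chem.BondStereo.STEREOE)
            return Chem.MolToSmiles(mol)
    return smiles  # pragma: no cover - callers check has_stereo first


def _strip_stereo_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _truncate(smiles: str) -> str | None:
    """Drop one terminal heavy atom — a wrong structure standing in for a
    truncated-name conversion."""
    mol = Chem.MolFromSmiles(smiles)
    targets = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() == 1]
    if not targets or mol.GetNumHeavyAtoms() < 3:
        return None
    em = Chem.RWMol(mol)
    em.RemoveAtom(targets[-1])
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
    except Exception:  # pragma: no cover - removal of a terminal atom is safe
        return None
    return Chem.MolToSmiles(out)


def corrupt_to_automated(
    gold: GoldStandard,
    rates: ErrorRates = ErrorRates(),
    seed: int = 0,
    source_tag: str = "automated",
) -> tuple[AutomatedExtract, SyntheticTruth]:
    """Simulate one mined source by corrupting the gold standard.

    Per (patent, compound), failure modes are checked in a fixed order
    (image, Markush, amino-acid code, truncation, ambiguity, salt, stereo
    loss, stereo error, tautomer shift); the first firing mode wins.
    Surviving records may be booked under a family member's patent number
    (``family_shift``).  Noise records are then injected per patent.
    Returns the extract and its planted truth log.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, int]] = []
    noise_rows: list[dict] = []
    # pass 1: decide emissions; (patent, compound, mode, emitted, emitted_patent)
    outcomes: list[tuple[GoldPatent, GoldCompound, str, str | None, str]] = []

    for patent in gold.patents:
        pkey = patent.key
        for c in patent.compounds:
            mode = "none"
            emitted: str | None = c.smiles
            if (
                c.image_only
                and patent.year < rates.image_year_min
                and rng.random() < rates.image_pre2007
            ):
                mode, emitted = "image_pre2007", None
            elif c.markush_only and rng.random() < rates.markush_only:
                mode, emitted = "markush_only", None
            elif c.aa_code and rng.random() < rates.aa_code:
                mode, emitted = "aa_code", None
            elif rng.random() < rates.name_truncation:
                mode, emitted = "name_truncation", _truncate(c.parent_smiles)
            elif rng.random() < rates.ambiguous_name:
                mode, emitted = "ambiguous_name", None
            elif c.is_multi_component and rng.random() < rates.salt_loss:
                mode, emitted = "salt_loss", c.counterion_smiles
            elif c.has_stereo and rng.random() < rates.stereo_loss:
                mode, emitted = "stereo_loss", _strip_stereo_smiles(c.smiles)
            elif c.has_stereo and rng.random() < rates.stereo_error:
                mode, emitted = "stereo_error", _invert_first_stereocenter(c.smiles)
            elif c.tautomer_alt and rng.random() < rates.tautomer_shift:
                mode, emitted = "tautomer_shift", c.tautomer_alt

            emitted_patent = pkey
            if (
                mode == "none"
                and patent.family_members
                and rng.random() < rates.family_shift
            ):
                emitted_patent = patent.family_members[
                    int(rng.integers(len(patent.family_members)))
                ]

            if emitted:
                count = gold.corpus_counts.get(c.parent_smiles, 1)
                if mode == "salt_loss":
                    count = gold.corpus_counts.get(c.counterion_smiles, 1000)
                elif mode == "name_truncation":
                    count = 1
                records.append((emitted, emitted_patent, count))
            outcomes.append((patent, c, mode, emitted, emitted_patent))

        n_noise = int(np.round(rates.noise_multiplier * len(patent.compounds)))
        if n_noise and gold.noise_pool:
            picks = rng.integers(len(gold.noise_pool), size=n_noise)
            for k in picks:
                smi = gold.noise_pool[int(k)]
                records.append((smi, pkey, gold.corpus_counts.get(smi, 1)))
                noise_rows.append({"source": source_tag, "patent_key": pkey, "smiles": smi})

    # pass 2: key every emitted record (noise included) and derive the truth
    # flags against the full per-patent emitted key sets, so coincidental key
    # collisions are booked exactly as the pipeline will see them
    key_cache: dict[str, tuple[str, str]] = {}

    def keys_of(smiles: str) -> tuple[str, str]:
        if smiles not in key_cache:
            key_cache[smiles] = _strict_and_nostereo_keys(smiles)
        return key_cache[smiles]

    strict_by_patent: dict[str, set[str]] = {}
    nostereo_by_patent: dict[str, set[str]] = {}
    for smi, epat, _count in records:
        ks, kn = keys_of(smi)
        strict_by_patent.setdefault(epat, set()).add(ks)
        nostereo_by_patent.setdefault(epat, set()).add(kn)

    truth_rows: list[dict] = []
    for patent, c, mode, emitted, emitted_patent in outcomes:
        pkey = patent.key
        fam = (pkey,) + patent.family_members
        truth_rows.append(
            {
                "source": source_tag,
                "patent_key": pkey,
                "compound_id": c.compound_id,
                "key_strict": c.key_strict,
                "key_nostereo": c.key_nostereo,
                "failure_mode": mode,
                "extracted": mode == "none",
                "emitted_smiles": emitted or "",
                "emitted_patent_key": emitted_patent if emitted else "",
                "match_strict_direct": c.key_strict
                in strict_by_patent.get(pkey, set()),
                "match_nostereo_direct": c.key_nostereo
                in nostereo_by_patent.get(pkey, set()),
                "match_strict_family": any(
                    c.key_strict in strict_by_patent.get(m, set()) for m in fam
                ),
                "match_nostereo_family": any(
                    c.key_nostereo in nostereo_by_patent.get(m, set()) for m in fam
                ),
            }
        )

    extract = AutomatedExtract(
        source_tag=source_tag,
        records=pd.DataFrame(records, columns=["smiles", "patent_raw", "corpus_count"]),
    )
    truth = SyntheticTruth(
        source_tag=source_tag,
        df=pd.DataFrame(truth_rows),
        noise_df=pd.DataFrame(noise_rows, columns=["source", "patent_key", "smiles"]),
    )
    return extract, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(
    gold: GoldStandard,
    extracts: Iterable[AutomatedExtract],
    out_dir: str | Path,
    truths: Iterable[SyntheticTruth] = (),
) -> dict[str, Path]:
    """Write the generated database as the file formats the pipeline reads.

    Produces ``gold.sdf`` (patent ID and annotations as SDF data fields),
    ``gold_pairs.csv``, ``family.csv``, ``corpus_counts.csv``, one
    ``<source>.smi`` SMILES-TSV per extract, and one ``<source>_truth.csv``
    per truth log.  Returns the path of every file written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sdf_path = out / "gold.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    try:
        for p in gold.patents:
            for c in p.compounds:
                mol = Chem.MolFromSmiles(c.smiles)
                # 2D coords so wedge bonds carry stereo through the molblock;
                # unspecified stereogenic double bonds become crossed bonds so
                # the drawing does not invent a geometry
                AllChem.Compute2DCoords(mol)
                Chem.FindPotentialStereoBonds(mol)
                Chem.WedgeMolBonds(mol, mol.GetConformer())
                mol.SetProp("_Name", c.compound_id)
                mol.SetProp("PATENT_ID", p.key)
                mol.SetProp("YEAR", str(p.year))
                mol.SetProp("BIOLOGICAL_STUDIES", "Y" if c.bio_studies else "N")
                writer.write(mol)
    finally:
        writer.close()
    paths["gold_sdf"] = sdf_path

    years = {p.key: p.year for p in gold.patents}
    pcio.write_pair_table(gold.reference_pairs(), out / "gold_pairs.csv", years=years)
    paths["gold_pairs"] = out / "gold_pairs.csv"

    pcio.write_family_table(gold.family_rows(), out / "family.csv")
    paths["family"] = out / "family.csv"

    pcio.write_corpus_counts(gold.corpus_counts_by_key(), out / "corpus_counts.csv")
    paths["corpus_counts"] = out / "corpus_counts.csv"

    for ex in extracts:
        p = out / f"{ex.source_tag}.smi"
        with open(p, "w") as fh:
            fh.write("smiles\tpatent_id\tcorpus_count\n")
            for smi, pk, cnt in ex.pairs():
                fh.write(f"{smi}\t{pk}\t{cnt}\n")
        paths[ex.source_tag] = p

    for t in truths:
        p = out / f"{t.source_tag}_truth.csv"
        t.df.to_csv(p, index=False)
        paths[f"{t.source_tag}_truth"] = p
        if len(t.noise_df):
            np_path = out / f"{t.source_tag}_noise.csv"
            t.noise_df.to_csv(np_path, index=False)
            paths[f"{t.source_tag}_noise"] = np_path

    return paths
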