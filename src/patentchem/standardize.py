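"""Structure reading and reduction to comparable match keys.

Every compound record — whether a connection table from a curated SDF
export or a mined SMILES line — is reduced to the keys used for
cross-database matching: canonical SMILES and standard InChI (version 1)
of the largest fragment, in strict and stereo-stripped variants.

Fragment handling groups identical disconnected copies: in a 2:1 salt such
as metoprolol tartrate the two metoprolol copies count as one component of
38 heavy atoms against the tartaric acid's 10, and the match keys are
computed on a single copy, so ``CCO.CCO`` and ``CCO`` share a key.  No
charge neutralization, tautomer canonicalization or salt-to-parent lookup
is applied beyond this largest-fragment reduction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.inchi import MolToInchi, MolToInchiKey

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RawStructureRecord",
    "StandardizedCompound",
    "Reject",
    "ReadResult",
    "StandardizeOptions",
    "StandardizationError",
    "read_structures",
    "write_rejects",
    "parse_structure",
    "select_largest_fragment",
    "normalize_nitro",
    "strip_stereo",
    "count_components",
    "standardize",
    "standardize_all",
    "filter_compound_set",
]

KeyMode = Literal["inchi_strict", "inchi_nostereo", "smiles_strict", "smiles_nostereo"]
KEY_MODES: tuple[str, ...] = (
    "inchi_strict",
    "inchi_nostereo",
    "smiles_strict",
    "smiles_nostereo",
)


class StandardizationError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""


@dataclass
class RawStructureRecord:
    """One input record: structure text plus provenance annotations."""

    record_id: str
    structure: str
    patent_ref: str = ""
    source_tag: str = ""
    structure_format: Literal["smiles", "molblock"] = "smiles"
    annotations: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Reject:
    """An input entry that could not be used, retained for the audit trail."""

    record_id: str
    reason: str
    position: int  # line number (TSV) or record index (SDF)


@dataclass
class ReadResult:
    records: list[RawStructureRecord]
    rejects: list[Reject]

    def __iter__(self) -> Iterator[RawStructureRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class StandardizeOptions:
    """Pipeline switches: parse -> nitro normalization -> largest fragment ->
    stereo stripping -> key computation."""

    strip_stereo: bool = False
    normalize_nitro: bool = False


@dataclass(frozen=True)
class StandardizedCompound:
    """A compound reduced to its match keys and descriptors.

    ``heavy_atom_count`` and ``mol_weight`` describe the retained fragment
    group (all copies of the largest distinct component); the keys are
    computed on one copy of it.
    """

    record_id: str
    n_components: int
    heavy_atom_count: int
    mol_weight: float
    key_inchi: str
    key_inchikey: str
    key_smiles: str
    key_nostereo: str
    key_smiles_nostereo: str
    patent_ref: str = ""
    source_tag: str = ""
    annotations: dict[str, str] = field(default_factory=dict, compare=False)

    def key(self, mode: KeyMode = "inchi_strict") -> str:
        """Return the match key for one of the four key modes."""
        return {
            "inchi_strict": self.key_inchi,
            "inchi_nostereo": self.key_nostereo,
            "smiles_strict": self.key_smiles,
            "smiles_nostereo": self.key_smiles_nostereo,
        }[mode]


# ---------------------------------------------------------------------------
# reading


def read_structures(
    path: str | Path,
    format: Literal["sdf", "smiles_tsv"],
    *,
    patent_field: str = "PATENT_ID",
    source_tag: str = "",
) -> ReadResult:
    """Read an SDF or SMILES-TSV file into raw records plus a rejects list.

    SDF: one record per molecule block, patent ID taken from the data field
    named ``patent_field``.  TSV: columns ``smiles``, ``patent_id``,
    optional ``corpus_count``; ``#`` starts a comment; a header row naming
    the columns is allowed.  Unparseable entries are routed to the rejects
    list (never dropped silently).
    """
    path = Path(path)
    if format == "sdf":
        result = _read_sdf(path, patent_field, source_tag)
    elif format == "smiles_tsv":
        result = _read_smiles_tsv(path, source_tag)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not result.records and not result.rejects:
        import warnings

        warnings.warn(f"{path} contained no records", stacklevel=2)
    return result


def _read_sdf(path: Path, patent_field: str, source_tag: str) -> ReadResult:
    records: list[RawStructureRecord] = []
    rejects: list[Reject] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i in range(len(supplier)):
        text = supplier.GetItemText(i)
        mol = supplier[i]
        if mol is None or _sanitized_copy(mol) is None:
            rejects.append(Reject(f"sdf:{i}", "unparseable molblock", i))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        props = {k: str(v) for k, v in mol.GetPropsAsDict().items()}
        records.append(
            RawStructureRecord(
                record_id=name or f"sdf:{i}",
                structure=text,
                patent_ref=props.get(patent_field, ""),
                source_tag=source_tag,
                structure_format="molblock",
                annotations=props,
            )
        )
    return ReadResult(records, rejects)


def _read_smiles_tsv(path: Path, source_tag: str) -> ReadResult:
    records: list[RawStructureRecord] = []
    rejects: list[Reject] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            # whole-line comments only: '#' is a bond symbol inside SMILES
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"smiles", "structure"}:
                continue
            smi = fields[0].strip()
            if Chem.MolFromSmiles(smi, sanitize=False) is None:
                rejects.append(Reject(f"line:{lineno}", "unparseable SMILES", lineno))
                continue
            ann: dict[str, str] = {}
            if len(fields) > 2 and fields[2].strip():
                ann["corpus_count"] = fields[2].strip()
            records.append(
                RawStructureRecord(
                    record_id=f"line:{lineno}",
                    structure=smi,
                    patent_ref=fields[1].strip() if len(fields) > 1 else "",
                    source_tag=source_tag,
                    structure_format="smiles",
                    annotations=ann,
                )
            )
    return ReadResult(records, rejects)


def write_rejects(rejects: Sequence[Reject], path: str | Path) -> None:
    """Persist the rejects report as CSV (record_id, reason, position)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "reason", "position"])
        for r in rejects:
            w.writerow([r.record_id, r.reason, r.position])


# ---------------------------------------------------------------------------
# molecule-level operations


def _sanitized_copy(mol: Chem.Mol) -> Chem.Mol | None:
    m = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return m


def _as_mol(structure: str | Chem.Mol, *, do_nitro: bool = False) -> Chem.Mol:
    """Parse SMILES/molblock text (or pass a Mol through), sanitizing after
    the optional nitro rewrite so hypervalent input notations survive."""
    if isinstance(structure, Chem.Mol):
        return structure
    text = structure
    if "\n" in text or "\r" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise StandardizationError(f"unparseable structure {text[:60]!r}")
    if do_nitro:
        _normalize_nitro_inplace(mol)
    mol = _sanitized_copy(mol)
    if mol is None:
        raise StandardizationError(f"structure failed sanitization {text[:60]!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise StandardizationError("structure has no heavy atoms")
    # keys must depend on the graph and perceived stereo flags only, never on
    # drawing coordinates (InChI would re-derive stereo from a conformer)
    mol.RemoveAllConformers()
    return mol


def _normalize_nitro_inplace(mol: Chem.Mol) -> None:
    """Rewrite pentavalent nitro N(=O)=O to the charge-separated convention
    [N+](=O)[O-]; operates before sanitization, deterministic (the lowest-
    index terminal oxygen takes the negative charge)."""
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetFormalCharge() != 0:
            continue
        dbl_os = [
            b
            for b in atom.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(atom).GetSymbol() == "O"
            and b.GetOtherAtom(atom).GetDegree() == 1
            and b.GetOtherAtom(atom).GetFormalCharge() == 0
        ]
        if len(dbl_os) != 2:
            continue
        target = min(dbl_os, key=lambda b: b.GetOtherAtom(atom).GetIdx())
        target.SetBondType(Chem.BondType.SINGLE)
        target.GetOtherAtom(atom).SetFormalCharge(-1)
        atom.SetFormalCharge(1)


def normalize_nitro(structure: str | Chem.Mol) -> Chem.Mol:
    """Return the structure with all nitro groups in charge-separated form."""
    if isinstance(structure, Chem.Mol):
        m = Chem.Mol(structure)
        _normalize_nitro_inplace(m)
        out = _sanitized_copy(m)
        if out is None:
            raise StandardizationError("nitro normalization broke sanitization")
        return out
    return _as_mol(structure, do_nitro=True)


def strip_stereo(structure: str | Chem.Mol) -> Chem.Mol:
    """Remove all atom- and bond-stereo descriptors."""
    mol = Chem.Mol(_as_mol(structure))
    Chem.RemoveStereochemistry(mol)
    return mol


def _distinct_components(mol: Chem.Mol) -> list[tuple[Chem.Mol, str, int]]:
    """Disconnected components grouped by canonical structure.

    Returns ``(representative, canonical_smiles, n_copies)`` per distinct
    component, in input order of first appearance.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    groups: dict[str, tuple[Chem.Mol, int]] = {}
    for f in frags:
        smi = Chem.MolToSmiles(f)
        rep, n = groups.get(smi, (f, 0))
        groups[smi] = (rep, n + 1)
    return [(rep, smi, n) for smi, (rep, n) in groups.items()]


def count_components(structure: str | Chem.Mol) -> int:
    """Number of distinct non-covalently-bound components (identical
    copies, as in a 2:1 salt, count once)."""
    return len(_distinct_components(_as_mol(structure)))


def _largest_group(mol: Chem.Mol) -> tuple[Chem.Mol, int]:
    """The winning distinct component and its copy count.

    Selection: most heavy atoms per copy; ties by higher molecular weight,
    then lexicographically smallest canonical SMILES.
    """
    groups = _distinct_components(mol)
    if not groups:
        raise StandardizationError("empty structure")

    def rank(g: tuple[Chem.Mol, str, int]):
        rep, smi, _ = g
        return (-rep.GetNumHeavyAtoms(), -Descriptors.MolWt(rep), smi)

    rep, _, copies = min(groups, key=rank)
    return rep, copies


def select_largest_fragment(structure: str | Chem.Mol) -> Chem.Mol:
    """Keep the largest distinct component, with all of its copies.

    For the 2:1 salt metoprolol tartrate this retains both metoprolol
    copies (38 heavy atoms in total) and discards the tartaric acid
    component (10 heavy atoms).  Idempotent.
    """
    rep, copies = _largest_group(_as_mol(structure))
    out = rep
    for _ in range(copies - 1):
        out = Chem.CombineMols(out, rep)
    return out


def parse_structure(structure: str, *, normalize_nitro: bool = False) -> Chem.Mol:
    """Parse structure text, optionally applying the nitro convention."""
    return _as_mol(structure, do_nitro=normalize_nitro)


# ---------------------------------------------------------------------------
# the standardization pipeline


def standardize(
    record: RawStructureRecord, opts: StandardizeOptions = StandardizeOptions()
) -> StandardizedCompound:
    """Reduce one raw record to its match keys and descriptors.

    Pipeline: parse -> optional nitro normalization -> largest-fragment
    reduction -> optional stereo stripping -> canonical SMILES / standard
    InChI keys in strict and no-stereo variants.  Raises
    :class:`StandardizationError` on unparseable input.
    """
    mol = _as_mol(record.structure, do_nitro=opts.normalize_nitro)
    n_comp = count_components(mol)
    rep, copies = _largest_group(mol)
    if opts.strip_stereo:
        rep = Chem.Mol(rep)
        Chem.RemoveStereochemistry(rep)
    key_smiles = Chem.MolToSmiles(rep)
    key_inchi = MolToInchi(rep)
    key_inchikey = MolToInchiKey(rep)
    nostereo = Chem.Mol(rep)
    Chem.RemoveStereochemistry(nostereo)
    return StandardizedCompound(
        record_id=record.record_id,
        n_components=n_comp,
        heavy_atom_count=rep.GetNumHeavyAtoms() * copies,
        mol_weight=Descriptors.MolWt(rep) * copies,
        key_inchi=key_inchi,
        key_inchikey=key_inchikey,
        key_smiles=key_smiles,
        key_nostereo=MolToInchi(nostereo),
        key_smiles_nostereo=Chem.MolToSmiles(nostereo),
        patent_ref=record.patent_ref,
        source_tag=record.source_tag,
        annotations=dict(record.annotations),
    )


def standardize_all(
    records: Iterable[RawStructureRecord],
    opts: StandardizeOptions = StandardizeOptions(),
) -> tuple[list[StandardizedCompound], list[Reject]]:
    """Standardize a batch; parse failures go to the rejects list."""
    out: list[StandardizedCompound] = []
    rejects: list[Reject] = []
    for i, rec in enumerate(records):
        try:
            out.append(standardize(rec, opts))
        except StandardizationError as exc:
            rejects.append(Reject(rec.record_id, str(exc), i))
    return out, rejects


def filter_compound_set(
    compounds: Iterable[StandardizedCompound],
    min_heavy_atoms_exclusive: int = 19,
    max_mw_exclusive: float = 500.0,
) -> list[StandardizedCompound]:
    """Drug-like windowing: heavy-atom count strictly greater than the
    threshold AND molecular weight strictly below the cap (the screening-
    collection filter used to assemble the compound->patents query set)."""
    return [
        c
        for c in compounds
        if c.heavy_atom_count > min_heavy_atoms_exclusive
        and c.mol_weight < max_mw_exclusive
    ]
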