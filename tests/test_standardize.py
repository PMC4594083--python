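"""Structure reading and match-key standardization."""

import pytest
from rdkit import Chem

from patentchem.standardize import (
    RawStructureRecord,
    StandardizationError,
    StandardizeOptions,
    count_components,
    filter_compound_set,
    normalize_nitro,
    read_structures,
    select_largest_fragment,
    standardize,
    strip_stereo,
)

METOPROLOL = "COCCc1ccc(OCC(O)CNC(C)C)cc1"
TARTARIC = "OC(=O)C(O)C(O)C(=O)O"
METOPROLOL_TARTRATE = f"{METOPROLOL}.{METOPROLOL}.{TARTARIC}"


def _rec(smiles, rid="r"):
    return RawStructureRecord(record_id=rid, structure=smiles)


def _key(smiles, **opts):
    return standardize(_rec(smiles), StandardizeOptions(**opts)).key_inchi


# ---------------------------------------------------------------------------
# reading


def _write_sdf(path, smiles_list, corrupt_at=None):
    blocks = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", f"mol{i}")
        block = Chem.MolToMolBlock(mol) + f">  <PATENT_ID>\nUS{4000000 + i}\n\n$$$$\n"
        if corrupt_at == i:
            # break the counts line so the molblock cannot be parsed
            block = "BROKEN HEADER LINE\n" + block
        blocks.append(block)
    path.write_text("".join(blocks))


def test_sdf_reading_preserves_count_and_routes_rejects(tmp_path):
    good = tmp_path / "good.sdf"
    _write_sdf(good, ["CCO", "c1ccccc1", "CC(=O)O"])
    result = read_structures(good, "sdf")
    assert len(result.records) == 3 and not result.rejects
    assert result.records[0].patent_ref == "US4000000"

    bad = tmp_path / "bad.sdf"
    _write_sdf(bad, ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "CCC"], corrupt_at=2)
    result = read_structures(bad, "sdf")
    assert len(result.records) == 4
    assert len(result.rejects) == 1 and result.rejects[0].position == 2


def test_smiles_tsv_field_mapping(tmp_path):
    p = tmp_path / "db.smi"
    p.write_text("# a comment line\nCCO\tUS4231938\nC#N\tEP1481667\t12\n")
    result = read_structures(p, "smiles_tsv")
    assert len(result.records) == 2
    assert result.records[0].structure == "CCO"
    assert result.records[0].patent_ref == "US4231938"
    # '#' inside a SMILES is a triple bond, not a comment
    assert result.records[1].structure == "C#N"
    assert result.records[1].annotations["corpus_count"] == "12"


def test_unknown_format_is_fatal(tmp_path):
    p = tmp_path / "x.smi"
    p.write_text("CCO\n")
    with pytest.raises(ValueError, match="unknown format"):
        read_structures(p, "mol2")


# ---------------------------------------------------------------------------
# fragment handling


def test_metoprolol_tartrate_largest_fragment():
    """The 2:1 tartrate salt keeps the 38-heavy-atom drug part; the
    discarded tartaric acid component has 10 heavy atoms."""
    frag = select_largest_fragment(METOPROLOL_TARTRATE)
    assert frag.GetNumHeavyAtoms() == 38
    assert Chem.MolFromSmiles(TARTARIC).GetNumHeavyAtoms() == 10


@pytest.mark.parametrize(
    "smiles,expected",
    [("CCO.C", "CCO"), ("CCO", "CCO"), ("CCCO.O.O.O", "CCCO")],
)
def test_largest_fragment_selection(smiles, expected):
    assert Chem.MolToSmiles(select_largest_fragment(smiles)) == expected


def test_largest_fragment_tie_breaks():
    # equal heavy atoms: higher molecular weight wins
    assert Chem.MolToSmiles(select_largest_fragment("CCO.CCS")) == "CCS"
    # equal heavy atoms and weight (constitutional isomers): lexicographic
    assert Chem.MolToSmiles(select_largest_fragment("COC.CCO")) == "CCO"


def test_largest_fragment_idempotent():
    once = select_largest_fragment(METOPROLOL_TARTRATE)
    twice = select_largest_fragment(once)
    assert Chem.MolToSmiles(once) == Chem.MolToSmiles(twice)


def test_empty_structure_errors():
    with pytest.raises(StandardizationError):
        select_largest_fragment("")


@pytest.mark.parametrize(
    "smiles,n",
    [(METOPROLOL_TARTRATE, 2), ("CCO", 1), ("c1ccccc1.CCO.[Na+]", 3)],
)
def test_count_components(smiles, n):
    assert count_components(smiles) == n


# ---------------------------------------------------------------------------
# nitro normalization


def test_nitro_representations_share_a_key():
    pentavalent = "O=N(=O)c1ccccc1"
    charged = "[O-][N+](=O)c1ccccc1"
    assert _key(pentavalent, normalize_nitro=True) == _key(charged, normalize_nitro=True)


def test_nitro_noop_on_ethanol():
    assert Chem.MolToSmiles(normalize_nitro("CCO")) == "CCO"


def test_dinitro_both_groups_rewritten():
    dinitro = "O=N(=O)c1ccc(N(=O)=O)cc1"
    hand = "[O-][N+](=O)c1ccc([N+](=O)[O-])cc1"
    assert _key(dinitro, normalize_nitro=True) == _key(hand, normalize_nitro=False)


def test_nitro_idempotent():
    m1 = normalize_nitro("O=N(=O)c1ccccc1")
    m2 = normalize_nitro(m1)
    assert Chem.MolToSmiles(m1) == Chem.MolToSmiles(m2)


# ---------------------------------------------------------------------------
# the full pipeline


def test_metoprolol_tartrate_standardization():
    sc = standardize(_rec(METOPROLOL_TARTRATE))
    assert sc.heavy_atom_count == 38
    assert sc.n_components == 2
    # the match key is a single metoprolol copy
    assert sc.key_inchi == standardize(_rec(METOPROLOL)).key_inchi


def test_enantiomers_collapse_under_stereo_stripping():
    r, s = "C[C@H](N)c1ccccc1", "C[C@@H](N)c1ccccc1"
    assert _key(r) != _key(s)
    assert _key(r, strip_stereo=True) == _key(s, strip_stereo=True)


def test_keys_invariant_under_atom_reordering():
    from patentchem.synthetic import load_pool

    pool = [m.smiles for m in load_pool() if m.role == "relevant"][:10]
    for smi in pool:
        mol = Chem.MolFromSmiles(smi)
        order = list(range(mol.GetNumAtoms()))[::-1]
        permuted = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        a, b = standardize(_rec(smi)), standardize(_rec(permuted))
        assert (a.key_inchi, a.key_smiles, a.key_nostereo) == (
            b.key_inchi,
            b.key_smiles,
            b.key_nostereo,
        )


def test_stereo_collapse_property():
    from patentchem.synthetic import load_pool

    stereo = [m.smiles for m in load_pool() if m.has_stereo][:8]
    assert stereo
    for smi in stereo:
        stripped = Chem.MolToSmiles(strip_stereo(smi))
        assert standardize(_rec(smi)).key_nostereo == standardize(_rec(stripped)).key_nostereo


def test_tautomers_keep_distinct_keys():
    """Imine and enamine forms must NOT match: standard InChI does not
    canonicalize this tautomerism and no extra tautomer matching is layered
    on top."""
    imine = "CC(C)=NC1CCCCC1"
    enamine = "C=C(C)NC1CCCCC1"
    assert _key(imine) != _key(enamine)
    keto, enol = "CC(=O)Cc1ccccc1", "CC(O)=Cc1ccccc1"
    assert _key(keto) != _key(enol)


def test_parse_failure_routes_to_rejects():
    from patentchem.standardize import standardize_all

    good = _rec("CCO", "ok")
    bad = _rec("not_a_smiles((", "bad")
    compounds, rejects = standardize_all([good, bad])
    assert [c.record_id for c in compounds] == ["ok"]
    assert [r.record_id for r in rejects] == ["bad"]


# ---------------------------------------------------------------------------
# descriptor filter


def test_filter_compound_set_boundaries_and_enumeration():
    smiles = {
        "c1ccc2cc3cc4ccccc4cc3cc2c1": False,  # 18 heavy: too small
        "CCCCCCCCCCCCCCCCCCC": False,  # 19 heavy: strict inequality
        "CCCCCCCCCCCCCCCCCCCC": True,  # 20 heavy, MW 282
        METOPROLOL: False,  # 19 heavy
        "O=C(NCCCCCCCCCCCC)c1ccc(-c2ccccc2)cc1": True,  # 25 heavy, MW < 500
        "ClC(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)C(Cl)(Cl)Cl": False,  # MW >> 500
    }
    compounds = [standardize(_rec(s, rid=s)) for s in smiles]
    kept = {c.record_id for c in filter_compound_set(compounds)}
    assert kept == {s for s, keep in smiles.items() if keep}
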