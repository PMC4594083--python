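"""Reduce compound records to match keys.

The classic pitfall in cross-database compound matching is the salt form:
a curated record of metoprolol tartrate (a 2:1 salt) must match a mined
record of plain metoprolol.  Largest-fragment reduction plus canonical
InChI/SMILES keys make the two comparable; nitro groups are rewritten to
one convention; tautomers deliberately stay distinct.
"""

from patentchem import RawStructureRecord, StandardizeOptions, standardize

metoprolol = "COCCc1ccc(OCC(O)CNC(C)C)cc1"
tartaric = "OC(=O)C(O)C(O)C(=O)O"
salt = f"{metoprolol}.{metoprolol}.{tartaric}"

sc = standardize(RawStructureRecord(record_id="metoprolol tartrate", structure=salt))
print(f"components: {sc.n_components} (metoprolol part + tartaric acid part)")
print(f"retained fragment heavy atoms: {sc.heavy_atom_count} (drug part, 2 copies)")
print(f"match key (InChI): {sc.key_inchi}")

free_base = standardize(RawStructureRecord(record_id="metoprolol", structure=metoprolol))
print(f"salt and free base share a key: {sc.key_inchi == free_base.key_inchi}")

# the two common ways of drawing a nitro group yield the same key
opts = StandardizeOptions(normalize_nitro=True)
pentavalent = standardize(RawStructureRecord("a", "O=N(=O)c1ccccc1"), opts)
charge_sep = standardize(RawStructureRecord("b", "[O-][N+](=O)c1ccccc1"), opts)
print(f"nitro conventions collapse: {pentavalent.key_inchi == charge_sep.key_inchi}")

# tautomers do NOT collapse: standard InChI keeps imine and enamine apart,
# and no further tautomer canonicalization is layered on top
imine = standardize(RawStructureRecord("i", "CC(C)=NC1CCCCC1"))
enamine = standardize(RawStructureRecord("e", "C=C(C)NC1CCCCC1"))
print(f"imine/enamine tautomers stay distinct: {imine.key_inchi != enamine.key_inchi}")

# enantiomers collapse only under the stereo-stripped key variant
r_amine = standardize(RawStructureRecord("r", "C[C@H](N)c1ccccc1"))
s_amine = standardize(RawStructureRecord("s", "C[C@@H](N)c1ccccc1"))
print(f"enantiomers, strict keys differ: {r_amine.key_inchi != s_amine.key_inchi}")
print(f"enantiomers, no-stereo keys equal: {r_amine.key_nostereo == s_amine.key_nostereo}")
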