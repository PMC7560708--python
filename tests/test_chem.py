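"""Standardization, canonical keying and single-atom mutation."""

import pytest
from hypothesis import given, strategies as st
from rdkit import Chem

from samcliff import (
    InvalidStructure,
    enumerate_mutant_keys,
    mutate_atom,
    standardize,
)
from samcliff.chem import strip_stereo_key


def _atom_index(mol, symbol):
    return next(a.GetIdx() for a in mol.mol.GetAtoms() if a.GetSymbol() == symbol)


def _renumbered_smiles(smiles, rng):
    """A non-canonical SMILES of the same structure with permuted atom order."""
    mol = Chem.MolFromSmiles(smiles)
    order = list(range(mol.GetNumAtoms()))
    rng.shuffle(order)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)


class TestStandardize:
    @pytest.mark.parametrize(
        "a, b",
        [
            ("c1ccncc1", "n1ccccc1"),
            ("c1ccccc1", "C1=CC=CC=C1"),
            ("OCC", "CCO"),
            ("Cc1ccncc1", "c1cc(C)ccn1"),
        ],
    )
    def test_canonical_key_is_representation_independent(self, a, b):
        assert standardize(a, "a").canonical_key == standardize(b, "b").canonical_key

    def test_formula_counts_heavy_atoms(self):
        assert standardize("c1ccncc1", "pyr").formula == {"C": 5, "N": 1}

    def test_salt_stripping_keeps_largest_organic_fragment(self):
        mol = standardize("CCO.Cl", "ethanol-hcl")
        assert mol.formula == {"C": 2, "O": 1}
        mol = standardize("[Na+].CC(=O)[O-]", "sodium-acetate")
        assert mol.formula == {"C": 2, "O": 2}
        # neutralized on the way
        assert mol.canonical_key == standardize("CC(=O)O", "x").canonical_key

    @pytest.mark.parametrize("bad", ["C1CC", "", "   ", "not-a-smiles", "C(C)(C)(C)(C)C"])
    def test_invalid_structures_are_rejected_not_kept(self, bad):
        with pytest.raises(InvalidStructure):
            standardize(bad, "bad")

    def test_min_heavy_atom_floor(self):
        standardize("CCO", "ok", min_heavy_atoms=3)
        with pytest.raises(InvalidStructure):
            standardize("CCO", "small", min_heavy_atoms=4)

    def test_isotopes_cleared(self):
        a = standardize("[13CH3]c1ccccc1", "labeled")
        b = standardize("Cc1ccccc1", "plain")
        assert a.canonical_key == b.canonical_key

    def test_stereo_kept_by_default_and_strippable(self):
        s = standardize("C[C@H](N)C(=O)O", "l-ala")
        r = standardize("C[C@@H](N)C(=O)O", "d-ala")
        assert s.canonical_key != r.canonical_key
        assert strip_stereo_key(s) == strip_stereo_key(r)
        flat = standardize("C[C@H](N)C(=O)O", "ala", keep_stereo=False)
        assert "@" not in flat.canonical_key

    def test_idempotence_of_standardization(self, mols, rng):
        for mol in mols.values():
            again = standardize(mol.canonical_key, mol.id)
            assert again.canonical_key == mol.canonical_key
            scrambled = standardize(_renumbered_smiles(mol.canonical_key, rng), "s")
            assert scrambled.canonical_key == mol.canonical_key


class TestMutateAtom:
    def test_ring_nitrogen_to_carbon_gives_benzene(self, mols):
        pyridine = mols["pyridine"]
        mutant = mutate_atom(pyridine, _atom_index(pyridine, "N"), "C")
        assert mutant is not None
        assert mutant.canonical_key == mols["benzene"].canonical_key

    def test_furan_oxygen_to_sulfur_gives_thiophene(self, mols):
        furan = mols["furan"]
        mutant = mutate_atom(furan, _atom_index(furan, "O"), "S")
        assert mutant.canonical_key == mols["thiophene"].canonical_key

    def test_valence_violating_mutation_yields_nothing(self):
        quat = standardize("C[N+](C)(C)C", "quat")
        assert mutate_atom(quat, _atom_index(quat, "N"), "O") is None

    def test_stereo_away_from_site_is_retained(self):
        ala = standardize("C[C@H](N)C(=O)O", "ala")
        mutant = mutate_atom(ala, _atom_index(ala, "N"), "O")
        assert mutant.canonical_key == standardize("C[C@H](O)C(=O)O", "lac").canonical_key

    def test_reversibility(self, mols):
        pyridine = mols["pyridine"]
        idx = _atom_index(pyridine, "N")
        benzene = mutate_atom(pyridine, idx, "C")
        back = [
            mutate_atom(benzene, a.GetIdx(), "N")
            for a in benzene.mol.GetAtoms()
            if a.GetSymbol() == "C"
        ]
        assert pyridine.canonical_key in {m.canonical_key for m in back if m}


class TestEnumerateMutantKeys:
    def test_benzene_has_one_distinct_aza_mutant(self, mols):
        keys = enumerate_mutant_keys(mols["benzene"], ("N-C",))
        assert len(keys) == 1
        assert keys[0].key == mols["pyridine"].canonical_key

    def test_pyridine_mutants_are_benzene_plus_three_diazines(self, mols):
        keys = {mk.key for mk in enumerate_mutant_keys(mols["pyridine"], ("N-C",))}
        expected = {
            mols["benzene"].canonical_key,
            mols["pyridazine"].canonical_key,
            mols["pyrimidine"].canonical_key,
            mols["pyrazine"].canonical_key,
        }
        assert keys == expected

    def test_single_atom_molecule(self):
        mol = standardize("C", "methane")
        keys = enumerate_mutant_keys(mol, ("O-C",))
        assert [mk.key for mk in keys] == ["O"]

    def test_dedup_equals_brute_force_over_all_atoms(self, mols):
        for name in ("benzene", "toluene", "furan", "pyrimidine"):
            mol = mols[name]
            keys = enumerate_mutant_keys(mol)
            brute = set()
            from samcliff.chem import _mutate_raw, directed_swaps

            for frm, to in directed_swaps(("N-C", "O-C", "N-O", "S-O")):
                for atom in mol.mol.GetAtoms():
                    if atom.GetSymbol() != frm:
                        continue
                    mut = _mutate_raw(mol.mol, atom.GetIdx(), to)
                    if mut is not None:
                        brute.add((Chem.MolToSmiles(mut), frm, to))
            assert {(mk.key, mk.from_element, mk.to_element) for mk in keys} == brute

    @given(data=st.data())
    def test_mutant_keys_invariant_to_parent_atom_order(self, data, mols):
        name = data.draw(st.sampled_from(["pyridine", "toluene", "furan"]))
        mol = mols[name]
        rdmol = Chem.MolFromSmiles(mol.canonical_key)
        order = data.draw(st.permutations(range(rdmol.GetNumAtoms())))
        scrambled = standardize(
            Chem.MolToSmiles(Chem.RenumberAtoms(rdmol, list(order)), canonical=False),
            "scrambled",
        )
        original = {(mk.key, mk.from_element, mk.to_element, mk.site, mk.parent_site)
                    for mk in enumerate_mutant_keys(mol)}
        permuted = {(mk.key, mk.from_element, mk.to_element, mk.site, mk.parent_site)
                    for mk in enumerate_mutant_keys(scrambled)}
        assert original == permuted
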