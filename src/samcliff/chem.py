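"""Molecule standardization, canonical keying, and single-atom mutation.

The identity currency throughout the package is the canonical SMILES of a
standardized structure (largest organic fragment, neutralized where a neutral
form exists, isotopes cleared, implicit hydrogens). Analog relationships are
detected by mutating one heavy atom at a time within the four admissible
element swaps (N-C, O-C, N-O, S-O) and joining on mutant canonical keys.

Stereochemistry is retained in canonical keys by default, so two compounds
that differ in stereochemistry *in addition to* an atom modification do not
pair; pass ``keep_stereo=False`` to relax this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import InvalidStructure

log = logging.getLogger(__name__)

# RDKit is chatty about every rejected mutant; errors surface as exceptions.
RDLogger.DisableLog("rdApp.*")

_PT = Chem.GetPeriodicTable()

#: The four admissible element swaps, rendered with the field's fixed labels.
SWAP_LABELS: Tuple[str, ...] = ("N-C", "O-C", "N-O", "S-O")

_LABEL_BY_PAIR: Dict[frozenset, str] = {
    frozenset({"N", "C"}): "N-C",
    frozenset({"O", "C"}): "O-C",
    frozenset({"N", "O"}): "N-O",
    frozenset({"S", "O"}): "S-O",
}

DEFAULT_SWAPS: Tuple[str, ...] = SWAP_LABELS


def swap_label(element_a: str, element_b: str) -> str:
    """Render an unordered element pair as its fixed swap label.

    Raises ``KeyError`` for a pair outside the admissible set.
    """
    return _LABEL_BY_PAIR[frozenset({element_a, element_b})]


def swap_elements(label: str) -> Tuple[str, str]:
    """Inverse of :func:`swap_label`: ``"N-C" -> ("N", "C")``."""
    a, b = label.split("-")
    if frozenset({a, b}) not in _LABEL_BY_PAIR:
        raise ValueError(f"not an admissible swap label: {label!r}")
    return a, b


def directed_swaps(swaps: Iterable[str]) -> List[Tuple[str, str]]:
    """Expand unordered swap labels into directed (from, to) element pairs."""
    out: List[Tuple[str, str]] = []
    for lab in swaps:
        a, b = swap_elements(lab)
        out.append((a, b))
        out.append((b, a))
    return out


@dataclass(eq=True)
class Molecule:
    """A standardized heavy-atom structure with a canonical textual key.

    ``canonical_key`` is identical for any atom-order permutation of the same
    structure and is the join currency for pair detection and ligand matching.
    ``formula`` counts heavy atoms only (hydrogens are implicit throughout).
    """

    id: str
    canonical_key: str
    formula: Dict[str, int]
    mol: Chem.Mol = field(compare=False, repr=False)

    @property
    def num_heavy_atoms(self) -> int:
        return sum(self.formula.values())


@dataclass(frozen=True)
class MutantKey:
    """Index entry for one valence-valid single-atom mutant of a parent.

    ``parent_site`` / ``site`` are canonical atom ranks of the mutated
    position in the parent and in the mutant, respectively; ``key`` is the
    mutant's canonical SMILES. No entry exists for mutations that fail
    valence sanitization.
    """

    parent_id: str
    from_element: str
    to_element: str
    parent_site: int
    site: int
    key: str

    @property
    def swap(self) -> str:
        return swap_label(self.from_element, self.to_element)


def _heavy_formula(mol: Chem.Mol) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
    return counts


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(
    smiles_string: str,
    id: str = "",
    *,
    keep_stereo: bool = True,
    min_heavy_atoms: int = 1,
) -> Molecule:
    """Parse and standardize a SMILES string into a :class:`Molecule`.

    Keeps the largest organic fragment (salt/solvent stripping), clears
    isotope labels, neutralizes charges where a chemically sensible neutral
    form exists, re-perceives aromaticity and computes the canonical key.

    Raises
    ------
    InvalidStructure
        For unparsable or valence-violating input, or when the surviving
        fragment has fewer than ``min_heavy_atoms`` heavy atoms. Callers in
        the curation layer count these as exclusions.
    """
    if not smiles_string or not smiles_string.strip():
        raise InvalidStructure("empty SMILES")
    mol = Chem.MolFromSmiles(smiles_string)
    if mol is None:
        raise InvalidStructure(f"unparsable or unsanitizable SMILES: {smiles_string!r}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
        pool = organic or list(frags)
        # largest fragment; canonical-SMILES tie-break keeps the choice stable
        mol = max(pool, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))

    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    mol = _UNCHARGER.uncharge(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - uncharger output normally sane
        raise InvalidStructure(f"sanitization failed for {smiles_string!r}: {exc}")
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)

    if mol.GetNumHeavyAtoms() < min_heavy_atoms:
        raise InvalidStructure(
            f"fragment below {min_heavy_atoms} heavy atoms: {smiles_string!r}"
        )
    key = Chem.MolToSmiles(mol)
    # re-parse so the stored graph is exactly the canonical form
    mol = Chem.MolFromSmiles(key)
    return Molecule(id=id, canonical_key=key, formula=_heavy_formula(mol), mol=mol)


def _mutate_raw(mol: Chem.Mol, atom_index: int, new_element: str) -> Optional[Chem.Mol]:
    """Substitute one heavy atom's element and re-sanitize; None on failure.

    The graph is kekulized before substitution so aromaticity is re-perceived
    from scratch rather than patched (pyridine -> benzene changes perception).
    Formal charge is preserved: a swap never doubles as a charge change.
    """
    rw = Chem.RWMol(mol)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Exception:
        return None
    atom = rw.GetAtomWithIdx(atom_index)
    atom.SetAtomicNum(_PT.GetAtomicNumber(new_element))
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(rw)
    except Exception:
        return None
    # drop stereo descriptors the mutation invalidated, keep the rest
    Chem.AssignStereochemistry(rw, cleanIt=True, force=True)
    return rw.GetMol()


def mutate_atom(mol: Molecule, atom_index: int, new_element: str) -> Optional[Molecule]:
    """Return the sanitized single-atom mutant, or ``None`` if none exists.

    ``None`` means the substitution violates valence rules (e.g. O cannot
    carry the four bonds of a quaternary nitrogen); callers treat it as
    "no such analog exists".
    """
    mutant = _mutate_raw(mol.mol, atom_index, new_element)
    if mutant is None:
        return None
    key = Chem.MolToSmiles(mutant)
    canon = Chem.MolFromSmiles(key)
    if canon is None:  # pragma: no cover - sanitized mutants re-parse
        return None
    return Molecule(
        id=f"{mol.id}|{atom_index}>{new_element}",
        canonical_key=key,
        formula=_heavy_formula(canon),
        mol=canon,
    )


def enumerate_mutant_keys(
    mol: Molecule, swaps: Sequence[str] = DEFAULT_SWAPS
) -> List[MutantKey]:
    """Enumerate all distinct valence-valid single-atom mutants of ``mol``.

    One entry per (mutant canonical key, directed swap); symmetry-equivalent
    atoms collapse onto the same entry, keeping the lowest canonical site
    ranks. The output is sorted and deterministic.
    """
    parent_ranks = list(Chem.CanonicalRankAtoms(mol.mol, breakTies=True))
    best: Dict[Tuple[str, str, str], MutantKey] = {}
    for frm, to in directed_swaps(swaps):
        for atom in mol.mol.GetAtoms():
            if atom.GetSymbol() != frm:
                continue
            idx = atom.GetIdx()
            mutant = _mutate_raw(mol.mol, idx, to)
            if mutant is None:
                continue
            key = Chem.MolToSmiles(mutant)
            site = list(Chem.CanonicalRankAtoms(mutant, breakTies=True))[idx]
            mk = MutantKey(
                parent_id=mol.id,
                from_element=frm,
                to_element=to,
                parent_site=parent_ranks[idx],
                site=site,
                key=key,
            )
            slot = (key, frm, to)
            prev = best.get(slot)
            if prev is None or (mk.site, mk.parent_site) < (prev.site, prev.parent_site):
                best[slot] = mk
    return sorted(
        best.values(), key=lambda m: (m.key, m.from_element, m.to_element, m.site)
    )


class Standardizer:
    """Memoizing wrapper around :func:`standardize`.

    Curation and pair enumeration standardize the same SMILES strings many
    times; the cache keys on the raw text and the standardization settings
    are fixed per instance.
    """

    def __init__(self, *, keep_stereo: bool = True, min_heavy_atoms: int = 1) -> None:
        self.keep_stereo = keep_stereo
        self.min_heavy_atoms = min_heavy_atoms
        self._cache: Dict[str, Molecule] = {}
        self._failures: Dict[str, str] = {}

    def __call__(self, smiles_string: str, id: str = "") -> Molecule:
        cached = self._cache.get(smiles_string)
        if cached is not None:
            return Molecule(
                id=id,
                canonical_key=cached.canonical_key,
                formula=dict(cached.formula),
                mol=cached.mol,
            )
        if smiles_string in self._failures:
            raise InvalidStructure(self._failures[smiles_string])
        try:
            mol = standardize(
                smiles_string,
                id,
                keep_stereo=self.keep_stereo,
                min_heavy_atoms=self.min_heavy_atoms,
            )
        except InvalidStructure as exc:
            self._failures[smiles_string] = str(exc)
            raise
        self._cache[smiles_string] = mol
        return mol


def strip_stereo_key(mol: Molecule) -> str:
    """Canonical key with stereo descriptors removed (ligand matching)."""
    return Chem.MolToSmiles(mol.mol, isomericSmiles=False)
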