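"""Synthetic ChEMBL-like fixtures with planted analog pairs and cliffs.

The generator builds series of small aromatic compounds in which the analog
relationships are known by construction and certified by an exhaustive
oracle: each series consists of a base structure plus two single-atom
mutants under the same directed swap, giving two atom-replacement pairs and
one atom-walk pair. Series are kept mutually un-pairable by assigning every
series a unique (heavy-atom count, halogen decoration) signature — an
analog pair requires identical heavy-atom counts and identical halogen
content, so distinct signatures make cross-series pairs impossible (this is
additionally asserted at generation time). Decoy compounds carry iodine,
which no series compound contains, and unique sizes, so they pair with
nothing.

Potencies are planted on the pPot scale with deterministic margins around
the 2.0 log-unit cliff boundary: compounds of a cliff series sit on a
ladder with 3.0 log-unit rungs; compounds of a non-cliff series sit within
0.4 log units of each other. Per-record replicate noise (Gaussian, sd 0.2,
clipped, re-centered per compound) leaves the aggregated mean exactly on
the planted value, so pipeline recovery of the planted truth is
deterministic despite the noise.

Everything is derived from a single integer seed; a fixed seed reproduces
byte-identical CSV text.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rdkit import Chem

from .chem import (
    DEFAULT_SWAPS,
    Molecule,
    _mutate_raw,
    directed_swaps,
    enumerate_mutant_keys,
    standardize,
    swap_label,
)
from .errors import DuplicateStructure, SizeLimit
from .pairs import AnalogPair, _ordered

#: exhaustive-oracle size bound (heavy atoms)
ORACLE_MAX_HEAVY = 14


# ---------------------------------------------------------------------------
# exhaustive oracle


def _exchange_raw(mol: Chem.Mol, i: int, j: int) -> Optional[Chem.Mol]:
    """Exchange the elements at positions i and j; None if unsanitizable."""
    rw = Chem.RWMol(mol)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Exception:
        return None
    ai, aj = rw.GetAtomWithIdx(i), rw.GetAtomWithIdx(j)
    zi, zj = ai.GetAtomicNum(), aj.GetAtomicNum()
    for atom, z in ((ai, zj), (aj, zi)):
        atom.SetAtomicNum(z)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(rw)
    except Exception:
        return None
    Chem.AssignStereochemistry(rw, cleanIt=True, force=True)
    return rw.GetMol()


def _formula_swap_delta(fa: Dict[str, int], fb: Dict[str, int]) -> Optional[frozenset]:
    """The element pair {X, Y} if fb = fa with one X replaced by Y, else None."""
    gained, lost = [], []
    for el in set(fa) | set(fb):
        d = fb.get(el, 0) - fa.get(el, 0)
        if d == 1:
            gained.append(el)
        elif d == -1:
            lost.append(el)
        elif d != 0:
            return None
    if len(gained) == 1 and len(lost) == 1:
        return frozenset({gained[0], lost[0]})
    return None


def oracle_pairs(
    compounds: Sequence[Molecule], swaps: Sequence[str] = DEFAULT_SWAPS
) -> List[AnalogPair]:
    """Brute-force reference enumeration of ar and aw pairs.

    For every unordered pair of compounds, tests all single-atom mutations
    of one member against the other's canonical key (ar) and all ordered
    position pairs for a heteroatom exchange (aw). This is the definitional
    truth the indexed join must reproduce exactly; it is restricted to
    molecules of at most ``ORACLE_MAX_HEAVY`` heavy atoms
    (:class:`SizeLimit` otherwise).
    """
    for c in compounds:
        if c.num_heavy_atoms > ORACLE_MAX_HEAVY:
            raise SizeLimit(
                f"{c.id}: {c.num_heavy_atoms} heavy atoms exceeds the "
                f"exhaustive bound of {ORACLE_MAX_HEAVY}"
            )
    seen: Dict[str, str] = {}
    for c in compounds:
        if c.canonical_key in seen and seen[c.canonical_key] != c.id:
            raise DuplicateStructure(
                f"{seen[c.canonical_key]!r} and {c.id!r} share a canonical key"
            )
        seen[c.canonical_key] = c.id

    admissible = {frozenset(swap_label_elements) for swap_label_elements in
                  (tuple(lbl.split("-")) for lbl in swaps)}
    directed = directed_swaps(swaps)
    pairs: List[AnalogPair] = []
    n = len(compounds)
    for x in range(n):
        for y in range(x + 1, n):
            a, b = compounds[x], compounds[y]
            delta = _formula_swap_delta(a.formula, b.formula)
            if delta is not None and delta in admissible:
                labels: Set[str] = set()
                for frm, to in directed:
                    if frozenset({frm, to}) != delta:
                        continue
                    for atom in a.mol.GetAtoms():
                        if atom.GetSymbol() != frm:
                            continue
                        mut = _mutate_raw(a.mol, atom.GetIdx(), to)
                        if mut is not None and Chem.MolToSmiles(mut) == b.canonical_key:
                            labels.add(swap_label(frm, to))
                for lbl in sorted(labels):
                    ca, cb, _, _ = _ordered(a.id, None, b.id, None)
                    pairs.append(AnalogPair(ca, cb, "ar", lbl))
            elif a.formula == b.formula:
                labels = set()
                atoms = list(a.mol.GetAtoms())
                for ai in atoms:
                    for aj in atoms:
                        i, j = ai.GetIdx(), aj.GetIdx()
                        if i >= j:
                            continue
                        ex, ey = ai.GetSymbol(), aj.GetSymbol()
                        if ex == ey or frozenset({ex, ey}) not in admissible:
                            continue
                        mut = _exchange_raw(a.mol, i, j)
                        if mut is not None and Chem.MolToSmiles(mut) == b.canonical_key:
                            labels.add(swap_label(ex, ey))
                for lbl in sorted(labels):
                    ca, cb, _, _ = _ordered(a.id, None, b.id, None)
                    pairs.append(AnalogPair(ca, cb, "aw", lbl))
    pairs.sort(key=lambda p: (p.compound_a, p.compound_b, p.kind, p.swap))
    return pairs


# ---------------------------------------------------------------------------
# random molecule batches (for oracle-equivalence certification)

_BATCH_SEEDS = (
    "Cc1ccccc1",
    "CCOc1ccccc1",
    "Cc1ccco1",
    "CCc1cccs1",
    "NCCc1ccccc1",
    "OCCOc1ccncc1",
    "CC(=O)Nc1ccccc1",
    "c1ccc2[nH]ccc2c1",
    "CN1CCNCC1",
    "O=C(O)Cc1ccccc1",
    "CSc1ccccc1",
    "OCc1ccncc1",
)


def random_molecules(
    n: int, rng: random.Random, swaps: Sequence[str] = DEFAULT_SWAPS
) -> List[Molecule]:
    """A batch of up to ``n`` distinct small molecules rich in analog pairs.

    Grown by random single-atom mutation walks from embedded seed scaffolds,
    so batches contain many genuine ar/aw relationships alongside unrelated
    structures. All molecules respect the oracle size bound.
    """
    start = standardize(rng.choice(_BATCH_SEEDS), "seed")
    pool: Dict[str, Molecule] = {start.canonical_key: start}
    keys: List[str] = [start.canonical_key]
    directed = directed_swaps(swaps)
    attempts = 0
    while len(pool) < n and attempts < 60 * n:
        attempts += 1
        parent = pool[rng.choice(keys)]
        atom = parent.mol.GetAtomWithIdx(rng.randrange(parent.mol.GetNumAtoms()))
        candidates = [to for frm, to in directed if frm == atom.GetSymbol()]
        if not candidates:
            continue
        mut = _mutate_raw(parent.mol, atom.GetIdx(), rng.choice(candidates))
        if mut is None or mut.GetNumHeavyAtoms() > ORACLE_MAX_HEAVY:
            continue
        key = Chem.MolToSmiles(mut)
        if key in pool:
            continue
        mol = standardize(key, "tmp")
        pool[mol.canonical_key] = mol
        keys.append(mol.canonical_key)
    out = []
    for idx, key in enumerate(sorted(pool)):
        m = pool[key]
        out.append(Molecule(id=f"M{idx:03d}", canonical_key=m.canonical_key,
                            formula=dict(m.formula), mol=m.mol))
    return out


# ---------------------------------------------------------------------------
# fixture generation

#: ring decorations with pairwise-distinct halogen multisets; each SMILES
#: starts at the (unsubstituted) attachment carbon so a tail can be prefixed
_RINGS = (
    "c1ccccc1",
    "c1ccc(F)cc1",
    "c1ccc(Cl)cc1",
    "c1ccc(Br)cc1",
    "c1cc(F)cc(F)c1",
    "c1cc(Cl)cc(Cl)c1",
    "c1cc(F)cc(Cl)c1",
    "c1cc(F)cc(Br)c1",
    "c1cc(Br)cc(Br)c1",
    "c1cc(Cl)cc(Br)c1",
    "c1c(F)cc(F)cc1F",
    "c1c(Cl)cc(Cl)cc1Cl",
    "c1c(F)cc(F)cc1Cl",
    "c1c(F)cc(Cl)cc1Cl",
)

_TARGET_FAMILIES = (
    ("Enzyme", "Kinase"),
    ("Enzyme", "Protease"),
    ("Membrane receptor", "Family A G protein-coupled receptor"),
    ("Enzyme", "Lyase"),
    ("Epigenetic regulator", "Eraser"),
    ("Transcription factor", "Nuclear receptor"),
    ("Enzyme", "Phosphodiesterase"),
    ("Enzyme", "Oxidoreductase"),
)

#: per-series tail skeletons keyed by the swap the series exercises;
#: "{pad}" is filled with extra carbons to reach the series' heavy-atom count
_TAILS = {
    "N-C": "C{pad}",    # alkyl tail; ring C -> N mutants (aza walk)
    "O-C": "CC{pad}",   # alkyl tail; tail C -> O mutants (ether/alcohol walk)
    "N-O": "NCCN{pad}", # diamine tail; N -> O mutants
    "S-O": "OCCO{pad}", # diether tail; O -> S mutants
}

_TAIL_DIRECTED = {
    "N-C": ("C", "N"),
    "O-C": ("C", "O"),
    "N-O": ("N", "O"),
    "S-O": ("O", "S"),
}

_HEAVY_RANGE = (10, 11, 12, 13, 14)

#: conservative bound on mutually un-pairable series signatures
MAX_SERIES = 60

_MEASUREMENTS = ("IC50", "Ki")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one generated fixture.

    ``pairs`` are the target-based analog pairs the pipeline must recover
    exactly; ``cliffs`` is the subset whose planted potency difference
    exceeds the 100-fold boundary; ``decoys`` lists compounds that must pair
    with nothing. ``ppot`` maps (compound, target, measurement) to the
    planted aggregated potency.
    """

    pairs: Tuple[AnalogPair, ...]
    cliffs: Tuple[AnalogPair, ...]
    decoys: Tuple[str, ...]
    ppot: Dict[Tuple[str, str, str], float] = field(compare=False, default_factory=dict)


@dataclass
class Fixture:
    """Generated fixture: CSV text blobs plus the planted truth."""

    activities_csv: str
    mappings_csv: str
    ligands_csv: str
    truth: PlantedTruth

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "activities": out / "activities.csv",
            "mappings": out / "mappings.csv",
            "ligands": out / "ligands.csv",
        }
        paths["activities"].write_text(self.activities_csv, encoding="utf-8")
        paths["mappings"].write_text(self.mappings_csv, encoding="utf-8")
        paths["ligands"].write_text(self.ligands_csv, encoding="utf-8")
        return paths


_ACTIVITY_HEADER = (
    "compound_id", "smiles", "target_id", "target_name", "target_class",
    "target_group", "organism", "assay_relationship", "assay_confidence",
    "assay_target_type", "measurement", "relation", "value", "units",
)


def _series_base(swap: str, ring: str, heavy_total: int) -> Optional[str]:
    tail_template = _TAILS[swap]
    fixed_heavy = standardize(tail_template.format(pad="") + ring, "t").num_heavy_atoms
    pad = heavy_total - fixed_heavy
    if pad < 0:
        return None
    return tail_template.format(pad="C" * pad) + ring


def _series_compounds(
    base: Molecule, swap: str, rng: random.Random
) -> Optional[List[Molecule]]:
    """Base plus two distinct mutants under the series' directed swap."""
    frm, to = _TAIL_DIRECTED[swap]
    mutants = [
        mk
        for mk in enumerate_mutant_keys(base, (swap,))
        if mk.from_element == frm and mk.to_element == to
    ]
    if len(mutants) < 2:
        return None
    picks = rng.sample(range(len(mutants)), 2)
    out = [base]
    for slot, p in enumerate(sorted(picks)):
        out.append(standardize(mutants[p].key, f"{base.id}_M{slot}"))
    return out


def _replicate_noise(n: int, rng: random.Random, sd: float = 0.2) -> List[float]:
    """Clipped, re-centered Gaussian noise: mean exactly 0, span < 1.0."""
    draws = [max(-0.45, min(0.45, rng.gauss(0.0, sd))) for _ in range(n)]
    mean = sum(draws) / n
    centered = [d - mean for d in draws]
    return centered


def _junk_records(rng: random.Random) -> List[List[str]]:
    """Records violating each curation criterion, one per reason."""
    base = dict(
        compound_id="", smiles="CCCCc1ccncc1", target_id="TJUNK",
        target_name="Junk target", target_class="Enzyme", target_group="Kinase",
        organism="Homo sapiens", assay_relationship="D", assay_confidence="9",
        assay_target_type="SINGLE PROTEIN", measurement="Ki", relation="=",
        value="10.0", units="nM",
    )
    variants = [
        ("organism", {"organism": "Rattus norvegicus"}),
        ("target_type", {"assay_target_type": "PROTEIN COMPLEX"}),
        ("relationship", {"assay_relationship": "H"}),
        ("confidence", {"assay_confidence": "8"}),
        ("measurement", {"measurement": "EC50"}),
        ("relation", {"relation": ">"}),
        ("units", {"units": "mg.kg-1"}),
        ("value", {"value": "-5"}),
        ("structure", {"smiles": "C1CC"}),
        ("structure_small", {"smiles": "CCO.Cl"}),  # largest fragment < 4 atoms
    ]
    rows = []
    for idx, (tag, override) in enumerate(variants):
        row = dict(base)
        row.update(override)
        row["compound_id"] = f"JUNK{idx:02d}"
        rows.append([row[col] for col in _ACTIVITY_HEADER])
    return rows


def generate_fixture(
    n_series: int,
    seed: int,
    *,
    swaps: Sequence[str] = DEFAULT_SWAPS,
    fraction_cliffs: float = 0.5,
    fraction_xray: float = 0.6,
    fraction_both_analogs: float = 0.15,
    n_decoys: Optional[int] = None,
    include_junk: bool = True,
) -> Fixture:
    """Generate a ChEMBL-like fixture with planted pairs, cliffs and decoys.

    Each of the ``n_series`` series contributes three compounds (a base and
    two same-swap mutants), three analog pairs (two ar, one aw), one target
    and one measurement type. ``fraction_cliffs`` of the series are planted
    as all-cliff series; X-ray mapping/ligand tables co-crystallize the most
    potent analog for ``fraction_xray`` of the cliff series (and also the
    weakest analog for ``fraction_both_analogs`` of those).

    Raises ``ValueError`` when ``n_series`` exceeds the number of mutually
    un-pairable series signatures (:data:`MAX_SERIES`).
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    if n_series > MAX_SERIES:
        raise ValueError(f"n_series is capped at {MAX_SERIES}")
    rng = random.Random(seed)

    # Assign each series a unique (heavy count, ring) signature feasible for
    # its swap skeleton; uniqueness is what precludes cross-series pairing.
    combos = [(h, r) for r in range(len(_RINGS)) for h in _HEAVY_RANGE]
    min_heavy = {
        (swap, r): standardize(
            _TAILS[swap].format(pad="") + _RINGS[r], "t"
        ).num_heavy_atoms
        for swap in swaps
        for r in range(len(_RINGS))
    }
    signatures: List[Tuple[int, int, str]] = []
    used = [False] * len(combos)
    for k in range(n_series):
        swap = swaps[k % len(swaps)]
        for idx, (h, r) in enumerate(combos):
            if not used[idx] and h >= min_heavy[(swap, r)]:
                used[idx] = True
                signatures.append((h, r, swap))
                break
        else:  # pragma: no cover - MAX_SERIES keeps this unreachable
            raise RuntimeError("ran out of un-pairable series signatures")

    activity_rows: List[List[str]] = []
    mapping_rows: List[List[str]] = []
    ligand_rows: List[List[str]] = []
    truth_pairs: List[AnalogPair] = []
    truth_cliffs: List[AnalogPair] = []
    planted_ppot: Dict[Tuple[str, str, str], float] = {}
    all_mutant_sets: Dict[str, Set] = {}
    series_targets: List[Tuple[str, str, str, str]] = []
    n_pdb = 0

    for k in range(n_series):
        heavy, ring_idx, swap = signatures[k]
        base_smiles = _series_base(swap, _RINGS[ring_idx], heavy)
        if base_smiles is None:  # pragma: no cover - signatures sized to fit
            raise RuntimeError("series signature too small for its tail skeleton")
        base = standardize(base_smiles, f"C{k:03d}_0")
        compounds = _series_compounds(base, swap, rng)
        if compounds is None:  # pragma: no cover - all skeletons admit 2 mutants
            raise RuntimeError(f"series skeleton admits <2 mutants: {base_smiles}")
        compounds = [
            Molecule(id=f"C{k:03d}_{i}", canonical_key=c.canonical_key,
                     formula=dict(c.formula), mol=c.mol)
            for i, c in enumerate(compounds)
        ]

        target_id = f"T{k:03d}"
        measurement = _MEASUREMENTS[k % 2]
        t_class, t_group = _TARGET_FAMILIES[k % len(_TARGET_FAMILIES)]
        series_targets.append((target_id, measurement, t_class, t_group))

        structural = oracle_pairs(compounds, swaps)
        series_pairs = [
            replace(p, target_id=target_id, measurement=measurement)
            for p in structural
        ]
        truth_pairs.extend(series_pairs)

        is_cliff_series = rng.random() < fraction_cliffs
        base_ppot = rng.uniform(4.0, 5.5)
        ordered = sorted(compounds, key=lambda c: c.canonical_key)
        ppots: Dict[str, float] = {}
        for rank, comp in enumerate(ordered):
            if is_cliff_series:
                ppots[comp.id] = base_ppot + 3.0 * rank
            else:
                ppots[comp.id] = base_ppot + rng.uniform(-0.2, 0.2)
        if is_cliff_series:
            truth_cliffs.extend(series_pairs)

        for comp in compounds:
            p = ppots[comp.id]
            planted_ppot[(comp.id, target_id, measurement)] = p
            n_rep = rng.randint(1, 3)
            for noise in _replicate_noise(n_rep, rng):
                value_nm = 10.0 ** (9.0 - (p + noise))
                activity_rows.append([
                    comp.id, comp.canonical_key, target_id, f"Target {k:03d}",
                    t_class, t_group, "Homo sapiens", "D", "9", "SINGLE PROTEIN",
                    measurement, "=", repr(value_nm), "nM",
                ])
            all_mutant_sets[comp.id] = {
                (mk.key, mk.from_element, mk.to_element)
                for mk in enumerate_mutant_keys(comp, swaps)
            } | {("OWN", comp.canonical_key, "")}

        if is_cliff_series and rng.random() < fraction_xray:
            uniprot = f"P{10000 + k}"
            most_potent = max(compounds, key=lambda c: ppots[c.id])
            pdb_id = f"9A{n_pdb:02d}"
            n_pdb += 1
            mapping_rows.append([target_id, uniprot, pdb_id])
            ligand_rows.append([pdb_id, "LIG", most_potent.canonical_key])
            if rng.random() < fraction_both_analogs:
                weakest = min(compounds, key=lambda c: ppots[c.id])
                pdb_id2 = f"9A{n_pdb:02d}"
                n_pdb += 1
                mapping_rows.append([target_id, uniprot, pdb_id2])
                ligand_rows.append([pdb_id2, "LIG", weakest.canonical_key])

    # decoys: iodoalkanes of pairwise-distinct sizes. No series compound
    # contains iodine and no two decoys share a heavy-atom count, so decoys
    # pair with nothing (certified below like everything else).
    if n_decoys is None:
        n_decoys = max(2, n_series // 5)
    n_decoys = min(n_decoys, ORACLE_MAX_HEAVY - 3)
    decoy_ids: List[str] = []
    for d in range(n_decoys):
        smiles = "IC" + "C" * (d + 2)
        decoy = standardize(smiles, f"D{d:03d}")
        decoy_ids.append(decoy.id)
        target_id, measurement, t_class, t_group = series_targets[
            d % len(series_targets)
        ]
        p = rng.uniform(4.0, 9.0)
        planted_ppot[(decoy.id, target_id, measurement)] = p
        activity_rows.append([
            decoy.id, decoy.canonical_key, target_id, f"Target {target_id[1:]}",
            t_class, t_group, "Homo sapiens", "D", "9", "SINGLE PROTEIN",
            measurement, "=", repr(10.0 ** (9.0 - p)), "nM",
        ])
        all_mutant_sets[decoy.id] = {
            (mk.key, mk.from_element, mk.to_element)
            for mk in enumerate_mutant_keys(decoy, swaps)
        } | {("OWN", decoy.canonical_key, "")}

    _assert_no_unplanned_relations(all_mutant_sets, truth_pairs)

    if include_junk:
        activity_rows.extend(_junk_records(rng))

    return Fixture(
        activities_csv=_render_csv(_ACTIVITY_HEADER, activity_rows),
        mappings_csv=_render_csv(("target_chembl_id", "uniprot", "pdb_id"), mapping_rows),
        ligands_csv=_render_csv(("pdb_id", "ligand_code", "smiles"), ligand_rows),
        truth=PlantedTruth(
            pairs=tuple(truth_pairs),
            cliffs=tuple(truth_cliffs),
            decoys=tuple(decoy_ids),
            ppot=planted_ppot,
        ),
    )


def _assert_no_unplanned_relations(
    mutant_sets: Dict[str, Set], planted: Sequence[AnalogPair]
) -> None:
    """Certify that no analog relation exists outside the planted truth.

    Two compounds are relatable iff one's mutant key set contains the
    other's own key (ar) or the sets share a (mutant, directed swap) entry
    (aw); any such contact between compounds not planted as a pair would
    corrupt the fixture, so it is a hard error.
    """
    planted_ids = {frozenset({p.compound_a, p.compound_b}) for p in planted}
    ids = sorted(mutant_sets)
    own = {cid: next(k for k in mutant_sets[cid] if k[0] == "OWN")[1] for cid in ids}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            if frozenset({a, b}) in planted_ids:
                continue
            sa, sb = mutant_sets[a], mutant_sets[b]
            ar_hit = any(k[0] == own[b] for k in sa if k[0] != "OWN") or any(
                k[0] == own[a] for k in sb if k[0] != "OWN"
            )
            aw_hit = bool(
                {k for k in sa if k[0] != "OWN"} & {k for k in sb if k[0] != "OWN"}
            )
            if ar_hit or aw_hit:
                raise RuntimeError(
                    f"fixture corrupt: unplanned analog relation {a} / {b}"
                )


def _render_csv(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()
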