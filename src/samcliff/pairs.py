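"""Enumeration of single-atom analog pairs (atom replacements and atom walks).

Two compounds form an *atom-replacement* (ar) pair when some single-atom
mutation of one, within the admissible swaps, yields exactly the other's
canonical key; their heavy-atom formulas then differ by one decrement and
one increment. They form an *atom-walk* (aw) pair when a single heteroatom
occupies a different position in otherwise identical structures; formulas
are identical.

Detection is a join on mutant canonical keys rather than an all-pairs
structure comparison:

* ar: index every valence-valid single-atom mutant of every compound; a
  pair exists exactly when a mutant key equals another compound's own key.
* aw: two compounds A and B are positional-exchange analogs iff they
  produce the SAME mutant under the SAME directed swap at different sites.
  (If A carries X at i and Y at j while B carries Y at i and X at j,
  mutating the Y of either one to X gives the common all-X intermediate;
  conversely a shared mutant means both are one Y-placement away from the
  same intermediate, i.e. they differ by exactly that exchange.)

This is near-linear in the total atom count and provably equivalent to the
definitional pairwise test; the test suite certifies the equivalence against
an exhaustive oracle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .chem import DEFAULT_SWAPS, Molecule, MutantKey, enumerate_mutant_keys, swap_label
from .curation import CompoundPotency
from .errors import DuplicateStructure


@dataclass(eq=True, frozen=True)
class AnalogPair:
    """An unordered pair of analogs related by one atom modification.

    ``compound_a`` < ``compound_b`` lexicographically. ``site_a``/``site_b``
    are canonical atom ranks of the modified position in each compound and
    are annotations only (excluded from equality). ``target_id`` and
    ``measurement`` are set once the pair is activity-restricted.
    """

    compound_a: str
    compound_b: str
    kind: str  # "ar" | "aw"
    swap: str  # "N-C" | "O-C" | "N-O" | "S-O"
    site_a: Optional[int] = field(default=None, compare=False)
    site_b: Optional[int] = field(default=None, compare=False)
    target_id: Optional[str] = None
    measurement: Optional[str] = None

    def __post_init__(self) -> None:
        if self.compound_a >= self.compound_b:
            raise ValueError("pair must be stored with compound_a < compound_b")


def _check_unique(compounds: Sequence[Molecule]) -> None:
    seen: Dict[str, str] = {}
    for c in compounds:
        other = seen.get(c.canonical_key)
        if other is not None and other != c.id:
            raise DuplicateStructure(
                f"compounds {other!r} and {c.id!r} share canonical key {c.canonical_key!r}"
            )
        seen[c.canonical_key] = c.id


def _ordered(
    id_x: str, site_x: Optional[int], id_y: str, site_y: Optional[int]
) -> Tuple[str, str, Optional[int], Optional[int]]:
    if id_x < id_y:
        return id_x, id_y, site_x, site_y
    return id_y, id_x, site_y, site_x


def _merge_site(
    store: Dict[Tuple[str, str, str], Tuple[int, int]],
    key: Tuple[str, str, str],
    sites: Tuple[int, int],
) -> None:
    prev = store.get(key)
    if prev is None or sites < prev:
        store[key] = sites


def find_replacement_pairs(
    compounds: Sequence[Molecule], swaps: Sequence[str] = DEFAULT_SWAPS
) -> List[AnalogPair]:
    """All ar pairs within ``compounds`` under the admissible ``swaps``.

    Each unordered pair is reported once per distinct swap type, with the
    lowest canonical site ranks as the site annotation. Raises
    :class:`DuplicateStructure` if two inputs share a canonical key.
    """
    _check_unique(compounds)
    by_key = {c.canonical_key: c for c in compounds}
    found: Dict[Tuple[str, str, str], Tuple[int, int]] = {}
    for comp in compounds:
        for mk in enumerate_mutant_keys(comp, swaps):
            hit = by_key.get(mk.key)
            if hit is None or hit.id == comp.id:
                continue
            a, b, sa, sb = _ordered(comp.id, mk.parent_site, hit.id, mk.site)
            _merge_site(found, (a, b, mk.swap), (sa, sb))
    return _build_pairs(found, "ar")


def find_walk_pairs(
    compounds: Sequence[Molecule], swaps: Sequence[str] = DEFAULT_SWAPS
) -> List[AnalogPair]:
    """All aw pairs within ``compounds``: a single heteroatom relocates.

    Implemented as the shared-mutant join described in the module docstring.
    Pairs whose exchange sites are symmetry-equivalent (the exchange maps a
    structure onto itself) never arise because both compounds would share a
    canonical key, which is rejected upfront.
    """
    _check_unique(compounds)
    shared: Dict[Tuple[str, str, str], List[Tuple[str, int]]] = {}
    for comp in compounds:
        for mk in enumerate_mutant_keys(comp, swaps):
            shared.setdefault((mk.key, mk.from_element, mk.to_element), []).append(
                (comp.id, mk.parent_site)
            )
    found: Dict[Tuple[str, str, str], Tuple[int, int]] = {}
    for (key, frm, to), parents in shared.items():
        if len(parents) < 2:
            continue
        label = swap_label(frm, to)
        for i in range(len(parents)):
            for j in range(i + 1, len(parents)):
                (id_x, site_x), (id_y, site_y) = parents[i], parents[j]
                if id_x == id_y:
                    continue
                a, b, sa, sb = _ordered(id_x, site_x, id_y, site_y)
                _merge_site(found, (a, b, label), (sa, sb))
    return _build_pairs(found, "aw")


def _build_pairs(
    found: Dict[Tuple[str, str, str], Tuple[int, int]], kind: str
) -> List[AnalogPair]:
    return [
        AnalogPair(
            compound_a=a,
            compound_b=b,
            kind=kind,
            swap=swap,
            site_a=sa,
            site_b=sb,
        )
        for (a, b, swap), (sa, sb) in sorted(found.items())
    ]


def find_pairs(
    compounds: Sequence[Molecule], swaps: Sequence[str] = DEFAULT_SWAPS
) -> List[AnalogPair]:
    """Convenience: ar and aw pairs together (disjoint by construction)."""
    return find_replacement_pairs(compounds, swaps) + find_walk_pairs(compounds, swaps)


def restrict_to_shared_activity(
    pairs: Sequence[AnalogPair], potencies: Sequence[CompoundPotency]
) -> List[AnalogPair]:
    """Expand structural pairs into target-based pairs.

    A pair is kept once per (target, measurement) under which *both*
    compounds have a curated potency; Ki and IC50 never mix.
    """
    activity: Dict[str, Set[Tuple[str, str]]] = {}
    for p in potencies:
        activity.setdefault(p.compound_id, set()).add((p.target_id, p.measurement))
    out: List[AnalogPair] = []
    for pair in pairs:
        shared = activity.get(pair.compound_a, set()) & activity.get(
            pair.compound_b, set()
        )
        for target_id, measurement in sorted(shared):
            out.append(replace(pair, target_id=target_id, measurement=measurement))
    out.sort(
        key=lambda p: (
            p.compound_a,
            p.compound_b,
            p.kind,
            p.swap,
            p.target_id or "",
            p.measurement or "",
        )
    )
    return out


def write_pairs_csv(
    pairs: Sequence[AnalogPair], molecules: Mapping[str, Molecule], path
) -> None:
    """Write a pair table with canonical SMILES for both compounds."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "compound_a", "compound_b", "smiles_a", "smiles_b",
                "kind", "swap", "target_id", "measurement",
            ]
        )
        for p in pairs:
            writer.writerow(
                [
                    p.compound_a,
                    p.compound_b,
                    molecules[p.compound_a].canonical_key,
                    molecules[p.compound_b].canonical_key,
                    p.kind,
                    p.swap,
                    p.target_id or "",
                    p.measurement or "",
                ]
            )
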