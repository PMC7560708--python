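"""Association of cliffs with X-ray complex structures.

Targets are mapped (ChEMBL target ID -> UniProt accession -> PDB entry IDs)
via local tables, and each mapped PDB entry's co-crystallized ligand is
compared against the cliff's two analogs by canonical-key identity. Ligand
matching is stereo-insensitive by default because chemical-component records
frequently omit or re-derive stereocenters; matches made only under stereo
relaxation are flagged. No network access is performed — mapping and ligand
tables are consumed as CSV files.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .chem import Molecule, Standardizer, strip_stereo_key
from .cliffs import ActivityCliff
from .errors import InvalidStructure

log = logging.getLogger(__name__)

_PDB_ID_RE = re.compile(r"^[0-9A-Za-z]{4}$")


@dataclass(frozen=True)
class TargetMapping:
    """One target's UniProt accession and associated PDB entries."""

    target_chembl_id: str
    uniprot: str
    pdb_ids: Tuple[str, ...]


@dataclass(frozen=True)
class PdbLigand:
    """A co-crystallized small-molecule component of one PDB entry."""

    pdb_id: str
    ligand_code: str
    smiles: str


def is_valid_pdb_id(pdb_id: str) -> bool:
    return bool(_PDB_ID_RE.match(pdb_id))


def read_mappings_csv(path) -> List[TargetMapping]:
    """Read target->UniProt->PDB rows (one PDB ID per row) and group them."""
    grouped: Dict[Tuple[str, str], List[str]] = {}
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pdb_id = row["pdb_id"].strip()
            if not is_valid_pdb_id(pdb_id):
                log.warning("skipping invalid PDB ID %r", pdb_id)
                continue
            key = (row["target_chembl_id"], row["uniprot"])
            if pdb_id not in grouped.setdefault(key, []):
                grouped[key].append(pdb_id)
    return [
        TargetMapping(target_chembl_id=t, uniprot=u, pdb_ids=tuple(sorted(ids)))
        for (t, u), ids in sorted(grouped.items())
    ]


def read_ligands_csv(path) -> List[PdbLigand]:
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        out = []
        for row in reader:
            pdb_id = row["pdb_id"].strip()
            if not is_valid_pdb_id(pdb_id):
                log.warning("skipping ligand with invalid PDB ID %r", pdb_id)
                continue
            out.append(
                PdbLigand(
                    pdb_id=pdb_id,
                    ligand_code=row["ligand_code"],
                    smiles=row["smiles"],
                )
            )
        return out


def ligand_matches(
    ligand: Molecule, compound: Molecule, *, stereo_sensitive: bool = False
) -> bool:
    """True iff the ligand and the compound are the same structure.

    With ``stereo_sensitive=False`` (default) the comparison ignores stereo
    descriptors, so an enantiomeric component record still matches.
    """
    if ligand.canonical_key == compound.canonical_key:
        return True
    if stereo_sensitive:
        return False
    return strip_stereo_key(ligand) == strip_stereo_key(compound)


def annotate_cliffs(
    cliffs: Sequence[ActivityCliff],
    mappings: Sequence[TargetMapping],
    ligands: Sequence[PdbLigand],
    *,
    stereo_sensitive: bool = False,
    standardizer: Optional[Standardizer] = None,
) -> List[ActivityCliff]:
    """Attach matching PDB entries (and UniProt accessions) to cliffs.

    A PDB entry is attached when it is reachable from the cliff's target
    mapping *and* one of its ligands matches an analog. ``pdb_ids`` come out
    lexicographically sorted, with a parallel ``pdb_roles`` entry saying
    which analog ("potent", "weak" or "both") is co-crystallized. Cliffs on
    unmapped targets come back unchanged with empty ``pdb_ids``. PDB entries
    referenced by a mapping but absent from the ligand table are logged and
    skipped.
    """
    if standardizer is None:
        standardizer = Standardizer()
    target_to_mapping: Dict[str, TargetMapping] = {
        m.target_chembl_id: m for m in mappings
    }
    ligands_by_pdb: Dict[str, List[Molecule]] = {}
    for lig in ligands:
        try:
            mol = standardizer(lig.smiles, f"{lig.pdb_id}:{lig.ligand_code}")
        except InvalidStructure as exc:
            log.warning(
                "skipping ligand %s of %s: %s", lig.ligand_code, lig.pdb_id, exc
            )
            continue
        ligands_by_pdb.setdefault(lig.pdb_id, []).append(mol)

    out: List[ActivityCliff] = []
    for cliff in cliffs:
        mapping = target_to_mapping.get(cliff.target_chembl_id)
        if mapping is None:
            out.append(replace(cliff, pdb_ids=(), pdb_roles=()))
            continue
        weak = standardizer(cliff.smiles_weak, cliff.compound_weak)
        potent = standardizer(cliff.smiles_potent, cliff.compound_potent)
        hits: List[Tuple[str, str]] = []
        for pdb_id in sorted(mapping.pdb_ids):
            entry_ligands = ligands_by_pdb.get(pdb_id)
            if entry_ligands is None:
                log.info("no ligand records for mapped PDB entry %s", pdb_id)
                continue
            has_weak = any(
                ligand_matches(l, weak, stereo_sensitive=stereo_sensitive)
                for l in entry_ligands
            )
            has_potent = any(
                ligand_matches(l, potent, stereo_sensitive=stereo_sensitive)
                for l in entry_ligands
            )
            if has_weak and has_potent:
                hits.append((pdb_id, "both"))
            elif has_potent:
                hits.append((pdb_id, "potent"))
            elif has_weak:
                hits.append((pdb_id, "weak"))
        out.append(
            replace(
                cliff,
                target_uniprot=mapping.uniprot,
                pdb_ids=tuple(h[0] for h in hits),
                pdb_roles=tuple(h[1] for h in hits),
            )
        )
    return out


def write_mappings_csv(mappings: Sequence[TargetMapping], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_chembl_id", "uniprot", "pdb_id"])
        for m in mappings:
            for pdb_id in m.pdb_ids:
                writer.writerow([m.target_chembl_id, m.uniprot, pdb_id])


def write_ligands_csv(ligands: Sequence[PdbLigand], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pdb_id", "ligand_code", "smiles"])
        for lig in ligands:
            writer.writerow([lig.pdb_id, lig.ligand_code, lig.smiles])
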