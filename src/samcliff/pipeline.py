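"""End-to-end orchestration: records -> potencies -> pairs -> cliffs -> X-ray.

This is the module the CLI and the reproduction script drive; each stage is
also usable on its own. Structural duplicates among curated compounds (two
compound IDs with the same canonical key) are collapsed onto the
lexicographically smallest ID before pair enumeration, which requires
structurally unique input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import DEFAULT_SWAPS, Molecule, Standardizer
from .cliffs import ActivityCliff, call_cliffs, summarize, write_dataset
from .curation import (
    ActivityRecord,
    CompoundPotency,
    aggregate_potencies,
    filter_records,
    read_activity_csv,
    target_table,
    write_exclusions_csv,
    write_potency_csv,
)
from .pairs import (
    AnalogPair,
    find_pairs,
    restrict_to_shared_activity,
    write_pairs_csv,
)
from .structures import (
    PdbLigand,
    TargetMapping,
    annotate_cliffs,
    read_ligands_csv,
    read_mappings_csv,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a pipeline run produces, stage by stage."""

    kept_records: List[ActivityRecord]
    exclusions: Dict[str, int]
    potencies: List[CompoundPotency]
    n_discarded_groups: int
    molecules: Dict[str, Molecule]
    structural_pairs: List[AnalogPair]
    target_pairs: List[AnalogPair]
    cliffs: List[ActivityCliff]
    summary_by_target: pd.DataFrame = field(repr=False, default=None)
    summary_by_swap: pd.DataFrame = field(repr=False, default=None)

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "potencies": out / "potencies.csv",
            "exclusions": out / "exclusions.csv",
            "pairs": out / "pairs.csv",
            "cliffs": out / "sam_acs.csv",
            "summary_by_target": out / "summary_by_target.csv",
            "summary_by_swap": out / "summary_by_swap.csv",
        }
        write_potency_csv(self.potencies, self.molecules, paths["potencies"])
        write_exclusions_csv(self.exclusions, paths["exclusions"])
        write_pairs_csv(self.target_pairs, self.molecules, paths["pairs"])
        write_dataset(self.cliffs, paths["cliffs"])
        self.summary_by_target.to_csv(paths["summary_by_target"], index=False)
        self.summary_by_swap.to_csv(paths["summary_by_swap"], index=False)
        return paths


def curate(
    records: Sequence[ActivityRecord],
    *,
    standardizer: Optional[Standardizer] = None,
    min_heavy_atoms: int = 4,
    max_span: float = 1.0,
) -> Tuple[List[ActivityRecord], Dict[str, int], List[CompoundPotency], int]:
    if standardizer is None:
        standardizer = Standardizer(min_heavy_atoms=min_heavy_atoms)
    kept, tally = filter_records(records, standardizer=standardizer)
    potencies, n_discarded = aggregate_potencies(kept, max_span=max_span)
    return kept, tally, potencies, n_discarded


def _curated_molecules(
    kept: Sequence[ActivityRecord],
    potencies: Sequence[CompoundPotency],
    standardizer: Standardizer,
) -> Dict[str, Molecule]:
    """Standardized structure per curated compound, deduplicated.

    Compounds whose canonical key collides with a smaller compound ID are
    dropped (with a log message) so that pair enumeration sees structurally
    unique input.
    """
    with_potency = {p.compound_id for p in potencies}
    smiles_by_id: Dict[str, str] = {}
    for rec in kept:
        if rec.compound_id in with_potency and rec.compound_id not in smiles_by_id:
            smiles_by_id[rec.compound_id] = rec.smiles
    by_key: Dict[str, str] = {}
    molecules: Dict[str, Molecule] = {}
    for cid in sorted(smiles_by_id):
        mol = standardizer(smiles_by_id[cid], cid)
        holder = by_key.get(mol.canonical_key)
        if holder is not None:
            log.info(
                "dropping %s: same structure as %s (%s)",
                cid, holder, mol.canonical_key,
            )
            continue
        by_key[mol.canonical_key] = cid
        molecules[cid] = mol
    return molecules


def run_pipeline(
    records: Sequence[ActivityRecord],
    mappings: Optional[Sequence[TargetMapping]] = None,
    ligands: Optional[Sequence[PdbLigand]] = None,
    *,
    swaps: Sequence[str] = DEFAULT_SWAPS,
    fold_threshold: float = 100.0,
    keep_stereo: bool = True,
    min_heavy_atoms: int = 4,
    max_span: float = 1.0,
    stereo_sensitive_ligands: bool = False,
) -> PipelineResult:
    """Run curation, pair enumeration, cliff calling and X-ray annotation."""
    standardizer = Standardizer(keep_stereo=keep_stereo, min_heavy_atoms=min_heavy_atoms)
    kept, tally, potencies, n_discarded = curate(
        records, standardizer=standardizer, max_span=max_span
    )
    molecules = _curated_molecules(kept, potencies, standardizer)
    potencies = [p for p in potencies if p.compound_id in molecules]
    compounds = [molecules[cid] for cid in sorted(molecules)]
    structural = find_pairs(compounds, swaps)
    target_pairs = restrict_to_shared_activity(structural, potencies)
    cliffs = call_cliffs(
        target_pairs,
        potencies,
        fold_threshold,
        targets=target_table(kept),
        smiles={cid: m.canonical_key for cid, m in molecules.items()},
    )
    if mappings is not None:
        cliffs = annotate_cliffs(
            cliffs,
            mappings,
            ligands or [],
            stereo_sensitive=stereo_sensitive_ligands,
            standardizer=Standardizer(keep_stereo=keep_stereo),
        )
    by_target, by_swap = summarize(cliffs)
    return PipelineResult(
        kept_records=kept,
        exclusions=tally,
        potencies=potencies,
        n_discarded_groups=n_discarded,
        molecules=molecules,
        structural_pairs=structural,
        target_pairs=target_pairs,
        cliffs=cliffs,
        summary_by_target=by_target,
        summary_by_swap=by_swap,
    )


def run_pipeline_files(
    activities_path,
    mappings_path=None,
    ligands_path=None,
    **kwargs,
) -> PipelineResult:
    """File-based variant of :func:`run_pipeline`."""
    records = read_activity_csv(activities_path)
    mappings = read_mappings_csv(mappings_path) if mappings_path else None
    ligands = read_ligands_csv(ligands_path) if ligands_path else None
    return run_pipeline(records, mappings, ligands, **kwargs)
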