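"""Curation of raw activity records into per-compound potencies.

Records are kept only when every high-confidence criterion holds: human
assay organism, single-protein target, direct binding assay ("D") at the
highest confidence score (9), a numerically exact Ki or IC50 measurement
("=" relation) in a recognized concentration unit, and a SMILES that
standardizes. Everything removed is tallied under its first failing
criterion, so ``|kept| + sum(tally.values()) == |input|`` always holds.

Potencies are expressed as pKi/pIC50 (negative decadic logarithm of the
molar value). Replicates for the same (compound, target, measurement) are
merged by the arithmetic mean of p-values — the geometric mean of molar
values — and groups whose replicates span more than 1.0 log unit are
discarded entirely: a cliff call should never rest on irreproducible
replicates. Ki- and IC50-derived values are never mixed.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import Molecule, Standardizer
from .errors import InvalidStructure, UnknownUnits

log = logging.getLogger(__name__)

MEASUREMENTS = ("Ki", "IC50")

#: molar conversion factors for the accepted unit spellings (case-insensitive)
_UNIT_FACTORS = {
    "nm": 1e-9,
    "um": 1e-6,
    "µm": 1e-6,  # µM
    "μm": 1e-6,  # Greek mu
    "m": 1.0,
}

#: exclusion reasons in test order; a record is tallied under the first failure
EXCLUSION_ORDER = (
    "organism",
    "target_type",
    "relationship",
    "confidence",
    "measurement",
    "relation",
    "units",
    "value",
    "structure",
)


@dataclass
class ActivityRecord:
    """One raw assay measurement with its assay and target metadata."""

    compound_id: str
    smiles: str
    target_id: str
    target_name: str
    target_class: str
    target_group: str
    organism: str
    assay_relationship: str
    assay_confidence: int
    assay_target_type: str
    measurement: str
    relation: str
    value: float
    units: str


@dataclass(frozen=True)
class CompoundPotency:
    """Aggregated pPot (pKi or pIC50) for one compound/target/measurement."""

    compound_id: str
    target_id: str
    measurement: str
    ppot: float
    n_records: int


@dataclass(frozen=True)
class TargetInfo:
    """Target metadata carried through to the cliff output rows."""

    target_id: str
    name: str
    target_class: str
    target_group: str


def to_ppot(value: float, units: str) -> float:
    """Negative decadic logarithm of the molar potency.

    10 nM -> 8.0, 1 uM -> 6.0, 1 M -> 0.0.

    Raises :class:`UnknownUnits` for units outside {nM, uM/µM, M} and
    ``ValueError`` for non-positive values.
    """
    factor = _UNIT_FACTORS.get(units.strip().lower())
    if factor is None:
        raise UnknownUnits(f"unrecognized concentration unit: {units!r}")
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"potency value must be positive and finite, got {value!r}")
    return -math.log10(value * factor)


def _normalize_measurement(text: str) -> Optional[str]:
    t = text.strip().lower()
    if t == "ki":
        return "Ki"
    if t == "ic50":
        return "IC50"
    return None


def _first_failure(record: ActivityRecord, standardizer: Standardizer) -> Optional[str]:
    if record.organism.strip().lower() != "homo sapiens":
        return "organism"
    if record.assay_target_type.strip().lower() != "single protein":
        return "target_type"
    if record.assay_relationship.strip().upper() != "D":
        return "relationship"
    if int(record.assay_confidence) != 9:
        return "confidence"
    if _normalize_measurement(record.measurement) is None:
        return "measurement"
    if record.relation.strip() != "=":
        return "relation"
    if record.units.strip().lower() not in _UNIT_FACTORS:
        return "units"
    try:
        value = float(record.value)
    except (TypeError, ValueError):
        return "value"
    if not (value > 0) or not math.isfinite(value):
        return "value"
    try:
        standardizer(record.smiles, record.compound_id)
    except InvalidStructure:
        return "structure"
    return None


def filter_records(
    records: Sequence[ActivityRecord],
    *,
    standardizer: Optional[Standardizer] = None,
    min_heavy_atoms: int = 4,
) -> Tuple[List[ActivityRecord], Dict[str, int]]:
    """Apply the high-confidence selection criteria.

    Returns the kept records and a tally of exclusions keyed by the first
    failing criterion. Structures below ``min_heavy_atoms`` heavy atoms
    (after salt stripping) count as structure failures: degenerate fragments
    produce trivial analog pairs.
    """
    if standardizer is None:
        standardizer = Standardizer(min_heavy_atoms=min_heavy_atoms)
    kept: List[ActivityRecord] = []
    tally: Dict[str, int] = {}
    for rec in records:
        reason = _first_failure(rec, standardizer)
        if reason is None:
            rec.measurement = _normalize_measurement(rec.measurement)  # type: ignore[assignment]
            kept.append(rec)
        else:
            tally[reason] = tally.get(reason, 0) + 1
    return kept, tally


def aggregate_potencies(
    records: Sequence[ActivityRecord], *, max_span: float = 1.0
) -> Tuple[List[CompoundPotency], int]:
    """Merge filtered records into one potency per compound/target/measurement.

    The group potency is the arithmetic mean of per-record p-values; groups
    whose p-values span more than ``max_span`` log units are discarded
    entirely (returned count reports how many groups were dropped). The span
    check is inclusive: exactly ``max_span`` is kept.
    """
    groups: Dict[Tuple[str, str, str], List[float]] = {}
    for rec in records:
        meas = _normalize_measurement(rec.measurement)
        if meas is None:
            raise ValueError(f"unfiltered record with measurement {rec.measurement!r}")
        key = (rec.compound_id, rec.target_id, meas)
        groups.setdefault(key, []).append(to_ppot(float(rec.value), rec.units))

    out: List[CompoundPotency] = []
    n_discarded = 0
    for (cid, tid, meas), pvals in sorted(groups.items()):
        span = max(pvals) - min(pvals)
        if span > max_span:
            n_discarded += 1
            log.debug("discarding %s/%s/%s: replicate span %.2f", cid, tid, meas, span)
            continue
        # summation over sorted values: the mean is bit-identical no matter
        # how the input records were ordered
        out.append(
            CompoundPotency(
                compound_id=cid,
                target_id=tid,
                measurement=meas,
                ppot=sum(sorted(pvals)) / len(pvals),
                n_records=len(pvals),
            )
        )
    return out, n_discarded


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = (
    "compound_id",
    "smiles",
    "target_id",
    "target_name",
    "target_class",
    "target_group",
    "organism",
    "assay_relationship",
    "assay_confidence",
    "assay_target_type",
    "measurement",
    "relation",
    "value",
    "units",
)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_activity_csv(path) -> List[ActivityRecord]:
    """Read an activity table (comma- or tab-delimited, auto-detected).

    Extra columns are ignored; all documented columns must be present.
    """
    with open(path, "r", newline="", encoding="utf-8") as fh:
        text = fh.read()
    return read_activity_text(text)


def read_activity_text(text: str) -> List[ActivityRecord]:
    lines = text.splitlines()
    if not lines:
        return []
    delim = _detect_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    missing = set(_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    out: List[ActivityRecord] = []
    for row in reader:
        try:
            conf = int(float(row["assay_confidence"]))
        except (TypeError, ValueError):
            conf = -1
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            value = float("nan")
        out.append(
            ActivityRecord(
                compound_id=row["compound_id"],
                smiles=row["smiles"],
                target_id=row["target_id"],
                target_name=row["target_name"],
                target_class=row["target_class"],
                target_group=row["target_group"],
                organism=row["organism"],
                assay_relationship=row["assay_relationship"],
                assay_confidence=conf,
                assay_target_type=row["assay_target_type"],
                measurement=row["measurement"],
                relation=row["relation"],
                value=value,
                units=row["units"],
            )
        )
    return out


def target_table(records: Iterable[ActivityRecord]) -> Dict[str, TargetInfo]:
    """Collect target metadata (first occurrence wins) from records."""
    out: Dict[str, TargetInfo] = {}
    for rec in records:
        if rec.target_id not in out:
            out[rec.target_id] = TargetInfo(
                target_id=rec.target_id,
                name=rec.target_name,
                target_class=rec.target_class,
                target_group=rec.target_group,
            )
    return out


def write_potency_csv(
    potencies: Sequence[CompoundPotency],
    molecules: Mapping[str, Molecule],
    path,
) -> None:
    """Write the curated-potency table (canonical SMILES included)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["compound_id", "smiles", "target_id", "measurement", "ppot", "n_records"]
        )
        for p in sorted(
            potencies, key=lambda p: (p.compound_id, p.target_id, p.measurement)
        ):
            smiles = molecules[p.compound_id].canonical_key
            writer.writerow(
                [p.compound_id, smiles, p.target_id, p.measurement, repr(p.ppot), p.n_records]
            )


def write_exclusions_csv(tally: Mapping[str, int], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reason", "count"])
        for reason in EXCLUSION_ORDER:
            if reason in tally:
                writer.writerow([reason, tally[reason]])
        for reason in sorted(set(tally) - set(EXCLUSION_ORDER)):
            writer.writerow([reason, tally[reason]])
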