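"""Cliff calling, summary tables, and the published dataset schema.

A target-based analog pair becomes an activity cliff when its two curated
potencies differ by at least 100-fold, i.e. ``|pPot_a - pPot_b| >= 2.0`` log
units. The threshold is inclusive — a pair at exactly 100-fold qualifies —
and is compared on p-values carried at full precision, with no
floating-point slack.

Output rows follow the deposited-dataset field list: compound IDs and
canonical SMILES of both analogs, measurement type, both p-values, target
name/UniProt/ChEMBL IDs, target class and group, sam_AC type (ar_AC|aw_AC),
modification type, and semicolon-separated PDB IDs (empty when none). The
weaker analog is written first, the more potent one second.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .curation import CompoundPotency, TargetInfo
from .errors import MissingPotency, WriteFailure
from .pairs import AnalogPair


@dataclass(eq=True, frozen=True)
class ActivityCliff:
    """A qualifying analog pair with potencies, target metadata and PDB IDs.

    ``*_weak`` refers to the less potent analog, ``*_potent`` to the more
    potent one. ``pdb_roles`` records, per matched PDB entry, which analog
    is co-crystallized ("potent", "weak" or "both"); it parallels
    ``pdb_ids`` and is an annotation only (excluded from equality, not part
    of the published schema).
    """

    pair: AnalogPair
    compound_weak: str
    compound_potent: str
    smiles_weak: str
    smiles_potent: str
    ppot_weak: float
    ppot_potent: float
    target_name: str = ""
    target_uniprot: str = ""
    target_chembl_id: str = ""
    target_class: str = ""
    target_group: str = ""
    pdb_ids: Tuple[str, ...] = ()
    pdb_roles: Tuple[str, ...] = field(default=(), compare=False)

    @property
    def delta_ppot(self) -> float:
        return self.ppot_potent - self.ppot_weak

    @property
    def measurement(self) -> str:
        return self.pair.measurement or ""

    @property
    def kind(self) -> str:
        return self.pair.kind

    @property
    def swap(self) -> str:
        return self.pair.swap


def call_cliffs(
    pairs: Sequence[AnalogPair],
    potencies: Sequence[CompoundPotency],
    fold_threshold: float = 100.0,
    *,
    targets: Optional[Mapping[str, TargetInfo]] = None,
    smiles: Optional[Mapping[str, str]] = None,
) -> List[ActivityCliff]:
    """Select the pairs whose potency difference is at least ``fold_threshold``.

    ``pairs`` must already be target/measurement-restricted; a pair member
    without a potency for its (target, measurement) raises
    :class:`MissingPotency`. ``targets`` and ``smiles`` fill the output
    metadata columns when provided.
    """
    delta_min = math.log10(fold_threshold)
    pot: Dict[Tuple[str, str, str], CompoundPotency] = {
        (p.compound_id, p.target_id, p.measurement): p for p in potencies
    }
    out: List[ActivityCliff] = []
    for pair in pairs:
        if pair.target_id is None or pair.measurement is None:
            raise MissingPotency(
                f"pair {pair.compound_a}/{pair.compound_b} is not activity-restricted"
            )
        pa = pot.get((pair.compound_a, pair.target_id, pair.measurement))
        pb = pot.get((pair.compound_b, pair.target_id, pair.measurement))
        if pa is None or pb is None:
            missing = pair.compound_a if pa is None else pair.compound_b
            raise MissingPotency(
                f"no {pair.measurement} potency for {missing} on {pair.target_id}"
            )
        if abs(pa.ppot - pb.ppot) < delta_min:
            continue
        weak, potent = (pa, pb) if pa.ppot <= pb.ppot else (pb, pa)
        info = (targets or {}).get(pair.target_id)
        out.append(
            ActivityCliff(
                pair=pair,
                compound_weak=weak.compound_id,
                compound_potent=potent.compound_id,
                smiles_weak=(smiles or {}).get(weak.compound_id, ""),
                smiles_potent=(smiles or {}).get(potent.compound_id, ""),
                ppot_weak=weak.ppot,
                ppot_potent=potent.ppot,
                target_name=info.name if info else "",
                target_chembl_id=pair.target_id,
                target_class=info.target_class if info else "",
                target_group=info.target_group if info else "",
            )
        )
    return out


def summarize(
    cliffs: Sequence[ActivityCliff], *, xray_only: bool = False
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables over a cliff list.

    Returns ``(by_target, by_swap)``:

    * ``by_target`` — counts by measurement, target class and target group
      (optionally restricted to cliffs with at least one PDB structure);
    * ``by_swap`` — counts by measurement, sam_AC kind and swap type.

    Rows are ordered by descending count, then label.
    """
    pool = [c for c in cliffs if c.pdb_ids] if xray_only else list(cliffs)
    t_counts: Dict[Tuple[str, str, str], int] = {}
    s_counts: Dict[Tuple[str, str, str], int] = {}
    for c in pool:
        tk = (c.measurement, c.target_class, c.target_group)
        t_counts[tk] = t_counts.get(tk, 0) + 1
        sk = (c.measurement, c.kind, c.swap)
        s_counts[sk] = s_counts.get(sk, 0) + 1

    by_target = pd.DataFrame(
        [(m, tc, tg, n) for (m, tc, tg), n in t_counts.items()],
        columns=["measurement", "target_class", "target_group", "n_cliffs"],
    )
    by_swap = pd.DataFrame(
        [(m, k, s, n) for (m, k, s), n in s_counts.items()],
        columns=["measurement", "kind", "swap", "n_cliffs"],
    )
    if len(by_target):
        by_target = by_target.sort_values(
            ["measurement", "n_cliffs", "target_class", "target_group"],
            ascending=[True, False, True, True],
        ).reset_index(drop=True)
    if len(by_swap):
        by_swap = by_swap.sort_values(
            ["measurement", "n_cliffs", "kind", "swap"],
            ascending=[True, False, True, True],
        ).reset_index(drop=True)
    return by_target, by_swap


# ---------------------------------------------------------------------------
# dataset serialization

DATASET_COLUMNS = (
    "compound_id_1",
    "compound_id_2",
    "smiles_1",
    "smiles_2",
    "measurement",
    "ppot_1",
    "ppot_2",
    "target_name",
    "target_uniprot",
    "target_chembl_id",
    "target_class",
    "target_group",
    "sam_ac_type",
    "modification",
    "pdb_ids",
)

_KIND_TO_LABEL = {"ar": "ar_AC", "aw": "aw_AC"}
_LABEL_TO_KIND = {v: k for k, v in _KIND_TO_LABEL.items()}


def dataset_rows(cliffs: Sequence[ActivityCliff]) -> List[List[str]]:
    """Render cliffs as dataset rows (weak analog first, potent second)."""
    rows: List[List[str]] = []
    for c in cliffs:
        rows.append(
            [
                c.compound_weak,
                c.compound_potent,
                c.smiles_weak,
                c.smiles_potent,
                c.measurement,
                repr(c.ppot_weak),
                repr(c.ppot_potent),
                c.target_name,
                c.target_uniprot,
                c.target_chembl_id,
                c.target_class,
                c.target_group,
                _KIND_TO_LABEL[c.kind],
                c.swap,
                ";".join(c.pdb_ids),
            ]
        )
    return rows


def write_dataset(cliffs: Sequence[ActivityCliff], path) -> None:
    """Write the dataset CSV. Raises :class:`WriteFailure` on I/O errors."""
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(DATASET_COLUMNS)
            writer.writerows(dataset_rows(cliffs))
    except OSError as exc:
        raise WriteFailure(f"cannot write dataset to {path!r}: {exc}") from exc


def read_dataset(path) -> List[ActivityCliff]:
    """Read a dataset CSV back into :class:`ActivityCliff` values.

    Inverse of :func:`write_dataset` up to annotation-only fields (pair
    sites and PDB roles, which the published schema does not carry).
    """
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(DATASET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        out: List[ActivityCliff] = []
        for row in reader:
            cid_weak, cid_potent = row["compound_id_1"], row["compound_id_2"]
            a, b = sorted([cid_weak, cid_potent])
            pair = AnalogPair(
                compound_a=a,
                compound_b=b,
                kind=_LABEL_TO_KIND[row["sam_ac_type"]],
                swap=row["modification"],
                target_id=row["target_chembl_id"],
                measurement=row["measurement"],
            )
            pdb_ids = tuple(p for p in row["pdb_ids"].split(";") if p)
            out.append(
                ActivityCliff(
                    pair=pair,
                    compound_weak=cid_weak,
                    compound_potent=cid_potent,
                    smiles_weak=row["smiles_1"],
                    smiles_potent=row["smiles_2"],
                    ppot_weak=float(row["ppot_1"]),
                    ppot_potent=float(row["ppot_2"]),
                    target_name=row["target_name"],
                    target_uniprot=row["target_uniprot"],
                    target_chembl_id=row["target_chembl_id"],
                    target_class=row["target_class"],
                    target_group=row["target_group"],
                    pdb_ids=pdb_ids,
                )
            )
        return out
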