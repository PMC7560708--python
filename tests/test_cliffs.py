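"""Cliff calling at the 100-fold boundary, summaries, dataset round-trip."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from samcliff import MissingPotency, call_cliffs, read_dataset, summarize, write_dataset
from samcliff.cliffs import ActivityCliff
from samcliff.curation import CompoundPotency, TargetInfo
from samcliff.pairs import AnalogPair


def tpair(a="A", b="B", kind="ar", swap="N-C", target="T1", meas="Ki"):
    return AnalogPair(a, b, kind, swap, target_id=target, measurement=meas)


def pots(ppa, ppb, target="T1", meas="Ki"):
    return [
        CompoundPotency("A", target, meas, ppa, 1),
        CompoundPotency("B", target, meas, ppb, 1),
    ]


class TestCallCliffs:
    def test_exact_100_fold_is_a_cliff(self):
        (cliff,) = call_cliffs([tpair()], pots(5.0, 7.0))
        assert cliff.delta_ppot == pytest.approx(2.0)
        assert (cliff.compound_weak, cliff.compound_potent) == ("A", "B")

    def test_79_fold_is_not_a_cliff(self):
        assert call_cliffs([tpair()], pots(5.0, 6.9)) == []

    def test_99_fold_is_not_a_cliff(self):
        delta = math.log10(99.0)
        assert call_cliffs([tpair()], pots(5.0, 5.0 + delta)) == []

    def test_large_difference(self):
        (cliff,) = call_cliffs([tpair()], pots(8.5, 4.0))
        assert cliff.delta_ppot == pytest.approx(4.5)
        assert cliff.compound_potent == "A"

    def test_missing_potency_raises(self):
        with pytest.raises(MissingPotency):
            call_cliffs([tpair()], pots(5.0, 8.0, target="OTHER"))

    def test_target_metadata_filled(self):
        targets = {"T1": TargetInfo("T1", "Thrombin", "Enzyme", "Protease")}
        (cliff,) = call_cliffs([tpair()], pots(5.0, 8.0), targets=targets,
                               smiles={"A": "CCO", "B": "CCN"})
        assert cliff.target_name == "Thrombin"
        assert cliff.target_class == "Enzyme"
        assert cliff.smiles_weak == "CCO"

    @given(
        deltas=st.lists(
            st.floats(min_value=0.0, max_value=6.0, allow_nan=False),
            min_size=1,
            max_size=20,
        ),
        folds=st.tuples(
            st.floats(min_value=1.0, max_value=1e4),
            st.floats(min_value=1.0, max_value=1e4),
        ),
    )
    def test_threshold_monotonicity(self, deltas, folds):
        pairs, potencies = [], []
        for i, d in enumerate(deltas):
            a, b = f"A{i:03d}", f"B{i:03d}"
            pairs.append(tpair(a, b))
            potencies.append(CompoundPotency(a, "T1", "Ki", 5.0, 1))
            potencies.append(CompoundPotency(b, "T1", "Ki", 5.0 + d, 1))
        lo, hi = sorted(folds)
        n_lo = len(call_cliffs(pairs, potencies, lo))
        n_hi = len(call_cliffs(pairs, potencies, hi))
        assert n_hi <= n_lo
        assert len(call_cliffs(pairs, potencies, 1.0)) == len(pairs)

    def test_conservation_every_cliff_comes_from_an_input_pair(self):
        pairs = [tpair("A", "B"), tpair("C", "D", kind="aw")]
        potencies = pots(4.0, 7.0) + [
            CompoundPotency("C", "T1", "Ki", 5.0, 1),
            CompoundPotency("D", "T1", "Ki", 5.1, 1),
        ]
        cliffs = call_cliffs(pairs, potencies)
        assert [c.pair for c in cliffs] == [pairs[0]]


def make_cliff(rng, idx):
    a, b = f"CPD{2 * idx:05d}", f"CPD{2 * idx + 1:05d}"
    kind = rng.choice(["ar", "aw"])
    swap = rng.choice(["N-C", "O-C", "N-O", "S-O"])
    meas = rng.choice(["Ki", "IC50"])
    pair = AnalogPair(a, b, kind, swap, target_id=f"T{idx % 17}", measurement=meas)
    weak_p = rng.uniform(3.0, 6.0)
    n_pdb = rng.choice([0, 0, 1, 2, 3])
    pdb_ids = tuple(sorted(f"{rng.randint(1, 9)}{rng.choice('ABC')}X{i}" for i in range(n_pdb)))
    weak, potent = (a, b) if rng.random() < 0.5 else (b, a)
    return ActivityCliff(
        pair=pair,
        compound_weak=weak,
        compound_potent=potent,
        smiles_weak="CCOc1ccccc1",
        smiles_potent="CCNc1ccccc1",
        ppot_weak=weak_p,
        ppot_potent=weak_p + rng.uniform(2.0, 5.0),
        target_name=f"Target {idx % 17}",
        target_uniprot=f"P{10000 + idx % 17}",
        target_chembl_id=f"T{idx % 17}",
        target_class="Enzyme",
        target_group="Kinase",
        pdb_ids=pdb_ids,
    )


class TestSummarize:
    def test_target_table_counts_with_xray_restriction(self, rng):
        cliffs = [make_cliff(rng, i) for i in range(40)]
        by_target, _ = summarize(cliffs, xray_only=True)
        assert by_target["n_cliffs"].sum() == sum(1 for c in cliffs if c.pdb_ids)

    def test_swap_table_counts(self):
        rng = random.Random(5)
        cliffs = [make_cliff(rng, i) for i in range(60)]
        _, by_swap = summarize(cliffs)
        assert by_swap["n_cliffs"].sum() == 60
        row = by_swap[(by_swap.measurement == "Ki") & (by_swap.kind == "ar")]
        manual = sum(1 for c in cliffs if c.measurement == "Ki" and c.kind == "ar")
        assert row["n_cliffs"].sum() == manual

    def test_empty_input_gives_empty_tables(self):
        by_target, by_swap = summarize([])
        assert len(by_target) == 0 and len(by_swap) == 0


class TestDatasetRoundTrip:
    def test_write_then_read_is_identity(self, rng, tmp_path):
        cliffs = [make_cliff(rng, i) for i in range(200)]
        assert any(not c.pdb_ids for c in cliffs) and any(len(c.pdb_ids) > 1 for c in cliffs)
        path = tmp_path / "dataset.csv"
        write_dataset(cliffs, path)
        assert read_dataset(path) == cliffs

    def test_weak_analog_written_first(self, rng, tmp_path):
        cliffs = [make_cliff(rng, 0)]
        path = tmp_path / "one.csv"
        write_dataset(cliffs, path)
        lines = path.read_text().splitlines()
        fields = lines[1].split(",")
        assert fields[0] == cliffs[0].compound_weak
        assert float(fields[5]) <= float(fields[6])

    def test_unwritable_path_raises(self, rng):
        from samcliff import WriteFailure

        with pytest.raises(WriteFailure):
            write_dataset([make_cliff(rng, 0)], "/nonexistent-dir/out.csv")
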