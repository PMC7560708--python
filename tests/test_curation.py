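"""Record filtering, unit conversion and potency aggregation."""

import math

import pytest
from hypothesis import given, strategies as st

from samcliff import UnknownUnits, aggregate_potencies, filter_records, to_ppot
from samcliff.curation import ActivityRecord, read_activity_text


def make_record(**overrides):
    base = dict(
        compound_id="C1",
        smiles="CCCCc1ccncc1",
        target_id="T1",
        target_name="Target 1",
        target_class="Enzyme",
        target_group="Kinase",
        organism="Homo sapiens",
        assay_relationship="D",
        assay_confidence=9,
        assay_target_type="SINGLE PROTEIN",
        measurement="Ki",
        relation="=",
        value=10.0,
        units="nM",
    )
    base.update(overrides)
    return ActivityRecord(**base)


class TestToPpot:
    @pytest.mark.parametrize(
        "value, units, expected",
        [
            (10.0, "nM", 8.0),
            (1.0, "uM", 6.0),
            (1.0, "µM", 6.0),
            (1.0, "M", 0.0),
            (100.0, "nM", 7.0),
        ],
    )
    def test_molar_log_conversion(self, value, units, expected):
        assert to_ppot(value, units) == pytest.approx(expected, abs=1e-12)

    def test_unknown_units_rejected(self):
        with pytest.raises(UnknownUnits):
            to_ppot(10.0, "mg.kg-1")

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            to_ppot(0.0, "nM")


class TestFilterRecords:
    @pytest.mark.parametrize(
        "override, reason",
        [
            ({"organism": "Rattus norvegicus"}, "organism"),
            ({"assay_target_type": "PROTEIN COMPLEX"}, "target_type"),
            ({"assay_relationship": "H"}, "relationship"),
            ({"assay_confidence": 8}, "confidence"),
            ({"measurement": "EC50"}, "measurement"),
            ({"relation": ">"}, "relation"),
            ({"units": "mg"}, "units"),
            ({"value": -1.0}, "value"),
            ({"smiles": "C1CC"}, "structure"),
            ({"smiles": "CCO.Cl"}, "structure"),  # largest fragment < 4 atoms
        ],
    )
    def test_exclusion_reasons(self, override, reason):
        kept, tally = filter_records([make_record(**override)])
        assert kept == []
        assert tally == {reason: 1}

    def test_fully_compliant_record_kept(self):
        kept, tally = filter_records([make_record()])
        assert len(kept) == 1 and tally == {}

    def test_first_failing_criterion_wins(self):
        rec = make_record(organism="Mus musculus", relation=">")
        _, tally = filter_records([rec])
        assert tally == {"organism": 1}

    def test_partition_property(self):
        records = [
            make_record(),
            make_record(compound_id="C2", measurement="IC50"),
            make_record(organism="Bos taurus"),
            make_record(relation="<"),
            make_record(smiles="bogus"),
        ]
        kept, tally = filter_records(records)
        assert len(kept) + sum(tally.values()) == len(records)


class TestAggregatePotencies:
    def test_mean_of_p_values_span_boundary_kept(self):
        records = [make_record(value=10.0), make_record(value=100.0)]
        potencies, dropped = aggregate_potencies(records)
        assert dropped == 0
        (p,) = potencies
        assert p.ppot == pytest.approx(7.5)
        assert p.n_records == 2

    def test_wide_replicate_span_discards_group(self):
        records = [make_record(value=10.0), make_record(value=10.0, units="uM")]
        potencies, dropped = aggregate_potencies(records)
        assert potencies == [] and dropped == 1

    def test_ki_and_ic50_never_mixed(self):
        records = [make_record(), make_record(measurement="IC50")]
        potencies, _ = aggregate_potencies(records)
        assert {(p.compound_id, p.measurement) for p in potencies} == {
            ("C1", "Ki"),
            ("C1", "IC50"),
        }
        assert all(p.n_records == 1 for p in potencies)

    @given(
        pvals=st.lists(
            st.floats(min_value=4.0, max_value=9.0, allow_nan=False), min_size=1, max_size=5
        ),
        drop=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_lowering_a_molar_value_never_decreases_group_ppot(self, pvals, drop):
        # keep both variants inside the span filter
        pvals = [5.0 + (p - 4.0) * 0.15 for p in pvals]
        records = [make_record(value=10 ** (9 - p)) for p in pvals]
        before, _ = aggregate_potencies(records)
        lowered = list(pvals)
        lowered[0] += drop * 0.1  # lower molar value == higher p-value
        records2 = [make_record(value=10 ** (9 - p)) for p in lowered]
        after, _ = aggregate_potencies(records2)
        assert after[0].ppot >= before[0].ppot - 1e-12


class TestReader:
    def test_tab_delimiter_and_extra_columns(self):
        header = (
            "compound_id\tsmiles\ttarget_id\ttarget_name\ttarget_class\t"
            "target_group\torganism\tassay_relationship\tassay_confidence\t"
            "assay_target_type\tmeasurement\trelation\tvalue\tunits\textra"
        )
        row = (
            "C1\tCCCCO\tT1\tTarget\tEnzyme\tKinase\tHomo sapiens\tD\t9\t"
            "SINGLE PROTEIN\tKi\t=\t10\tnM\tignored"
        )
        records = read_activity_text(header + "\n" + row + "\n")
        assert len(records) == 1
        assert records[0].compound_id == "C1"
        assert records[0].value == 10.0

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            read_activity_text("compound_id,smiles\nC1,CCO\n")
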