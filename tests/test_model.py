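"""Data model: validity contract, associatedTaxa parsing, canonicalization."""

import dataclasses
import random

import pytest
from hypothesis import given, strategies as st

from ppidata import (
    InteractionEvent,
    canonicalize,
    datasets_equal,
    format_associated_taxa,
    inject_fault,
    parse_associated_taxa,
    validate_dataset,
)
from ppidata.errors import DatasetContractError
from .conftest import add_measurement, make_minimal_dataset


class TestValidityContract:
    def test_complete_minimal_dataset_is_valid(self, minimal_dataset, registry):
        report = validate_dataset(minimal_dataset, registry)
        assert report.is_valid
        assert report.findings == []

    @pytest.mark.parametrize("fault,code", [
        ("scientific_name", "MISSING_SCIENTIFIC_NAME"),
        ("event_id", "MISSING_EVENT_ID"),
        ("resource_id", "DANGLING_REFERENCE"),
        ("related_resource_id", "DANGLING_REFERENCE"),
        ("relationship_type", "MISSING_RELATIONSHIP_TYPE"),
        ("according_to", "MISSING_ACCORDING_TO"),
    ])
    def test_single_fault_yields_exactly_one_matching_error(
            self, minimal_dataset, registry, fault, code):
        faulty = inject_fault(minimal_dataset, fault)
        errors = validate_dataset(faulty, registry).errors
        assert [f.code for f in errors] == [code]

    def test_unresolvable_related_resource_is_dangling(self, minimal_dataset):
        minimal_dataset.relationships[0].related_resource_id = "ghost"
        errors = validate_dataset(minimal_dataset).errors
        assert [f.code for f in errors] == ["DANGLING_REFERENCE"]

    def test_self_relationship_flagged(self, minimal_dataset):
        minimal_dataset.relationships[0].related_resource_id = "o2"
        codes = {f.code for f in validate_dataset(minimal_dataset).errors}
        assert "SELF_RELATIONSHIP" in codes

    def test_duplicate_ids_flagged(self, minimal_dataset):
        minimal_dataset.occurrences.append(
            dataclasses.replace(minimal_dataset.occurrences[0]))
        codes = [f.code for f in validate_dataset(minimal_dataset).errors]
        assert codes == ["DUPLICATE_ID"]

    def test_cv_violation_is_a_warning(self, minimal_dataset, registry):
        add_measurement(
            minimal_dataset, occurrence_id="o1",
            measurement_type="Flower Opening Type",
            measurement_type_iri="http://rs.rebipp.org.br/ppi/terms/flowerOpeningType",
            measurement_value="open")
        report = validate_dataset(minimal_dataset, registry)
        assert report.is_valid
        assert [f.code for f in report.warnings] == ["CV_VIOLATION"]

    def test_unknown_measurement_type_iri_warns(self, minimal_dataset, registry):
        add_measurement(minimal_dataset,
                        measurement_type_iri="http://example.org/notAterm")
        warnings = validate_dataset(minimal_dataset, registry).warnings
        assert [f.code for f in warnings] == ["UNKNOWN_MEASUREMENT_TYPE"]

    def test_measurement_of_foreign_occurrence_is_dangling(self, minimal_dataset):
        m = add_measurement(minimal_dataset, occurrence_id="o1")
        m.event_id = "e1"
        minimal_dataset.occurrences[0].event_id = "e1"
        # target occurrence moved to another (existing) event
        minimal_dataset.events.append(InteractionEvent(event_id="e2"))
        minimal_dataset.occurrences[0] = dataclasses.replace(
            minimal_dataset.occurrences[0], event_id="e2")
        codes = {f.code for f in validate_dataset(minimal_dataset).errors}
        assert "DANGLING_REFERENCE" in codes

    def test_event_without_relationship_warns(self, minimal_dataset):
        minimal_dataset.events.append(InteractionEvent(event_id="e2"))
        report = validate_dataset(minimal_dataset)
        assert report.is_valid
        assert [(f.code, f.record_ref) for f in report.warnings] == [
            ("EVENT_WITHOUT_RELATIONSHIP", "e2")]

    def test_findings_sorted_and_deterministic(self, minimal_dataset, registry):
        minimal_dataset.occurrences[0].scientific_name = ""
        minimal_dataset.relationships[0].relationship_according_to = ""
        first = validate_dataset(minimal_dataset, registry)
        second = validate_dataset(minimal_dataset, registry)
        assert first == second
        assert [f.code for f in first.errors] == [
            "MISSING_SCIENTIFIC_NAME", "MISSING_ACCORDING_TO"]

    def test_coordinates_out_of_range_rejected_at_construction(self):
        with pytest.raises(ValueError, match="latitude"):
            InteractionEvent(event_id="e", latitude=91.0)
        with pytest.raises(ValueError, match="longitude"):
            InteractionEvent(event_id="e", longitude=-181.0)


class TestAssociatedTaxa:
    @pytest.mark.parametrize("raw,expected", [
        ('"pollinator of":"Fuchsia magellanica"',
         [("pollinator of", "Fuchsia magellanica")]),
        ("", []),
        ("visits flowers of: Salvia guaranitica | preys on: Apis mellifera",
         [("visits flowers of", "Salvia guaranitica"), ("preys on", "Apis mellifera")]),
        ("Apis mellifera", [("", "Apis mellifera")]),
        ("a:b:c", [("a", "b:c")]),  # split on the FIRST colon only
    ])
    def test_split_grammar(self, raw, expected):
        assert parse_associated_taxa(raw) == expected

    @given(st.lists(st.tuples(
        st.text(alphabet="abcdefgh X.-", min_size=0, max_size=12).map(str.strip),
        st.text(alphabet="abcdefgh X.-", min_size=1, max_size=20).map(str.strip),
    ).filter(lambda p: p[1] != ""), max_size=6))
    def test_formatter_parser_roundtrip(self, pairs):
        assert parse_associated_taxa(format_associated_taxa(pairs)) == pairs


class TestCanonicalize:
    def test_idempotent(self, fixture_dataset):
        once = canonicalize(fixture_dataset)
        assert canonicalize(once) == once

    def test_invariant_under_record_permutation(self, fixture_dataset):
        shuffled = dataclasses.replace(
            fixture_dataset,
            events=random.Random(5).sample(fixture_dataset.events,
                                           len(fixture_dataset.events)),
            occurrences=list(reversed(fixture_dataset.occurrences)),
        )
        assert canonicalize(shuffled) == canonicalize(fixture_dataset)

    def test_padding_whitespace_equalized(self, minimal_dataset):
        padded = make_minimal_dataset()
        padded.occurrences[0].scientific_name = "  Fuchsia magellanica "
        padded.relationships[0].relationship_according_to += "  "
        assert datasets_equal(padded, minimal_dataset)

    def test_invalid_dataset_rejected(self, minimal_dataset):
        minimal_dataset.occurrences[0].scientific_name = ""
        with pytest.raises(DatasetContractError):
            canonicalize(minimal_dataset)
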