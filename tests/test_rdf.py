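"""RDF mapping: structural triple counts, serialization, round trips.

The structural checks are compared against a brute-force triple builder that
enumerates the expected link triples directly from the record lists with
plain string concatenation, independently of the mapping implementation.
"""

from urllib.parse import quote

import pytest
from rdflib import RDF, URIRef

from ppidata import (
    FixtureProfile,
    InteractionDataset,
    datasets_equal,
    from_triples,
    generate_dataset,
    parse_graph,
    serialize_graph,
    to_triples,
)
from ppidata.errors import (
    RDFSerializationError,
    RDFStructureError,
    UnsupportedFormatError,
)
from .conftest import add_measurement

BASE = "http://example.org/ppi"
DSW_AT_EVENT = "http://purl.org/dsw/atEvent"
DCT_RELATION = "http://purl.org/dc/terms/relation"
RO_NS = "http://purl.obolibrary.org/obo/RO_"


def brute_force_link_triples(dataset: InteractionDataset, base: str = BASE):
    """Independently enumerate the expected structural link triples."""

    def iri(kind, local):
        return f"{base}/{kind}/{quote(local, safe='')}"

    at_event = {(iri("occurrence", o.occurrence_id), DSW_AT_EVENT,
                 iri("event", o.event_id)) for o in dataset.occurrences}
    interaction = {(iri("occurrence", r.resource_id),
                    r.relationship_of_resource_iri,
                    iri("occurrence", r.related_resource_id))
                   for r in dataset.relationships}
    relation = set()
    for m in dataset.measurements:
        owner = (iri("occurrence", m.occurrence_id) if m.occurrence_id
                 else iri("event", m.event_id))
        relation.add((owner, DCT_RELATION, iri("mof", m.measurement_id)))
    return at_event, interaction, relation


def graph_triples_str(graph):
    return {(str(s), str(p), str(o)) for s, p, o in graph}


class TestStructure:
    def test_minimal_interaction_counts(self, minimal_dataset):
        graph = to_triples(minimal_dataset, base=BASE)
        triples = graph_triples_str(graph)
        at_event = {t for t in triples if t[1] == DSW_AT_EVENT}
        ro = {t for t in triples if t[1].startswith(RO_NS)}
        assert len(at_event) == 2
        assert len(ro) == 1

    def test_empty_dataset_gives_empty_graph(self):
        assert len(to_triples(InteractionDataset())) == 0

    def test_flower_color_measurement_triples(self, minimal_dataset, registry):
        add_measurement(minimal_dataset, occurrence_id="o1",
                        measurement_type="Flower Color",
                        measurement_type_iri="http://rs.rebipp.org.br/ppi/terms/flowerColor",
                        measurement_value="red")
        triples = graph_triples_str(to_triples(minimal_dataset, registry, base=BASE))
        relation = [t for t in triples if t[1] == DCT_RELATION]
        assert relation == [(f"{BASE}/occurrence/o1", DCT_RELATION, f"{BASE}/mof/m1")]
        type_iris = [t for t in triples
                     if t[1] == "http://rs.tdwg.org/dwc/iri/measurementType"]
        assert type_iris == [(f"{BASE}/mof/m1",
                              "http://rs.tdwg.org/dwc/iri/measurementType",
                              "http://rs.rebipp.org.br/ppi/terms/flowerColor")]

    def test_cv_value_travels_as_anyuri_literal(self, minimal_dataset):
        add_measurement(minimal_dataset, occurrence_id="o1",
                        measurement_value_iri="http://example.org/cv/red")
        graph = to_triples(minimal_dataset, base=BASE)
        values = [o for o in graph.objects(
            URIRef(f"{BASE}/mof/m1"),
            URIRef("http://rs.tdwg.org/dwc/terms/measurementValue"))]
        typed = [o for o in values
                 if getattr(o, "datatype", None) is not None
                 and str(o.datatype).endswith("anyURI")]
        assert [str(o) for o in typed] == ["http://example.org/cv/red"]

    @pytest.mark.parametrize("seed", range(8))
    def test_link_triples_match_brute_force_builder(self, seed, registry):
        dataset = generate_dataset(FixtureProfile(
            seed=seed, n_plants=2 + seed % 2, n_animals=3,
            connectance=0.5, cv_source=registry))
        assert len(dataset.events) <= 10
        triples = graph_triples_str(to_triples(dataset, registry, base=BASE))
        at_event, interaction, relation = brute_force_link_triples(dataset)
        assert {t for t in triples if t[1] == DSW_AT_EVENT} == at_event
        assert {t for t in triples if t[1].startswith(RO_NS)} == interaction
        assert {t for t in triples if t[1] == DCT_RELATION} == relation
        # cardinalities per record kind
        assert len(at_event) == len(dataset.occurrences)
        assert len(interaction) == len(dataset.relationships)
        assert len(relation) == len(dataset.measurements)

    def test_free_text_only_relationship_is_a_serialization_error(
            self, minimal_dataset):
        minimal_dataset.relationships[0].relationship_of_resource_iri = None
        with pytest.raises(RDFSerializationError, match="r1"):
            to_triples(minimal_dataset)


class TestSerialization:
    def test_turtle_and_ntriples_parse_to_the_same_set(self, fixture_dataset, registry):
        graph = to_triples(fixture_dataset, registry)
        from_ttl = parse_graph(serialize_graph(graph, "turtle"), "turtle")
        from_nt = parse_graph(serialize_graph(graph, "ntriples"), "ntriples")
        assert set(from_ttl) == set(from_nt) == set(graph)

    def test_ntriples_line_count_equals_triple_count(self, fixture_dataset):
        graph = to_triples(fixture_dataset)
        payload = serialize_graph(graph, "ntriples").decode("utf-8")
        lines = [line for line in payload.splitlines() if line.strip()]
        assert len(lines) == len(graph)

    def test_unknown_format_rejected(self, fixture_dataset):
        graph = to_triples(fixture_dataset)
        with pytest.raises(UnsupportedFormatError):
            serialize_graph(graph, "rdfxml")
        with pytest.raises(UnsupportedFormatError):
            parse_graph(b"", "rdfxml")


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(10))
    def test_dataset_graph_dataset_identity(self, seed, registry):
        dataset = generate_dataset(FixtureProfile(
            seed=seed, n_plants=2 + seed % 3, n_animals=2 + seed % 4,
            connectance=0.2 + 0.1 * (seed % 6), cv_source=registry))
        graph = to_triples(dataset, registry, base=BASE)
        assert datasets_equal(from_triples(graph, base=BASE), dataset)

    def test_graph_dataset_graph_identity(self, fixture_dataset, registry):
        graph = to_triples(fixture_dataset, registry, base=BASE)
        back = to_triples(from_triples(graph, base=BASE), registry, base=BASE)
        assert set(back) == set(graph)

    def test_bare_form_loses_according_to_but_keeps_structure(self, minimal_dataset):
        graph = to_triples(minimal_dataset, base=BASE, reify_relationships=False)
        back = from_triples(graph, base=BASE)
        assert len(back.relationships) == 1
        rel = back.relationships[0]
        assert rel.resource_id == "o2" and rel.related_resource_id == "o1"
        assert rel.relationship_of_resource == "pollinates"  # from the RO mapping
        assert rel.relationship_according_to == ""  # documented lossiness

    def test_missing_event_type_statement_is_a_structure_error(self, minimal_dataset):
        graph = to_triples(minimal_dataset, base=BASE)
        graph.remove((URIRef(f"{BASE}/event/e1"), RDF.type, None))
        with pytest.raises(RDFStructureError):
            from_triples(graph, base=BASE)

    def test_occurrence_without_at_event_is_a_structure_error(self, minimal_dataset):
        graph = to_triples(minimal_dataset, base=BASE)
        graph.remove((URIRef(f"{BASE}/occurrence/o1"),
                      URIRef(DSW_AT_EVENT), None))
        with pytest.raises(RDFStructureError):
            from_triples(graph, base=BASE)

    def test_extraneous_triples_are_ignored(self, minimal_dataset, caplog):
        import logging

        graph = to_triples(minimal_dataset, base=BASE)
        graph.add((URIRef("http://example.org/unrelated"),
                   URIRef("http://example.org/p"),
                   URIRef("http://example.org/o")))
        with caplog.at_level(logging.INFO, logger="ppidata.rdfio"):
            back = from_triples(graph, base=BASE)
        assert datasets_equal(back, minimal_dataset)
        assert any("ignoring" in record.message for record in caplog.records)
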