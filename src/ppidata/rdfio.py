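"""RDF graph representation of interaction datasets.

The mapping follows the Darwin-SW pattern: each organism occurrence is an
instance of the Occurrence class linked to its interaction event (an
instance of the Event class) by ``dsw:atEvent``; the type and direction of
the interaction are given naturally by a triple with the two occurrence
instances as subject and object and a Relations Ontology term as predicate;
measurements are MeasurementOrFact instances linked from their owning event
or occurrence via ``dcterms:relation``, with ``dwciri:measurementType``
pointing at the vocabulary term IRI (non-literal) and ``dwc:measurementType``
carrying the human-readable literal. Controlled-vocabulary values travel by
default as literals typed ``xsd:anyURI`` holding the value IRI; a config
switch emits a true object property instead (non-default).

All mapped nodes carry minted IRIs (``<base>/event/<id>``,
``<base>/occurrence/<id>``, ``<base>/mof/<id>``) rather than blank nodes, so
graph round trips are exact set equality.

Representing the ResourceRelationship class itself in RDF is unsettled in
the Darwin Core community; this module therefore also emits (by default) a
``dwc:ResourceRelationship``-typed node carrying the six relationship fields
as literals, so that the assertion source (``relationshipAccordingTo``)
survives round trips. Disable with ``reify_relationships=False`` for the
bare occurrence-to-occurrence form, in which case that field is lost.
"""

from __future__ import annotations

import logging
from urllib.parse import quote, unquote

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from . import _terms as T
from .errors import (
    DatasetContractError,
    RDFSerializationError,
    RDFStructureError,
    UnsupportedFormatError,
)
from .model import (
    InteractionDataset,
    InteractionEvent,
    InteractionRelationship,
    Measurement,
    OrganismOccurrence,
    validate_dataset,
)
from .registry import TermRegistry

logger = logging.getLogger(__name__)

DWC = Namespace(T.DWC)
DWCIRI = Namespace(T.DWCIRI)
DSW = Namespace(T.DSW)
DCTERMS = Namespace(T.DCTERMS)
APP = Namespace(T.APP)

DEFAULT_BASE = "http://example.org/ppi"

# Editable default mapping between interaction-type labels and Relations
# Ontology IRIs; the standard recommends RO predicates but fixes no list.
RO_TERMS: dict[str, str] = {
    "pollinates": T.RO + "0002455",
    "is pollinated by": T.RO + "0002456",
    "visits flowers of": T.RO + "0002622",
    "has flowers visited by": T.RO + "0002623",
    "visits": T.RO + "0002618",
    "is visited by": T.RO + "0002619",
    "biotically interacts with": T.RO + "0002437",
}

_EVENT_LITERALS = [(f, DWC[tok]) for f, tok, _ in T.EVENT_FIELDS]
_OCC_LITERALS = ([(f, DWC[tok]) for f, tok, _ in T.OCCURRENCE_FIELDS
                  if f != "organism_role"] + [("organism_role", APP["organismRole"])])
_REL_LITERALS = [(f, DWC[tok]) for f, tok, _ in T.RELATIONSHIP_FIELDS]


def mint(base: str, kind: str, local_id: str) -> URIRef:
    """Mint the IRI of a record: ``<base>/<kind>/<quoted id>``."""
    return URIRef(f"{base.rstrip('/')}/{kind}/{quote(local_id, safe='')}")


def parse_minted(iri: str, base: str) -> tuple[str, str] | None:
    """Inverse of :func:`mint`: recover (kind, local id), or None."""
    prefix = base.rstrip("/") + "/"
    if not iri.startswith(prefix):
        return None
    rest = iri[len(prefix):]
    if "/" not in rest:
        return None
    kind, local = rest.split("/", 1)
    return kind, unquote(local)


def _bind(graph: Graph) -> Graph:
    graph.bind("dwc", DWC)
    graph.bind("dwciri", DWCIRI)
    graph.bind("dsw", DSW)
    graph.bind("dcterms", DCTERMS)
    graph.bind("ppi", T.PPI)
    graph.bind("obo", "http://purl.obolibrary.org/obo/")
    return graph


def to_triples(dataset: InteractionDataset, registry: TermRegistry | None = None,
               base: str = DEFAULT_BASE, *, reify_relationships: bool = True,
               cv_values_as_objects: bool = False) -> Graph:
    """Map a valid dataset onto an RDF graph.

    Every relationship must carry ``relationship_of_resource_iri``: a
    free-text-only interaction type cannot become a predicate. When a
    registry is given, measurements whose human-readable type names a
    registry term get their term IRI filled in.
    """
    report = validate_dataset(dataset)
    if not report.is_valid:
        raise DatasetContractError(
            "refusing to serialize an invalid dataset: "
            + "; ".join(f.message for f in report.errors[:5]))
    for rel in dataset.relationships:
        if not rel.relationship_of_resource_iri:
            raise RDFSerializationError(
                f"relationship {rel.relationship_id!r} has only a free-text type; "
                f"an IRI (e.g. a Relations Ontology term) is required as predicate")

    graph = _bind(Graph())
    occurrence_iri = {o.occurrence_id: mint(base, "occurrence", o.occurrence_id)
                      for o in dataset.occurrences}
    event_iri = {e.event_id: mint(base, "event", e.event_id) for e in dataset.events}

    def literals(node, record, spec) -> None:
        for field_name, predicate in spec:
            value = getattr(record, field_name)
            if value is not None and value != "":
                graph.add((node, predicate, Literal(str(value))))

    for event in dataset.events:
        node = event_iri[event.event_id]
        graph.add((node, RDF.type, DWC.Event))
        literals(node, event, _EVENT_LITERALS)
        for token, value in event.extra_terms.items():
            graph.add((node, URIRef(T.token_to_iri(token)), Literal(value)))

    for occ in dataset.occurrences:
        node = occurrence_iri[occ.occurrence_id]
        graph.add((node, RDF.type, DWC.Occurrence))
        literals(node, occ, [(f, p) for f, p in _OCC_LITERALS if f != "event_id"])
        for token, value in occ.extra_terms.items():
            graph.add((node, URIRef(T.token_to_iri(token)), Literal(value)))
        graph.add((node, DSW.atEvent, event_iri[occ.event_id]))

    for rel in dataset.relationships:
        graph.add((occurrence_iri[rel.resource_id],
                   URIRef(rel.relationship_of_resource_iri),
                   occurrence_iri[rel.related_resource_id]))
        if reify_relationships:
            node = mint(base, "relationship", rel.relationship_id)
            graph.add((node, RDF.type, DWC.ResourceRelationship))
            graph.add((node, DWC.eventID, Literal(rel.event_id)))
            literals(node, rel, _REL_LITERALS)

    if registry is not None:
        from .dwca import _enrich_measurements
        measurements = _enrich_measurements(dataset, registry)
    else:
        measurements = dataset.measurements
    for m in measurements:
        node = mint(base, "mof", m.measurement_id)
        owner = (occurrence_iri[m.occurrence_id] if m.occurrence_id
                 else event_iri[m.event_id])
        graph.add((node, RDF.type, DWC.MeasurementOrFact))
        graph.add((owner, DCTERMS.relation, node))
        graph.add((node, DWC.measurementID, Literal(m.measurement_id)))
        if m.measurement_type_iri:
            graph.add((node, DWCIRI.measurementType, URIRef(m.measurement_type_iri)))
        if m.measurement_type:
            graph.add((node, DWC.measurementType, Literal(m.measurement_type)))
        if m.measurement_value is not None:
            graph.add((node, DWC.measurementValue, Literal(m.measurement_value)))
        if m.measurement_value_iri:
            if cv_values_as_objects:
                graph.add((node, DWCIRI.measurementValue, URIRef(m.measurement_value_iri)))
            else:
                graph.add((node, DWC.measurementValue,
                           Literal(m.measurement_value_iri, datatype=XSD.anyURI)))
        if m.measurement_unit:
            graph.add((node, DWC.measurementUnit, Literal(m.measurement_unit)))
        if m.measurement_unit_iri:
            graph.add((node, DWCIRI.measurementUnit, URIRef(m.measurement_unit_iri)))

    if dataset.provenance:
        graph.add((URIRef(base), DCTERMS.description, Literal(dataset.provenance)))
    return graph


def serialize_graph(graph: Graph, format: str = "turtle") -> bytes:
    """Serialize a graph as Turtle or N-Triples."""
    if format not in ("turtle", "ntriples"):
        raise UnsupportedFormatError(
            f"unsupported RDF format {format!r}; expected 'turtle' or 'ntriples'")
    rdflib_format = "nt" if format == "ntriples" else "turtle"
    payload = graph.serialize(format=rdflib_format)
    return payload.encode("utf-8") if isinstance(payload, str) else payload


def parse_graph(document: bytes | str, format: str = "turtle") -> Graph:
    """Parse Turtle or N-Triples back into a graph."""
    if format not in ("turtle", "ntriples"):
        raise UnsupportedFormatError(
            f"unsupported RDF format {format!r}; expected 'turtle' or 'ntriples'")
    rdflib_format = "nt" if format == "ntriples" else "turtle"
    graph = _bind(Graph())
    graph.parse(data=document, format=rdflib_format)
    return graph


def _str_of(graph: Graph, node, predicate) -> str | None:
    value = graph.value(node, predicate)
    return str(value) if value is not None else None


def from_triples(graph: Graph, base: str = DEFAULT_BASE,
                 ro_terms: dict[str, str] | None = None) -> InteractionDataset:
    """Reconstruct a dataset from a graph produced by :func:`to_triples`.

    Occurrences must be typed and linked to a typed event via
    ``dsw:atEvent``. Relationships come from reified
    ``dwc:ResourceRelationship`` nodes when present; otherwise from the bare
    occurrence-to-occurrence predicate triples, with deterministic minted
    identifiers, the predicate's label looked up in the (editable) RO
    mapping, and an empty assertion source (documented lossiness of the bare
    form). Unrelated triples are ignored with a logged notice.
    """
    ro_labels = {iri: label for label, iri in (ro_terms or RO_TERMS).items()}

    event_nodes = set(graph.subjects(RDF.type, DWC.Event))
    occ_nodes = set(graph.subjects(RDF.type, DWC.Occurrence))
    mof_nodes = set(graph.subjects(RDF.type, DWC.MeasurementOrFact))
    rr_nodes = set(graph.subjects(RDF.type, DWC.ResourceRelationship))

    def local_id(node, kind: str, predicate) -> str:
        value = _str_of(graph, node, predicate)
        if value:
            return value
        parsed = parse_minted(str(node), base)
        if parsed and parsed[0] == kind:
            return parsed[1]
        return str(node)

    events = []
    event_id_of: dict = {}
    for node in sorted(event_nodes):
        eid = local_id(node, "event", DWC.eventID)
        event_id_of[node] = eid
        known = {str(p) for _, p in _EVENT_LITERALS}
        extras = {}
        for _, p, o in graph.triples((node, None, None)):
            if p == RDF.type or str(p) in known:
                continue
            if isinstance(o, Literal):
                extras[T.iri_local_name(str(p))] = str(o)
        lat = _str_of(graph, node, DWC.decimalLatitude)
        lon = _str_of(graph, node, DWC.decimalLongitude)
        events.append(InteractionEvent(
            event_id=eid,
            event_date=_str_of(graph, node, DWC.eventDate),
            latitude=float(lat) if lat else None,
            longitude=float(lon) if lon else None,
            location_id=_str_of(graph, node, DWC.locationID),
            locality=_str_of(graph, node, DWC.locality),
            sampling_protocol=_str_of(graph, node, DWC.samplingProtocol),
            extra_terms=extras,
        ))

    occurrences = []
    occ_info: dict = {}
    for node in sorted(occ_nodes):
        event_node = graph.value(node, DSW.atEvent)
        if event_node is None:
            raise RDFStructureError(f"occurrence {node} has no dsw:atEvent triple")
        if event_node not in event_nodes:
            raise RDFStructureError(
                f"occurrence {node} is at event {event_node}, which lacks a "
                f"dwc:Event type statement")
        oid = local_id(node, "occurrence", DWC.occurrenceID)
        occ_info[node] = (oid, event_id_of[event_node])
        known = {str(p) for _, p in _OCC_LITERALS} | {str(DSW.atEvent)}
        extras = {}
        for _, p, o in graph.triples((node, None, None)):
            if p == RDF.type or str(p) in known:
                continue
            if isinstance(o, Literal):
                extras[T.iri_local_name(str(p))] = str(o)
        occurrences.append(OrganismOccurrence(
            occurrence_id=oid,
            event_id=event_id_of[event_node],
            scientific_name=_str_of(graph, node, DWC.scientificName) or "",
            taxon_rank=_str_of(graph, node, DWC.taxonRank),
            organism_role=_str_of(graph, node, APP.organismRole),  # type: ignore[arg-type]
            remarks=_str_of(graph, node, DWC.occurrenceRemarks),
            extra_terms=extras,
        ))

    measurements = []
    for node in sorted(mof_nodes):
        owners = [s for s in graph.subjects(DCTERMS.relation, node)]
        occurrence_id = None
        event_id = ""
        for owner in owners:
            if owner in occ_nodes:
                occurrence_id, event_id = occ_info[owner]
            elif owner in event_nodes:
                event_id = event_id_of[owner]
        value = None
        value_iri = None
        for v in graph.objects(node, DWC.measurementValue):
            if isinstance(v, Literal) and v.datatype == XSD.anyURI:
                value_iri = str(v)
            else:
                value = str(v)
        obj_value = graph.value(node, DWCIRI.measurementValue)
        if obj_value is not None:
            value_iri = str(obj_value)
        type_iri = graph.value(node, DWCIRI.measurementType)
        unit_iri = graph.value(node, DWCIRI.measurementUnit)
        measurements.append(Measurement(
            measurement_id=local_id(node, "mof", DWC.measurementID),
            event_id=event_id,
            occurrence_id=occurrence_id,
            measurement_type=_str_of(graph, node, DWC.measurementType),
            measurement_type_iri=str(type_iri) if type_iri is not None else None,
            measurement_value=value,
            measurement_value_iri=value_iri,
            measurement_unit=_str_of(graph, node, DWC.measurementUnit),
            measurement_unit_iri=str(unit_iri) if unit_iri is not None else None,
        ))

    relationships = []
    covered: set[tuple] = set()
    for node in sorted(rr_nodes):
        rel = InteractionRelationship(
            relationship_id=local_id(node, "relationship", DWC.resourceRelationshipID),
            event_id=_str_of(graph, node, DWC.eventID) or "",
            resource_id=_str_of(graph, node, DWC.resourceID) or "",
            related_resource_id=_str_of(graph, node, DWC.relatedResourceID) or "",
            relationship_of_resource=_str_of(graph, node, DWC.relationshipOfResource),
            relationship_of_resource_iri=_str_of(graph, node, DWC.relationshipOfResourceID),
            relationship_according_to=_str_of(graph, node, DWC.relationshipAccordingTo) or "",
        )
        relationships.append(rel)
        covered.add((rel.resource_id, rel.relationship_of_resource_iri,
                     rel.related_resource_id))

    bare = []
    for s, p, o in graph:
        if s in occ_nodes and o in occ_nodes and p not in (DSW.atEvent, RDF.type):
            sid, s_event = occ_info[s]
            oid, _ = occ_info[o]
            if (sid, str(p), oid) in covered:
                continue
            bare.append((sid, str(p), oid, s_event))
    for n, (sid, predicate, oid, s_event) in enumerate(sorted(bare)):
        relationships.append(InteractionRelationship(
            relationship_id=f"relationship-{n + 1:04d}",
            event_id=s_event,
            resource_id=sid,
            related_resource_id=oid,
            relationship_of_resource=ro_labels.get(predicate),
            relationship_of_resource_iri=predicate,
            relationship_according_to="",
        ))

    mapped_nodes = event_nodes | occ_nodes | mof_nodes | rr_nodes
    stray = [s for s in set(graph.subjects())
             if s not in mapped_nodes and str(s) != base.rstrip("/") and str(s) != base]
    if stray:
        logger.info("ignoring %d subject(s) outside the interaction mapping", len(stray))

    provenance = _str_of(graph, URIRef(base), DCTERMS.description)
    return InteractionDataset(events=events, occurrences=occurrences,
                              measurements=measurements, relationships=relationships,
                              provenance=provenance)
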