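"""Single-document XML serialization of interaction datasets.

One-to-many links that the archive star schema can only express through the
eMoF workaround are expressed here by identifier references: the document
holds flat ``Event``, ``Occurrence``, ``MeasurementOrFact`` and
``ResourceRelationship`` elements (in that order), each record's Darwin Core
terms as child elements in the DWC term namespace. Every measurement appears
exactly once as a ``MeasurementOrFact`` element carrying a ``measurementID``;
the owning ``Event`` or ``Occurrence`` element repeats that identifier in a
``measurementID`` child to claim it. ``docs/xml-layout.md`` describes the
dialect.

Parsing rejects any document carrying a DTD, so external entity
declarations cannot be smuggled in.
"""

from __future__ import annotations

from lxml import etree

from . import _terms as T
from .errors import DatasetContractError, XMLSecurityError
from .model import (
    InteractionDataset,
    InteractionEvent,
    InteractionRelationship,
    Measurement,
    OrganismOccurrence,
    validate_dataset,
)

_NSMAP = {"dwc": T.DWC, "obis": T.OBIS, "app": "urn:ppidata:xml"}
_ROOT_TAG = "{urn:ppidata:xml}interactionDataset"

_DWC = f"{{{T.DWC}}}"
_OBIS = f"{{{T.OBIS}}}"

# token -> qualified element name; measurement ID-terms live in the OBIS
# namespace, organismRole in the artifact namespace, all else in DWC.
_OBIS_TOKENS = {"measurementTypeID", "measurementValueID", "measurementUnitID"}
_APP_TOKENS = {"organismRole"}


def _qname(token: str) -> str:
    if token in _OBIS_TOKENS:
        return _OBIS + token
    if token in _APP_TOKENS:
        return "{urn:ppidata:xml}" + token
    return _DWC + token


def _add(parent, token: str, value) -> None:
    if value is None or value == "":
        return
    el = etree.SubElement(parent, _qname(token))
    el.text = str(value)


def write_xml(dataset: InteractionDataset) -> bytes:
    """Serialize a valid dataset as one namespaced XML document."""
    report = validate_dataset(dataset)
    if not report.is_valid:
        raise DatasetContractError(
            "refusing to serialize an invalid dataset: "
            + "; ".join(f.message for f in report.errors[:5]))

    root = etree.Element(_ROOT_TAG, nsmap=_NSMAP)
    if dataset.provenance:
        root.set("provenance", dataset.provenance)

    # measurement ownership: occurrence if occurrence_id is set, else event
    event_refs: dict[str, list[str]] = {}
    occ_refs: dict[str, list[str]] = {}
    for m in dataset.measurements:
        if m.occurrence_id:
            occ_refs.setdefault(m.occurrence_id, []).append(m.measurement_id)
        else:
            event_refs.setdefault(m.event_id, []).append(m.measurement_id)

    for event in dataset.events:
        el = etree.SubElement(root, _DWC + "Event")
        _add(el, "eventID", event.event_id)
        _add(el, "eventDate", event.event_date)
        _add(el, "decimalLatitude", event.latitude)
        _add(el, "decimalLongitude", event.longitude)
        _add(el, "locationID", event.location_id)
        _add(el, "locality", event.locality)
        _add(el, "samplingProtocol", event.sampling_protocol)
        for token, value in event.extra_terms.items():
            if token != "measurementID":
                _add(el, token, value)
        for mid in event_refs.get(event.event_id, ()):
            _add(el, "measurementID", mid)
        # unmatched references carried in extra_terms stay references
        for mid in (event.extra_terms.get("measurementID") or "").split(";"):
            if mid.strip():
                _add(el, "measurementID", mid.strip())

    for occ in dataset.occurrences:
        el = etree.SubElement(root, _DWC + "Occurrence")
        _add(el, "occurrenceID", occ.occurrence_id)
        _add(el, "eventID", occ.event_id)
        _add(el, "scientificName", occ.scientific_name)
        _add(el, "taxonRank", occ.taxon_rank)
        _add(el, "organismRole", occ.organism_role)
        _add(el, "occurrenceRemarks", occ.remarks)
        for token, value in occ.extra_terms.items():
            if token != "measurementID":
                _add(el, token, value)
        for mid in occ_refs.get(occ.occurrence_id, ()):
            _add(el, "measurementID", mid)
        for mid in (occ.extra_terms.get("measurementID") or "").split(";"):
            if mid.strip():
                _add(el, "measurementID", mid.strip())

    for m in dataset.measurements:
        el = etree.SubElement(root, _DWC + "MeasurementOrFact")
        _add(el, "measurementID", m.measurement_id)
        _add(el, "measurementType", m.measurement_type)
        _add(el, "measurementTypeID", m.measurement_type_iri)
        _add(el, "measurementValue", m.measurement_value)
        _add(el, "measurementValueID", m.measurement_value_iri)
        _add(el, "measurementUnit", m.measurement_unit)
        _add(el, "measurementUnitID", m.measurement_unit_iri)

    for rel in dataset.relationships:
        el = etree.SubElement(root, _DWC + "ResourceRelationship")
        _add(el, "resourceRelationshipID", rel.relationship_id)
        _add(el, "eventID", rel.event_id)
        _add(el, "resourceID", rel.resource_id)
        _add(el, "relatedResourceID", rel.related_resource_id)
        _add(el, "relationshipOfResource", rel.relationship_of_resource)
        _add(el, "relationshipOfResourceID", rel.relationship_of_resource_iri)
        _add(el, "relationshipAccordingTo", rel.relationship_according_to)

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _parse_secure(document: bytes):
    parser = etree.XMLParser(resolve_entities=False, no_network=True)
    root = etree.fromstring(document, parser=parser)
    docinfo = root.getroottree().docinfo
    if docinfo.doctype or docinfo.internalDTD is not None:
        raise XMLSecurityError("documents with DTD/entity declarations are rejected")
    return root


def _texts(el, token: str) -> list[str]:
    return [child.text or "" for child in el.findall(_qname(token))]


def _text(el, token: str) -> str | None:
    values = _texts(el, token)
    return values[0] if values else None


def _float_text(el, token: str) -> float | None:
    value = _text(el, token)
    return float(value) if value not in (None, "") else None


_KNOWN_EVENT = {"eventID", "eventDate", "decimalLatitude", "decimalLongitude",
                "locationID", "locality", "samplingProtocol", "measurementID"}
_KNOWN_OCC = {"occurrenceID", "eventID", "scientificName", "taxonRank",
              "organismRole", "occurrenceRemarks", "measurementID"}


def _extras(el, known: set[str]) -> dict[str, str]:
    extras: dict[str, str] = {}
    for child in el:
        token = etree.QName(child).localname
        if token not in known and child.text:
            extras[token] = child.text
    return extras


def read_xml(document: bytes) -> InteractionDataset:
    """Parse a document produced by :func:`write_xml` back into a dataset.

    ``measurementID`` references are resolved against the
    ``MeasurementOrFact`` elements; a reference with no matching element is
    preserved in the owner's ``extra_terms`` and surfaces as a
    ``DANGLING_REFERENCE`` finding on validation rather than a read failure.
    """
    root = _parse_secure(document)

    measurements: list[Measurement] = []
    mof_ids: set[str] = set()
    for el in root.findall(_DWC + "MeasurementOrFact"):
        m = Measurement(
            measurement_id=_text(el, "measurementID") or "",
            event_id="",  # filled below from the owning element
            measurement_type=_text(el, "measurementType"),
            measurement_type_iri=_text(el, "measurementTypeID"),
            measurement_value=_text(el, "measurementValue"),
            measurement_value_iri=_text(el, "measurementValueID"),
            measurement_unit=_text(el, "measurementUnit"),
            measurement_unit_iri=_text(el, "measurementUnitID"),
        )
        measurements.append(m)
        mof_ids.add(m.measurement_id)
    by_id = {m.measurement_id: m for m in measurements}

    def claim(refs: list[str], event_id: str, occurrence_id: str | None,
              extras: dict[str, str]) -> None:
        unmatched = []
        for mid in refs:
            m = by_id.get(mid)
            if m is None:
                unmatched.append(mid)
                continue
            m.event_id = event_id
            m.occurrence_id = occurrence_id
        if unmatched:
            extras["measurementID"] = ";".join(unmatched)

    events = []
    for el in root.findall(_DWC + "Event"):
        extras = _extras(el, _KNOWN_EVENT)
        event = InteractionEvent(
            event_id=_text(el, "eventID") or "",
            event_date=_text(el, "eventDate"),
            latitude=_float_text(el, "decimalLatitude"),
            longitude=_float_text(el, "decimalLongitude"),
            location_id=_text(el, "locationID"),
            locality=_text(el, "locality"),
            sampling_protocol=_text(el, "samplingProtocol"),
            extra_terms=extras,
        )
        claim(_texts(el, "measurementID"), event.event_id, None, extras)
        events.append(event)

    occurrences = []
    for el in root.findall(_DWC + "Occurrence"):
        extras = _extras(el, _KNOWN_OCC)
        occ = OrganismOccurrence(
            occurrence_id=_text(el, "occurrenceID") or "",
            event_id=_text(el, "eventID") or "",
            scientific_name=_text(el, "scientificName") or "",
            taxon_rank=_text(el, "taxonRank"),
            organism_role=_text(el, "organismRole"),  # type: ignore[arg-type]
            remarks=_text(el, "occurrenceRemarks"),
            extra_terms=extras,
        )
        claim(_texts(el, "measurementID"), occ.event_id, occ.occurrence_id, extras)
        occurrences.append(occ)

    relationships = []
    for el in root.findall(_DWC + "ResourceRelationship"):
        relationships.append(InteractionRelationship(
            relationship_id=_text(el, "resourceRelationshipID") or "",
            event_id=_text(el, "eventID") or "",
            resource_id=_text(el, "resourceID") or "",
            related_resource_id=_text(el, "relatedResourceID") or "",
            relationship_of_resource=_text(el, "relationshipOfResource"),
            relationship_of_resource_iri=_text(el, "relationshipOfResourceID"),
            relationship_according_to=_text(el, "relationshipAccordingTo") or "",
        ))

    return InteractionDataset(
        events=events, occurrences=occurrences, measurements=measurements,
        relationships=relationships, provenance=root.get("provenance"))
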