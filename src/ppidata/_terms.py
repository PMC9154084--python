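"""Namespace constants and field-to-term mapping tables shared by the serializers.

Every serializer (flat tables, DwC-Archive, XML, RDF) names record fields by
the same Darwin Core term tokens; the tables here are the single source of
truth for the token and IRI attached to each model field, and for the fixed
column orders of the archive tables.
"""

from __future__ import annotations

# Namespaces
DWC = "http://rs.tdwg.org/dwc/terms/"
DWCIRI = "http://rs.tdwg.org/dwc/iri/"
DSW = "http://purl.org/dsw/"
DCTERMS = "http://purl.org/dc/terms/"
PPI = "http://rs.rebipp.org.br/ppi/terms/"
RO = "http://purl.obolibrary.org/obo/RO_"
OBIS = "http://rs.iobis.org/obis/terms/"
DWC_TEXT = "http://rs.tdwg.org/dwc/text/"
# Artifact-defined dialect terms with no Darwin Core equivalent.
APP = "urn:ppidata:terms:"

# Row-type IRIs (DwC text guide / OBIS registered extensions)
EVENT_ROWTYPE = DWC + "Event"
OCCURRENCE_ROWTYPE = DWC + "Occurrence"
EMOF_ROWTYPE = OBIS + "ExtendedMeasurementOrFact"
RESOURCERELATIONSHIP_ROWTYPE = DWC + "ResourceRelationship"

# model field -> (term token, term IRI), in serialization order.
EVENT_FIELDS: list[tuple[str, str, str]] = [
    ("event_id", "eventID", DWC + "eventID"),
    ("event_date", "eventDate", DWC + "eventDate"),
    ("latitude", "decimalLatitude", DWC + "decimalLatitude"),
    ("longitude", "decimalLongitude", DWC + "decimalLongitude"),
    ("location_id", "locationID", DWC + "locationID"),
    ("locality", "locality", DWC + "locality"),
    ("sampling_protocol", "samplingProtocol", DWC + "samplingProtocol"),
]

OCCURRENCE_FIELDS: list[tuple[str, str, str]] = [
    ("occurrence_id", "occurrenceID", DWC + "occurrenceID"),
    ("scientific_name", "scientificName", DWC + "scientificName"),
    ("taxon_rank", "taxonRank", DWC + "taxonRank"),
    ("remarks", "occurrenceRemarks", DWC + "occurrenceRemarks"),
    ("organism_role", "organismRole", APP + "organismRole"),
]

MEASUREMENT_FIELDS: list[tuple[str, str, str]] = [
    ("measurement_id", "measurementID", DWC + "measurementID"),
    ("measurement_type", "measurementType", DWC + "measurementType"),
    ("measurement_type_iri", "measurementTypeID", OBIS + "measurementTypeID"),
    ("measurement_value", "measurementValue", DWC + "measurementValue"),
    ("measurement_value_iri", "measurementValueID", OBIS + "measurementValueID"),
    ("measurement_unit", "measurementUnit", DWC + "measurementUnit"),
    ("measurement_unit_iri", "measurementUnitID", OBIS + "measurementUnitID"),
]

RELATIONSHIP_FIELDS: list[tuple[str, str, str]] = [
    ("relationship_id", "resourceRelationshipID", DWC + "resourceRelationshipID"),
    ("resource_id", "resourceID", DWC + "resourceID"),
    ("related_resource_id", "relatedResourceID", DWC + "relatedResourceID"),
    ("relationship_of_resource", "relationshipOfResource", DWC + "relationshipOfResource"),
    ("relationship_of_resource_iri", "relationshipOfResourceID", DWC + "relationshipOfResourceID"),
    ("relationship_according_to", "relationshipAccordingTo", DWC + "relationshipAccordingTo"),
]

# The classic MeasurementOrFact column set (DwC MeasurementOrFact class terms
# usable in a flat extension); the eMoF extension adds exactly three ID terms.
CLASSIC_MOF_COLUMNS = frozenset({
    "measurementID", "measurementType", "measurementValue", "measurementAccuracy",
    "measurementUnit", "measurementDeterminedDate", "measurementDeterminedBy",
    "measurementMethod", "measurementRemarks", "occurrenceID", "eventID",
})
EMOF_NEW_COLUMNS = ("measurementTypeID", "measurementValueID", "measurementUnitID")

FLOAT_FIELDS = {"latitude", "longitude"}


def token_to_iri(token: str) -> str:
    """Best-effort IRI for an unmapped column token (open-world extras)."""
    if token == "organismRole":
        return APP + token
    return DWC + token


def iri_local_name(iri: str) -> str:
    for sep in ("#", "/", ":"):
        if sep in iri:
            return iri.rsplit(sep, 1)[1]
    return iri
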