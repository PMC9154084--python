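"""In-memory model for individual-level plant-pollinator interaction records.

An interaction is modelled as a Darwin Core Event: an action at a place and
time. Each event owns the occurrences of the two interacting organisms, zero
or more typed measurements (of the interaction itself, or of one of the
participants), and one or more directed relationships whose subject and
object are occurrences of that same event. The minimal contract for a
shareable interaction record is:

* every occurrence carries a scientific name (any determinable rank),
* every event carries an event identifier,
* every relationship names its subject (``resourceID``), its object
  (``relatedResourceID``), an interaction type (text or IRI), and the source
  of the assertion (``relationshipAccordingTo``).

``validate_dataset`` turns violations into coded findings rather than
exceptions; ``canonicalize`` defines the normal form under which datasets
are compared for serialization round trips.

Reference-resolution semantics: an event link (``event_id`` on a child
record) that is *non-empty* but unresolvable is a ``DANGLING_REFERENCE``
error; an *empty* event link produces no finding, because in the star-schema
reading the core identifier lives on the event record and its absence is
already reported there as ``MISSING_EVENT_ID``. Relationship subject/object
references, by contrast, are themselves part of the minimal contract, so for
them empty and unresolvable are both ``DANGLING_REFERENCE``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterable, Literal

from .errors import DatasetContractError
from .registry import TermRegistry, validate_controlled_value

Severity = Literal["error", "warning"]

# Finding codes, in one place so tools can enumerate them.
MISSING_SCIENTIFIC_NAME = "MISSING_SCIENTIFIC_NAME"
MISSING_EVENT_ID = "MISSING_EVENT_ID"
DANGLING_REFERENCE = "DANGLING_REFERENCE"
MISSING_RELATIONSHIP_TYPE = "MISSING_RELATIONSHIP_TYPE"
MISSING_ACCORDING_TO = "MISSING_ACCORDING_TO"
SELF_RELATIONSHIP = "SELF_RELATIONSHIP"
DUPLICATE_ID = "DUPLICATE_ID"
UNKNOWN_MEASUREMENT_TYPE = "UNKNOWN_MEASUREMENT_TYPE"
CV_VIOLATION = "CV_VIOLATION"
EVENT_WITHOUT_RELATIONSHIP = "EVENT_WITHOUT_RELATIONSHIP"


@dataclass
class InteractionEvent:
    """One interaction: an action at some location during some time."""

    event_id: str
    event_date: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    location_id: str | None = None
    locality: str | None = None
    sampling_protocol: str | None = None
    extra_terms: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"event {self.event_id!r}: latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"event {self.event_id!r}: longitude {self.longitude} outside [-180, 180]"
            )


@dataclass
class OrganismOccurrence:
    """The occurrence of one interacting organism (or homogeneous group)."""

    occurrence_id: str
    event_id: str
    scientific_name: str
    taxon_rank: str | None = None
    organism_role: Literal["plant", "animal", "unknown"] | None = None
    remarks: str | None = None  # houses functional-group annotations
    extra_terms: dict[str, str] = dc_field(default_factory=dict)


@dataclass
class Measurement:
    """A typed measurement of an interaction or of one of its participants.

    An empty ``occurrence_id`` means the measurement describes the
    interaction itself (event level); otherwise it describes the referenced
    occurrence. ``measurement_type_iri`` should carry a vocabulary term IRI;
    ``measurement_type`` the human-readable counterpart.
    """

    measurement_id: str
    event_id: str
    occurrence_id: str | None = None
    measurement_type: str | None = None
    measurement_type_iri: str | None = None
    measurement_value: str | None = None
    measurement_value_iri: str | None = None
    measurement_unit: str | None = None
    measurement_unit_iri: str | None = None

    def __post_init__(self) -> None:
        if not (self.measurement_type or self.measurement_type_iri):
            raise ValueError(
                f"measurement {self.measurement_id!r}: needs measurement_type or measurement_type_iri"
            )


@dataclass
class InteractionRelationship:
    """The directed, typed link between the two interacting occurrences."""

    relationship_id: str
    event_id: str
    resource_id: str  # subject of the interaction
    related_resource_id: str  # object of the interaction
    relationship_of_resource: str | None = None
    relationship_of_resource_iri: str | None = None
    relationship_according_to: str = ""


@dataclass
class InteractionDataset:
    """An ordered collection of events, occurrences, measurements, relationships."""

    events: list[InteractionEvent] = dc_field(default_factory=list)
    occurrences: list[OrganismOccurrence] = dc_field(default_factory=list)
    measurements: list[Measurement] = dc_field(default_factory=list)
    relationships: list[InteractionRelationship] = dc_field(default_factory=list)
    provenance: str | None = None

    def events_by_id(self) -> dict[str, InteractionEvent]:
        return {e.event_id: e for e in self.events if e.event_id}

    def occurrences_by_id(self) -> dict[str, OrganismOccurrence]:
        return {o.occurrence_id: o for o in self.occurrences if o.occurrence_id}

    def measurements_by_id(self) -> dict[str, Measurement]:
        return {m.measurement_id: m for m in self.measurements if m.measurement_id}


@dataclass(frozen=True)
class Finding:
    severity: Severity
    code: str
    record_ref: str
    message: str


@dataclass
class ValidationReport:
    """Ordered list of coded findings from :func:`validate_dataset`."""

    findings: list[Finding] = dc_field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]


_KIND_ORDER = {"event": 0, "occurrence": 1, "measurement": 2, "relationship": 3}


def validate_dataset(
    dataset: InteractionDataset, registry: TermRegistry | None = None
) -> ValidationReport:
    """Check a dataset against the minimal-record contract.

    Structural problems (missing minimal fields, unresolvable references,
    duplicate identifiers, self-relationships) are errors; vocabulary
    problems (unknown measurement-type IRIs, controlled-vocabulary
    violations) and events without any relationship are warnings. Registry
    checks are skipped when no registry is given. Findings are deterministic,
    sorted by (record kind, record id, code).
    """
    raw: list[tuple[str, Finding]] = []

    def add(kind: str, severity: Severity, code: str, ref: str, message: str) -> None:
        raw.append((kind, Finding(severity, code, ref, message)))

    for kind, records, key in (
        ("event", dataset.events, lambda r: r.event_id),
        ("occurrence", dataset.occurrences, lambda r: r.occurrence_id),
        ("measurement", dataset.measurements, lambda r: r.measurement_id),
        ("relationship", dataset.relationships, lambda r: r.relationship_id),
    ):
        seen: set[str] = set()
        for record in records:
            rid = key(record)
            if rid and rid in seen:
                add(kind, "error", DUPLICATE_ID, rid, f"duplicate {kind} id {rid!r}")
            seen.add(rid)

    events = dataset.events_by_id()
    occurrences = dataset.occurrences_by_id()
    measurements = dataset.measurements_by_id()

    events_with_relationship = {r.event_id for r in dataset.relationships}
    for event in dataset.events:
        if not event.event_id.strip():
            add("event", "error", MISSING_EVENT_ID, event.event_id,
                "event is missing its eventID")
        elif event.event_id not in events_with_relationship:
            add("event", "warning", EVENT_WITHOUT_RELATIONSHIP, event.event_id,
                f"event {event.event_id!r} has no relationship documenting an interaction")
        _check_measurement_refs(event.extra_terms, measurements,
                                lambda *a: add("event", *a), event.event_id)

    for occ in dataset.occurrences:
        if not occ.scientific_name.strip():
            add("occurrence", "error", MISSING_SCIENTIFIC_NAME, occ.occurrence_id,
                f"occurrence {occ.occurrence_id!r} is missing its scientificName")
        if occ.event_id.strip() and occ.event_id not in events:
            add("occurrence", "error", DANGLING_REFERENCE, occ.occurrence_id,
                f"occurrence {occ.occurrence_id!r} references unknown event {occ.event_id!r}")
        _check_measurement_refs(occ.extra_terms, measurements,
                                lambda *a: add("occurrence", *a), occ.occurrence_id)

    for m in dataset.measurements:
        if m.event_id.strip() and m.event_id not in events:
            add("measurement", "error", DANGLING_REFERENCE, m.measurement_id,
                f"measurement {m.measurement_id!r} references unknown event {m.event_id!r}")
        if m.occurrence_id:
            target = occurrences.get(m.occurrence_id)
            if target is None:
                add("measurement", "error", DANGLING_REFERENCE, m.measurement_id,
                    f"measurement {m.measurement_id!r} references unknown occurrence "
                    f"{m.occurrence_id!r}")
            elif target.event_id != m.event_id:
                add("measurement", "error", DANGLING_REFERENCE, m.measurement_id,
                    f"measurement {m.measurement_id!r} targets occurrence {m.occurrence_id!r} "
                    f"of a different event")
        if registry is not None and m.measurement_type_iri:
            term = registry.index_by_iri.get(m.measurement_type_iri)
            if term is None:
                add("measurement", "warning", UNKNOWN_MEASUREMENT_TYPE, m.measurement_id,
                    f"measurement type IRI {m.measurement_type_iri!r} is not in the registry")
            elif m.measurement_value is not None:
                accepted, _ = validate_controlled_value(term, m.measurement_value)
                if not accepted:
                    add("measurement", "warning", CV_VIOLATION, m.measurement_id,
                        f"value {m.measurement_value!r} is not in the controlled vocabulary "
                        f"of {term.term_name}")

    for rel in dataset.relationships:
        if rel.event_id.strip() and rel.event_id not in events:
            add("relationship", "error", DANGLING_REFERENCE, rel.relationship_id,
                f"relationship {rel.relationship_id!r} references unknown event "
                f"{rel.event_id!r}")
        for role, ref in (("subject", rel.resource_id), ("object", rel.related_resource_id)):
            target = occurrences.get(ref) if ref else None
            if target is None:
                add("relationship", "error", DANGLING_REFERENCE, rel.relationship_id,
                    f"relationship {rel.relationship_id!r} {role} {ref!r} does not resolve "
                    f"to an occurrence")
            elif target.event_id != rel.event_id:
                add("relationship", "error", DANGLING_REFERENCE, rel.relationship_id,
                    f"relationship {rel.relationship_id!r} {role} {ref!r} belongs to a "
                    f"different event")
        if rel.resource_id and rel.resource_id == rel.related_resource_id:
            add("relationship", "error", SELF_RELATIONSHIP, rel.relationship_id,
                f"relationship {rel.relationship_id!r} relates an occurrence to itself")
        if not ((rel.relationship_of_resource or "").strip()
                or (rel.relationship_of_resource_iri or "").strip()):
            add("relationship", "error", MISSING_RELATIONSHIP_TYPE, rel.relationship_id,
                f"relationship {rel.relationship_id!r} has no interaction type")
        if not rel.relationship_according_to.strip():
            add("relationship", "error", MISSING_ACCORDING_TO, rel.relationship_id,
                f"relationship {rel.relationship_id!r} has no relationshipAccordingTo source")

    raw.sort(key=lambda pair: (_KIND_ORDER[pair[0]], pair[1].record_ref, pair[1].code))
    return ValidationReport(findings=[finding for _, finding in raw])


def _check_measurement_refs(extra_terms, measurements, add, ref) -> None:
    # measurementID references kept in extra_terms (XML dialect) must resolve
    for mid in (extra_terms.get("measurementID") or "").split(";"):
        mid = mid.strip()
        if mid and mid not in measurements:
            add("error", DANGLING_REFERENCE, ref,
                f"measurementID reference {mid!r} does not resolve to a measurement")


def parse_associated_taxa(raw: str) -> list[tuple[str, str]]:
    """Parse a legacy ``associatedTaxa`` string into (relationship, taxon) pairs.

    The term holds a concatenated-and-separated list of taxon names, each
    optionally qualified by the kind of association, e.g.
    ``'"pollinator of":"Fuchsia magellanica"'``. Entries are split on ``|``;
    within each entry the first ``:`` separates the relationship qualifier
    from the taxon name, and surrounding quotes and whitespace are stripped.
    An entry with no ``:`` yields an empty relationship and the whole entry
    as the taxon.
    """
    def unquote(text: str) -> str:
        text = text.strip()
        if len(text) >= 2 and text[0] == text[-1] and text[0] in "\"'":
            text = text[1:-1]
        return text.strip()

    pairs: list[tuple[str, str]] = []
    for entry in raw.split("|"):
        entry = entry.strip()
        if not entry:
            continue
        if ":" in entry:
            relationship, taxon = entry.split(":", 1)
            pairs.append((unquote(relationship), unquote(taxon)))
        else:
            pairs.append(("", unquote(entry)))
    return pairs


def format_associated_taxa(pairs: Iterable[tuple[str, str]]) -> str:
    """Companion formatter to :func:`parse_associated_taxa`."""
    entries = []
    for relationship, taxon in pairs:
        entries.append(f'"{relationship}":"{taxon}"' if relationship else f'"{taxon}"')
    return " | ".join(entries)


def _strip_record(record):
    updates = {}
    for f in dataclasses.fields(record):
        value = getattr(record, f.name)
        if isinstance(value, str):
            updates[f.name] = value.strip()
        elif isinstance(value, dict):
            updates[f.name] = {
                k.strip(): v.strip() if isinstance(v, str) else v
                for k, v in sorted(value.items())
            }
    return dataclasses.replace(record, **updates)


def canonicalize(dataset: InteractionDataset) -> InteractionDataset:
    """Return the dataset in normal form: trimmed fields, records sorted by id.

    The normal form defines dataset equality for round-trip comparisons. The
    dataset must be free of validation errors (warnings are fine);
    canonicalization is idempotent and invariant under record-order
    permutations.
    """
    trimmed = InteractionDataset(
        events=[_strip_record(e) for e in dataset.events],
        occurrences=[_strip_record(o) for o in dataset.occurrences],
        measurements=[_strip_record(m) for m in dataset.measurements],
        relationships=[_strip_record(r) for r in dataset.relationships],
        provenance=dataset.provenance.strip() if dataset.provenance else None,
    )
    report = validate_dataset(trimmed)
    if not report.is_valid:
        raise DatasetContractError(
            "cannot canonicalize an invalid dataset: "
            + "; ".join(f.message for f in report.errors[:5])
        )
    trimmed.events.sort(key=lambda e: e.event_id)
    trimmed.occurrences.sort(key=lambda o: o.occurrence_id)
    trimmed.measurements.sort(key=lambda m: m.measurement_id)
    trimmed.relationships.sort(key=lambda r: r.relationship_id)
    return trimmed


def datasets_equal(a: InteractionDataset, b: InteractionDataset) -> bool:
    """Equality after canonicalization."""
    return canonicalize(a) == canonicalize(b)
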