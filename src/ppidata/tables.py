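"""Flat CSV ingest/export: four tables keyed by Darwin Core term tokens.

A dataset is exchanged as ``events.csv``, ``occurrences.csv``,
``measurements.csv`` and ``relationships.csv`` in one directory, with header
tokens equal to the DWC/OBIS term names (``eventID``, ``scientificName``,
``measurementTypeID``, ...). Unknown columns are preserved verbatim in each
record's ``extra_terms``. This module also provides the cell-level record
conversion reused by the archive writer.
"""

from __future__ import annotations

import csv
from pathlib import Path

from . import _terms as T
from .model import (
    InteractionDataset,
    InteractionEvent,
    InteractionRelationship,
    Measurement,
    OrganismOccurrence,
)

_EVENT_TOKENS = {tok for _, tok, _ in T.EVENT_FIELDS}
_OCC_TOKENS = {tok for _, tok, _ in T.OCCURRENCE_FIELDS} | {"eventID"}
_MEAS_TOKENS = {tok for _, tok, _ in T.MEASUREMENT_FIELDS} | {"eventID", "occurrenceID"}
_REL_TOKENS = {tok for _, tok, _ in T.RELATIONSHIP_FIELDS} | {"eventID"}


def _cell(value) -> str:
    if value is None:
        return ""
    return str(value)


def event_to_cells(event: InteractionEvent) -> dict[str, str]:
    cells = {tok: _cell(getattr(event, f)) for f, tok, _ in T.EVENT_FIELDS}
    cells.update(event.extra_terms)
    return cells


def occurrence_to_cells(occ: OrganismOccurrence) -> dict[str, str]:
    cells = {"eventID": occ.event_id}
    cells.update({tok: _cell(getattr(occ, f)) for f, tok, _ in T.OCCURRENCE_FIELDS})
    cells.update(occ.extra_terms)
    return cells


def measurement_to_cells(m: Measurement) -> dict[str, str]:
    cells = {"eventID": m.event_id, "occurrenceID": _cell(m.occurrence_id)}
    cells.update({tok: _cell(getattr(m, f)) for f, tok, _ in T.MEASUREMENT_FIELDS})
    return cells


def relationship_to_cells(rel: InteractionRelationship) -> dict[str, str]:
    cells = {"eventID": rel.event_id}
    cells.update({tok: _cell(getattr(rel, f)) for f, tok, _ in T.RELATIONSHIP_FIELDS})
    return cells


def _opt(cells: dict[str, str], token: str) -> str | None:
    value = cells.get(token, "")
    return value if value != "" else None


def _float(cells: dict[str, str], token: str) -> float | None:
    value = cells.get(token, "")
    return float(value) if value != "" else None


def event_from_cells(cells: dict[str, str]) -> InteractionEvent:
    extras = {k: v for k, v in cells.items() if k not in _EVENT_TOKENS and v != ""}
    return InteractionEvent(
        event_id=cells.get("eventID", ""),
        event_date=_opt(cells, "eventDate"),
        latitude=_float(cells, "decimalLatitude"),
        longitude=_float(cells, "decimalLongitude"),
        location_id=_opt(cells, "locationID"),
        locality=_opt(cells, "locality"),
        sampling_protocol=_opt(cells, "samplingProtocol"),
        extra_terms=extras,
    )


def occurrence_from_cells(cells: dict[str, str]) -> OrganismOccurrence:
    extras = {k: v for k, v in cells.items() if k not in _OCC_TOKENS and v != ""}
    role = _opt(cells, "organismRole")
    return OrganismOccurrence(
        occurrence_id=cells.get("occurrenceID", ""),
        event_id=cells.get("eventID", ""),
        scientific_name=cells.get("scientificName", ""),
        taxon_rank=_opt(cells, "taxonRank"),
        organism_role=role,  # type: ignore[arg-type]
        remarks=_opt(cells, "occurrenceRemarks"),
        extra_terms=extras,
    )


def measurement_from_cells(cells: dict[str, str]) -> Measurement:
    return Measurement(
        measurement_id=cells.get("measurementID", ""),
        event_id=cells.get("eventID", ""),
        occurrence_id=_opt(cells, "occurrenceID"),
        measurement_type=_opt(cells, "measurementType"),
        measurement_type_iri=_opt(cells, "measurementTypeID"),
        measurement_value=_opt(cells, "measurementValue"),
        measurement_value_iri=_opt(cells, "measurementValueID"),
        measurement_unit=_opt(cells, "measurementUnit"),
        measurement_unit_iri=_opt(cells, "measurementUnitID"),
    )


def relationship_from_cells(cells: dict[str, str]) -> InteractionRelationship:
    return InteractionRelationship(
        relationship_id=cells.get("resourceRelationshipID", ""),
        event_id=cells.get("eventID", ""),
        resource_id=cells.get("resourceID", ""),
        related_resource_id=cells.get("relatedResourceID", ""),
        relationship_of_resource=_opt(cells, "relationshipOfResource"),
        relationship_of_resource_iri=_opt(cells, "relationshipOfResourceID"),
        relationship_according_to=cells.get("relationshipAccordingTo", ""),
    )


def table_columns(dataset: InteractionDataset) -> dict[str, list[str]]:
    """Column order per table: fixed columns first, then sorted extras."""
    event_extras = sorted({k for e in dataset.events for k in e.extra_terms})
    occ_extras = sorted({k for o in dataset.occurrences for k in o.extra_terms})
    return {
        "events": [tok for _, tok, _ in T.EVENT_FIELDS] + event_extras,
        "occurrences": (["eventID"] + [tok for _, tok, _ in T.OCCURRENCE_FIELDS] + occ_extras),
        "measurements": (["eventID", "occurrenceID", "measurementID", "measurementType",
                          "measurementTypeID", "measurementValue", "measurementValueID",
                          "measurementUnit", "measurementUnitID"]),
        "relationships": ["eventID"] + [tok for _, tok, _ in T.RELATIONSHIP_FIELDS],
    }


_TO_CELLS = {
    "events": event_to_cells,
    "occurrences": occurrence_to_cells,
    "measurements": measurement_to_cells,
    "relationships": relationship_to_cells,
}
_FROM_CELLS = {
    "events": event_from_cells,
    "occurrences": occurrence_from_cells,
    "measurements": measurement_from_cells,
    "relationships": relationship_from_cells,
}


def write_tables(dataset: InteractionDataset, directory) -> None:
    """Write the four flat CSV tables into ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = table_columns(dataset)
    records = {
        "events": dataset.events,
        "occurrences": dataset.occurrences,
        "measurements": dataset.measurements,
        "relationships": dataset.relationships,
    }
    for name, cols in columns.items():
        with open(directory / f"{name}.csv", "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(cols)
            to_cells = _TO_CELLS[name]
            for record in records[name]:
                cells = to_cells(record)
                writer.writerow([cells.get(col, "") for col in cols])


def read_tables(directory) -> InteractionDataset:
    """Read a dataset from the four flat CSV tables in ``directory``.

    Missing tables are treated as empty.
    """
    directory = Path(directory)
    parts: dict[str, list] = {}
    for name, from_cells in _FROM_CELLS.items():
        path = directory / f"{name}.csv"
        rows: list = []
        if path.exists():
            with open(path, "r", encoding="utf-8", newline="") as handle:
                for row in csv.DictReader(handle):
                    rows.append(from_cells({k: v for k, v in row.items() if k is not None}))
        parts[name] = rows
    return InteractionDataset(
        events=parts["events"],
        occurrences=parts["occurrences"],
        measurements=parts["measurements"],
        relationships=parts["relationships"],
    )
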