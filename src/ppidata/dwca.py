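"""Darwin Core Archive serialization of interaction datasets.

The archive uses the extended sampling-event star schema: the core table
holds events (one row per interaction), and three extension tables attach to
it through the core identifier (``eventID``): an Occurrence extension for
the interacting organisms, an ExtendedMeasurementOrFact (eMoF) extension for
typed measurements, and a ResourceRelationship extension for the directed
interaction links. The eMoF's ``occurrenceID`` column circumvents the star
schema's one-hop limit so a measurement can target a participant occurrence
rather than the event; it is empty for event-level measurements. Column
meaning is declared in ``meta.xml`` by term IRI and column index, so readers
must not rely on column position or header spelling.
"""

from __future__ import annotations

import csv
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from . import _terms as T
from . import tables
from .errors import ArchiveManifestError, ArchiveSchemaError, DatasetContractError
from .model import InteractionDataset, validate_dataset
from .registry import TermRegistry, validate_controlled_value

_META_NS = T.DWC_TEXT
_EML_FILENAME = "eml.xml"

# (file name, row type, column tokens builder) for the fixed tables
_CSV_DIALECT = dict(delimiter=",", lineterminator="\n", quotechar='"',
                    quoting=csv.QUOTE_MINIMAL)


@dataclass
class TableManifest:
    """One core or extension table declaration from meta.xml."""

    row_type: str
    file_name: str
    id_index: int
    fields: list[tuple[int, str]] = field(default_factory=list)  # (index, term IRI)


@dataclass
class ArchiveManifest:
    """Parsed meta.xml: the event core plus its extensions."""

    core: TableManifest
    extensions: list[TableManifest] = field(default_factory=list)
    encoding: str = "UTF-8"
    field_delimiter: str = ","
    line_terminator: str = "\n"
    quote_char: str = '"'
    metadata: str | None = None


def _iri_for_token(token: str) -> str:
    for fields in (T.EVENT_FIELDS, T.OCCURRENCE_FIELDS, T.MEASUREMENT_FIELDS,
                   T.RELATIONSHIP_FIELDS):
        for _, tok, iri in fields:
            if tok == token:
                return iri
    return T.token_to_iri(token)


def _enrich_measurements(dataset: InteractionDataset, registry: TermRegistry):
    """Fill measurementTypeID/ValueID from the registry when types match by name."""
    import dataclasses

    enriched = []
    for m in dataset.measurements:
        updates = {}
        term = None
        if m.measurement_type_iri:
            term = registry.index_by_iri.get(m.measurement_type_iri)
        elif m.measurement_type:
            term = registry.index_by_name.get(m.measurement_type) or next(
                (t for t in registry if t.label == m.measurement_type), None)
            if term is not None:
                updates["measurement_type_iri"] = term.iri
        if term is not None and m.measurement_value and not m.measurement_value_iri:
            accepted, value_iri = validate_controlled_value(term, m.measurement_value)
            if accepted and value_iri:
                updates["measurement_value_iri"] = value_iri
        enriched.append(dataclasses.replace(m, **updates) if updates else m)
    return enriched


def write_archive(dataset: InteractionDataset, destination,
                  registry: TermRegistry | None = None) -> Path:
    """Write a dataset as a DwC-Archive zip at ``destination``.

    The dataset must be free of validation errors. When a registry is given,
    measurement type/value IRIs are filled in from it wherever the
    human-readable type matches a registry term and no IRI was provided.
    """
    report = validate_dataset(dataset)
    if not report.is_valid:
        raise DatasetContractError(
            "refusing to write an invalid dataset: "
            + "; ".join(f.message for f in report.errors[:5]))

    measurements = (_enrich_measurements(dataset, registry)
                    if registry is not None else dataset.measurements)
    columns = tables.table_columns(dataset)

    def render(cols: list[str], records, to_cells) -> str:
        buffer = io.StringIO()
        writer = csv.writer(buffer, **_CSV_DIALECT)
        writer.writerow(cols)
        for record in records:
            cells = to_cells(record)
            writer.writerow([cells.get(col, "") for col in cols])
        return buffer.getvalue()

    files = {
        "event.csv": (T.EVENT_ROWTYPE, columns["events"],
                      render(columns["events"], dataset.events, tables.event_to_cells)),
        "occurrence.csv": (T.OCCURRENCE_ROWTYPE, columns["occurrences"],
                           render(columns["occurrences"], dataset.occurrences,
                                  tables.occurrence_to_cells)),
        "extendedmeasurementorfact.csv": (T.EMOF_ROWTYPE, columns["measurements"],
                                          render(columns["measurements"], measurements,
                                                 tables.measurement_to_cells)),
        "resourcerelationship.csv": (T.RESOURCERELATIONSHIP_ROWTYPE, columns["relationships"],
                                     render(columns["relationships"], dataset.relationships,
                                            tables.relationship_to_cells)),
    }

    destination = Path(destination)
    with zipfile.ZipFile(destination, "w", zipfile.ZIP_DEFLATED) as archive:
        archive.writestr("meta.xml", _render_meta(files))
        archive.writestr(_EML_FILENAME, _render_eml(dataset))
        for name, (_, _, payload) in files.items():
            archive.writestr(name, payload)
    return destination


def _render_meta(files: dict[str, tuple[str, list[str], str]]) -> bytes:
    nsmap = {None: _META_NS}
    root = etree.Element(f"{{{_META_NS}}}archive", nsmap=nsmap,
                         metadata=_EML_FILENAME)

    def table_element(tag: str, name: str, row_type: str, cols: list[str]):
        el = etree.SubElement(
            root, f"{{{_META_NS}}}{tag}", rowType=row_type, encoding="UTF-8",
            fieldsTerminatedBy=",", linesTerminatedBy="\\n", fieldsEnclosedBy='"',
            ignoreHeaderLines="1")
        loc = etree.SubElement(etree.SubElement(el, f"{{{_META_NS}}}files"),
                               f"{{{_META_NS}}}location")
        loc.text = name
        id_tag = "id" if tag == "core" else "coreid"
        etree.SubElement(el, f"{{{_META_NS}}}{id_tag}", index="0")
        for index, token in enumerate(cols):
            if tag != "core" and index == 0:
                continue  # the coreid column itself (eventID) is declared above
            etree.SubElement(el, f"{{{_META_NS}}}field", index=str(index),
                             term=_iri_for_token(token))

    core_name = "event.csv"
    row_type, cols, _ = files[core_name]
    table_element("core", core_name, row_type, cols)
    for name, (row_type, cols, _) in files.items():
        if name != core_name:
            table_element("extension", name, row_type, cols)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _render_eml(dataset: InteractionDataset) -> bytes:
    eml_ns = "eml://ecoinformatics.org/eml-2.1.1"
    root = etree.Element(f"{{{eml_ns}}}eml", nsmap={"eml": eml_ns},
                         packageId="ppidata-dataset", system="ppidata")
    ds = etree.SubElement(root, "dataset")
    title = etree.SubElement(ds, "title")
    title.text = "Plant-pollinator interaction dataset"
    if dataset.provenance:
        para = etree.SubElement(etree.SubElement(ds, "abstract"), "para")
        para.text = dataset.provenance
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


_SAFE_PARSER = etree.XMLParser(resolve_entities=False, no_network=True)


def read_manifest(source) -> ArchiveManifest:
    """Parse meta.xml from an archive without reading the data tables."""
    with zipfile.ZipFile(source) as archive:
        return _parse_meta(archive)


def _parse_meta(archive: zipfile.ZipFile) -> ArchiveManifest:
    try:
        payload = archive.read("meta.xml")
    except KeyError:
        raise ArchiveManifestError("archive has no meta.xml manifest") from None
    root = etree.fromstring(payload, parser=_SAFE_PARSER)

    def parse_table(el, id_tag: str) -> TableManifest:
        location = el.findtext(f"{{{_META_NS}}}files/{{{_META_NS}}}location")
        id_el = el.find(f"{{{_META_NS}}}{id_tag}")
        id_index = int(id_el.get("index", "0")) if id_el is not None else 0
        fields = [(int(f.get("index")), f.get("term"))
                  for f in el.findall(f"{{{_META_NS}}}field")]
        return TableManifest(row_type=el.get("rowType", ""), file_name=location,
                             id_index=id_index, fields=fields)

    core_el = root.find(f"{{{_META_NS}}}core")
    if core_el is None:
        raise ArchiveManifestError("meta.xml declares no core table")
    core = parse_table(core_el, "id")
    if core.row_type != T.EVENT_ROWTYPE:
        raise ArchiveSchemaError(
            f"archive core row type is {core.row_type!r}, expected the Event class "
            f"({T.EVENT_ROWTYPE!r})")
    extensions = [parse_table(el, "coreid")
                  for el in root.findall(f"{{{_META_NS}}}extension")]
    return ArchiveManifest(core=core, extensions=extensions,
                           metadata=root.get("metadata"))


def _read_table(archive: zipfile.ZipFile, manifest: TableManifest,
                id_token: str) -> list[dict[str, str]]:
    """Read one table into cell dicts keyed by term token (from meta.xml IRIs)."""
    raw = archive.read(manifest.file_name).decode("utf-8")
    reader = csv.reader(io.StringIO(raw), **{k: v for k, v in _CSV_DIALECT.items()
                                             if k != "lineterminator"})
    rows = list(reader)[1:]  # ignoreHeaderLines=1
    index_to_token = {index: T.iri_local_name(iri) for index, iri in manifest.fields}
    index_to_token.setdefault(manifest.id_index, id_token)
    records = []
    for row in rows:
        if not row:
            continue
        cells = {}
        for index, token in index_to_token.items():
            if index < len(row):
                cells[token] = row[index]
        records.append(cells)
    return records


def read_archive(source) -> InteractionDataset:
    """Read a DwC-Archive written by :func:`write_archive` (or compatible).

    Column meaning is taken from the meta.xml term IRIs, not from column
    order; unknown columns are preserved in ``extra_terms``. Unresolvable
    references surface later as validation findings, not read failures.
    """
    with zipfile.ZipFile(source) as archive:
        manifest = _parse_meta(archive)
        events = [tables.event_from_cells(cells)
                  for cells in _read_table(archive, manifest.core, "eventID")]
        occurrences, measurements, relationships = [], [], []
        for ext in manifest.extensions:
            cells_rows = _read_table(archive, ext, "eventID")
            if ext.row_type == T.OCCURRENCE_ROWTYPE:
                occurrences += [tables.occurrence_from_cells(c) for c in cells_rows]
            elif ext.row_type == T.EMOF_ROWTYPE:
                measurements += [tables.measurement_from_cells(c) for c in cells_rows]
            elif ext.row_type == T.RESOURCERELATIONSHIP_ROWTYPE:
                relationships += [tables.relationship_from_cells(c) for c in cells_rows]
            # unknown extensions are ignored (open world)
        provenance = _read_provenance(archive, manifest)
    return InteractionDataset(events=events, occurrences=occurrences,
                              measurements=measurements, relationships=relationships,
                              provenance=provenance)


def _read_provenance(archive: zipfile.ZipFile, manifest: ArchiveManifest) -> str | None:
    name = manifest.metadata or _EML_FILENAME
    if name not in archive.namelist():
        return None
    root = etree.fromstring(archive.read(name), parser=_SAFE_PARSER)
    para = root.find(".//abstract/para")
    return para.text if para is not None and para.text else None


def emof_schema_columns() -> list[str]:
    """The eMoF extension columns as written by :func:`write_archive`."""
    return tables.table_columns(InteractionDataset())["measurements"]
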