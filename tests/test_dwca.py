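"""Darwin Core Archive star-schema writer/reader."""

import csv
import io
import zipfile

import pytest
from lxml import etree

from ppidata import (
    FixtureProfile,
    datasets_equal,
    generate_dataset,
    read_archive,
    read_manifest,
    write_archive,
)
from ppidata.dwca import emof_schema_columns
from ppidata._terms import CLASSIC_MOF_COLUMNS, EVENT_ROWTYPE, OCCURRENCE_ROWTYPE
from ppidata.errors import (
    ArchiveManifestError,
    ArchiveSchemaError,
    DatasetContractError,
)
from .conftest import add_measurement, make_minimal_dataset


def _table(path, name):
    with zipfile.ZipFile(path) as z:
        return list(csv.reader(io.StringIO(z.read(name).decode("utf-8"))))


class TestWrite:
    def test_minimal_dataset_table_shapes(self, minimal_dataset, tmp_path):
        path = write_archive(minimal_dataset, tmp_path / "a.zip")
        assert len(_table(path, "extendedmeasurementorfact.csv")) == 1  # header only
        assert len(_table(path, "resourcerelationship.csv")) == 2
        assert len(_table(path, "occurrence.csv")) == 3

    def test_occurrence_level_measurement_has_occurrence_id(self, minimal_dataset,
                                                            tmp_path):
        add_measurement(minimal_dataset, occurrence_id="o1")
        path = write_archive(minimal_dataset, tmp_path / "a.zip")
        header, row = _table(path, "extendedmeasurementorfact.csv")
        assert row[header.index("occurrenceID")] == "o1"

    def test_event_level_measurement_has_empty_occurrence_id(self, minimal_dataset,
                                                             tmp_path):
        add_measurement(
            minimal_dataset, measurement_type="Resource Collected",
            measurement_type_iri="http://rs.rebipp.org.br/ppi/terms/resourceCollected",
            measurement_value="pollen")
        path = write_archive(minimal_dataset, tmp_path / "a.zip")
        header, row = _table(path, "extendedmeasurementorfact.csv")
        assert row[header.index("occurrenceID")] == ""
        assert row[header.index("eventID")] == "e1"

    def test_emof_adds_exactly_the_three_id_terms(self):
        extra = set(emof_schema_columns()) - CLASSIC_MOF_COLUMNS
        assert extra == {"measurementTypeID", "measurementValueID",
                         "measurementUnitID"}

    def test_invalid_dataset_refused(self, minimal_dataset, tmp_path):
        minimal_dataset.occurrences[0].scientific_name = ""
        with pytest.raises(DatasetContractError):
            write_archive(minimal_dataset, tmp_path / "a.zip")

    def test_core_is_event_and_extension_coreids_resolve(self, fixture_dataset,
                                                         tmp_path):
        path = write_archive(fixture_dataset, tmp_path / "a.zip")
        manifest = read_manifest(path)
        assert manifest.core.row_type == EVENT_ROWTYPE
        core_rows = _table(path, "event.csv")[1:]
        event_ids = {row[manifest.core.id_index] for row in core_rows}
        for ext in manifest.extensions:
            for row in _table(path, ext.file_name)[1:]:
                assert row[ext.id_index] in event_ids

    def test_registry_fills_type_and_value_iris(self, minimal_dataset, registry,
                                                tmp_path):
        add_measurement(minimal_dataset, occurrence_id="o1",
                        measurement_type="Flower Color",
                        measurement_type_iri=None, measurement_value="yellow")
        path = write_archive(minimal_dataset, tmp_path / "a.zip", registry=registry)
        header, row = _table(path, "extendedmeasurementorfact.csv")
        assert row[header.index("measurementTypeID")].endswith("/flowerColor")


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(10))
    def test_write_read_identity_on_fixtures(self, seed, registry, tmp_path):
        dataset = generate_dataset(FixtureProfile(
            seed=seed, n_plants=2 + seed % 3, n_animals=2 + seed % 4,
            connectance=0.2 + 0.1 * (seed % 6), cv_source=registry))
        path = write_archive(dataset, tmp_path / "a.zip", registry=registry)
        assert datasets_equal(read_archive(path), dataset)

    def test_provenance_survives_via_eml_stub(self, minimal_dataset, tmp_path):
        minimal_dataset.provenance = "Digitized from field notebooks, 2021."
        path = write_archive(minimal_dataset, tmp_path / "a.zip")
        assert read_archive(path).provenance == minimal_dataset.provenance

    def test_column_meaning_comes_from_meta_xml_not_position(self, minimal_dataset,
                                                             tmp_path):
        original = write_archive(minimal_dataset, tmp_path / "a.zip")
        shuffled = tmp_path / "shuffled.zip"
        _permute_occurrence_columns(original, shuffled)
        assert datasets_equal(read_archive(shuffled), minimal_dataset)


def _permute_occurrence_columns(src, dst):
    """Rotate occurrence.csv columns left by one, updating meta.xml indices."""
    with zipfile.ZipFile(src) as z:
        payloads = {name: z.read(name) for name in z.namelist()}
    rows = list(csv.reader(io.StringIO(payloads["occurrence.csv"].decode("utf-8"))))
    n = len(rows[0])
    rotated = [[row[(i + 1) % n] for i in range(n)] for row in rows]
    buffer = io.StringIO()
    csv.writer(buffer, lineterminator="\n").writerows(rotated)
    payloads["occurrence.csv"] = buffer.getvalue().encode("utf-8")

    meta = etree.fromstring(payloads["meta.xml"])
    ns = {"d": "http://rs.tdwg.org/dwc/text/"}
    for ext in meta.findall("d:extension", ns):
        if ext.findtext("d:files/d:location", namespaces=ns) != "occurrence.csv":
            continue
        coreid = ext.find("d:coreid", ns)
        coreid.set("index", str((int(coreid.get("index")) - 1) % n))
        for field in ext.findall("d:field", ns):
            field.set("index", str((int(field.get("index")) - 1) % n))
    payloads["meta.xml"] = etree.tostring(meta, xml_declaration=True,
                                          encoding="UTF-8")
    with zipfile.ZipFile(dst, "w") as z:
        for name, payload in payloads.items():
            z.writestr(name, payload)


class TestReadErrors:
    def test_missing_meta_xml(self, tmp_path):
        path = tmp_path / "bad.zip"
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("event.csv", "eventID\ne1\n")
        with pytest.raises(ArchiveManifestError):
            read_archive(path)

    def test_occurrence_core_row_type_named_in_error(self, minimal_dataset, tmp_path):
        original = write_archive(minimal_dataset, tmp_path / "a.zip")
        with zipfile.ZipFile(original) as z:
            payloads = {name: z.read(name) for name in z.namelist()}
        payloads["meta.xml"] = payloads["meta.xml"].replace(
            EVENT_ROWTYPE.encode(), OCCURRENCE_ROWTYPE.encode(), 1)
        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(bad, "w") as z:
            for name, payload in payloads.items():
                z.writestr(name, payload)
        with pytest.raises(ArchiveSchemaError, match="Occurrence"):
            read_archive(bad)

    def test_unresolvable_emof_occurrence_is_a_finding_not_a_crash(
            self, minimal_dataset, registry, tmp_path):
        from ppidata import validate_dataset
        add_measurement(minimal_dataset, occurrence_id="o1")
        path = write_archive(minimal_dataset, tmp_path / "a.zip")
        with zipfile.ZipFile(path) as z:
            payloads = {name: z.read(name) for name in z.namelist()}
        payloads["extendedmeasurementorfact.csv"] = payloads[
            "extendedmeasurementorfact.csv"].replace(b",o1,", b",ghost,")
        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(bad, "w") as z:
            for name, payload in payloads.items():
                z.writestr(name, payload)
        dataset = read_archive(bad)  # no exception
        codes = {f.code for f in validate_dataset(dataset, registry).errors}
        assert codes == {"DANGLING_REFERENCE"}
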