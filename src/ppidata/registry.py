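"""Controlled-vocabulary term registry for plant-pollinator interaction data.

The registry holds the term list of the plant-pollinator interactions (PPI)
vocabulary: 48 properties organised in six categories (Animal, Plant, Flower,
Interaction, Reproductive Success, Nectar Dynamics), each defined with the
normative elements of the TDWG Standards Documentation Standard (term name,
label, IRI, definition, modified date, type) plus optional usage comments,
references, protocol, examples and a recommended controlled vocabulary of
values.

The bundled term list (``data/ppi_terms_synthetic.csv``) is a synthetic
reconstruction of the official REBIPP roster: the handful of terms that are
fixed by the standard's published template and figures appear verbatim
(``flowerOpeningType`` with its full template, ``flowerColor``,
``floralAttractants``, ``caste``, ``resourceCollected``,
``nectarCollectingBodyPart``, ``numberOfRemovedPollenGrains``); the remaining
entries are representative domain terms filling the normative count of 48.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterator, Union

import yaml
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import DCTERMS as RDF_DCTERMS, XSD

from .errors import (
    DuplicateIRIError,
    RegistrySchemaError,
    TermNotFoundError,
    UnknownCategoryError,
    UnsupportedFormatError,
)

CATEGORIES = (
    "Animal",
    "Plant",
    "Flower",
    "Interaction",
    "Reproductive Success",
    "Nectar Dynamics",
)

PPI_NAMESPACE = "http://rs.rebipp.org.br/ppi/terms/"

_REQUIRED_COLUMNS = ("term_name", "iri", "category", "definition")
_ALL_COLUMNS = (
    "term_name", "label", "iri", "category", "definition", "comments",
    "details", "protocol", "controlled_vocabulary", "controlled_vocabulary_iris",
    "examples", "modified", "term_type",
)

Source = Union[str, os.PathLike, IO[str]]


@dataclass(frozen=True)
class ControlledValue:
    """One admissible value of a term's controlled vocabulary."""

    token: str
    iri: str | None = None


@dataclass(frozen=True)
class TermDefinition:
    """One vocabulary term with its SDS normative elements."""

    term_name: str
    label: str
    iri: str
    category: str
    definition: str
    comments: str | None = None
    details: str | None = None
    protocol: str | None = None
    controlled_vocabulary: tuple[ControlledValue, ...] | None = None
    examples: str | None = None
    modified: str | None = None
    term_type: str = "Property"

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValueError(f"term {self.term_name!r} has an empty IRI")
        if self.category not in CATEGORIES:
            raise UnknownCategoryError(
                f"unknown category {self.category!r} for term {self.term_name!r}; "
                f"expected one of {', '.join(CATEGORIES)}"
            )
        if self.controlled_vocabulary is not None:
            tokens = [cv.token for cv in self.controlled_vocabulary]
            if not tokens:
                raise ValueError(
                    f"term {self.term_name!r}: controlled vocabulary present but empty"
                )
            if len(set(tokens)) != len(tokens):
                raise ValueError(
                    f"term {self.term_name!r}: duplicate controlled-vocabulary values"
                )


@dataclass
class TermRegistry:
    """An ordered, indexed collection of term definitions."""

    terms: tuple[TermDefinition, ...]
    version: str = "1.0"
    index_by_name: dict[str, TermDefinition] = field(init=False, repr=False)
    index_by_iri: dict[str, TermDefinition] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_name: dict[str, TermDefinition] = {}
        by_iri: dict[str, TermDefinition] = {}
        for term in self.terms:
            if term.iri in by_iri:
                raise DuplicateIRIError(f"duplicate term IRI {term.iri!r}")
            if term.term_name in by_name:
                raise DuplicateIRIError(f"duplicate term name {term.term_name!r}")
            by_iri[term.iri] = term
            by_name[term.term_name] = term
        self.index_by_name = by_name
        self.index_by_iri = by_iri

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[TermDefinition]:
        return iter(self.terms)

    def __contains__(self, key: str) -> bool:
        return key in self.index_by_name or key in self.index_by_iri

    @property
    def categories(self) -> tuple[str, ...]:
        """Distinct categories present, in the canonical category order."""
        present = {t.category for t in self.terms}
        return tuple(c for c in CATEGORIES if c in present)


def _split_cv(cell: str, iri_cell: str = "") -> tuple[ControlledValue, ...] | None:
    tokens = [v.strip() for v in cell.split(";") if v.strip()] if cell else []
    if not tokens:
        return None
    iris = [v.strip() for v in iri_cell.split(";")] if iri_cell else []
    values = []
    for i, tok in enumerate(tokens):
        iri = iris[i] if i < len(iris) and iris[i] else None
        values.append(ControlledValue(tok, iri))
    return tuple(values)


def _row_to_term(row: dict[str, str]) -> TermDefinition:
    def opt(key: str) -> str | None:
        value = (row.get(key) or "").strip()
        return value or None

    return TermDefinition(
        term_name=row["term_name"].strip(),
        label=(row.get("label") or row["term_name"]).strip(),
        iri=row["iri"].strip(),
        category=row["category"].strip(),
        definition=row["definition"].strip(),
        comments=opt("comments"),
        details=opt("details"),
        protocol=opt("protocol"),
        controlled_vocabulary=_split_cv(
            (row.get("controlled_vocabulary") or "").strip(),
            (row.get("controlled_vocabulary_iris") or "").strip(),
        ),
        examples=opt("examples"),
        modified=opt("modified"),
        term_type=(row.get("term_type") or "Property").strip(),
    )


def load_registry(source: Source, format: str = "tabular") -> TermRegistry:
    """Load a term registry from a CSV table or a structured-config (YAML) file.

    The tabular form has one row per term with a ";"-delimited controlled
    vocabulary column (surrounding whitespace trimmed), mirroring the term
    template's own presentation of controlled values.
    """
    if format == "tabular":
        return _load_tabular(source)
    if format == "structured-config":
        return _load_structured(source)
    raise UnsupportedFormatError(
        f"unsupported registry format {format!r}; expected 'tabular' or 'structured-config'"
    )


def _open_text(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8", newline=""), True


def _load_tabular(source: Source) -> TermRegistry:
    handle, close = _open_text(source)
    try:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in _REQUIRED_COLUMNS:
            if column not in header:
                raise RegistrySchemaError(f"registry table is missing required column {column!r}")
        terms = tuple(_row_to_term(row) for row in reader)
    finally:
        if close:
            handle.close()
    return TermRegistry(terms=terms)


def _load_structured(source: Source) -> TermRegistry:
    handle, close = _open_text(source)
    try:
        doc = yaml.safe_load(handle)
    finally:
        if close:
            handle.close()
    if not isinstance(doc, dict) or "terms" not in doc:
        raise RegistrySchemaError("structured-config registry is missing the 'terms' key")
    terms = []
    for entry in doc["terms"]:
        for key in _REQUIRED_COLUMNS:
            if key not in entry:
                raise RegistrySchemaError(
                    f"registry entry {entry.get('term_name', '?')!r} is missing required key {key!r}"
                )
        cv = entry.get("controlled_vocabulary")
        values = None
        if cv:
            values = tuple(
                ControlledValue(v["value"], v.get("iri")) if isinstance(v, dict)
                else ControlledValue(str(v))
                for v in cv
            )
        terms.append(TermDefinition(
            term_name=entry["term_name"],
            label=entry.get("label", entry["term_name"]),
            iri=entry["iri"],
            category=entry["category"],
            definition=entry["definition"],
            comments=entry.get("comments"),
            details=entry.get("details"),
            protocol=entry.get("protocol"),
            controlled_vocabulary=values,
            examples=entry.get("examples"),
            modified=entry.get("modified"),
            term_type=entry.get("term_type", "Property"),
        ))
    return TermRegistry(terms=tuple(terms), version=str(doc.get("version", "1.0")))


def load_default_registry() -> TermRegistry:
    """Load the bundled 48-term registry."""
    ref = resources.files("ppidata").joinpath("data/ppi_terms_synthetic.csv")
    with ref.open("r", encoding="utf-8") as handle:
        return load_registry(handle, format="tabular")


def get_term(registry: TermRegistry, key: str) -> TermDefinition:
    """Resolve a term by name first, then by IRI."""
    term = registry.index_by_name.get(key) or registry.index_by_iri.get(key)
    if term is None:
        raise TermNotFoundError(key)
    return term


def validate_controlled_value(
    term: TermDefinition, value: str, case_sensitive: bool = True
) -> tuple[bool, str | None]:
    """Test a value against a term's controlled vocabulary.

    Returns ``(accepted, matched value IRI or None)``. Terms without a
    controlled vocabulary accept any non-empty value: the vocabulary's
    recommendations of controlled values are explicitly non-normative.
    Matching trims surrounding whitespace and is case-sensitive by default.
    """
    trimmed = value.strip()
    if term.controlled_vocabulary is None:
        return (bool(trimmed), None)
    for cv in term.controlled_vocabulary:
        if trimmed == cv.token or (not case_sensitive and trimmed.lower() == cv.token.lower()):
            return (True, cv.iri)
    return (False, None)


def export_term_list(registry: TermRegistry, format: str = "tabular") -> bytes:
    """Export the term list as a CSV table or as RDF (Turtle).

    The tabular export round-trips through :func:`load_registry`. The RDF
    export declares each term an ``rdf:Property`` with its label, definition
    and modified date.
    """
    if format == "tabular":
        buffer = io.StringIO()
        writer = csv.DictWriter(buffer, fieldnames=list(_ALL_COLUMNS), lineterminator="\n")
        writer.writeheader()
        for term in registry:
            cv = term.controlled_vocabulary or ()
            writer.writerow({
                "term_name": term.term_name,
                "label": term.label,
                "iri": term.iri,
                "category": term.category,
                "definition": term.definition,
                "comments": term.comments or "",
                "details": term.details or "",
                "protocol": term.protocol or "",
                "controlled_vocabulary": ";".join(v.token for v in cv),
                "controlled_vocabulary_iris": ";".join(v.iri or "" for v in cv)
                if any(v.iri for v in cv) else "",
                "examples": term.examples or "",
                "modified": term.modified or "",
                "term_type": term.term_type,
            })
        return buffer.getvalue().encode("utf-8")
    if format == "rdf":
        graph = Graph()
        skos = Namespace("http://www.w3.org/2004/02/skos/core#")
        graph.bind("skos", skos)
        graph.bind("dcterms", RDF_DCTERMS)
        graph.bind("ppi", PPI_NAMESPACE)
        for term in registry:
            node = URIRef(term.iri)
            graph.add((node, RDF.type, RDF.Property))
            graph.add((node, RDFS.label, Literal(term.label)))
            graph.add((node, skos.definition, Literal(term.definition)))
            if term.modified:
                graph.add((node, RDF_DCTERMS.modified, Literal(term.modified, datatype=XSD.date)))
        return graph.serialize(format="turtle").encode("utf-8")
    raise UnsupportedFormatError(
        f"unsupported export format {format!r}; expected 'tabular' or 'rdf'"
    )
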