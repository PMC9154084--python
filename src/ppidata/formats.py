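"""Dataset reading/writing dispatch across the supported serializations."""

from __future__ import annotations

from pathlib import Path

from . import dwca, rdfio, tables, xmlio
from .errors import UnsupportedFormatError
from .model import InteractionDataset
from .registry import TermRegistry

FORMATS = ("dwca", "xml", "turtle", "ntriples", "tables")


def guess_format(path) -> str:
    """Guess a serialization format from a path's suffix (directory = tables)."""
    path = Path(path)
    if path.is_dir() or path.suffix == "":
        return "tables"
    suffix = path.suffix.lower()
    mapping = {".zip": "dwca", ".xml": "xml", ".ttl": "turtle",
               ".nt": "ntriples", ".turtle": "turtle"}
    if suffix not in mapping:
        raise UnsupportedFormatError(
            f"cannot guess a dataset format from {path.name!r}; pass one of {FORMATS}")
    return mapping[suffix]


def read_dataset(path, format: str | None = None,
                 base: str = rdfio.DEFAULT_BASE) -> InteractionDataset:
    """Read a dataset from any supported serialization."""
    format = format or guess_format(path)
    if format == "dwca":
        return dwca.read_archive(path)
    if format == "xml":
        return xmlio.read_xml(Path(path).read_bytes())
    if format in ("turtle", "ntriples"):
        graph = rdfio.parse_graph(Path(path).read_bytes(), format=format)
        return rdfio.from_triples(graph, base=base)
    if format == "tables":
        return tables.read_tables(path)
    raise UnsupportedFormatError(f"unsupported format {format!r}; expected one of {FORMATS}")


def write_dataset(dataset: InteractionDataset, path, format: str | None = None,
                  registry: TermRegistry | None = None,
                  base: str = rdfio.DEFAULT_BASE) -> None:
    """Write a dataset in any supported serialization."""
    format = format or guess_format(path)
    if format == "dwca":
        dwca.write_archive(dataset, path, registry=registry)
    elif format == "xml":
        Path(path).write_bytes(xmlio.write_xml(dataset))
    elif format in ("turtle", "ntriples"):
        graph = rdfio.to_triples(dataset, registry=registry, base=base)
        Path(path).write_bytes(rdfio.serialize_graph(graph, format=format))
    elif format == "tables":
        tables.write_tables(dataset, path)
    else:
        raise UnsupportedFormatError(
            f"unsupported format {format!r}; expected one of {FORMATS}")
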