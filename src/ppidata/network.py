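"""Conversion between record-level interaction datasets and bipartite networks.

Species-level interaction networks are the dominant summary format in the
pollination literature: a plants-by-animals adjacency matrix, binary or
weighted. Species-level interactions can be derived by aggregating
individual-level records, but not the other way round, so aggregation is
lossy while expansion must invent record identifiers. Expansion documents
each nonzero cell (edge) as one interaction event owning one plant and one
animal occurrence plus one directed relationship; edge weights travel either
as an event-level "interaction frequency" measurement (compact mode,
default) or as weight-many replicate events (expanded mode).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._terms import RO
from .errors import DatasetContractError, RoleResolutionError
from .model import (
    InteractionDataset,
    InteractionEvent,
    InteractionRelationship,
    Measurement,
    OrganismOccurrence,
)

# Artifact-defined measurement type for edge weights; the vocabulary defines
# no count term, so this label carries no term IRI.
WEIGHT_MEASUREMENT_TYPE = "interaction frequency"

DEFAULT_RELATIONSHIP_TYPE = ("visits flowers of", RO + "0002622")


@dataclass
class AdjacencyNetwork:
    """A bipartite plants-by-animals matrix with taxon labels.

    Rows are plants, columns are animals; entries are non-negative integer
    interaction counts (or presence/absence when ``binary``).
    """

    plant_taxa: list[str]
    animal_taxa: list[str]
    weights: np.ndarray
    binary: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=int)
        if self.weights.shape != (len(self.plant_taxa), len(self.animal_taxa)):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{len(self.plant_taxa)} plants x {len(self.animal_taxa)} animals")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if self.binary and not np.isin(self.weights, (0, 1)).all():
            raise ValueError("binary network entries must be 0 or 1")

    def __eq__(self, other) -> bool:
        if not isinstance(other, AdjacencyNetwork):
            return NotImplemented
        return (self.plant_taxa == other.plant_taxa
                and self.animal_taxa == other.animal_taxa
                and self.binary == other.binary
                and np.array_equal(self.weights, other.weights))


RoleRule = Callable[[OrganismOccurrence], str]


def _default_role(occ: OrganismOccurrence) -> str:
    return occ.organism_role or "unknown"


def aggregate_to_network(dataset: InteractionDataset, roles: RoleRule | None = None,
                         binary: bool = False) -> AdjacencyNetwork:
    """Aggregate individual-level relationships into a species-level matrix.

    Each relationship contributes to the cell of its plant's and animal's
    scientific names (verbatim; no rank collapsing), with multiplicity given
    by an event-level "interaction frequency" measurement on its event when
    one is present (the compact edge-weight representation), else 1. Taxa
    are sorted lexicographically. ``roles`` maps an occurrence to "plant" or
    "animal"; by default the occurrence's ``organism_role`` is used.
    """
    role_of = roles or _default_role
    occurrences = dataset.occurrences_by_id()
    weight_of_event: dict[str, int] = {}
    for m in dataset.measurements:
        if not m.occurrence_id and m.measurement_type == WEIGHT_MEASUREMENT_TYPE:
            weight_of_event[m.event_id] = int(float(m.measurement_value or "1"))

    counts: dict[tuple[str, str], int] = {}
    for rel in dataset.relationships:
        members = []
        for ref in (rel.resource_id, rel.related_resource_id):
            occ = occurrences.get(ref)
            if occ is None:
                raise RoleResolutionError(
                    f"relationship {rel.relationship_id!r}: member {ref!r} does not "
                    f"resolve to an occurrence")
            members.append(occ)
        by_role = {role_of(occ): occ for occ in members}
        if set(by_role) != {"plant", "animal"}:
            raise RoleResolutionError(
                f"relationship {rel.relationship_id!r} does not link one plant and "
                f"one animal (roles: {[role_of(o) for o in members]})")
        key = (by_role["plant"].scientific_name, by_role["animal"].scientific_name)
        counts[key] = counts.get(key, 0) + weight_of_event.get(rel.event_id, 1)

    plants = sorted({p for p, _ in counts})
    animals = sorted({a for _, a in counts})
    weights = np.zeros((len(plants), len(animals)), dtype=int)
    for (p, a), n in counts.items():
        weights[plants.index(p), animals.index(a)] = n
    if binary:
        weights = (weights >= 1).astype(int)
    return AdjacencyNetwork(plant_taxa=plants, animal_taxa=animals,
                            weights=weights, binary=binary)


def network_to_dataset(network: AdjacencyNetwork,
                       event_template: InteractionEvent | None = None,
                       relationship_type: tuple[str | None, str | None] = DEFAULT_RELATIONSHIP_TYPE,
                       according_to: str = "",
                       mode: str = "compact",
                       subject_role: str = "animal") -> InteractionDataset:
    """Expand an adjacency matrix into record-level interaction records.

    One event per nonzero cell (or per unit of weight in ``expanded`` mode),
    each owning a fresh plant occurrence and a fresh animal occurrence (a
    star-schema occurrence row belongs to exactly one event) and one
    relationship, by default with the animal as subject. In compact mode a
    non-binary network records each edge weight as an event-level
    measurement. ``according_to`` (the source of the interaction assertions)
    is required.
    """
    if not according_to.strip():
        raise DatasetContractError("according_to must be non-empty")
    if mode not in ("compact", "expanded"):
        raise DatasetContractError(f"unknown mode {mode!r}")
    rel_text, rel_iri = relationship_type
    if not (rel_text or rel_iri):
        raise DatasetContractError("relationship_type needs a label or an IRI")

    dataset = InteractionDataset()
    k = 0
    for i, plant in enumerate(network.plant_taxa):
        for j, animal in enumerate(network.animal_taxa):
            weight = int(network.weights[i, j])
            if weight == 0:
                continue
            replicates = weight if mode == "expanded" else 1
            for _ in range(replicates):
                k += 1
                event_id = f"evt-{k:04d}"
                if event_template is not None:
                    event = dataclasses.replace(event_template, event_id=event_id)
                    event.extra_terms = dict(event_template.extra_terms)
                else:
                    event = InteractionEvent(event_id=event_id)
                plant_occ = OrganismOccurrence(
                    occurrence_id=f"occ-{k:04d}-p", event_id=event_id,
                    scientific_name=plant, organism_role="plant")
                animal_occ = OrganismOccurrence(
                    occurrence_id=f"occ-{k:04d}-a", event_id=event_id,
                    scientific_name=animal, organism_role="animal")
                subject, related = ((animal_occ, plant_occ) if subject_role == "animal"
                                    else (plant_occ, animal_occ))
                dataset.events.append(event)
                dataset.occurrences += [plant_occ, animal_occ]
                dataset.relationships.append(InteractionRelationship(
                    relationship_id=f"rel-{k:04d}", event_id=event_id,
                    resource_id=subject.occurrence_id,
                    related_resource_id=related.occurrence_id,
                    relationship_of_resource=rel_text,
                    relationship_of_resource_iri=rel_iri,
                    relationship_according_to=according_to))
                if mode == "compact" and (weight > 1 or not network.binary):
                    dataset.measurements.append(Measurement(
                        measurement_id=f"mof-{k:04d}", event_id=event_id,
                        measurement_type=WEIGHT_MEASUREMENT_TYPE,
                        measurement_value=str(weight)))
    return dataset


def write_matrix_csv(network: AdjacencyNetwork, destination) -> None:
    """Write the matrix as labelled CSV: plant rows, animal columns."""
    frame = pd.DataFrame(network.weights, index=network.plant_taxa,
                         columns=network.animal_taxa)
    frame.to_csv(destination, index_label="scientificName")


def read_matrix_csv(source, binary: bool | None = None) -> AdjacencyNetwork:
    """Read a labelled CSV matrix; ``binary`` is inferred when not given."""
    frame = pd.read_csv(source, index_col=0)
    weights = frame.to_numpy(dtype=int)
    if binary is None:
        binary = bool(np.isin(weights, (0, 1)).all())
    return AdjacencyNetwork(plant_taxa=[str(x) for x in frame.index],
                            animal_taxa=[str(x) for x in frame.columns],
                            weights=weights, binary=binary)


def connectance(network: AdjacencyNetwork) -> float:
    """Realized fraction of possible plant-animal links."""
    cells = network.weights.size
    if cells == 0:
        return math.nan
    return float((network.weights > 0).sum()) / cells
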