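"""Deterministic generator of valid interaction datasets.

The generator emulates a small field campaign of individual-level
plant-pollinator records: two taxonomically labelled pools (plants,
animals) with synthetic binomial names, a seeded choice of realized
plant-animal edges at a target connectance, one interaction event per
record with a date and coordinates, two occurrences and one directed
relationship (animal subject, Relations Ontology predicate) per event, and
vocabulary-typed measurements whose values are drawn from each term's
controlled vocabulary when it has one.

A single seeded pseudo-random stream with a fixed draw order makes the
output byte-stable: identical profile and seed give the canonicalize-equal
dataset on every run. The topology is deliberately naive (uniform edge
choice, no degree-distribution modelling): fixtures exercise the data
model and serializers, not ecological realism.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass, field

from ._terms import RO
from .errors import DatasetContractError
from .model import (
    InteractionDataset,
    InteractionEvent,
    InteractionRelationship,
    Measurement,
    OrganismOccurrence,
)
from .registry import TermRegistry, load_default_registry

ACCORDING_TO = "synthetic fixture"

# (term name, level) pairs the generator draws measurements from; level
# decides whether the measurement targets the plant occurrence, the animal
# occurrence, or the interaction event itself.
_MEASURED_TERMS = (
    ("flowerColor", "plant"),
    ("flowerOpeningType", "plant"),
    ("caste", "animal"),
    ("resourceCollected", "event"),
    ("visitDuration", "event"),
)


@dataclass
class FixtureProfile:
    """Parameters of one synthetic dataset."""

    n_plants: int = 4
    n_animals: int = 5
    connectance: float = 0.3
    records_per_edge: int = 1
    measurement_rate: float = 0.5
    seed: int = 0
    cv_source: TermRegistry | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.n_animals < 1:
            raise DatasetContractError("n_plants and n_animals must be positive")
        if not 0.0 <= self.connectance <= 1.0:
            raise DatasetContractError("connectance must be in [0, 1]")
        if self.records_per_edge < 1:
            raise DatasetContractError("records_per_edge must be positive")
        if not 0.0 <= self.measurement_rate <= 1.0:
            raise DatasetContractError("measurement_rate must be in [0, 1]")


def generate_dataset(profile: FixtureProfile) -> InteractionDataset:
    """Build a valid dataset from a profile; deterministic in (profile, seed)."""
    registry = profile.cv_source or load_default_registry()
    rng = random.Random(profile.seed)

    plants = [f"Plantus sp{i + 1:02d}" for i in range(profile.n_plants)]
    animals = [f"Animalus sp{j + 1:02d}" for j in range(profile.n_animals)]

    all_edges = [(i, j) for i in range(profile.n_plants) for j in range(profile.n_animals)]
    n_edges = math.ceil(profile.connectance * len(all_edges))
    edges = sorted(rng.sample(all_edges, n_edges))

    dataset = InteractionDataset(provenance=None)
    k = 0
    for i, j in edges:
        for _ in range(profile.records_per_edge):
            k += 1
            event_id = f"evt{k:04d}"
            # draw order: month, day, latitude, longitude, [measurement draws]
            month = rng.randint(1, 12)
            day = rng.randint(1, 28)
            event = InteractionEvent(
                event_id=event_id,
                event_date=f"2021-{month:02d}-{day:02d}",
                latitude=round(rng.uniform(-25.0, -20.0), 4),
                longitude=round(rng.uniform(-50.0, -45.0), 4),
                locality="Synthetic study site",
                sampling_protocol="focal observation",
            )
            plant_occ = OrganismOccurrence(
                occurrence_id=f"occ{k:04d}p", event_id=event_id,
                scientific_name=plants[i], taxon_rank="species",
                organism_role="plant",
                extra_terms={"basisOfRecord": "HumanObservation"})
            animal_occ = OrganismOccurrence(
                occurrence_id=f"occ{k:04d}a", event_id=event_id,
                scientific_name=animals[j], taxon_rank="species",
                organism_role="animal",
                extra_terms={"basisOfRecord": "HumanObservation"})
            relationship = InteractionRelationship(
                relationship_id=f"rel{k:04d}", event_id=event_id,
                resource_id=animal_occ.occurrence_id,
                related_resource_id=plant_occ.occurrence_id,
                relationship_of_resource="pollinates",
                relationship_of_resource_iri=RO + "0002455",
                relationship_according_to=ACCORDING_TO)
            dataset.events.append(event)
            dataset.occurrences += [plant_occ, animal_occ]
            dataset.relationships.append(relationship)

            if rng.random() < profile.measurement_rate:
                term_name, level = _MEASURED_TERMS[rng.randrange(len(_MEASURED_TERMS))]
                term = registry.index_by_name[term_name]
                if term.controlled_vocabulary:
                    choice = term.controlled_vocabulary[
                        rng.randrange(len(term.controlled_vocabulary))]
                    value, value_iri = choice.token, choice.iri
                    unit = None
                else:
                    value, value_iri = str(rng.randint(1, 60)), None
                    unit = "s" if term_name == "visitDuration" else None
                occurrence_id = {"plant": plant_occ.occurrence_id,
                                 "animal": animal_occ.occurrence_id,
                                 "event": None}[level]
                dataset.measurements.append(Measurement(
                    measurement_id=f"mof{k:04d}", event_id=event_id,
                    occurrence_id=occurrence_id,
                    measurement_type=term.label,
                    measurement_type_iri=term.iri,
                    measurement_value=value,
                    measurement_value_iri=value_iri,
                    measurement_unit=unit))
    return dataset


FAULTS = ("scientific_name", "event_id", "resource_id", "related_resource_id",
          "relationship_type", "according_to")


def inject_fault(dataset: InteractionDataset, fault: str) -> InteractionDataset:
    """Return a deep copy of the dataset with one minimal field blanked.

    The ``event_id`` fault blanks the identifier everywhere it appears (the
    event record and the child rows referencing it), as blanking the core-id
    column of a star-schema row group would.
    """
    if fault not in FAULTS:
        raise ValueError(f"unknown fault {fault!r}; expected one of {FAULTS}")
    faulty = copy.deepcopy(dataset)
    if fault == "scientific_name":
        faulty.occurrences[0].scientific_name = ""
    elif fault == "event_id":
        target = faulty.events[0].event_id
        faulty.events[0].event_id = ""
        for record in faulty.occurrences + faulty.measurements + faulty.relationships:
            if record.event_id == target:
                record.event_id = ""
    elif fault == "resource_id":
        faulty.relationships[0].resource_id = ""
    elif fault == "related_resource_id":
        faulty.relationships[0].related_resource_id = ""
    elif fault == "relationship_type":
        faulty.relationships[0].relationship_of_resource = None
        faulty.relationships[0].relationship_of_resource_iri = None
    elif fault == "according_to":
        faulty.relationships[0].relationship_according_to = ""
    return faulty
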