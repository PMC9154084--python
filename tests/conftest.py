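import pytest
from hypothesis import settings

from ppidata import (
    FixtureProfile,
    InteractionDataset,
    InteractionEvent,
    InteractionRelationship,
    Measurement,
    OrganismOccurrence,
    generate_dataset,
    load_default_registry,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


def make_minimal_dataset() -> InteractionDataset:
    """One interaction: an event, a plant and an animal occurrence, one relationship."""
    return InteractionDataset(
        events=[InteractionEvent(event_id="e1", event_date="2021-10-05",
                                 latitude=-22.01, longitude=-47.89)],
        occurrences=[
            OrganismOccurrence(occurrence_id="o1", event_id="e1",
                               scientific_name="Fuchsia magellanica",
                               organism_role="plant"),
            OrganismOccurrence(occurrence_id="o2", event_id="e1",
                               scientific_name="Sephanoides sephaniodes",
                               organism_role="animal"),
        ],
        relationships=[InteractionRelationship(
            relationship_id="r1", event_id="e1",
            resource_id="o2", related_resource_id="o1",
            relationship_of_resource="pollinates",
            relationship_of_resource_iri="http://purl.obolibrary.org/obo/RO_0002455",
            relationship_according_to="Fontúrbel field notes")],
    )


@pytest.fixture
def minimal_dataset() -> InteractionDataset:
    return make_minimal_dataset()


@pytest.fixture
def fixture_dataset(registry) -> InteractionDataset:
    return generate_dataset(FixtureProfile(seed=1, cv_source=registry))


def add_measurement(dataset, *, measurement_id="m1", occurrence_id=None,
                    measurement_type="Flower Color",
                    measurement_type_iri="http://rs.rebipp.org.br/ppi/terms/flowerColor",
                    measurement_value="yellow", **kwargs) -> Measurement:
    m = Measurement(measurement_id=measurement_id, event_id="e1",
                    occurrence_id=occurrence_id, measurement_type=measurement_type,
                    measurement_type_iri=measurement_type_iri,
                    measurement_value=measurement_value, **kwargs)
    dataset.measurements.append(m)
    return m
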