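# ppidata

Tools for standardized plant–pollinator interaction data: a controlled
vocabulary registry, an event-centred Darwin Core interaction data model with
a validity contract, lossless serialization as Darwin Core Archives, XML and
RDF, and bidirectional conversion between record-level interaction datasets
and species-level bipartite networks.

## Who this is for

Pollination biologists, biodiversity data managers and aggregator operators
who need to publish, validate or integrate interaction records — individual
"this bee visited this flower here, then" observations — rather than only
the species-by-species summary matrices that dominate the literature.
Species-level interactions can always be derived from individual-level
records by aggregation, never the other way round.

## The model

An interaction is a `dwc:Event`: an action at some location during some
time. Each event owns:

- two (or more) `dwc:Occurrence` records for the interacting organisms,
  identified by `dwc:scientificName` at any determinable rank;
- one or more `dwc:ResourceRelationship` records giving the interaction's
  direction and type: subject (`dwc:resourceID`), object
  (`dwc:relatedResourceID`), type (`dwc:relationshipOfResource` /
  `relationshipOfResourceID`, ideally a Relations Ontology term such as
  RO_0002455 *pollinates*), and the source of the assertion
  (`dwc:relationshipAccordingTo`);
- zero or more typed measurements (`MeasurementOrFact`), either of the
  interaction itself (resource collected, visit duration, ...) or of one
  participant (flower colour, caste, ...), typed with IRIs from the
  plant–pollinator interactions (PPI) vocabulary — 48 property terms in six
  categories (Animal, Plant, Flower, Interaction, Reproductive Success,
  Nectar Dynamics), many with recommended controlled vocabularies.

A record set is *valid* when every occurrence has a scientific name, every
event an identifier, every relationship a resolvable subject and object, a
type and a source, and all cross-references resolve. `validate_dataset`
reports violations as coded findings (errors) and vocabulary problems
(warnings) rather than exceptions.

Serializations:

- **DwC-Archive** — the extended sampling-event star schema: an event core
  plus Occurrence, ExtendedMeasurementOrFact (eMoF) and ResourceRelationship
  extensions. The eMoF's `occurrenceID` lets a measurement target a
  participant across the star schema's one-hop limit; its three ID terms
  (`measurementTypeID`, `measurementValueID`, `measurementUnitID`) carry the
  vocabulary IRIs.
- **XML** — one flat document; one-to-many links via repeated
  `measurementID` references (see `docs/xml-layout.md`).
- **RDF** (Turtle / N-Triples) — Darwin-SW: `occurrence dsw:atEvent event`,
  interaction direction as an `occurrence → RO predicate → occurrence`
  triple, measurements linked by `dcterms:relation` with
  `dwciri:measurementType` pointing at the vocabulary term IRI.

## Worked example

```python
import ppidata as p

registry = p.load_default_registry()          # the bundled 48-term vocabulary
profile = p.FixtureProfile(n_plants=2, n_animals=2, connectance=0.5,
                           seed=4, cv_source=registry)
dataset = p.generate_dataset(profile)
print(len(dataset.events), len(dataset.occurrences), len(dataset.measurements))
# 2 4 1    -> 2 interaction events, each with a plant and an animal occurrence

report = p.validate_dataset(dataset, registry)
print(report.is_valid)                        # True: fixtures satisfy the contract

net = p.aggregate_to_network(dataset)
print(net.plant_taxa, net.animal_taxa, net.weights.tolist())
# ['Plantus sp01', 'Plantus sp02'] ['Animalus sp02'] [[1], [1]]
# both realized edges involve the same animal taxon, once each

graph = p.to_triples(dataset, registry, base="http://example.org/ppi")
print(len(graph))                             # 66 triples
```

A slice of the Turtle output for one animal occurrence — note the Darwin-SW
event link and the direct interaction predicate:

```turtle
<http://example.org/ppi/occurrence/occ0001a> a dwc:Occurrence ;
    obo:RO_0002455 <http://example.org/ppi/occurrence/occ0001p> ;
    dsw:atEvent <http://example.org/ppi/event/evt0001> ;
    dwc:occurrenceID "occ0001a" ;
    dwc:scientificName "Animalus sp02" ;
    dwc:taxonRank "species" .
```

The same dataset round-trips bytes-to-records through every serialization:
`read_archive(write_archive(d))`, `read_xml(write_xml(d))` and
`from_triples(to_triples(d))` are all identity after canonicalization.

From the shell:

```bash
ppidata generate demo.zip --seed 4            # a DwC-Archive fixture
ppidata validate demo.zip                     # exit 0, no findings
ppidata convert demo.zip demo.ttl             # archive -> Turtle
ppidata network demo.zip matrix.csv --to-matrix
ppidata terms show flowerOpeningType
```

## Layout

- `src/ppidata/registry.py` — vocabulary registry, controlled-value checks,
  CSV/YAML loading, CSV/Turtle export
- `src/ppidata/model.py` — record types, validity contract,
  `associatedTaxa` legacy parsing, canonicalization
- `src/ppidata/dwca.py`, `xmlio.py`, `rdfio.py`, `tables.py` — serializers
- `src/ppidata/network.py` — adjacency-matrix aggregation/expansion
- `src/ppidata/fixtures.py` — deterministic synthetic datasets
- `src/ppidata/cli.py` — the `ppidata` command
- `docs/methods.md` — model assumptions, parameters, design notes
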