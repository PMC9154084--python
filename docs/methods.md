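# Methods and design notes

## The interaction model and its assumptions

The package treats one interaction as one `dwc:Event` — an action at a
location during some time — rather than as an attribute dangling off an
occurrence. The event owns the occurrences of the interacting organisms,
the directed relationship(s) between them, and any typed measurements.
This event-centred reading has three consequences the code enforces:

1. **Relationships are intra-event.** A relationship's subject and object
   occurrences must belong to the same event as the relationship itself.
   Cross-event relationships would break the archive star schema, where
   every extension row attaches to exactly one core event.
2. **Occurrences are per-event.** When a matrix is expanded to records,
   each edge's event gets fresh plant/animal occurrence rows even when the
   same taxon participates in many edges. A single shared occurrence
   referenced by many events is not representable in a star-schema
   extension row, so we deliberately diverge from a literal "each node is
   one occurrence" reading.
3. **Species-level data are derived.** Aggregation (records → matrix) is
   supported and lossy; the reverse direction must invent identifiers and
   is only used to standardize literature networks.

### The minimal-record contract

Validity requires: `scientificName` on every occurrence; `eventID` on every
event; a resolvable subject (`resourceID`) and object (`relatedResourceID`),
a type (text or IRI) and a non-empty `relationshipAccordingTo` on every
relationship; resolvable cross-references; unique identifiers per
collection; no self-relationships. Everything else — including all 48
vocabulary terms — is optional, matching Darwin Core's none-mandatory
philosophy. Vocabulary-level problems are warnings: a measurement type IRI
absent from the registry (`UNKNOWN_MEASUREMENT_TYPE`), a value outside a
term's controlled vocabulary (`CV_VIOLATION`), and events documenting no
relationship (`EVENT_WITHOUT_RELATIONSHIP`).

**Reference semantics.** A *non-empty* event link that does not resolve is
a `DANGLING_REFERENCE` error. An *empty* event link on a child record
produces no finding of its own: in the star-schema reading the core
identifier lives on the event record, whose absence is already reported as
`MISSING_EVENT_ID`, and blanking a core id blanks it across the row group.
Relationship subject/object references are part of the minimal contract, so
for them empty and unresolvable are both `DANGLING_REFERENCE`. This makes
single-fault injection exact: each blanked minimal field maps to exactly
one error code.

## The vocabulary registry

The registry holds 48 `Property` terms in six categories (Animal, Plant,
Flower, Interaction, Reproductive Success, Nectar Dynamics) under the
namespace `http://rs.rebipp.org.br/ppi/terms/`, each with the normative
elements of the TDWG documentation standard (name, label, IRI, definition,
ISO 8601 modified date, type) plus optional comments, references, protocol,
examples and controlled vocabulary. Controlled-value recommendations are
non-normative: a term without a controlled vocabulary accepts any non-empty
value, and matching is trim-then-compare, case-sensitive by default (the
controlled tokens are lowercase values; a case-insensitive option exists
for dirty legacy data).

The bundled file `data/ppi_terms_synthetic.csv` is a **synthetic
reconstruction** of the official roster: the terms fixed by the published
standard appear verbatim (`flowerOpeningType` with its complete template —
controlled values *cleistogamous*, *chasmogamous*, *both* — plus
`flowerColor`, `floralAttractants`, `caste`, `resourceCollected`,
`nectarCollectingBodyPart`, `numberOfRemovedPollenGrains`); the remaining
entries are representative pollination-biology terms (floral traits, nectar
dynamics, pollen counts, reproductive outcomes) filling the normative count
of 48. Analyses that depend on the exact official wording of the other 41
terms should load the official term list via `load_registry` / `--registry`
instead.

## Serialization dialects

### DwC-Archive

Event core (`eventID` first) plus Occurrence, eMoF and ResourceRelationship
extensions, CSV (UTF-8, comma, `\n`, minimal quoting, one declared header
line), `meta.xml` mapping every column to a term IRI by index, and a
minimal EML stub carrying title and provenance only. Readers take column
meaning from `meta.xml`, never from position or header text. The eMoF table
is exactly the classic MeasurementOrFact column set plus
`measurementTypeID`, `measurementValueID`, `measurementUnitID` (and
`occurrenceID`, empty for event-level measurements). When a registry is
supplied at write time, human-readable measurement types that name a
registry term get the term IRI (and matching controlled-value IRI) filled
into the ID columns.

`organism_role` (plant/animal/unknown) has no Darwin Core term; it is
serialized under the artifact-defined IRI `urn:ppidata:terms:organismRole`
so that round trips are lossless and aggregation needs no external role
rule. Readers that do not know the term simply see an extra column.

### XML

A flat document: `Event`, `Occurrence`, `MeasurementOrFact`,
`ResourceRelationship` elements in the DWC namespace, record fields as
child elements named by term token. Each measurement element appears
exactly once; its owner (event or occurrence) claims it by repeating the
identifier in a `measurementID` child. A reference with no matching
measurement element survives parsing (kept in the owner's `extra_terms`)
and is reported as `DANGLING_REFERENCE` at validation time. Parsing uses
lxml with entity resolution and network access disabled and rejects any
document that declares a DTD. See `docs/xml-layout.md`.

### RDF

The Darwin-SW mapping: minted IRIs (`<base>/event/<id>`,
`<base>/occurrence/<id>`, `<base>/mof/<id>` — no blank nodes, so graph
equality is plain set equality), `rdf:type` statements per record, literals
for term values, `dsw:atEvent` from each occurrence to its event, and the
interaction itself as a single triple with the subject and object
occurrences and a Relations Ontology predicate. Measurements hang off their
owner via `dcterms:relation`; `dwciri:measurementType` points at the term
IRI while `dwc:measurementType` carries the human-readable literal;
controlled values travel by default as literals typed `xsd:anyURI` holding
the value IRI (semantically a literal that *names* a resource — an
acknowledged tension; `cv_values_as_objects=True` emits a real
`dwciri:measurementValue` object property instead, non-default).

Whether the `ResourceRelationship` class itself belongs in RDF is unsettled
in the Darwin Core community, because its ID terms conflate typing with
identification. The bare occurrence→occurrence predicate cannot carry
`relationshipAccordingTo`, so by default `to_triples` additionally emits a
`dwc:ResourceRelationship`-typed node with the six relationship fields as
literals. This keeps dataset→graph→dataset round trips exact.
`reify_relationships=False` yields the bare form; graphs in that form still
parse, with relationship identifiers minted deterministically and an empty
assertion source (documented lossiness). The RO label↔IRI mapping
(`rdfio.RO_TERMS`) is an editable module-level table seeded with the common
pollination predicates (RO_0002455 *pollinates*, RO_0002622 *visits flowers
of*, ...), since no fixed list is normative.

## Networks and edge weights

`aggregate_to_network` keys cells by verbatim `scientificName` (no rank
collapsing), sorts taxa lexicographically, and needs each relationship to
resolve to one plant and one animal — from `organism_role` by default, or a
caller-supplied rule.

Edge weights have two representations. *Compact* (default): one event per
nonzero cell plus an event-level measurement typed ``"interaction
frequency"`` (an artifact-defined label with no vocabulary IRI — the
vocabulary defines no count term) recording the weight; aggregation counts
each relationship with that multiplicity, so matrix → records → matrix is
the identity. *Expanded*: weight-many replicate events, each counting 1; the
total relationship count then equals the matrix sum. The default subject
orientation is animal-acts-on-plant, matching how the usual predicates
(*pollinates*, *visits flowers of*) read.

The round-trip identity is stated over matrices with no all-zero row or
column: aggregation can only ever see taxa observed interacting at least
once, which is also the class that published networks belong to.

## The synthetic fixture generator

`FixtureProfile` defaults describe a small field campaign: 4 plant and 5
animal taxa, connectance 0.3 (6 realized edges), one record per edge, and a
measurement on half the events, drawn from five vocabulary terms spanning
occurrence-level (flower colour, flower opening type, caste) and
event-level (resource collected, visit duration) types, with values drawn
from each term's controlled vocabulary when it has one. A single seeded
`random.Random` stream with a fixed draw order (edge sample; then per
event: date month, day, latitude, longitude, measurement coin, term choice,
value choice) makes output byte-stable across runs and releases.

What the fixtures do *not* emulate: ecological network topology (edges are
uniform draws — no nestedness, degree heterogeneity or forbidden links),
taxonomy (names are synthetic binomials like *Plantus sp01* precisely to
avoid implying real taxa), messy data (no encoding noise, no partial dates,
no synonymy). Passing round-trip and contract tests on fixtures therefore
demonstrates the serializers and the validity contract, not robustness to
arbitrary real-world archives.

## Numerical and procedural choices

- Coordinates are stored as floats and serialized with Python's shortest
  round-tripping `str`; range checks (lat ∈ [−90, 90], lon ∈ [−180, 180])
  are construction-time errors, not findings.
- `canonicalize` defines dataset equality: trim all string fields, sort
  each collection by its identifier, sort `extra_terms` keys. It refuses
  datasets with validation errors.
- Legacy `associatedTaxa` strings are split on `|` between entries and on
  the *first* `:` within an entry, stripping quotes and whitespace; an
  unqualified entry yields an empty relationship qualifier. This is the
  dominant observed dialect; other delimiters would need a custom parser.
- Findings are sorted by (record kind, record id, code), so reports are
  deterministic and diffable.
- Problem sizes in the test suite and acceptance script (fixture grids up
  to 4×4 with 100 seeded profiles for round trips; 100 random matrices up
  to 20×20; RDF structure checks on datasets of ≤ 10 events) were chosen as
  the smallest sizes that exercise every code path — multi-edge events,
  occurrence- and event-level measurements, weighted and binary cells —
  while keeping the whole suite fast.

## Known limitations

- EML output is a title/provenance stub, not metadata authoring.
- No taxon-name reconciliation: aggregation keys are verbatim strings, so
  synonyms and spelling variants form separate nodes.
- RDF ingestion expects graphs following this package's mapping (typed
  nodes, `dsw:atEvent` links); arbitrary external biodiversity graphs are
  out of scope, and unrelated triples are skipped with a logged notice.
- The bare (non-reified) RDF form loses `relationshipAccordingTo` and
  free-text relationship types cannot be serialized to RDF at all — the
  CLI refuses such conversions unless `--allow-lossy` drops the affected
  relationships.
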