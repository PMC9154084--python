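# XML document layout

One interaction dataset is one XML document. The root element is
`interactionDataset` in the namespace `urn:ppidata:xml`, with an optional
`provenance` attribute. It contains, in order:

1. `dwc:Event` elements
2. `dwc:Occurrence` elements
3. `dwc:MeasurementOrFact` elements
4. `dwc:ResourceRelationship` elements

All record elements and their field children live in the Darwin Core terms
namespace `http://rs.tdwg.org/dwc/terms/` (prefix `dwc`), except the three
measurement ID terms (`measurementTypeID`, `measurementValueID`,
`measurementUnitID`) in `http://rs.iobis.org/obis/terms/` (prefix `obis`)
and `organismRole` in `urn:ppidata:xml` (prefix `app`). Element names equal
term tokens; empty fields are omitted.

## Identifier references

Unlike the archive star schema, one-to-many links are expressed directly:

- `Occurrence` and `ResourceRelationship` elements carry a `dwc:eventID`
  child referencing their event.
- Each measurement appears exactly once as a `dwc:MeasurementOrFact`
  element carrying a `dwc:measurementID` child. The owning `dwc:Event` (for
  measurements of the interaction) or `dwc:Occurrence` (for measurements of
  a participant) element repeats that identifier in its own
  `dwc:measurementID` child — once per owned measurement, so an element may
  carry several.

A `measurementID` reference with no matching `MeasurementOrFact` element is
not a parse error: the reference is preserved and reported as a
`DANGLING_REFERENCE` finding when the dataset is validated.

## Example

```xml
<?xml version='1.0' encoding='UTF-8'?>
<app:interactionDataset xmlns:dwc="http://rs.tdwg.org/dwc/terms/"
    xmlns:obis="http://rs.iobis.org/obis/terms/" xmlns:app="urn:ppidata:xml">
  <dwc:Event>
    <dwc:eventID>e1</dwc:eventID>
    <dwc:eventDate>2021-10-05</dwc:eventDate>
  </dwc:Event>
  <dwc:Occurrence>
    <dwc:occurrenceID>o1</dwc:occurrenceID>
    <dwc:eventID>e1</dwc:eventID>
    <dwc:scientificName>Fuchsia magellanica</dwc:scientificName>
    <app:organismRole>plant</app:organismRole>
    <dwc:measurementID>m1</dwc:measurementID>
  </dwc:Occurrence>
  <dwc:Occurrence>
    <dwc:occurrenceID>o2</dwc:occurrenceID>
    <dwc:eventID>e1</dwc:eventID>
    <dwc:scientificName>Sephanoides sephaniodes</dwc:scientificName>
    <app:organismRole>animal</app:organismRole>
  </dwc:Occurrence>
  <dwc:MeasurementOrFact>
    <dwc:measurementID>m1</dwc:measurementID>
    <dwc:measurementType>Flower Color</dwc:measurementType>
    <obis:measurementTypeID>http://rs.rebipp.org.br/ppi/terms/flowerColor</obis:measurementTypeID>
    <dwc:measurementValue>red</dwc:measurementValue>
  </dwc:MeasurementOrFact>
  <dwc:ResourceRelationship>
    <dwc:resourceRelationshipID>r1</dwc:resourceRelationshipID>
    <dwc:eventID>e1</dwc:eventID>
    <dwc:resourceID>o2</dwc:resourceID>
    <dwc:relatedResourceID>o1</dwc:relatedResourceID>
    <dwc:relationshipOfResource>pollinates</dwc:relationshipOfResource>
    <dwc:relationshipOfResourceID>http://purl.obolibrary.org/obo/RO_0002455</dwc:relationshipOfResourceID>
    <dwc:relationshipAccordingTo>field notes</dwc:relationshipAccordingTo>
  </dwc:ResourceRelationship>
</app:interactionDataset>
```

## Safety

Documents are parsed with entity resolution and network access disabled;
any document declaring a DTD (internal or external) is rejected outright.
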