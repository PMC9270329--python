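# Methods

## The representation model

The schema is a typed graph, not a reasoned ontology: a set of class
IRIs, acyclic subclass axioms rooted at exactly `Entity`, `Utility` and
`Data`, object properties with declared domain/range, and datatype
properties with literal ranges (`string`, `integer`, `decimal`).
Multi-parentage is allowed — `NeoplasticCell` sits under both `Cell` and
`Tumor`, `NeoplasticArea` under both `Tissue` and `Tumor` — so the
invariant enforced is acyclicity (Kahn topological sort), not tree-ness.
Subclass "inference" everywhere in the package is explicit closure
traversal; no OWL reasoner is involved, which keeps query results
deterministic and the dependency surface small.

The intermediate `PhysicalEntity` groupings are named `Cell`,
`CellularComponent`, `Substance` and `AnatomicalEntity` (the latter
splitting into `Tissue` and `AnatomicalStructure`); these names are the
one place the grouping vocabulary is recorded, and the `hasCell` /
`hasCellularComponent` / `hasAnatomicalEntity` child properties of
`hasComponent` range over them respectively. `hasProduct`/`hasReserve`
are declared on `PhysicalEntity` (they are among its four main
properties) but the builder enforces the stricter precondition that the
subject is a cell — microscopically observable inclusions (mucin,
glycogen, …) are products or reserves *of cells*.

Property names that the model needs but that have no canonical
vocabulary are package choices, recorded once in the schema module:
`hasQuantification` (attribute → quantification), `hasRelationship`
(phenotype → relationship), `movingObject`/`towards`/`movementType` on
`Relationship`, `attributeName`, `parameterName`/`value`/`unit`/
`formula`/`sourceLink` on `Quantification`, and `xrefId` on `Xref`.
`hasXref` is declared with a wildcard domain because both physical
entities and attributes legitimately carry cross-references. Xrefs are
opaque CURIE strings (`PREFIX:LOCALID`); a prefix registry (NCIt, CMPO,
FMA, GO, PATO, UO) exists for serialization only and nothing is ever
resolved against a live ontology, so an xref's biological correctness is
out of scope by design.

Individual IRIs are minted deterministically as
`{base_iri}/{slide_id}/{ClassLocalName}_{counter}` (default base
`https://histoml.example/wsi`; schema namespace
`https://histoml.example/histoml#`, configurable). Deterministic naming
plus a strict no-blank-node rule makes round-trips stable, files
diffable, and document equality a plain triple-set comparison.

## Validation semantics

`validate_document` checks every link and value against the schema:
unknown classes/properties, domain/range violations (with subclass
closure), dangling target IRIs, containment cycles (DFS), malformed
CURIEs, and phenotypes lacking a `present_Entity` are errors. An
`EntityAttribute` with neither an xref nor a quantification is a
*warning*, not an error — a purely named attribute (e.g. "eosinophilic"
with only a display name) is legal but conveys no machine-comparable
content. The builder API re-runs the same domain/range checks at
construction time, so documents built exclusively through it always
validate clean; this construction-correctness property is exercised by
randomized builder sequences in the test suite.

## Serialization

Turtle and RDF/XML via rdflib. Measured values are written as
`xsd:decimal`, pixel counts and slide dimensions as `xsd:integer`,
everything else as `xsd:string`; Python floats survive the
decimal-lexical round-trip because their shortest repr is exact. Slide
metadata (height, width in px; objective magnification, dimensionless;
optional microns-per-pixel, µm/px) is one `SlideData` individual at a
reserved IRI. File dialect on read is sniffed from content, since `.owl`
files carry either syntax. Reading collects unknown classes and
properties into a report instead of dropping them.

## Morphometry

All metrics operate on a `LabelMask`: a 2D nonnegative integer array
(row-major, origin top-left, 0 = background) plus a sidecar map from
segmentation-id strings to positive label values, serialized as 16-bit
PNG + JSON.

- **area** — pixel count; multiplied by (µm/px)² when the mask carries a
  resolution.
- **circularity** — 4πA/P² with P the weighted crack-length perimeter
  estimate from `skimage.measure.regionprops`. A rasterized disk of
  radius 50 px scores ≈ 0.92 (the estimator slightly over-measures
  digital circle boundaries, well inside the ±0.1 band a closed-form
  check uses); requested on a disconnected region it raises rather than
  silently merging components.
- **eccentricity** — from the region's second central moments
  (moment-equivalent ellipse); defined for any region with ≥ 2 pixels,
  approaching 1 for collinear pixels without erroring.
- **image entropy** — Shannon entropy, base 2, of the 256-bin intensity
  histogram over the region's pixels of the paired 8-bit grayscale image
  (RGB is converted by luminance). Constant regions give 0 bits, a 50/50
  two-level region exactly 1 bit, i.i.d. uniform noise ≈ 8 bits.

`quantify_entity` composes these with the document: one Quantification
individual per parameter per segmentation id, attached under the
entity's matching `EntityAttribute` (matched by an existing
quantification with the same parameter name, or by attribute name;
created if absent). Units are `px`/`um^2`, `dimensionless`, and `bit`.

## Stromal TILs

The score is semantic-first, mirroring a query-then-measure pipeline:
the lymphocyte set is the individuals of `Lymphocyte` (or subclasses) in
the containment closure of the document's stromal components, and all
areas come from segmentations. A flat label image cannot hold a nested
region and its parent on the same pixel, so nested regions overwrite the
parent label and the stromal denominator is reconstituted as the stroma
labels' pixels plus the pixels of every entity contained in the stroma.
A consequence is that each region must keep at least one exposed pixel
(a segmentation id must resolve), so full lymphocyte coverage saturates
at (A − 1)/A — a one-pixel effect. If lymphocyte masks could leak
outside the stroma, `clip_to_stroma=True` intersects them with the
stromal extent first; the shipped fixtures guarantee subset geometry, so
the default leaves pixels untouched.

## Queries

`run_sparql` evaluates SPARQL SELECT on the document's graph (cached
until the document changes). The canned queries are generated SPARQL:
class filters expand to the subclass closure at query-build time
(`VALUES`), containment closure is a SPARQL 1.1 property path over
`hasComponent|hasCell|hasCellularComponent|hasAnatomicalEntity`, and row
order is fixed lexicographically because SPARQL itself leaves it
undefined. Each canned query is property-tested against a pure
graph-traversal oracle on randomized documents.

## Synthetic fixtures

The generators emulate four exemplar scenes with exact ground truth;
images are cartoons (flat tints + Gaussian noise, σ = 4–7 gray levels) —
the package tests representation and measurement, not stain realism, so
passing tests say nothing about H&E color distributions, scanner
artifacts, or segmentation-model quality on real tissue.

- **TILs region** (default 10,000 px stroma, fraction 0.30,
  25 lymphocytes): stroma filled row-major to the exact pixel count
  under a parenchyma band; lymphocytes are seeded blobs grown
  breadth-first over free stroma pixels with per-blob quotas summing to
  `round(f·A)`, the last blob trimmed — coverage is exact by
  construction, not approximate. At extreme packing a blob may continue
  from a fresh seed (possibly disconnecting), which trades blob shape
  for guaranteed feasibility.
- **Rhabdoid cells** (default 4 cells, target areas 1,500–3,000 px,
  nucleus eccentricity 0.6–0.9): ellipse cells on a non-overlapping
  grid, each with an off-center nucleus (base ellipse whose axis ratio
  encodes the drawn eccentricity, plus boundary bumps for irregularity)
  and a bright nucleolus spot; the four characteristics are attached as
  attributes quantified from the generated mask itself.
- **Alveolar nests** (default 3): parenchyma disk of neoplastic cells
  ringed by a capillary holding erythrocytes and endothelia; containment
  runs three levels deep.
- **Tumor extension**: a mask-free document with one `Relationship`
  individual (type "extension") from the tumor towards the renal sinus.

Every bundle records a manifest whose quantities (per-region pixel
counts, true TILs fraction, drawn parameters, seed) are recomputable by
brute force from the emitted mask, and every bundle's document validates
clean. One seeded generator drives each bundle; identical parameters and
seed give bit-identical bundles. A fifth exemplar from the source domain
(papillary thyroid carcinoma) is not reconstructible from published main
text and is deliberately omitted.

`random_document` (also in the fixtures module) drives the property
suites: randomized builder sequences over the schema with containment
kept acyclic by linking only earlier-created to later-created entities.

## Problem sizes and tolerances

The randomized round-trip and query-equivalence suites use 200 documents
of 3–50 individuals; the acceptance script uses 100 per rate. Closed-form
morphometry checks use a radius-50 disk (±0.1 on circularity, ±0.05 on
eccentricity), a 60×30 ellipse (±0.05 against √3/2), and ≤64×64 random
masks against naive double-loop pixel oracles. TILs recovery is checked
at fractions {0, 0.1, 0.3, 0.5, 1.0} on a 10,000-px stroma to within one
pixel of rounding (1/A).

## Known limitations

- No pyramidal WSI formats; the unit of work is a tile + mask pair.
- No OWL reasoning; classification beyond explicit subclass closure
  (e.g. property-based inference) is unsupported.
- Overlapping regions cannot share pixels in a flat label mask; deeply
  nested quantification relies on the semantic reconstitution above.
- The ontology covers only the classes needed for the implemented
  exemplars; real deployments would extend the class list.
- Lymphocyte-within-stroma is determined by containment links, not by
  geometric testing; a document whose links contradict its masks will be
  scored by its links (use `clip_to_stroma` as a partial guard).
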