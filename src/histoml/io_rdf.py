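"""Read and write HistoML documents as OWL/RDF (Turtle and RDF/XML).

Every individual is a named node — blank nodes are avoided entirely — so
document equality reduces to plain triple-set comparison and SPARQL
results are stable.  Measured values are written as xsd:decimal, counts
as xsd:integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import rdflib
from rdflib import RDF, XSD, Literal, URIRef
from rdflib.namespace import Namespace

from .model import HistoMLDocument, Individual, SlideMetadata, validate_document
from .schema import XREF_PREFIXES, SchemaDefinition, schema_to_graph

_FORMATS = {"turtle": "turtle", "rdfxml": "xml", "xml": "xml"}


class SerializationError(ValueError):
    pass


@dataclass(frozen=True)
class SerializationConfig:
    """How a document is written: dialect, schema embedding, prefixes."""

    dialect: str = "turtle"
    embed_schema: bool = False
    prefix_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in _FORMATS:
            raise SerializationError(
                f"dialect must be one of {sorted(_FORMATS)}, got {self.dialect!r}"
            )


def _metadata_iri(doc: HistoMLDocument) -> str:
    return f"{doc.base_iri}/{doc.slide_id}/SlideData_0"


def document_to_graph(
    doc: HistoMLDocument, config: SerializationConfig | None = None
) -> rdflib.Graph:
    """Render a document (individuals + metadata) as an rdflib graph."""
    config = config or SerializationConfig()
    g = rdflib.Graph()
    ns = doc.schema.namespace
    g.bind("histoml", Namespace(ns))
    g.bind("wsi", Namespace(doc.base_iri + "/"))
    for prefix, base in {**XREF_PREFIXES, **config.prefix_map}.items():
        g.bind(prefix, Namespace(base))

    for ind in doc.individuals.values():
        subject = URIRef(ind.iri)
        g.add((subject, RDF.type, URIRef(ind.class_iri)))
        for prop, target in ind.object_links:
            g.add((subject, URIRef(prop), URIRef(target)))
        for prop, value in ind.data_values:
            g.add((subject, URIRef(prop), _literal(doc.schema, prop, value)))

    meta = URIRef(_metadata_iri(doc))
    md = doc.metadata
    g.add((meta, RDF.type, URIRef(ns + "SlideData")))
    g.add((meta, URIRef(ns + "height"), Literal(md.height, datatype=XSD.integer)))
    g.add((meta, URIRef(ns + "width"), Literal(md.width, datatype=XSD.integer)))
    g.add(
        (meta, URIRef(ns + "magnification"), Literal(md.magnification, datatype=XSD.decimal))
    )
    if md.microns_per_pixel is not None:
        g.add(
            (
                meta,
                URIRef(ns + "micronsPerPixel"),
                Literal(md.microns_per_pixel, datatype=XSD.decimal),
            )
        )
    if config.embed_schema:
        g += schema_to_graph(doc.schema)
    return g


def _literal(schema: SchemaDefinition, prop_iri: str, value: object) -> Literal:
    decl = schema.datatype_property(prop_iri)
    if decl is not None and decl.literal_type == "integer":
        return Literal(int(value), datatype=XSD.integer)
    if decl is not None and decl.literal_type == "decimal":
        return Literal(float(value), datatype=XSD.decimal)
    return Literal(str(value), datatype=XSD.string)


def write_document(
    doc: HistoMLDocument, path, config: SerializationConfig | None = None
) -> None:
    """Serialize a document to Turtle or RDF/XML; refuses invalid documents."""
    config = config or SerializationConfig()
    report = validate_document(doc)
    if not report.ok:
        msgs = "; ".join(v.message for v in report.errors[:5])
        raise SerializationError(f"refusing to write invalid document: {msgs}")
    g = document_to_graph(doc, config)
    g.serialize(destination=str(path), format=_FORMATS[config.dialect])


def read_document(
    path, schema: SchemaDefinition, base_iri: str = "https://histoml.example/wsi"
) -> tuple[HistoMLDocument, list[str]]:
    """Parse an RDF file into a document.

    Returns ``(document, report)`` where the report lists unknown classes
    or properties encountered (they are collected, never silently dropped).
    Raises on unparseable input.
    """
    from .schema import parse_rdf_file

    g = parse_rdf_file(path)
    return graph_to_document(g, schema, base_iri=base_iri)


def graph_to_document(
    g: rdflib.Graph, schema: SchemaDefinition, base_iri: str = "https://histoml.example/wsi"
) -> tuple[HistoMLDocument, list[str]]:
    ns = schema.namespace
    report: list[str] = []
    slide_data_iri = None
    typed: dict[str, str] = {}
    for s, o in sorted(g.subject_objects(RDF.type)):
        s_iri, cls = str(s), str(o)
        if cls in ("http://www.w3.org/2002/07/owl#Class",):
            continue
        if cls == ns + "SlideData":
            slide_data_iri = s_iri
            continue
        if cls.startswith("http://www.w3.org/"):
            continue
        if not schema.has_class(cls):
            report.append(f"unknown class {cls} on {s_iri}")
        typed[s_iri] = cls

    def _meta_value(prop: str, default=None):
        if slide_data_iri is None:
            return default
        v = g.value(URIRef(slide_data_iri), URIRef(ns + prop))
        return v.toPython() if v is not None else default

    metadata = SlideMetadata(
        height=int(_meta_value("height", 1)),
        width=int(_meta_value("width", 1)),
        magnification=float(_meta_value("magnification", 40.0)),
        microns_per_pixel=(
            float(v) if (v := _meta_value("micronsPerPixel")) is not None else None
        ),
    )
    # slide_id recovered from the metadata node's IRI path when possible
    slide_id = "slide"
    if slide_data_iri and slide_data_iri.startswith(base_iri + "/"):
        slide_id = slide_data_iri[len(base_iri) + 1 :].split("/")[0]
    doc = HistoMLDocument(metadata, schema, base_iri=base_iri, slide_id=slide_id)

    for s_iri, cls in typed.items():
        doc.individuals[s_iri] = Individual(iri=s_iri, class_iri=cls)
    for s, p, o in sorted(g):
        s_iri, p_iri = str(s), str(p)
        if s_iri not in doc.individuals or p_iri == str(RDF.type):
            continue
        ind = doc.individuals[s_iri]
        if isinstance(o, Literal):
            if schema.datatype_property(p_iri) is None:
                report.append(f"unknown datatype property {p_iri} on {s_iri}")
            ind.add_value(p_iri, _plain(schema, p_iri, o))
        else:
            if schema.object_property(p_iri) is None:
                report.append(f"unknown object property {p_iri} on {s_iri}")
            ind.add_link(p_iri, str(o))
    _restore_counters(doc)
    return doc, report


def _plain(schema: SchemaDefinition, prop_iri: str, lit: Literal) -> object:
    decl = schema.datatype_property(prop_iri)
    if decl is not None and decl.literal_type == "integer":
        return int(lit)
    if decl is not None and decl.literal_type == "decimal":
        return float(lit)
    return str(lit)


def _restore_counters(doc: HistoMLDocument) -> None:
    # keep IRI minting collision-free after a round-trip
    for iri in doc.individuals:
        local = iri.rsplit("/", 1)[-1]
        name, _, num = local.rpartition("_")
        if name and num.isdigit():
            doc._counters[name] = max(doc._counters.get(name, 0), int(num))


def canonical_triples(doc: HistoMLDocument) -> frozenset[tuple[str, str, str]]:
    """The document's triple set in canonical string form."""
    g = document_to_graph(doc, SerializationConfig())
    return frozenset((str(s), str(p), _canon_object(o)) for s, p, o in g)


def _canon_object(o) -> str:
    if isinstance(o, Literal):
        return f"literal:{o.datatype}:{o.toPython()!r}"
    return str(o)


def documents_equal(a: HistoMLDocument, b: HistoMLDocument) -> bool:
    """True iff the documents serialize to identical triple sets.

    All nodes are named (no blank nodes), so set equality of canonical
    triples is exact graph equality.
    """
    return canonical_triples(a) == canonical_triples(b)
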