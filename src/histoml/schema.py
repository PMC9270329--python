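"""HistoML Level 1 schema: classes, subclass axioms and properties.

The schema is a plain typed graph (no OWL reasoner involved): a set of
class IRIs, parent-child subclass pairs, object properties with declared
domain/range, and datatype properties with literal ranges.  ``Entity``,
``Utility`` and ``Data`` are the three root classes.  ``PhysicalEntity``
covers microscopically observable entities (cells, cellular components,
substances, tissues and other anatomical structures), cross-classified
into ``NormalEntity`` and ``Tumor``; ``Phenotype`` has the three
subclasses ``Cellular_Appearances``, ``Product_or_Reserve`` and
``Architectural_Pattern``.

Multi-parentage is allowed (``NeoplasticCell`` sits under both ``Cell``
and ``Tumor``); the structural invariant is acyclicity, not tree-ness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import rdflib
from rdflib import OWL, RDF, RDFS, XSD, URIRef
from rdflib.namespace import Namespace

#: Default namespace for HistoML classes and properties.
DEFAULT_NAMESPACE = "https://histoml.example/histoml#"

#: CURIE prefix registry for the reference vocabularies HistoML cross-links
#: to.  Prefixes are used for serialization only; terms are never resolved.
XREF_PREFIXES: dict[str, str] = {
    "NCIt": "http://purl.obolibrary.org/obo/NCIT_",
    "CMPO": "http://www.ebi.ac.uk/cmpo/CMPO_",
    "FMA": "http://purl.obolibrary.org/obo/FMA_",
    "GO": "http://purl.obolibrary.org/obo/GO_",
    "PATO": "http://purl.obolibrary.org/obo/PATO_",
    "UO": "http://purl.obolibrary.org/obo/UO_",
}


class SchemaError(ValueError):
    """Raised when a schema violates a structural invariant."""


class UndeclaredClassError(KeyError):
    """Raised when an operation references a class IRI not in the schema."""


@dataclass(frozen=True)
class ObjectProperty:
    """An object property with its declared domain and range.

    ``domain``/``range`` of ``None`` mean "any individual" (used for
    ``hasXref``, which applies across the hierarchy).
    """

    iri: str
    domain: str | None
    range: str | None
    parent: str | None = None


@dataclass(frozen=True)
class DatatypeProperty:
    iri: str
    domain: str | None
    literal_type: str  # local name of an XSD type: "string", "integer", "decimal"


@dataclass(frozen=True)
class SchemaDefinition:
    """The HistoML class/property hierarchy as an immutable typed graph."""

    namespace: str
    classes: frozenset[str]
    subclass_of: frozenset[tuple[str, str]]  # (child, parent)
    object_properties: frozenset[ObjectProperty]
    datatype_properties: frozenset[DatatypeProperty]
    _parents: dict[str, set[str]] = field(
        default_factory=dict, compare=False, repr=False
    )
    _children: dict[str, set[str]] = field(
        default_factory=dict, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        for child, parent in self.subclass_of:
            if child not in self.classes or parent not in self.classes:
                raise SchemaError(
                    f"subclass axiom references undeclared class: {child} -> {parent}"
                )
            self._parents.setdefault(child, set()).add(parent)
            self._children.setdefault(parent, set()).add(child)
        self._check_roots()
        self._check_acyclic()
        self._check_property_signatures()

    # -- invariants -------------------------------------------------------

    def _check_roots(self) -> None:
        roots = {c for c in self.classes if not self._parents.get(c)}
        expected = {self.iri(n) for n in ("Entity", "Utility", "Data")}
        if roots != expected:
            raise SchemaError(
                f"root classes must be exactly Entity/Utility/Data, got {sorted(roots)}"
            )

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over child -> parent edges; leftover nodes = cycle.
        indeg = {c: len(self._parents.get(c, ())) for c in self.classes}
        queue = [c for c, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for child in self._children.get(node, ()):  # pragma: no branch
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self.classes):
            raise SchemaError("subclass graph contains a cycle")

    def _check_property_signatures(self) -> None:
        prop_iris = {p.iri for p in self.object_properties}
        for p in self.object_properties:
            for cls in (p.domain, p.range):
                if cls is not None and cls not in self.classes:
                    raise SchemaError(f"property {p.iri} references undeclared {cls}")
            if p.parent is not None and p.parent not in prop_iris:
                raise SchemaError(f"{p.iri} has undeclared parent property {p.parent}")
        for d in self.datatype_properties:
            if d.domain is not None and d.domain not in self.classes:
                raise SchemaError(f"property {d.iri} references undeclared {d.domain}")
            if d.literal_type not in ("string", "integer", "decimal"):
                raise SchemaError(f"unsupported literal type {d.literal_type}")

    # -- lookups ----------------------------------------------------------

    def iri(self, local_name: str) -> str:
        """Expand a local class/property name against the schema namespace."""
        return self.namespace + local_name

    def local(self, iri: str) -> str:
        return iri.removeprefix(self.namespace)

    def has_class(self, class_iri: str) -> bool:
        return class_iri in self.classes

    def direct_subclasses(self, class_iri: str) -> set[str]:
        self._require(class_iri)
        return set(self._children.get(class_iri, ()))

    def object_property(self, iri: str) -> ObjectProperty | None:
        for p in self.object_properties:
            if p.iri == iri:
                return p
        return None

    def datatype_property(self, iri: str) -> DatatypeProperty | None:
        for d in self.datatype_properties:
            if d.iri == iri:
                return d
        return None

    def subproperties_of(self, prop_iri: str) -> set[str]:
        """The property and all its descendants under sub-property-of."""
        out = {prop_iri}
        frontier = [prop_iri]
        while frontier:
            cur = frontier.pop()
            for p in self.object_properties:
                if p.parent == cur and p.iri not in out:
                    out.add(p.iri)
                    frontier.append(p.iri)
        return out

    def is_subclass(self, class_iri: str, ancestor_iri: str) -> bool:
        return class_iri in subclass_closure(self, ancestor_iri)

    def _require(self, class_iri: str) -> None:
        if class_iri not in self.classes:
            raise UndeclaredClassError(class_iri)


def subclass_closure(schema: SchemaDefinition, class_iri: str) -> set[str]:
    """The class and all its descendants under the subclass relation."""
    schema._require(class_iri)
    out = {class_iri}
    frontier = [class_iri]
    while frontier:
        cur = frontier.pop()
        for child in schema._children.get(cur, ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


# -- the Level 1 schema ----------------------------------------------------

# (child, parent) pairs; local names, expanded in build_schema.
_SUBCLASS_AXIOMS: tuple[tuple[str, str], ...] = (
    # Entity branch
    ("PhysicalEntity", "Entity"),
    ("Phenotype", "Entity"),
    ("NormalEntity", "PhysicalEntity"),
    ("Tumor", "PhysicalEntity"),
    ("Cell", "PhysicalEntity"),
    ("CellularComponent", "PhysicalEntity"),
    ("Substance", "PhysicalEntity"),
    ("AnatomicalEntity", "PhysicalEntity"),
    ("Tissue", "AnatomicalEntity"),
    ("AnatomicalStructure", "AnatomicalEntity"),
    # cells
    ("NeoplasticCell", "Cell"),
    ("NeoplasticCell", "Tumor"),  # multi-parentage
    ("Lymphocyte", "Cell"),
    ("Lymphocyte", "NormalEntity"),
    ("Erythrocyte", "Cell"),
    ("Erythrocyte", "NormalEntity"),
    ("EndothelialCell", "Cell"),
    # cellular components
    ("Nucleus", "CellularComponent"),
    ("Nucleolus", "CellularComponent"),
    ("Cytoplasm", "CellularComponent"),
    # substances (granular cytoplasmic inclusions)
    ("Mucin", "Substance"),
    ("Glycogen", "Substance"),
    # tissues / structures
    ("Stroma", "Tissue"),
    ("Parenchyma", "Tissue"),
    ("NeoplasticArea", "Tissue"),
    ("NeoplasticArea", "Tumor"),
    ("Capillary", "AnatomicalStructure"),
    ("RenalSinus", "AnatomicalStructure"),
    # phenotypes
    ("Cellular_Appearances", "Phenotype"),
    ("Product_or_Reserve", "Phenotype"),
    ("Architectural_Pattern", "Phenotype"),
    # Utility branch
    ("EntityReference", "Utility"),
    ("EntityAttribute", "Utility"),
    ("Quantification", "Utility"),
    ("Relationship", "Utility"),
    ("Xref", "Utility"),
    # Data branch
    ("SlideData", "Data"),
)

# (local name, domain local, range local, parent local)
_OBJECT_PROPERTIES: tuple[tuple[str, str | None, str | None, str | None], ...] = (
    ("entityReference", "PhysicalEntity", "EntityReference", None),
    ("hasAttribute", "PhysicalEntity", "EntityAttribute", None),
    ("hasProduct", "PhysicalEntity", "Substance", None),
    ("hasReserve", "PhysicalEntity", "Substance", None),
    ("hasComponent", "PhysicalEntity", "PhysicalEntity", None),
    ("hasCell", "PhysicalEntity", "Cell", "hasComponent"),
    ("hasCellularComponent", "PhysicalEntity", "CellularComponent", "hasComponent"),
    ("hasAnatomicalEntity", "PhysicalEntity", "AnatomicalEntity", "hasComponent"),
    ("present_Entity", "Phenotype", "PhysicalEntity", None),
    ("hasRelationship", "Phenotype", "Relationship", None),
    ("movingObject", "Relationship", "PhysicalEntity", None),
    ("towards", "Relationship", "PhysicalEntity", None),
    ("hasQuantification", "EntityAttribute", "Quantification", None),
    ("hasXref", None, "Xref", None),
)

_DATATYPE_PROPERTIES: tuple[tuple[str, str | None, str], ...] = (
    ("segmentation", "PhysicalEntity", "string"),
    ("displayName", None, "string"),
    ("attributeName", "EntityAttribute", "string"),
    ("parameterName", "Quantification", "string"),
    ("value", "Quantification", "decimal"),
    ("unit", "Quantification", "string"),
    ("formula", "Quantification", "string"),
    ("sourceLink", "Quantification", "string"),
    ("movementType", "Relationship", "string"),
    ("xrefId", "Xref", "string"),
    ("height", "SlideData", "integer"),
    ("width", "SlideData", "integer"),
    ("magnification", "SlideData", "decimal"),
    ("micronsPerPixel", "SlideData", "decimal"),
)

#: The four "main" object properties of PhysicalEntity.
PHYSICAL_ENTITY_MAIN_PROPERTIES = (
    "entityReference",
    "hasAttribute",
    "hasProduct",
    "hasComponent",
)


def build_schema(namespace: str = DEFAULT_NAMESPACE) -> SchemaDefinition:
    """Construct the complete HistoML Level 1 schema.

    Parameters
    ----------
    namespace:
        Base IRI under which all class and property local names live.
    """
    n = lambda x: None if x is None else namespace + x
    classes = {"Entity", "Utility", "Data"}
    for child, parent in _SUBCLASS_AXIOMS:
        classes.add(child)
        classes.add(parent)
    return SchemaDefinition(
        namespace=namespace,
        classes=frozenset(namespace + c for c in classes),
        subclass_of=frozenset(
            (namespace + c, namespace + p) for c, p in _SUBCLASS_AXIOMS
        ),
        object_properties=frozenset(
            ObjectProperty(namespace + p, n(d), n(r), n(parent))
            for p, d, r, parent in _OBJECT_PROPERTIES
        ),
        datatype_properties=frozenset(
            DatatypeProperty(namespace + p, n(d), t)
            for p, d, t in _DATATYPE_PROPERTIES
        ),
    )


# -- OWL serialization -----------------------------------------------------

_XSD_TYPES = {"string": XSD.string, "integer": XSD.integer, "decimal": XSD.decimal}
_DIALECTS = {"turtle": "turtle", "rdfxml": "xml", "xml": "xml"}


def schema_to_graph(schema: SchemaDefinition) -> rdflib.Graph:
    """Render the schema as an rdflib OWL graph."""
    g = rdflib.Graph()
    ns = Namespace(schema.namespace)
    g.bind("histoml", ns)
    g.bind("owl", OWL)
    ontology = URIRef(schema.namespace.rstrip("#/"))
    g.add((ontology, RDF.type, OWL.Ontology))
    for cls in sorted(schema.classes):
        g.add((URIRef(cls), RDF.type, OWL.Class))
    for child, parent in sorted(schema.subclass_of):
        g.add((URIRef(child), RDFS.subClassOf, URIRef(parent)))
    for p in sorted(schema.object_properties, key=lambda p: p.iri):
        g.add((URIRef(p.iri), RDF.type, OWL.ObjectProperty))
        if p.domain:
            g.add((URIRef(p.iri), RDFS.domain, URIRef(p.domain)))
        if p.range:
            g.add((URIRef(p.iri), RDFS.range, URIRef(p.range)))
        if p.parent:
            g.add((URIRef(p.iri), RDFS.subPropertyOf, URIRef(p.parent)))
    for d in sorted(schema.datatype_properties, key=lambda d: d.iri):
        g.add((URIRef(d.iri), RDF.type, OWL.DatatypeProperty))
        if d.domain:
            g.add((URIRef(d.iri), RDFS.domain, URIRef(d.domain)))
        g.add((URIRef(d.iri), RDFS.range, _XSD_TYPES[d.literal_type]))
    return g


def export_schema(schema: SchemaDefinition, path, dialect: str = "turtle") -> None:
    """Write the schema as an OWL file in Turtle or RDF/XML."""
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {sorted(_DIALECTS)}, got {dialect!r}")
    schema_to_graph(schema).serialize(destination=str(path), format=_DIALECTS[dialect])


def canonical_schema_path():
    """Path of the canonical Level 1 schema file shipped with the package."""
    from importlib.resources import files

    return files("histoml") / "data" / "histoml_level1.ttl"


def parse_rdf_file(path) -> rdflib.Graph:
    """Parse an RDF file, sniffing the dialect from its content (an .owl
    extension may carry either Turtle or RDF/XML)."""
    with open(path, "rb") as fh:
        head = fh.read(512).lstrip()
    fmt = "xml" if head.startswith(b"<") else "turtle"
    g = rdflib.Graph()
    g.parse(str(path), format=fmt)
    return g


def import_schema(path, namespace: str = DEFAULT_NAMESPACE) -> SchemaDefinition:
    """Read an OWL schema file back into a :class:`SchemaDefinition`."""
    g = parse_rdf_file(path)
    classes = {str(s) for s in g.subjects(RDF.type, OWL.Class)}
    subclass_of = {
        (str(s), str(o))
        for s, o in g.subject_objects(RDFS.subClassOf)
        if str(s) in classes and str(o) in classes
    }
    obj_props = set()
    for s in g.subjects(RDF.type, OWL.ObjectProperty):
        dom = g.value(s, RDFS.domain)
        rng = g.value(s, RDFS.range)
        par = g.value(s, RDFS.subPropertyOf)
        obj_props.add(
            ObjectProperty(
                str(s),
                str(dom) if dom is not None else None,
                str(rng) if rng is not None else None,
                str(par) if par is not None else None,
            )
        )
    dt_props = set()
    xsd_back = {str(v): k for k, v in _XSD_TYPES.items()}
    for s in g.subjects(RDF.type, OWL.DatatypeProperty):
        dom = g.value(s, RDFS.domain)
        rng = g.value(s, RDFS.range)
        dt_props.add(
            DatatypeProperty(
                str(s),
                str(dom) if dom is not None else None,
                xsd_back.get(str(rng), "string"),
            )
        )
    return SchemaDefinition(
        namespace=namespace,
        classes=frozenset(classes),
        subclass_of=frozenset(subclass_of),
        object_properties=frozenset(obj_props),
        datatype_properties=frozenset(dt_props),
    )
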