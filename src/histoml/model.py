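"""In-memory HistoML document: typed individuals, links and validation.

A :class:`HistoMLDocument` holds the individuals describing one slide (or
tile): physical entities, their attributes and quantifications, phenotypes
and relationships, plus slide metadata.  The builder API validates every
edge against the schema's domain/range declarations as it is added, so a
document built exclusively through it never fails :func:`validate_document`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .schema import SchemaDefinition, subclass_closure

CURIE_PATTERN = re.compile(r"^[A-Za-z][A-Za-z0-9]*:\S+$")


class DocumentError(ValueError):
    """Base class for document construction errors."""


class DomainError(DocumentError):
    """An individual or link violates a declared domain/range."""


class ContainmentCycleError(DocumentError):
    """Adding a containment edge would create a cycle."""


@dataclass(frozen=True)
class SlideMetadata:
    """Pixel dimensions and acquisition metadata of a slide or tile.

    ``magnification`` is the objective power (e.g. 40 for 40x);
    ``microns_per_pixel`` converts pixel areas to physical units.
    """

    height: int
    width: int
    magnification: float = 40.0
    microns_per_pixel: float | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise DocumentError("slide height and width must be positive")
        if self.magnification <= 0:
            raise DocumentError("magnification must be positive")
        if self.microns_per_pixel is not None and self.microns_per_pixel <= 0:
            raise DocumentError("microns_per_pixel must be positive when given")


@dataclass(frozen=True)
class QuantificationNode:
    """A single quantitative measurement attached to an entity attribute."""

    parameter_name: str
    value: float
    unit: str | None = None
    formula: str | None = None
    source_link: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise DocumentError(f"quantification value must be finite: {self.value!r}")


@dataclass(frozen=True)
class RelationshipSpec:
    """A movement/behaviour: its type plus moving object and target IRIs."""

    movement_type: str
    moving_object: "Individual"
    target: "Individual"


@dataclass
class Individual:
    """One typed individual: its class, object links and data values.

    Links and values are kept in insertion order and deduplicated, so
    serialization is deterministic.  Multiple values per property are
    allowed.
    """

    iri: str
    class_iri: str
    object_links: list[tuple[str, str]] = field(default_factory=list)
    data_values: list[tuple[str, object]] = field(default_factory=list)

    def add_link(self, prop_iri: str, target_iri: str) -> None:
        if (prop_iri, target_iri) not in self.object_links:
            self.object_links.append((prop_iri, target_iri))

    def add_value(self, prop_iri: str, value: object) -> None:
        if (prop_iri, value) not in self.data_values:
            self.data_values.append((prop_iri, value))

    def links(self, prop_iri: str) -> list[str]:
        return [t for p, t in self.object_links if p == prop_iri]

    def values(self, prop_iri: str) -> list[object]:
        return [v for p, v in self.data_values if p == prop_iri]


@dataclass(frozen=True)
class Violation:
    kind: str
    subject: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __len__(self) -> int:
        return len(self.errors)


class HistoMLDocument:
    """A set of typed individuals plus slide metadata, bound to a schema."""

    def __init__(
        self,
        metadata: SlideMetadata,
        schema: SchemaDefinition,
        base_iri: str = "https://histoml.example/wsi",
        slide_id: str = "slide",
    ):
        self.metadata = metadata
        self.schema = schema
        self.base_iri = base_iri.rstrip("/")
        self.slide_id = slide_id
        self.individuals: dict[str, Individual] = {}
        self._counters: dict[str, int] = {}

    # -- plumbing ---------------------------------------------------------

    def _mint_iri(self, class_iri: str) -> str:
        local = self.schema.local(class_iri)
        n = self._counters.get(local, 0) + 1
        self._counters[local] = n
        return f"{self.base_iri}/{self.slide_id}/{local}_{n}"

    def _new_individual(self, class_iri: str) -> Individual:
        if not self.schema.has_class(class_iri):
            raise DomainError(f"class not in schema: {class_iri}")
        ind = Individual(iri=self._mint_iri(class_iri), class_iri=class_iri)
        self.individuals[ind.iri] = ind
        return ind

    def _cls(self, local_name: str) -> str:
        return self.schema.iri(local_name)

    def _require_kind(self, ind: Individual, ancestor_local: str) -> None:
        if ind.class_iri not in subclass_closure(self.schema, self._cls(ancestor_local)):
            raise DomainError(
                f"{ind.iri} has class {ind.class_iri}, expected a {ancestor_local}"
            )

    @property
    def containment_properties(self) -> set[str]:
        return self.schema.subproperties_of(self._cls("hasComponent"))

    def contained_iris(self, container_iri: str) -> set[str]:
        """Transitive closure of a container under hasComponent and children."""
        props = self.containment_properties
        out: set[str] = set()
        frontier = [container_iri]
        while frontier:
            cur = frontier.pop()
            ind = self.individuals.get(cur)
            if ind is None:
                continue
            for p, t in ind.object_links:
                if p in props and t not in out:
                    out.add(t)
                    frontier.append(t)
        return out

    # -- builder API ------------------------------------------------------

    def add_physical_entity(
        self,
        class_iri: str,
        entity_reference: str | None = None,
        segmentation_ids: list[str] | None = None,
        display_name: str | None = None,
    ) -> Individual:
        """Create a physical-entity individual.

        ``entity_reference`` links the individual to a shared generic
        description (an EntityReference individual, created on first use);
        ``segmentation_ids`` are the mask identifiers locating it.
        """
        if class_iri not in subclass_closure(self.schema, self._cls("PhysicalEntity")):
            raise DomainError(f"{class_iri} is not a PhysicalEntity class")
        ind = self._new_individual(class_iri)
        if entity_reference is not None:
            if entity_reference not in self.individuals:
                ref = Individual(iri=entity_reference, class_iri=self._cls("EntityReference"))
                self.individuals[ref.iri] = ref
            ind.add_link(self._cls("entityReference"), entity_reference)
        for seg_id in segmentation_ids or []:
            ind.add_value(self._cls("segmentation"), seg_id)
        if display_name is not None:
            ind.add_value(self._cls("displayName"), display_name)
        return ind

    def attach_attribute(
        self,
        entity: Individual,
        attribute_name: str,
        xrefs: list[str] | None = None,
        quantifications: list[QuantificationNode] | None = None,
    ) -> Individual:
        """Attach an EntityAttribute (with xrefs and quantifications).

        An attribute carrying neither an xref nor a quantification is legal
        but flagged as a warning by :func:`validate_document` — a purely
        named attribute conveys no machine-comparable content.
        """
        self._require_kind(entity, "PhysicalEntity")
        attr = self._new_individual(self._cls("EntityAttribute"))
        attr.add_value(self._cls("attributeName"), attribute_name)
        entity.add_link(self._cls("hasAttribute"), attr.iri)
        for curie in xrefs or []:
            self.add_xref(attr, curie)
        for q in quantifications or []:
            self.attach_quantification(attr, q)
        return attr

    def add_xref(self, individual: Individual, curie: str) -> Individual:
        """Store a cross-reference CURIE as an Xref individual."""
        if not CURIE_PATTERN.match(curie):
            raise DocumentError(f"malformed CURIE: {curie!r}")
        xref = self._new_individual(self._cls("Xref"))
        xref.add_value(self._cls("xrefId"), curie)
        individual.add_link(self._cls("hasXref"), xref.iri)
        return xref

    def attach_quantification(
        self, attribute: Individual, node: QuantificationNode
    ) -> Individual:
        self._require_kind(attribute, "EntityAttribute")
        q = self._new_individual(self._cls("Quantification"))
        q.add_value(self._cls("parameterName"), node.parameter_name)
        q.add_value(self._cls("value"), float(node.value))
        if node.unit is not None:
            q.add_value(self._cls("unit"), node.unit)
        if node.formula is not None:
            q.add_value(self._cls("formula"), node.formula)
        if node.source_link is not None:
            q.add_value(self._cls("sourceLink"), node.source_link)
        attribute.add_link(self._cls("hasQuantification"), q.iri)
        return q

    def link_component(
        self, parent: Individual, child: Individual, prop: str = "hasComponent"
    ) -> None:
        """Add a containment edge; rejects edges that would close a cycle."""
        prop_iri = self._cls(prop)
        if prop_iri not in self.containment_properties:
            raise DomainError(f"{prop} is not a containment property")
        self._check_link(prop_iri, parent, child)
        if parent.iri == child.iri or parent.iri in self.contained_iris(child.iri):
            raise ContainmentCycleError(
                f"linking {parent.iri} -> {child.iri} would create a containment cycle"
            )
        parent.add_link(prop_iri, child.iri)

    def add_product_or_reserve(
        self, cell: Individual, substance: Individual, relation: str = "hasProduct"
    ) -> None:
        """Record a cell's product or reserve (e.g. mucin, glycogen)."""
        if relation not in ("hasProduct", "hasReserve"):
            raise DomainError(f"relation must be hasProduct or hasReserve, got {relation}")
        prop_iri = self._cls(relation)
        self._require_kind(cell, "Cell")  # stricter than the declared domain
        self._check_link(prop_iri, cell, substance)
        cell.add_link(prop_iri, substance.iri)

    def add_phenotype(
        self,
        subclass: str,
        components: list[Individual],
        relationships: list[RelationshipSpec] | None = None,
        display_name: str | None = None,
    ) -> Individual:
        """Create a phenotype linked to its component entities.

        ``subclass`` is one of the three Phenotype subclasses.  Each
        component is linked through present_Entity; each relationship spec
        materializes as a Relationship individual carrying the movement
        type plus movingObject/towards links.
        """
        subclass_iri = subclass if subclass.startswith("http") else self._cls(subclass)
        phen_classes = subclass_closure(self.schema, self._cls("Phenotype"))
        if subclass_iri not in phen_classes or subclass_iri == self._cls("Phenotype"):
            raise DomainError(f"{subclass} is not a Phenotype subclass")
        if not components:
            raise DocumentError("a phenotype needs at least one component entity")
        for c in components:
            self._require_kind(c, "PhysicalEntity")
        phen = self._new_individual(subclass_iri)
        if display_name is not None:
            phen.add_value(self._cls("displayName"), display_name)
        for c in components:
            phen.add_link(self._cls("present_Entity"), c.iri)
        for spec in relationships or []:
            rel = self._new_individual(self._cls("Relationship"))
            rel.add_value(self._cls("movementType"), spec.movement_type)
            rel.add_link(self._cls("movingObject"), spec.moving_object.iri)
            rel.add_link(self._cls("towards"), spec.target.iri)
            phen.add_link(self._cls("hasRelationship"), rel.iri)
        return phen

    def _check_link(self, prop_iri: str, subject: Individual, target: Individual) -> None:
        prop = self.schema.object_property(prop_iri)
        if prop is None:
            raise DomainError(f"undeclared object property: {prop_iri}")
        if prop.domain is not None and subject.class_iri not in subclass_closure(
            self.schema, prop.domain
        ):
            raise DomainError(
                f"{subject.iri} ({subject.class_iri}) not in domain of {prop_iri}"
            )
        if prop.range is not None and target.class_iri not in subclass_closure(
            self.schema, prop.range
        ):
            raise DomainError(
                f"{target.iri} ({target.class_iri}) not in range of {prop_iri}"
            )

    # -- convenience ------------------------------------------------------

    def individuals_of(self, class_local_or_iri: str, closure: bool = True) -> list[Individual]:
        """All individuals of a class (by default including subclasses)."""
        cls = (
            class_local_or_iri
            if class_local_or_iri.startswith("http")
            else self._cls(class_local_or_iri)
        )
        wanted = subclass_closure(self.schema, cls) if closure else {cls}
        return [i for i in self.individuals.values() if i.class_iri in wanted]

    def segmentation_ids(self, individual: Individual) -> list[str]:
        return [str(v) for v in individual.values(self._cls("segmentation"))]


def new_document(
    metadata: SlideMetadata,
    schema: SchemaDefinition,
    base_iri: str = "https://histoml.example/wsi",
    slide_id: str = "slide",
) -> HistoMLDocument:
    """Create an empty document bound to a schema."""
    return HistoMLDocument(metadata, schema, base_iri=base_iri, slide_id=slide_id)


def validate_document(doc: HistoMLDocument) -> ValidationReport:
    """Check a document triple-by-triple against its schema.

    Reports domain/range violations, dangling IRIs, containment cycles,
    malformed xref CURIEs, component-less phenotypes (errors) and
    content-free attributes (warnings).  An empty report means valid.
    """
    schema = doc.schema
    report = ValidationReport()
    add = report.violations.append
    phen_classes = subclass_closure(schema, schema.iri("Phenotype"))

    for ind in doc.individuals.values():
        if not schema.has_class(ind.class_iri):
            add(Violation("unknown-class", ind.iri, f"class {ind.class_iri} not in schema"))
            continue
        for prop_iri, target_iri in ind.object_links:
            prop = schema.object_property(prop_iri)
            if prop is None:
                add(Violation("unknown-property", ind.iri, f"undeclared {prop_iri}"))
                continue
            target = doc.individuals.get(target_iri)
            if target is None:
                add(Violation("dangling-iri", ind.iri, f"{prop_iri} -> missing {target_iri}"))
                continue
            if prop.domain is not None and ind.class_iri not in subclass_closure(
                schema, prop.domain
            ):
                add(Violation("domain", ind.iri, f"not in domain of {prop_iri}"))
            if prop.range is not None and target.class_iri not in subclass_closure(
                schema, prop.range
            ):
                add(Violation("range", target_iri, f"not in range of {prop_iri}"))
        for prop_iri, value in ind.data_values:
            if schema.datatype_property(prop_iri) is None:
                add(Violation("unknown-property", ind.iri, f"undeclared {prop_iri}"))
            if prop_iri == schema.iri("xrefId") and not CURIE_PATTERN.match(str(value)):
                add(Violation("malformed-curie", ind.iri, f"bad CURIE {value!r}"))

        if ind.class_iri in phen_classes:
            if not ind.links(schema.iri("present_Entity")):
                add(Violation("empty-phenotype", ind.iri, "phenotype has no present_Entity"))
        if ind.class_iri == schema.iri("EntityAttribute"):
            if not ind.links(schema.iri("hasXref")) and not ind.links(
                schema.iri("hasQuantification")
            ):
                add(
                    Violation(
                        "empty-attribute",
                        ind.iri,
                        "attribute carries neither xref nor quantification",
                        severity="warning",
                    )
                )

    # containment acyclicity: DFS cycle detection over containment edges
    props = doc.containment_properties
    color: dict[str, int] = {}

    def visit(iri: str, stack: list[str]) -> None:
        color[iri] = 1
        ind = doc.individuals.get(iri)
        if ind is not None:
            for p, t in ind.object_links:
                if p not in props:
                    continue
                if color.get(t) == 1:
                    add(Violation("containment-cycle", t, " -> ".join(stack + [iri, t])))
                elif color.get(t, 0) == 0 and t in doc.individuals:
                    visit(t, stack + [iri])
        color[iri] = 2

    for iri in doc.individuals:
        if color.get(iri, 0) == 0:
            visit(iri, [])
    return report
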