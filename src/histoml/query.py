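"""SPARQL querying over HistoML documents.

Queries are evaluated by rdflib on the document's serialized graph.
Canned queries (phenotype decomposition, spatial containment, segmentation
lookup) are generated as SPARQL text: subclass inference is performed by
expanding a class IRI to its subclass closure at query-build time, and
containment closure uses a SPARQL 1.1 property path over hasComponent and
its child properties.  Row order is fixed (lexicographic) so results are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Literal
from rdflib.plugins.sparql import prepareQuery  # noqa: F401  (import check)

from .io_rdf import document_to_graph
from .model import HistoMLDocument
from .schema import subclass_closure


class QueryError(ValueError):
    pass


@dataclass
class QueryResult:
    """Tabular SPARQL bindings with a fixed, sorted row order."""

    variables: list[str]
    rows: list[dict[str, object]] = field(default_factory=list)

    def column(self, var: str) -> list[object]:
        return [r.get(var) for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def _sort_key(row: dict[str, object], variables: list[str]) -> tuple:
    return tuple(str(row.get(v, "")) for v in variables)


def _graph_for(doc: HistoMLDocument):
    """The document's RDF graph, cached until the document grows/shrinks."""
    signature = (
        len(doc.individuals),
        sum(len(i.object_links) for i in doc.individuals.values()),
        sum(len(i.data_values) for i in doc.individuals.values()),
    )
    cached = getattr(doc, "_graph_cache", None)
    if cached is not None and cached[0] == signature:
        return cached[1]
    g = document_to_graph(doc)
    doc._graph_cache = (signature, g)
    return g


def run_sparql(doc: HistoMLDocument, query_text: str) -> QueryResult:
    """Execute a SPARQL SELECT query against the document's RDF graph."""
    g = _graph_for(doc)
    try:
        res = g.query(query_text)
    except Exception as exc:  # rdflib raises pyparsing/Exception subclasses
        raise QueryError(f"malformed SPARQL: {exc}") from exc
    if res.type != "SELECT":
        raise QueryError(f"only SELECT queries are supported, got {res.type}")
    variables = [str(v) for v in res.vars]
    rows = []
    for binding in res:
        row = {}
        for var, term in zip(res.vars, binding):
            if term is None:
                continue
            row[str(var)] = term.toPython() if isinstance(term, Literal) else str(term)
        rows.append(row)
    rows.sort(key=lambda r: _sort_key(r, variables))
    return QueryResult(variables=variables, rows=rows)


def _containment_path(doc: HistoMLDocument) -> str:
    props = sorted(doc.containment_properties)
    return "(" + "|".join(f"<{p}>" for p in props) + ")+"


def _values_clause(var: str, iris) -> str:
    return f"VALUES ?{var} {{ " + " ".join(f"<{i}>" for i in sorted(iris)) + " }"


def components_of_phenotype(
    doc: HistoMLDocument, phenotype_iri: str, include_components: bool = False
) -> list[str]:
    """Entities a phenotype presents, via present_Entity.

    With ``include_components`` the hasComponent closure of each presented
    entity is included as well.
    """
    ind = doc.individuals.get(phenotype_iri)
    phen_classes = subclass_closure(doc.schema, doc.schema.iri("Phenotype"))
    if ind is None or ind.class_iri not in phen_classes:
        raise TypeError(f"{phenotype_iri} is not a Phenotype individual")
    ns = doc.schema.namespace
    path = f"<{ns}present_Entity>"
    if include_components:
        path = f"{path}/({_containment_path(doc)})?"
    query = f"SELECT DISTINCT ?e WHERE {{ <{phenotype_iri}> {path} ?e . }}"
    return [str(r["e"]) for r in run_sparql(doc, query)]


def entities_within(doc: HistoMLDocument, container_iri: str, class_iri: str) -> list[str]:
    """Individuals of a class (or subclass) contained, transitively, in a
    container — e.g. the lymphocytes within a stromal component."""
    if container_iri not in doc.individuals:
        raise QueryError(f"unknown container individual {container_iri}")
    classes = subclass_closure(doc.schema, class_iri)  # raises on undeclared
    query = (
        "SELECT DISTINCT ?e WHERE { "
        f"<{container_iri}> {_containment_path(doc)} ?e . "
        "?e a ?cls . "
        f"{_values_clause('cls', classes)} }}"
    )
    return [str(r["e"]) for r in run_sparql(doc, query)]


def segmentations_of(doc: HistoMLDocument, iris: list[str]) -> dict[str, list[str]]:
    """Map each IRI to its ``segmentation`` identifier values (maybe [])."""
    ns = doc.schema.namespace
    out: dict[str, list[str]] = {iri: [] for iri in iris}
    if iris:
        query = (
            "SELECT ?e ?s WHERE { "
            f"?e <{ns}segmentation> ?s . {_values_clause('e', iris)} }}"
        )
        for row in run_sparql(doc, query):
            out[str(row["e"])].append(str(row["s"]))
    for v in out.values():
        v.sort()
    return out
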