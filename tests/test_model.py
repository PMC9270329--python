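"""Document builder API and validation."""

import pytest

import histoml as h
from histoml.model import (
    ContainmentCycleError,
    DocumentError,
    DomainError,
    QuantificationNode,
    SlideMetadata,
)


@pytest.fixture()
def doc(schema):
    return h.new_document(SlideMetadata(height=1000, width=1000), schema)


class TestNewDocument:
    def test_empty_on_construction(self, doc):
        assert len(doc.individuals) == 0

    @pytest.mark.parametrize(
        "kwargs", [{"height": 0, "width": 10}, {"height": 10, "width": -1},
                   {"height": 10, "width": 10, "microns_per_pixel": 0.0}]
    )
    def test_invalid_metadata_rejected(self, kwargs):
        with pytest.raises(DocumentError):
            SlideMetadata(**kwargs)


class TestAddPhysicalEntity:
    def test_segmentation_value_stored(self, doc, schema):
        cell = doc.add_physical_entity(
            schema.iri("NeoplasticCell"), segmentation_ids=["seg:cell_1"]
        )
        assert doc.segmentation_ids(cell) == ["seg:cell_1"]

    def test_non_physical_class_rejected(self, doc, schema):
        with pytest.raises(DomainError):
            doc.add_physical_entity(schema.iri("Phenotype"))

    def test_shared_entity_reference_resolves_once(self, doc, schema):
        ref = f"{doc.base_iri}/slide/EntityReference_generic"
        a = doc.add_physical_entity(schema.iri("NeoplasticCell"), entity_reference=ref)
        b = doc.add_physical_entity(schema.iri("NeoplasticCell"), entity_reference=ref)
        prop = schema.iri("entityReference")
        assert a.links(prop) == b.links(prop) == [ref]
        assert sum(1 for i in doc.individuals.values()
                   if i.class_iri == schema.iri("EntityReference")) == 1

    def test_iris_deterministic_and_unique(self, doc, schema):
        a = doc.add_physical_entity(schema.iri("Lymphocyte"))
        b = doc.add_physical_entity(schema.iri("Lymphocyte"))
        assert a.iri.endswith("Lymphocyte_1") and b.iri.endswith("Lymphocyte_2")


class TestAttachAttribute:
    def test_quantification_linked(self, doc, schema):
        cell = doc.add_physical_entity(schema.iri("NeoplasticCell"))
        attr = doc.attach_attribute(
            cell, "large",
            quantifications=[QuantificationNode("area", 812.0, unit="um^2")],
        )
        q_iris = attr.links(schema.iri("hasQuantification"))
        assert len(q_iris) == 1
        q = doc.individuals[q_iris[0]]
        assert q.values(schema.iri("parameterName")) == ["area"]
        assert q.values(schema.iri("value")) == [812.0]

    def test_opaque_curie_stored_verbatim(self, doc, schema):
        cell = doc.add_physical_entity(schema.iri("NeoplasticCell"))
        attr = doc.attach_attribute(cell, "small", xrefs=["PATO:0000587"])
        xref = doc.individuals[attr.links(schema.iri("hasXref"))[0]]
        assert xref.values(schema.iri("xrefId")) == ["PATO:0000587"]

    def test_malformed_curie_rejected(self, doc, schema):
        cell = doc.add_physical_entity(schema.iri("NeoplasticCell"))
        with pytest.raises(DocumentError, match="CURIE"):
            doc.attach_attribute(cell, "bad", xrefs=["no curie here"])

    def test_empty_attribute_is_warning_not_error(self, doc, schema):
        cell = doc.add_physical_entity(schema.iri("NeoplasticCell"))
        doc.attach_attribute(cell, "eosinophilic")
        report = h.validate_document(doc)
        assert report.ok
        assert [v.kind for v in report.warnings] == ["empty-attribute"]

    def test_non_finite_value_rejected(self):
        with pytest.raises(DocumentError, match="finite"):
            QuantificationNode("area", float("nan"))


class TestLinkComponent:
    def test_contained_entity_reachable(self, doc, schema):
        stroma = doc.add_physical_entity(schema.iri("Stroma"))
        lym = doc.add_physical_entity(schema.iri("Lymphocyte"))
        doc.link_component(stroma, lym, "hasCell")
        assert lym.iri in doc.contained_iris(stroma.iri)

    def test_cycle_rejected(self, doc, schema):
        a = doc.add_physical_entity(schema.iri("Stroma"))
        b = doc.add_physical_entity(schema.iri("Parenchyma"))
        doc.link_component(a, b)
        with pytest.raises(ContainmentCycleError):
            doc.link_component(b, a)

    def test_self_containment_rejected(self, doc, schema):
        a = doc.add_physical_entity(schema.iri("Stroma"))
        with pytest.raises(ContainmentCycleError):
            doc.link_component(a, a)

    def test_transitive_closure_matches_reachability(self, doc, schema):
        a = doc.add_physical_entity(schema.iri("NeoplasticArea"))
        b = doc.add_physical_entity(schema.iri("Capillary"))
        c = doc.add_physical_entity(schema.iri("Erythrocyte"))
        doc.link_component(a, b, "hasAnatomicalEntity")
        doc.link_component(b, c, "hasCell")
        assert doc.contained_iris(a.iri) == {b.iri, c.iri}

    def test_range_violation_rejected(self, doc, schema):
        a = doc.add_physical_entity(schema.iri("Stroma"))
        b = doc.add_physical_entity(schema.iri("Stroma"))
        with pytest.raises(DomainError):
            doc.link_component(a, b, "hasCell")  # a Stroma is not a Cell


class TestProductOrReserve:
    def test_product_edge_added(self, doc, schema):
        cell = doc.add_physical_entity(schema.iri("NeoplasticCell"))
        mucin = doc.add_physical_entity(schema.iri("Mucin"))
        doc.add_product_or_reserve(cell, mucin, "hasProduct")
        assert cell.links(schema.iri("hasProduct")) == [mucin.iri]

    def test_reversed_domain_rejected(self, doc, schema):
        cell = doc.add_physical_entity(schema.iri("NeoplasticCell"))
        mucin = doc.add_physical_entity(schema.iri("Mucin"))
        with pytest.raises(DomainError):
            doc.add_product_or_reserve(mucin, cell, "hasProduct")


class TestAddPhenotype:
    def test_components_linked_via_present_entity(self, doc, schema):
        s = doc.add_physical_entity(schema.iri("Stroma"))
        p = doc.add_physical_entity(schema.iri("Parenchyma"))
        phen = doc.add_phenotype("Architectural_Pattern", [s, p])
        assert set(phen.links(schema.iri("present_Entity"))) == {s.iri, p.iri}

    def test_empty_components_rejected(self, doc):
        with pytest.raises(DocumentError):
            doc.add_phenotype("Cellular_Appearances", [])

    def test_relationship_materialized_with_three_links(self, doc, schema):
        tumor = doc.add_physical_entity(schema.iri("NeoplasticArea"))
        sinus = doc.add_physical_entity(schema.iri("RenalSinus"))
        phen = doc.add_phenotype(
            "Architectural_Pattern",
            [tumor, sinus],
            relationships=[h.RelationshipSpec("extension", tumor, sinus)],
        )
        rel_iris = phen.links(schema.iri("hasRelationship"))
        assert len(rel_iris) == 1
        rel = doc.individuals[rel_iris[0]]
        assert rel.values(schema.iri("movementType")) == ["extension"]
        assert rel.links(schema.iri("movingObject")) == [tumor.iri]
        assert rel.links(schema.iri("towards")) == [sinus.iri]


class TestValidateDocument:
    def test_fixture_documents_are_clean(
        self, tils_bundle, rhabdoid_bundle, alveolar_bundle
    ):
        for bundle in (tils_bundle, rhabdoid_bundle, alveolar_bundle):
            assert h.validate_document(bundle.document).ok

    def test_phenotype_without_component_reported(self, doc, schema):
        s = doc.add_physical_entity(schema.iri("Stroma"))
        phen = doc.add_phenotype("Architectural_Pattern", [s])
        phen.object_links.clear()  # corrupt behind the builder's back
        report = h.validate_document(doc)
        assert [v.kind for v in report.errors] == ["empty-phenotype"]

    def test_dangling_target_reported(self, doc, schema):
        s = doc.add_physical_entity(schema.iri("Stroma"))
        s.add_link(schema.iri("hasComponent"), doc.base_iri + "/slide/Ghost_1")
        assert [v.kind for v in h.validate_document(doc).errors] == ["dangling-iri"]

    def test_violation_count_matches_naive_check(self, doc, schema):
        # corrupt a document in three distinct ways; count per-triple
        s = doc.add_physical_entity(schema.iri("Stroma"))
        lym = doc.add_physical_entity(schema.iri("Lymphocyte"))
        doc.link_component(s, lym, "hasCell")
        s.add_link(schema.iri("hasComponent"), "https://x/ghost")  # dangling
        lym.add_link(schema.iri("hasCell"), s.iri)  # range violation + cycle
        lym.add_value(schema.iri("xrefId"), "not a curie")  # malformed
        report = h.validate_document(doc)
        assert {v.kind for v in report.errors} == {
            "dangling-iri",
            "range",
            "containment-cycle",
            "malformed-curie",
        }

    def test_builder_sequences_always_validate(self):
        for seed in range(30):
            doc = h.random_document(seed, max_individuals=25)
            assert h.validate_document(doc).ok, f"seed {seed}"
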