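@prefix histoml: <https://histoml.example/histoml#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

<https://histoml.example/histoml> a owl:Ontology .

histoml:Architectural_Pattern a owl:Class ;
    rdfs:subClassOf histoml:Phenotype .

histoml:Capillary a owl:Class ;
    rdfs:subClassOf histoml:AnatomicalStructure .

histoml:Cellular_Appearances a owl:Class ;
    rdfs:subClassOf histoml:Phenotype .

histoml:Cytoplasm a owl:Class ;
    rdfs:subClassOf histoml:CellularComponent .

histoml:EndothelialCell a owl:Class ;
    rdfs:subClassOf histoml:Cell .

histoml:Erythrocyte a owl:Class ;
    rdfs:subClassOf histoml:Cell,
        histoml:NormalEntity .

histoml:Glycogen a owl:Class ;
    rdfs:subClassOf histoml:Substance .

histoml:Lymphocyte a owl:Class ;
    rdfs:subClassOf histoml:Cell,
        histoml:NormalEntity .

histoml:Mucin a owl:Class ;
    rdfs:subClassOf histoml:Substance .

histoml:NeoplasticArea a owl:Class ;
    rdfs:subClassOf histoml:Tissue,
        histoml:Tumor .

histoml:NeoplasticCell a owl:Class ;
    rdfs:subClassOf histoml:Cell,
        histoml:Tumor .

histoml:Nucleolus a owl:Class ;
    rdfs:subClassOf histoml:CellularComponent .

histoml:Nucleus a owl:Class ;
    rdfs:subClassOf histoml:CellularComponent .

histoml:Parenchyma a owl:Class ;
    rdfs:subClassOf histoml:Tissue .

histoml:Product_or_Reserve a owl:Class ;
    rdfs:subClassOf histoml:Phenotype .

histoml:RenalSinus a owl:Class ;
    rdfs:subClassOf histoml:AnatomicalStructure .

histoml:Stroma a owl:Class ;
    rdfs:subClassOf histoml:Tissue .

histoml:attributeName a owl:DatatypeProperty ;
    rdfs:domain histoml:EntityAttribute ;
    rdfs:range xsd:string .

histoml:displayName a owl:DatatypeProperty ;
    rdfs:range xsd:string .

histoml:entityReference a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:EntityReference .

histoml:formula a owl:DatatypeProperty ;
    rdfs:domain histoml:Quantification ;
    rdfs:range xsd:string .

histoml:hasAnatomicalEntity a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:AnatomicalEntity ;
    rdfs:subPropertyOf histoml:hasComponent .

histoml:hasAttribute a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:EntityAttribute .

histoml:hasCell a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:Cell ;
    rdfs:subPropertyOf histoml:hasComponent .

histoml:hasCellularComponent a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:CellularComponent ;
    rdfs:subPropertyOf histoml:hasComponent .

histoml:hasProduct a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:Substance .

histoml:hasQuantification a owl:ObjectProperty ;
    rdfs:domain histoml:EntityAttribute ;
    rdfs:range histoml:Quantification .

histoml:hasRelationship a owl:ObjectProperty ;
    rdfs:domain histoml:Phenotype ;
    rdfs:range histoml:Relationship .

histoml:hasReserve a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:Substance .

histoml:hasXref a owl:ObjectProperty ;
    rdfs:range histoml:Xref .

histoml:height a owl:DatatypeProperty ;
    rdfs:domain histoml:SlideData ;
    rdfs:range xsd:integer .

histoml:magnification a owl:DatatypeProperty ;
    rdfs:domain histoml:SlideData ;
    rdfs:range xsd:decimal .

histoml:micronsPerPixel a owl:DatatypeProperty ;
    rdfs:domain histoml:SlideData ;
    rdfs:range xsd:decimal .

histoml:movementType a owl:DatatypeProperty ;
    rdfs:domain histoml:Relationship ;
    rdfs:range xsd:string .

histoml:movingObject a owl:ObjectProperty ;
    rdfs:domain histoml:Relationship ;
    rdfs:range histoml:PhysicalEntity .

histoml:parameterName a owl:DatatypeProperty ;
    rdfs:domain histoml:Quantification ;
    rdfs:range xsd:string .

histoml:present_Entity a owl:ObjectProperty ;
    rdfs:domain histoml:Phenotype ;
    rdfs:range histoml:PhysicalEntity .

histoml:segmentation a owl:DatatypeProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range xsd:string .

histoml:sourceLink a owl:DatatypeProperty ;
    rdfs:domain histoml:Quantification ;
    rdfs:range xsd:string .

histoml:towards a owl:ObjectProperty ;
    rdfs:domain histoml:Relationship ;
    rdfs:range histoml:PhysicalEntity .

histoml:unit a owl:DatatypeProperty ;
    rdfs:domain histoml:Quantification ;
    rdfs:range xsd:string .

histoml:value a owl:DatatypeProperty ;
    rdfs:domain histoml:Quantification ;
    rdfs:range xsd:decimal .

histoml:width a owl:DatatypeProperty ;
    rdfs:domain histoml:SlideData ;
    rdfs:range xsd:integer .

histoml:xrefId a owl:DatatypeProperty ;
    rdfs:domain histoml:Xref ;
    rdfs:range xsd:string .

histoml:Data a owl:Class .

histoml:EntityReference a owl:Class ;
    rdfs:subClassOf histoml:Utility .

histoml:AnatomicalStructure a owl:Class ;
    rdfs:subClassOf histoml:AnatomicalEntity .

histoml:Entity a owl:Class .

histoml:NormalEntity a owl:Class ;
    rdfs:subClassOf histoml:PhysicalEntity .

histoml:Tumor a owl:Class ;
    rdfs:subClassOf histoml:PhysicalEntity .

histoml:Xref a owl:Class ;
    rdfs:subClassOf histoml:Utility .

histoml:AnatomicalEntity a owl:Class ;
    rdfs:subClassOf histoml:PhysicalEntity .

histoml:EntityAttribute a owl:Class ;
    rdfs:subClassOf histoml:Utility .

histoml:Tissue a owl:Class ;
    rdfs:subClassOf histoml:AnatomicalEntity .

histoml:hasComponent a owl:ObjectProperty ;
    rdfs:domain histoml:PhysicalEntity ;
    rdfs:range histoml:PhysicalEntity .

histoml:CellularComponent a owl:Class ;
    rdfs:subClassOf histoml:PhysicalEntity .

histoml:Relationship a owl:Class ;
    rdfs:subClassOf histoml:Utility .

histoml:SlideData a owl:Class ;
    rdfs:subClassOf histoml:Data .

histoml:Substance a owl:Class ;
    rdfs:subClassOf histoml:PhysicalEntity .

histoml:Cell a owl:Class ;
    rdfs:subClassOf histoml:PhysicalEntity .

histoml:Phenotype a owl:Class ;
    rdfs:subClassOf histoml:Entity .

histoml:Utility a owl:Class .

histoml:Quantification a owl:Class ;
    rdfs:subClassOf histoml:Utility .

histoml:PhysicalEntity a owl:Class ;
    rdfs:subClassOf histoml:Entity .

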