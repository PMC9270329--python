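"""Generate rhabdoid-like cells and read back their quantified attributes.

Each synthetic cell is a large ellipse with an off-center irregular
nucleus holding a bright nucleolus.  The document is a
Cellular_Appearances phenotype; the four defining characteristics (cell
size, nucleus shape, nucleus position, nucleolus prominence) are
objectified by area, circularity, eccentricity and image entropy.
"""

import histoml as h

bundle = h.make_rhabdoid_fixture(n_cells=2, seed=7)
doc, schema = bundle.document, bundle.document.schema

cell = doc.individuals_of("NeoplasticCell")[0]
print(f"cell: {cell.iri.rsplit('/', 1)[-1]}")
for attr_iri in cell.links(schema.iri("hasAttribute")):
    attr = doc.individuals[attr_iri]
    name = attr.values(schema.iri("attributeName"))[0]
    for q_iri in attr.links(schema.iri("hasQuantification")):
        q = doc.individuals[q_iri]
        param = q.values(schema.iri("parameterName"))[0]
        value = q.values(schema.iri("value"))[0]
        unit = q.values(schema.iri("unit"))[0]
        print(f"  {name}: {param} = {value:.3f} {unit}")

# Cross-check: the attached area equals a direct measurement on the mask.
direct = h.region_area(bundle.mask, "seg:cell_1")
print(f"direct area of seg:cell_1: {direct} px")
# Circularity well below 1 reflects the irregular nucleus outline;
# eccentricity near the drawn value reflects the elongated nucleus.
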