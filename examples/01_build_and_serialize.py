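"""Build a document describing a tumor extending into the renal sinus,
validate it, and round-trip it through Turtle.

The document holds a tumor region, the renal sinus, and an
Architectural_Pattern phenotype whose Relationship individual records the
movement (type "extension", moving object = tumor, towards = sinus).
"""

import tempfile
from pathlib import Path

import histoml as h

doc = h.build_extension_exemplar()
report = h.validate_document(doc)
print(f"individuals: {len(doc.individuals)}")
print(f"validation errors: {len(report.errors)}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "extension.ttl"
    h.write_document(doc, path)
    print(f"turtle bytes written: {path.stat().st_size}")
    back, unknown = h.read_document(path, doc.schema)
    print(f"round-trip identical: {h.documents_equal(doc, back)}")

# The relationship is queryable: who moves towards the renal sinus?
schema = doc.schema
rows = h.run_sparql(
    doc,
    f"""SELECT ?mover ?type WHERE {{
        ?rel <{schema.iri('movingObject')}> ?mover ;
             <{schema.iri('movementType')}> ?type ;
             <{schema.iri('towards')}> ?sinus .
        ?sinus a <{schema.iri('RenalSinus')}> }}""",
)
for row in rows:
    print(f"movement: {row['type']}, moving object: {row['mover'].rsplit('/', 1)[-1]}")
# One row: the tumor individual is the single moving object recorded.
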