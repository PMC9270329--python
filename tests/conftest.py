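import numpy as np
import pytest
from skimage import draw

import histoml as h


@pytest.fixture(scope="session")
def schema():
    return h.build_schema()


@pytest.fixture(scope="session")
def tils_bundle():
    return h.make_tils_fixture(10_000, 0.3, 25, seed=1)


@pytest.fixture(scope="session")
def rhabdoid_bundle():
    return h.make_rhabdoid_fixture(n_cells=3, seed=2)


@pytest.fixture(scope="session")
def alveolar_bundle():
    return h.make_alveolar_fixture(n_nests=2, seed=3)


@pytest.fixture()
def disk_mask():
    labels = np.zeros((120, 120), dtype=np.int64)
    rr, cc = draw.disk((60, 60), 50)
    labels[rr, cc] = 1
    return h.LabelMask(labels=labels, id_map={"seg:disk": 1})


def containment_closure_oracle(doc, start_iri):
    """Brute-force reachability over containment edges (edge scan)."""
    props = doc.containment_properties
    out, frontier = set(), [start_iri]
    while frontier:
        cur = frontier.pop()
        ind = doc.individuals.get(cur)
        if ind is None:
            continue
        for p, t in ind.object_links:
            if p in props and t not in out:
                out.add(t)
                frontier.append(t)
    return out


def entities_within_oracle(doc, container_iri, class_iri):
    wanted = h.subclass_closure(doc.schema, class_iri)
    return sorted(
        iri
        for iri in containment_closure_oracle(doc, container_iri)
        if doc.individuals[iri].class_iri in wanted
    )


def components_oracle(doc, phenotype_iri, include_components=False):
    prop = doc.schema.iri("present_Entity")
    direct = set(doc.individuals[phenotype_iri].links(prop))
    if include_components:
        for iri in list(direct):
            direct |= containment_closure_oracle(doc, iri)
    return sorted(direct)


def segmentations_oracle(doc, iris):
    prop = doc.schema.iri("segmentation")
    return {
        iri: sorted(str(v) for v in doc.individuals[iri].values(prop)) for iri in iris
    }
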