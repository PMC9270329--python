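"""Synthetic fixture generation: paired (image, mask, document) bundles.

Each generator emits a cartoon tile (flat tints plus seeded noise — no
attempt at H&E realism), an integer label mask with a segmentation-id
sidecar mapping, a HistoML document describing the scene, and a manifest
of ground truth that is recomputable by brute force from the mask.  The
bundles emulate three canonical renal-cancer phenotypes — rhabdoid cells,
the alveolar pattern, tumor extension into the renal sinus — and a
breast-cancer stromal-TILs region, with exact, programmatically known
ground truth.

Determinism contract: identical parameters and seed produce bit-identical
bundles.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import draw

from . import io_rdf, quantify
from .model import (
    HistoMLDocument,
    Individual,
    QuantificationNode,
    RelationshipSpec,
    SlideMetadata,
    new_document,
)
from .quantify import IntensityImage, LabelMask
from .schema import SchemaDefinition, build_schema, subclass_closure


class PackingError(ValueError):
    """Requested regions cannot be packed into the available area."""


@dataclass
class FixtureBundle:
    """A synthetic (image, mask, document) triple with its ground truth."""

    image: IntensityImage
    mask: LabelMask
    document: HistoMLDocument
    manifest: dict

    def save(self, out_dir) -> None:
        """Write image.png, mask.png + mask.json, document.ttl, manifest.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        quantify.write_image(self.image, out / "image.png")
        quantify.write_mask(self.mask, out / "mask.png", out / "mask.json")
        io_rdf.write_document(self.document, out / "document.ttl")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _noise(rng: np.random.Generator, base: np.ndarray, sigma: float = 4.0) -> np.ndarray:
    noisy = base.astype(float) + rng.normal(0, sigma, base.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8)


# -- stromal TILs fixture --------------------------------------------------


def make_tils_fixture(
    stroma_area_px: int = 10_000,
    til_fraction: float = 0.3,
    n_lymphocytes: int = 25,
    seed: int = 0,
) -> FixtureBundle:
    """A tumor-immune region: parenchyma band over a stroma block in which
    lymphocyte blobs cover exactly ``round(til_fraction * stroma_area_px)``
    pixels.

    Lymphocytes are rejection-sampled disks grown (and the last one
    trimmed) to hit the target pixel count exactly; they are disjoint
    pixel-subsets of the stroma extent.  One stroma pixel is always kept
    exposed so every segmentation id resolves, which caps achievable
    coverage at (A-1)/A for ``til_fraction`` = 1.
    """
    if not 0 <= til_fraction <= 1:
        raise PackingError(f"til_fraction must be in [0, 1], got {til_fraction}")
    if stroma_area_px < 2:
        raise PackingError("stroma_area_px must be at least 2")
    rng = np.random.default_rng(seed)

    width = int(np.ceil(np.sqrt(stroma_area_px)))
    stroma_rows = int(np.ceil(stroma_area_px / width))
    par_rows = max(4, stroma_rows // 4)
    height = par_rows + stroma_rows
    labels = np.zeros((height, width), dtype=np.int64)
    labels[:par_rows, :] = 1  # parenchyma
    # stroma block: fill row-major to the exact pixel count
    flat = labels[par_rows:, :].reshape(-1)
    flat[:stroma_area_px] = 2
    labels[par_rows:, :] = flat.reshape(stroma_rows, width)
    stroma_extent = labels == 2

    target = round(til_fraction * stroma_area_px)
    target = min(target, stroma_area_px - 1)  # keep >=1 exposed stroma pixel
    lymph_labels: list[int] = []
    if target > 0:
        if n_lymphocytes < 1 or n_lymphocytes > target:
            raise PackingError(
                f"cannot split {target} lymphocyte pixels into {n_lymphocytes} regions"
            )
        quotas = [target // n_lymphocytes] * n_lymphocytes
        for i in range(target % n_lymphocytes):
            quotas[i] += 1
        free = stroma_extent.copy()
        for k, quota in enumerate(quotas):
            label = 3 + k
            _grow_blob(rng, labels, free, quota, label)
            lymph_labels.append(label)

    id_map = {"seg:parenchyma": 1, "seg:stroma": 2}
    for k, label in enumerate(lymph_labels):
        id_map[f"seg:lymphocyte_{k + 1}"] = label
    mask = LabelMask(labels=labels, id_map=id_map)

    tints = np.full(labels.shape, 235, dtype=np.uint8)
    tints[labels == 1] = 200
    tints[labels == 2] = 170
    for label in lymph_labels:
        tints[labels == label] = 90
    image = IntensityImage(pixels=_noise(rng, tints))

    schema = build_schema()
    doc = new_document(
        SlideMetadata(height=height, width=width), schema, slide_id="tils"
    )
    parenchyma = doc.add_physical_entity(
        schema.iri("Parenchyma"), segmentation_ids=["seg:parenchyma"]
    )
    stroma = doc.add_physical_entity(
        schema.iri("Stroma"), segmentation_ids=["seg:stroma"]
    )
    lymph_ref = f"{doc.base_iri}/{doc.slide_id}/EntityReference_lymphocyte"
    lymphocytes = []
    for k in range(len(lymph_labels)):
        lym = doc.add_physical_entity(
            schema.iri("Lymphocyte"),
            entity_reference=lymph_ref,
            segmentation_ids=[f"seg:lymphocyte_{k + 1}"],
        )
        doc.link_component(stroma, lym, "hasCell")
        lymphocytes.append(lym)
    doc.add_phenotype(
        "Architectural_Pattern",
        components=[parenchyma, stroma],
        display_name="tumor-immune phenotype",
    )

    lymph_px = {
        f"seg:lymphocyte_{k + 1}": int(np.count_nonzero(labels == label))
        for k, label in enumerate(lymph_labels)
    }
    total_lymph = sum(lymph_px.values())
    manifest = {
        "seed": seed,
        "stroma_area_px": stroma_area_px,
        "requested_til_fraction": til_fraction,
        "true_til_fraction": total_lymph / stroma_area_px,
        "lymphocyte_px": lymph_px,
        "parenchyma_px": int(np.count_nonzero(labels == 1)),
        "segmentation_ids": sorted(id_map),
    }
    return FixtureBundle(image=image, mask=mask, document=doc, manifest=manifest)


def _grow_blob(
    rng: np.random.Generator,
    labels: np.ndarray,
    free: np.ndarray,
    quota: int,
    label: int,
) -> None:
    """Paint a compact blob of exactly ``quota`` pixels on free pixels.

    Starts from a random free seed and grows breadth-first (disk-like for
    small quotas); if the seed's free component is exhausted, growth
    continues from a fresh seed, so packing always succeeds while free
    pixels remain.
    """
    if int(np.count_nonzero(free)) < quota:
        raise PackingError("not enough free stroma pixels for lymphocyte placement")
    remaining = quota
    h, w = labels.shape
    while remaining > 0:
        free_idx = np.flatnonzero(free.reshape(-1))
        seed_flat = int(rng.choice(free_idx))
        queue = deque([(seed_flat // w, seed_flat % w)])
        free[seed_flat // w, seed_flat % w] = False
        labels[seed_flat // w, seed_flat % w] = label
        remaining -= 1
        while queue and remaining > 0:
            r, c = queue.popleft()
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and free[rr, cc] and remaining > 0:
                    free[rr, cc] = False
                    labels[rr, cc] = label
                    remaining -= 1
                    queue.append((rr, cc))


# -- rhabdoid fixture ------------------------------------------------------


def make_rhabdoid_fixture(
    n_cells: int = 4,
    size_range_px: tuple[int, int] = (1500, 3000),
    eccentricity_range: tuple[float, float] = (0.6, 0.9),
    seed: int = 0,
) -> FixtureBundle:
    """Large neoplastic cells, each with an off-center irregular nucleus
    holding a bright nucleolus spot; a Cellular_Appearances phenotype
    quantified by area, circularity, eccentricity and image entropy.

    ``size_range_px`` bounds the target cell area; ``eccentricity_range``
    bounds the nucleus ellipse's drawn eccentricity.
    """
    if n_cells < 1:
        raise ValueError("a phenotype needs at least one component cell")
    lo, hi = size_range_px
    e_lo, e_hi = eccentricity_range
    if not (0 < lo <= hi) or not (0 <= e_lo <= e_hi < 1):
        raise ValueError("invalid size or eccentricity range")
    rng = np.random.default_rng(seed)

    tile = int(np.ceil(2.6 * np.sqrt(hi / np.pi)))
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    height, width = rows * tile, cols * tile
    labels = np.zeros((height, width), dtype=np.int64)
    tints = np.full((height, width), 225, dtype=np.uint8)

    id_map: dict[str, int] = {}
    per_cell: list[dict] = []
    next_label = 1
    for i in range(n_cells):
        cy = (i // cols) * tile + tile // 2
        cx = (i % cols) * tile + tile // 2
        area = float(rng.uniform(lo, hi))
        ratio = float(rng.uniform(1.0, 1.5))
        a = np.sqrt(area * ratio / np.pi)
        b = a / ratio
        theta = float(rng.uniform(0, np.pi))
        cell_lbl, nuc_lbl, nol_lbl = next_label, next_label + 1, next_label + 2
        next_label += 3

        rr, cc = draw.ellipse(cy, cx, a, b, shape=labels.shape, rotation=theta)
        labels[rr, cc] = cell_lbl
        tints[rr, cc] = 180  # eosinophilic cytoplasm

        # eccentric nucleus: moment eccentricity e fixes the axis ratio
        ecc = float(rng.uniform(e_lo, e_hi))
        nuc_a = 0.45 * b
        nuc_b = nuc_a * np.sqrt(1 - ecc**2)
        off = 0.45 * b
        ny = cy + off * np.cos(theta)
        nx = cx - off * np.sin(theta)
        cell_region = labels == cell_lbl
        nrr, ncc = draw.ellipse(ny, nx, nuc_a, nuc_b, shape=labels.shape, rotation=theta)
        nucleus = np.zeros_like(cell_region)
        nucleus[nrr, ncc] = True
        # irregular margin: a few bumps on the nucleus boundary
        for _ in range(3):
            phi = float(rng.uniform(0, 2 * np.pi))
            br = ny + 0.9 * nuc_a * np.cos(phi)
            bc = nx + 0.9 * nuc_b * np.sin(phi)
            brr, bcc = draw.disk((br, bc), max(2.0, 0.3 * nuc_b), shape=labels.shape)
            nucleus[brr, bcc] = True
        nucleus &= cell_region  # nucleus stays inside its cell
        labels[nucleus] = nuc_lbl
        tints[nucleus] = 70

        srr, scc = draw.disk((ny, nx), max(2.0, 0.18 * nuc_b), shape=labels.shape)
        nucleolus = np.zeros_like(cell_region)
        nucleolus[srr, scc] = True
        nucleolus &= labels == nuc_lbl
        labels[nucleolus] = nol_lbl
        tints[nucleolus] = 245  # prominent nucleolus

        id_map[f"seg:cell_{i + 1}"] = cell_lbl
        id_map[f"seg:nucleus_{i + 1}"] = nuc_lbl
        id_map[f"seg:nucleolus_{i + 1}"] = nol_lbl
        per_cell.append(
            {
                "cell_px": int(np.count_nonzero(labels == cell_lbl)),
                "nucleus_px": int(np.count_nonzero(labels == nuc_lbl)),
                "nucleolus_px": int(np.count_nonzero(labels == nol_lbl)),
                "drawn_eccentricity": ecc,
                "target_area_px": area,
            }
        )

    image = IntensityImage(pixels=_noise(rng, tints, sigma=7.0))
    mask = LabelMask(labels=labels, id_map=id_map)

    schema = build_schema()
    doc = new_document(
        SlideMetadata(height=height, width=width), schema, slide_id="rhabdoid"
    )
    cell_ref = f"{doc.base_iri}/{doc.slide_id}/EntityReference_rhabdoid_cell"
    cells = []
    for i in range(n_cells):
        cell = doc.add_physical_entity(
            schema.iri("NeoplasticCell"),
            entity_reference=cell_ref,
            segmentation_ids=[f"seg:cell_{i + 1}"],
            display_name=f"Rhabdoid_Cell{i + 1}",
        )
        nucleus = doc.add_physical_entity(
            schema.iri("Nucleus"), segmentation_ids=[f"seg:nucleus_{i + 1}"]
        )
        nucleolus = doc.add_physical_entity(
            schema.iri("Nucleolus"), segmentation_ids=[f"seg:nucleolus_{i + 1}"]
        )
        doc.link_component(cell, nucleus, "hasCellularComponent")
        doc.link_component(nucleus, nucleolus, "hasCellularComponent")
        # the four rhabdoid characteristics, each objectified by one parameter
        _attach(doc, cell, "large", ["PATO:0000586"], "area",
                quantify.region_area(mask, f"seg:cell_{i + 1}"), "px")
        _attach(doc, cell, "irregularly-shaped nucleus", ["PATO:0000944"], "circularity",
                quantify.region_circularity(mask, f"seg:nucleus_{i + 1}"), "dimensionless")
        _attach(doc, cell, "eccentric nucleus", ["PATO:0001575"], "eccentricity",
                quantify.region_eccentricity(mask, f"seg:nucleus_{i + 1}"), "dimensionless")
        _attach(doc, cell, "prominent nucleolus", ["PATO:0000591"], "image entropy",
                quantify.region_entropy(image, mask, f"seg:nucleus_{i + 1}"), "bit")
        doc.attach_attribute(cell, "eosinophilic cytoplasm", xrefs=["PATO:0002097"])
        cells.append(cell)
    doc.add_phenotype(
        "Cellular_Appearances", components=cells, display_name="rhabdoid feature"
    )

    manifest = {
        "seed": seed,
        "n_cells": n_cells,
        "size_range_px": list(size_range_px),
        "eccentricity_range": list(eccentricity_range),
        "cells": per_cell,
        "segmentation_ids": sorted(id_map),
    }
    return FixtureBundle(image=image, mask=mask, document=doc, manifest=manifest)


def _attach(doc, entity, attr_name, xrefs, parameter, value, unit) -> None:
    doc.attach_attribute(
        entity,
        attr_name,
        xrefs=xrefs,
        quantifications=[
            QuantificationNode(parameter_name=parameter, value=float(value), unit=unit)
        ],
    )


# -- alveolar fixture ------------------------------------------------------


def make_alveolar_fixture(n_nests: int = 3, seed: int = 0) -> FixtureBundle:
    """Alveolar nests: neoplastic parenchyma disks ringed by a capillary
    (the stroma) containing erythrocytes and endothelia; an
    Architectural_Pattern document with nested containment.
    """
    if n_nests < 1:
        raise ValueError("n_nests must be >= 1")
    rng = np.random.default_rng(seed)
    tile = 64
    cols = int(np.ceil(np.sqrt(n_nests)))
    rows = int(np.ceil(n_nests / cols))
    height, width = rows * tile, cols * tile
    labels = np.zeros((height, width), dtype=np.int64)
    tints = np.full((height, width), 235, dtype=np.uint8)

    id_map: dict[str, int] = {}
    next_label = 1
    nests_manifest: list[dict] = []

    schema = build_schema()
    doc = new_document(
        SlideMetadata(height=height, width=width), schema, slide_id="alveolar"
    )
    nest_entities: list[Individual] = []

    for i in range(n_nests):
        cy = (i // cols) * tile + tile // 2
        cx = (i % cols) * tile + tile // 2
        r_outer, r_inner = 26, 19
        cap_lbl, par_lbl = next_label, next_label + 1
        next_label += 2
        rr, cc = draw.disk((cy, cx), r_outer, shape=labels.shape)
        labels[rr, cc] = cap_lbl
        tints[rr, cc] = 150  # capillary ring
        rr, cc = draw.disk((cy, cx), r_inner, shape=labels.shape)
        labels[rr, cc] = par_lbl
        tints[rr, cc] = 205  # clear-cell parenchyma

        # small cells: erythrocytes + endothelia in the ring, neoplastic
        # cells in the parenchyma
        ring_cells, par_cells = [], []
        for kind, count, radius_band, tint in (
            ("erythrocyte", 2, (r_inner + 2, r_outer - 2), 120),
            ("endothelium", 2, (r_inner + 2, r_outer - 2), 100),
            ("neoplastic_cell", 3, (2, r_inner - 4), 180),
        ):
            for j in range(count):
                rho = float(rng.uniform(*radius_band))
                phi = float(rng.uniform(0, 2 * np.pi))
                py, px = cy + rho * np.sin(phi), cx + rho * np.cos(phi)
                lbl = next_label
                next_label += 1
                parent_lbl = cap_lbl if kind != "neoplastic_cell" else par_lbl
                prr, pcc = draw.disk((py, px), 2.2, shape=labels.shape)
                blob = np.zeros_like(labels, dtype=bool)
                blob[prr, pcc] = True
                blob &= labels == parent_lbl
                if not blob.any():  # fell entirely on an earlier blob; skip a step
                    blob[int(py) % labels.shape[0], int(px) % labels.shape[1]] = (
                        labels[int(py) % labels.shape[0], int(px) % labels.shape[1]]
                        == parent_lbl
                    )
                if not blob.any():
                    continue
                labels[blob] = lbl
                tints[blob] = tint
                seg = f"seg:{kind}_{i + 1}_{j + 1}"
                id_map[seg] = lbl
                (ring_cells if kind != "neoplastic_cell" else par_cells).append(
                    (kind, seg)
                )

        id_map[f"seg:capillary_{i + 1}"] = cap_lbl
        id_map[f"seg:parenchyma_{i + 1}"] = par_lbl

        nest = doc.add_physical_entity(
            schema.iri("NeoplasticArea"),
            display_name=f"alveolar_nest_{i + 1}",
        )
        capillary = doc.add_physical_entity(
            schema.iri("Capillary"), segmentation_ids=[f"seg:capillary_{i + 1}"]
        )
        parenchyma = doc.add_physical_entity(
            schema.iri("Parenchyma"), segmentation_ids=[f"seg:parenchyma_{i + 1}"]
        )
        doc.link_component(nest, capillary, "hasAnatomicalEntity")
        doc.link_component(nest, parenchyma, "hasAnatomicalEntity")
        cls_for = {
            "erythrocyte": "Erythrocyte",
            "endothelium": "EndothelialCell",
            "neoplastic_cell": "NeoplasticCell",
        }
        for kind, seg in ring_cells:
            cell = doc.add_physical_entity(
                schema.iri(cls_for[kind]), segmentation_ids=[seg]
            )
            doc.link_component(capillary, cell, "hasCell")
        for kind, seg in par_cells:
            cell = doc.add_physical_entity(
                schema.iri(cls_for[kind]), segmentation_ids=[seg]
            )
            doc.link_component(parenchyma, cell, "hasCell")
        nest_entities.append(nest)
        nests_manifest.append(
            {
                "capillary_px": int(np.count_nonzero(labels == cap_lbl)),
                "parenchyma_px": int(np.count_nonzero(labels == par_lbl)),
                "n_erythrocytes": sum(1 for k, _ in ring_cells if k == "erythrocyte"),
                "n_endothelia": sum(1 for k, _ in ring_cells if k == "endothelium"),
                "n_neoplastic_cells": len(par_cells),
            }
        )

    doc.add_phenotype(
        "Architectural_Pattern", components=nest_entities, display_name="alveolar pattern"
    )
    image = IntensityImage(pixels=_noise(rng, tints))
    mask = LabelMask(labels=labels, id_map=id_map)
    manifest = {
        "seed": seed,
        "n_nests": n_nests,
        "nests": nests_manifest,
        "segmentation_ids": sorted(id_map),
    }
    return FixtureBundle(image=image, mask=mask, document=doc, manifest=manifest)


# -- tumor-extension exemplar ---------------------------------------------


def build_extension_exemplar(schema: SchemaDefinition | None = None) -> HistoMLDocument:
    """A tumor extending into the renal sinus: one Relationship individual
    carrying the movement type plus movingObject/towards links."""
    schema = schema or build_schema()
    doc = new_document(
        SlideMetadata(height=512, width=512), schema, slide_id="extension"
    )
    tumor = doc.add_physical_entity(
        schema.iri("NeoplasticArea"),
        segmentation_ids=["seg:tumor"],
        display_name="tumor",
    )
    sinus = doc.add_physical_entity(
        schema.iri("RenalSinus"),
        segmentation_ids=["seg:renal_sinus"],
        display_name="renal sinus",
    )
    doc.add_phenotype(
        "Architectural_Pattern",
        components=[tumor, sinus],
        relationships=[
            RelationshipSpec(movement_type="extension", moving_object=tumor, target=sinus)
        ],
        display_name="tumor extension into renal sinus",
    )
    return doc


# -- randomized documents (property-testing support) -----------------------

_ENTITY_CLASSES = (
    "NeoplasticCell",
    "Lymphocyte",
    "Erythrocyte",
    "EndothelialCell",
    "Nucleus",
    "Nucleolus",
    "Cytoplasm",
    "Mucin",
    "Glycogen",
    "Stroma",
    "Parenchyma",
    "NeoplasticArea",
    "Capillary",
    "RenalSinus",
)
_PHENOTYPE_CLASSES = ("Cellular_Appearances", "Product_or_Reserve", "Architectural_Pattern")
_XREF_POOL = ("PATO:0000587", "PATO:0000586", "NCIt:C12917", "GO:0005634", "FMA:9637")


def random_document(
    seed: int, max_individuals: int = 30, schema: SchemaDefinition | None = None
) -> HistoMLDocument:
    """A random valid document built through the builder API.

    Used by the property suites: randomized builder sequences cover
    entities, references, attributes with xrefs and quantifications,
    containment (kept acyclic by linking only parent-before-child),
    products/reserves and phenotypes.
    """
    schema = schema or build_schema()
    rng = np.random.default_rng(seed)
    doc = new_document(
        SlideMetadata(
            height=int(rng.integers(64, 4096)),
            width=int(rng.integers(64, 4096)),
            magnification=float(rng.choice([20.0, 40.0])),
            microns_per_pixel=float(np.round(rng.uniform(0.2, 1.0), 4)),
        ),
        schema,
        slide_id=f"random{seed}",
    )
    n = int(rng.integers(3, max(4, max_individuals + 1)))
    entities: list[Individual] = []
    for i in range(n):
        cls = str(rng.choice(_ENTITY_CLASSES))
        segs = [f"seg:r{seed}_{i}_{k}" for k in range(int(rng.integers(0, 3)))]
        ref = None
        if rng.random() < 0.3:
            ref = f"{doc.base_iri}/{doc.slide_id}/EntityReference_shared_{int(rng.integers(3))}"
        ent = doc.add_physical_entity(
            schema.iri(cls), entity_reference=ref, segmentation_ids=segs
        )
        entities.append(ent)
        if rng.random() < 0.4:
            quants = []
            if rng.random() < 0.7:
                quants.append(
                    QuantificationNode(
                        parameter_name=str(rng.choice(quantify.PARAMETERS)),
                        value=float(np.round(rng.uniform(0, 1000), 4)),
                        unit="px",
                    )
                )
            xrefs = (
                [str(rng.choice(_XREF_POOL))] if (rng.random() < 0.7 or not quants) else []
            )
            doc.attach_attribute(ent, f"attr_{i}", xrefs=xrefs, quantifications=quants)

    cell_cls = subclass_closure(schema, schema.iri("Cell"))
    comp_cls = subclass_closure(schema, schema.iri("CellularComponent"))
    anat_cls = subclass_closure(schema, schema.iri("AnatomicalEntity"))
    subst_cls = subclass_closure(schema, schema.iri("Substance"))
    for _ in range(int(rng.integers(0, n))):
        pi, ci = sorted(rng.choice(len(entities), size=2, replace=False))
        parent, child = entities[int(pi)], entities[int(ci)]
        if child.class_iri in subst_cls:
            if parent.class_iri in cell_cls:
                doc.add_product_or_reserve(
                    parent, child, str(rng.choice(["hasProduct", "hasReserve"]))
                )
            continue
        if child.class_iri in cell_cls:
            prop = "hasCell"
        elif child.class_iri in comp_cls:
            prop = "hasCellularComponent"
        elif child.class_iri in anat_cls:
            prop = "hasAnatomicalEntity"
        else:
            prop = "hasComponent"
        doc.link_component(parent, child, prop)

    for _ in range(int(rng.integers(0, 3))):
        k = int(rng.integers(1, min(4, len(entities) + 1)))
        idx = rng.choice(len(entities), size=k, replace=False)
        comps = [entities[int(i)] for i in idx]
        rels = []
        if len(entities) >= 2 and rng.random() < 0.3:
            a, b = rng.choice(len(entities), size=2, replace=False)
            rels = [RelationshipSpec("extension", entities[int(a)], entities[int(b)])]
        doc.add_phenotype(str(rng.choice(_PHENOTYPE_CLASSES)), comps, relationships=rels)
    return doc
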