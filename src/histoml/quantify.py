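"""Quantitative histomorphometry on segmentation label masks.

Implements the four region parameters used to objectify cellular
characteristics — area, circularity (4*pi*A/P^2), eccentricity of the
moment-equivalent ellipse, and Shannon image entropy — plus the stromal
tumor-infiltrating-lymphocyte (TILs) score, and attaches the results to a
document as Quantification individuals.

Masks are integer label images (0 = background), row-major with the
origin at the top-left, paired with a sidecar mapping from segmentation
identifier strings to label values.  Because one pixel carries one label,
a nested region (a lymphocyte inside stroma) overwrites its parent's
label; semantically derived areas (see :func:`stromal_tils`) reconstitute
the parent's full extent from the containment links.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import measure

from .model import HistoMLDocument, Individual, QuantificationNode
from .schema import subclass_closure

#: Canonical parameter names, as used in Quantification individuals.
PARAMETERS = ("area", "circularity", "eccentricity", "image entropy")
_ALIASES = {"image_entropy": "image entropy", "entropy": "image entropy"}


class SegmentationIdError(KeyError):
    """A segmentation identifier does not resolve to pixels in the mask."""


class MultiComponentError(ValueError):
    """A shape metric was requested on a disconnected region."""


class PairingError(ValueError):
    """Image and mask shapes do not match."""


class UndefinedRatioError(ZeroDivisionError):
    """The stromal TILs denominator (stromal area) is zero."""


@dataclass
class LabelMask:
    """2D integer label image plus segmentation-id mapping.

    ``id_map`` maps segmentation identifier strings to positive label
    values; every mapped value must be present in ``labels``.
    """

    labels: np.ndarray
    id_map: dict[str, int]
    microns_per_pixel: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        values = list(self.id_map.values())
        if len(set(values)) != len(values):
            raise ValueError("id_map label values must be distinct")
        present = set(np.unique(self.labels).tolist())
        for seg_id, label in self.id_map.items():
            if label <= 0:
                raise ValueError(f"label for {seg_id!r} must be positive")
            if label not in present:
                raise SegmentationIdError(
                    f"segmentation id {seg_id!r} maps to label {label} absent from mask"
                )

    def region(self, seg_id: str) -> np.ndarray:
        """Boolean pixel mask of one segmentation id."""
        if seg_id not in self.id_map:
            raise SegmentationIdError(f"unknown segmentation id {seg_id!r}")
        region = self.labels == self.id_map[seg_id]
        if not region.any():
            raise SegmentationIdError(f"segmentation id {seg_id!r} has no pixels")
        return region


@dataclass
class IntensityImage:
    """8-bit grayscale tile paired with a label mask of the same shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3:  # RGB -> luminance
            self.pixels = np.asarray(
                Image.fromarray(self.pixels.astype(np.uint8)).convert("L")
            )
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D grayscale (or RGB)")
        self.pixels = self.pixels.astype(np.uint8)


# -- region metrics --------------------------------------------------------


def region_area(mask: LabelMask, seg_id: str, units: str = "px") -> float:
    """Pixel count of a region; ``units='um2'`` converts via microns/px."""
    count = int(np.count_nonzero(mask.region(seg_id)))
    if units == "px":
        return count
    if units == "um2":
        if mask.microns_per_pixel is None:
            raise ValueError("mask has no microns_per_pixel; cannot report um2")
        return count * mask.microns_per_pixel**2
    raise ValueError(f"units must be 'px' or 'um2', got {units!r}")


def _single_regionprops(region: np.ndarray, seg_id: str):
    labeled, n = measure.label(region, connectivity=2, return_num=True)
    if n != 1:
        raise MultiComponentError(
            f"region {seg_id!r} has {n} connected components; split before measuring"
        )
    return measure.regionprops(labeled)[0]


def region_circularity(mask: LabelMask, seg_id: str) -> float:
    """Isoperimetric circularity 4*pi*A/P^2 of a connected region.

    The perimeter P is the weighted contour-length (crack-length)
    estimate; a rasterized disk scores close to 1, elongated shapes
    score near 0.
    """
    props = _single_regionprops(mask.region(seg_id), seg_id)
    perimeter = props.perimeter
    if perimeter == 0:  # single pixel or degenerate
        return 1.0
    return 4.0 * np.pi * props.area / perimeter**2


def region_eccentricity(mask: LabelMask, seg_id: str) -> float:
    """Eccentricity of the ellipse with identical second central moments.

    0 for a disk, approaching 1 for elongated/collinear regions.
    """
    region = mask.region(seg_id)
    if np.count_nonzero(region) < 2:
        raise ValueError(f"region {seg_id!r} needs >=2 pixels for eccentricity")
    labeled = measure.label(region, connectivity=2)
    # moments are well defined for disconnected regions too; measure jointly
    labeled[labeled > 0] = 1
    return float(measure.regionprops(labeled)[0].eccentricity)


def region_entropy(image: IntensityImage, mask: LabelMask, seg_id: str) -> float:
    """Shannon entropy (base 2) of the 256-bin intensity histogram of the
    region's pixels."""
    if image.pixels.shape != mask.labels.shape:
        raise PairingError(
            f"image shape {image.pixels.shape} != mask shape {mask.labels.shape}"
        )
    values = image.pixels[mask.region(seg_id)]
    counts = np.bincount(values, minlength=256).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)


# -- document integration --------------------------------------------------

_FORMULAS = {
    "area": "A = |pixels|",
    "circularity": "4*pi*A/P^2",
    "eccentricity": "sqrt(1 - (b/a)^2) of the moment-equivalent ellipse",
    "image entropy": "-sum(p_i * log2(p_i)) over the 256-bin intensity histogram",
}


def _units_for(parameter: str, mask: LabelMask) -> str:
    if parameter == "area":
        return "um^2" if mask.microns_per_pixel is not None else "px"
    if parameter == "image entropy":
        return "bit"
    return "dimensionless"


def measure_parameter(
    parameter: str, mask: LabelMask, seg_id: str, image: IntensityImage | None = None
) -> float:
    parameter = _ALIASES.get(parameter, parameter)
    if parameter == "area":
        units = "um2" if mask.microns_per_pixel is not None else "px"
        return region_area(mask, seg_id, units=units)
    if parameter == "circularity":
        return region_circularity(mask, seg_id)
    if parameter == "eccentricity":
        return region_eccentricity(mask, seg_id)
    if parameter == "image entropy":
        if image is None:
            raise ValueError("image entropy needs the paired intensity image")
        return region_entropy(image, mask, seg_id)
    raise ValueError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")


def quantify_entity(
    doc: HistoMLDocument,
    entity_iri: str,
    mask: LabelMask,
    image: IntensityImage | None = None,
    parameters: tuple[str, ...] = PARAMETERS,
    attribute_names: dict[str, str] | None = None,
) -> list[QuantificationNode]:
    """Measure the requested parameters on an entity's segmentations and
    attach them as Quantification individuals.

    One node is produced per parameter per segmentation id, attached under
    the entity's EntityAttribute matching that parameter (created if
    absent; ``attribute_names`` overrides the attribute's display name per
    parameter).
    """
    entity = doc.individuals.get(entity_iri)
    if entity is None:
        raise KeyError(f"no individual {entity_iri} in document")
    seg_ids = doc.segmentation_ids(entity)
    if parameters and not seg_ids:
        raise SegmentationIdError(f"{entity_iri} carries no segmentation ids")
    unresolved = [s for s in seg_ids if s not in mask.id_map]
    if parameters and unresolved:
        raise SegmentationIdError(f"segmentation ids not in mask: {unresolved}")
    nodes: list[QuantificationNode] = []
    for parameter in parameters:
        parameter = _ALIASES.get(parameter, parameter)
        attr = _matching_attribute(doc, entity, parameter)
        if attr is None:
            name = (attribute_names or {}).get(parameter, parameter)
            attr = doc.attach_attribute(entity, name)
        for seg_id in seg_ids:
            node = QuantificationNode(
                parameter_name=parameter,
                value=float(measure_parameter(parameter, mask, seg_id, image)),
                unit=_units_for(parameter, mask),
                formula=_FORMULAS[parameter],
            )
            doc.attach_quantification(attr, node)
            nodes.append(node)
    return nodes


def _matching_attribute(
    doc: HistoMLDocument, entity: Individual, parameter: str
) -> Individual | None:
    s = doc.schema
    for attr_iri in entity.links(s.iri("hasAttribute")):
        attr = doc.individuals[attr_iri]
        for q_iri in attr.links(s.iri("hasQuantification")):
            q = doc.individuals[q_iri]
            if parameter in q.values(s.iri("parameterName")):
                return attr
        if parameter in attr.values(s.iri("attributeName")):
            return attr
    return None


# -- stromal TILs ----------------------------------------------------------


def stromal_tils(
    doc: HistoMLDocument, mask: LabelMask, clip_to_stroma: bool = False
) -> float:
    """Fraction of the stromal area covered by infiltrated lymphocytes.

    The lymphocyte set is derived semantically: individuals of Lymphocyte
    (or subclasses) in the containment closure of the document's stromal
    components.  Areas come from segmentations.  The stromal denominator
    is the stroma labels' pixels plus the pixels of every entity contained
    in the stroma — a nested region's pixels overwrite the stroma label in
    a flat mask but still lie within the stroma.

    With ``clip_to_stroma`` lymphocyte pixels are first intersected
    geometrically with that stromal extent (guards against lymphocyte
    masks that leak outside the stroma).
    """
    schema = doc.schema
    stroma_classes = subclass_closure(schema, schema.iri("Stroma"))
    stromas = [i for i in doc.individuals.values() if i.class_iri in stroma_classes]
    if not stromas:
        raise UndefinedRatioError("document contains no stromal component")
    lymph_classes = subclass_closure(schema, schema.iri("Lymphocyte"))

    stroma_ids: set[str] = set()
    contained_ids: set[str] = set()
    lymph_ids: set[str] = set()
    for stroma in stromas:
        stroma_ids.update(doc.segmentation_ids(stroma))
        for iri in doc.contained_iris(stroma.iri):
            ind = doc.individuals.get(iri)
            if ind is None:
                continue
            ids = doc.segmentation_ids(ind)
            if ind.class_iri in lymph_classes:
                if not ids:
                    raise SegmentationIdError(f"lymphocyte {iri} has no segmentation")
                lymph_ids.update(ids)
            contained_ids.update(ids)

    stroma_extent = np.zeros(mask.labels.shape, dtype=bool)
    for seg_id in stroma_ids | contained_ids:
        stroma_extent |= mask.region(seg_id)
    lymph_pixels = np.zeros(mask.labels.shape, dtype=bool)
    for seg_id in lymph_ids:
        lymph_pixels |= mask.region(seg_id)
    if clip_to_stroma:
        lymph_pixels &= stroma_extent

    denominator = int(np.count_nonzero(stroma_extent))
    if denominator == 0:
        raise UndefinedRatioError("stromal area is zero")
    return float(np.count_nonzero(lymph_pixels)) / denominator


# -- PNG + sidecar I/O -----------------------------------------------------


def write_mask(mask: LabelMask, png_path, sidecar_path) -> None:
    """Write a label mask as 16-bit PNG plus a JSON sidecar (id map, mpp)."""
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit PNG range")
    Image.fromarray(mask.labels.astype(np.uint16)).save(str(png_path))
    sidecar = {"id_map": mask.id_map, "microns_per_pixel": mask.microns_per_pixel}
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_mask(png_path, sidecar_path) -> LabelMask:
    labels = np.asarray(Image.open(str(png_path))).astype(np.int64)
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    return LabelMask(
        labels=labels,
        id_map={k: int(v) for k, v in sidecar["id_map"].items()},
        microns_per_pixel=sidecar.get("microns_per_pixel"),
    )


def write_image(image: IntensityImage, path) -> None:
    Image.fromarray(image.pixels).save(str(path))


def read_image(path) -> IntensityImage:
    return IntensityImage(pixels=np.asarray(Image.open(str(path)).convert("L")))
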