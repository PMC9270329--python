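"""Region morphometry: closed forms, naive pixel oracle, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw

import histoml as h
from histoml.quantify import (
    IntensityImage,
    LabelMask,
    MultiComponentError,
    PairingError,
    SegmentationIdError,
    UndefinedRatioError,
)


def naive_area(labels, value):
    """Brute-force double loop pixel count."""
    count = 0
    for row in labels:
        for px in row:
            if px == value:
                count += 1
    return count


def naive_entropy(pixels, labels, value):
    counts = [0] * 256
    n = 0
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if labels[r, c] == value:
                counts[pixels[r, c]] += 1
                n += 1
    ent = 0.0
    for k in counts:
        if k:
            p = k / n
            ent -= p * np.log2(p)
    return ent


class TestRegionArea:
    def test_solid_square(self):
        labels = np.zeros((20, 20), dtype=np.int64)
        labels[5:15, 5:15] = 1
        mask = LabelMask(labels, {"sq": 1})
        assert h.region_area(mask, "sq") == 100

    def test_micron_conversion(self):
        labels = np.ones((4, 5), dtype=np.int64)
        mask = LabelMask(labels, {"a": 1}, microns_per_pixel=0.5)
        assert h.region_area(mask, "a", units="um2") == pytest.approx(20 * 0.25)

    def test_unknown_id_raises(self, disk_mask):
        with pytest.raises(SegmentationIdError):
            h.region_area(disk_mask, "seg:ghost")

    def test_id_without_pixels_rejected_at_construction(self):
        with pytest.raises(SegmentationIdError):
            LabelMask(np.zeros((4, 4), dtype=np.int64), {"empty": 3})

    def test_additive_over_disjoint_regions(self):
        labels = np.zeros((10, 10), dtype=np.int64)
        labels[:5] = 1
        labels[7:] = 2
        mask = LabelMask(labels, {"a": 1, "b": 2})
        merged = labels.copy()
        merged[merged == 2] = 1
        both = LabelMask(merged, {"ab": 1})
        assert h.region_area(mask, "a") + h.region_area(mask, "b") == h.region_area(
            both, "ab"
        )


class TestRegionCircularity:
    def test_disk_near_one(self, disk_mask):
        assert h.region_circularity(disk_mask, "seg:disk") == pytest.approx(1.0, abs=0.1)

    def test_thin_bar_far_below_half(self):
        labels = np.zeros((5, 110), dtype=np.int64)
        labels[2, 5:105] = 1
        mask = LabelMask(labels, {"bar": 1})
        assert h.region_circularity(mask, "bar") < 0.5

    def test_monotone_decrease_with_elongation(self):
        values = []
        for ratio in (1.0, 1.5, 2.5, 4.0, 6.0):
            labels = np.zeros((300, 300), dtype=np.int64)
            rr, cc = draw.ellipse(
                150, 150, 20 * ratio, 20 / np.sqrt(ratio), shape=labels.shape
            )
            labels[rr, cc] = 1
            values.append(h.region_circularity(LabelMask(labels, {"e": 1}), "e"))
        assert values == sorted(values, reverse=True)

    def test_disconnected_region_rejected(self):
        labels = np.zeros((10, 10), dtype=np.int64)
        labels[0, 0] = 1
        labels[9, 9] = 1
        with pytest.raises(MultiComponentError):
            h.region_circularity(LabelMask(labels, {"two": 1}), "two")


class TestRegionEccentricity:
    def test_disk_near_zero(self, disk_mask):
        assert h.region_eccentricity(disk_mask, "seg:disk") == pytest.approx(0, abs=0.05)

    def test_two_to_one_ellipse_analytic(self):
        labels = np.zeros((200, 200), dtype=np.int64)
        rr, cc = draw.ellipse(100, 100, 60, 30)
        labels[rr, cc] = 1
        ecc = h.region_eccentricity(LabelMask(labels, {"e": 1}), "e")
        assert ecc == pytest.approx(np.sqrt(1 - 1 / 4), abs=0.05)

    def test_invariant_under_quarter_rotation(self):
        labels = np.zeros((200, 200), dtype=np.int64)
        rr, cc = draw.ellipse(100, 100, 60, 25, rotation=0.4)
        labels[rr, cc] = 1
        a = h.region_eccentricity(LabelMask(labels, {"e": 1}), "e")
        b = h.region_eccentricity(LabelMask(np.rot90(labels).copy(), {"e": 1}), "e")
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_pixel_rejected(self):
        labels = np.zeros((5, 5), dtype=np.int64)
        labels[2, 2] = 1
        with pytest.raises(ValueError, match="2 pixels"):
            h.region_eccentricity(LabelMask(labels, {"p": 1}), "p")


class TestRegionEntropy:
    def test_constant_region_zero_bits(self, disk_mask):
        img = IntensityImage(np.full((120, 120), 42, dtype=np.uint8))
        assert h.region_entropy(img, disk_mask, "seg:disk") == 0.0

    def test_uniform_noise_near_eight_bits(self):
        rng = np.random.default_rng(5)
        labels = np.ones((100, 100), dtype=np.int64)
        img = IntensityImage(rng.integers(0, 256, (100, 100)).astype(np.uint8))
        ent = h.region_entropy(img, LabelMask(labels, {"a": 1}), "a")
        assert ent == pytest.approx(8.0, abs=0.05)

    def test_two_level_region_one_bit(self):
        pixels = np.zeros((10, 10), dtype=np.uint8)
        pixels[:, 5:] = 255
        labels = np.ones((10, 10), dtype=np.int64)
        ent = h.region_entropy(IntensityImage(pixels), LabelMask(labels, {"a": 1}), "a")
        assert ent == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, disk_mask):
        img = IntensityImage(np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(PairingError):
            h.region_entropy(img, disk_mask, "seg:disk")


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_metrics_agree_with_naive_pixel_oracle(seed):
    """On random small masks, area and entropy equal a brute-force double
    loop, and translation leaves all four metrics unchanged."""
    rng = np.random.default_rng(seed)
    size = int(rng.integers(16, 64))
    labels = np.zeros((size, size), dtype=np.int64)
    r = int(rng.integers(3, size // 3))
    cy, cx = rng.integers(r + 1, size - r - 1, size=2)
    rr, cc = draw.ellipse(cy, cx, r, max(2, r // 2), shape=labels.shape)
    labels[rr, cc] = 1
    mask = LabelMask(labels, {"blob": 1})
    pixels = rng.integers(0, 256, labels.shape).astype(np.uint8)
    img = IntensityImage(pixels)

    assert h.region_area(mask, "blob") == naive_area(labels, 1)
    assert h.region_entropy(img, mask, "blob") == pytest.approx(
        naive_entropy(pixels, labels, 1)
    )

    # translation invariance: roll mask and image together (blob is interior)
    shifted_labels = np.roll(labels, (2, 3), axis=(0, 1))
    shifted_img = IntensityImage(np.roll(pixels, (2, 3), axis=(0, 1)))
    shifted = LabelMask(shifted_labels, {"blob": 1})
    if naive_area(shifted_labels, 1) == naive_area(labels, 1):  # no wraparound
        for metric in (h.region_area, h.region_circularity, h.region_eccentricity):
            assert metric(mask, "blob") == pytest.approx(metric(shifted, "blob"))
        assert h.region_entropy(img, mask, "blob") == pytest.approx(
            h.region_entropy(shifted_img, shifted, "blob")
        )


class TestQuantifyEntity:
    def test_rhabdoid_cell_carries_four_parameters(self, rhabdoid_bundle, schema):
        doc = rhabdoid_bundle.document
        cell = doc.individuals_of("NeoplasticCell")[0]
        params = set()
        for attr_iri in cell.links(schema.iri("hasAttribute")):
            for q_iri in doc.individuals[attr_iri].links(schema.iri("hasQuantification")):
                params.update(
                    doc.individuals[q_iri].values(schema.iri("parameterName"))
                )
        assert params == {"area", "circularity", "eccentricity", "image entropy"}

    def test_empty_parameter_set_is_noop(self, tils_bundle):
        doc = tils_bundle.document
        stroma = doc.individuals_of("Stroma")[0]
        before = len(doc.individuals)
        assert h.quantify_entity(doc, stroma.iri, tils_bundle.mask, parameters=()) == []
        assert len(doc.individuals) == before

    def test_values_equal_direct_region_calls(self, schema):
        bundle = h.make_rhabdoid_fixture(n_cells=1, seed=9)
        doc, mask, image = bundle.document, bundle.mask, bundle.image
        cell = doc.individuals_of("NeoplasticCell")[0]
        fresh = h.new_document(doc.metadata, schema)
        twin = fresh.add_physical_entity(
            schema.iri("NeoplasticCell"), segmentation_ids=["seg:cell_1"]
        )
        nodes = h.quantify_entity(fresh, twin.iri, mask, image)
        by_param = {n.parameter_name: n.value for n in nodes}
        assert by_param["area"] == h.region_area(mask, "seg:cell_1")
        assert by_param["circularity"] == pytest.approx(
            h.region_circularity(mask, "seg:cell_1")
        )
        assert by_param["eccentricity"] == pytest.approx(
            h.region_eccentricity(mask, "seg:cell_1")
        )
        assert by_param["image entropy"] == pytest.approx(
            h.region_entropy(image, mask, "seg:cell_1")
        )
        assert h.validate_document(fresh).ok

    def test_unresolvable_segmentation_listed(self, schema):
        bundle = h.make_tils_fixture(1_000, 0.2, 3, seed=8)  # private, mutable copy
        doc = bundle.document
        ghost = doc.add_physical_entity(
            schema.iri("NeoplasticCell"), segmentation_ids=["seg:ghost"]
        )
        with pytest.raises(SegmentationIdError, match="seg:ghost"):
            h.quantify_entity(doc, ghost.iri, bundle.mask, parameters=("area",))


class TestStromalTils:
    def test_thirty_percent_fixture(self, tils_bundle):
        got = h.stromal_tils(tils_bundle.document, tils_bundle.mask)
        assert got == pytest.approx(0.30, abs=1 / 10_000)

    def test_no_lymphocytes_yields_zero(self):
        bundle = h.make_tils_fixture(5_000, 0.0, 0, seed=4)
        assert h.stromal_tils(bundle.document, bundle.mask) == 0.0

    def test_full_coverage_saturates(self):
        bundle = h.make_tils_fixture(5_000, 1.0, 10, seed=4)
        got = h.stromal_tils(bundle.document, bundle.mask)
        assert got == pytest.approx(1.0, abs=1 / 5_000)

    def test_result_in_unit_interval(self):
        for f in (0.05, 0.42, 0.77):
            bundle = h.make_tils_fixture(4_000, f, 8, seed=11)
            assert 0 <= h.stromal_tils(bundle.document, bundle.mask) <= 1

    def test_no_stroma_raises(self, schema):
        doc = h.new_document(h.SlideMetadata(height=10, width=10), schema)
        labels = np.ones((4, 4), dtype=np.int64)
        mask = LabelMask(labels, {"a": 1})
        with pytest.raises(UndefinedRatioError):
            h.stromal_tils(doc, mask)

    def test_clip_flag_bounds_fraction(self, tils_bundle):
        clipped = h.stromal_tils(
            tils_bundle.document, tils_bundle.mask, clip_to_stroma=True
        )
        assert clipped == pytest.approx(0.30, abs=1 / 10_000)


class TestMaskIO:
    def test_png_sidecar_round_trip(self, tils_bundle, tmp_path):
        mask = tils_bundle.mask
        h.write_mask(mask, tmp_path / "m.png", tmp_path / "m.json")
        back = h.read_mask(tmp_path / "m.png", tmp_path / "m.json")
        assert np.array_equal(back.labels, mask.labels)
        assert back.id_map == mask.id_map
        assert back.microns_per_pixel == mask.microns_per_pixel

    def test_image_round_trip(self, tils_bundle, tmp_path):
        h.write_image(tils_bundle.image, tmp_path / "i.png")
        back = h.read_image(tmp_path / "i.png")
        assert np.array_equal(back.pixels, tils_bundle.image.pixels)
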