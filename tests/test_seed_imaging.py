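"""Segmentation and morphometrics against generator ground truth."""

import numpy as np
import pytest
from PIL import Image

from fadseed.seed_imaging import (
    MaskSet,
    SeedImage,
    SegmentationError,
    batch_measure,
    measure_seed,
    render_layers,
    segment_seed,
)
from fadseed.synthetic_data import ImageGenParams, generate_seed_image


def _iou(a, b):
    union = (a | b).sum()
    return 1.0 if union == 0 else (a & b).sum() / union


class TestSegmentSeed:
    def test_recovers_cover_and_masks(self, default_image):
        _, img, truth = default_image
        masks = segment_seed(SeedImage(img))
        rec = measure_seed(masks).spot_cover_pct
        true = 100.0 * truth.spot.sum() / truth.seed.sum()
        assert abs(rec - true) <= 2.0
        assert _iou(masks.seed, truth.seed) >= 0.90
        assert _iou(masks.spot, truth.spot) >= 0.90

    def test_spotless_seed_gives_empty_spot_mask(self):
        img, _ = generate_seed_image(ImageGenParams(target_cover=0.0, seed=2))
        assert not segment_seed(SeedImage(img)).spot.any()

    def test_blank_image_raises_no_seed(self, rng):
        blank = np.clip(rng.normal(205, 6, (128, 128, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(SegmentationError, match="no seed"):
            segment_seed(SeedImage(blank))

    def test_two_seeds_listed_as_candidates(self):
        img = np.full((200, 200, 3), 205, np.uint8)
        rr, cc = np.mgrid[0:200, 0:200]
        img[((rr - 60) ** 2 + (cc - 60) ** 2) < 900] = (140, 110, 85)
        img[((rr - 150) ** 2 + (cc - 150) ** 2) < 900] = (140, 110, 85)
        with pytest.raises(SegmentationError, match="multiple candidate"):
            segment_seed(SeedImage(img))

    def test_monotone_in_target_cover(self):
        covers = [0.10, 0.25, 0.40]
        recovered = []
        for c in covers:
            img, _ = generate_seed_image(ImageGenParams(target_cover=c, seed=5))
            recovered.append(
                measure_seed(segment_seed(SeedImage(img))).spot_cover_pct
            )
        assert recovered[0] < recovered[1] < recovered[2]

    def test_scale_equivariance(self):
        """Doubling resolution scales areas x4 but moves cover by < 1 point."""
        base = ImageGenParams(target_cover=0.3, seed=9)
        double = ImageGenParams(
            size=(512, 512),
            axes=(160.0, 110.0),
            spot_granularity=18.0,
            elaiosome_area=4400,
            target_cover=0.3,
            seed=9,
        )
        m1 = measure_seed(segment_seed(SeedImage(generate_seed_image(base)[0])))
        m2 = measure_seed(segment_seed(SeedImage(generate_seed_image(double)[0])))
        assert abs(m1.spot_cover_pct - m2.spot_cover_pct) < 1.0
        assert m2.seed_area / m1.seed_area == pytest.approx(4.0, rel=0.05)

    def test_idempotent_on_composite_original_panel(self, default_image):
        _, img, _ = default_image
        masks = segment_seed(SeedImage(img))
        comp = render_layers(SeedImage(img), masks)
        h, w = img.shape[:2]
        again = segment_seed(SeedImage(comp[:h, :w]))
        assert np.array_equal(masks.seed, again.seed)
        assert np.array_equal(masks.spot, again.spot)
        assert np.array_equal(masks.elaiosome, again.elaiosome)


class TestMeasureSeed:
    def test_cover_is_spot_over_seed(self):
        seed = np.zeros((20, 20), bool)
        seed[:10, :10] = True  # 100 px
        spot = np.zeros_like(seed)
        spot[:3, :10] = True  # 30 px
        m = measure_seed(MaskSet(seed=seed, spot=spot, elaiosome=np.zeros_like(seed)))
        assert m.spot_cover_pct == 30.0
        assert m.seed_area == 100 and m.spot_area == 30

    def test_zero_spots_zero_cover(self):
        seed = np.ones((5, 5), bool)
        m = measure_seed(
            MaskSet(seed=seed, spot=np.zeros_like(seed), elaiosome=np.zeros_like(seed))
        )
        assert m.spot_cover_pct == 0.0

    def test_empty_seed_mask_rejected(self):
        z = np.zeros((5, 5), bool)
        with pytest.raises(ValueError, match="empty seed"):
            measure_seed(MaskSet(seed=z, spot=z, elaiosome=z))

    def test_truth_masks_measured_exactly(self, default_image):
        _, _, truth = default_image
        m = measure_seed(truth)
        assert m.seed_area == truth.seed.sum()
        assert m.spot_area == truth.spot.sum()
        assert m.elaiosome_area == truth.elaiosome.sum()
        assert m.spot_cover_pct == 100.0 * truth.spot.sum() / truth.seed.sum()

    def test_physical_scale_converts_areas(self, default_image):
        _, _, truth = default_image
        m = measure_seed(truth, scale=0.01)  # e.g. mm per px
        assert m.seed_area == pytest.approx(truth.seed.sum() * 1e-4)
        assert m.spot_cover_pct == pytest.approx(
            100.0 * truth.spot.sum() / truth.seed.sum()
        )

    def test_mask_invariants_enforced(self):
        seed = np.zeros((4, 4), bool)
        seed[0, 0] = True
        bad_spot = np.zeros_like(seed)
        bad_spot[1, 1] = True
        with pytest.raises(ValueError, match="subset"):
            MaskSet(seed=seed, spot=bad_spot, elaiosome=np.zeros_like(seed))
        with pytest.raises(ValueError, match="disjoint"):
            MaskSet(seed=seed, spot=np.zeros_like(seed), elaiosome=seed.copy())


class TestRenderLayers:
    def test_empty_masks_reproduce_original(self, default_image):
        _, img, _ = default_image
        z = np.zeros(img.shape[:2], bool)
        comp = render_layers(SeedImage(img), MaskSet(seed=z, spot=z, elaiosome=z))
        h, w = img.shape[:2]
        for panel in (comp[:h, :w], comp[:h, w:], comp[h:, :w], comp[h:, w:]):
            assert np.array_equal(panel, img)

    def test_full_spot_mask_paints_seed_green(self, default_image):
        _, img, truth = default_image
        full = MaskSet(
            seed=truth.seed, spot=truth.seed.copy(), elaiosome=np.zeros_like(truth.seed)
        )
        comp = render_layers(SeedImage(img), full)
        h, w = img.shape[:2]
        spot_panel = comp[:h, w:]
        assert (spot_panel[truth.seed] == [0, 255, 0]).all()

    def test_output_is_2x2_tiling(self, default_image):
        _, img, truth = default_image
        comp = render_layers(SeedImage(img), truth)
        assert comp.shape == (2 * img.shape[0], 2 * img.shape[1], 3)

    def test_shape_mismatch_rejected(self, default_image):
        _, img, _ = default_image
        z = np.zeros((10, 10), bool)
        with pytest.raises(ValueError, match="shape"):
            render_layers(SeedImage(img), MaskSet(seed=z, spot=z, elaiosome=z))


class TestBatchMeasure:
    @pytest.fixture
    def image_dir(self, tmp_path):
        covers = {}
        for i, c in enumerate(np.linspace(0.1, 0.4, 6)):
            img, truth = generate_seed_image(
                ImageGenParams(target_cover=float(c), seed=100 + i)
            )
            name = f"seed_{i}.png"
            Image.fromarray(img).save(tmp_path / name)
            covers[name] = 100.0 * truth.spot.sum() / truth.seed.sum()
        return tmp_path, covers

    def test_one_row_per_image_within_tolerance(self, image_dir):
        d, covers = image_dir
        table, failures = batch_measure(d)
        assert len(table) == 6 and not failures
        for _, row in table.iterrows():
            assert abs(row["spot_cover_pct"] - covers[row["source"]]) <= 2.0

    def test_corrupt_file_logged_not_dropped_silently(self, image_dir):
        d, _ = image_dir
        (d / "broken.png").write_text("not an image")
        table, failures = batch_measure(d)
        assert len(table) == 6
        assert len(failures) == 1 and failures[0][0] == "broken.png"

    def test_rerun_is_identical(self, image_dir):
        d, _ = image_dir
        t1, _ = batch_measure(d)
        t2, _ = batch_measure(d)
        assert t1.equals(t2)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no PNG"):
            batch_measure(tmp_path)
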