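"""Synthetic scenes, polygon rasterization, denoising, augmentation,
splitting and raster I/O."""

import numpy as np
import pytest

import organoidseg as og
from organoidseg.data import apply_tile_transform

from conftest import brute_force_point_in_polygon, random_simple_polygon


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------


class TestSyntheticScene:
    def test_no_organoids_gives_empty_mask(self):
        s = og.generate_synthetic_scene(
            og.SyntheticSceneSpec(n_organoids=0, noise_sigma=0, seed=1)
        )
        assert s.mask.sum() == 0

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_disc_area_close_to_pi_r_squared(self, seed):
        # degenerate radius range -> a disc; area must sit within 10% of pi r^2
        s = og.generate_synthetic_scene(
            og.SyntheticSceneSpec(
                width=64, height=64, n_organoids=1, radius_range=(10, 10),
                overlap_allowed=False, noise_sigma=0, seed=seed,
            )
        )
        assert 283 <= s.mask.sum() <= 346

    def test_seed_determinism_bit_identical(self):
        a = og.generate_synthetic_scene(og.SyntheticSceneSpec(seed=9))
        b = og.generate_synthetic_scene(og.SyntheticSceneSpec(seed=9))
        assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)

    def test_different_seeds_differ(self):
        a = og.generate_synthetic_scene(og.SyntheticSceneSpec(seed=1))
        b = og.generate_synthetic_scene(og.SyntheticSceneSpec(seed=2))
        assert not np.array_equal(a.image, b.image)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            og.generate_synthetic_scene(
                og.SyntheticSceneSpec(width=40, height=40, radius_range=(5, 30))
            )


# ---------------------------------------------------------------------------
# polygon rasterization
# ---------------------------------------------------------------------------


class TestRasterization:
    def test_axis_aligned_square_boundary_inclusive(self):
        ann = og.PolygonAnnotation([("sq", [(0, 0), (4, 0), (4, 4), (0, 4)])], 10, 10)
        mask = og.rasterize_polygons(ann)
        assert mask.sum() == 25
        assert mask[:5, :5].all() and not mask[5:, :].any() and not mask[:, 5:].any()

    def test_empty_shape_list_all_zero(self):
        assert og.rasterize_polygons(og.PolygonAnnotation([], 8, 8)).sum() == 0

    def test_disjoint_triangles_areas_add(self):
        t1 = [(1.0, 1.0), (6.0, 1.0), (1.0, 6.0)]
        t2 = [(10.0, 10.0), (15.0, 10.0), (10.0, 15.0)]
        both = og.rasterize_polygons(og.PolygonAnnotation([("a", t1), ("b", t2)], 20, 20))
        m1 = og.rasterize_polygons(og.PolygonAnnotation([("a", t1)], 20, 20))
        m2 = og.rasterize_polygons(og.PolygonAnnotation([("b", t2)], 20, 20))
        assert both.sum() == m1.sum() + m2.sum()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            og.rasterize_polygons(og.PolygonAnnotation([("bad", [(0, 0), (1, 1)])], 8, 8))

    def test_matches_brute_force_point_in_polygon(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            canvas = int(rng.integers(8, 33))
            verts = random_simple_polygon(rng, canvas)
            ann = og.PolygonAnnotation([("p", verts)], canvas, canvas)
            mask = og.rasterize_polygons(ann)
            oracle = np.zeros((canvas, canvas), dtype=np.uint8)
            for r in range(canvas):
                for c in range(canvas):
                    oracle[r, c] = brute_force_point_in_polygon(float(c), float(r), verts)
            assert np.array_equal(mask, oracle)

    def test_labelme_roundtrip(self, tmp_path):
        ann = og.PolygonAnnotation([("organoid", [(1.5, 2.0), (5.0, 2.0), (3.0, 6.5)])], 10, 12)
        og.write_labelme(ann, tmp_path / "a.json")
        back = og.read_labelme(tmp_path / "a.json")
        assert back.image_height == 10 and back.image_width == 12
        assert back.shapes == ann.shapes


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32, 3), 128, np.uint8)
        assert np.array_equal(og.denoise_image(img), img)

    def test_reduces_noise_on_synthetic_disc(self):
        clean = og.generate_synthetic_scene(
            og.SyntheticSceneSpec(width=64, height=64, n_organoids=2,
                                  radius_range=(8, 12), noise_sigma=0, seed=4)
        ).image
        rng = np.random.default_rng(0)
        noisy = np.clip(clean.astype(float) + rng.normal(0, 20, clean.shape), 0, 255)
        noisy = noisy.astype(np.uint8)
        den = og.denoise_image(noisy, strength=15)
        mad_before = np.abs(noisy.astype(float) - clean).mean()
        mad_after = np.abs(den.astype(float) - clean).mean()
        assert mad_after < mad_before

    def test_zero_strength_is_identity(self):
        img = np.random.default_rng(1).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.abs(og.denoise_image(img, strength=0).astype(int) - img).max() <= 1

    @pytest.mark.parametrize("patch,search", [(6, 21), (7, 20), (21, 7)])
    def test_bad_windows_rejected(self, patch, search):
        with pytest.raises(ValueError):
            og.denoise_image(np.zeros((8, 8), np.uint8), patch_size=patch,
                             search_window=search)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


class TestAugmentation:
    def test_count_law(self):
        srcs = [
            og.generate_synthetic_scene(
                og.SyntheticSceneSpec(width=320, height=320, seed=i)
            )
            for i in range(3)
        ]
        cfg = og.AugmentationConfig(tile_size=256, tiles_per_image=5, seed=0)
        tiles = og.augment_dataset(srcs, cfg)
        assert len(tiles) == 15
        assert all(t.image.shape == (256, 256, 3) and t.mask.shape == (256, 256)
                   for t in tiles)

    def test_identity_augmentation(self):
        src = og.generate_synthetic_scene(og.SyntheticSceneSpec(width=256, height=256, seed=2))
        cfg = og.AugmentationConfig(tile_size=256, tiles_per_image=1, allow_hflip=False,
                                    allow_vflip=False, scale_range=(1, 1), seed=0)
        t = og.augment_dataset([src], cfg)[0]
        assert np.array_equal(t.image, src.image) and np.array_equal(t.mask, src.mask)

    def test_geometric_consistency_with_logged_transform(self):
        src = og.generate_synthetic_scene(og.SyntheticSceneSpec(width=320, height=300, seed=3))
        cfg = og.AugmentationConfig(tile_size=128, tiles_per_image=6, seed=11)
        for t in og.augment_dataset([src], cfg):
            _, mask_redo = apply_tile_transform(src.image, src.mask, t.meta["augment"])
            assert np.array_equal(t.mask, mask_redo)
            assert np.isin(t.mask, (0, 1)).all()

    def test_determinism(self):
        src = og.generate_synthetic_scene(og.SyntheticSceneSpec(width=320, height=320, seed=5))
        cfg = og.AugmentationConfig(tile_size=256, tiles_per_image=3, seed=21)
        a = og.augment_dataset([src], cfg)
        b = og.augment_dataset([src], cfg)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_too_small_source_rejected(self):
        src = og.AnnotatedImage(np.zeros((64, 64, 3), np.uint8), np.zeros((64, 64), np.uint8))
        with pytest.raises(ValueError, match="cannot yield"):
            og.augment_dataset([src], og.AugmentationConfig(tile_size=256, tiles_per_image=1))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _stub_samples(n_sources, tiles_each):
    img = np.zeros((1, 1, 3), np.uint8)
    msk = np.zeros((1, 1), np.uint8)
    return [
        og.AnnotatedImage(img, msk, {"source_id": f"s{i}", "culture_day": 1,
                                     "group_label": "CTR", "pixel_size_um": 1.0})
        for i in range(n_sources)
        for _ in range(tiles_each)
    ]


class TestSplit:
    def test_8_1_1_of_6400_gives_5120_640_640(self):
        samples = _stub_samples(200, 32)
        train, val, test = og.split_dataset(samples, og.SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (5120, 640, 640)

    def test_everything_in_train_when_ratio_1(self):
        samples = _stub_samples(10, 1)
        train, val, test = og.split_dataset(samples, og.SplitSpec(ratios=(1, 0, 0)))
        assert len(train) == 10 and not val and not test

    def test_partition_and_leakage_guard(self):
        samples = _stub_samples(25, 4)
        train, val, test = og.split_dataset(samples, og.SplitSpec(ratios=(0.6, 0.2, 0.2),
                                                                  seed=3))
        assert len(train) + len(val) + len(test) == 100
        ids = [set(s.meta["source_id"] for s in part) for part in (train, val, test)]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            og.split_dataset(_stub_samples(3, 1), og.SplitSpec(ratios=(0.5, 0.2, 0.2)))


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


class TestRasterIO:
    def test_mask_roundtrip(self, tmp_path):
        mask = (np.random.default_rng(0).random((37, 53)) > 0.5).astype(np.uint8)
        og.write_mask(tmp_path / "m.png", mask)
        assert np.array_equal(og.read_mask(tmp_path / "m.png"), mask)

    def test_image_shape_convention(self, tmp_path):
        img = np.random.default_rng(1).integers(0, 256, (30, 40, 3), dtype=np.uint8)
        og.write_image(tmp_path / "i.png", img)
        back = og.read_image(tmp_path / "i.png")
        assert back.shape == (30, 40, 3)
        assert np.array_equal(back, img)

    def test_tiff_roundtrip(self, tmp_path):
        img = np.random.default_rng(2).integers(0, 256, (20, 25, 3), dtype=np.uint8)
        og.write_image(tmp_path / "i.tiff", img)
        assert np.array_equal(og.read_image(tmp_path / "i.tiff"), img)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            og.read_image(tmp_path / "nope.png")
        with pytest.raises(FileNotFoundError):
            og.read_mask(tmp_path / "nope.png")

    def test_non_binary_mask_write_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            og.write_mask(tmp_path / "m.png", np.full((4, 4), 7))
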