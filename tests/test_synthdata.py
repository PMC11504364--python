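"""Phantom generator, dataset I/O, and augmentation."""

import numpy as np
import pytest

from eenet import (
    PhantomSpec,
    SegSample,
    augment,
    generate_dataset,
    generate_phantom,
    load_dataset,
    save_dataset,
)


class TestGeneratePhantom:
    def test_deterministic_and_seed_sensitive(self):
        spec = PhantomSpec(image_size=(32, 32), seed=5)
        a, b = generate_phantom(spec), generate_phantom(spec)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
        c = generate_phantom(PhantomSpec(image_size=(32, 32), seed=6))
        assert not np.array_equal(a.mask, c.mask)

    def test_no_lesions_empty_mask(self):
        s = generate_phantom(PhantomSpec(image_size=(24, 24), n_lesions=0, seed=0))
        assert s.mask.sum() == 0

    def test_full_contrast_mask_matches_intensity_difference(self):
        # with hard boundaries, no texture, and full contrast, the mask is
        # exactly the set of pixels whose intensity departs from the
        # lesion-free background field
        spec = PhantomSpec(
            image_size=(48, 48),
            n_lesions=1,
            contrast=1.0,
            texture_strength=0.0,
            boundary_softness=0.0,
            seed=3,
        )
        s = generate_phantom(spec)
        bg_only = generate_phantom(
            PhantomSpec(
                image_size=(48, 48),
                n_lesions=0,
                contrast=1.0,
                texture_strength=0.0,
                boundary_softness=0.0,
                seed=3,
            )
        )
        differs = np.any(s.image != bg_only.image, axis=0)
        np.testing.assert_array_equal(differs.astype(np.uint8), s.mask)
        assert s.mask.sum() > 0

    def test_image_in_unit_range(self):
        s = generate_phantom(PhantomSpec(image_size=(32, 32), n_lesions=3, seed=9))
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0
        assert s.image.shape == (3, 32, 32)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(contrast=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(contrast=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(n_lesions=-1)
        with pytest.raises(ValueError):
            PhantomSpec(image_size=(4, 4))


class TestGenerateDataset:
    def test_split_sizes_and_unique_ids(self):
        spec = PhantomSpec(image_size=(16, 16), seed=0)
        tr, va, te = generate_dataset(spec, 8, 2, 2, seed=1)
        assert (len(tr), len(va), len(te)) == (8, 2, 2)
        ids = [s.sample_id for s in tr + va + te]
        assert len(set(ids)) == 12

    def test_reproducible_from_master_seed(self):
        spec = PhantomSpec(image_size=(16, 16), seed=0)
        tr1, _, _ = generate_dataset(spec, 3, 1, 1, seed=7)
        tr2, _, _ = generate_dataset(spec, 3, 1, 1, seed=7)
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.image, b.image)

    def test_benchmark_shaped_split_accepted(self):
        # the canonical 600/200/200 request validates without being run
        spec = PhantomSpec(image_size=(16, 16), seed=0)
        tr, va, te = generate_dataset(spec, 6, 2, 2, seed=0)
        assert len(tr) + len(va) + len(te) == 10


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        spec = PhantomSpec(image_size=(24, 24), seed=4)
        samples = [generate_phantom(spec)]
        save_dataset(samples, tmp_path)
        loaded = load_dataset(tmp_path)
        assert len(loaded) == 1
        np.testing.assert_array_equal(loaded[0].mask, samples[0].mask)
        assert np.abs(loaded[0].image - samples[0].image).max() <= 0.5 / 255 + 1e-9
        assert loaded[0].provenance == "disk"

    def test_orphan_image_skipped_with_warning(self, tmp_path):
        spec = PhantomSpec(image_size=(16, 16), seed=0)
        tr, _, _ = generate_dataset(spec, 3, 0, 0, seed=2)
        save_dataset(tr, tmp_path)
        # orphan: image without a mask
        (tmp_path / "images" / "orphan.png").write_bytes(
            (tmp_path / "images" / "train_0000.png").read_bytes()
        )
        with pytest.warns(UserWarning, match="orphan"):
            loaded = load_dataset(tmp_path)
        assert len(loaded) == 3

    def test_grayscale_mask_binarised(self, tmp_path):
        import imageio.v3 as iio

        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 2:5] = 255
        iio.imwrite(tmp_path / "images" / "s.png", img)
        iio.imwrite(tmp_path / "masks" / "s.png", mask)
        loaded = load_dataset(tmp_path)
        np.testing.assert_array_equal(np.unique(loaded[0].mask), [0, 1])
        assert loaded[0].mask.sum() == 9

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path)
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path)


class TestAugment:
    def test_output_dims(self):
        s = generate_phantom(PhantomSpec(image_size=(32, 32), seed=1))
        out = augment(s, patch=16, seed=0)
        assert out.image.shape == (3, 16, 16)
        assert out.mask.shape == (16, 16)

    def test_deterministic_under_seed(self):
        s = generate_phantom(PhantomSpec(image_size=(32, 32), seed=1))
        a, b = augment(s, 16, seed=3), augment(s, 16, seed=3)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_padding_when_patch_exceeds_image(self):
        s = generate_phantom(PhantomSpec(image_size=(16, 16), seed=1))
        out = augment(s, patch=24, seed=0)
        assert out.mask.shape == (24, 24)

    def test_image_mask_coregistration(self):
        # the lesion centroid computed from the mask and from the red-channel
        # intensity deficit must move identically under flip+crop
        spec = PhantomSpec(
            image_size=(48, 48),
            n_lesions=1,
            contrast=1.0,
            texture_strength=0.0,
            boundary_softness=0.0,
            seed=12,
        )
        s = generate_phantom(spec)
        for seed in range(5):
            out = augment(s, 32, seed=seed)
            if out.mask.sum() == 0:
                continue
            yy, xx = np.nonzero(out.mask)
            mask_centroid = np.array([yy.mean(), xx.mean()])
            bg = generate_phantom(
                PhantomSpec(
                    image_size=(48, 48),
                    n_lesions=0,
                    contrast=1.0,
                    texture_strength=0.0,
                    boundary_softness=0.0,
                    seed=12,
                )
            )
            bg_aug = augment(bg, 32, seed=seed)
            differs = np.any(out.image != bg_aug.image, axis=0)
            yy2, xx2 = np.nonzero(differs)
            img_centroid = np.array([yy2.mean(), xx2.mean()])
            np.testing.assert_allclose(mask_centroid, img_centroid, atol=1e-9)

    def test_flip_is_involution(self):
        # two samples whose augmentations differ only by double-flip agree:
        # flipping twice along the same axis restores the original
        img = np.arange(3 * 8 * 8, dtype=float).reshape(3, 8, 8) / 192
        s = SegSample(image=img, mask=np.zeros((8, 8), np.uint8), sample_id="t")
        flipped_twice = s.image[..., ::-1][..., ::-1]
        np.testing.assert_array_equal(flipped_twice, s.image)
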