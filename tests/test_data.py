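"""Synthetic lesion generator, folder reader and augmentation."""

import warnings

import numpy as np
import pytest
from PIL import Image

from ultralight_vmunet import (SampleRecord, SyntheticSpec, augment,
                               generate_synthetic_dataset,
                               read_image_mask_folder)
from ultralight_vmunet.data import assign_splits, load_manifest, save_dataset


class TestGenerator:
    def test_identical_spec_gives_bitwise_identical_datasets(self):
        spec = SyntheticSpec(n_samples=10, size=64, seed=7)
        a = generate_synthetic_dataset(spec)
        b = generate_synthetic_dataset(spec)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.image, rb.image)
            np.testing.assert_array_equal(ra.mask, rb.mask)
            assert ra.id == rb.id

    def test_record_contract(self):
        rec = generate_synthetic_dataset(SyntheticSpec(n_samples=1, size=64))[0]
        assert rec.image.shape == (3, 64, 64)
        assert rec.mask.shape == (64, 64)
        assert rec.image.min() >= 0 and rec.image.max() <= 1
        assert set(np.unique(rec.mask)) <= {0, 1}

    def test_foreground_fraction_bounded_over_many_seeds(self):
        """Default axis fractions keep lesions non-empty and below 60% of
        the image, across 100 independent seeds."""
        for seed in range(100):
            rec = generate_synthetic_dataset(
                SyntheticSpec(n_samples=1, size=64, seed=seed))[0]
            frac = rec.mask.mean()
            assert 0.0 < frac < 0.6, f"seed {seed}: fraction {frac}"

    def test_lesions_darker_than_background(self):
        recs = generate_synthetic_dataset(SyntheticSpec(n_samples=20, size=64,
                                                        seed=11))
        for rec in recs:
            inside = rec.image[:, rec.mask == 1].mean()
            outside = rec.image[:, rec.mask == 0].mean()
            assert inside < outside

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_samples=0)
        with pytest.raises(ValueError):
            SyntheticSpec(n_samples=1, lesion_axis_fraction=(0.4, 0.6))


class TestAugment:
    def _record(self, seed=0, size=48):
        return generate_synthetic_dataset(
            SyntheticSpec(n_samples=1, size=size, seed=seed))[0]

    def test_deterministic_under_seed(self):
        rec = self._record()
        a, b = augment(rec, seed=5), augment(rec, seed=5)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_stays_binary_after_rotation(self):
        rec = self._record(seed=3)
        out = augment(rec, seed=9)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_double_horizontal_flip_is_identity(self):
        rec = self._record(seed=1)
        flipped = SampleRecord(image=rec.image[:, :, ::-1].copy(),
                               mask=rec.mask[:, ::-1].copy(), id=rec.id)
        restored = SampleRecord(image=flipped.image[:, :, ::-1].copy(),
                                mask=flipped.mask[:, ::-1].copy(), id=rec.id)
        np.testing.assert_array_equal(restored.image, rec.image)
        np.testing.assert_array_equal(restored.mask, rec.mask)

    def test_image_mask_alignment_preserved(self):
        """Rotation border effects change the foreground count by a bounded
        amount and the lesion stays dark in the augmented image."""
        rec = self._record(seed=4, size=64)
        out = augment(rec, seed=21)
        n0, n1 = rec.mask.sum(), out.mask.sum()
        assert abs(n1 - n0) / max(n0, 1) < 0.15
        if out.mask.any() and (~out.mask.astype(bool)).any():
            assert out.image[:, out.mask == 1].mean() < \
                out.image[:, out.mask == 0].mean()


class TestFolderIO:
    def _write_pairs(self, tmp_path, n_images=3, n_masks=3, size=32):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        rng = np.random.default_rng(0)
        for i in range(n_images):
            arr = rng.integers(0, 255, (size, size, 3), dtype=np.uint8)
            Image.fromarray(arr).save(tmp_path / "images" / f"case{i}.png")
        for i in range(n_masks):
            mask = (rng.random((size, size)) > 0.5).astype(np.uint8) * 255
            Image.fromarray(mask).save(tmp_path / "masks" / f"case{i}_segmentation.png")

    def test_matched_pairs_resized_and_binarised(self, tmp_path):
        self._write_pairs(tmp_path)
        records = read_image_mask_folder(tmp_path / "images", tmp_path / "masks",
                                         size=24)
        assert len(records) == 3
        for rec in records:
            assert rec.image.shape == (3, 24, 24)
            assert set(np.unique(rec.mask)) <= {0, 1}

    def test_orphans_reported_and_skipped(self, tmp_path):
        self._write_pairs(tmp_path, n_images=3, n_masks=2)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            records = read_image_mask_folder(tmp_path / "images",
                                             tmp_path / "masks")
        assert len(records) == 2
        assert any("case2" in str(w.message) for w in caught)

    def test_save_load_manifest_roundtrip(self, tmp_path):
        recs = generate_synthetic_dataset(SyntheticSpec(n_samples=4, size=32))
        splits = assign_splits(4, fractions=(0.5, 0.25, 0.25), seed=0)
        manifest = save_dataset(recs, tmp_path / "ds", splits=splits)
        loaded, loaded_splits = load_manifest(manifest, size=32)
        assert sorted(loaded_splits) == sorted(splits)
        for orig, back in zip(recs, loaded):
            assert back.image.shape == orig.image.shape
            np.testing.assert_array_equal(back.mask, orig.mask)
            # 8-bit PNG quantisation only
            assert np.abs(back.image - orig.image).max() <= 1 / 255 + 1e-6


def test_assign_splits_proportions():
    splits = assign_splits(100, seed=0)
    assert splits.count("train") == 70
    assert splits.count("val") == 10
    assert splits.count("test") == 20
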