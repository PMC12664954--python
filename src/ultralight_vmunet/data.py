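"""Synthetic dermoscopy-style fixtures and ISIC-style folder I/O.

The generator emulates the layout of dermoscopy lesion datasets: RGB images
with a smooth skin-toned background, multiplicative texture noise, and one
or two darker elliptical lesions with irregular boundaries and a radial
intensity gradient; the paired mask is the union of the lesion regions.
Identical specs produce bitwise-identical datasets.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["SyntheticSpec", "SampleRecord", "generate_synthetic_dataset",
           "read_image_mask_folder", "augment", "assign_splits",
           "save_dataset", "load_manifest"]

_MASK_SUFFIXES = ("_segmentation", "_mask", "-mask")


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of the synthetic lesion generator."""

    n_samples: int
    size: int = 256
    seed: int = 0
    lesion_count_range: tuple = (1, 2)
    lesion_axis_fraction: tuple = (0.10, 0.35)
    noise_sd: float = 0.04

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.size < 32:
            raise ValueError("size must be >= 32")
        lo, hi = self.lesion_axis_fraction
        if not (0 < lo <= hi < 0.5):
            raise ValueError("lesion_axis_fraction must satisfy 0 < lo <= hi < 0.5")
        lo_n, hi_n = self.lesion_count_range
        if not (1 <= lo_n <= hi_n):
            raise ValueError("lesion_count_range must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SampleRecord:
    """One image/mask pair: ``image`` is (3, S, S) float in [0, 1],
    ``mask`` is (S, S) in {0, 1}."""

    image: np.ndarray
    mask: np.ndarray
    id: str


def _lesion_region(rng, S: int, axis_fraction):
    """Boolean region and normalised radius map of one irregular ellipse."""
    lo, hi = axis_fraction
    cy, cx = rng.uniform(0.3 * S, 0.7 * S, size=2)
    a, b = rng.uniform(lo * S, hi * S, size=2)
    angle = rng.uniform(0, np.pi)
    # low-order radial harmonics give an irregular (non-elliptic) boundary
    n_modes = 4
    amps = rng.uniform(0, 0.10, size=n_modes) / np.arange(1, n_modes + 1)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)

    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    yr = (yy - cy) * np.cos(angle) - (xx - cx) * np.sin(angle)
    xr = (yy - cy) * np.sin(angle) + (xx - cx) * np.cos(angle)
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    phi = np.arctan2(yr / b, xr / a)
    wobble = 1.0 + sum(amp * np.cos((m + 2) * phi + ph)
                       for m, (amp, ph) in enumerate(zip(amps, phases)))
    region = rho <= wobble
    return region, np.clip(rho / np.maximum(wobble, 1e-9), 0, 1)


def _generate_sample(rng, spec: SyntheticSpec, sample_id: str) -> SampleRecord:
    S = spec.size
    base = np.array([0.75, 0.58, 0.48]) + rng.uniform(-0.06, 0.06, size=3)
    gy, gx = rng.uniform(-0.08, 0.08, size=2)
    yy, xx = np.mgrid[0:S, 0:S] / S
    background = base[:, None, None] * (1.0 + gy * (yy - 0.5) + gx * (xx - 0.5))
    texture = ndimage.gaussian_filter(rng.standard_normal((S, S)), sigma=2.0)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    image = background * (1.0 + spec.noise_sd * texture)

    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    axis_fraction = spec.lesion_axis_fraction
    for _ in range(10):  # shrink and redraw if lesions swamp the image
        mask = np.zeros((S, S), dtype=bool)
        factors = np.ones((S, S))
        for _ in range(n_lesions):
            region, rho = _lesion_region(rng, S, axis_fraction)
            depth = rng.uniform(0.45, 0.70)  # centre darkening factor
            lesion_factor = depth + (1.0 - depth) * rho ** 1.5
            factors = np.where(region, np.minimum(factors, lesion_factor), factors)
            mask |= region
        if 0 < mask.mean() < 0.55:
            break
        axis_fraction = (axis_fraction[0] * 0.8, axis_fraction[1] * 0.8)
    factors = ndimage.gaussian_filter(factors, sigma=1.0)  # soften edges
    image = np.clip(image * factors[None], 0.0, 1.0)
    return SampleRecord(image=image.astype(np.float32),
                        mask=mask.astype(np.uint8), id=sample_id)


def generate_synthetic_dataset(spec: SyntheticSpec) -> list:
    """Generate ``spec.n_samples`` image/mask pairs, deterministically."""
    records = []
    for i in range(spec.n_samples):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        records.append(_generate_sample(rng, spec, f"synth_{spec.seed}_{i:05d}"))
    return records


def augment(record: SampleRecord, seed: int, max_rotation: float = 30.0) -> SampleRecord:
    """Random horizontal/vertical flips (p = 0.5 each) and rotation by a
    uniform angle in +-``max_rotation`` degrees.  The identical geometric
    transform is applied to image and mask; the mask is resampled
    nearest-neighbour (stays binary) with edge reflection at the border."""
    rng = np.random.default_rng(seed)
    image, mask = record.image, record.mask
    if rng.random() < 0.5:
        image, mask = image[:, :, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        image, mask = image[:, ::-1, :], mask[::-1, :]
    angle = rng.uniform(-max_rotation, max_rotation)
    image = ndimage.rotate(image, angle, axes=(1, 2), reshape=False,
                           order=1, mode="reflect")
    mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False,
                          order=0, mode="reflect")
    return SampleRecord(image=np.ascontiguousarray(np.clip(image, 0, 1), dtype=np.float32),
                        mask=np.ascontiguousarray(mask, dtype=np.uint8),
                        id=record.id)


def _stem_key(stem: str) -> str:
    for suffix in _MASK_SUFFIXES:
        if stem.endswith(suffix):
            return stem[: -len(suffix)]
    return stem


def read_image_mask_folder(images_dir, masks_dir, size: int = 256) -> list:
    """Read paired RGB images and single-channel masks from two folders.

    Images are bilinearly resized to ``size`` x ``size``; masks are resized
    nearest-neighbour and binarised at 127/255.  Pairs are matched by file
    stem (mask suffixes like ``_segmentation``/``_mask`` are stripped);
    unmatched files are reported in a warning and skipped.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    images = {p.stem: p for p in sorted(images_dir.iterdir())
              if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
    masks = {_stem_key(p.stem): p for p in sorted(masks_dir.iterdir())
             if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
    shared = sorted(set(images) & set(masks))
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        warnings.warn(f"unpaired image/mask files skipped: {orphans}",
                      stacklevel=2)
    records = []
    for stem in shared:
        with Image.open(images[stem]) as im:
            img = im.convert("RGB").resize((size, size), Image.BILINEAR)
        with Image.open(masks[stem]) as mm:
            msk = mm.convert("L").resize((size, size), Image.NEAREST)
        image = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
        mask = (np.asarray(msk) > 127).astype(np.uint8)
        records.append(SampleRecord(image=image, mask=mask, id=stem))
    return records


def assign_splits(n: int, fractions=(0.7, 0.1, 0.2), seed: int = 0) -> list:
    """Random train/val/test assignment with fixed proportions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:n_train + n_val]] = "val"
    labels[order[n_train + n_val:]] = "test"
    return labels.tolist()


def save_dataset(records, out_dir, splits=None) -> Path:
    """Write records as 8-bit PNGs (``images/``, ``masks/``) plus a manifest
    CSV (id, image_path, mask_path, split)."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    if splits is None:
        splits = ["train"] * len(records)
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "mask_path", "split"])
        for rec, split in zip(records, splits):
            img_path = out_dir / "images" / f"{rec.id}.png"
            msk_path = out_dir / "masks" / f"{rec.id}.png"
            arr = (np.clip(rec.image, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr.transpose(1, 2, 0)).save(img_path)
            Image.fromarray((rec.mask * 255).astype(np.uint8)).save(msk_path)
            writer.writerow([rec.id, str(img_path.relative_to(out_dir)),
                             str(msk_path.relative_to(out_dir)), split])
    return manifest


def load_manifest(manifest_path, size: int = 256):
    """Load records listed in a manifest CSV; returns (records, splits)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    records, splits = [], []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            with Image.open(root / row["image_path"]) as im:
                img = im.convert("RGB").resize((size, size), Image.BILINEAR)
            with Image.open(root / row["mask_path"]) as mm:
                msk = mm.convert("L").resize((size, size), Image.NEAREST)
            records.append(SampleRecord(
                image=np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0,
                mask=(np.asarray(msk) > 127).astype(np.uint8), id=row["id"]))
            splits.append(row["split"])
    return records, splits
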