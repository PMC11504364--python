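"""Synthetic low-contrast polyp phantoms, dataset I/O, and augmentation.

Colonoscopy lesions are hard to segment chiefly because the lesion/mucosa
intensity gap is small and the boundary is soft.  The phantom generator
reproduces exactly those properties with fully known ground truth: a smooth
low-frequency "mucosa" background field (a sum of random sinusoids) with
optional speckle texture, on which each lesion is a randomly placed, rotated
ellipse rendered at ``background +/- contrast`` with a Gaussian-blurred rim.
The binary mask is the union of the *unblurred* ellipse interiors.  All
randomness flows from the integer seed in the spec, so a sample is
bit-reproducible across runs and platforms.

Datasets on disk follow the common paired-raster layout used by the public
polyp benchmarks: ``images/*.png`` and ``masks/*.png`` with matching file
stems.  Augmentation is the standard random flip + random square crop, applied
identically to image and mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .tensor import reflect_indices

__all__ = [
    "SegSample",
    "PhantomSpec",
    "generate_phantom",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "augment",
]

# intensity band the background field is normalised into; keeps lesions
# representable at any contrast in (0, 1] after clipping
_BG_LO, _BG_HI = 0.35, 0.65
# per-channel weights of the lesion intensity offset (mucosa is reddish, so
# the contrast is strongest in the red channel)
_CHANNEL_WEIGHTS = (1.0, 0.85, 0.75)
_SPECKLE_STD = 0.04


@dataclass
class SegSample:
    """One image/mask pair with provenance."""

    image: np.ndarray  # (3, H, W) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    sample_id: str
    provenance: str = "synthetic"  # "synthetic" or "disk"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be (3, H, W), got {self.image.shape}")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("mask extent must match the image")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask must be binary")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom."""

    image_size: Tuple[int, int] = (256, 256)
    n_lesions: int = 1
    contrast: float = 0.4
    texture_strength: float = 1.0
    boundary_softness: float = 1.5
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size must be at least 8x8")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if self.texture_strength < 0:
            raise ValueError("texture_strength must be >= 0")
        if self.boundary_softness < 0:
            raise ValueError("boundary_softness must be >= 0")


def _background(rng: np.random.Generator, h: int, w: int, texture_strength: float) -> np.ndarray:
    """Smooth low-frequency field in [_BG_LO, _BG_HI] plus speckle."""
    yy, xx = np.meshgrid(np.arange(h) / h, np.arange(w) / w, indexing="ij")
    fld = np.zeros((h, w))
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        fld += amp * np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
    lo, hi = fld.min(), fld.max()
    if hi - lo < 1e-12:
        fld = np.full((h, w), 0.5 * (_BG_LO + _BG_HI))
    else:
        fld = _BG_LO + (_BG_HI - _BG_LO) * (fld - lo) / (hi - lo)
    if texture_strength > 0:
        fld = fld + rng.normal(0.0, _SPECKLE_STD * texture_strength, size=(h, w))
    return fld


def _draw_ellipse(rng: np.random.Generator, h: int, w: int) -> Optional[np.ndarray]:
    """Random rotated ellipse interior fully inside the frame, or None."""
    smin = min(h, w)
    for _ in range(50):
        a = rng.uniform(0.05, 0.25) * smin
        b = rng.uniform(0.05, 0.25) * smin
        theta = rng.uniform(0, np.pi)
        r = max(a, b)
        if 2 * r + 2 >= smin:
            continue
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        yy, xx = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
        u = (xx * np.cos(theta) + yy * np.sin(theta)) / a
        v = (-xx * np.sin(theta) + yy * np.cos(theta)) / b
        return (u * u + v * v) <= 1.0
    return None


def generate_phantom(spec: PhantomSpec) -> SegSample:
    """Render one phantom; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    bg = _background(rng, h, w, spec.texture_strength)

    delta = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_lesions):
        interior = _draw_ellipse(rng, h, w)
        if interior is None:
            warnings.warn("lesion could not be placed inside the frame; skipped")
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        soft = interior.astype(float)
        if spec.boundary_softness > 0:
            soft = gaussian_filter(soft, spec.boundary_softness)
        delta = delta + sign * spec.contrast * soft
        mask |= interior

    image = np.stack([np.clip(bg + cw * delta, 0.0, 1.0) for cw in _CHANNEL_WEIGHTS])
    return SegSample(
        image=image,
        mask=mask.astype(np.uint8),
        sample_id=f"phantom_{spec.seed:08d}",
        provenance="synthetic",
    )


def generate_dataset(
    spec: PhantomSpec,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int = 0,
) -> Tuple[List[SegSample], List[SegSample], List[SegSample]]:
    """Disjoint seeded train/val/test splits of phantoms shaped like ``spec``.

    Every sample gets its own seed drawn from a master generator, so split
    membership and each sample's content are reproducible from ``seed``.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be >= 0")
    master = np.random.default_rng(seed)
    splits = []
    for split_name, count in (("train", n_train), ("val", n_val), ("test", n_test)):
        samples = []
        for i in range(count):
            sub_seed = int(master.integers(0, 2**31 - 1))
            sample_spec = PhantomSpec(
                image_size=spec.image_size,
                n_lesions=spec.n_lesions,
                contrast=spec.contrast,
                texture_strength=spec.texture_strength,
                boundary_softness=spec.boundary_softness,
                seed=sub_seed,
            )
            s = generate_phantom(sample_spec)
            s.sample_id = f"{split_name}_{i:04d}"
            samples.append(s)
        splits.append(samples)
    return splits[0], splits[1], splits[2]


def save_dataset(samples: Sequence[SegSample], root_dir) -> None:
    """Write samples as 8-bit PNG pairs under images/ and masks/."""
    root = Path(root_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(root / "images" / f"{s.sample_id}.png", img8.transpose(1, 2, 0))
        iio.imwrite(root / "masks" / f"{s.sample_id}.png", (s.mask * 255).astype(np.uint8))


def load_dataset(root_dir) -> List[SegSample]:
    """Load image/mask PNG (or JPEG) pairs with matching stems.

    Images are scaled to [0, 1]; masks are binarised at half their maximum.
    Stems are matched case-insensitively and samples are returned sorted by
    stem.  Images without a mask are skipped with a warning.
    """
    root = Path(root_dir)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{root} must contain images/ and masks/ directories")
    exts = {".png", ".jpg", ".jpeg"}
    images = {p.stem.lower(): p for p in sorted(img_dir.iterdir()) if p.suffix.lower() in exts}
    masks = {p.stem.lower(): p for p in sorted(mask_dir.iterdir()) if p.suffix.lower() in exts}
    if not images:
        raise FileNotFoundError(f"no images found under {img_dir}")
    samples = []
    for stem in sorted(images):
        if stem not in masks:
            warnings.warn(f"no mask for image {images[stem].name}; sample skipped")
            continue
        img = np.asarray(iio.imread(images[stem]), dtype=float)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3].transpose(2, 0, 1) / 255.0
        m = np.asarray(iio.imread(masks[stem]), dtype=float)
        if m.ndim == 3:
            m = m[..., 0]
        thresh = m.max() / 2.0 if m.max() > 0 else 0.5
        samples.append(
            SegSample(
                image=img,
                mask=(m > thresh).astype(np.uint8),
                sample_id=stem,
                provenance="disk",
            )
        )
    return samples


def _reflect_pad_to(arr: np.ndarray, min_h: int, min_w: int) -> np.ndarray:
    h, w = arr.shape[-2:]
    ph, pw = max(0, min_h - h), max(0, min_w - w)
    if ph == 0 and pw == 0:
        return arr
    hh = reflect_indices(h, ph)[ph:]  # trailing-side mirror pad
    ww = reflect_indices(w, pw)[pw:]
    return arr[..., hh, :][..., :, ww]


def augment(sample: SegSample, patch: int, seed: int = 0) -> SegSample:
    """Random horizontal/vertical flip (p = 0.5 each) + random patch crop.

    Image and mask receive identical transforms; samples smaller than the
    patch are mirror-padded first.  Deterministic given ``seed``.
    """
    if patch < 1:
        raise ValueError("patch must be positive")
    rng = np.random.default_rng(seed)
    img = _reflect_pad_to(sample.image, patch, patch)
    mask = _reflect_pad_to(sample.mask, patch, patch)
    if rng.random() < 0.5:  # horizontal flip
        img, mask = img[..., ::-1], mask[..., ::-1]
    if rng.random() < 0.5:  # vertical flip
        img, mask = img[..., ::-1, :], mask[::-1, :]
    h, w = mask.shape
    top = int(rng.integers(0, h - patch + 1))
    left = int(rng.integers(0, w - patch + 1))
    return SegSample(
        image=np.ascontiguousarray(img[:, top : top + patch, left : left + patch]),
        mask=np.ascontiguousarray(mask[top : top + patch, left : left + patch]),
        sample_id=sample.sample_id,
        provenance=sample.provenance,
    )
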