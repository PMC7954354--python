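"""Image/mask pair loading, resizing, augmentation, and dataset layout.

A dataset directory is ``images/*.png`` + ``masks/*.png`` with matching
stems and a ``manifest.csv`` (id, image, mask, split).  Images are min-max
scaled to [0, 1]; masks map 0 -> 0 and anything positive -> 1.

The augmentation set is the four geometric ops rotation (uniform +-15
degrees), translation (uniform +-10% per axis), flip (up-down) and mirror
(left-right).  Image and mask receive the identical transform; the mask is
warped with nearest-neighbour interpolation so it stays binary, and
out-of-canvas regions are zero-filled (background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ShapeError

__all__ = ["ImageMaskPair", "load_pair", "resize_pair", "augment",
           "apply_transform", "save_dataset", "load_dataset", "AUGMENT_OPS",
           "ROTATION_RANGE_DEG", "TRANSLATION_RANGE_FRAC"]

AUGMENT_OPS = ("rotation", "flip", "translation", "mirror")
ROTATION_RANGE_DEG = 15.0
TRANSLATION_RANGE_FRAC = 0.10


@dataclass
class ImageMaskPair:
    """One grayscale image in [0, 1] with its binary ground-truth mask."""

    image: np.ndarray
    mask: np.ndarray
    identifier: str = ""
    provenance: str = "synthetic"
    transform: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ShapeError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _scale_01(arr: np.ndarray) -> np.ndarray:
    arr = arr.astype(np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:  # constant image: all zeros by convention
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def load_pair(image_path, mask_path) -> ImageMaskPair:
    """Read a grayscale raster pair (PNG/TIFF/JPEG, 8- or 16-bit)."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        img = np.asarray(Image.open(image_path)).astype(np.float32)
    except Exception as exc:
        raise IOError(f"cannot read image {image_path}: {exc}") from exc
    try:
        msk = np.asarray(Image.open(mask_path))
    except Exception as exc:
        raise IOError(f"cannot read mask {mask_path}: {exc}") from exc
    if img.ndim == 3:
        img = img.mean(axis=2)
    if msk.ndim == 3:
        msk = msk.mean(axis=2)
    if img.shape != msk.shape:
        raise ShapeError(
            f"image {image_path.name} {img.shape} does not match mask "
            f"{mask_path.name} {msk.shape}")
    return ImageMaskPair(_scale_01(img), (msk > 0).astype(np.uint8),
                         identifier=image_path.stem, provenance="file")


def resize_pair(pair: ImageMaskPair, size=(512, 512)) -> ImageMaskPair:
    """Bilinear for the image, nearest-neighbour for the mask (stays binary)."""
    h, w = size
    if h < 1 or w < 1:
        raise ValueError("target size must be positive")
    if pair.image.shape == (h, w):
        return replace(pair)
    img = _sk_resize(pair.image, (h, w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(pair.mask, (h, w), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return ImageMaskPair(np.clip(img, 0, 1).astype(np.float32),
                         msk.astype(np.uint8),
                         identifier=pair.identifier, provenance=pair.provenance)


def apply_transform(arr: np.ndarray, transform: dict,
                    is_mask: bool) -> np.ndarray:
    """Apply a recorded geometric transform; masks use order-0 warping."""
    op = transform["op"]
    order = 0 if is_mask else 1
    a = arr.astype(np.float32)
    if op == "rotation":
        out = ndimage.rotate(a, transform["angle_deg"], reshape=False,
                             order=order, mode="constant", cval=0.0)
    elif op == "translation":
        out = ndimage.shift(a, (transform["dy"], transform["dx"]),
                            order=order, mode="constant", cval=0.0)
    elif op == "flip":
        out = np.flipud(a)
    elif op == "mirror":
        out = np.fliplr(a)
    else:
        raise ValueError(f"unknown augmentation op {op!r}; "
                         f"valid ops: {AUGMENT_OPS}")
    if is_mask:
        return (out > 0.5).astype(np.uint8)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def augment(pair: ImageMaskPair, ops=AUGMENT_OPS, seed: int = 0) -> list[ImageMaskPair]:
    """One augmented copy per op, parameters drawn from the seeded generator.

    The applied transform is recorded on each emitted pair so that
    re-applying it to the parent mask reproduces the emitted mask exactly.
    """
    unknown = set(ops) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops {sorted(unknown)}; "
                         f"valid ops: {AUGMENT_OPS}")
    rng = np.random.default_rng(seed)
    h, w = pair.image.shape
    out = []
    for op in ops:
        transform = {"op": op}
        if op == "rotation":
            transform["angle_deg"] = float(
                rng.uniform(-ROTATION_RANGE_DEG, ROTATION_RANGE_DEG))
        elif op == "translation":
            transform["dy"] = float(rng.uniform(-TRANSLATION_RANGE_FRAC,
                                                TRANSLATION_RANGE_FRAC) * h)
            transform["dx"] = float(rng.uniform(-TRANSLATION_RANGE_FRAC,
                                                TRANSLATION_RANGE_FRAC) * w)
        out.append(ImageMaskPair(
            apply_transform(pair.image, transform, is_mask=False),
            apply_transform(pair.mask, transform, is_mask=True),
            identifier=f"{pair.identifier}_{op}",
            provenance=f"augmented({pair.identifier}|{op})",
            transform=transform,
        ))
    return out


# ---------------------------------------------------------------------------
# directory layout
# ---------------------------------------------------------------------------

def save_dataset(pairs, out_dir, splits=None) -> pd.DataFrame:
    """Write ``images/``, ``masks/`` (8-bit PNG) and ``manifest.csv``."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pair in enumerate(pairs):
        stem = pair.identifier or f"sample_{i:04d}"
        img8 = np.round(np.clip(pair.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img8).save(out_dir / "images" / f"{stem}.png")
        Image.fromarray(pair.mask * 255).save(out_dir / "masks" / f"{stem}.png")
        rows.append({"id": stem,
                     "image": f"images/{stem}.png",
                     "mask": f"masks/{stem}.png",
                     "split": splits[i] if splits is not None else ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(root) -> list[ImageMaskPair]:
    """Read a dataset directory back (manifest-driven if present)."""
    root = Path(root)
    manifest_path = root / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path, keep_default_na=False)
        entries = [(root / r["image"], root / r["mask"])
                   for _, r in manifest.iterrows()]
    else:
        entries = [(p, root / "masks" / p.name)
                   for p in sorted((root / "images").glob("*.png"))]
    if not entries:
        raise FileNotFoundError(f"no image/mask pairs under {root}")
    return [load_pair(img, msk) for img, msk in entries]
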