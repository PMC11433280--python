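"""Dataset curation, patch preparation and manifest handling.

Implements the annotation-driven curation rules used to turn per-reader
nodule annotations into a benign/malignant dataset:

* each reader rates malignancy 1-5; the per-nodule aggregate is the
  median score.  Aggregate <= 2 is benign, >= 4 malignant, anything in
  between is excluded as indeterminate;
* nodules with illegible identifiers, diameter < 3 mm or > 25 mm, or
  delineated by fewer than two thirds of the readers are excluded;
* pixel-level ground truth is the majority vote (>= 50 % of readers) over
  the reader masks.

Patches are cropped to 64 x 64 around the nodule centroid (zero-padded at
borders), augmented 9x by random center-crop (50-100 %), 110 % zoom,
horizontal and vertical flips, and resampled to 224 x 224 (bilinear for
images, nearest-neighbour for masks so they stay binary).  The manifest
is split 6:2:2 into train/val/test, stratified by class, with all
augmented copies of a source image kept in the same split.

File contracts: images are 8-bit 3-channel PNG; masks are 8-bit
single-channel PNG with {0, 255} mapped to {0, 1}; the manifest is a CSV
with header ``image_path,mask_path,label,source_id,split``; annotation
tables are CSV with header
``nodule_id,reader_scores,diameter_mm,reader_mask_count,id_legible``
(scores semicolon-separated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "NoduleAnnotation", "AugmentationSpec",
    "label_nodule", "consensus_mask", "crop_patch", "augment", "resample",
    "split_manifest", "read_annotations", "read_manifest", "write_manifest",
    "load_image", "load_mask", "save_image", "save_mask", "load_split_arrays",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["image_path", "mask_path", "label", "source_id", "split"]
LABELS = ("benign", "malignant")
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class NoduleAnnotation:
    """Per-nodule reader annotations feeding the curation rules."""

    nodule_id: str
    reader_scores: tuple[int, ...]
    diameter_mm: float
    reader_mask_count: int
    id_legible: bool = True

    def __post_init__(self):
        if len(self.reader_scores) == 0:
            raise ValueError(f"nodule {self.nodule_id}: no reader scores")
        if any(not 1 <= s <= 5 for s in self.reader_scores):
            raise ValueError(f"nodule {self.nodule_id}: scores must be 1..5")
        if self.diameter_mm <= 0:
            raise ValueError(f"nodule {self.nodule_id}: diameter must be > 0")


@dataclass(frozen=True)
class AugmentationSpec:
    crop_fraction_range: tuple[float, float] = (0.5, 1.0)
    zoom_factor: float = 1.10
    flips: tuple[str, ...] = ("horizontal", "vertical")
    copies: int = 9
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.crop_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("crop fractions must lie in (0, 1]")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


# ---------------------------------------------------------------------------
# curation rules
# ---------------------------------------------------------------------------

def label_nodule(ann: NoduleAnnotation, *, min_diameter_mm: float = 3.0,
                 max_diameter_mm: float = 25.0,
                 consensus_fraction: float = 2.0 / 3.0) -> str:
    """Map one annotation to 'benign', 'malignant' or 'excluded'.

    The reader scores are aggregated by their median; <= 2 is benign,
    >= 4 malignant, the indeterminate middle band (around score 3) is
    excluded.  Size, legibility and delineation-consensus exclusions are
    applied first.  Thresholds are exposed because consensus conventions
    vary between curation efforts.
    """
    if not ann.id_legible:
        return "excluded"
    if ann.diameter_mm < min_diameter_mm or ann.diameter_mm > max_diameter_mm:
        return "excluded"
    n_readers = len(ann.reader_scores)
    if ann.reader_mask_count < math.ceil(consensus_fraction * n_readers):
        return "excluded"
    aggregate = float(np.median(ann.reader_scores))
    if aggregate <= 2.0:
        return "benign"
    if aggregate >= 4.0:
        return "malignant"
    return "excluded"


def consensus_mask(reader_masks: list[np.ndarray],
                   vote_fraction: float = 0.5) -> np.ndarray:
    """Pixelwise majority vote over reader masks (>= 50 % by default)."""
    if len(reader_masks) == 0:
        raise ValueError("need at least one reader mask")
    masks = [np.asarray(m) for m in reader_masks]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("reader masks differ in shape")
    votes = np.sum([m > 0 for m in masks], axis=0)
    return (votes >= vote_fraction * len(masks)).astype(np.uint8)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def crop_patch(image: np.ndarray, mask: np.ndarray,
               center: tuple[int, int], size: int = 64
               ) -> tuple[np.ndarray, np.ndarray]:
    """Crop a ``size`` x ``size`` window centred on ``center`` (row, col).

    Windows extending past the image border are zero-padded, keeping the
    requested centre at the patch centre.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image/mask shape mismatch")
    r, c = int(round(center[0])), int(round(center[1]))
    h, w = image.shape[:2]
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("center lies outside the image")
    half = size // 2
    r0, c0 = r - half, c - half
    out_img = np.zeros((size, size) + image.shape[2:], dtype=image.dtype)
    out_msk = np.zeros((size, size), dtype=mask.dtype)
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + size, h), min(c0 + size, w)
    out_img[rs - r0:re - r0, cs - c0:ce - c0] = image[rs:re, cs:ce]
    out_msk[rs - r0:re - r0, cs - c0:ce - c0] = mask[rs:re, cs:ce]
    return out_img, out_msk


def _resize_pair(image: np.ndarray, mask: np.ndarray, size: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    img = _sk_resize(image.astype(np.float32), (size, size),
                     order=1, preserve_range=True, anti_aliasing=False)
    msk = _sk_resize(mask, (size, size), order=0, preserve_range=True,
                     anti_aliasing=False).astype(mask.dtype)
    return img.astype(np.float32), msk


def _center_crop(image: np.ndarray, mask: np.ndarray, crop: int):
    h, w = mask.shape
    r0 = (h - crop) // 2
    c0 = (w - crop) // 2
    return image[r0:r0 + crop, c0:c0 + crop], mask[r0:r0 + crop, c0:c0 + crop]


def augment(patch: np.ndarray, mask_patch: np.ndarray,
            spec: AugmentationSpec = AugmentationSpec()
            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Produce ``spec.copies`` augmented (image, mask) pairs.

    Each copy applies one transform drawn uniformly from: random
    centre-crop at a fraction in ``crop_fraction_range`` (resized back),
    110 % zoom (upscale then centre-crop), horizontal flip, vertical
    flip.  The identical geometric transform is applied to image and
    mask; reproducible under ``spec.seed``.
    """
    patch = np.asarray(patch)
    mask_patch = np.asarray(mask_patch)
    if patch.shape[:2] != mask_patch.shape[:2]:
        raise ValueError("patch/mask shape mismatch")
    size = mask_patch.shape[0]
    rng = np.random.default_rng(spec.seed)
    families = ["crop", "zoom"] + list(spec.flips)
    out = []
    for _ in range(spec.copies):
        family = families[rng.integers(len(families))]
        if family == "crop":
            lo, hi = spec.crop_fraction_range
            frac = rng.uniform(lo, hi)
            crop = max(1, int(round(frac * size)))
            img, msk = _center_crop(patch, mask_patch, crop)
            img, msk = _resize_pair(img, msk, size)
        elif family == "zoom":
            big = int(round(spec.zoom_factor * size))
            img, msk = _resize_pair(patch, mask_patch, big)
            img, msk = _center_crop(img, msk, size)
        elif family == "horizontal":
            img, msk = patch[:, ::-1].copy(), mask_patch[:, ::-1].copy()
        elif family == "vertical":
            img, msk = patch[::-1].copy(), mask_patch[::-1].copy()
        else:
            raise ValueError(f"unknown flip family {family!r}")
        out.append((img, msk))
    return out


def resample(patch: np.ndarray, mask_patch: np.ndarray, size: int = 224
             ) -> tuple[np.ndarray, np.ndarray]:
    """Resample a square patch pair: bilinear image, nearest-neighbour mask."""
    if mask_patch.shape[0] != mask_patch.shape[1]:
        raise ValueError("expected a square patch")
    return _resize_pair(patch, mask_patch, size)


# ---------------------------------------------------------------------------
# manifest handling
# ---------------------------------------------------------------------------

def _allocate(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items to len(ratios) buckets."""
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    counts = [int(math.floor(e)) for e in exact]
    rema = sorted(range(len(ratios)), key=lambda i: exact[i] - counts[i],
                  reverse=True)
    for i in range(n - sum(counts)):
        counts[rema[i % len(ratios)]] += 1
    return counts


def split_manifest(manifest: pd.DataFrame, ratios: tuple[float, ...] = (6, 2, 2),
                   seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test splits, stratified by class label.

    Splitting operates on unique ``source_id`` values so every augmented
    copy of a source image lands in the same split (leakage guard).
    Split sizes per class are within one item of the exact fractions.
    """
    if len(ratios) != len(SPLITS) or any(r <= 0 for r in ratios):
        raise ValueError("need three positive ratios")
    manifest = manifest.copy()
    sources = manifest[["source_id", "label"]].drop_duplicates("source_id")
    if len(sources) < len(SPLITS):
        raise ValueError("fewer source images than splits")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label, group in sources.groupby("label", sort=True):
        ids = group["source_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        counts = _allocate(len(ids), tuple(ratios))
        start = 0
        for split_name, cnt in zip(SPLITS, counts):
            for sid in ids[start:start + cnt]:
                assignment[sid] = split_name
            start += cnt
    manifest["split"] = manifest["source_id"].map(assignment)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"source_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels in manifest: {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    cols = [c for c in MANIFEST_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)


def read_annotations(path) -> list[NoduleAnnotation]:
    df = pd.read_csv(path, dtype={"nodule_id": str})
    anns = []
    for row in df.itertuples(index=False):
        scores = tuple(int(s) for s in str(row.reader_scores).split(";"))
        anns.append(NoduleAnnotation(
            nodule_id=row.nodule_id, reader_scores=scores,
            diameter_mm=float(row.diameter_mm),
            reader_mask_count=int(row.reader_mask_count),
            id_legible=bool(row.id_legible)))
    return anns


# ---------------------------------------------------------------------------
# PNG I/O  (images: 3-channel uint8; masks: single-channel {0,255})
# ---------------------------------------------------------------------------

def save_image(path, image: np.ndarray) -> None:
    """Save a float image in [0,1] (H,W,3) or (3,H,W) as 8-bit RGB PNG."""
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[0] == 3:
        img = np.moveaxis(img, 0, -1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected 3-channel image, got {img.shape}")
    arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    """Load an RGB PNG as float32 (3, H, W) in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return np.moveaxis(arr, -1, 0)


def save_mask(path, mask: np.ndarray) -> None:
    """Save a {0,1} (binary) or [0,1] (probability) map as 8-bit gray PNG."""
    m = np.asarray(mask, dtype=np.float32)
    if m.ndim == 3 and m.shape[0] == 1:
        m = m[0]
    if m.ndim != 2:
        raise ValueError(f"expected single-channel mask, got {m.shape}")
    Image.fromarray(np.clip(np.round(m * 255.0), 0, 255).astype(np.uint8),
                    mode="L").save(path)


def load_mask(path, binary: bool = True) -> np.ndarray:
    """Load a gray PNG; ``binary=True`` maps {0,255} to {0,1} (threshold 128)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    if binary:
        return (arr >= 128).astype(np.uint8)
    return arr.astype(np.float32) / 255.0


def load_split_arrays(manifest: pd.DataFrame, split: str, root=None,
                      mask_column: str = "mask_path", binary_masks: bool = True
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Materialise one split as arrays.

    Returns ``(images (N,3,H,W) float32, masks (N,H,W), labels (N,) uint8)``
    with benign = 0, malignant = 1.
    """
    rows = manifest[manifest["split"] == split]
    if len(rows) == 0:
        raise ValueError(f"split {split!r} is empty")
    root = Path(root) if root is not None else Path(".")
    images, masks, labels = [], [], []
    for row in rows.itertuples(index=False):
        images.append(load_image(root / row.image_path))
        masks.append(load_mask(root / getattr(row, mask_column),
                               binary=binary_masks))
        labels.append(1 if row.label == "malignant" else 0)
    return (np.stack(images), np.stack(masks),
            np.asarray(labels, dtype=np.uint8))
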