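"""Synthetic CT-like nodule patches for desk-scale training and testing.

Emulates the two visual features the cascade must learn from real chest-CT
patches: a bright nodule on a noisy parenchyma-like background with a
fuzzy boundary, and the radiological distinction between *smooth* (benign-
like) and *spiculated* (malignant-like) margins.  Benign nodules are
low-eccentricity ellipses; malignant nodules are star-shaped regions

    r(theta) = r0 * (1 + a * max(0, sin(m * theta + phi)))

with spiculation amplitude ``a`` and ``m`` lobes.  The mask is the exact
generating region; the image is the mask times a random intensity,
Gaussian-blurred (boundary fuzziness), plus Gaussian background noise,
replicated to three channels and clipped to [0, 1].  Intensity ranges of
the two classes overlap fully, so brightness alone cannot solve the
classification task — boundary shape can.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import datapipe

__all__ = ["SynthConfig", "make_sample", "generate_dataset", "compactness"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults give 300 balanced 64 x 64 patches whose two classes are
    separated by boundary smoothness (standardised mean difference of the
    compactness statistic well above 2) but not by brightness.
    """

    n_per_class: int = 150
    image_size: int = 64
    background_level: float = 0.25
    background_noise_sd: float = 0.08
    blob_intensity_range: tuple[float, float] = (0.45, 0.75)
    benign_radius_px: tuple[float, float] = (6.0, 14.0)
    malignant_radius_px: tuple[float, float] = (6.0, 14.0)
    benign_axis_ratio_max: float = 1.25
    spiculation_amplitude: float = 0.5
    spiculation_lobes: int = 9
    blur_sd: float = 1.0
    center_jitter_px: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 <= self.spiculation_amplitude < 1:
            raise ValueError("spiculation amplitude must be in [0, 1)")
        rmax = max(self.benign_radius_px[1], self.malignant_radius_px[1])
        if rmax * (1 + self.spiculation_amplitude) + self.center_jitter_px \
                >= self.image_size / 2:
            raise ValueError("radii too large for the image size")


def make_sample(config: SynthConfig, class_label: str,
                rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray, str]:
    """One (image (3,H,W) float32, mask (H,W) uint8, label) triple."""
    if class_label not in ("benign", "malignant"):
        raise ValueError(f"unknown class {class_label!r}")
    s = config.image_size
    cy, cx = (s - 1) / 2.0 + rng.uniform(-config.center_jitter_px,
                                         config.center_jitter_px, size=2)
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    phi = rng.uniform(0, 2 * np.pi)
    if class_label == "benign":
        r0 = rng.uniform(*config.benign_radius_px)
        ratio = rng.uniform(1.0, config.benign_axis_ratio_max)
        ca, sa = np.cos(phi), np.sin(phi)
        u = (dx * ca + dy * sa) / (r0 * ratio)
        v = (-dx * sa + dy * ca) / r0
        mask = (u * u + v * v) <= 1.0
    else:
        r0 = rng.uniform(*config.malignant_radius_px)
        a, m = config.spiculation_amplitude, config.spiculation_lobes
        boundary = r0 * (1.0 + a * np.maximum(0.0, np.sin(m * theta + phi)))
        mask = rr <= boundary
    mask = mask.astype(np.uint8)
    intensity = rng.uniform(*config.blob_intensity_range)
    fg = gaussian_filter(mask.astype(np.float32) * intensity, config.blur_sd)
    img = fg + config.background_level \
        + rng.normal(0.0, config.background_noise_sd, size=(s, s))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return np.repeat(img[None], 3, axis=0), mask, class_label


def compactness(mask: np.ndarray) -> float:
    """Isoperimetric shape statistic ``4*pi*area / perimeter**2``.

    1 for a perfect disc, smaller for spiculated shapes.
    """
    from skimage.measure import perimeter as _perimeter
    area = float(np.sum(mask > 0))
    per = float(_perimeter(mask > 0, neighborhood=8))
    if per == 0:
        raise ValueError("empty mask has no perimeter")
    return 4.0 * np.pi * area / per ** 2


def generate_dataset(config: SynthConfig, out_dir,
                     split_ratios: tuple[float, ...] = (6, 2, 2)
                     ) -> pd.DataFrame:
    """Write ``2 * n_per_class`` PNG pairs plus a split manifest CSV.

    Layout: ``out_dir/images/<id>.png``, ``out_dir/masks/<id>.png`` and
    ``out_dir/manifest.csv`` with relative paths.  Per-sample generators
    are derived arithmetically from ``config.seed`` so the dataset is
    platform-reproducible.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    idx = 0
    for label in ("benign", "malignant"):
        for i in range(config.n_per_class):
            rng = np.random.default_rng(config.seed * 1_000_003 + idx)
            img, mask, _ = make_sample(config, label, rng)
            sid = f"{label}_{i:05d}"
            img_rel = f"images/{sid}.png"
            msk_rel = f"masks/{sid}.png"
            datapipe.save_image(out_dir / img_rel, img)
            datapipe.save_mask(out_dir / msk_rel, mask)
            rows.append({"image_path": img_rel, "mask_path": msk_rel,
                         "label": label, "source_id": sid, "split": ""})
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest = datapipe.split_manifest(manifest, ratios=split_ratios,
                                       seed=config.seed)
    datapipe.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
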