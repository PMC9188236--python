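"""Image preprocessing and data augmentation.

Preprocessing converts colour micrographs to grayscale and applies histogram
stretching with a small saturation tolerance.  Augmentation enlarges the
dataset by tiling each image into halves or quadrants, and optionally (OGRN
regime) perturbing the four quadrants: first kept Original, second Gaussian
smoothed (sigma 1), third Rotated 90 degrees, fourth salted with impulse
Noise at density 0.05.  Labels, tree ids and views are never altered.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .taxonomy_io import DatasetIndex, ImageRecord, save_manifest

PARTITION_MODES = ("original", "halves", "quadrants")
AUGMENT_MODES = PARTITION_MODES + ("ogrn",)

# transforms applied to quadrants 1..4 in the OGRN regime
OGRN_SEQUENCE = ("original", "smoothed", "rotated", "noisy")


@dataclass(frozen=True)
class AugmentConfig:
    mode: str = "original"
    gaussian_sigma: float = 1.0
    sp_density: float = 0.05
    rotation_degrees: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in AUGMENT_MODES:
            raise ValueError(f"unknown augmentation mode {self.mode!r}")
        if not (0.0 <= self.sp_density <= 1.0):
            raise ValueError("sp_density must lie in [0, 1]")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


def to_grayscale(color_image: np.ndarray) -> np.ndarray:
    """Luma conversion 0.299 R + 0.587 G + 0.114 B, output in [0, 1].

    Accepts float images in [0, 1] or integer images (rescaled by the dtype
    maximum).  A 2-D input is returned unchanged apart from rescaling.
    """
    img = np.asarray(color_image)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(color_image.dtype).max
    else:
        img = img.astype(np.float64)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel image (H, W, 3), got shape {img.shape}"
        )
    return img @ np.array([0.299, 0.587, 0.114])


def stretch_contrast(img: np.ndarray, saturation: float = 0.01) -> np.ndarray:
    """Histogram stretching: clip at the ``saturation`` quantiles and rescale.

    With the default 1% tolerance the darkest and brightest percentile
    saturate at 0 and 1.  Constant images are returned unchanged.
    """
    if not (0.0 <= saturation < 0.5):
        raise ValueError("saturation must lie in [0, 0.5)")
    img = np.asarray(img, dtype=np.float64)
    lo, hi = np.quantile(img, [saturation, 1.0 - saturation])
    if hi <= lo:
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def partition(img: np.ndarray, mode: str) -> list[np.ndarray]:
    """Tile an image into 1, 2 (top/bottom halves) or 4 (quadrants) pieces.

    Quadrants are returned in row-major order: top-left, top-right,
    bottom-left, bottom-right.  The pieces reassemble to the input exactly.
    """
    if mode not in PARTITION_MODES:
        raise ValueError(f"unknown partition mode {mode!r}")
    img = np.asarray(img)
    h, w = img.shape[:2]
    if mode == "original":
        return [img.copy()]
    if mode == "halves":
        if h % 2:
            raise ValueError(f"height {h} is odd; cannot split into halves")
        return [img[: h // 2].copy(), img[h // 2 :].copy()]
    if h % 2 or w % 2:
        raise ValueError(f"dimensions {h}x{w} are odd; cannot split into quadrants")
    hh, hw = h // 2, w // 2
    return [
        img[:hh, :hw].copy(), img[:hh, hw:].copy(),
        img[hh:, :hw].copy(), img[hh:, hw:].copy(),
    ]


def transform_piece(img: np.ndarray, kind: str, cfg: AugmentConfig) -> np.ndarray:
    """Apply one OGRN perturbation to a piece.

    ``smoothed`` uses a Gaussian kernel (sigma from config, truncated at 4
    sigma, reflective borders); ``rotated`` is a 90-degree counter-clockwise
    rotation; ``noisy`` flips exactly round(density * N) pixels chosen without
    replacement to black/white in equal shares (the odd extra pixel is black).
    """
    img = np.asarray(img, dtype=np.float64)
    if kind == "original":
        return img.copy()
    if kind == "smoothed":
        return gaussian_filter(img, sigma=cfg.gaussian_sigma, mode="reflect", truncate=4.0)
    if kind == "rotated":
        return np.rot90(img, k=cfg.rotation_degrees // 90).copy()
    if kind == "noisy":
        rng = np.random.default_rng(cfg.seed)
        out = img.copy()
        n_alter = int(round(cfg.sp_density * img.size))
        flat = rng.choice(img.size, size=n_alter, replace=False)
        n_pepper = n_alter - n_alter // 2  # odd count: extra pixel goes dark
        out.flat[flat[:n_pepper]] = 0.0
        out.flat[flat[n_pepper:]] = 1.0
        return out
    raise ValueError(f"unknown transform kind {kind!r}")


def _load_gray(record: ImageRecord, root: Path) -> np.ndarray:
    raw = iio.imread(root / record.path)
    return to_grayscale(raw)


def augment_dataset(
    index: DatasetIndex,
    cfg: AugmentConfig,
    out_dir: str | Path,
    stretch: bool = True,
    saturation: float = 0.01,
) -> DatasetIndex:
    """Produce one of the four augmentation regimes as a new on-disk dataset.

    Every source image is preprocessed (grayscale + optional histogram
    stretching on the full image), partitioned, and (for OGRN) the four
    quadrants perturbed with original/smoothed/rotated/noisy respectively.
    Output records inherit species, tree and view; ``piece_index`` and
    ``transform`` record the lineage.  The new manifest is written to
    ``out_dir/manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    part_mode = "quadrants" if cfg.mode == "ogrn" else cfg.mode

    new_records = []
    for rec in index.records:
        gray = _load_gray(rec, index.root)
        if stretch:
            gray = stretch_contrast(gray, saturation)
        try:
            pieces = partition(gray, part_mode)
        except ValueError as exc:
            raise ValueError(f"image {rec.image_id!r}: {exc}") from exc
        for i, piece in enumerate(pieces):
            kind = OGRN_SEQUENCE[i] if cfg.mode == "ogrn" else "original"
            if kind == "noisy":
                # per-image seed so noise patterns differ across source images
                per_img = (cfg.seed * 1000003 + zlib.crc32(rec.image_id.encode())) % 2**31
                piece_cfg = replace(cfg, seed=per_img)
            else:
                piece_cfg = cfg
            piece = transform_piece(piece, kind, piece_cfg)
            image_id = f"{rec.image_id}_p{i}" if part_mode != "original" else rec.image_id
            fname = f"{image_id}.png"
            iio.imwrite(out_dir / fname, (np.clip(piece, 0, 1) * 255).astype(np.uint8))
            new_records.append(
                ImageRecord(
                    image_id=image_id,
                    path=fname,
                    species=rec.species,
                    tree_id=rec.tree_id,
                    view=rec.view,
                    specimen_id=rec.specimen_id,
                    piece_index=i,
                    transform=kind,
                )
            )
    out = DatasetIndex(new_records, index.taxonomy, root=out_dir)
    save_manifest(out, out_dir / "manifest.csv")
    return out


__all__ = [
    "AugmentConfig", "AUGMENT_MODES", "PARTITION_MODES", "OGRN_SEQUENCE",
    "to_grayscale", "stretch_contrast", "partition", "transform_piece",
    "augment_dataset",
]
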