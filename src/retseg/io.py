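"""Raster I/O and dataset directory loading.

Reads the raster formats the standard fundus benchmarks ship (TIFF, PNG,
PPM, GIF) through imageio and writes PNG.  A dataset directory follows the
DRIVE-style layout the synthetic generator produces::

    <root>/images/*.png|tif|ppm|gif     RGB fundus photographs
    <root>/masks/*                      optional binary FOV masks
    <root>/truths/*                     optional binary vessel annotations

Images are matched to masks/truths by sorted filename order.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DataError
from .types import FundusImage, GrayImage, NORMALIZED

RASTER_SUFFIXES = (".png", ".tif", ".tiff", ".ppm", ".gif", ".jpg", ".jpeg")


def read_raster(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def _as_binary(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > arr.max() / 2 if arr.max() > 1 else arr > 0).astype(np.uint8)


def read_fundus(
    image_path: str | Path,
    mask_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> FundusImage:
    pixels = read_raster(image_path)
    if pixels.ndim == 2:  # promote grayscale to RGB so the green channel exists
        pixels = np.stack([pixels] * 3, axis=2)
    mask = _as_binary(read_raster(mask_path)) if mask_path else None
    truth = _as_binary(read_raster(truth_path)) if truth_path else None
    return FundusImage(pixels=pixels, fov_mask=mask, truth=truth)


def list_rasters(directory: Path) -> list[Path]:
    return sorted(
        p for p in Path(directory).iterdir() if p.suffix.lower() in RASTER_SUFFIXES
    )


def load_dataset(root: str | Path, require_truth: bool = False) -> list[FundusImage]:
    """Load every image in a DRIVE-style directory, pairing masks and truths."""
    root = Path(root)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise DataError(f"no images/ directory under {root}")
    images = list_rasters(img_dir)
    if not images:
        raise DataError(f"no raster images in {img_dir}")
    masks = list_rasters(root / "masks") if (root / "masks").is_dir() else []
    truths = list_rasters(root / "truths") if (root / "truths").is_dir() else []
    if masks and len(masks) != len(images):
        raise DataError("mask count does not match image count")
    if truths and len(truths) != len(images):
        raise DataError("truth count does not match image count")
    if require_truth and not truths:
        raise DataError(f"no truths/ directory under {root}")
    out = []
    for i, ip in enumerate(images):
        out.append(
            read_fundus(
                ip,
                masks[i] if masks else None,
                truths[i] if truths else None,
            )
        )
    return out


def write_gray_png(path: str | Path, g: GrayImage | np.ndarray) -> None:
    """Write a grayscale image (normalized [0,1] or integer) as 8-bit PNG."""
    if isinstance(g, GrayImage):
        arr = g.values
        if g.convention == NORMALIZED:
            arr = arr * 255.0
    else:
        arr = np.asarray(g)
        if arr.dtype.kind == "f" and arr.max() <= 1.0:
            arr = arr * 255.0
    iio.imwrite(Path(path), np.clip(np.round(arr), 0, 255).astype(np.uint8))
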