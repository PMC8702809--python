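"""Sliding-window patch extraction, per-epoch augmentation, and stitching.

Full fundus images are too large to feed to the network directly, so a
64 x 64 window slides over the (zero-padded) image with a 16-pixel step.
Padding first extends both dimensions to the next multiple of the window
(the stated protocol), then — for arbitrary sizes — to the next size at
which ``(dim - window)`` is a multiple of the step so the grid closes
exactly; for the standard 584x584 and 605x700 inputs the first padding
already closes (640x640 -> 37x37 = 1369 patches, 640x704 -> 37x41 = 1517).
Predictions are stitched back by overlap averaging and cropped to the
original size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import resize

from .errors import GridError, ParameterError
from .types import GrayImage


@dataclass
class PatchGrid:
    """Sliding-window geometry over a padded image."""

    window: int
    step: int
    padded_shape: tuple[int, int]
    origins: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.origins:
            self.origins = list(self._enumerate())

    def _enumerate(self):
        h, w = self.padded_shape
        for r in range(0, h - self.window + 1, self.step):
            for c in range(0, w - self.window + 1, self.step):
                yield (r, c)

    @property
    def n_patches(self) -> int:
        return len(self.origins)


@dataclass
class PatchSet:
    """Input patches (and optional label patches) plus their grid."""

    inputs: list[np.ndarray]
    grid: PatchGrid
    labels: Optional[list[np.ndarray]] = None
    source_id: str = ""
    original_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.inputs) != self.grid.n_patches:
            raise GridError(
                f"{len(self.inputs)} patches but grid has {self.grid.n_patches} origins"
            )
        if self.labels is not None and len(self.labels) != self.grid.n_patches:
            raise GridError("label count does not match grid")


def n_patches_for_shape(shape: tuple[int, int], window: int = 64, step: int = 16) -> int:
    """Patch count after padding: product over dims of (dim_pad - window)/step + 1."""
    hp, wp = padded_dims(shape, window, step)
    return ((hp - window) // step + 1) * ((wp - window) // step + 1)


def _next_multiple(x: int, m: int) -> int:
    return ((x + m - 1) // m) * m


def padded_dims(shape: tuple[int, int], window: int, step: int) -> tuple[int, int]:
    """Padded dimensions: next multiple of window, then grow until the grid closes."""
    out = []
    for dim in shape:
        d = _next_multiple(max(dim, window), window)
        while (d - window) % step != 0:
            d += 1
        out.append(d)
    return tuple(out)


def pad_to_multiple(g: GrayImage, multiple: int = 64) -> tuple[GrayImage, PatchGrid]:
    """Zero-pad bottom/right so both dimensions are multiples of `multiple`.

    Returns the padded image and a PatchGrid with window = step = multiple
    (non-overlapping tiling); callers that slide with a finer step build
    their grid via :func:`extract_patches`.
    """
    if multiple < 1:
        raise ParameterError("multiple must be >= 1")
    h, w = g.shape
    hp = _next_multiple(max(h, multiple), multiple)
    wp = _next_multiple(max(w, multiple), multiple)
    padded = np.zeros((hp, wp), dtype=g.values.dtype)
    padded[:h, :w] = g.values
    grid = PatchGrid(window=multiple, step=multiple, padded_shape=(hp, wp))
    return GrayImage(padded, g.convention, g.L), grid


def extract_patches(
    g: GrayImage,
    truth: Optional[np.ndarray] = None,
    window: int = 64,
    step: int = 16,
    source_id: str = "",
) -> PatchSet:
    """Slide a window over the padded image left-to-right, top-to-bottom.

    Pads with zeros so both dimensions are multiples of `window` and the grid
    closes exactly; label patches are cut identically when `truth` is given.
    """
    if step < 1 or window < 1:
        raise ParameterError("window and step must be positive")
    if step > window:
        raise ParameterError("step greater than window would skip pixels")
    h, w = g.shape
    hp, wp = padded_dims((h, w), window, step)
    padded = np.zeros((hp, wp), dtype=g.values.dtype)
    padded[:h, :w] = g.values
    grid = PatchGrid(window=window, step=step, padded_shape=(hp, wp))
    inputs = [padded[r : r + window, c : c + window].copy() for r, c in grid.origins]
    labels = None
    if truth is not None:
        truth = np.asarray(truth)
        if truth.shape != (h, w):
            raise GridError("truth shape does not match image")
        tp = np.zeros((hp, wp), dtype=np.uint8)
        tp[:h, :w] = (truth > 0).astype(np.uint8)
        labels = [tp[r : r + window, c : c + window].copy() for r, c in grid.origins]
    return PatchSet(
        inputs=inputs,
        grid=grid,
        labels=labels,
        source_id=source_id,
        original_shape=(h, w),
    )


def augment(
    patch: np.ndarray,
    label: np.ndarray,
    seed: int,
    flip: bool = True,
    rot90: bool = True,
    crop_min_frac: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded geometric augmentation applied identically to patch and label.

    Independent 50% horizontal and vertical flips, a rotation by a random
    multiple of 90 degrees, and a random crop of at least ``crop_min_frac``
    of the side length resized back to the window; the label is re-binarized
    at 0.5 after the resize interpolation.
    """
    if patch.shape != label.shape:
        raise GridError("patch and label shapes differ")
    rng = np.random.default_rng(seed)
    p = np.asarray(patch, dtype=np.float64)
    lb = (np.asarray(label) > 0).astype(np.float64)
    if flip:
        if rng.random() < 0.5:
            p, lb = p[:, ::-1], lb[:, ::-1]
        if rng.random() < 0.5:
            p, lb = p[::-1, :], lb[::-1, :]
    if rot90:
        k = int(rng.integers(0, 4))
        p, lb = np.rot90(p, k), np.rot90(lb, k)
    window = patch.shape[0]
    if crop_min_frac < 1.0:
        side = int(rng.integers(int(np.ceil(crop_min_frac * window)), window + 1))
        if side < window:
            r0 = int(rng.integers(0, window - side + 1))
            c0 = int(rng.integers(0, window - side + 1))
            p = resize(
                p[r0 : r0 + side, c0 : c0 + side],
                (window, window),
                order=1,
                anti_aliasing=False,
            )
            lb = resize(
                lb[r0 : r0 + side, c0 : c0 + side],
                (window, window),
                order=1,
                anti_aliasing=False,
            )
            lb = (lb >= 0.5).astype(np.float64)
    return np.ascontiguousarray(p), np.ascontiguousarray(lb)


def stitch_predictions(
    patch_probs: list[np.ndarray],
    grid: PatchGrid,
    original_shape: tuple[int, int],
) -> np.ndarray:
    """Reassemble per-patch probabilities by overlap averaging, then crop.

    Each output pixel is the mean of every patch prediction covering it, so
    identical patch values round-trip losslessly and overlapping patches
    blend without seams.
    """
    if len(patch_probs) != grid.n_patches:
        raise GridError(
            f"{len(patch_probs)} patches for a grid of {grid.n_patches}"
        )
    acc = np.zeros(grid.padded_shape, dtype=np.float64)
    cnt = np.zeros(grid.padded_shape, dtype=np.float64)
    w = grid.window
    for prob, (r, c) in zip(patch_probs, grid.origins):
        prob = np.asarray(prob, dtype=np.float64)
        if prob.shape != (w, w):
            raise GridError(f"patch shape {prob.shape} != window {(w, w)}")
        acc[r : r + w, c : c + w] += prob
        cnt[r : r + w, c : c + w] += 1.0
    covered = cnt > 0
    acc[covered] /= cnt[covered]
    h, wd = original_shape
    return acc[:h, :wd]
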