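"""Core domain containers: fundus images, grayscale images, histograms.

A :class:`FundusImage` is the raw RGB photograph plus the optional binary
field-of-view (FOV) mask and the optional expert vessel annotation.  A
:class:`GrayImage` is a single-channel image that explicitly carries which
intensity convention it uses: integer levels ``0..L-1`` or normalized
``[0, 1]`` floats.  Keeping the convention on the object avoids the classic
bug of gamma-transforming integer data or histogramming floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ShapeError

INTEGER = "integer"
NORMALIZED = "normalized"


@dataclass
class FundusImage:
    """RGB fundus photograph with optional FOV mask and vessel ground truth.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8-valued array, channel order red/green/blue.
    fov_mask
        Optional ``(H, W)`` binary array; 1 marks the eyeball region.
    truth
        Optional ``(H, W)`` binary array; 1 marks vessel pixels.
    """

    pixels: np.ndarray
    fov_mask: Optional[np.ndarray] = None
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            # deliberately not raising ChannelCountError here: construction of
            # odd-shaped arrays is allowed, extract_green_channel validates.
            pass
        h, w = self.pixels.shape[:2]
        for name in ("fov_mask", "truth"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (h, w):
                    raise ShapeError(
                        f"{name} shape {arr.shape} does not match image {(h, w)}"
                    )
                setattr(self, name, (arr > 0).astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GrayImage:
    """Single-channel intensity image with an explicit value convention.

    ``convention`` is ``"integer"`` (values in ``0..L-1``) or ``"normalized"``
    (floats in ``[0, 1]``).  ``L`` is the number of gray levels (default 256).
    """

    values: np.ndarray
    convention: str = INTEGER
    L: int = 256

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.convention not in (INTEGER, NORMALIZED):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def as_normalized(self) -> "GrayImage":
        """Return a normalized-convention copy (divide integer levels by L-1)."""
        if self.convention == NORMALIZED:
            return GrayImage(self.values.astype(np.float64), NORMALIZED, self.L)
        return GrayImage(
            self.values.astype(np.float64) / (self.L - 1), NORMALIZED, self.L
        )


@dataclass
class GrayHistogram:
    """Per-level pixel counts n_k for k = 0..L-1 over n counted pixels."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if int(self.counts.sum()) != self.n:
            raise ValueError("histogram counts do not sum to n")

    @property
    def probabilities(self) -> np.ndarray:
        """p(r_k) = n_k / n."""
        return self.counts / float(self.n)
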