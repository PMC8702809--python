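"""Fundus-image preprocessing: green channel, denoising, FOV-masked
histogram equalization, gamma transform.

The chain mirrors the common practice for fundus photographs: the green
channel carries the highest vessel/tissue contrast, so it is extracted and
lightly Gaussian-smoothed; histogram equalization is then restricted to the
eyeball region (the field of view, FOV) because the black camera background
would otherwise dominate the gray-level distribution; finally a gamma
transform (default gamma = 1.3) on normalized intensities deepens vessel
contrast.  Pixels outside the FOV are forced to 0 so background never leaks
into training patches.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import ChannelCountError, DegenerateImageError, ParameterError
from .types import INTEGER, NORMALIZED, FundusImage, GrayHistogram, GrayImage


def extract_green_channel(img: FundusImage) -> GrayImage:
    """Return the green channel as an integer-convention GrayImage (L=256).

    The channel is copied untouched — no rescaling or dtype games.
    """
    px = np.asarray(img.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ChannelCountError(
            f"expected a 3-channel RGB image, got shape {px.shape}"
        )
    return GrayImage(px[:, :, 1].copy(), INTEGER, 256)


def estimate_fov_mask(img: FundusImage) -> np.ndarray:
    """Return the FOV mask: the supplied one, or a brightness-based estimate.

    When the dataset ships no mask, the eyeball disc is recovered by Otsu
    thresholding the mean channel, keeping the largest connected component
    and filling its holes.
    """
    if img.fov_mask is not None:
        return img.fov_mask
    mean = np.asarray(img.pixels, dtype=np.float64).mean(axis=2)
    if mean.max() <= 0 or np.ptp(mean) == 0:
        raise DegenerateImageError("cannot estimate a FOV mask from a flat image")
    thr = threshold_otsu(mean)
    rough = mean > thr
    if not rough.any():
        raise DegenerateImageError("FOV estimation produced an empty mask")
    lab = label(rough)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(lab == largest)
    if not mask.any():
        raise DegenerateImageError("FOV estimation produced an empty mask")
    return mask.astype(np.uint8)


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of odd side length `size`."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if size < 1 or size % 2 == 0:
        raise ParameterError("kernel size must be a positive odd integer")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_denoise(g: GrayImage, size: int = 3, sigma: float = 1.0) -> GrayImage:
    """Smooth an integer-convention image with a size x size Gaussian kernel.

    Uses a reflective border; the result is rounded back to integer levels.
    """
    if g.convention != INTEGER:
        raise ParameterError("gaussian_denoise expects an integer-convention image")
    k = gaussian_kernel(size, sigma)
    sm = ndimage.convolve(g.values.astype(np.float64), k, mode="reflect")
    out = np.clip(np.floor(sm + 0.5), 0, g.L - 1).astype(g.values.dtype)
    return GrayImage(out, INTEGER, g.L)


def compute_histogram(g: GrayImage, mask: np.ndarray) -> GrayHistogram:
    """Count gray levels over mask==1 pixels only (n_k, n of p(r_k)=n_k/n)."""
    if g.convention != INTEGER:
        raise ParameterError("compute_histogram expects an integer-convention image")
    mask = np.asarray(mask) > 0
    if mask.shape != g.shape:
        raise ParameterError("mask shape does not match image")
    if not mask.any():
        raise DegenerateImageError("empty mask: nothing to histogram")
    vals = g.values[mask].astype(np.int64)
    counts = np.bincount(vals, minlength=g.L)[: g.L]
    return GrayHistogram(counts, int(mask.sum()))


def masked_hist_equalize(g: GrayImage, mask: np.ndarray) -> GrayImage:
    """Histogram-equalize inside the mask; set outside pixels to 0.

    Each masked pixel at level r_k maps to
    ``s_k = round((L-1) * sum_{j<=k} n_j / n)`` with the histogram taken over
    masked pixels only; rounding is half-up so the mapping is reproducible
    exactly.  The map is monotone non-decreasing by construction (cumulative
    sums are).
    """
    hist = compute_histogram(g, mask)  # validates mask
    cdf = np.cumsum(hist.counts) / hist.n
    lut = np.floor((g.L - 1) * cdf + 0.5).astype(g.values.dtype)
    out = np.zeros_like(g.values)
    m = np.asarray(mask) > 0
    out[m] = lut[g.values[m].astype(np.int64)]
    return GrayImage(out, INTEGER, g.L)


def gamma_transform(g: GrayImage, gamma: float = 1.3, c: float = 1.0) -> GrayImage:
    """Pointwise power law s = c * r^gamma on normalized intensities.

    Integer-convention input is first normalized to [0, 1]; the output is a
    normalized-convention image.  gamma > 1 darkens midtones, gamma < 1
    brightens them; endpoints 0 and 1 are fixed when c = 1.
    """
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    if c <= 0:
        raise ParameterError("c must be positive")
    r = g.as_normalized().values
    return GrayImage(c * np.power(r, gamma), NORMALIZED, g.L)


def preprocess(
    img: FundusImage,
    kernel: int = 3,
    sigma: float = 1.0,
    gamma: float = 1.3,
    c: float = 1.0,
) -> GrayImage:
    """Full chain: green channel -> Gaussian denoise -> FOV-masked histogram
    equalization -> gamma transform.  Returns a normalized [0,1] image with
    the original spatial dimensions; deterministic for a given input."""
    green = extract_green_channel(img)
    mask = estimate_fov_mask(img)
    smooth = gaussian_denoise(green, kernel, sigma)
    eq = masked_hist_equalize(smooth, mask)
    return gamma_transform(eq, gamma, c)
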