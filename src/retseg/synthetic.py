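"""Synthetic fundus-like images with paired vessel truth and FOV masks.

The generator emulates the geometry that the rest of the pipeline cares
about: a bright disc-shaped field of view on a near-black background,
green-dominant tissue with gentle radial shading, and a branching tree of
smooth curvilinear vessels that are darker than the surrounding tissue in
the green channel.  Vessels are drawn as quadratic Bezier segments with a
soft (anti-aliased) stroke whose width decays with branching depth from
about 6 px down to 1 px; the binary truth is the stroke coverage
re-binarized at 0.5.  Everything is deterministic per seed.

It does not attempt photorealism: no optic disc, no lesions or exudates, no
camera vignetting beyond the radial shade.  It exists so preprocessing,
patching, training and evaluation can be exercised end to end without
downloading DRIVE/STARE-style datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ParameterError
from .types import FundusImage


@dataclass
class SynthSpec:
    """Parameters of the synthetic fundus generator."""

    height: int = 584
    width: int = 584
    fov_radius_frac: float = 0.47
    n_roots: int = 5
    branch_prob: float = 0.75
    max_depth: int = 5
    width_decay: float = 0.78
    root_width: float = 6.0
    vessel_darkening: float = 0.45
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ParameterError("synthetic images must be at least 64x64")
        if not 0 < self.fov_radius_frac <= 1:
            raise ParameterError("fov_radius_frac must be in (0, 1]")


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _stamp_soft_disc(canvas: np.ndarray, cy: float, cx: float, radius: float) -> None:
    """Max-combine a soft disc of given radius into `canvas` (coverage in [0,1])."""
    h, w = canvas.shape
    r_ext = int(np.ceil(radius + 1.5))
    y0, y1 = max(0, int(cy) - r_ext), min(h, int(cy) + r_ext + 1)
    x0, x1 = max(0, int(cx) - r_ext), min(w, int(cx) + r_ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    cov = np.clip(radius + 0.5 - d, 0.0, 1.0)  # 1 inside, linear falloff at rim
    np.maximum(canvas[y0:y1, x0:x1], cov, out=canvas[y0:y1, x0:x1])


def _draw_vessel_tree(
    coverage: np.ndarray, spec: SynthSpec, rng: np.random.Generator
) -> None:
    h, w = coverage.shape
    cy, cx = h / 2.0, w / 2.0
    R = spec.fov_radius_frac * min(h, w) / 2.0

    def grow(pos: np.ndarray, direction: float, width: float, depth: int) -> None:
        if depth > spec.max_depth or width < 0.6:
            return
        seg_len = rng.uniform(0.25, 0.45) * R
        bend = rng.uniform(-0.7, 0.7)
        d0 = np.array([np.sin(direction), np.cos(direction)])
        mid = pos + d0 * seg_len * 0.5
        mid += np.array([np.sin(direction + np.pi / 2), np.cos(direction + np.pi / 2)]) * (
            bend * seg_len * 0.3
        )
        end_dir = direction + bend * 0.8
        end = pos + np.array([np.sin(end_dir), np.cos(end_dir)]) * seg_len
        n_pts = max(int(seg_len * 2), 8)
        pts = _bezier_points(pos, mid, end, n_pts)
        widths = np.linspace(width, width * 0.92, n_pts)
        for (py, px), wdt in zip(pts, widths):
            if (py - cy) ** 2 + (px - cx) ** 2 > (R - 1.0) ** 2:
                return  # stop at the FOV rim
            _stamp_soft_disc(coverage, py, px, wdt / 2.0)
        new_width = width * spec.width_decay
        if rng.random() < spec.branch_prob:
            split = rng.uniform(0.3, 0.7)
            grow(end, end_dir + split, new_width, depth + 1)
            grow(end, end_dir - split * rng.uniform(0.6, 1.2), new_width, depth + 1)
        else:
            grow(end, end_dir + rng.uniform(-0.3, 0.3), new_width, depth + 1)

    for _ in range(spec.n_roots):
        ang = rng.uniform(0, 2 * np.pi)
        start = np.array([cy, cx]) + np.array([np.sin(ang), np.cos(ang)]) * (0.12 * R)
        out_dir = ang + rng.uniform(-0.4, 0.4)
        grow(start, out_dir, spec.root_width, 0)


def generate_fundus(spec: SynthSpec) -> FundusImage:
    """Generate one synthetic fundus image with FOV mask and vessel truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = h / 2.0, w / 2.0
    R = spec.fov_radius_frac * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    fov = (dist <= R).astype(np.uint8)

    # green-dominant tissue with radial shading: brighter center, darker rim
    shade = np.clip(1.0 - 0.35 * (dist / R) ** 2, 0.0, 1.0)
    green = 60.0 + 90.0 * shade
    coverage = np.zeros((h, w), dtype=np.float64)
    _draw_vessel_tree(coverage, spec, rng)
    coverage *= fov
    green = green * (1.0 - spec.vessel_darkening * coverage)
    red = green * 0.55
    blue = green * 0.35

    img = np.stack([red, green, blue], axis=2)
    img *= fov[:, :, None]
    img += 3.0  # faint camera background so the image is not exactly zero
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = ((coverage >= 0.5) & (fov > 0)).astype(np.uint8)
    return FundusImage(pixels=pixels, fov_mask=fov, truth=truth)


def generate_dataset(spec: SynthSpec, n_images: int, out_dir: str | Path) -> Path:
    """Write n_images synthetic fundus images in a DRIVE-style layout.

    Layout: ``images/NN.png`` (RGB), ``masks/NN.png``, ``truths/NN.png``
    (binary as 0/255 grayscale); image i uses seed ``spec.seed + i``.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    out = Path(out_dir)
    for sub in ("images", "masks", "truths"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for i in range(n_images):
        s = SynthSpec(**{**vars(spec), "seed": spec.seed + i})
        fi = generate_fundus(s)
        name = f"{i + 1:02d}.png"
        iio.imwrite(out / "images" / name, fi.pixels)
        iio.imwrite(out / "masks" / name, (fi.fov_mask * 255).astype(np.uint8))
        iio.imwrite(out / "truths" / name, (fi.truth * 255).astype(np.uint8))
    return out
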