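"""CD31-style 2-D vascular fraction on stained RGB histology images.

The level of vascularisation is quantified by segmenting the colour range
associated with the endothelial (DAB-brown) staining and expressing the
stained area as a percentage of the pixels in each region of interest.  A
synthetic immunohistochemistry image generator provides ground truth for
validation: brown vessel-like structures on a pink counterstain background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.draw import disk

__all__ = ["StainRange", "Fraction2D", "DAB_BROWN_HSV", "cd31_fraction",
           "make_synthetic_ihc"]


@dataclass(frozen=True)
class StainRange:
    """Inclusive per-channel colour bounds in a named colour space."""

    colour_space: str
    low: tuple[float, float, float]
    high: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(l > h for l, h in zip(self.low, self.high)):
            raise ValueError("stain range bounds must be ordered per channel")
        if self.colour_space not in ("hsv", "rgb"):
            raise ValueError(f"unsupported colour space {self.colour_space!r}")


#: Default DAB-brown range (hue/sat/value in [0, 1]).
DAB_BROWN_HSV = StainRange("hsv", low=(0.02, 0.25, 0.10), high=(0.16, 1.00, 0.85))


@dataclass(frozen=True)
class Fraction2D:
    """Stained-pixel fraction of one ROI, as a percentage."""

    roi_id: int
    stained_pixels: int
    total_pixels: int

    @property
    def fraction(self) -> float:
        return 100.0 * self.stained_pixels / self.total_pixels


def _in_range(image: np.ndarray, stain: StainRange) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    chans = rgb2hsv(img) if stain.colour_space == "hsv" else img
    lo = np.asarray(stain.low)
    hi = np.asarray(stain.high)
    return np.all((chans >= lo) & (chans <= hi), axis=-1)


def cd31_fraction(image: np.ndarray, stain: StainRange = DAB_BROWN_HSV,
                  rois: list[tuple[int, int, int, int]] | None = None,
                  ) -> list[Fraction2D]:
    """Per-ROI percentage of pixels inside the stain colour range.

    ``rois`` are ``(row0, col0, height, width)`` rectangles; with none given
    the whole image is a single ROI.
    """
    mask = _in_range(image, stain)
    if rois is None:
        rois = [(0, 0, mask.shape[0], mask.shape[1])]
    out = []
    for i, (r0, c0, h, w) in enumerate(rois):
        if h <= 0 or w <= 0:
            raise ValueError(f"ROI {i} is empty")
        if r0 < 0 or c0 < 0 or r0 + h > mask.shape[0] or c0 + w > mask.shape[1]:
            raise ValueError(f"ROI {i} exceeds the image bounds")
        sub = mask[r0:r0 + h, c0:c0 + w]
        out.append(Fraction2D(roi_id=i, stained_pixels=int(sub.sum()),
                              total_pixels=sub.size))
    return out


_BROWN_RGB = np.array([0.47, 0.28, 0.15])
_PINK_RGB = np.array([0.91, 0.72, 0.80])


def make_synthetic_ihc(fraction: float, vessel_texture: str = "dots",
                       seed: int = 0, shape: tuple[int, int] = (512, 512),
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic CD31-like RGB image with ground-truth stain mask.

    Draws brown vessel-like structures ("dots" for transverse capillary
    profiles, "curvilinear" for longitudinal ones) on a pink background
    until the stained-pixel fraction matches ``fraction`` (percent) to
    within one pixel, then returns the float RGB image and the truth mask.
    """
    if not (0 <= fraction <= 50):
        raise ValueError("fraction must lie in [0, 50] percent")
    if vessel_texture not in ("dots", "curvilinear"):
        raise ValueError(f"unknown vessel texture {vessel_texture!r}")
    rng = np.random.default_rng(seed)
    h, w = shape
    target = int(round(fraction / 100.0 * h * w))
    mask = np.zeros(shape, dtype=bool)

    guard = 0
    while mask.sum() < target and guard < 100_000:
        guard += 1
        if vessel_texture == "dots":
            r = rng.uniform(2.0, 5.0)
            c = rng.uniform([r, r], [h - r, w - r])
            rr, cc = disk(c, r, shape=shape)
            mask[rr, cc] = True
        else:
            pos = rng.uniform([5, 5], [h - 5, w - 5])
            ang = rng.uniform(0, 2 * np.pi)
            for _ in range(rng.integers(15, 60)):
                rr, cc = disk(pos, 1.8, shape=shape)
                mask[rr, cc] = True
                ang += rng.normal(0, 0.3)
                pos = np.clip(pos + 2.0 * np.array([np.sin(ang), np.cos(ang)]),
                              2, [h - 3, w - 3])

    excess = int(mask.sum()) - target
    if excess > 0:  # un-stain random pixels for an exact pixel count
        on = np.flatnonzero(mask.ravel())
        drop = rng.choice(on, size=excess, replace=False)
        mask.ravel()[drop] = False

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _PINK_RGB
    img += rng.normal(0, 0.015, size=img.shape)
    img[mask] = _BROWN_RGB + rng.normal(0, 0.02, size=(int(mask.sum()), 3))
    return np.clip(img, 0, 1), mask
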