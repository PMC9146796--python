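"""Bright-field spheroid segmentation and size measurement.

A non-adherent spheroid in a well images as a single dark disk on a bright
background; because it stays spheroidal, the projected outer boundary is an
accurate proxy for volume.  Segmentation is deliberately simple: Gaussian
smoothing, a global Otsu threshold, keep the largest connected component,
fill holes.  Measurement converts pixel counts to physical area, equivalent
diameter and sphere-equivalent volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "SpheroidImage",
    "SpheroidMeasurement",
    "NoSpheroidFound",
    "segment_spheroid",
    "measure",
]

#: components smaller than this (pixels) are treated as debris, not spheroid
MIN_COMPONENT_PX = 100


class NoSpheroidFound(ValueError):
    """Segmentation found no plausible spheroid in the image."""


@dataclass(frozen=True)
class SpheroidImage:
    """A 2D grayscale image with physical pixel size in µm/pixel."""

    pixels: np.ndarray
    pixel_size: float  # µm per pixel

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D grayscale array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SpheroidMeasurement:
    """Projected area (mm²), equivalent diameter (mm), and sphere volume (mm³)."""

    area: float
    equivalent_diameter: float
    volume: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        expected = (4.0 / 3.0) * np.pi * (self.equivalent_diameter / 2.0) ** 3
        if abs(self.volume - expected) > 1e-12 * max(expected, 1e-300):
            raise ValueError("volume inconsistent with equivalent diameter")


def segment_spheroid(image: SpheroidImage, invert: bool = False,
                     sigma: float = 2.0) -> np.ndarray:
    """Binary mask of the single spheroid in a bright-field image.

    Assumes the spheroid is darker than the background (set ``invert=True``
    for the opposite polarity).  Raises :class:`NoSpheroidFound` when
    thresholding degenerates (flat image) or the largest component is
    smaller than ``MIN_COMPONENT_PX`` pixels.
    """
    img = gaussian(image.pixels, sigma=sigma, preserve_range=True)
    if np.ptp(img) < 1e-12:
        raise NoSpheroidFound("image has no intensity variation")
    thresh = threshold_otsu(img)
    fg = img > thresh if invert else img < thresh
    if not fg.any() or fg.all():
        raise NoSpheroidFound("thresholding produced a degenerate mask")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < MIN_COMPONENT_PX:
        raise NoSpheroidFound(
            f"largest component has {int(sizes[largest - 1])} px "
            f"(< {MIN_COMPONENT_PX})"
        )
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def measure(mask: np.ndarray, pixel_size: float) -> SpheroidMeasurement:
    """Convert a binary mask to physical area, equivalent diameter and volume.

    ``area = n_px * pixel_size²``; the equivalent diameter is that of the
    circle with the same area, ``2 * sqrt(area/π)``; volume is the sphere
    with that diameter, ``(4/3) π (d/2)³``.
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    px_mm = pixel_size / 1000.0
    area = n_px * px_mm**2
    diameter = 2.0 * np.sqrt(area / np.pi)
    volume = (4.0 / 3.0) * np.pi * (diameter / 2.0) ** 3
    return SpheroidMeasurement(area=area, equivalent_diameter=diameter, volume=volume)
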