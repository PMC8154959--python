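"""Green-channel conversion, mean filtering and fixed-threshold binarization.

H&E-stained tissue absorbs strongly in the green band, so the green channel
gives the highest tissue/lumen contrast: tissue is dark, the unstained oral
cavity bright.  Intensities are normalized to [0, 1]; the default pipeline
then averages over a 15x15 neighborhood (225 pixels per interior value) and
thresholds at 0.5 with bright-is-foreground polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DataError, ParameterError

__all__ = ["GreyImage", "BinaryMask", "green_channel", "mean_filter", "binarize"]


@dataclass
class GreyImage:
    """Scalar raster with values in [0, 1]; ``provenance`` is the source slice index."""

    pixels: np.ndarray
    provenance: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DataError(f"grey image must be 2-D, got shape {self.pixels.shape}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise DataError(f"grey values outside [0, 1]: min {lo}, max {hi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Raster of {0, 1}; ``provenance`` is the source slice index."""

    pixels: np.ndarray
    provenance: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DataError(f"mask must be 2-D, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise DataError(f"mask values must be 0/1, got {vals}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def green_channel(section) -> GreyImage:
    """Greyscale conversion keeping only the green channel, scaled to [0, 1]."""
    px = np.asarray(section.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise DataError(f"expected an RGB raster, got shape {px.shape}")
    return GreyImage(pixels=px[:, :, 1].astype(np.float64) / 255.0,
                     provenance=section.index)


def mean_filter(img: GreyImage, window: int = 15) -> GreyImage:
    """Square mean (average) filter with edge replication at the borders.

    Each output pixel is the arithmetic mean of the ``window``x``window``
    neighborhood centered on it (225 source pixels for the default 15).
    Edge replication avoids the artificial darkening that zero padding
    would introduce along the ROI border.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    out = ndimage.uniform_filter(img.pixels, size=window, mode="nearest")
    # separable filtering can under/overshoot the bounds by float epsilon
    return GreyImage(pixels=np.clip(out, 0.0, 1.0), provenance=img.provenance)


def binarize(img: GreyImage, threshold: float = 0.5, invert: bool = False) -> BinaryMask:
    """Threshold a grey image; foreground is strictly above ``threshold``.

    Default polarity keeps the bright (unstained cavity) pixels; ``invert``
    keeps the dark ones instead, for stains with opposite contrast.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    fg = img.pixels > threshold
    if invert:
        fg = ~fg
    return BinaryMask(pixels=fg.astype(np.uint8), provenance=img.provenance)
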