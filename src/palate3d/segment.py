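"""Connected-component labeling and oral-cavity selection.

After thresholding, the bright foreground is split into 8-connected
components and the largest one is taken as the oral cavity: the lumen is by
far the largest bright region in a coronal head section, while residual
bright specks are noise.  A minimum-area floor guards near-empty slices,
which are carried through as degenerate masks rather than aborting the run
(real serial sections contain damaged slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .preprocess import BinaryMask, binarize, green_channel, mean_filter

__all__ = [
    "LabelMap",
    "CavityMask",
    "SegmentParams",
    "label_components",
    "largest_component",
    "segment_slice",
    "segment_stack",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class LabelMap:
    """Connected-component labeling of a binary mask.

    ``pixels`` holds labels {0..n_components} (0 = background); ``areas[k]``
    is the pixel count of label ``k+1``.
    """

    pixels: np.ndarray
    n_components: int
    areas: np.ndarray

    def area_of(self, label: int) -> int:
        return int(self.areas[label - 1])


@dataclass
class CavityMask:
    """Binary mask of the selected cavity component with summary geometry.

    An empty selection (no component, or none above the area floor) is
    flagged ``degenerate``; downstream stages interpolate over such slices.
    """

    pixels: np.ndarray
    provenance: int | None = None
    pixel_size: float = 1.0
    area_px: int = field(init=False)
    centroid: tuple[float, float] | None = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        self.area_px = int(self.pixels.sum())
        if self.area_px:
            r, c = np.nonzero(self.pixels)
            self.centroid = (float(r.mean()), float(c.mean()))
        else:
            self.centroid = None

    @property
    def degenerate(self) -> bool:
        return self.area_px == 0

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SegmentParams:
    """Stage parameters with the pipeline defaults."""

    filter_window: int = 15
    threshold: float = 0.5
    invert: bool = False
    connectivity: int = 8
    min_area_px: int = 64
    keep_top_k: int = 1


def label_components(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Label foreground components; 8-connectivity joins diagonal neighbors."""
    if connectivity not in _STRUCTURES:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask.pixels, structure=_STRUCTURES[connectivity])
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabelMap(pixels=labels, n_components=int(n), areas=areas)


def largest_component(
    labels: LabelMap,
    min_area_px: int = 0,
    keep_top_k: int = 1,
    provenance: int | None = None,
    pixel_size: float = 1.0,
) -> CavityMask:
    """Keep the largest component(s) as the cavity mask.

    Area ties are broken by the smallest raster-scan first pixel, which is
    deterministic and independent of label numbering.  If no component
    reaches ``min_area_px`` the result is an empty, degenerate mask.
    """
    shape = labels.pixels.shape
    if labels.n_components == 0:
        return CavityMask(np.zeros(shape, np.uint8), provenance, pixel_size)

    flat = labels.pixels.ravel()
    first_idx = np.full(labels.n_components + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # first scan-order occurrence per label (reverse pass keeps the earliest)
    first_idx[flat[nz[::-1]]] = nz[::-1]
    # sort labels by (area desc, first scan index asc)
    order = sorted(
        range(1, labels.n_components + 1),
        key=lambda lab: (-labels.areas[lab - 1], first_idx[lab]),
    )
    keep = [lab for lab in order[: max(1, keep_top_k)]
            if labels.areas[lab - 1] >= max(min_area_px, 1)]
    if not keep:
        return CavityMask(np.zeros(shape, np.uint8), provenance, pixel_size)
    sel = np.isin(labels.pixels, keep).astype(np.uint8)
    return CavityMask(sel, provenance, pixel_size)


def segment_slice(section, params: SegmentParams = SegmentParams()) -> CavityMask:
    """Full per-slice segmentation: green channel, mean filter, threshold,
    8-connected labeling, largest-component selection.  Deterministic."""
    grey = mean_filter(green_channel(section), window=params.filter_window)
    mask = binarize(grey, threshold=params.threshold, invert=params.invert)
    labels = label_components(mask, connectivity=params.connectivity)
    return largest_component(
        labels,
        min_area_px=params.min_area_px,
        keep_top_k=params.keep_top_k,
        provenance=section.index,
        pixel_size=section.pixel_size,
    )


def segment_stack(stack, params: SegmentParams = SegmentParams()) -> list[CavityMask]:
    """Segment every slice of a stack in order."""
    return [segment_slice(s, params) for s in stack]
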