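"""Loading, ordering and cropping of serial-section image stacks.

A stack is an ordered list of RGB section photographs sharing one raster
size, one in-plane pixel size (µm/px, isotropic) and one section thickness
(µm).  Coordinates are 0-based ``(row, col)`` with row 0 at the image top.
File order comes from the caller's explicit path list (a manifest) or a
lexicographic sort of zero-padded names — never from file timestamps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import DataError, DimensionMismatchError, ParameterError, RoiBoundsError

__all__ = [
    "SectionImage",
    "ImageStack",
    "RoiSpec",
    "load_stack",
    "save_stack",
    "extract_roi",
    "plane_positions",
]


@dataclass
class SectionImage:
    """One RGB section photograph with physical sampling metadata.

    Parameters
    ----------
    pixels
        ``(rows, cols, 3)`` uint8 raster.
    index
        0-based section ordinal within the stack.
    pixel_size
        In-plane sampling, µm per pixel (isotropic).
    section_thickness
        Section thickness, µm.
    """

    pixels: np.ndarray
    index: int
    pixel_size: float
    section_thickness: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError(
                f"section {self.index}: expected an RGB raster (rows, cols, 3), "
                f"got shape {self.pixels.shape}"
            )
        if self.pixel_size <= 0 or self.section_thickness <= 0:
            raise ParameterError("pixel_size and section_thickness must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster dimensions ``(rows, cols)``."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class ImageStack:
    """Ordered serial sections sharing raster size and thickness."""

    slices: list[SectionImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slices) < 2:
            raise DataError("a stack needs at least 2 slices")
        idx = [s.index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise DataError(f"slice indices must be strictly increasing, got {idx}")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            offenders = [(s.index, s.shape) for s in self.slices]
            raise DimensionMismatchError(
                f"slices have mixed raster dimensions: {offenders}"
            )

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[SectionImage]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> SectionImage:
        return self.slices[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    @property
    def pixel_size(self) -> float:
        return self.slices[0].pixel_size

    @property
    def thickness(self) -> float:
        """Shared section thickness, µm."""
        return self.slices[0].section_thickness


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned rectangular region of interest in pixel coordinates."""

    origin_row: int
    origin_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ParameterError("ROI height and width must be positive")
        if self.origin_row < 0 or self.origin_col < 0:
            raise ParameterError("ROI origin must be non-negative")


def _to_uint8(arr: np.ndarray, path: os.PathLike | str) -> np.ndarray:
    """Normalize a loaded raster to 8-bit RGB."""
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    raise DataError(f"{path}: unsupported pixel dtype {arr.dtype}")


def load_stack(
    paths: Sequence[os.PathLike | str],
    pixel_size: float,
    thickness: float = 7.0,
) -> ImageStack:
    """Load ordered section files into an :class:`ImageStack`.

    ``paths`` is treated as the authoritative section order (slice 0 first).
    Rasters are normalized to 8-bit per channel.

    Raises
    ------
    DataError
        If a file is unreadable (the message names the path).
    DimensionMismatchError
        If the files do not all share one raster size.
    """
    if len(paths) < 2:
        raise DataError("need at least 2 section files")
    slices = []
    for i, p in enumerate(paths):
        try:
            arr = iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - re-raise with the path
            raise DataError(f"cannot read section image {p!s}: {exc}") from exc
        slices.append(
            SectionImage(
                pixels=_to_uint8(np.asarray(arr), p),
                index=i,
                pixel_size=float(pixel_size),
                section_thickness=float(thickness),
            )
        )
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        offenders = [
            (str(p), s.shape) for p, s in zip(paths, slices)
        ]
        raise DimensionMismatchError(f"mixed raster dimensions: {offenders}")
    return ImageStack(slices=slices)


def save_stack(stack: ImageStack, out_dir: os.PathLike | str, prefix: str = "section") -> list[Path]:
    """Write a stack as zero-padded numbered TIFFs; returns the paths in order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack) - 1)))
    paths = []
    for s in stack:
        p = out / f"{prefix}_{s.index:0{width}d}.tif"
        tifffile.imwrite(p, s.pixels)
        paths.append(p)
    return paths


def extract_roi(stack: ImageStack, roi: RoiSpec) -> ImageStack:
    """Crop every slice to ``roi``; pixel size and ordering are unchanged."""
    rows, cols = stack.shape
    if roi.origin_row + roi.height > rows or roi.origin_col + roi.width > cols:
        raise RoiBoundsError(
            f"ROI {roi} exceeds raster {rows}x{cols} (first offending slice "
            f"index {stack[0].index})"
        )
    cropped = [
        replace(
            s,
            pixels=s.pixels[
                roi.origin_row : roi.origin_row + roi.height,
                roi.origin_col : roi.origin_col + roi.width,
            ].copy(),
        )
        for s in stack
    ]
    return ImageStack(slices=cropped)


def plane_positions(
    first_index: int,
    interval: int,
    count: int,
    thickness: float,
    n_slices: int | None = None,
) -> list[tuple[int, float]]:
    """Section indices and depths (µm) of evenly spaced sampling planes.

    Plane ``k`` sits at section ``first_index + k*interval`` and depth
    ``k*interval*thickness`` µm below plane 0.  With 7 µm sections an
    interval of 15 gives 105 µm spacing; an interval of 10 gives 70 µm.

    ``n_slices``, if given, bounds the stack; a plane beyond it raises
    :class:`ParameterError`.
    """
    if interval < 1 or count < 1:
        raise ParameterError("interval and count must be >= 1")
    if first_index < 0:
        raise ParameterError("first_index must be >= 0")
    out = []
    for k in range(count):
        idx = first_index + k * interval
        if n_slices is not None and idx >= n_slices:
            raise ParameterError(
                f"plane {k} at section {idx} exceeds stack length {n_slices}"
            )
        out.append((idx, k * interval * thickness))
    return out
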