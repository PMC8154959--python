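"""Synthetic serial-section phantoms with exact ground truth.

The phantom emulates what the reconstruction pipeline actually sees in
H&E-stained brightfield sections of an embryonic mouse head: dark stained
tissue surrounding a bright oral-cavity silhouette composed of a lumen body,
a tongue and two lateral palatal-shelf structures.  Each rendered slice is
corrupted by additive Gaussian intensity noise and a per-slice rigid jitter
(slide-placement error), both drawn from a seeded generator and recorded, so
every pipeline stage can be scored against exact ground truth.

Only the green channel carries signal (both H&E dyes absorb green); the red
and blue channels mimic the stain's hue and are cosmetic — the pipeline must
ignore them, and tests verify this by scrambling them.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely

from .errors import PhantomSpecError
from .register import RigidTransform2D, apply_rigid
from .reconstruct import LabeledVolume
from .stack_io import ImageStack, SectionImage, save_stack

__all__ = [
    "Ellipsoid",
    "Box",
    "ExtrudedPolygon",
    "PhantomSpec",
    "PhantomTruth",
    "build_truth",
    "render_stack",
    "embryo_preset",
    "write_phantom",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in µm, (row, col, z)."""

    label: int
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def contains(self, r, c, z):
        cr, cc, cz = self.center
        ar, ac, az = self.semiaxes
        return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    def bounds(self):
        c, a = np.array(self.center), np.array(self.semiaxes)
        return c - a, c + a

    def analytic_volume(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * math.pi * a * b * c

    def scaled(self, s: float) -> "Ellipsoid":
        return Ellipsoid(self.label,
                         tuple(v * s for v in self.center),
                         tuple(v * s for v in self.semiaxes))


@dataclass(frozen=True)
class Box:
    """Axis-aligned cuboid: center and full edge lengths in µm, (row, col, z)."""

    label: int
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def contains(self, r, c, z):
        cr, cc, cz = self.center
        hr, hc, hz = (s / 2.0 for s in self.size)
        return (np.abs(r - cr) <= hr) & (np.abs(c - cc) <= hc) & (np.abs(z - cz) <= hz)

    def bounds(self):
        c = np.array(self.center)
        h = np.array(self.size) / 2.0
        return c - h, c + h

    def analytic_volume(self) -> float:
        a, b, c = self.size
        return a * b * c

    def scaled(self, s: float) -> "Box":
        return Box(self.label,
                   tuple(v * s for v in self.center),
                   tuple(v * s for v in self.size))


@dataclass(frozen=True)
class ExtrudedPolygon:
    """A 2-D polygon in the (row, col) plane extruded along z, µm units.

    ``vertices`` are (row, col) pairs; the solid spans ``z_min..z_max``.
    """

    label: int
    vertices: tuple[tuple[float, float], ...]
    z_min: float
    z_max: float

    def _poly(self):
        return shapely.Polygon(self.vertices)

    def contains(self, r, c, z):
        inside_z = (z >= self.z_min) & (z <= self.z_max)
        flat = shapely.contains_xy(self._poly(), np.ravel(r), np.ravel(c))
        return flat.reshape(np.shape(r)) & inside_z

    def bounds(self):
        v = np.array(self.vertices)
        lo = np.array([v[:, 0].min(), v[:, 1].min(), self.z_min])
        hi = np.array([v[:, 0].max(), v[:, 1].max(), self.z_max])
        return lo, hi

    def analytic_volume(self) -> float:
        return float(self._poly().area) * (self.z_max - self.z_min)

    def scaled(self, s: float) -> "ExtrudedPolygon":
        return ExtrudedPolygon(
            self.label,
            tuple((r * s, c * s) for r, c in self.vertices),
            self.z_min * s,
            self.z_max * s,
        )


Shape = Ellipsoid | Box | ExtrudedPolygon

#: Gaussian jitter draws are clipped at this many standard deviations so the
#: "shapes stay in frame" guarantee can be checked analytically.
JITTER_CLIP_SIGMA = 3.0


@dataclass
class PhantomSpec:
    """Full description of a synthetic section stack.

    Intensities are mean green-channel levels in [0, 1]; ``noise_sd`` is the
    additive Gaussian sd on intensity; ``jitter_sd`` is (px translation,
    degrees rotation) per slice.  The tissue/cavity gap must exceed three
    noise standard deviations so that the fixed 0.5 threshold separates the
    classes by construction.
    """

    image_size: tuple[int, int]  # (rows, cols) px
    n_slices: int
    pixel_size: float  # µm/px
    shapes: tuple[Shape, ...]
    thickness: float = 7.0  # µm/section
    tissue_level: float = 0.15
    cavity_level: float = 0.85
    noise_sd: float = 0.08
    jitter_sd: tuple[float, float] = (5.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_level - self.tissue_level < 3.0 * self.noise_sd:
            raise PhantomSpecError(
                "cavity/tissue intensity gap must be >= 3 noise sd "
                f"(gap {self.cavity_level - self.tissue_level}, sd {self.noise_sd})"
            )
        self._check_fit()

    def _check_fit(self) -> None:
        rows_um = self.image_size[0] * self.pixel_size
        cols_um = self.image_size[1] * self.pixel_size
        depth_um = self.n_slices * self.thickness
        jt_um = JITTER_CLIP_SIGMA * self.jitter_sd[0] * self.pixel_size
        jr = math.radians(JITTER_CLIP_SIGMA * self.jitter_sd[1])
        center = np.array([rows_um / 2.0, cols_um / 2.0])
        for sh in self.shapes:
            lo, hi = sh.bounds()
            if lo[2] < 0 or hi[2] > depth_um:
                raise PhantomSpecError(f"shape {sh} exceeds stack depth")
            corners = np.array([[lo[0], lo[1]], [lo[0], hi[1]],
                                [hi[0], lo[1]], [hi[0], hi[1]]])
            r_max = float(np.linalg.norm(corners - center, axis=1).max())
            margin = jt_um + r_max * math.sin(jr) if jr else jt_um
            if (lo[0] - margin < 0 or lo[1] - margin < 0
                    or hi[0] + margin > rows_um or hi[1] + margin > cols_um):
                raise PhantomSpecError(
                    f"shape {sh} may leave the frame under maximal jitter "
                    f"(margin {margin:.1f} µm)"
                )

    @property
    def spacing(self) -> tuple[float, float, float]:
        """(row_um, col_um, z_um) voxel spacing."""
        return (self.pixel_size, self.pixel_size, self.thickness)


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: labeled volume, applied jitters, volumes."""

    volume: LabeledVolume
    volumes_um3: dict = field(default_factory=dict)
    analytic_volumes_um3: dict = field(default_factory=dict)
    jitters: list[RigidTransform2D] = field(default_factory=list)

    @property
    def cavity_volume_um3(self) -> float:
        """Volume of the whole bright silhouette (union of all labels)."""
        return self.volumes_um3["union"]


def build_truth(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize a :class:`PhantomSpec`'s shapes into a ground-truth volume.

    Voxels are sampled at their centers; later shapes overwrite earlier ones
    on overlap.  Analytic volumes are recorded where a closed form exists.
    """
    rows, cols = spec.image_size
    r_um = (np.arange(rows) + 0.5) * spec.pixel_size
    c_um = (np.arange(cols) + 0.5) * spec.pixel_size
    z_um = (np.arange(spec.n_slices) + 0.5) * spec.thickness
    rr, cc = np.meshgrid(r_um, c_um, indexing="ij")

    vox = np.zeros((spec.n_slices, rows, cols), dtype=np.int16)
    for k, z in enumerate(z_um):
        for sh in spec.shapes:
            lo, hi = sh.bounds()
            if z < lo[2] or z > hi[2]:
                continue
            inside = sh.contains(rr, cc, z)
            vox[k][inside] = sh.label
    vol = LabeledVolume(voxels=vox, spacing=spec.spacing)
    vv = vol.voxel_volume_um3
    volumes = {int(lab): float(np.count_nonzero(vox == lab)) * vv
               for lab in np.unique(vox) if lab != 0}
    volumes["union"] = float(np.count_nonzero(vox)) * vv
    analytic = {sh.label: sh.analytic_volume() for sh in spec.shapes}
    return PhantomTruth(volume=vol, volumes_um3=volumes,
                        analytic_volumes_um3=analytic)


def _hue(level_green: np.ndarray, tissue: np.ndarray) -> np.ndarray:
    """Cosmetic H&E-like RGB around a green-channel plane: tissue renders
    purple-pink (high red/blue, low green), the cavity near-white."""
    red = np.where(tissue, 0.75, 0.92)
    blue = np.where(tissue, 0.70, 0.90)
    return np.stack([red, level_green, blue], axis=-1)


def render_stack(truth: PhantomTruth, spec: PhantomSpec) -> ImageStack:
    """Render the truth volume into a noisy, jittered RGB section stack.

    Per slice: the green channel takes ``cavity_level`` on the silhouette and
    ``tissue_level`` elsewhere; seeded Gaussian noise is added and clipped to
    [0, 1]; the slice is then warped by a seeded rigid jitter (translation sd
    ``jitter_sd[0]`` px, rotation sd ``jitter_sd[1]`` degrees, both clipped
    at 3 sd) about the image center.  The applied jitters are recorded in
    ``truth.jitters`` — they are exactly what registration must invert.
    Identical spec + seed reproduces the stack bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    jt, jr = spec.jitter_sd
    clip = JITTER_CLIP_SIGMA

    truth.jitters = []
    slices = []
    for k in range(spec.n_slices):
        sil = truth.volume.voxels[k] > 0
        green = np.where(sil, spec.cavity_level, spec.tissue_level)
        rgb = _hue(green, ~sil)
        if spec.noise_sd > 0:
            rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
        rgb = np.clip(rgb, 0.0, 1.0)

        dtr = float(np.clip(rng.normal(0.0, jt), -clip * jt, clip * jt)) if jt else 0.0
        dtc = float(np.clip(rng.normal(0.0, jt), -clip * jt, clip * jt)) if jt else 0.0
        dth = float(np.clip(rng.normal(0.0, jr), -clip * jr, clip * jr)) if jr else 0.0
        J = RigidTransform2D(math.radians(dth), dtr, dtc, center)
        truth.jitters.append(J)

        fills = (0.75, spec.tissue_level, 0.70)  # off-frame regions look like tissue
        chans = [apply_rigid(rgb[:, :, i], J, fill=fills[i]) for i in range(3)]
        warped = np.clip(np.stack(chans, axis=-1), 0.0, 1.0)
        px = np.clip(np.rint(warped * 255.0), 0, 255).astype(np.uint8)
        slices.append(SectionImage(pixels=px, index=k,
                                   pixel_size=spec.pixel_size,
                                   section_thickness=spec.thickness))
    return ImageStack(slices=slices)


# Base preset geometry, µm, for a 1000 x 2000 µm field of view.  The lumen
# body (label 1) spans the oral cavity; the tongue (2) sits in the midline;
# the shelves (3 left, 4 right) flank it vertically before elevation.  The
# "elevating" stage reproduces the typical transient asymmetry: one shelf
# already horizontal above the tongue, the other still vertical.
_BASE_FIELD = (1000.0, 2000.0)  # rows x cols, µm
_BASE_PIXEL = 2.5  # µm/px
_BASE_SLICES = {"pre-elevation": 160, "elevating": 200}

def _base_shapes(stage: str) -> tuple[Shape, ...]:
    if stage == "pre-elevation":
        return (
            Ellipsoid(1, (500.0, 1000.0, 560.0), (280.0, 700.0, 520.0)),
            Ellipsoid(2, (560.0, 1000.0, 560.0), (180.0, 320.0, 420.0)),
            Box(3, (540.0, 570.0, 560.0), (360.0, 110.0, 700.0)),
            Box(4, (540.0, 1430.0, 560.0), (360.0, 110.0, 700.0)),
        )
    if stage == "elevating":
        return (
            Ellipsoid(1, (500.0, 1000.0, 700.0), (280.0, 700.0, 650.0)),
            Ellipsoid(2, (600.0, 960.0, 700.0), (170.0, 320.0, 520.0)),
            Box(3, (350.0, 850.0, 700.0), (110.0, 420.0, 880.0)),  # horizontal
            Box(4, (540.0, 1430.0, 700.0), (360.0, 110.0, 880.0)),  # vertical
        )
    raise PhantomSpecError(f"unknown stage {stage!r}; use 'pre-elevation' or 'elevating'")


def embryo_preset(stage: str, size_factor: float = 1.0, seed: int = 0,
                  noise_sd: float = 0.08,
                  jitter_sd: tuple[float, float] | None = None) -> PhantomSpec:
    """Phantom spec mimicking a coronal palate/tongue section series.

    ``stage`` is ``"pre-elevation"`` (two vertical shelves flanking a midline
    tongue) or ``"elevating"`` (one shelf horizontal above a shifted tongue,
    one still vertical).  ``size_factor`` scales all spatial dimensions —
    image, slice count and shapes — for fast desk tests; section thickness
    (7 µm) and pixel size (2.5 µm) are unchanged.

    The default jitter models a ~12.5 µm slide-placement sd (5 px at full
    scale) and a 3° rotation sd; the translation component scales with
    ``size_factor`` so the scene geometry, including the stay-in-frame
    guarantee, is scale-invariant.
    """
    if size_factor <= 0:
        raise PhantomSpecError("size_factor must be > 0")
    if jitter_sd is None:
        jitter_sd = (5.0 * size_factor, 3.0)
    shapes = tuple(sh.scaled(size_factor) for sh in _base_shapes(stage))
    rows = round(_BASE_FIELD[0] * size_factor / _BASE_PIXEL)
    cols = round(_BASE_FIELD[1] * size_factor / _BASE_PIXEL)
    n_slices = max(2, round(_BASE_SLICES[stage] * size_factor))
    # z-extent shrinks with the slice count; rescale shape depth to match
    depth_ratio = n_slices / (_BASE_SLICES[stage] * size_factor)
    shapes = tuple(_rescale_z(sh, depth_ratio) for sh in shapes)
    return PhantomSpec(
        image_size=(rows, cols),
        n_slices=n_slices,
        pixel_size=_BASE_PIXEL,
        shapes=shapes,
        thickness=7.0,
        noise_sd=noise_sd,
        jitter_sd=jitter_sd,
        seed=seed,
    )


def _rescale_z(sh: Shape, ratio: float) -> Shape:
    if abs(ratio - 1.0) < 1e-12:
        return sh
    if isinstance(sh, Ellipsoid):
        cr, cc, cz = sh.center
        ar, ac, az = sh.semiaxes
        return Ellipsoid(sh.label, (cr, cc, cz * ratio), (ar, ac, az * ratio))
    if isinstance(sh, Box):
        cr, cc, cz = sh.center
        sr, sc, sz = sh.size
        return Box(sh.label, (cr, cc, cz * ratio), (sr, sc, sz * ratio))
    return ExtrudedPolygon(sh.label, sh.vertices,
                           sh.z_min * ratio, sh.z_max * ratio)


def write_phantom(spec: PhantomSpec, out_dir) -> dict:
    """Render a phantom to disk: numbered TIFFs plus a truth sidecar
    (volume grid as .npz, jitter CSV, volumes CSV).  Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = build_truth(spec)
    stack = render_stack(truth, spec)
    image_paths = save_stack(stack, out / "images")

    vol_path = out / "truth_volume.npz"
    np.savez_compressed(vol_path, voxels=truth.volume.voxels,
                        spacing=np.array(truth.volume.spacing))

    jit_path = out / "truth_jitters.csv"
    with open(jit_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slice_index", "theta_deg", "t_row_px", "t_col_px",
                    "center_row", "center_col"])
        for i, J in enumerate(truth.jitters):
            w.writerow([i, math.degrees(J.theta), J.t_row, J.t_col,
                        J.center[0], J.center[1]])

    volumes_path = out / "truth_volumes.csv"
    with open(volumes_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "volume_um3"])
        for lab, v in truth.volumes_um3.items():
            w.writerow([lab, repr(v)])

    return {
        "images": image_paths,
        "volume": vol_path,
        "jitters": jit_path,
        "volumes": volumes_path,
        "truth": truth,
        "stack": stack,
    }
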