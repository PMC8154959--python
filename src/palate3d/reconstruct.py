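"""Voxel volume assembly, volume measurement, surface meshing and export.

Aligned per-slice masks are stacked into an anisotropic labeled voxel grid
(sections are typically 7 µm apart while in-plane sampling is finer; the
anisotropy is honored in µm space rather than resampled away).  Structure
volumes are voxel counts times the voxel volume.  Surfaces come from
marching cubes on the 0.5 iso-level of a label's indicator field, followed
by spike removal (outlier vertices snapped to their one-ring centroid) and
Taubin smoothing (alternating shrink/inflate Laplacian steps, which smooths
without net shrinkage).  Meshes export to binary STL (geometry only) or PLY
(with the structure's display color per vertex).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse
from skimage import measure

from .errors import DataError, EmptyStructureError, ParameterError, StageError
from .register import AlignedStack

__all__ = [
    "LabeledVolume",
    "SurfaceMesh",
    "STRUCTURE_COLORS",
    "assemble_volume",
    "measure_volume",
    "extract_surface",
    "remove_spikes",
    "smooth_mesh",
    "export_mesh",
    "load_mesh",
    "volume_report",
]

#: Display colors by structure name (the shelves are orange, the tongue pink,
#: everything else gray), as 8-bit RGB.
STRUCTURE_COLORS: dict[str, tuple[int, int, int]] = {
    "orange": (255, 165, 0),
    "pink": (255, 192, 203),
    "gray": (128, 128, 128),
    "white": (255, 255, 255),
}

#: Conventional label ids used by the pipeline and the phantom.
LABEL_CAVITY, LABEL_TONGUE, LABEL_SHELF_LEFT, LABEL_SHELF_RIGHT = 1, 2, 3, 4

DEFAULT_LABEL_COLORS = {
    LABEL_CAVITY: "gray",
    LABEL_TONGUE: "pink",
    LABEL_SHELF_LEFT: "orange",
    LABEL_SHELF_RIGHT: "orange",
}


@dataclass
class LabeledVolume:
    """Anisotropic voxel grid of structure labels.

    ``voxels`` has axes ``(z, row, col)`` — one z-plane per section —
    and ``spacing`` is ``(row_um, col_um, z_um)`` µm per voxel edge.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DataError(f"volume must be 3-D, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_um3(self) -> float:
        r, c, z = self.spacing
        return r * c * z

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    def labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.voxels) if v != 0]


@dataclass
class SurfaceMesh:
    """Triangle mesh of one labeled structure, vertices in µm.

    Vertex axes are ``(x, y, z) = (col_um, row_um, depth_um)``.  Faces wind
    outward: the signed volume of a closed mesh is positive.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: int = 0
    color: str = "gray"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise DataError("face indices out of vertex range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def enclosed_volume_um3(self) -> float:
        """Signed volume of the (closed) mesh, µm³."""
        return float(self.to_trimesh().volume)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def assemble_volume(
    aligned: AlignedStack,
    spacing: tuple[float, float, float],
) -> LabeledVolume:
    """Stack aligned cavity masks into a label-1 voxel volume.

    Degenerate slices are filled with a copy of the nearest non-degenerate
    plane (the predecessor on ties), so one damaged section does not punch
    a hole through the reconstruction.
    """
    good = [i for i, m in enumerate(aligned.masks) if not m.degenerate]
    if not good:
        raise StageError("cannot assemble an all-degenerate stack")
    shapes = {m.shape for m in aligned.masks}
    if len(shapes) != 1:
        raise DataError(f"aligned masks have mixed raster sizes: {shapes}")
    planes = []
    for i, m in enumerate(aligned.masks):
        if m.degenerate:
            src = min(good, key=lambda j: (abs(j - i), 0 if j < i else 1))
            planes.append(aligned.masks[src].pixels)
        else:
            planes.append(m.pixels)
    vox = np.stack(planes).astype(np.int16)
    return LabeledVolume(voxels=vox, spacing=spacing)


def measure_volume(vol: LabeledVolume, label: int) -> float:
    """Volume of one label in µm³ (voxel count × voxel volume; absent → 0)."""
    return float(np.count_nonzero(vol.voxels == label)) * vol.voxel_volume_um3


def extract_surface(vol: LabeledVolume, label: int, color: str | None = None) -> SurfaceMesh:
    """Marching-cubes triangulation of the 0.5 iso-level of a label.

    The indicator field is zero-padded by one voxel on every side so that
    structures touching the grid boundary still yield closed surfaces.
    Vertices are scaled by the voxel spacing into µm and faces wound so the
    enclosed signed volume is positive.
    """
    indicator = (vol.voxels == label).astype(np.float32)
    if not indicator.any():
        raise EmptyStructureError(f"label {label} occupies no voxels")
    row_um, col_um, z_um = vol.spacing
    padded = np.pad(indicator, 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(z_um, row_um, col_um)
    )
    verts -= np.array([z_um, row_um, col_um])  # undo the pad offset
    # reorder (z, row, col) -> (x, y, z) = (col, row, depth)
    verts = verts[:, [2, 1, 0]]
    mesh = trimesh.Trimesh(verts, faces, process=False)
    if mesh.volume < 0:
        faces = faces[:, ::-1]
    if color is None:
        color = DEFAULT_LABEL_COLORS.get(label, "gray")
    return SurfaceMesh(vertices=verts, faces=faces, label=label, color=color)


def _vertex_adjacency(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    """Symmetric 0/1 vertex adjacency from the face list."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    data = np.ones(len(e) * 2)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(n_vertices, n_vertices))
    adj = adj.tocsr()
    adj.data[:] = 1.0  # collapse duplicate edges
    return adj


def _neighbor_centroids(verts: np.ndarray, adj: sparse.csr_matrix) -> np.ndarray:
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return (adj @ verts) / deg[:, None]


def remove_spikes(mesh: SurfaceMesh, iqr_factor: float = 3.0) -> SurfaceMesh:
    """Snap outlier vertices onto the centroid of their one-ring neighbors.

    A vertex is an outlier when its distance to the neighbor centroid exceeds
    ``median + iqr_factor * IQR`` of that statistic over the whole mesh —
    a scale-free criterion that removes isolated reconstruction spikes while
    leaving smooth regions untouched.  Face topology is unchanged; meshes
    with fewer than 5 vertices are returned as-is.
    """
    if mesh.n_vertices < 5:
        return replace(mesh, vertices=mesh.vertices.copy(), faces=mesh.faces.copy())
    adj = _vertex_adjacency(mesh.n_vertices, mesh.faces)
    cen = _neighbor_centroids(mesh.vertices, adj)
    d = np.linalg.norm(mesh.vertices - cen, axis=1)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    thresh = med + iqr_factor * (q3 - q1) + 1e-9 * max(med, 1e-30)
    out = mesh.vertices.copy()
    spikes = d > thresh
    out[spikes] = cen[spikes]
    return replace(mesh, vertices=out, faces=mesh.faces.copy())


def smooth_mesh(
    mesh: SurfaceMesh,
    iterations: int = 10,
    lam: float = 0.5,
    mu: float = -0.53,
) -> SurfaceMesh:
    """Taubin smoothing: alternating Laplacian steps with factors ``lam``
    (shrink) and ``mu`` (inflate, ``|mu| > lam``), ``iterations`` passes.

    The negative second step compensates the shrinkage of plain Laplacian
    smoothing, so the enclosed volume is approximately preserved.  Topology
    is unchanged; 0 iterations is the identity.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    verts = mesh.vertices.copy()
    if iterations == 0 or mesh.n_vertices == 0:
        return replace(mesh, vertices=verts, faces=mesh.faces.copy())
    adj = _vertex_adjacency(mesh.n_vertices, mesh.faces)
    for _ in range(iterations):
        for factor in (lam, mu):
            verts = verts + factor * (_neighbor_centroids(verts, adj) - verts)
    return replace(mesh, vertices=verts, faces=mesh.faces.copy())


def export_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> Path:
    """Write a mesh as binary STL (geometry only) or PLY with vertex color.

    ``fmt`` defaults to the file extension.  STL carries no color, so the
    display color ("orange"/"pink" for shelves/tongue) is only written in
    PLY output.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "ply"):
        raise ParameterError(f"format must be stl or ply, got {fmt!r}")
    tm = mesh.to_trimesh()
    if fmt == "ply":
        rgb = STRUCTURE_COLORS.get(mesh.color, STRUCTURE_COLORS["gray"])
        tm.visual.vertex_colors = np.tile(
            np.array([*rgb, 255], np.uint8), (mesh.n_vertices, 1)
        )
    try:
        tm.export(path, file_type=fmt)
    except OSError as exc:
        raise DataError(f"cannot write mesh to {path}: {exc}") from exc
    return path


def load_mesh(path) -> SurfaceMesh:
    """Re-import an exported STL/PLY file as a :class:`SurfaceMesh`."""
    tm = trimesh.load(Path(path), process=False)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def volume_report(vol: LabeledVolume, path) -> Path:
    """Write a CSV of (label, voxels, volume_um3) for every present label."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "voxels", "volume_um3"])
        for lab in vol.labels():
            n = int(np.count_nonzero(vol.voxels == lab))
            w.writerow([lab, n, repr(n * vol.voxel_volume_um3)])
    return path
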