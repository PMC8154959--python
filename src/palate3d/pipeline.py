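"""End-to-end orchestration: config, stage sequencing, artifacts, manifest.

A run takes an ordered section-image directory (or explicit manifest), crops
the ROI, segments each slice, rigidly aligns the stack, assembles the voxel
volume, and meshes/cleans/smooths/exports the cavity surface.  Every stage
writes its artifact before the next starts, so a failed run preserves prior
outputs; the run manifest records the config echo and a checksum per
artifact, and a rerun with the same config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import reconstruct, stack_io
from .errors import ConfigError, PipelineError, StageError
from .qc import slice_qc_csv, transform_table_csv
from .register import RegisterParams, align_stack
from .segment import SegmentParams, segment_stack

logger = logging.getLogger("palate3d")

__all__ = ["PipelineConfig", "ReconstructParams", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class ReconstructParams:
    smooth_iterations: int = 10
    spike_iqr_factor: float = 3.0
    export_format: str = "both"  # stl | ply | both


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Defaults follow the published workflow where it states a value: 15x15
    filter window, threshold 0.5, 8-connectivity, 7 µm section thickness.
    The in-plane pixel size has no safe default and must be supplied.
    """

    input_dir: str
    output_dir: str
    pixel_size_um: float
    section_thickness_um: float = 7.0
    roi: stack_io.RoiSpec | None = None
    order: str = "name"  # name | manifest
    manifest: list[str] | None = None
    segment: SegmentParams = field(default_factory=SegmentParams)
    register: RegisterParams = field(default_factory=RegisterParams)
    reconstruct: ReconstructParams = field(default_factory=ReconstructParams)

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ConfigError("pixel_size_um and section_thickness_um must be > 0")
        if self.order not in ("name", "manifest"):
            raise ConfigError(f"order must be 'name' or 'manifest', got {self.order!r}")
        if self.order == "manifest" and not self.manifest:
            raise ConfigError("order 'manifest' requires a manifest file list")
        if not Path(self.input_dir).is_dir():
            raise ConfigError(f"input directory does not exist: {self.input_dir}")
        if self.reconstruct.export_format not in ("stl", "ply", "both"):
            raise ConfigError(
                f"export_format must be stl|ply|both, got {self.reconstruct.export_format!r}"
            )


def load_config(path) -> PipelineConfig:
    """Load a YAML run configuration."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        roi = None
        if "roi" in raw and raw["roi"] is not None:
            r = raw.pop("roi")
            roi = stack_io.RoiSpec(
                origin_row=int(r["row"]), origin_col=int(r["col"]),
                height=int(r["height"]), width=int(r["width"]),
            )
        seg = SegmentParams(**raw.pop("segment", {}))
        reg = RegisterParams(**raw.pop("register", {}))
        rec = ReconstructParams(**raw.pop("reconstruct", {}))
        cfg = PipelineConfig(roi=roi, segment=seg, register=reg,
                             reconstruct=rec, **raw)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    cfg.validate()
    return cfg


def _section_paths(cfg: PipelineConfig) -> list[Path]:
    root = Path(cfg.input_dir)
    if cfg.order == "manifest":
        paths = [root / p for p in cfg.manifest]
        missing = [str(p) for p in paths if not p.is_file()]
        if missing:
            raise ConfigError(f"manifest entries not found: {missing}")
        return paths
    exts = {".tif", ".tiff", ".png"}
    paths = sorted(p for p in root.iterdir() if p.suffix.lower() in exts)
    if len(paths) < 2:
        raise ConfigError(f"found {len(paths)} section images in {root}; need >= 2")
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full reconstruction; returns artifact paths and summaries.

    Stage order: load → ROI crop → per-slice segmentation (QC CSV) → rigid
    alignment (transform CSV) → volume assembly (report CSV) → surface
    extraction, spike removal, smoothing → STL/PLY export → run manifest.
    A stage failure raises with the stage name; prior artifacts remain.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        paths = _section_paths(cfg)
        logger.info("stage=load n_files=%d", len(paths))
        stack = stack_io.load_stack(paths, cfg.pixel_size_um,
                                    cfg.section_thickness_um)
        if cfg.roi is not None:
            stage = "roi"
            stack = stack_io.extract_roi(stack, cfg.roi)

        stage = "segment"
        logger.info("stage=segment n_slices=%d", len(stack))
        masks = segment_stack(stack, cfg.segment)
        artifacts["slice_qc"] = slice_qc_csv(masks, out / "slice_qc.csv")
        np.savez_compressed(out / "masks.npz",
                            masks=np.stack([m.pixels for m in masks]))
        artifacts["masks"] = out / "masks.npz"

        stage = "register"
        logger.info("stage=register")
        aligned = align_stack(masks, cfg.register)
        artifacts["transforms"] = transform_table_csv(
            aligned, out / "transforms.csv")

        stage = "assemble"
        spacing = (cfg.pixel_size_um, cfg.pixel_size_um,
                   cfg.section_thickness_um)
        volume = reconstruct.assemble_volume(aligned, spacing)
        artifacts["volume_report"] = reconstruct.volume_report(
            volume, out / "volume_report.csv")
        np.savez_compressed(out / "volume.npz", voxels=volume.voxels,
                            spacing=np.array(spacing))
        artifacts["volume"] = out / "volume.npz"

        stage = "mesh"
        logger.info("stage=mesh")
        mesh = reconstruct.extract_surface(volume, reconstruct.LABEL_CAVITY)
        mesh = reconstruct.remove_spikes(
            mesh, iqr_factor=cfg.reconstruct.spike_iqr_factor)
        mesh = reconstruct.smooth_mesh(
            mesh, iterations=cfg.reconstruct.smooth_iterations)

        stage = "export"
        fmts = {"stl": ["stl"], "ply": ["ply"],
                "both": ["stl", "ply"]}[cfg.reconstruct.export_format]
        for f in fmts:
            artifacts[f"mesh_{f}"] = reconstruct.export_mesh(
                mesh, out / f"cavity.{f}", fmt=f)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - unexpected stage faults
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": _config_echo(cfg),
        "n_slices": len(stack),
        "reference_index": aligned.reference_index,
        "cavity_volume_um3": reconstruct.measure_volume(
            volume, reconstruct.LABEL_CAVITY),
        "mesh_volume_um3": mesh.enclosed_volume_um3,
        "checksums": {k: _sha256(p) for k, p in sorted(artifacts.items())},
    }
    manifest_path = out / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["manifest"] = manifest_path
    return {"artifacts": artifacts, "manifest": manifest,
            "mesh": mesh, "volume": volume, "aligned": aligned}
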