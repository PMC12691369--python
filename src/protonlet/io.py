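"""Persistence: grid containers, YAML configs, run manifests, CSV
outputs, and optional DICOM RT Dose import/export.

Grids are stored as NPY arrays with a JSON sidecar documenting shape,
voxel size, origin and units, so they remain self-describing outside
the package.  Manifests contain the config, the seed, the package
version and content hashes of every written artifact — enough to re-run
a case bit-identically — and deliberately no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import VoxelGrid

__all__ = [
    "save_grid",
    "load_grid",
    "load_config",
    "save_config",
    "config_hash",
    "write_manifest",
    "write_cohort_outputs",
    "write_rtdose",
    "read_rtdose",
]


def save_grid(values: np.ndarray, grid: VoxelGrid, path, units: str = "Gy") -> Path:
    """Write an array + JSON sidecar; returns the array path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), np.asarray(values, dtype=float))
    sidecar = {
        "shape": list(grid.shape),
        "voxel_size_mm": list(grid.voxel_size),
        "origin_mm": list(grid.origin),
        "units": units,
        "order": "C",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path.with_suffix(".npy")


def load_grid(path) -> tuple[np.ndarray, VoxelGrid, str]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = VoxelGrid(
        tuple(meta["shape"]), tuple(meta["voxel_size_mm"]), tuple(meta["origin_mm"])
    )
    return values, grid, meta.get("units", "")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int | None, artifacts: list) -> Path:
    """JSON manifest with config, seed, version and artifact hashes.
    Deterministic for a fixed (config, seed, artifact contents)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": config_hash(config),
        "artifacts": {
            str(Path(a).relative_to(out_dir)): _file_sha256(Path(a))
            for a in sorted(map(str, artifacts))
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def write_cohort_outputs(out: dict, specs, out_dir, selection_threshold: float) -> None:
    """CSV tables + manifest for a cohort run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    for name, key in [
        ("enhancement_records.csv", "records"),
        ("cohort_summary.csv", "summary"),
        ("case_metrics.csv", "cases"),
        ("per_case.csv", "per_case"),
    ]:
        df = out[key]
        p = out_dir / name
        df.to_csv(p, index=False)
        artifacts.append(p)
    config = {
        "cases": [s.to_dict() for s in specs],
        "selection_threshold_gy": selection_threshold,
        "failures": out["failures"],
    }
    write_manifest(out_dir, config, None, artifacts)


# --- DICOM RT Dose ---------------------------------------------------------

_RTDOSE_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.2"


def write_rtdose(values: np.ndarray, grid: VoxelGrid, path, units: str = "GY",
                 dose_comment: str = "") -> Path:
    """Minimal RT Dose export (16-bit scaled, GRID type).

    LET grids can be exported as dose-like grids with a units tag in
    ``dose_comment`` (e.g. "LET_d keV/um").
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    values = np.asarray(values, dtype=float)
    if tuple(values.shape) != grid.shape:
        raise ValueError("values shape does not match grid")
    scale = float(values.max()) / 65000.0 if values.max() > 0 else 1.0
    scale = max(scale, 1e-12)
    pixels = np.round(values / scale).astype(np.uint16)
    # DICOM frames are z-slices with rows=y, cols=x.
    frames = np.transpose(pixels, (2, 1, 0))

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = units
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseComment = dose_comment
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = grid.shape[2]
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[0]
    ds.PixelSpacing = [grid.voxel_size[1], grid.voxel_size[0]]
    ds.ImagePositionPatient = [
        grid.origin[0] + grid.voxel_size[0] / 2,
        grid.origin[1] + grid.voxel_size[1] / 2,
        grid.origin[2] + grid.voxel_size[2] / 2,
    ]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [k * grid.voxel_size[2] for k in range(grid.shape[2])]
    ds.DoseGridScaling = scale
    ds.PixelData = frames.tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return Path(path)


def read_rtdose(path) -> tuple[np.ndarray, VoxelGrid, str]:
    """Read a dose-like grid from an RT Dose file."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    frames = np.frombuffer(ds.PixelData, dtype=np.uint16).reshape(
        n_frames, int(ds.Rows), int(ds.Columns)
    )
    values = np.transpose(frames, (2, 1, 0)).astype(float) * float(ds.DoseGridScaling)
    vx = float(ds.PixelSpacing[1])
    vy = float(ds.PixelSpacing[0])
    offsets = [float(v) for v in getattr(ds, "GridFrameOffsetVector", [0.0])]
    vz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    ipp = [float(v) for v in ds.ImagePositionPatient]
    grid = VoxelGrid(
        (int(ds.Columns), int(ds.Rows), n_frames),
        (vx, vy, vz),
        (ipp[0] - vx / 2, ipp[1] - vy / 2, ipp[2] - vz / 2),
    )
    return values, grid, str(getattr(ds, "DoseUnits", ""))
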