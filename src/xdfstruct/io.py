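"""Volume IO: multi-page TIFF stacks and raw binary, with a JSON sidecar.

The sidecar records voxel size, the axes convention and the phase
convention, e.g. ``{"voxel_size_um": 2.0, "axes": "xyz",
"phase_convention": "cavity=1"}``. TIFF pages are x-slices (axis 0).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .volumes import PhaseMap, Volume3D

__all__ = ["save_volume", "load_volume", "save_phase_map", "load_phase_map"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, voxel_size: float, phase: bool, shape, dtype) -> None:
    meta = {
        "voxel_size_um": voxel_size,
        "axes": "xyz",
        "phase_convention": "cavity=1" if phase else None,
        "shape": list(shape),
        "dtype": str(dtype),
        "byteorder": "little",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sc}")
    return json.loads(sc.read_text())


def save_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (pages = x-slices) or raw binary."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.data.astype(np.float32))
        _write_sidecar(path, vol.voxel_size, phase=False, shape=vol.shape, dtype="float32")
    else:
        vol.data.astype("<f4").tofile(path)
        _write_sidecar(path, vol.voxel_size, phase=False, shape=vol.shape, dtype="<f4")


def load_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.fromfile(path, dtype=meta.get("dtype", "<f4")).reshape(meta["shape"])
    return Volume3D(np.asarray(data, dtype=np.float64), meta["voxel_size_um"])


def save_phase_map(pm: PhaseMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pm.data)
        _write_sidecar(path, pm.voxel_size, phase=True, shape=pm.data.shape, dtype="uint8")
    else:
        pm.data.astype(np.uint8).tofile(path)
        _write_sidecar(path, pm.voxel_size, phase=True, shape=pm.data.shape, dtype="uint8")


def load_phase_map(path: str | Path) -> PhaseMap:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.fromfile(path, dtype="uint8").reshape(meta["shape"])
    return PhaseMap(np.asarray(data), meta["voxel_size_um"])
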