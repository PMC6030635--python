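"""Voxel volume container and 16-bit TIFF slice-stack I/O.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` with the apicobasal axis along ``z``;
* voxel indices are 0-based and the physical coordinate of a voxel centre
  is ``(index + 0.5) * voxel_size_mm``;
* greyscale values are attenuation coefficients (arbitrary reconstruction
  units).  On disk they are linearly quantized to 16-bit over a declared
  global ``value_range`` stored in a JSON sidecar next to the slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: tissue label codes shared by the whole package
BACKGROUND, ENAMEL, DENTINE, PULP = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", ENAMEL: "enamel",
               DENTINE: "dentine", PULP: "pulp"}

_SIDECAR = "volume.json"
_U16_MAX = 65535


@dataclass
class VoxelVolume:
    """A 3D scalar attenuation grid with isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_size_mm: float
    value_range: tuple[float, float] = (0.0, 3.2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional (z, y, x)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be strictly positive")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError("value_range must satisfy low < high")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def grey_level_scale(self) -> float:
        """Attenuation units per 16-bit grey level."""
        lo, hi = self.value_range
        return (hi - lo) / _U16_MAX

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size_mm,
                           tuple(self.value_range), dict(self.meta))


@dataclass
class TissueLabelMap:
    """Per-voxel label in {background, enamel, dentine, pulp}."""

    labels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3-dimensional (z, y, x)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == code))
                for code, name in LABEL_NAMES.items()}

    def copy(self) -> "TissueLabelMap":
        return TissueLabelMap(self.labels.copy(), self.voxel_size_mm)


def _quantize(data: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    lo, hi = value_range
    scaled = (np.asarray(data, dtype=np.float64) - lo) / (hi - lo) * _U16_MAX
    return np.clip(np.rint(scaled), 0, _U16_MAX).astype(np.uint16)


def _dequantize(raw: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    lo, hi = value_range
    return (raw.astype(np.float32) / _U16_MAX) * (hi - lo) + lo


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as a 16-bit TIFF slice stack plus JSON sidecar.

    One file per z-slice, zero-padded numeric suffix.  Attenuation values
    are linearly mapped onto [0, 65535] over ``volume.value_range``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    raw = _quantize(volume.data, volume.value_range)
    for i in range(raw.shape[0]):
        tifffile.imwrite(path / f"slice_{i:04d}.tif", raw[i])
    sidecar = {
        "voxel_size_mm": volume.voxel_size_mm,
        "value_range": list(volume.value_range),
        "n_slices": int(raw.shape[0]),
        "dtype": "uint16",
        "meta": volume.meta,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a 16-bit TIFF slice stack written by :func:`write_volume`."""
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    slices = sorted(path.glob("slice_*.tif"))
    if not slices:
        raise FileNotFoundError(f"no slice files under {path}")
    arrays = [tifffile.imread(p) for p in slices]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    raw = np.stack(arrays, axis=0)
    value_range = tuple(sidecar["value_range"])
    return VoxelVolume(_dequantize(raw, value_range),
                       float(sidecar["voxel_size_mm"]),
                       value_range, sidecar.get("meta", {}))


def write_labelmap(labelmap: TissueLabelMap, path: str | Path) -> Path:
    """Write a label map as an 8-bit TIFF stack (0 bg, 1 enamel, 2 dentine, 3 pulp)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i in range(labelmap.labels.shape[0]):
        tifffile.imwrite(path / f"labels_{i:04d}.tif", labelmap.labels[i])
    sidecar = {"voxel_size_mm": labelmap.voxel_size_mm,
               "label_codes": {str(k): v for k, v in LABEL_NAMES.items()}}
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return path


def read_labelmap(path: str | Path) -> TissueLabelMap:
    path = Path(path)
    sidecar = json.loads((path / _SIDECAR).read_text())
    slices = sorted(path.glob("labels_*.tif"))
    if not slices:
        raise FileNotFoundError(f"no label slices under {path}")
    arrays = [tifffile.imread(p) for p in slices]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    return TissueLabelMap(np.stack(arrays, axis=0),
                          float(sidecar["voxel_size_mm"]))
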