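"""Reconstruction-side volume filters: despeckling and edge-stopping diffusion.

Both filters are deterministic and operate on the 6-connected
neighbourhood.  Grey-value parameters (the diffusion stop criterion, the
despeckle tie-break) are specified on the declared 16-bit scale of the
volume and converted through its ``value_range``, mirroring how the
reconstruction software expresses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume

#: offsets of the 6-connected neighbourhood
_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass(frozen=True)
class DiffusionParams:
    """Edge-stopping diffusion: stop criterion (16-bit grey levels), iterations."""

    stop_criterion: float = 3327.0
    iterations: int = 5
    update_weight: float = 1.0 / 6.0  # explicit-scheme weight, <= 1/6 for stability

    def __post_init__(self) -> None:
        if self.stop_criterion < 0:
            raise ValueError("stop criterion must be non-negative")
        if self.iterations < 0:
            raise ValueError("iteration count must be non-negative")
        if not 0 < self.update_weight <= 1.0 / 6.0:
            raise ValueError("update weight must lie in (0, 1/6]")


@dataclass(frozen=True)
class DespeckleParams:
    """Aberrance rule: |v - median| > k * (MAD + one grey level), radius-1 window."""

    radius: int = 1
    outlier_k: float = 6.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.outlier_k <= 0:
            raise ValueError("outlier multiplier must be positive")


def _neighbour_sums(arr: np.ndarray, valid: np.ndarray | None = None):
    """Sum over 6-neighbours (borders omitted), optionally masked."""
    total = np.zeros_like(arr, dtype=np.float64)
    count = np.zeros(arr.shape, dtype=np.int32)
    for dz, dy, dx in _OFFSETS:
        src = tuple(slice(max(o, 0), arr.shape[i] + min(o, 0))
                    for i, o in enumerate((dz, dy, dx)))
        dst = tuple(slice(max(-o, 0), arr.shape[i] + min(-o, 0))
                    for i, o in enumerate((dz, dy, dx)))
        if valid is None:
            total[dst] += arr[src]
            count[dst] += 1
        else:
            total[dst] += np.where(valid[src], arr[src], 0.0)
            count[dst] += valid[src]
    return total, count


def despeckle(volume: VoxelVolume, params: DespeckleParams = DespeckleParams()) -> VoxelVolume:
    """Replace aberrant voxels by the mean of their non-aberrant 6-neighbours.

    A voxel is aberrant when it deviates from its local neighbourhood
    median by more than ``k`` times the neighbourhood MAD (plus one grey
    level, so perfectly flat regions are never flagged).  Single pass;
    non-aberrant voxels are untouched.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if data.size == 0:
        raise ValueError("empty volume")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    size = 2 * params.radius + 1
    med = ndimage.median_filter(data, size=size, mode="nearest")
    mad = ndimage.median_filter(np.abs(data - med), size=size, mode="nearest")
    grey = volume.grey_level_scale()
    deviant = np.abs(data - med) > params.outlier_k * (mad + grey)
    # a speckle is a lone outlier: it must also be a strict extremum of its
    # 6-neighbourhood, which spares tissue-boundary voxels whose values lie
    # between those of their neighbours
    nb_max = np.full_like(data, -np.inf)
    nb_min = np.full_like(data, np.inf)
    for dz, dy, dx in _OFFSETS:
        src = tuple(slice(max(o, 0), data.shape[i] + min(o, 0))
                    for i, o in enumerate((dz, dy, dx)))
        dst = tuple(slice(max(-o, 0), data.shape[i] + min(-o, 0))
                    for i, o in enumerate((dz, dy, dx)))
        np.maximum(nb_max[dst], data[src], out=nb_max[dst])
        np.minimum(nb_min[dst], data[src], out=nb_min[dst])
    aberrant = deviant & ((data > nb_max) | (data < nb_min))

    total, count = _neighbour_sums(data, valid=~aberrant)
    out = data.copy()
    replace = aberrant & (count > 0)
    out[replace] = total[replace] / count[replace]
    # aberrant voxels with no clean neighbour fall back to the local median
    fallback = aberrant & (count == 0)
    out[fallback] = med[fallback]

    result = volume.copy()
    result.data = out.astype(volume.data.dtype)
    result.meta = dict(volume.meta, despeckled_voxels=int(aberrant.sum()))
    return result


def anisotropic_diffusion(volume: VoxelVolume,
                          params: DiffusionParams = DiffusionParams()) -> VoxelVolume:
    """Explicit 6-neighbour diffusion gated by a grey-value stop criterion.

    Per iteration each voxel moves toward those neighbours whose absolute
    difference from it does not exceed the stop criterion:
    ``v <- v + lambda * sum_q (n - v)``.  Neighbours across strong edges
    never qualify, so inter-tissue boundaries are preserved while
    in-tissue noise is smoothed.  The update is a convex combination, so
    the global value range never expands.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if data.size == 0:
        raise ValueError("empty volume")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    threshold = params.stop_criterion * volume.grey_level_scale()
    lam = params.update_weight
    for _ in range(params.iterations):
        accum = np.zeros_like(data)
        for dz, dy, dx in _OFFSETS:
            src = tuple(slice(max(o, 0), data.shape[i] + min(o, 0))
                        for i, o in enumerate((dz, dy, dx)))
            dst = tuple(slice(max(-o, 0), data.shape[i] + min(-o, 0))
                        for i, o in enumerate((dz, dy, dx)))
            diff = data[src] - data[dst]
            accum[dst] += np.where(np.abs(diff) <= threshold, diff, 0.0)
        data = data + lam * accum
    result = volume.copy()
    result.data = data.astype(volume.data.dtype)
    result.meta = dict(volume.meta, diffusion_iterations=params.iterations)
    return result
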