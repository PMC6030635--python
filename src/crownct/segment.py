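"""Threshold segmentation of a crown volume into enamel, dentine and pulp.

The five-step protocol:

1. a tooth-vs-background threshold captures the whole tooth (holes filled
   so the pulp infill belongs to the tooth mask);
2. mask voxels above the enamel-dentine boundary become dentine; the
   remaining mask voxels are split spatially - the exterior-connected
   shell is the outer tissue (enamel);
3. enclosed interior voxels below the dentine-pulp boundary become pulp
   (interior voxels at or above it are boundary dentine);
4. small isolated islands are reabsorbed into their surrounding material;
5. the pulp cavity is closed at a horizontal plane through the
   ventralmost enamel voxel.

Steps 2-3 require a separable attenuation model (neutron windows); X-ray
windows overlap and raise :class:`NonSeparableError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import AttenuationModel
from .volume import (BACKGROUND, DENTINE, ENAMEL, LABEL_NAMES, PULP,
                     TissueLabelMap, VoxelVolume)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class NonSeparableError(ValueError):
    """Raised when no enamel-dentine separating threshold exists."""


class EmptyMaskError(ValueError):
    """Raised when the tooth-vs-background threshold selects nothing."""


@dataclass(frozen=True)
class SegmentOptions:
    """Tunable thresholds and rules of the segmentation protocol."""

    tooth_threshold: float = 0.15
    island_size_fraction: float = 0.5
    apicobasal_axis: int = 0  # +z of the stack points apically
    close_base: bool = True
    reabsorb: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.island_size_fraction <= 1:
            raise ValueError("island size fraction must lie in (0, 1]")
        if self.apicobasal_axis != 0:
            raise ValueError("only the stack z-axis is supported as apicobasal")


def segment_tooth(volume: VoxelVolume, model: AttenuationModel,
                  options: SegmentOptions = SegmentOptions()) -> TissueLabelMap:
    """Run the full five-step protocol and return the tissue partition."""
    if not model.separable:
        raise NonSeparableError(
            "no separating enamel-dentine threshold exists for this "
            "attenuation model (overlapping windows)")
    data = np.asarray(volume.data, dtype=np.float64)

    # step 1: whole-tooth mask
    mask = data > options.tooth_threshold
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise EmptyMaskError("tooth-vs-background threshold selected no voxels")
    # keep the dominant connected object (stray speckle may survive filtering)
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)

    ed = model.enamel_dentine_boundary
    dp = model.dentine_pulp_boundary

    # step 2: dentine by threshold; remaining mask voxels split spatially.
    # The outer tissue (enamel) lies outside the dentine ring of each
    # horizontal slice, the cavity inside it; slice-wise hole filling keeps
    # this robust to the open crown base.
    dentine = mask & (data > ed)
    rest = mask & ~dentine
    labels = np.full(volume.shape, BACKGROUND, dtype=np.uint8)
    labels[dentine] = DENTINE

    inside_ring = np.zeros_like(dentine)
    for z in range(dentine.shape[0]):
        if dentine[z].any():
            inside_ring[z] = ndimage.binary_fill_holes(dentine[z]) & ~dentine[z]
    inner = rest & inside_ring
    outer = rest & ~inner
    labels[outer] = ENAMEL
    # step 3: interior split at the dentine-pulp boundary
    labels[inner & (data < dp)] = PULP
    labels[inner & (data >= dp)] = DENTINE

    result = TissueLabelMap(labels, volume.voxel_size_mm)
    # steps 4 and 5
    if options.reabsorb:
        result = reabsorb_islands(result, options.island_size_fraction)
    if options.close_base:
        result = close_pulp_base(result, volume=volume, model=model)
    return result


def reabsorb_islands(labelmap: TissueLabelMap,
                     size_fraction: float = 0.5,
                     min_island_voxels: int = 8,
                     max_passes: int = 10) -> TissueLabelMap:
    """Relabel small isolated components to their surrounding material.

    For each tissue, 26-connected components smaller than
    ``size_fraction`` x (largest component of that tissue) — or smaller
    than ``min_island_voxels`` outright — are relabelled to the majority
    label of their 6-adjacent boundary voxels.  Iterated to a fixed
    point.
    """
    labels = labelmap.labels.copy()
    for _ in range(max_passes):
        changed = False
        for code in (ENAMEL, DENTINE, PULP):
            tissue = labels == code
            if not tissue.any():
                continue
            comp, n = ndimage.label(tissue, structure=_STRUCT26)
            sizes = np.bincount(comp.ravel())[1:]
            largest = sizes.max()
            small = (sizes < size_fraction * largest) | \
                (sizes < min_island_voxels)
            for cid in np.nonzero(small)[0] + 1:
                island = comp == cid
                ring = ndimage.binary_dilation(island, structure=_STRUCT6) & ~island
                ring_labels = labels[ring]
                ring_labels = ring_labels[ring_labels != code]
                if ring_labels.size == 0:
                    continue
                majority = int(np.bincount(ring_labels).argmax())
                labels[island] = majority
                changed = True
        if not changed:
            break
    return TissueLabelMap(labels, labelmap.voxel_size_mm)


def close_pulp_base(labelmap: TissueLabelMap,
                    volume: VoxelVolume | None = None,
                    model: AttenuationModel | None = None) -> TissueLabelMap:
    """Close the pulp cavity at the plane of the ventralmost enamel voxel.

    Pulp voxels below the horizontal plane through the lowest enamel
    voxel are relabelled background (they are matrix infill, not cavity).
    When the greyscale volume is supplied, dentine-labelled voxels whose
    attenuation lies inside the enamel window and which touch the plane
    slice adjacent to existing enamel are added to the enamel's basal
    ring.
    """
    labels = labelmap.labels.copy()
    enamel_z = np.nonzero((labels == ENAMEL).any(axis=(1, 2)))[0]
    if enamel_z.size == 0:
        raise ValueError("no enamel voxels present; cannot place the basal plane")
    z_plane = int(enamel_z.min())
    if z_plane > 0:
        below = np.zeros_like(labels, dtype=bool)
        below[:z_plane] = labels[:z_plane] == PULP
        labels[below] = BACKGROUND

    if volume is not None and model is not None:
        data = np.asarray(volume.data)
        band = np.zeros_like(labels, dtype=bool)
        lo = max(z_plane - 1, 0)
        band[lo:z_plane + 2] = True
        # only annex dense material (labelled dentine) whose attenuation
        # falls in the enamel window; cavity infill stays untouched
        candidate = band & (labels == DENTINE)
        candidate &= model.enamel.contains(data)
        near_enamel = ndimage.binary_dilation(labels == ENAMEL, structure=_STRUCT6)
        labels[candidate & near_enamel] = ENAMEL

    return TissueLabelMap(labels, labelmap.voxel_size_mm)


@dataclass(frozen=True)
class TissueVolumes:
    """Per-tissue volumes in mm^3 and the enamel-to-dentine ratio."""

    enamel: float
    dentine: float
    pulp: float

    def __post_init__(self) -> None:
        for v in (self.enamel, self.dentine, self.pulp):
            if v < 0:
                raise ValueError("volumes must be non-negative")

    @property
    def enamel_dentine_ratio(self) -> float:
        if self.dentine <= 0:
            raise ZeroDivisionError("dentine volume is zero; ratio undefined")
        return self.enamel / self.dentine

    def as_dict(self) -> dict[str, float]:
        return {"enamel_mm3": self.enamel, "dentine_mm3": self.dentine,
                "pulp_mm3": self.pulp,
                "enamel_dentine_ratio": self.enamel_dentine_ratio}


def tissue_volumes(labelmap: TissueLabelMap) -> TissueVolumes:
    """Volume = voxel count x (voxel size)^3 for each tissue."""
    vox = labelmap.voxel_size_mm ** 3
    counts = labelmap.counts()
    return TissueVolumes(enamel=counts["enamel"] * vox,
                         dentine=counts["dentine"] * vox,
                         pulp=counts["pulp"] * vox)


def dice_coefficient(a: TissueLabelMap, b: TissueLabelMap,
                     code: int) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|) for one tissue label."""
    ma, mb = a.labels == code, b.labels == code
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((ma & mb).sum()) / denom


def dice_per_tissue(a: TissueLabelMap, b: TissueLabelMap) -> dict[str, float]:
    return {name: dice_coefficient(a, b, code)
            for code, name in LABEL_NAMES.items() if code != BACKGROUND}
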