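"""Enamel-cap surface extraction and opposing-surface thickness mapping.

Surfaces are extracted by marching cubes at the 0.5 level of the tissue
indicator (after a sub-voxel Gaussian interpolation of the indicator;
the mesh geometry itself is never smoothed).  Thickness is measured per
outer-surface element as the distance along the inward normal to the
first intersection with the inner surface, accepting only intersections
whose triangle opposes the ray within a configurable cone; when the ray
misses, the distance to the nearest opposing inner triangle is used, and
elements where neither applies are flagged undefined rather than
zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .volume import BACKGROUND, LABEL_NAMES, TissueLabelMap


class TissueAbsentError(ValueError):
    """Raised when the requested tissue has no voxels."""


@dataclass(frozen=True)
class ThicknessParams:
    """Measurement rule parameters.

    ``cone_half_angle_deg`` gates which inner triangles count as
    "opposing" the inward ray (90 degrees accepts any front-facing
    triangle).  Normals are averaged over ``normal_smoothing_factor``
    median-edge-lengths before casting; raw facet normals of a voxel
    isosurface wobble by up to 45 degrees and would bias ray lengths.
    """

    cone_half_angle_deg: float = 90.0
    max_search_mm: float = 1.5
    normal_smoothing_factor: float = 3.0
    k_candidates: int = 64
    direction: str = "outer_to_inner"

    def __post_init__(self) -> None:
        if not 0 < self.cone_half_angle_deg <= 90:
            raise ValueError("cone half-angle must lie in (0, 90] degrees")
        if self.max_search_mm <= 0:
            raise ValueError("max search distance must be positive")
        if self.k_candidates < 1:
            raise ValueError("candidate count must be >= 1")
        if self.direction not in ("outer_to_inner", "inner_to_outer"):
            raise ValueError("direction must be outer_to_inner or inner_to_outer")


@dataclass
class ThicknessField:
    """Per-element thickness (mm) over a source surface.

    Undefined elements hold NaN and ``defined`` False.
    """

    thickness_mm: np.ndarray
    defined: np.ndarray
    areas_mm2: np.ndarray
    source: str = "enamel-outer"

    @property
    def defined_values(self) -> np.ndarray:
        return self.thickness_mm[self.defined]

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


@dataclass
class ThicknessHistogram:
    """Surface-element counts binned by thickness; edges anchored at 0."""

    bin_width_mm: float
    bin_edges_mm: np.ndarray
    counts: np.ndarray
    modal_thickness_mm: float

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        centres = 0.5 * (self.bin_edges_mm[:-1] + self.bin_edges_mm[1:])
        return centres, self.counts


def _label_at(labels: np.ndarray, points: np.ndarray, voxel_size: float) -> np.ndarray:
    """Nearest-voxel label lookup; points outside the grid read background."""
    idx = np.rint(points / voxel_size - 0.5).astype(np.int64)
    out = np.full(len(points), BACKGROUND, dtype=np.uint8)
    inside = np.all((idx >= 0) & (idx < np.array(labels.shape)), axis=1)
    ii = idx[inside]
    out[inside] = labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def extract_surfaces(labelmap: TissueLabelMap, tissue: int,
                     presmooth_sigma_vox: float = 1.0,
                     exterior_labels: tuple[int, ...] = (BACKGROUND,)
                     ) -> tuple[trimesh.Trimesh, trimesh.Trimesh | None]:
    """Extract the outer and inner boundary meshes of a shell-like tissue.

    The outer mesh is the part of the isosurface facing an exterior-side
    label (background by default; pass e.g. enamel+background to treat
    the enamel-dentine junction as the dentine shell's outer surface);
    the inner mesh faces the remaining interior tissues.  Face normals of
    both meshes point away from the tissue.  Returns ``(outer, None)``
    with a warning when the tissue has no interior boundary (solid
    region).
    """
    vs = labelmap.voxel_size_mm
    indicator = (labelmap.labels == tissue).astype(np.float32)
    if indicator.sum() == 0:
        raise TissueAbsentError(
            f"tissue {LABEL_NAMES.get(tissue, tissue)} has no voxels")
    fld = indicator
    if presmooth_sigma_vox > 0:
        fld = ndimage.gaussian_filter(indicator, presmooth_sigma_vox)
        # keep the 0.5 level inside the voxelized tissue
        fld = np.maximum(fld, indicator * 0.501)
    verts, faces, _, _ = measure.marching_cubes(fld, level=0.5,
                                                spacing=(vs, vs, vs))
    verts = verts + 0.5 * vs  # voxel centre convention: (index + 0.5) * size

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    delta = 0.75 * vs
    lab_plus = _label_at(labelmap.labels, centroids + delta * normals, vs)
    lab_minus = _label_at(labelmap.labels, centroids - delta * normals, vs)

    # orient each face away from the tissue and record what lies outside
    plus_is_tissue = lab_plus == tissue
    minus_is_tissue = lab_minus == tissue
    flip = plus_is_tissue & ~minus_is_tissue
    outside_label = np.where(flip, lab_minus, lab_plus)

    faces_oriented = faces.copy()
    faces_oriented[flip] = faces_oriented[flip][:, ::-1]

    outer_sel = np.isin(outside_label, np.asarray(exterior_labels, dtype=np.uint8))
    inner_sel = ~outer_sel & (outside_label != tissue)

    def _sub(sel: np.ndarray) -> trimesh.Trimesh | None:
        if not sel.any():
            return None
        return trimesh.Trimesh(vertices=verts, faces=faces_oriented[sel],
                               process=False)

    outer = _sub(outer_sel)
    inner = _sub(inner_sel)
    if outer is None:
        # a shell fully enclosed by other tissues: treat the whole surface
        # as outer so the caller still gets a mesh
        outer, inner = _sub(np.ones(len(faces), dtype=bool)), None
    if inner is None:
        warnings.warn(f"tissue {LABEL_NAMES.get(tissue, tissue)} has no "
                      "interior boundary; returning a single mesh")
    return outer, inner


def _smoothed_normals(mesh: trimesh.Trimesh, radius: float) -> np.ndarray:
    """Average face normals over a small centroid neighbourhood."""
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    if radius <= 0 or len(centroids) < 4:
        return normals
    tree = cKDTree(centroids)
    k = min(32, len(centroids))
    dist, idx = tree.query(centroids, k=k, distance_upper_bound=radius)
    valid = np.isfinite(dist)
    idx = np.where(valid, idx, 0)
    acc = normals[idx] * valid[..., None]
    summed = acc.sum(axis=1)
    norms = np.linalg.norm(summed, axis=1, keepdims=True)
    ok = norms[:, 0] > 1e-12
    out = normals.copy()
    out[ok] = summed[ok] / norms[ok]
    return out


def _moller_trumbore(origins, dirs, tri):
    """Vectorized ray-triangle intersection distances (NaN on miss)."""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    pvec = np.cross(dirs, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origins - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", dirs, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
    return np.where(hit, t, np.nan)


def measure_thickness(outer: trimesh.Trimesh, inner: trimesh.Trimesh,
                      params: ThicknessParams = ThicknessParams()
                      ) -> ThicknessField:
    """Distance from each outer element to the opposing inner surface."""
    if inner is None:
        raise ValueError("measurement requires an inner surface")
    src, dst = (outer, inner) if params.direction == "outer_to_inner" else (inner, outer)
    for m in (src, dst):
        if not np.all(np.isfinite(m.vertices)):
            raise ValueError("non-finite mesh geometry")

    edge_len = float(np.median(src.edges_unique_length))
    n_radius = params.normal_smoothing_factor * edge_len
    origins = src.triangles_center
    dirs = -_smoothed_normals(src, n_radius)  # inward rays

    dst_centroids = dst.triangles_center
    dst_normals = dst.face_normals
    dst_tris = dst.triangles
    tree = cKDTree(dst_centroids)
    cone_cos = np.cos(np.radians(params.cone_half_angle_deg)) - 1e-12

    n = len(origins)
    thickness = np.full(n, np.nan)

    def _cast(ray_ids: np.ndarray, tri_ids: np.ndarray) -> None:
        """Intersect ray/triangle candidate pairs, keep per-ray first hits."""
        chunk = 2_000_000
        for s in range(0, len(ray_ids), chunk):
            ri, ti = ray_ids[s:s + chunk], tri_ids[s:s + chunk]
            t = _moller_trumbore(origins[ri], dirs[ri], dst_tris[ti])
            opposing = np.einsum("ij,ij->i", dst_normals[ti], dirs[ri]) > cone_cos
            t = np.where(opposing & (t <= params.max_search_mm), t, np.nan)
            good = np.isfinite(t)
            if not good.any():
                continue
            order = np.lexsort((t[good], ri[good]))
            rid, tv = ri[good][order], t[good][order]
            first = np.ones(len(rid), dtype=bool)
            first[1:] = rid[1:] != rid[:-1]
            rid, tv = rid[first], tv[first]
            better = ~(thickness[rid] <= tv)  # NaN-aware improvement
            thickness[rid[better]] = tv[better]

    # candidate opposing triangles: k nearest inner centroids per ray
    # (surfaces of a shell are near-parallel, so the first-hit triangle is
    # essentially always among the nearest candidates; rays that miss all
    # candidates take the nearest-opposing fallback below)
    k1 = min(params.k_candidates, len(dst_centroids))
    dist1, idx1 = tree.query(origins, k=k1,
                             distance_upper_bound=params.max_search_mm)
    if k1 == 1:
        dist1, idx1 = dist1[:, None], idx1[:, None]
    valid = np.isfinite(dist1)
    ray_ids = np.repeat(np.arange(n), valid.sum(axis=1))
    _cast(ray_ids, idx1[valid])

    # fallback: nearest opposing inner triangle (centroid distance)
    missing = ~np.isfinite(thickness)
    if missing.any():
        k = min(16, len(dst_centroids))
        dist, idx = tree.query(origins[missing], k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        opp = np.einsum("mkj,mj->mk", dst_normals[idx], dirs[missing]) > cone_cos
        dist = np.where(opp & (dist <= params.max_search_mm), dist, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            thickness[missing] = np.nanmin(dist, axis=1)

    defined = np.isfinite(thickness)
    return ThicknessField(thickness_mm=thickness, defined=defined,
                          areas_mm2=src.area_faces.copy(),
                          source=params.direction)


def thickness_histogram(fld: ThicknessField,
                        bin_width_mm: float = 0.026) -> ThicknessHistogram:
    """Element counts per thickness bin; bins anchored at 0.

    The modal thickness is the centre of the most populated bin (ties
    resolve to the lower bin).
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    values = fld.defined_values
    if values.size == 0:
        raise ValueError("all elements undefined; nothing to bin")
    n_bins = int(np.ceil(values.max() / bin_width_mm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_mm
    counts, _ = np.histogram(values, bins=edges)
    modal = (int(np.argmax(counts)) + 0.5) * bin_width_mm
    return ThicknessHistogram(bin_width_mm=bin_width_mm, bin_edges_mm=edges,
                              counts=counts, modal_thickness_mm=modal)


def summarize_regions(fld: ThicknessField,
                      regions: dict[str, np.ndarray]):
    """Min/median/max thickness per named surface region.

    ``regions`` maps region name to a boolean mask over surface elements.
    """
    import pandas as pd

    rows = []
    for name, mask in regions.items():
        sel = np.asarray(mask, dtype=bool) & fld.defined
        if not sel.any():
            raise ValueError(f"region {name!r} contains no measured elements")
        vals = fld.thickness_mm[sel]
        rows.append({"region": name, "n": int(sel.sum()),
                     "min_mm": float(vals.min()),
                     "median_mm": float(np.median(vals)),
                     "max_mm": float(vals.max())})
    return pd.DataFrame(rows).set_index("region")
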