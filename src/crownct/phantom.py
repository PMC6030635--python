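"""Synthetic three-tissue tooth-crown phantoms with known ground truth.

The generator builds a rounded, four-crested pyramidal crown as an implicit
solid: a superellipse cross-section (exponent > 2 puts crests toward the
four corners) tapering from the basal half-widths to the cusp tip.  The
pulp cavity is an inward-scaled copy of the dentine core, so it inherits
the pyramid-with-crests shape; the enamel cap is an outward offset of the
core whose thickness varies apicobasally (thin at the cusp, thicker toward
the base) and carries angularly modulated apicobasal ridges.

Per-tissue attenuation values are drawn from truncated normal
distributions centred on the modal attenuation peaks of the neutron
(0.35 pulp / 0.76 enamel / 1.15 dentine) or X-ray reconstruction, bounded
by the corresponding tissue windows.  In neutron mode the windows are
additionally truncated at the enamel-dentine (1.0399) and dentine-pulp
(0.9185) segmentation boundaries so a noiseless phantom is exactly
threshold-separable; in X-ray mode the windows overlap by construction and
no separating threshold exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .volume import (BACKGROUND, DENTINE, ENAMEL, PULP, TissueLabelMap,
                     VoxelVolume)

NEUTRON, XRAY = "neutron", "xray"


@dataclass(frozen=True)
class TissueWindow:
    """Attenuation window (low, high) and modal peak for one tissue."""

    low: float
    high: float
    peak: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("window must satisfy low < high")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.low) & (values <= self.high)


@dataclass(frozen=True)
class AttenuationModel:
    """Per-tissue attenuation windows plus inter-tissue boundaries.

    ``separable`` is True when an enamel-dentine threshold exists (neutron
    reconstruction); the X-ray windows overlap and carry no boundary.
    """

    mode: str
    enamel: TissueWindow
    dentine: TissueWindow
    pulp: TissueWindow
    enamel_dentine_boundary: float | None
    dentine_pulp_boundary: float | None
    separable: bool

    @property
    def windows(self) -> dict[str, TissueWindow]:
        return {"enamel": self.enamel, "dentine": self.dentine,
                "pulp": self.pulp}

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        """Pairs of tissues whose attenuation windows share a value range."""
        names = list(self.windows)
        out = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                wa, wb = self.windows[a], self.windows[b]
                if min(wa.high, wb.high) > max(wa.low, wb.low):
                    out.append((a, b))
        return out


def build_attenuation_model(mode: str) -> AttenuationModel:
    """Return the published attenuation windows for a reconstruction mode.

    Neutron windows are mutually separable and carry the enamel-dentine
    (1.0399) and dentine-pulp (0.9185) segmentation boundaries; X-ray
    windows overlap and are flagged non-separable.
    """
    if mode == NEUTRON:
        return AttenuationModel(
            mode=NEUTRON,
            enamel=TissueWindow(0.5199, 1.0399, 0.76),
            dentine=TissueWindow(1.0254, 1.5887, 1.15),
            pulp=TissueWindow(0.2311, 0.9243, 0.35),
            enamel_dentine_boundary=1.0399,
            dentine_pulp_boundary=0.9185,
            separable=True,
        )
    if mode == XRAY:
        return AttenuationModel(
            mode=XRAY,
            enamel=TissueWindow(0.0191, 0.0791, 0.060),
            dentine=TissueWindow(0.0722, 0.1066, 0.080),
            pulp=TissueWindow(0.0551, 0.0837, 0.070),
            enamel_dentine_boundary=None,
            dentine_pulp_boundary=None,
            separable=False,
        )
    raise ValueError(f"unknown attenuation mode {mode!r}")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic crown and its attenuation model."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: float = 0.026
    crown_height_mm: float = 2.6
    half_width_labiolingual_mm: float = 1.1
    half_width_mesiodistal_mm: float = 0.8
    apex_thickness_mm: float = 0.10
    basal_thickness_mm: float = 0.20
    ridge_amplitude_mm: float = 0.25
    ridge_count: int = 8
    pulp_scale: float = 0.66
    mode: str = NEUTRON
    noise_sd: float = 0.02
    speckle_fraction: float = 0.01
    seed: int = 0
    # shape-detail knobs (rarely changed)
    superellipse_exponent: float = 3.0
    taper_exponent: float = 0.8
    ridge_sharpness: float = 8.0
    apex_blend_start: float = 0.55
    basal_pulp_overhang_mm: float = 0.0
    background_value: float = 0.05
    thickness_scale: float = 1.0

    def validate(self) -> None:
        lengths = dict(voxel_size=self.voxel_size_mm,
                       crown_height=self.crown_height_mm,
                       half_width_labiolingual=self.half_width_labiolingual_mm,
                       half_width_mesiodistal=self.half_width_mesiodistal_mm,
                       apex_thickness=self.apex_thickness_mm,
                       basal_thickness=self.basal_thickness_mm)
        for name, value in lengths.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ridge_amplitude_mm < 0:
            raise ValueError("ridge amplitude must be non-negative")
        if self.apex_thickness_mm > self.basal_thickness_mm + self.ridge_amplitude_mm:
            raise ValueError("apex thickness exceeds basal thickness + ridge amplitude")
        if not 0 <= self.speckle_fraction < 1:
            raise ValueError("speckle fraction must lie in [0, 1)")
        if not 0 < self.pulp_scale < 1:
            raise ValueError("pulp scale must lie in (0, 1)")
        if self.mode not in (NEUTRON, XRAY):
            raise ValueError(f"unknown attenuation mode {self.mode!r}")
        if self.basal_pulp_overhang_mm < 0:
            raise ValueError("basal pulp overhang must be non-negative")
        nz, ny, nx = self.shape
        vs = self.voxel_size_mm
        margin = 2 * vs
        t_max = self.thickness_scale * (self.basal_thickness_mm
                                        + self.ridge_amplitude_mm)
        need_x = 2 * (self.half_width_labiolingual_mm + t_max) + 2 * margin
        need_y = 2 * (self.half_width_mesiodistal_mm + t_max) + 2 * margin
        need_z = self.crown_height_mm + self.thickness_scale * self.apex_thickness_mm + 2 * margin
        if nx * vs < need_x or ny * vs < need_y or nz * vs < need_z:
            raise ValueError(
                f"grid {self.shape} too small for crown plus 2-voxel margin "
                f"(needs >= {need_z / vs:.0f} x {need_y / vs:.0f} x {need_x / vs:.0f} voxels)")


@dataclass
class GroundTruth:
    """Exact labels, volumes and thickness-field parameters of a phantom."""

    labelmap: TissueLabelMap
    volumes_mm3: dict[str, float]
    spec: PhantomSpec
    close_plane_z_mm: float
    thickness_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)

    def volume_ratios(self) -> tuple[float, float, float]:
        e, d, p = (self.volumes_mm3[k] for k in ("enamel", "dentine", "pulp"))
        total = e + d + p
        return e / total, d / total, p / total


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _thickness_field(spec: PhantomSpec, theta: np.ndarray,
                     u: np.ndarray) -> np.ndarray:
    """True enamel thickness (mm) at crown angle ``theta``, height fraction ``u``.

    Constant at the basal value over the lower crown, blending to the apex
    value near the cusp; apicobasal ridges fade linearly toward the apex.
    """
    u = np.clip(u, 0.0, 1.0)
    w = _smoothstep((u - spec.apex_blend_start) / (1.0 - spec.apex_blend_start))
    base = spec.basal_thickness_mm + (spec.apex_thickness_mm
                                      - spec.basal_thickness_mm) * w
    ridge = np.maximum(np.cos(spec.ridge_count * theta), 0.0) ** spec.ridge_sharpness
    t = base + spec.ridge_amplitude_mm * (1.0 - u) * ridge
    return spec.thickness_scale * t


def _crown_geometry(spec: PhantomSpec):
    """Coordinate grids and centre/base placement for a spec."""
    nz, ny, nx = spec.shape
    vs = spec.voxel_size_mm
    z = (np.arange(nz) + 0.5)[:, None, None] * vs
    y = (np.arange(ny) + 0.5)[None, :, None] * vs
    x = (np.arange(nx) + 0.5)[None, None, :] * vs
    cx, cy = nx * vs / 2.0, ny * vs / 2.0
    z0 = 2 * vs + 0.5 * vs  # basal plane: 2-voxel margin below the crown
    return z, y, x, cx, cy, z0


def _superellipse_inside(dx, dy, a, b, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (np.abs(dx) / a) ** p + (np.abs(dy) / b) ** p
    return r <= 1.0


def generate_labels(spec: PhantomSpec) -> tuple[TissueLabelMap, GroundTruth]:
    """Build the ground-truth label map for a spec (no attenuation draw)."""
    spec.validate()
    vs = spec.voxel_size_mm
    z, y, x, cx, cy, z0 = _crown_geometry(spec)
    h = spec.crown_height_mm
    p = spec.superellipse_exponent
    min_radius = vs  # keep the tapered cross-section non-degenerate

    u = (z - z0) / h
    in_height = (u >= 0.0) & (u <= 1.0)
    taper = np.where(in_height, (1.0 - np.clip(u, 0, 1)) ** spec.taper_exponent, 0.0)
    a_u = np.maximum(spec.half_width_labiolingual_mm * taper, min_radius)
    b_u = np.maximum(spec.half_width_mesiodistal_mm * taper, min_radius)
    dx, dy = x - cx, y - cy
    core = in_height & _superellipse_inside(dx, dy, a_u, b_u, p)

    # pulp: core scaled by pulp_scale about the basal centre (x, y and z)
    s = spec.pulp_scale
    up = (z - z0) / (s * h)
    in_height_p = (up >= 0.0) & (up <= 1.0)
    taper_p = np.where(in_height_p, (1.0 - np.clip(up, 0, 1)) ** spec.taper_exponent, 0.0)
    a_p = np.maximum(spec.half_width_labiolingual_mm * taper_p, min_radius) * s
    b_p = np.maximum(spec.half_width_mesiodistal_mm * taper_p, min_radius) * s
    pulp_full = in_height_p & _superellipse_inside(dx, dy, a_p, b_p, p)
    pulp_full &= core  # cavity cannot leave the core

    close_plane_z = z0 + spec.basal_pulp_overhang_mm
    pulp = pulp_full & (z >= close_plane_z)
    cavity_below_plane = pulp_full & ~pulp

    # enamel: outward Euclidean offset of the core, thickness T(theta, u)
    dist_mm = ndimage.distance_transform_edt(~core, sampling=vs)
    theta = np.arctan2(np.broadcast_to(dy, spec.shape),
                       np.broadcast_to(dx, spec.shape))
    t_field = _thickness_field(spec, theta, np.broadcast_to(u, spec.shape))
    enamel = (~core) & (z >= close_plane_z) & (dist_mm > 0) & (dist_mm <= t_field)

    labels = np.full(spec.shape, BACKGROUND, dtype=np.uint8)
    labels[core] = DENTINE
    labels[pulp] = PULP
    # cavity infill below the closure plane is matrix, not tooth tissue
    labels[cavity_below_plane] = BACKGROUND
    labels[enamel] = ENAMEL

    labelmap = TissueLabelMap(labels, vs)
    vox = vs ** 3
    volumes = {name: count * vox for name, count in labelmap.counts().items()}
    truth = GroundTruth(labelmap=labelmap, volumes_mm3=volumes, spec=spec,
                        close_plane_z_mm=close_plane_z,
                        thickness_fn=lambda th, uu: _thickness_field(spec, th, uu))
    truth.cavity_below_plane = cavity_below_plane  # sampled as pulp infill
    return labelmap, truth


def _draw_windows(model: AttenuationModel) -> dict[int, tuple[float, float, float]]:
    """Per-tissue sampling windows (low, high, peak).

    Neutron windows are clipped at the segmentation boundaries so the
    noiseless phantom is exactly separable; X-ray windows overlap as
    published.
    """
    e, d, q = model.enamel, model.dentine, model.pulp
    if model.separable:
        ed, dp = model.enamel_dentine_boundary, model.dentine_pulp_boundary
        return {ENAMEL: (e.low, min(e.high, ed), e.peak),
                DENTINE: (max(d.low, ed), d.high, d.peak),
                PULP: (q.low, min(q.high, dp), q.peak)}
    return {ENAMEL: (e.low, e.high, e.peak),
            DENTINE: (d.low, d.high, d.peak),
            PULP: (q.low, q.high, q.peak)}


def _truncated_normal(rng, low, high, peak, size):
    sd = (high - low) / 6.0
    loc = min(max(peak, low), high)
    a, b = (low - loc) / sd, (high - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Generate a seeded synthetic crown volume and its ground truth.

    Deterministic for a fixed seed.  Tissue voxels are drawn from
    truncated normals over the tissue's sampling window; Gaussian noise of
    ``noise_sd`` is then added everywhere, and ``speckle_fraction`` of all
    voxels is replaced by uniform outliers on [0, 2 x max window high].
    """
    labelmap, truth = generate_labels(spec)
    model = build_attenuation_model(spec.mode)
    rng = np.random.default_rng(spec.seed)

    values = np.full(spec.shape, spec.background_value, dtype=np.float64)
    draw = _draw_windows(model)
    for code in (ENAMEL, DENTINE, PULP):
        mask = labelmap.labels == code
        low, high, peak = draw[code]
        values[mask] = _truncated_normal(rng, low, high, peak,
                                         int(mask.sum()))
    # matrix infill below the pulp-closure plane samples like pulp
    below = getattr(truth, "cavity_below_plane", None)
    if below is not None and below.any():
        low, high, peak = draw[PULP]
        values[below] = _truncated_normal(rng, low, high, peak,
                                          int(below.sum()))

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.speckle_fraction > 0:
        n = values.size
        k = int(round(spec.speckle_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        hi = 2.0 * max(w.high for w in model.windows.values())
        values.ravel()[idx] = rng.uniform(0.0, hi, size=k)

    # declared 16-bit range: headroom below zero for reconstruction noise
    max_window = max(w.high for w in model.windows.values())
    volume = VoxelVolume(values.astype(np.float32), spec.voxel_size_mm,
                         value_range=(-0.25 * max_window, 2.0 * max_window),
                         meta={"mode": spec.mode, "seed": spec.seed})
    return volume, truth


def calibrate_spec_to_volume_ratios(
        spec: PhantomSpec,
        target_volumes: tuple[float, float, float] = (6.60, 14.15, 5.54),
        tol: float = 0.015, max_iter: int = 8) -> PhantomSpec:
    """Tune pulp scale and enamel thickness so true tissue volumes match a ratio.

    ``target_volumes`` is (enamel, dentine, pulp); only the ratios matter.
    Pulp/dentine is controlled by the cube of the pulp scale and
    enamel/dentine scales nearly linearly with the thickness multiplier,
    so alternating one-dimensional updates converge in a few iterations.
    """
    te, td, tp = target_volumes
    r_pd = tp / td          # pulp : dentine
    r_ed = te / td          # enamel : dentine
    current = replace(spec)
    for _ in range(max_iter):
        _, truth = generate_labels(current)
        e = truth.volumes_mm3["enamel"]
        d = truth.volumes_mm3["dentine"]
        p = truth.volumes_mm3["pulp"]
        err_pd = abs(p / d - r_pd) / r_pd
        err_ed = abs(e / d - r_ed) / r_ed
        if err_pd <= tol and err_ed <= tol:
            break
        core = p + d
        frac_target = r_pd / (1.0 + r_pd)  # pulp fraction of the core
        s_new = current.pulp_scale * (frac_target / (p / core)) ** (1.0 / 3.0)
        s_new = min(max(s_new, 0.05), 0.95)
        m_new = current.thickness_scale * (r_ed / (e / d))
        current = replace(current, pulp_scale=s_new,
                          thickness_scale=float(m_new))
    return current
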