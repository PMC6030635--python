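"""Crown fracture mechanics: critical loads, resistance ratios, bite force.

The model treats the crown as a brittle enamel shell on a compliant
dentine core.  The peak force a crown sustains before a margin crack
(failure starting low on the crown under a spread load) is

    F = c * K_c * sqrt(t) * R

with tooth-shape coefficient ``c`` (dimensionless, a function of crown
height over base radius h/R), enamel fracture toughness ``K_c``
(MPa m^0.5), enamel thickness ``t`` and crown-base radius ``R`` (mm).
Inputs are accepted in mm and MPa m^0.5 and converted to SI internally;
the result is in newtons.  Radial cracks (concentrated loads flexing the
enamel on the dentine) halve the resistance irrespective of toughness.

All quantities may be given as intervals; because the load is strictly
increasing in every parameter, interval propagation by corner evaluation
is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

MARGIN, RADIAL = "margin", "radial"
_RADIAL_FACTOR = 0.5


@dataclass(frozen=True)
class Interval:
    """A closed numeric interval [low, high]; scalars are degenerate intervals."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ValueError("interval must satisfy low <= high")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    def scaled(self, k: float) -> "Interval":
        lo, hi = sorted((self.low * k, self.high * k))
        return Interval(lo, hi)


def as_interval(x) -> Interval:
    if isinstance(x, Interval):
        return x
    if isinstance(x, (tuple, list)):
        return Interval(float(x[0]), float(x[1]))
    return Interval(float(x), float(x))


@dataclass(frozen=True)
class ToothMechanicsInput:
    """Crown geometry and enamel material values (or intervals).

    R: crown-base radius (mm); h: crown height (mm); t: enamel thickness
    (mm); K_c: enamel fracture toughness (MPa m^0.5).
    """

    radius_mm: Interval
    height_mm: Interval
    thickness_mm: Interval
    toughness_mpa_sqrt_m: Interval

    def __post_init__(self) -> None:
        for name in ("radius_mm", "height_mm", "thickness_mm",
                     "toughness_mpa_sqrt_m"):
            iv = getattr(self, name)
            if iv.low <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def create(cls, radius_mm, height_mm, thickness_mm, toughness_mpa_sqrt_m):
        return cls(as_interval(radius_mm), as_interval(height_mm),
                   as_interval(thickness_mm), as_interval(toughness_mpa_sqrt_m))

    @property
    def h_over_r(self) -> Interval:
        return Interval(self.height_mm.low / self.radius_mm.high,
                        self.height_mm.high / self.radius_mm.low)


#: anchors (h/R, c low edge, c high edge): bunodont band 6-8 at h/R 0.5,
#: plateau band 50-55 from h/R 3.0 upward
DEFAULT_CURVE_ANCHORS: tuple[tuple[float, float, float], ...] = (
    (0.5, 6.0, 8.0),
    (1.9, 17.0, 17.0),
    (2.1, 36.0, 36.0),
    (2.32, 42.0, 42.0),
    (3.0, 50.0, 55.0),
)


@dataclass(frozen=True)
class ShapeCoefficientCurve:
    """Monotone piecewise-linear band c(h/R) between published anchors.

    Clamped to the bunodont band below the first anchor and to the
    hypsodont plateau at and above the last anchor.
    """

    anchors: tuple[tuple[float, float, float], ...] = DEFAULT_CURVE_ANCHORS

    def __post_init__(self) -> None:
        hr = [a[0] for a in self.anchors]
        lo = [a[1] for a in self.anchors]
        hi = [a[2] for a in self.anchors]
        if sorted(hr) != hr or len(set(hr)) != len(hr):
            raise ValueError("anchor h/R values must be strictly increasing")
        if any(b < a for a, b in zip(lo, lo[1:])) or any(b < a for a, b in zip(hi, hi[1:])):
            raise ValueError("band edges must be non-decreasing in h/R")
        if any(l <= 0 or h < l for _, l, h in self.anchors):
            raise ValueError("anchors must satisfy 0 < c_low <= c_high")

    def _edge(self, h_over_r: float, which: int) -> float:
        xs = [a[0] for a in self.anchors]
        ys = [a[which] for a in self.anchors]
        if h_over_r <= xs[0]:
            return ys[0]
        if h_over_r >= xs[-1]:
            return ys[-1]
        for (x0, x1), (y0, y1) in zip(zip(xs, xs[1:]), zip(ys, ys[1:])):
            if x0 <= h_over_r <= x1:
                f = (h_over_r - x0) / (x1 - x0)
                return y0 + f * (y1 - y0)
        raise AssertionError("unreachable")

    def __call__(self, h_over_r) -> Interval:
        iv = as_interval(h_over_r)
        if iv.low <= 0:
            raise ValueError("h/R must be strictly positive")
        return Interval(self._edge(iv.low, 1), self._edge(iv.high, 2))


def shape_coefficient(h_over_r, curve: ShapeCoefficientCurve | None = None) -> Interval:
    """Shape coefficient band for a crown aspect ratio h/R (value or interval)."""
    return (curve or ShapeCoefficientCurve())(h_over_r)


def margin_crack_load(c: float, k_c_mpa_sqrt_m: float,
                      t_mm: float, r_mm: float) -> float:
    """Peak margin-crack force (N): F = c * K_c * sqrt(t) * R in SI."""
    for name, v in dict(c=c, K_c=k_c_mpa_sqrt_m, t=t_mm, R=r_mm).items():
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    k_c = k_c_mpa_sqrt_m * 1e6          # Pa m^0.5
    t = t_mm * 1e-3                     # m
    r = r_mm * 1e-3                     # m
    return c * k_c * math.sqrt(t) * r


def radial_crack_load(c: float, k_c_mpa_sqrt_m: float,
                      t_mm: float, r_mm: float) -> float:
    """Radial-crack force: exactly half the margin-crack load."""
    return _RADIAL_FACTOR * margin_crack_load(c, k_c_mpa_sqrt_m, t_mm, r_mm)


@dataclass(frozen=True)
class CriticalLoadRange:
    """Propagated critical-load interval (N) for one crack mode."""

    mode: str
    load: Interval
    corner_low: dict = field(default_factory=dict)
    corner_high: dict = field(default_factory=dict)

    @property
    def low(self) -> float:
        return self.load.low

    @property
    def high(self) -> float:
        return self.load.high


def critical_load_range(geometry: ToothMechanicsInput, c,
                        mode: str = MARGIN) -> CriticalLoadRange:
    """Evaluate the load over all corners of the (c, K_c, t, R) box.

    The load is strictly increasing in each parameter, so the endpoints
    are attained at the all-low and all-high corners; this is asserted
    against the exhaustive corner evaluation.
    """
    if mode not in (MARGIN, RADIAL):
        raise ValueError(f"unknown crack mode {mode!r}")
    fn = margin_crack_load if mode == MARGIN else radial_crack_load
    c_iv = as_interval(c)
    axes = {"c": c_iv, "K_c": geometry.toughness_mpa_sqrt_m,
            "t": geometry.thickness_mm, "R": geometry.radius_mm}
    corners = []
    for combo in product(*[(iv.low, iv.high) for iv in axes.values()]):
        params = dict(zip(axes, combo))
        corners.append((params, fn(params["c"], params["K_c"],
                                   params["t"], params["R"])))
    lo_corner, lo = min(corners, key=lambda cv: cv[1])
    hi_corner, hi = max(corners, key=lambda cv: cv[1])
    all_low = fn(c_iv.low, geometry.toughness_mpa_sqrt_m.low,
                 geometry.thickness_mm.low, geometry.radius_mm.low)
    all_high = fn(c_iv.high, geometry.toughness_mpa_sqrt_m.high,
                  geometry.thickness_mm.high, geometry.radius_mm.high)
    assert math.isclose(lo, all_low, rel_tol=1e-12), "monotonicity violated"
    assert math.isclose(hi, all_high, rel_tol=1e-12), "monotonicity violated"
    return CriticalLoadRange(mode=mode, load=Interval(lo, hi),
                             corner_low=lo_corner, corner_high=hi_corner)


def resistance_ratio(target: Interval | CriticalLoadRange,
                     reference: Interval | CriticalLoadRange
                     ) -> tuple[float, float]:
    """Endpoint ratios (target low / reference low, target high / reference high)."""
    t = target.load if isinstance(target, CriticalLoadRange) else as_interval(target)
    r = reference.load if isinstance(reference, CriticalLoadRange) else as_interval(reference)
    if r.low <= 0 or r.high <= 0:
        raise ZeroDivisionError("reference range endpoints must be positive")
    return t.low / r.low, t.high / r.high


@dataclass(frozen=True)
class BiteForcePrediction:
    """Bite force extrapolated from a reference taxon's load-to-bite ratios."""

    reference_bite_n: float
    reference_range: Interval
    ratio_to_highest: float
    ratio_to_lowest: float
    predicted: Interval


def extrapolate_bite_force(reference_bite_n: float,
                           reference_range, target_range) -> BiteForcePrediction:
    """Scale a measured bite force by critical-load endpoint ratios.

    The conservative (ratio-to-highest) multiplier applied to the target
    high endpoint gives the predicted low bound; the ratio-to-lowest
    multiplier applied to the target low endpoint gives the high bound.
    When target equals reference the prediction collapses to the
    reference bite force.
    """
    ref = reference_range.load if isinstance(reference_range, CriticalLoadRange) \
        else as_interval(reference_range)
    tgt = target_range.load if isinstance(target_range, CriticalLoadRange) \
        else as_interval(target_range)
    if reference_bite_n <= 0:
        raise ValueError("reference bite force must be positive")
    if ref.low <= 0 or ref.high <= 0 or tgt.low <= 0 or tgt.high <= 0:
        raise ValueError("range endpoints must be positive")
    r_hi = reference_bite_n / ref.high
    r_lo = reference_bite_n / ref.low
    predicted = Interval(r_hi * tgt.high, r_lo * tgt.low) \
        if r_hi * tgt.high <= r_lo * tgt.low \
        else Interval(r_lo * tgt.low, r_hi * tgt.high)
    return BiteForcePrediction(reference_bite_n=reference_bite_n,
                               reference_range=ref,
                               ratio_to_highest=r_hi, ratio_to_lowest=r_lo,
                               predicted=predicted)


def geometry_from_measurements(labiolingual_width_mm: float,
                               mesiodistal_length_mm: float,
                               height_mm: float,
                               radius_mm=None) -> dict:
    """Crown-base radius and aspect ratio from linear crown dimensions.

    R defaults to the mean of the two half-widths; pass ``radius_mm`` (a
    value or interval) to override, e.g. to carry measurement uncertainty
    into h/R.
    """
    for name, v in dict(labiolingual=labiolingual_width_mm,
                        mesiodistal=mesiodistal_length_mm,
                        height=height_mm).items():
        if v <= 0:
            raise ValueError(f"{name} dimension must be strictly positive")
    if radius_mm is None:
        r = Interval(*(2 * [(labiolingual_width_mm / 2
                             + mesiodistal_length_mm / 2) / 2]))
    else:
        r = as_interval(radius_mm)
    h = as_interval(height_mm)
    h_over_r = Interval(h.low / r.high, h.high / r.low)
    return {"radius_mm": r, "height_mm": h, "h_over_r": h_over_r}
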