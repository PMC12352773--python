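"""Percentage-depth-dose (PDD) normalization and beam-quality metric extraction.

For a 6 MeV electron beam the depth-dose curve rises through a short buildup,
peaks at R100 (~14 mm for clinical field sizes), falls steeply through the
therapeutic range and levels off on a small bremsstrahlung tail.  The metrics
extracted here are the standard electron beam-quality descriptors:

R100
    depth of maximum dose, refined parabolically through the peak sample and
    its neighbours (a flat plateau of equal maxima reports its midpoint).
R90 / R70 / R50
    distal-side depths where the normalized curve crosses 90 / 70 / 50 %,
    located by linear interpolation between bracketing samples.  R50 defines
    electron beam quality.  The buildup side also crosses these levels; by
    dosimetric convention only crossings beyond R100 count.
Rp (practical range)
    depth where the tangent through the steepest point of the distal falloff
    intersects the straight-line extrapolation of the bremsstrahlung tail.
half-R90
    R90 / 2, a standard intermediate profile-measurement depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import ScanCurve, ValidationError

__all__ = [
    "PddMetrics",
    "normalize_pdd",
    "extract_pdd_metrics",
    "pdd_at_depth",
    "RangeUndefinedError",
]


class RangeUndefinedError(ValueError):
    """A requested range metric does not exist on this curve."""


@dataclass(frozen=True)
class PddMetrics:
    """Beam-quality depths (mm) extracted from one depth-dose curve.

    ``rp_mm`` is ``None`` when the curve has no usable bremsstrahlung-tail
    samples to anchor the practical-range construction.
    """

    r100_mm: float
    r90_mm: float
    r70_mm: float
    r50_mm: float
    rp_mm: Optional[float]
    half_r90_mm: float

    def __post_init__(self) -> None:
        if not (self.r100_mm < self.r90_mm < self.r70_mm < self.r50_mm):
            raise ValidationError(
                "expected r100 < r90 < r70 < r50, got "
                f"{self.r100_mm}, {self.r90_mm}, {self.r70_mm}, {self.r50_mm}"
            )
        if self.rp_mm is not None and self.rp_mm <= self.r50_mm:
            raise ValidationError(f"rp ({self.rp_mm}) must exceed r50 ({self.r50_mm})")


def half_r90(r90_mm: float) -> float:
    """Half of R90, the shallowest standard profile-measurement depth."""
    return r90_mm / 2.0


def normalize_pdd(curve: ScanCurve) -> ScanCurve:
    """Scale a depth-dose curve so its maximum is exactly 100.

    Positions are unchanged; an all-zero curve is rejected.
    """
    _require_depth(curve)
    peak = float(np.max(curve.doses))
    if peak <= 0:
        raise ValidationError("cannot normalize an all-zero depth-dose curve")
    return curve.with_doses(curve.doses * (100.0 / peak))


def pdd_at_depth(curve: ScanCurve, depth_mm: float) -> float:
    """PDD (%) at a depth, by linear interpolation on the normalized curve.

    Raises if the depth lies outside the sampled range: depth-dose data are
    never extrapolated.
    """
    _require_depth(curve)
    z = curve.positions
    if depth_mm < z[0] or depth_mm > z[-1]:
        raise RangeUndefinedError(
            f"depth {depth_mm} mm outside sampled range [{z[0]}, {z[-1]}] mm"
        )
    norm = normalize_pdd(curve)
    return float(np.interp(depth_mm, norm.positions, norm.doses))


def extract_pdd_metrics(curve: ScanCurve) -> PddMetrics:
    """Extract R100, R90, R70, R50, Rp and half-R90 from a depth-dose curve.

    The curve is normalized internally, so all metrics are invariant under
    positive rescaling of the doses.
    """
    norm = normalize_pdd(curve)
    z = norm.positions
    d = norm.doses

    r100 = _depth_of_maximum(z, d)
    r90 = _distal_crossing(z, d, 90.0, r100)
    r70 = _distal_crossing(z, d, 70.0, r100)
    r50 = _distal_crossing(z, d, 50.0, r100)
    rp = _practical_range(z, d, r100)
    return PddMetrics(
        r100_mm=r100,
        r90_mm=r90,
        r70_mm=r70,
        r50_mm=r50,
        rp_mm=rp,
        half_r90_mm=half_r90(r90),
    )


# ---------------------------------------------------------------------------


def _require_depth(curve: ScanCurve) -> None:
    if curve.axis != "depth":
        raise ValidationError(f"expected a depth scan, got axis={curve.axis!r}")


def _depth_of_maximum(z: np.ndarray, d: np.ndarray) -> float:
    """Peak depth with parabolic refinement; plateau of equal maxima -> midpoint."""
    peak = np.max(d)
    at_peak = np.flatnonzero(d == peak)
    if at_peak.size > 1:
        return float(0.5 * (z[at_peak[0]] + z[at_peak[-1]]))
    i = int(at_peak[0])
    if i == 0 or i == d.size - 1:
        return float(z[i])
    # Lagrange parabola through (z[i-1..i+1], d[i-1..i+1]); vertex abscissa.
    z0, z1, z2 = z[i - 1 : i + 2]
    d0, d1, d2 = d[i - 1 : i + 2]
    denom = (z0 - z1) * (z0 - z2) * (z1 - z2)
    a = (z2 * (d1 - d0) + z1 * (d0 - d2) + z0 * (d2 - d1)) / denom
    b = (z2**2 * (d0 - d1) + z1**2 * (d2 - d0) + z0**2 * (d1 - d2)) / denom
    if a >= 0:  # degenerate / non-concave neighbourhood: keep the sample
        return float(z[i])
    vertex = -b / (2 * a)
    if not (z0 <= vertex <= z2):
        return float(z[i])
    return float(vertex)


def _distal_crossing(z: np.ndarray, d: np.ndarray, level: float, r100: float) -> float:
    """First downward crossing of `level` beyond the depth of maximum."""
    distal = z >= r100
    zi, di = z[distal], d[distal]
    if zi.size == 0 or np.min(di) >= level:
        raise RangeUndefinedError(f"curve never falls below {level}% distally")
    below = np.flatnonzero(di < level)
    j = below[0]
    if j == 0:
        # maximum itself below level cannot happen for level < 100 on a
        # normalized curve unless the peak sits at the last sample
        return float(zi[0])
    z_lo, z_hi = zi[j - 1], zi[j]
    d_lo, d_hi = di[j - 1], di[j]
    return float(z_lo + (d_lo - level) * (z_hi - z_lo) / (d_lo - d_hi))


def _practical_range(z: np.ndarray, d: np.ndarray, r100: float) -> Optional[float]:
    """Tangent-through-inflection construction of the practical range Rp.

    The distal falloff is smoothed with a 3-point moving average; the tangent
    is taken at the sample of steepest negative finite-difference gradient
    beyond R100.  The bremsstrahlung tail is a least-squares line through the
    samples beyond the depth where the dose first falls below
    (tail estimate + 5) percent; Rp is the tangent/tail intersection.
    Returns None (with a warning) when fewer than two tail samples exist.
    """
    if d.size < 5:
        warnings.warn("too few samples for a practical-range construction")
        return None
    smooth = d.copy()
    smooth[1:-1] = (d[:-2] + d[1:-1] + d[2:]) / 3.0

    grad = np.gradient(smooth, z)
    distal = np.flatnonzero(z > r100)
    if distal.size < 3:
        warnings.warn("no distal falloff samples; practical range undefined")
        return None
    i_inf = distal[np.argmin(grad[distal])]
    slope = grad[i_inf]
    if slope >= 0:
        warnings.warn("no negative distal gradient; practical range undefined")
        return None
    z_inf, d_inf = z[i_inf], smooth[i_inf]

    # tail level estimate: median of the last samples (at most 5)
    tail_est = float(np.median(smooth[-min(5, d.size) :]))
    threshold = tail_est + 5.0
    past = np.flatnonzero((z > z_inf) & (smooth < threshold))
    if past.size < 2:
        warnings.warn("no distal tail samples; practical range reported absent")
        return None
    zt, dt = z[past], smooth[past]
    b_slope, b_icpt = np.polyfit(zt, dt, 1)

    denom = slope - b_slope
    if denom == 0:
        warnings.warn("tangent parallel to tail; practical range undefined")
        return None
    rp = (b_icpt - (d_inf - slope * z_inf)) / denom
    if not np.isfinite(rp) or rp <= z_inf:
        warnings.warn("degenerate tangent/tail intersection; practical range undefined")
        return None
    return float(rp)
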