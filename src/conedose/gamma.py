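"""Gamma-index comparison of 1D scan curves and 2D planar dose distributions.

The gamma index combines a dose-difference criterion (percent of a
normalization dose) with a distance-to-agreement (DTA, mm).  For a reference
point r the evaluated distribution is searched in a neighbourhood for the
best compromise between spatial offset and dose deviation:

    gamma(r) = min over e of sqrt( (|x_e - x_r| / dta)^2
                                 + ((D_e - D_r) / (p/100 * D_norm))^2 )

A point passes when gamma <= 1; the pass rate is the passing fraction of the
evaluated points.  Points below a low-dose cutoff are excluded from the pass
rate, as is standard for small fields whose planes are dominated by
out-of-field area.

Defaults follow commercial water-tank/film analysis software: global
normalization to the reference distribution's maximum, 10 % low-dose cutoff,
search radius 3 x DTA, interpolation step DTA/10.  Local-dose gamma is
available as an option but is never the default.  Gamma is asymmetric in
(reference, evaluated); callers fix the reference arm explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .io import DoseGrid, ScanCurve, ValidationError

__all__ = ["GammaCriteria", "GammaResult", "gamma_1d", "gamma_2d"]


@dataclass(frozen=True)
class GammaCriteria:
    """Acceptance criterion and evaluation settings for a gamma comparison.

    dose_percent / dta_mm: the criterion, e.g. 3 %/3 mm.
    normalization: 'global_max' (reference maximum) or 'global_prescribed'
    (a caller-supplied ``prescribed_dose``); ``local=True`` switches the dose
    denominator to the local reference dose (the cutoff still uses the
    global value).
    """

    dose_percent: float
    dta_mm: float
    low_dose_cutoff_percent: float = 10.0
    normalization: str = "global_max"
    prescribed_dose: Optional[float] = None
    local: bool = False
    search_radius_factor: float = 3.0
    step_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0:
            raise ValidationError("dose and DTA criteria must be positive")
        if self.low_dose_cutoff_percent < 0:
            raise ValidationError("low-dose cutoff must be nonnegative")
        if self.normalization not in ("global_max", "global_prescribed"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "global_prescribed" and (
            self.prescribed_dose is None or self.prescribed_dose <= 0
        ):
            raise ValidationError("global_prescribed normalization needs prescribed_dose > 0")
        if self.search_radius_factor <= 0 or not 0 < self.step_fraction <= 1:
            raise ValidationError("invalid search-grid settings")


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma values and pass rate for one comparison."""

    gamma_values: np.ndarray
    pass_rate_percent: float
    n_evaluated: int
    criteria: GammaCriteria
    gamma_map: Optional[np.ndarray] = None  # 2D map with NaN at excluded points


def _offset_axis(criteria: GammaCriteria) -> np.ndarray:
    """Search offsets, exactly symmetric with an exact zero sample."""
    step = criteria.dta_mm * criteria.step_fraction
    n = int(round(criteria.search_radius_factor / criteria.step_fraction))
    return step * np.arange(-n, n + 1)


def _normalization_dose(ref_doses: np.ndarray, criteria: GammaCriteria) -> float:
    if criteria.normalization == "global_prescribed":
        return float(criteria.prescribed_dose)
    return float(np.max(ref_doses))


def _finish(gammas: np.ndarray, criteria: GammaCriteria,
            gamma_map: Optional[np.ndarray] = None) -> GammaResult:
    if gammas.size == 0:
        raise ValidationError("low-dose cutoff excluded every reference point")
    pass_rate = 100.0 * float(np.count_nonzero(gammas <= 1.0)) / gammas.size
    return GammaResult(
        gamma_values=gammas,
        pass_rate_percent=pass_rate,
        n_evaluated=int(gammas.size),
        criteria=criteria,
        gamma_map=gamma_map,
    )


def gamma_1d(reference: ScanCurve, evaluated: ScanCurve,
             criteria: GammaCriteria) -> GammaResult:
    """Gamma of a 1D evaluated curve against a 1D reference curve.

    The evaluated curve is linearly interpolated on a search grid of step
    ``dta * step_fraction`` within ``search_radius_factor * dta`` of each
    reference point.  Reference points outside the evaluated curve's
    positional range are not evaluated.
    """
    if reference.axis != evaluated.axis:
        raise ValidationError("reference and evaluated curves measure different axes")
    xr, dr = reference.positions, reference.doses
    xe, de = evaluated.positions, evaluated.doses
    lo, hi = max(xr[0], xe[0]), min(xr[-1], xe[-1])
    if lo >= hi:
        raise ValidationError("reference and evaluated curves do not overlap")

    d_norm = _normalization_dose(dr, criteria)
    cutoff = criteria.low_dose_cutoff_percent / 100.0 * d_norm
    keep = (dr >= cutoff) & (xr >= xe[0]) & (xr <= xe[-1])
    xr_k, dr_k = xr[keep], dr[keep]
    if xr_k.size == 0:
        raise ValidationError("low-dose cutoff excluded every reference point")

    offsets = _offset_axis(criteria)

    # (n_points, n_offsets) candidate positions, clipped to the evaluated range
    cand = xr_k[:, None] + offsets[None, :]
    valid = (cand >= xe[0]) & (cand <= xe[-1])
    de_cand = np.interp(np.clip(cand, xe[0], xe[-1]), xe, de)

    dose_tol = criteria.dose_percent / 100.0 * (
        dr_k[:, None] if criteria.local else d_norm
    )
    g2 = (offsets[None, :] / criteria.dta_mm) ** 2 + (
        (de_cand - dr_k[:, None]) / dose_tol
    ) ** 2
    g2 = np.where(valid, g2, np.inf)
    gammas = np.sqrt(np.min(g2, axis=1))
    return _finish(gammas, criteria)


def gamma_2d(reference: DoseGrid, evaluated: DoseGrid,
             criteria: GammaCriteria) -> GammaResult:
    """Gamma of a 2D evaluated plane against a 2D reference plane.

    Grids need not share spacing or origin.  The evaluated plane is
    bilinearly interpolated on a disc of radius ``search_radius_factor *
    dta`` sampled at step ``dta * step_fraction`` around each reference
    point; the per-point minimisation is chunked over offsets to bound
    memory.  The returned ``gamma_map`` has the reference grid's shape with
    NaN at excluded (below-cutoff or out-of-overlap) points.
    """
    rrows, rcols = reference.axis_coords()
    erows, ecols = evaluated.axis_coords()
    if rrows[-1] < erows[0] or erows[-1] < rrows[0] or \
            rcols[-1] < ecols[0] or ecols[-1] < rcols[0]:
        raise ValidationError("reference and evaluated grids do not overlap")

    dr = reference.values
    d_norm = _normalization_dose(dr, criteria)
    cutoff = criteria.low_dose_cutoff_percent / 100.0 * d_norm

    rr, cc = np.meshgrid(rrows, rcols, indexing="ij")
    inside = (
        (dr >= cutoff)
        & (rr >= erows[0]) & (rr <= erows[-1])
        & (cc >= ecols[0]) & (cc <= ecols[-1])
    )
    pts = np.column_stack([rr[inside], cc[inside]])
    dref = dr[inside]
    if pts.shape[0] == 0:
        raise ValidationError("low-dose cutoff excluded every reference point")

    radius = criteria.search_radius_factor * criteria.dta_mm
    axis = _offset_axis(criteria)
    orow, ocol = np.meshgrid(axis, axis, indexing="ij")
    disc = orow**2 + ocol**2 <= radius**2 + 1e-12
    offsets = np.column_stack([orow[disc], ocol[disc]])
    dist2 = (offsets[:, 0] ** 2 + offsets[:, 1] ** 2) / criteria.dta_mm**2

    interp = RegularGridInterpolator(
        (erows, ecols), evaluated.values, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    dose_tol = criteria.dose_percent / 100.0 * (dref if criteria.local else d_norm)

    best = np.full(pts.shape[0], np.inf)
    chunk = max(1, int(4e6 // max(pts.shape[0], 1)))
    for start in range(0, offsets.shape[0], chunk):
        off = offsets[start : start + chunk]
        cand = pts[None, :, :] + off[:, None, :]  # (n_off, n_pts, 2)
        de = interp(cand.reshape(-1, 2)).reshape(off.shape[0], -1)
        g2 = dist2[start : start + chunk, None] + ((de - dref[None, :]) / dose_tol) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        np.minimum(best, np.min(g2, axis=0), out=best)
    gammas = np.sqrt(best)

    gamma_map = np.full(dr.shape, np.nan)
    gamma_map[inside] = gammas
    return _finish(gammas, criteria, gamma_map=gamma_map)
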