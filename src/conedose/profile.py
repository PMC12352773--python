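"""Transverse beam-profile analysis: field size (FWHM) and 80-20 % penumbras.

Field size is measured at 50 % of the central-axis dose; each penumbra is the
lateral distance over which the central-axis-normalized profile falls from
80 % to 20 % on its edge.  Crossings are located by scanning outward from the
central axis with linear interpolation between bracketing samples, which makes
the result deterministic under tail ripple: the innermost crossing on each
side wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import ScanCurve, ValidationError

__all__ = ["ProfileMetrics", "extract_profile_metrics", "normalize_profile"]


class FieldSizeUndefinedError(ValueError):
    """The profile never drops below the field-defining 50 % level."""


@dataclass(frozen=True)
class ProfileMetrics:
    """Field size and penumbra widths (mm) of one transverse profile.

    ``cax_dose`` is the (unnormalized) dose interpolated at position 0.
    Penumbras are ``None`` when the profile never reaches 20 % on that side.
    """

    fwhm_mm: float
    penumbra_left_mm: Optional[float]
    penumbra_right_mm: Optional[float]
    cax_dose: float

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValidationError(f"fwhm must be positive, got {self.fwhm_mm}")
        for side, p in (("left", self.penumbra_left_mm), ("right", self.penumbra_right_mm)):
            if p is not None and p <= 0:
                raise ValidationError(f"{side} penumbra must be positive, got {p}")


def _require_profile(curve: ScanCurve) -> None:
    if curve.axis not in ("inplane", "crossplane"):
        raise ValidationError(f"expected a profile scan, got axis={curve.axis!r}")


def _cax_dose(curve: ScanCurve) -> float:
    x = curve.positions
    if x[0] > 0 or x[-1] < 0:
        raise ValidationError("no samples bracketing the central axis (x = 0)")
    return float(np.interp(0.0, x, curve.doses))


def normalize_profile(curve: ScanCurve, mode: str = "cax") -> ScanCurve:
    """Scale a profile so the reference dose equals 100.

    mode='cax' normalizes to the dose interpolated at the central axis
    (x = 0); mode='max' to the profile maximum.
    """
    _require_profile(curve)
    if mode == "cax":
        ref = _cax_dose(curve)
    elif mode == "max":
        ref = float(np.max(curve.doses))
    else:
        raise ValueError(f"mode must be 'cax' or 'max', got {mode!r}")
    if ref <= 0:
        raise ValidationError("reference dose for profile normalization must be positive")
    return curve.with_doses(curve.doses * (100.0 / ref))


def extract_profile_metrics(curve: ScanCurve) -> ProfileMetrics:
    """Extract FWHM and 80-20 % penumbras from a transverse profile.

    The profile is normalized to 100 % on the central axis; all levels
    (50, 80, 20 %) refer to that normalization, not to local edge maxima.
    """
    _require_profile(curve)
    cax = _cax_dose(curve)
    norm = normalize_profile(curve, mode="cax")
    x, d = norm.positions, norm.doses
    i_cax = int(np.searchsorted(x, 0.0))
    i_cax = min(max(i_cax, 0), x.size - 1)

    x50_r = _outward_crossing(x, d, 50.0, i_cax, direction=+1)
    x50_l = _outward_crossing(x, d, 50.0, i_cax, direction=-1)
    if x50_r is None or x50_l is None:
        raise FieldSizeUndefinedError("profile never drops below 50% of the central axis dose")
    fwhm = x50_r - x50_l

    pen_left = _penumbra(x, d, i_cax, direction=-1)
    pen_right = _penumbra(x, d, i_cax, direction=+1)
    return ProfileMetrics(
        fwhm_mm=float(fwhm),
        penumbra_left_mm=pen_left,
        penumbra_right_mm=pen_right,
        cax_dose=cax,
    )


def _outward_crossing(
    x: np.ndarray, d: np.ndarray, level: float, i_start: int, direction: int
) -> Optional[float]:
    """Innermost downward crossing of `level`, scanning outward from i_start."""
    idx = range(i_start, x.size - 1) if direction > 0 else range(i_start, 0, -1)
    for i in idx:
        j = i + 1 if direction > 0 else i - 1
        if d[i] >= level > d[j]:
            return float(x[i] + (d[i] - level) * (x[j] - x[i]) / (d[i] - d[j]))
    return None


def _penumbra(x: np.ndarray, d: np.ndarray, i_cax: int, direction: int) -> Optional[float]:
    x80 = _outward_crossing(x, d, 80.0, i_cax, direction)
    x20 = _outward_crossing(x, d, 20.0, i_cax, direction)
    if x80 is None:
        raise FieldSizeUndefinedError("profile never drops below 80% of the central axis dose")
    if x20 is None:
        side = "right" if direction > 0 else "left"
        warnings.warn(f"profile never reaches 20% on the {side} side; penumbra absent")
        return None
    return abs(x20 - x80)
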