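"""Electron output factors, applicator percent differences and relative OFs.

The output factor Se(ra, SSD) is the ratio of dose per monitor unit at the
depth of maximum for a small field ra to that of the 10 x 10 cm reference
field, per TG-70.  Two applicator types are compared: a circular cerrobend
cutout in a standard applicator (C) and a fixed-size stainless-steel cone (FC).

Two percent-difference conventions exist for (OF_C - OF_FC) and they do not
agree numerically: dividing by OF_FC (the typeset equation form) or by OF_C
(the form the benchmark table values follow).  Both are implemented; the
denominator must be named at every call site and defaults to 'c'.

The relative output factor OF_relative = OF_FC / OF_C at the same field size
and SSD is the scaling factor of the indirect monitor-unit method (see
:mod:`conedose.mu`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError

__all__ = [
    "OutputFactorRecord",
    "RelativeOf",
    "compute_output_factor",
    "percent_of_difference",
    "relative_of",
    "summarize_of_differences",
]


@dataclass(frozen=True)
class OutputFactorRecord:
    """One measured output factor Se for (applicator, field diameter, SSD)."""

    applicator: str  # 'cutout' or 'fixed_cone'
    field_diameter_cm: float
    ssd_cm: float
    se: float

    def __post_init__(self) -> None:
        if self.applicator not in ("cutout", "fixed_cone"):
            raise ValidationError(f"unknown applicator {self.applicator!r}")
        if not 0 < self.se <= 1.2:
            raise ValidationError(f"output factor {self.se} outside plausible range (0, 1.2]")


@dataclass(frozen=True)
class RelativeOf:
    """Fixed-cone-to-cutout output-factor ratio at one (field, SSD)."""

    field_diameter_cm: float
    ssd_cm: float
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(f"relative OF must be positive, got {self.value}")


def compute_output_factor(dose_per_mu_field: float, dose_per_mu_ref: float) -> float:
    """Output factor Se: dose/MU at R100 of the field over that of the reference.

    Both doses must be per identical monitor units, each at its own depth of
    maximum.
    """
    if dose_per_mu_field <= 0 or dose_per_mu_ref <= 0:
        raise ValidationError("dose per MU values must be positive")
    return dose_per_mu_field / dose_per_mu_ref


def percent_of_difference(of_c: float, of_fc: float, denominator: str = "c") -> float:
    """Percent difference between cutout and fixed-cone output factors.

    denominator='fc' computes 100*(OF_C - OF_FC)/OF_FC; denominator='c'
    computes 100*(OF_C - OF_FC)/OF_C.  The conventions differ by tens of
    percent for small fields; 'c' is the default because it is the one the
    benchmark difference values follow.
    """
    if denominator not in ("c", "fc"):
        raise ValueError(f"denominator must be 'c' or 'fc', got {denominator!r}")
    denom = of_c if denominator == "c" else of_fc
    if denom <= 0:
        raise ValidationError("denominator output factor must be positive")
    return 100.0 * (of_c - of_fc) / denom


def relative_of(of_fc: float, of_c: float, field_diameter_cm: float = float("nan"),
                ssd_cm: float = float("nan")) -> RelativeOf:
    """Relative output factor OF_FC / OF_C for the same field size and SSD."""
    if of_c <= 0:
        raise ValidationError("cutout output factor must be positive")
    if of_fc <= 0:
        raise ValidationError("fixed-cone output factor must be positive")
    return RelativeOf(field_diameter_cm=field_diameter_cm, ssd_cm=ssd_cm,
                      value=of_fc / of_c)


def summarize_of_differences(differences) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of OF percent differences.

    Used to aggregate the per-SSD differences of one field size.
    """
    values = np.asarray(list(differences), dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a mean +/- SD summary")
    return float(np.mean(values)), float(np.std(values, ddof=1))
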