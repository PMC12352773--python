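"""TG-71 electron monitor-unit calculation, direct and indirect.

Direct (TG-71)
    MU = D * 100 / (D0' * PDD(d, ra, SSD0) * Se(ra, SSD0))
    with D the prescribed dose (cGy), D0' the reference output (cGy/MU at
    calibration, 1.0 by convention here), PDD the percentage depth dose at
    the prescription depth, and Se the field's output factor.

Indirect (relative-OF scaling)
    A fixed-size cone applicator that a planning system cannot model is
    handled by planning the equivalent cerrobend-cutout field in the TPS and
    scaling its monitor units by the relative output factor:
    MU_FC = MU_C_from_TPS / OF_relative,   OF_relative = OF_FC / OF_C.

Monitor units are rounded to the nearest integer, halves away from zero,
matching how a treatment console accepts them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .io import ValidationError
from .output_factors import RelativeOf

__all__ = [
    "MuInput",
    "MuResult",
    "mu_tg71",
    "mu_indirect",
    "percent_mu_difference",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class MuInput:
    """Operands of the TG-71 electron MU equation.

    ref_dose_per_mu_cGy is D0', the dose per monitor unit delivered at the
    reference calibration point (defaults to 1 cGy/MU, the standard linac
    calibration).
    """

    prescribed_dose_cGy: float
    pdd_percent: float
    se: float
    ref_dose_per_mu_cGy: float = 1.0
    depth_mm: Optional[float] = None
    field_diameter_cm: Optional[float] = None
    ssd_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.prescribed_dose_cGy <= 0:
            raise ValidationError("prescribed dose must be positive")
        if self.ref_dose_per_mu_cGy <= 0:
            raise ValidationError("reference dose per MU must be positive")
        if not 0 < self.pdd_percent <= 100:
            raise ValidationError(f"PDD percent must be in (0, 100], got {self.pdd_percent}")
        if self.se <= 0:
            raise ValidationError("output factor must be positive")


@dataclass(frozen=True)
class MuResult:
    """Monitor units with provenance of the calculation that produced them."""

    mu_exact: float
    mu_rounded: int
    method: str  # 'tg71_direct' | 'indirect_relative_of' | 'tps_external'
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu_exact <= 0:
            raise ValidationError("monitor units must be positive")
        if abs(self.mu_exact - self.mu_rounded) > 0.5 + 1e-9:
            raise ValidationError("rounded MU inconsistent with exact MU")


def mu_tg71(inp: MuInput) -> MuResult:
    """Direct TG-71 electron monitor units from measured PDD and output factor."""
    mu = inp.prescribed_dose_cGy * 100.0 / (
        inp.ref_dose_per_mu_cGy * inp.pdd_percent * inp.se
    )
    return MuResult(
        mu_exact=mu,
        mu_rounded=_round_half_away(mu),
        method="tg71_direct",
        provenance={
            "D_cGy": inp.prescribed_dose_cGy,
            "D0_cGy_per_MU": inp.ref_dose_per_mu_cGy,
            "pdd_percent": inp.pdd_percent,
            "se": inp.se,
        },
    )


def mu_indirect(mu_c_from_tps: float, of_relative: Union[RelativeOf, float]) -> MuResult:
    """Indirect fixed-cone monitor units: TPS cutout MU scaled by the relative OF."""
    ratio = of_relative.value if isinstance(of_relative, RelativeOf) else float(of_relative)
    if ratio <= 0:
        raise ValidationError("relative output factor must be positive")
    if mu_c_from_tps <= 0:
        raise ValidationError("TPS monitor units must be positive")
    mu = mu_c_from_tps / ratio
    return MuResult(
        mu_exact=mu,
        mu_rounded=_round_half_away(mu),
        method="indirect_relative_of",
        provenance={"mu_c_from_tps": mu_c_from_tps, "of_relative": ratio},
    )


def percent_mu_difference(mu_a: float, mu_b: float) -> float:
    """100 * (mu_a - mu_b) / mu_b; mu_b is the comparison basis."""
    if mu_b <= 0:
        raise ValidationError("comparison-basis MU must be positive")
    return 100.0 * (mu_a - mu_b) / mu_b
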