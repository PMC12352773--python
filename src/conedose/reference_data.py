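"""Packaged benchmark dataset: 6 MeV small-field electron applicator study.

Scalar results of a published two-applicator comparison measured with a
microdiamond detector in a water phantom on an Elekta linac: a circular
cerrobend cutout in the standard 6 cm applicator ('cutout', C) versus a
fixed-size stainless-steel cone applicator ('fixed_cone', FC), at circular
field diameters 2, 3, 4 and 5 cm and SSDs 95, 100 and 105 cm.

These values serve three roles:

* calibration targets for the synthetic beam generator
  (:mod:`conedose.synth`), so generated data reproduce the study's metric
  magnitudes;
* fixtures for the end-to-end pipeline tests;
* operands for the monitor-unit worked examples (prescription: 500 cGy at
  14 mm depth, SSD 100 cm, reference output 1 cGy/MU).

Known transcription quirks of the source table are preserved, not repaired:
the 5 cm output-factor difference cells at SSD 100/105 cm are not
reproducible from the tabulated output factors under either percent-
difference convention and are flagged ``diff_consistent=False``; some
monitor-unit rows round inconsistently and are flagged ``mu_exact_round``.
"""

from __future__ import annotations

import pandas as pd

FIELDS_CM = (2.0, 3.0, 4.0, 5.0)
SSDS_CM = (95.0, 100.0, 105.0)

#: prescription used throughout the monitor-unit comparison
PRESCRIPTION = {"dose_cGy": 500.0, "depth_mm": 14.0, "ssd0_cm": 100.0,
                "ref_dose_per_mu_cGy": 1.0}

# --------------------------------------------------------------------------
# Beam quality vs field size and SSD: R100 / R50 / Rp in mm.
# Keys: (applicator, field_cm, ssd_cm); applicator 'reference' is 10x10 cm.

BEAM_QUALITY_MM = {
    # (app, field, ssd): (r100, r50, rp)
    ("cutout", 2.0, 95.0): (10.00, 23.01, 31.62),
    ("cutout", 3.0, 95.0): (13.01, 25.21, 32.10),
    ("cutout", 4.0, 95.0): (14.07, 25.48, 31.86),
    ("cutout", 5.0, 95.0): (14.01, 25.66, 32.07),
    ("cutout", 2.0, 100.0): (9.01, 23.19, 31.94),
    ("cutout", 3.0, 100.0): (12.99, 24.93, 31.72),
    ("cutout", 4.0, 100.0): (14.00, 25.30, 31.70),
    ("cutout", 5.0, 100.0): (14.00, 25.34, 31.72),
    ("cutout", 2.0, 105.0): (9.01, 23.19, 31.94),
    ("cutout", 3.0, 105.0): (12.99, 24.93, 31.72),
    ("cutout", 4.0, 105.0): (14.00, 25.30, 31.70),
    ("cutout", 5.0, 105.0): (14.00, 25.34, 31.72),
    ("fixed_cone", 2.0, 95.0): (9.02, 23.27, 31.58),
    ("fixed_cone", 3.0, 95.0): (13.02, 25.16, 31.09),
    ("fixed_cone", 4.0, 95.0): (14.00, 25.68, 32.04),
    ("fixed_cone", 5.0, 95.0): (14.00, 25.44, 31.91),
    ("fixed_cone", 2.0, 100.0): (9.99, 23.74, 31.93),
    ("fixed_cone", 3.0, 100.0): (13.01, 24.97, 31.82),
    ("fixed_cone", 4.0, 100.0): (14.01, 25.25, 31.72),
    ("fixed_cone", 5.0, 100.0): (14.00, 25.31, 31.68),
    ("fixed_cone", 2.0, 105.0): (9.99, 23.74, 31.93),
    ("fixed_cone", 3.0, 105.0): (13.01, 24.97, 31.82),
    ("fixed_cone", 4.0, 105.0): (14.01, 25.25, 31.72),
    ("fixed_cone", 5.0, 105.0): (14.00, 25.31, 31.68),
    ("reference", 10.0, 95.0): (13.98, 25.16, 31.52),
    ("reference", 10.0, 100.0): (14.00, 25.06, 31.47),
    ("reference", 10.0, 105.0): (13.97, 25.14, 31.54),
}

# --------------------------------------------------------------------------
# Profile characteristics at SSD 100 cm, evaluated at depth R100.
# Depth ladder (mm) per (applicator, field): R100, R90, R70, R50, half-R90.

PROFILE_DEPTHS_MM = {
    ("cutout", 2.0): (9.01, 15.33, 19.50, 23.19, 7.67),
    ("cutout", 3.0): (12.99, 18.38, 23.30, 24.93, 9.19),
    ("cutout", 4.0): (14.00, 19.16, 22.90, 25.30, 9.58),
    ("cutout", 5.0): (14.00, 19.35, 21.60, 25.34, 9.68),
    ("fixed_cone", 2.0): (9.99, 15.53, 20.00, 23.74, 7.77),
    ("fixed_cone", 3.0): (13.01, 18.36, 23.30, 24.97, 9.18),
    ("fixed_cone", 4.0): (14.01, 19.27, 23.00, 25.25, 9.64),
    ("fixed_cone", 5.0): (14.00, 19.11, 23.00, 25.31, 9.56),
}

#: (applicator, field, plane): (fwhm_mm, penumbra_left_mm, penumbra_right_mm)
PROFILE_SHAPE_MM = {
    ("cutout", 2.0, "inplane"): (20.80, 7.26, 7.40),
    ("cutout", 3.0, "inplane"): (31.30, 9.31, 9.48),
    ("cutout", 4.0, "inplane"): (41.70, 10.49, 10.44),
    ("cutout", 5.0, "inplane"): (53.20, 10.78, 10.61),
    ("cutout", 2.0, "crossplane"): (20.90, 7.16, 7.47),
    ("cutout", 3.0, "crossplane"): (31.00, 9.35, 9.57),
    ("cutout", 4.0, "crossplane"): (41.60, 10.48, 10.53),
    ("cutout", 5.0, "crossplane"): (53.10, 10.74, 10.73),
    ("fixed_cone", 2.0, "inplane"): (22.70, 7.49, 7.50),
    ("fixed_cone", 3.0, "inplane"): (32.50, 9.70, 9.60),
    ("fixed_cone", 4.0, "inplane"): (42.90, 11.07, 10.88),
    ("fixed_cone", 5.0, "inplane"): (53.60, 11.30, 11.33),
    ("fixed_cone", 2.0, "crossplane"): (22.60, 7.43, 7.47),
    ("fixed_cone", 3.0, "crossplane"): (32.50, 9.54, 9.35),
    ("fixed_cone", 4.0, "crossplane"): (43.00, 11.09, 10.72),
    ("fixed_cone", 5.0, "crossplane"): (53.60, 11.74, 11.61),
}

# --------------------------------------------------------------------------
# Output factors Se vs field size and SSD, and the tabulated percent
# differences (computed with the /OF_C denominator convention).
# (field_cm, ssd_cm): (of_c, of_fc, printed_diff_percent, diff_consistent)
# diff_consistent=False marks cells whose printed difference is not
# reproducible from the tabulated OFs under either convention.

OUTPUT_FACTORS = {
    (2.0, 95.0): (0.903, 0.676, 25.1, True),
    (2.0, 100.0): (0.685, 0.452, 34.0, True),
    (2.0, 105.0): (0.485, 0.299, 38.4, True),
    (3.0, 95.0): (0.970, 0.861, 11.2, True),
    (3.0, 100.0): (0.790, 0.650, 17.7, True),
    (3.0, 105.0): (0.632, 0.478, 24.4, True),
    (4.0, 95.0): (1.005, 0.936, 6.9, True),
    (4.0, 100.0): (0.843, 0.767, 9.0, True),
    (4.0, 105.0): (0.704, 0.604, 14.2, True),
    (5.0, 95.0): (1.012, 0.939, 7.2, True),
    (5.0, 100.0): (0.867, 0.791, 7.7, False),
    (5.0, 105.0): (0.742, 0.644, 8.8, False),
}

# --------------------------------------------------------------------------
# Monitor-unit comparison at the prescription above (d = 14 mm, SSD 100 cm).
# Per field: TG-71 operands for both applicators, tabulated MU values, the
# TPS-calculated cutout MU, the indirect fixed-cone MU, and the 3-dp
# relative OF used for the indirect scaling.  mu_*_exact_round is False for
# rows whose tabulated MU does not follow round-half-away from the exact
# value of the tabulated operands.

MU_TABLE = pd.DataFrame.from_records(
    [
        # field, se_c, pdd_c, mu_c, c_round_ok, mu_c_tps,
        #        se_fc, pdd_fc, mu_fc, fc_round_ok, mu_fc_for_tps, of_rel
        (2.0, 0.685, 93.2, 783, True, 770, 0.452, 95.0, 1165, False, 1168, 0.659),
        (3.0, 0.790, 99.1, 638, False, 631, 0.650, 99.5, 773, True, 767, 0.822),
        (4.0, 0.843, 100.0, 593, True, 590, 0.767, 100.0, 651, False, 649, 0.910),
        (5.0, 0.867, 100.0, 577, True, 579, 0.791, 100.0, 632, True, 634, 0.912),
    ],
    columns=[
        "field_cm", "se_c", "pdd_c", "mu_c", "mu_c_exact_round", "mu_c_tps",
        "se_fc", "pdd_fc", "mu_fc", "mu_fc_exact_round", "mu_fc_for_tps",
        "of_relative",
    ],
)

#: reference 10x10 field row of the MU comparison: 500 MU measured, 501 from TPS
MU_REFERENCE_FIELD = {"se": 1.0, "pdd": 100.0, "mu": 500, "mu_tps": 501}


def output_factor_frame() -> pd.DataFrame:
    """Output-factor benchmark as a tidy DataFrame (one row per field x SSD)."""
    records = [
        {"field_cm": f, "ssd_cm": s, "of_c": c, "of_fc": fc,
         "diff_percent": d, "diff_consistent": ok}
        for (f, s), (c, fc, d, ok) in sorted(OUTPUT_FACTORS.items())
    ]
    return pd.DataFrame.from_records(records)


def output_factor_records():
    """Benchmark OFs as :class:`~conedose.output_factors.OutputFactorRecord`."""
    from .output_factors import OutputFactorRecord

    out = []
    for (f, s), (c, fc, _, _) in sorted(OUTPUT_FACTORS.items()):
        out.append(OutputFactorRecord("cutout", f, s, c))
        out.append(OutputFactorRecord("fixed_cone", f, s, fc))
    return out
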