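"""Two-step study orchestration over measured-format or synthetic datasets.

Step 1 — dosimetric comparison: beam-quality metrics per depth-dose curve,
profile metrics per transverse scan, the output-factor table with applicator
percent differences and per-field mean +/- SD across SSDs, and gamma
evaluations (cutout fixed as the reference arm).

Step 2 — monitor-unit comparison: direct TG-71 MU for both applicators,
the relative output factor, the indirect fixed-cone MU scaled from an
externally supplied TPS monitor-unit column, and percent-difference columns
checked against the 2.0 % (direct vs TPS) and 1.0 % (indirect vs direct)
agreement bounds.  TPS monitor units are always an input — this package
never computes treatment-planning-system doses.

Reports are plain CSV tables plus a text summary; every cell carries a
provenance column naming the operation and inputs that produced it, and a
given config and dataset always reproduce byte-identical report files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import reference_data as refdata
from .gamma import GammaCriteria, gamma_1d, gamma_2d
from .io import DoseGrid, ValidationError
from .mu import MuInput, mu_indirect, mu_tg71, percent_mu_difference
from .output_factors import (
    compute_output_factor,
    percent_of_difference,
    relative_of,
    summarize_of_differences,
)
from .pdd import extract_pdd_metrics, normalize_pdd, pdd_at_depth
from .profile import extract_profile_metrics
from .synth import StudyDataset, gen_applicator_pair

__all__ = [
    "StudyConfig",
    "Step1Report",
    "Step2Report",
    "MissingDataError",
    "run_step1",
    "run_step2",
    "run_study",
    "write_report",
    "load_config",
    "benchmark_operands",
]

#: agreement bounds of the monitor-unit comparison (percent)
MU_DIRECT_VS_TPS_BOUND = 2.0
MU_INDIRECT_VS_DIRECT_BOUND = 1.0


class MissingDataError(ValueError):
    """The dataset lacks curves for requested conditions (lists the gaps)."""


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the paired applicator study.

    ``tps_mu`` maps field diameter (cm) to the TPS-calculated cutout monitor
    units; when None the packaged benchmark values are used for benchmark
    field sets, otherwise the indirect columns are omitted.
    """

    fields_cm: tuple = refdata.FIELDS_CM
    ssds_cm: tuple = refdata.SSDS_CM
    dose_cGy: float = 500.0
    depth_mm: float = 14.0
    ssd0_cm: float = 100.0
    ref_dose_per_mu_cGy: float = 1.0
    gamma_criteria: tuple = ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))
    plane_criterion: tuple = (3.0, 3.0)
    denominator: str = "c"
    seed: int = 0
    noise_sd: float = 0.0
    include_planes: bool = True
    tps_mu: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.fields_cm or not self.ssds_cm:
            raise ValidationError("need at least one field size and one SSD")
        if self.dose_cGy <= 0 or self.depth_mm <= 0:
            raise ValidationError("prescription dose and depth must be positive")
        if self.denominator not in ("c", "fc"):
            raise ValidationError("denominator must be 'c' or 'fc'")


@dataclass
class Step1Report:
    pdd_metrics: pd.DataFrame
    pdd_summary: pd.DataFrame
    profile_metrics: pd.DataFrame
    of_table: pd.DataFrame
    of_summary: pd.DataFrame
    gamma_pdd: pd.DataFrame
    gamma_planes: pd.DataFrame


@dataclass
class Step2Report:
    mu_table: pd.DataFrame
    max_abs_diff_direct_vs_tps: Optional[float]
    max_abs_diff_indirect_vs_direct: Optional[float]


def _check_complete(dataset: StudyDataset, config: StudyConfig) -> None:
    gaps = []
    for app in ("cutout", "fixed_cone"):
        for fld in config.fields_cm:
            for ssd in config.ssds_cm:
                if (app, float(fld), float(ssd)) not in dataset.pdds:
                    gaps.append((app, float(fld), float(ssd), "depth"))
            for plane in ("inplane", "crossplane"):
                if (app, float(fld), plane) not in dataset.profiles:
                    gaps.append((app, float(fld), 100.0, plane))
    for ssd in config.ssds_cm:
        if float(ssd) not in dataset.reference_pdds:
            gaps.append(("reference", 10.0, float(ssd), "depth"))
    if gaps:
        raise MissingDataError(f"dataset is missing {len(gaps)} curves: {gaps}")


def run_step1(dataset: StudyDataset, config: StudyConfig) -> Step1Report:
    """Dosimetric comparison: metric tables, OF table and gamma evaluations."""
    _check_complete(dataset, config)

    pdd_rows = []
    for (app, fld, ssd), curve in sorted(dataset.pdds.items()):
        if fld not in config.fields_cm or ssd not in config.ssds_cm:
            continue
        m = extract_pdd_metrics(curve)
        pdd_rows.append({
            "applicator": app, "field_cm": fld, "ssd_cm": ssd,
            "r100_mm": m.r100_mm, "r90_mm": m.r90_mm, "r70_mm": m.r70_mm,
            "r50_mm": m.r50_mm, "rp_mm": m.rp_mm, "half_r90_mm": m.half_r90_mm,
            "provenance": f"extract_pdd_metrics({app},{fld:g}cm,SSD{ssd:g})",
        })
    pdd_metrics = pd.DataFrame(pdd_rows)

    summary_rows = []
    for (app, fld), grp in pdd_metrics.groupby(["applicator", "field_cm"]):
        for col in ("r100_mm", "r50_mm", "rp_mm"):
            vals = grp[col].dropna().to_numpy()
            if vals.size >= 2:
                mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
            else:
                mean, sd = (float(vals[0]) if vals.size else np.nan), np.nan
            summary_rows.append({
                "applicator": app, "field_cm": fld, "metric": col,
                "mean_mm": mean, "sd_mm": sd,
                "provenance": f"mean/sd of {col} across SSDs {tuple(grp.ssd_cm)}",
            })
    pdd_summary = pd.DataFrame(summary_rows)

    prof_rows = []
    for (app, fld, plane), curve in sorted(dataset.profiles.items()):
        if fld not in config.fields_cm:
            continue
        m = extract_profile_metrics(curve)
        prof_rows.append({
            "applicator": app, "field_cm": fld, "plane": plane,
            "depth_mm": curve.meta.depth_mm, "fwhm_mm": m.fwhm_mm,
            "penumbra_left_mm": m.penumbra_left_mm,
            "penumbra_right_mm": m.penumbra_right_mm,
            "provenance": f"extract_profile_metrics({app},{fld:g}cm,{plane})",
        })
    profile_metrics = pd.DataFrame(prof_rows)

    of_rows = []
    for fld in config.fields_cm:
        for ssd in config.ssds_cm:
            ref_max = float(np.max(dataset.reference_pdds[float(ssd)].doses))
            of = {}
            for app in ("cutout", "fixed_cone"):
                curve = dataset.pdds[(app, float(fld), float(ssd))]
                of[app] = compute_output_factor(float(np.max(curve.doses)), ref_max)
            diff = percent_of_difference(of["cutout"], of["fixed_cone"],
                                         denominator=config.denominator)
            of_rows.append({
                "field_cm": float(fld), "ssd_cm": float(ssd),
                "of_c": of["cutout"], "of_fc": of["fixed_cone"],
                "diff_percent": diff,
                "provenance": (
                    "compute_output_factor(max dose@R100)/percent_of_difference"
                    f"(denominator={config.denominator})"
                ),
            })
    of_table = pd.DataFrame(of_rows)

    of_sum_rows = []
    for fld, grp in of_table.groupby("field_cm"):
        if len(grp) >= 2:
            mean, sd = summarize_of_differences(grp["diff_percent"])
        else:
            mean, sd = float(grp["diff_percent"].iloc[0]), np.nan
        of_sum_rows.append({
            "field_cm": fld, "mean_diff_percent": mean, "sd_diff_percent": sd,
            "provenance": f"summarize_of_differences across SSDs {tuple(grp.ssd_cm)}",
        })
    of_summary = pd.DataFrame(of_sum_rows)

    gamma_rows = []
    for fld in config.fields_cm:
        for ssd in config.ssds_cm:
            ref = normalize_pdd(dataset.pdds[("cutout", float(fld), float(ssd))])
            ev = normalize_pdd(dataset.pdds[("fixed_cone", float(fld), float(ssd))])
            for dose_pc, dta in config.gamma_criteria:
                res = gamma_1d(ref, ev, GammaCriteria(dose_percent=dose_pc, dta_mm=dta))
                gamma_rows.append({
                    "field_cm": float(fld), "ssd_cm": float(ssd),
                    "dose_percent": dose_pc, "dta_mm": dta,
                    "pass_rate_percent": res.pass_rate_percent,
                    "n_evaluated": res.n_evaluated,
                    "provenance": f"gamma_1d(ref=cutout PDD,eval=fixed_cone PDD,{dose_pc:g}%/{dta:g}mm)",
                })
    gamma_pdd = pd.DataFrame(gamma_rows)

    plane_rows = []
    if config.include_planes:
        dose_pc, dta = config.plane_criterion
        for fld in config.fields_cm:
            key_c, key_fc = ("cutout", float(fld)), ("fixed_cone", float(fld))
            if key_c not in dataset.planes or key_fc not in dataset.planes:
                continue
            ref = _normalized_plane(dataset.planes[key_c])
            ev = _normalized_plane(dataset.planes[key_fc])
            res = gamma_2d(ref, ev, GammaCriteria(dose_percent=dose_pc, dta_mm=dta))
            plane_rows.append({
                "field_cm": float(fld), "dose_percent": dose_pc, "dta_mm": dta,
                "pass_rate_percent": res.pass_rate_percent,
                "n_evaluated": res.n_evaluated,
                "provenance": f"gamma_2d(ref=cutout plane,eval=fixed_cone plane,{dose_pc:g}%/{dta:g}mm)",
            })
    gamma_planes = pd.DataFrame(plane_rows)

    return Step1Report(pdd_metrics, pdd_summary, profile_metrics,
                       of_table, of_summary, gamma_pdd, gamma_planes)


def _normalized_plane(grid: DoseGrid) -> DoseGrid:
    peak = float(np.max(grid.values))
    return DoseGrid(grid.values * (100.0 / peak), spacing_mm=grid.spacing_mm,
                    origin_mm=grid.origin_mm, meta=grid.meta)


def benchmark_operands() -> pd.DataFrame:
    """The packaged benchmark monitor-unit operand table (one row per field)."""
    return refdata.MU_TABLE[
        ["field_cm", "se_c", "pdd_c", "se_fc", "pdd_fc", "mu_c_tps"]
    ].copy()


def operands_from_dataset(dataset: StudyDataset, config: StudyConfig,
                          of_table: pd.DataFrame) -> pd.DataFrame:
    """Monitor-unit operands measured from a dataset at the prescription SSD."""
    rows = []
    for fld in config.fields_cm:
        of_row = of_table[(of_table.field_cm == float(fld))
                          & (of_table.ssd_cm == config.ssd0_cm)]
        if of_row.empty:
            raise MissingDataError(
                f"no output factors at the prescription SSD {config.ssd0_cm} "
                f"for field {fld} cm"
            )
        row = {"field_cm": float(fld),
               "se_c": float(of_row.of_c.iloc[0]),
               "se_fc": float(of_row.of_fc.iloc[0])}
        for app, col in (("cutout", "pdd_c"), ("fixed_cone", "pdd_fc")):
            curve = dataset.pdds[(app, float(fld), config.ssd0_cm)]
            row[col] = pdd_at_depth(curve, config.depth_mm)
        if config.tps_mu and float(fld) in config.tps_mu:
            row["mu_c_tps"] = float(config.tps_mu[float(fld)])
        rows.append(row)
    return pd.DataFrame(rows)


def run_step2(operands: pd.DataFrame, config: StudyConfig) -> Step2Report:
    """Monitor-unit comparison from an operand table.

    ``operands`` columns: field_cm, se_c, pdd_c, se_fc, pdd_fc and optionally
    mu_c_tps (the TPS-calculated cutout MU).  Without the TPS column the
    indirect columns are omitted with a warning and only direct TG-71 MU are
    reported.  Percent differences are (measured basis - TPS basis) / TPS
    basis for the direct comparison and (indirect - direct) / direct for the
    fixed cone.
    """
    has_tps = "mu_c_tps" in operands.columns and operands["mu_c_tps"].notna().all()
    if not has_tps:
        warnings.warn("no TPS monitor-unit column; indirect MU columns omitted")

    rows = []
    for rec in operands.itertuples(index=False):
        mu_c = mu_tg71(MuInput(
            prescribed_dose_cGy=config.dose_cGy, pdd_percent=rec.pdd_c, se=rec.se_c,
            ref_dose_per_mu_cGy=config.ref_dose_per_mu_cGy,
            depth_mm=config.depth_mm, field_diameter_cm=rec.field_cm,
            ssd_cm=config.ssd0_cm,
        ))
        mu_fc = mu_tg71(MuInput(
            prescribed_dose_cGy=config.dose_cGy, pdd_percent=rec.pdd_fc, se=rec.se_fc,
            ref_dose_per_mu_cGy=config.ref_dose_per_mu_cGy,
            depth_mm=config.depth_mm, field_diameter_cm=rec.field_cm,
            ssd_cm=config.ssd0_cm,
        ))
        of_rel = relative_of(rec.se_fc, rec.se_c, field_diameter_cm=rec.field_cm,
                             ssd_cm=config.ssd0_cm)
        row = {
            "field_cm": rec.field_cm,
            "mu_c": mu_c.mu_rounded, "mu_c_exact": mu_c.mu_exact,
            "mu_fc": mu_fc.mu_rounded, "mu_fc_exact": mu_fc.mu_exact,
            "of_relative": of_rel.value,
            "provenance": (
                f"mu_tg71(D={config.dose_cGy:g},d={config.depth_mm:g}mm)"
                "/relative_of(se_fc,se_c)"
            ),
        }
        if has_tps:
            mu_tps = float(rec.mu_c_tps)
            indirect = mu_indirect(mu_tps, of_rel)
            diff_direct = percent_mu_difference(mu_c.mu_exact, mu_tps)
            diff_indirect = percent_mu_difference(indirect.mu_exact, mu_fc.mu_exact)
            row.update({
                "mu_c_tps": mu_tps,
                "mu_fc_for_tps": indirect.mu_rounded,
                "mu_fc_for_tps_exact": indirect.mu_exact,
                "diff_c_vs_tps_percent": diff_direct,
                "diff_fc_indirect_vs_direct_percent": diff_indirect,
                "pass_direct_2pc": abs(diff_direct) <= MU_DIRECT_VS_TPS_BOUND,
                "pass_indirect_1pc": abs(diff_indirect) <= MU_INDIRECT_VS_DIRECT_BOUND,
            })
        rows.append(row)
    table = pd.DataFrame(rows)

    max_direct = max_indirect = None
    if has_tps:
        max_direct = float(table["diff_c_vs_tps_percent"].abs().max())
        max_indirect = float(table["diff_fc_indirect_vs_direct_percent"].abs().max())
    return Step2Report(table, max_direct, max_indirect)


def run_study(config: StudyConfig,
              dataset: Optional[StudyDataset] = None) -> tuple[StudyDataset, Step1Report, Step2Report]:
    """Simulate (unless a dataset is given) and run both study steps."""
    if dataset is None:
        dataset = gen_applicator_pair(
            fields_cm=config.fields_cm, ssds_cm=config.ssds_cm,
            noise_sd=config.noise_sd, seed=config.seed,
            include_planes=config.include_planes,
        )
    step1 = run_step1(dataset, config)
    # TPS monitor units are an external input; without them the indirect
    # columns are simply omitted
    operands = operands_from_dataset(dataset, config, step1.of_table)
    with warnings.catch_warnings():
        if config.tps_mu is None:
            warnings.simplefilter("ignore")
        step2 = run_step2(operands, config)
    return dataset, step1, step2


# ---------------------------------------------------------------------------
# report files


_FLOAT_FMT = "%.6f"


def write_report(step1: Step1Report, step2: Optional[Step2Report], outdir) -> list:
    """Write the CSV tables and a text summary; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    tables = {
        "pdd_metrics.csv": step1.pdd_metrics,
        "pdd_summary.csv": step1.pdd_summary,
        "profile_metrics.csv": step1.profile_metrics,
        "of_table.csv": step1.of_table,
        "of_summary.csv": step1.of_summary,
        "gamma_pdd.csv": step1.gamma_pdd,
        "gamma_planes.csv": step1.gamma_planes,
    }
    if step2 is not None:
        tables["mu_table.csv"] = step2.mu_table
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        written.append(path)

    lines = ["paired applicator study report", ""]
    lines.append("[step 1] output-factor differences "
                 f"(denominator convention printed per row in of_table.csv)")
    for r in step1.of_summary.itertuples(index=False):
        sd = "n/a" if pd.isna(r.sd_diff_percent) else f"{r.sd_diff_percent:.2f}"
        lines.append(f"  field {r.field_cm:g} cm: mean diff {r.mean_diff_percent:.2f}% "
                     f"+/- {sd}%")
    if not step1.gamma_pdd.empty:
        worst = step1.gamma_pdd.loc[step1.gamma_pdd.pass_rate_percent.idxmin()]
        lines.append(f"  worst PDD gamma pass rate: {worst.pass_rate_percent:.1f}% "
                     f"({worst.dose_percent:g}%/{worst.dta_mm:g}mm, "
                     f"field {worst.field_cm:g} cm, SSD {worst.ssd_cm:g} cm)")
    if step2 is not None:
        lines.append("")
        lines.append("[step 2] monitor units: "
                     "diff_c = 100*(MU_c - MU_c_TPS)/MU_c_TPS; "
                     "diff_fc = 100*(MU_FC_indirect - MU_FC)/MU_FC")
        if step2.max_abs_diff_direct_vs_tps is not None:
            ok1 = step2.max_abs_diff_direct_vs_tps <= MU_DIRECT_VS_TPS_BOUND
            ok2 = step2.max_abs_diff_indirect_vs_direct <= MU_INDIRECT_VS_DIRECT_BOUND
            lines.append(f"  max |diff_c| = {step2.max_abs_diff_direct_vs_tps:.3f}% "
                         f"(bound {MU_DIRECT_VS_TPS_BOUND}%): {'PASS' if ok1 else 'FAIL'}")
            lines.append(f"  max |diff_fc| = {step2.max_abs_diff_indirect_vs_direct:.3f}% "
                         f"(bound {MU_INDIRECT_VS_DIRECT_BOUND}%): {'PASS' if ok2 else 'FAIL'}")
        else:
            lines.append("  no TPS monitor-unit input: indirect comparison omitted")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(summary)
    return written


# ---------------------------------------------------------------------------
# plain-text key=value study configs


def load_config(path) -> StudyConfig:
    """Parse a plain-text ``key = value`` study config file.

    Lists are comma separated; gamma criteria use ``dose/dta`` pairs, e.g.
    ``gamma_criteria = 1/1, 2/2, 3/3``.  Unknown keys raise.
    """
    kw: dict = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in ("fields_cm", "ssds_cm"):
            kw[key] = tuple(float(v) for v in value.split(","))
        elif key in ("dose_cGy", "depth_mm", "ssd0_cm", "ref_dose_per_mu_cGy", "noise_sd"):
            kw[key] = float(value)
        elif key == "seed":
            kw[key] = int(value)
        elif key == "denominator":
            kw[key] = value
        elif key == "include_planes":
            kw[key] = value.lower() in ("1", "true", "yes")
        elif key == "gamma_criteria":
            kw[key] = tuple(
                tuple(float(v) for v in pair.split("/")) for pair in value.split(",")
            )
        elif key == "tps_mu":
            # field:mu pairs, e.g. "2:770, 3:631"
            pairs = (p.split(":") for p in value.split(","))
            kw[key] = {float(f): float(m) for f, m in pairs}
        else:
            raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
    return StudyConfig(**kw)
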