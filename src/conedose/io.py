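"""Scan-curve and dose-grid containers with a plain-text interchange dialect.

Water-tank scans (depth-dose along the beam axis, transverse profiles at a
fixed depth) and planar 2D dose distributions are exchanged as UTF-8 text:
``# key=value`` header lines followed by comma-separated samples.  Vendor
formats (PTW mcc, RIT) are deliberately out of scope; this dialect is the
canonical interchange format of the package.

Conventions
-----------
* Positions are geometric coordinates in mm.
* The depth axis is positive downward from the water surface.
* Profile coordinates are centred so 0 = central axis.
* Dose values are stored unnormalized; normalization is always an explicit
  operation, never implicit on read.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ScanCurve",
    "DoseGrid",
    "ScanMeta",
    "ParseError",
    "ValidationError",
    "read_scan",
    "write_scan",
    "read_grid",
    "write_grid",
]

AXES = ("depth", "inplane", "crossplane")
APPLICATORS = ("cutout", "fixed_cone", "reference")

#: decimal places written by the text dialect (round-trip precision)
_PRECISION = 6


class ParseError(ValueError):
    """A file does not conform to the text dialect (message names the line)."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata shared by curves and grids.

    applicator: ``cutout`` (cerrobend insert in a standard applicator),
    ``fixed_cone`` (fixed-size stainless-steel cone) or ``reference``
    (the 10x10 cm calibration field).
    """

    applicator: Optional[str] = None
    field_diameter_cm: Optional[float] = None
    ssd_cm: Optional[float] = None
    energy_MeV: Optional[float] = None
    depth_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.applicator is not None and self.applicator not in APPLICATORS:
            raise ValidationError(
                f"applicator must be one of {APPLICATORS}, got {self.applicator!r}"
            )


@dataclass(frozen=True)
class ScanCurve:
    """A 1D sampled dose curve: depth dose or transverse profile.

    positions are strictly increasing sample coordinates in mm; doses are
    nonnegative and in arbitrary units (unnormalized).  ``axis`` is ``depth``
    for a percentage-depth-dose scan, ``inplane``/``crossplane`` for a
    transverse profile; profiles carry the measurement depth in ``meta``.
    """

    positions: np.ndarray
    doses: np.ndarray
    axis: str
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        doses = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "doses", doses)
        if self.axis not in AXES:
            raise ValidationError(f"axis must be one of {AXES}, got {self.axis!r}")
        if positions.ndim != 1 or doses.ndim != 1:
            raise ValidationError("positions and doses must be 1-dimensional")
        if positions.shape != doses.shape:
            raise ValidationError(
                f"positions ({positions.size}) and doses ({doses.size}) differ in length"
            )
        if positions.size < 4:
            raise ValidationError("a scan curve needs at least 4 samples")
        if not np.all(np.isfinite(positions)) or not np.all(np.isfinite(doses)):
            raise ValidationError("positions and doses must be finite")
        if np.any(np.diff(positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(doses < 0):
            raise ValidationError("doses must be nonnegative")
        if self.axis == "depth" and self.meta.depth_mm is not None:
            raise ValidationError("depth scans must not carry meta.depth_mm")
        if self.axis != "depth" and self.meta.depth_mm is None:
            raise ValidationError("profiles must carry meta.depth_mm")

    def __len__(self) -> int:
        return int(self.positions.size)

    def with_doses(self, doses: np.ndarray) -> "ScanCurve":
        """Copy of the curve with replaced dose values (re-validated)."""
        return dataclasses.replace(self, doses=np.asarray(doses, dtype=float))


@dataclass(frozen=True)
class DoseGrid:
    """A 2D planar dose distribution on a uniform rectangular grid.

    ``values[i, j]`` is the dose at coordinate
    ``origin_mm + (i * spacing_mm[0], j * spacing_mm[1])``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if values.ndim != 2:
            raise ValidationError("grid values must be 2-dimensional")
        if values.shape[0] < 4 or values.shape[1] < 4:
            raise ValidationError("a dose grid needs at least 4x4 samples")
        if not np.all(np.isfinite(values)):
            raise ValidationError("grid values must be finite")
        if np.any(values < 0):
            raise ValidationError("grid values must be nonnegative")
        if len(self.spacing_mm) != 2 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing_mm must be two strictly positive numbers")
        if len(self.origin_mm) != 2:
            raise ValidationError("origin_mm must have two components")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column sample coordinates in mm."""
        nr, nc = self.values.shape
        rows = self.origin_mm[0] + self.spacing_mm[0] * np.arange(nr)
        cols = self.origin_mm[1] + self.spacing_mm[1] * np.arange(nc)
        return rows, cols


# ---------------------------------------------------------------------------
# dialect helpers

_META_KEYS = ("applicator", "field_diameter_cm", "ssd_cm", "energy_MeV", "depth_mm")


def _format_meta(meta: ScanMeta) -> list[str]:
    lines = []
    for key in _META_KEYS:
        value = getattr(meta, key)
        if value is None:
            continue
        if isinstance(value, float):
            value = format(value, "g")
        lines.append(f"# {key}={value}")
    return lines


def _parse_header(lines: list[str], path: str) -> tuple[dict, int]:
    """Consume leading '# key=value' lines; return (header dict, first data line index)."""
    header: dict[str, str] = {}
    i = 0
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line:
            continue
        if not line.startswith("#"):
            return header, i
        body = line.lstrip("#").strip()
        if "=" not in body:
            raise ParseError(f"{path}:{i + 1}: malformed header line {line!r} (expected key=value)")
        key, _, value = body.partition("=")
        header[key.strip()] = value.strip()
    return header, i + 1


def _meta_from_header(header: dict, path: str) -> ScanMeta:
    kwargs = {}
    for key in _META_KEYS:
        if key not in header:
            continue
        raw = header[key]
        if key == "applicator":
            kwargs[key] = raw
        else:
            try:
                kwargs[key] = float(raw)
            except ValueError as exc:
                raise ParseError(f"{path}: header {key}={raw!r} is not numeric") from exc
    try:
        return ScanMeta(**kwargs)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_scan(path) -> ScanCurve:
    """Read a 1D scan curve from the text dialect.

    Raises :class:`ParseError` for malformed files (the message names the
    offending line) and :class:`ValidationError` when the parsed samples
    violate a curve invariant (e.g. non-monotone positions).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header, start = _parse_header(lines, str(path))
    if "axis" not in header:
        raise ParseError(f"{path}: missing required header key 'axis'")
    axis = header["axis"]
    meta = _meta_from_header(header, str(path))

    positions, doses = [], []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'position_mm,dose', got {line!r}")
        try:
            positions.append(float(parts[0]))
            doses.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric sample {line!r}") from exc
    return ScanCurve(np.array(positions), np.array(doses), axis=axis, meta=meta)


def write_scan(curve: ScanCurve, path) -> None:
    """Write a scan curve in the text dialect (bit-stable for equal inputs)."""
    buf = _stdio.StringIO()
    buf.write(f"# axis={curve.axis}\n")
    for line in _format_meta(curve.meta):
        buf.write(line + "\n")
    for x, d in zip(curve.positions, curve.doses):
        buf.write(f"{x:.{_PRECISION}f},{d:.{_PRECISION}f}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_grid(path) -> DoseGrid:
    """Read a planar dose grid from the text dialect."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header, start = _parse_header(lines, str(path))
    for key in ("rows", "cols", "spacing_mm", "origin_mm"):
        if key not in header:
            raise ParseError(f"{path}: missing required header key {key!r}")
    try:
        nrows, ncols = int(header["rows"]), int(header["cols"])
        spacing = tuple(float(v) for v in header["spacing_mm"].split(","))
        origin = tuple(float(v) for v in header["origin_mm"].split(","))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed grid geometry header: {exc}") from exc
    meta = _meta_from_header(header, str(path))

    rows: list[list[float]] = []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            row = [float(v) for v in line.split(",")]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric dose row") from exc
        if len(row) != ncols:
            raise ParseError(
                f"{path}:{lineno}: expected {ncols} columns, got {len(row)}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise ParseError(f"{path}: expected {nrows} dose rows, got {len(rows)}")
    return DoseGrid(np.array(rows), spacing_mm=spacing, origin_mm=origin, meta=meta)


def write_grid(grid: DoseGrid, path) -> None:
    """Write a planar dose grid in the text dialect."""
    buf = _stdio.StringIO()
    nr, nc = grid.shape
    buf.write(f"# rows={nr}\n# cols={nc}\n")
    buf.write(f"# spacing_mm={grid.spacing_mm[0]:g},{grid.spacing_mm[1]:g}\n")
    buf.write(f"# origin_mm={grid.origin_mm[0]:g},{grid.origin_mm[1]:g}\n")
    for line in _format_meta(grid.meta):
        buf.write(line + "\n")
    for row in grid.values:
        buf.write(",".join(f"{v:.{_PRECISION}f}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
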