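# Methods

## Scope and data model

`conedose` analyses 1D water-phantom scan curves (`ScanCurve`: depth dose or
transverse profile) and 2D planar dose grids (`DoseGrid`).  Positions are
geometric millimetres; depth is positive downward from the water surface;
profile coordinates are centred on the beam axis.  Doses are stored
unnormalized and normalization is always an explicit operation — reading a
file never rescales anything.  The interchange format is a minimal documented
text dialect (`# key=value` headers + CSV samples) rather than any vendor
format: it keeps every fixture human-readable and diffable, and vendor
parsers are out of scope.

Two applicator types are compared throughout: a circular cerrobend cutout in
a standard 6 cm electron applicator (`cutout`, C) and a fixed-size
stainless-steel cone (`fixed_cone`, FC), at field diameters 2–5 cm and SSDs
95/100/105 cm, for a 6 MeV beam.  The packaged benchmark tables
(`conedose.reference_data`) hold the measured scalar results for these
conditions and are used as fixtures and generator targets.

## Depth-dose metrics

The PDD is normalized to 100 at its maximum.  Metric definitions and the
numerical choices where the standard definitions leave freedom:

* **R100** — depth of maximum, refined by a parabola through the peak sample
  and its neighbours.  A plateau of equal maxima reports its midpoint
  (symmetric, deterministic tie-break).  The refinement falls back to the
  raw sample when the neighbourhood is not concave.
* **R90/R70/R50** — linear interpolation between the bracketing samples of
  the *first distal* (beyond-R100) downward crossing.  The buildup region
  also crosses these levels; by dosimetric convention only distal crossings
  count.  A curve that never falls below the level distally raises a
  range-undefined error.
* **Rp** — the distal falloff is smoothed with a 3-point moving average; the
  tangent is taken at the sample of steepest negative gradient beyond R100;
  the bremsstrahlung tail is a least-squares line through the samples beyond
  the depth where the smoothed dose first falls below (tail estimate + 5) %,
  the tail estimate being the median of the last five samples; Rp is the
  tangent/tail intersection.  With fewer than two usable tail samples Rp is
  reported absent with a warning rather than extrapolated.  This is the
  ICRU-style practical-range construction; the exact smoothing and tail
  window are implementation choices, so Rp carries a larger tolerance
  (0.3 mm against a dense-grid numeric oracle) than the interpolated ranges.
* **½R90** — defined as exactly R90/2.

All metrics are invariant under positive rescaling of the doses.

## Profile metrics

Profiles are normalized to 100 % at the central axis (dose interpolated at
x = 0).  FWHM is the distance between the 50 % crossings found by scanning
*outward* from the centre on each side with linear interpolation; under
noise this takes the innermost crossing per side, a deterministic choice
robust to tail ripple.  Each 80–20 % penumbra uses the same outward scan;
levels refer to the central-axis normalization, not to local edge maxima.
A profile that never reaches 20 % on a side reports that penumbra absent
with a warning.  `normalize_profile` also offers max-normalization for
tilted profiles; metrics always use the central-axis convention.

## Output factors and monitor units

`Se` is a plain ratio of dose-per-MU values, each at its own R100 (TG-70).
Two percent-difference conventions for (OF_C − OF_FC) circulate — dividing
by OF_FC or by OF_C — and they differ by tens of percent at small fields,
so the denominator must be named at every call site.  The default is `c`,
which is the convention the packaged benchmark differences follow; the
benchmark's two 5 cm cells that are not reproducible from the tabulated OFs
under either convention are flagged `diff_consistent=False` and excluded
from exact tests rather than repaired.  Field-size summaries use the
arithmetic mean and the sample (n−1) standard deviation.

TG-71 monitor units use D0′ = 1 cGy/MU by default (the standard calibration:
the benchmark's reference row, 500 MU for 500 cGy at Se = 1, PDD = 100,
forces it).  MU are rounded to the nearest integer, halves away from zero.
The benchmark MU table rounds inconsistently in places (651.9 printed as
651 but 576.7 as 577), so exact-integer assertions are restricted to the
rows whose printed operands reproduce the printed MU under this rule; the
others are held to ±1 MU.  The indirect fixed-cone MU divides the TPS's
cutout MU by the relative output factor OF_FC/OF_C; TPS monitor units are
always an *input* column — the package never computes TPS doses.  The study
bounds tested are ≤2.0 % (direct vs TPS) and ≤1.0 % (indirect vs direct).

## Gamma index

For each reference point the evaluated distribution is minimised over

γ² = (Δr/dta)² + (ΔD/(p/100 · D_norm))²

on a search grid of step `dta × step_fraction` (default dta/10) within a
radius `search_radius_factor × dta` (default 3·dta), with linear (1D) or
bilinear (2D) interpolation of the evaluated distribution.  Defaults follow
commercial water-tank/film software: global normalization to the reference
maximum and a 10 % low-dose cutoff (excluded points do not enter the pass
rate — essential for small fields whose planes are mostly out-of-field).
Local-dose gamma is available but never the default.  Gamma is asymmetric;
the pipeline fixes the cutout applicator as the reference arm.  The search
radius caps reportable gamma at `search_radius_factor`; points whose true
gamma exceeds it are still reported as failing.  The windowed, chunked
implementation is validated in the tests against an exhaustive all-pairs
brute-force oracle on identical search lattices (agreement within 0.01) and
against closed forms (flat-field dose offset → γ = 1; steep shifted ramp →
γ = β/√(1+β²) with β = g·dta/ΔD_tol).

## Synthetic beam generator

Measured commissioning data are not redistributable, so a paired virtual
experiment stands in:

* **Depth dose**: (1 − c·e^(−z/λ)) × logistic(z; z50, k) + linear tail.
  Defaults: surface dose 80 % of maximum, buildup scale λ = 5 mm, falloff
  scale k = 3 mm, tail 1.5 % — typical 6 MeV magnitudes.
* **Profile/plane**: difference of error functions (ideal aperture convolved
  with a Gaussian edge kernel); the plane is the radially symmetric
  analogue, so its central row equals the 1D profile by construction.
* **Noise**: multiplicative Gaussian, truncated at −3σ so doses stay
  nonnegative, fanned out from one top-level seed via independent
  per-purpose streams (bit-identical output under a fixed seed).

The analytic forms are a modelling choice: every target metric has a
closed-form or easily bisected relation to the parameters.  Generation
calibrates by bisection **on the extracted metric** — the generator adjusts
the logistic midpoint until `extract_pdd_metrics` returns the target R50
(within 0.02 mm), the buildup scale until R100 matches (with the surface
constraint re-solved for every trial, since the two couple strongly), and
the aperture/edge scale until FWHM and mean penumbra match (alternated,
because wide penumbras overlap at small fields).  This keeps generator and
extractor honest with respect to each other: round-trip tests verify a
consistent definition of each metric, not a shared formula.  Infeasible
targets (e.g. R100 a millimetre below R50, or a 7.5 mm penumbra on a 10 mm
field) raise a generation error rather than silently approximating.

`gen_applicator_pair` assembles the full study: per-condition R100/R50 from
the benchmark beam-quality table, profile FWHM/penumbras from the benchmark
profile table (the cone ~1.2 mm broader with ~0.4 mm wider penumbras), and
absolute outputs equal to the benchmark output factors (reference field
scaled to 1), so the output-factor pipeline reproduces the benchmark OF
table exactly on noiseless data.

What the generator does **not** emulate: detector volume averaging, SSD
divergence of profile width, depth dependence of the profile shape (planes
and profiles are generated at R100 only), asymmetries, beam time structure,
and film/scanner response.  Passing tests therefore demonstrate the
correctness of the analysis chain under controlled conditions, not the
physics fidelity of any real applicator.

## Problem sizes and determinism

Generated PDDs use a 0.5 mm grid (0.01 mm for dense oracle curves), profiles
0.1 mm, planes 1 mm; gamma oracle comparisons run on grids up to ~40×40 with
a 0.05 mm search lattice.  These sizes keep the full suite fast while being
dense relative to every feature scale involved (penumbra ≥ 2.5 mm, falloff
scale 3 mm).  All pipelines are deterministic given a config and seed:
reports are byte-identical across runs, with no timestamps in any output.

## Known limitations

* Rp depends mildly on sampling and smoothing choices; values from other
  software can differ by ~0.1–0.3 mm on identical curves.
* The indirect-MU method presumes the two applicators share PDD shape at the
  prescription depth; the benchmark data support this for ≥3 cm fields
  (PDD ≥ 99 %) and approximately at 2 cm.
* No inverse-square or effective-SSD corrections: MU are computed at the
  reference SSD only, matching the benchmark study's design.
* 3D gamma, DICOM-RT, film calibration and TPS dose engines are out of
  scope.
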