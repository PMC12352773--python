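"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the production code paths: the gamma oracles do an
exhaustive all-pairs minimisation over a densely interpolated evaluated
distribution with no search-radius shortcut or chunking, the practical-range
oracle builds the tangent construction on a fine grid with plain
finite-difference gradients and no smoothing, and the crossing oracle scans
a dense resampling for level crossings.
"""

from __future__ import annotations

import numpy as np


def brute_gamma_1d(ref_x, ref_d, ev_x, ev_d, dose_percent, dta_mm,
                   cutoff_percent=10.0, d_norm=None, dense_step=None):
    """Exhaustive 1D gamma: per reference point, minimise over a dense global
    resampling of the evaluated curve.  Returns (kept reference x, gamma)."""
    ref_x, ref_d = np.asarray(ref_x, float), np.asarray(ref_d, float)
    ev_x, ev_d = np.asarray(ev_x, float), np.asarray(ev_d, float)
    if d_norm is None:
        d_norm = ref_d.max()
    if dense_step is None:
        dense_step = dta_mm / 250.0
    xs = np.arange(ev_x[0], ev_x[-1] + dense_step / 2, dense_step)
    ds = np.interp(xs, ev_x, ev_d)
    tol = dose_percent / 100.0 * d_norm
    keep = (ref_d >= cutoff_percent / 100.0 * d_norm) \
        & (ref_x >= ev_x[0]) & (ref_x <= ev_x[-1])
    gammas = np.empty(np.count_nonzero(keep))
    for i, (x0, d0) in enumerate(zip(ref_x[keep], ref_d[keep])):
        g2 = ((xs - x0) / dta_mm) ** 2 + ((ds - d0) / tol) ** 2
        gammas[i] = np.sqrt(g2.min())
    return ref_x[keep], gammas


def brute_gamma_2d(ref_coords, ref_vals, ev_coords, ev_vals, dose_percent,
                   dta_mm, cutoff_percent=10.0, dense_step=None,
                   gamma_bound=None):
    """Exhaustive 2D gamma against a dense global bilinear resampling.

    ref_coords/ev_coords are (rows, cols) axis vectors.  Returns the gamma
    values of the evaluated (above-cutoff, in-overlap) reference points in
    row-major order.

    ``gamma_bound`` (per point, optional) prunes the search without changing
    the result: a candidate farther than gamma_bound*dta from the reference
    point has a distance term alone exceeding gamma_bound, so it cannot
    matter whenever the point's true gamma is below that bound.
    """
    from scipy.interpolate import RegularGridInterpolator

    rrows, rcols = (np.asarray(a, float) for a in ref_coords)
    erows, ecols = (np.asarray(a, float) for a in ev_coords)
    ref_vals = np.asarray(ref_vals, float)
    d_norm = ref_vals.max()
    tol = dose_percent / 100.0 * d_norm
    if dense_step is None:
        dense_step = dta_mm / 100.0

    xs = np.minimum(np.arange(erows[0], erows[-1] + dense_step / 2, dense_step),
                    erows[-1])
    ys = np.minimum(np.arange(ecols[0], ecols[-1] + dense_step / 2, dense_step),
                    ecols[-1])
    interp = RegularGridInterpolator((erows, ecols), np.asarray(ev_vals, float))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dense = interp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(gx.shape)

    rr, cc = np.meshgrid(rrows, rcols, indexing="ij")
    keep = (
        (ref_vals >= cutoff_percent / 100.0 * d_norm)
        & (rr >= erows[0]) & (rr <= erows[-1])
        & (cc >= ecols[0]) & (cc <= ecols[-1])
    )
    pts_r, pts_c, pts_d = rr[keep], cc[keep], ref_vals[keep]
    gammas = np.empty(pts_r.size)
    for i in range(pts_r.size):
        if gamma_bound is None:
            sx = sy = slice(None)
        else:
            radius = float(gamma_bound[i]) * dta_mm
            sx = slice(np.searchsorted(xs, pts_r[i] - radius),
                       np.searchsorted(xs, pts_r[i] + radius, side="right"))
            sy = slice(np.searchsorted(ys, pts_c[i] - radius),
                       np.searchsorted(ys, pts_c[i] + radius, side="right"))
        dist2 = ((xs[sx, None] - pts_r[i]) ** 2
                 + (ys[None, sy] - pts_c[i]) ** 2) / dta_mm**2
        g2 = dist2 + ((dense[sx, sy] - pts_d[i]) / tol) ** 2
        gammas[i] = np.sqrt(g2.min())
    return gammas


def rp_tangent_oracle(z, d):
    """Practical range by brute-force tangent construction on a fine grid.

    Steepest-gradient tangent (plain finite differences, no smoothing)
    intersected with a straight-line fit to the bremsstrahlung tail.
    """
    z, d = np.asarray(z, float), np.asarray(d, float)
    d = 100.0 * d / d.max()
    g = np.gradient(d, z)
    ipk = int(np.argmax(d))
    distal = np.flatnonzero(z > z[ipk])
    i_inf = distal[np.argmin(g[distal])]
    slope, z_inf, d_inf = g[i_inf], z[i_inf], d[i_inf]
    tail_est = float(np.median(d[-max(10, d.size // 20):]))
    past = np.flatnonzero((z > z_inf) & (d < tail_est + 5.0))
    b_slope, b_icpt = np.polyfit(z[past], d[past], 1)
    return float((b_icpt - (d_inf - slope * z_inf)) / (slope - b_slope))


def crossing_oracle(x, d, level, side, dense_step=0.001):
    """Dense-grid outward crossing search: position where the curve first
    falls below `level` moving outward from x=0 on the given side."""
    x, d = np.asarray(x, float), np.asarray(d, float)
    xs = np.arange(x[0], x[-1] + dense_step / 2, dense_step)
    ds = np.interp(xs, x, d)
    center = int(np.argmin(np.abs(xs)))
    if side == "right":
        idx = np.flatnonzero(ds[center:] < level)
        return float(xs[center + idx[0]]) if idx.size else None
    idx = np.flatnonzero(ds[:center + 1][::-1] < level)
    return float(xs[center - idx[0]]) if idx.size else None
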