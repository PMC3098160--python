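"""Replicate averaging and polynomial interpolation of time courses.

The optimiser consumes a densely and equally spaced series together with
derivative estimates.  Raw replicated measurements are first averaged
pointwise, then each gene's profile is fitted with a single least-squares
polynomial (degree chosen per gene by leave-one-out error) and evaluated —
together with its analytic derivative — on a dense grid (200 points by
default) over the observation window.  Fitting is done on a time axis
rescaled to [0, 1] for numerical conditioning and mapped back.
"""

from __future__ import annotations

import numpy as np

from .datasets import InterpolatedSeries, TimeCourse

__all__ = ["average_replicates", "interpolate_timecourse", "estimate_derivatives"]


def average_replicates(tc: TimeCourse) -> TimeCourse:
    """Pointwise arithmetic mean across replicates (times unchanged)."""
    mean = tc.values.mean(axis=2, keepdims=True)
    return TimeCourse(mean, tc.times, list(tc.gene_names), meta=dict(tc.meta))


def _loo_degree(t: np.ndarray, y: np.ndarray, degrees: range) -> int:
    """Pick the polynomial degree with the smallest leave-one-out error."""
    best_deg, best_err = degrees.start, np.inf
    n = t.size
    for deg in degrees:
        if n < deg + 2:
            break
        err = 0.0
        for k in range(n):
            mask = np.ones(n, dtype=bool)
            mask[k] = False
            c = np.polyfit(t[mask], y[mask], deg)
            err += (np.polyval(c, t[k]) - y[k]) ** 2
        if err < best_err - 1e-12:
            best_err, best_deg = err, deg
    return best_deg


def interpolate_timecourse(
    tc: TimeCourse,
    n_points: int = 200,
    max_degree: int = 6,
    min_degree: int = 2,
) -> InterpolatedSeries:
    """Fit one global polynomial per gene and sample it densely.

    Parameters
    ----------
    tc
        Single-replicate time course (average replicates first).
    n_points
        Size of the equally spaced output grid spanning ``[t_min, t_max]``.
    max_degree, min_degree
        Candidate polynomial degrees; the degree minimising the
        leave-one-out prediction error is selected per gene.
    """
    if tc.n_replicates != 1:
        raise ValueError("interpolate_timecourse expects a single-replicate input; "
                         "call average_replicates first")
    if tc.n_timepoints < max_degree + 1:
        raise ValueError(
            f"need at least max_degree+1={max_degree + 1} timepoints, "
            f"got {tc.n_timepoints}"
        )
    t_raw = tc.times
    span = t_raw[-1] - t_raw[0]
    ts = (t_raw - t_raw[0]) / span  # rescaled to [0, 1] for conditioning
    dense = np.linspace(0.0, 1.0, n_points)
    times_out = t_raw[0] + dense * span

    n = tc.n_genes
    values = np.empty((n, n_points))
    derivs = np.empty((n, n_points))
    degrees = np.empty(n, dtype=int)
    for i in range(n):
        y = tc.values[i, :, 0]
        if np.ptp(y) == 0:  # constant profile: exact fit, zero derivative
            degrees[i] = 0
            values[i] = y[0]
            derivs[i] = 0.0
            continue
        deg = _loo_degree(ts, y, range(min_degree, max_degree + 1))
        degrees[i] = deg
        coeff = np.polyfit(ts, y, deg)
        values[i] = np.polyval(coeff, dense)
        derivs[i] = np.polyval(np.polyder(coeff), dense) / span
    return InterpolatedSeries(
        values=values,
        derivatives=derivs,
        times=times_out,
        gene_names=list(tc.gene_names),
        fit_degree=degrees,
        meta=dict(tc.meta),
    )


def estimate_derivatives(series: InterpolatedSeries) -> np.ndarray:
    """Derivative matrix (genes x timepoints) of an interpolated series.

    Returns the stored analytic polynomial derivatives; if a series was
    built without them (non-polynomial backend), falls back to central
    finite differences on the dense grid.
    """
    if series.derivatives is not None and np.any(series.derivatives):
        return series.derivatives
    if np.ptp(series.values) == 0:
        return np.zeros_like(series.values)
    return np.gradient(series.values, series.times, axis=1)
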