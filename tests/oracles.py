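"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (truncated
power basis, Cox–de Boor recursion, trapezoid grids, hand-rolled partial
likelihood) and never calls the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def truncated_power_ncs(times, boundary, interior):
    """Natural-cubic-spline basis via the classical truncated power
    construction (constant + linear + one column per interior knot).

    Spans the full NCS space including the constant; column count K+2.
    """
    t = np.asarray(times, dtype=float)
    knots = np.concatenate([[boundary[0]], np.asarray(interior, dtype=float),
                            [boundary[1]]])
    M = knots.size

    def d(k, x):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[M - 1], 0, None) ** 3
        return num / (knots[M - 1] - knots[k])

    cols = [np.ones_like(t), t]
    for k in range(M - 2):
        cols.append(d(k, t) - d(M - 2, t))
    return np.column_stack(cols)


def fit_in_span(basis_fn, times, target):
    """Least-squares projection of ``target`` onto the column span of
    ``basis_fn(times)``; returns the fitted values."""
    B = basis_fn(times)
    coef, *_ = np.linalg.lstsq(B, target, rcond=None)
    return B @ coef


def cox_de_boor(x, knots, degree, j):
    """One B-spline basis function by the raw Cox–de Boor recursion."""
    if degree == 0:
        # half-open intervals, closed at the final break
        last = j + 1 == len(knots) - 1 or knots[j + 1] == knots[-1]
        if last:
            return 1.0 if knots[j] <= x <= knots[j + 1] else 0.0
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    out = 0.0
    den1 = knots[j + degree] - knots[j]
    if den1 > 0:
        out += (x - knots[j]) / den1 * cox_de_boor(x, knots, degree - 1, j)
    den2 = knots[j + degree + 1] - knots[j + 1]
    if den2 > 0:
        out += (knots[j + degree + 1] - x) / den2 * cox_de_boor(x, knots, degree - 1, j + 1)
    return out


def trapezoid_integral(fn, lo, hi, n=100_001):
    grid = np.linspace(lo, hi, n)
    return np.trapezoid(fn(grid), grid)


def breslow_partial_loglik(table, beta, covariates):
    """Counting-process Cox partial log-likelihood with Breslow ties.

    ``table`` needs columns start, stop, event and the covariates; risk sets
    use (start, stop] interval-covering semantics.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = table[list(covariates)].to_numpy(dtype=float)
    eta = X @ beta
    start = table["start"].to_numpy(dtype=float)
    stop = table["stop"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    ll = 0.0
    for i in np.flatnonzero(event):
        t = stop[i]
        at_risk = (start < t) & (t <= stop)
        ll += eta[i] - np.log(np.exp(eta[at_risk]).sum())
    return float(ll)
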