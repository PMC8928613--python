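"""Natural cubic spline bases for time-trend adjustment.

Both the exposure split (24 total degrees of freedom over the series) and
the health regression (280 degrees of freedom per year) regress on a
natural cubic spline of the day index: a cubic B-spline basis with
interior knots at equally spaced quantiles of time, boundary knots at the
range endpoints, and second derivatives constrained to zero at both
boundaries so the fit is linear beyond the data.  What the downstream
regressions consume is the *column span* of {1, spline basis}; this
module returns that span directly as an orthonormal matrix, which keeps
the 800+-column health-model fits numerically stable.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["natural_spline_basis", "orthonormal_time_basis"]


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis on ``x`` with ``df`` degrees of freedom.

    Returns an (n, df + 1) matrix whose columns span the natural-spline
    space *including* the constant function: ``df`` non-intercept degrees
    of freedom plus the intercept, matching a regression on
    ``1 + ns(x, df)``.  Interior knots sit at the df - 1 equally spaced
    quantiles of ``x``; boundary knots at min(x) and max(x).
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("need df >= 2")
    if np.unique(x).size <= df + 1:
        raise ValueError("not enough distinct x values for the requested df")
    lo, hi = x.min(), x.max()
    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs)
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    n_basis = len(knots) - 4  # df + 3 cubic B-splines
    design = BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()
    # Natural boundary constraints: second derivative of the fit vanishes
    # at both boundary knots -> 2 linear constraints on the coefficients.
    constraints = np.empty((2, n_basis))
    for i in range(n_basis):
        coef = np.zeros(n_basis)
        coef[i] = 1.0
        d2 = BSpline(knots, coef, 3).derivative(2)
        constraints[0, i] = d2(lo)
        constraints[1, i] = d2(hi)
    z = null_space(constraints)  # (df + 3, df + 1)
    basis = design @ z
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("rank-deficient natural spline basis")
    return basis


@functools.lru_cache(maxsize=8)
def orthonormal_time_basis(n: int, df: int) -> np.ndarray:
    """Orthonormal basis (n, df + 1) spanning {1, ns(day index, df)}.

    Built once per (n, df) and reused across regressions that share the
    same time covariate (the returned array is marked read-only).
    """
    basis = natural_spline_basis(np.arange(n, dtype=float), df)
    q, r = np.linalg.qr(basis)
    if np.min(np.abs(np.diag(r))) < 1e-9 * np.max(np.abs(np.diag(r))):
        raise ValueError("rank-deficient natural spline basis")
    q.setflags(write=False)
    return q
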