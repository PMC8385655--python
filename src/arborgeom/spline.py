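"""Interpolating B-splines over chord-length parameters.

Each segment of trace points is fitted with a B-spline that passes exactly
through every point (zero smoothing), parameterized by cumulative chord
length so that the parameter is in micrometres and approximates arclength
for densely sampled traces.  The spline degree is chosen from the point
count: degree 5 for more than five points (the minimal degree that makes
the curve thrice continuously differentiable), degree 3 for four or five
points, degree 2 for three, and degree 1 for two — low enough to keep the
fit fully constrained, odd wherever possible (large even-degree
interpolation is ill-behaved), and high enough for curvature and torsion
to be non-vanishing when the data allow it.

The basis functions follow the Cox–de Boor recursion

    B[j,p](x) = (x - t[j]) / (t[j+p] - t[j]) * B[j,p-1](x)
              + (t[j+p+1] - x) / (t[j+p+1] - t[j+1]) * B[j+1,p-1](x)

with B[j,0] the half-open indicator of [t[j], t[j+1]) and the convention
that fractions with zero denominator vanish.  Derivatives use the
closed-form recurrence

    B'[j,p](x) = p * ( B[j,p-1](x) / (t[j+p] - t[j])
                     - B[j+1,p-1](x) / (t[j+p+1] - t[j+1]) )

applied repeatedly for higher orders, so curve derivatives up to order
three are exact, not finite-differenced.  Fitting itself is delegated to
scipy's FITPACK wrapper ``splprep`` (interior knot placement beyond the
interpolation contract follows that standard construction); evaluation
goes through the recurrences above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splprep

from .decompose import SegmentPath, DegenerateSegmentError

__all__ = [
    "BSplineCurve",
    "DomainError",
    "basis",
    "basis_derivative",
    "select_degree",
    "fit_segment",
    "evaluate",
]


class DomainError(ValueError):
    """Evaluation requested outside the curve's parameter domain."""


# ---------------------------------------------------------------------------
# Cox–de Boor recursion (single basis function; reference form)


def _check_index(j: int, p: int, knots: np.ndarray) -> None:
    if p < 0:
        raise IndexError(f"degree must be non-negative, got {p}")
    if not 0 <= j <= len(knots) - p - 2:
        raise IndexError(
            f"basis index {j} invalid for {len(knots)} knots and degree {p}"
        )


def basis(j: int, p: int, knots, x):
    """Value of the ``j``-th degree-``p`` basis function at ``x``.

    Textbook recursion; the degree-0 base case is the half-open indicator
    of ``[knots[j], knots[j+1])``.  Vectorized over ``x``.
    """
    knots = np.asarray(knots, dtype=float)
    _check_index(j, p, knots)
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    out = _basis_rec(j, p, knots, xa)
    return float(out[0]) if scalar else out


def _basis_rec(j: int, p: int, knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    if p == 0:
        return ((x >= knots[j]) & (x < knots[j + 1])).astype(float)
    out = np.zeros_like(x)
    den1 = knots[j + p] - knots[j]
    if den1 > 0:
        out += (x - knots[j]) / den1 * _basis_rec(j, p - 1, knots, x)
    den2 = knots[j + p + 1] - knots[j + 1]
    if den2 > 0:
        out += (knots[j + p + 1] - x) / den2 * _basis_rec(j + 1, p - 1, knots, x)
    return out


def basis_derivative(j: int, p: int, knots, x, order: int = 1):
    """Closed-form ``order``-th derivative of the basis function.

    Uses the degree-lowering recurrence; an order exceeding the degree
    returns zero everywhere (the polynomial is exhausted).
    """
    knots = np.asarray(knots, dtype=float)
    _check_index(j, p, knots)
    if order < 0:
        raise ValueError("order must be non-negative")
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    out = _basis_deriv_rec(j, p, knots, xa, order)
    return float(out[0]) if scalar else out


def _basis_deriv_rec(
    j: int, p: int, knots: np.ndarray, x: np.ndarray, order: int
) -> np.ndarray:
    if order == 0:
        return _basis_rec(j, p, knots, x)
    if order > p:
        return np.zeros_like(x)
    out = np.zeros_like(x)
    den1 = knots[j + p] - knots[j]
    if den1 > 0:
        out += _basis_deriv_rec(j, p - 1, knots, x, order - 1) / den1
    den2 = knots[j + p + 1] - knots[j + 1]
    if den2 > 0:
        out -= _basis_deriv_rec(j + 1, p - 1, knots, x, order - 1) / den2
    return p * out


# ---------------------------------------------------------------------------
# Whole-basis design matrices (used for curve evaluation; right endpoint of
# the domain is treated as belonging to the last non-empty span so that the
# curve is defined on the closed interval [0, L]).


def _basis_matrix(p: int, knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    nk = len(knots)
    m = len(x)
    B = np.zeros((m, nk - 1))
    nonempty = np.flatnonzero(np.diff(knots) > 0)
    for i in nonempty:
        B[:, i] = (x >= knots[i]) & (x < knots[i + 1])
    if len(nonempty):
        last = nonempty[-1]
        B[x == knots[last + 1], last] = 1.0
    for d in range(1, p + 1):
        newB = np.zeros((m, nk - 1 - d))
        for i in range(nk - 1 - d):
            acc = None
            den1 = knots[i + d] - knots[i]
            if den1 > 0:
                acc = (x - knots[i]) / den1 * B[:, i]
            den2 = knots[i + d + 1] - knots[i + 1]
            if den2 > 0:
                term = (knots[i + d + 1] - x) / den2 * B[:, i + 1]
                acc = term if acc is None else acc + term
            if acc is not None:
                newB[:, i] = acc
        B = newB
    return B


def _deriv_matrix(p: int, knots: np.ndarray, x: np.ndarray, order: int) -> np.ndarray:
    if order == 0:
        return _basis_matrix(p, knots, x)
    n_basis = len(knots) - p - 1
    if order > p:
        return np.zeros((len(x), n_basis))
    M = _deriv_matrix(p - 1, knots, x, order - 1)  # (m, n_basis + 1)
    D = np.zeros((len(x), n_basis))
    for j in range(n_basis):
        acc = np.zeros(len(x))
        den1 = knots[j + p] - knots[j]
        if den1 > 0:
            acc += M[:, j] / den1
        den2 = knots[j + p + 1] - knots[j + 1]
        if den2 > 0:
            acc -= M[:, j + 1] / den2
        D[:, j] = p * acc
    return D


# ---------------------------------------------------------------------------
# Curves


@dataclass
class BSplineCurve:
    """A 3D B-spline curve on the chord-length parameter domain ``[0, L]``."""

    degree: int
    knots: np.ndarray
    coefficients: np.ndarray  # (n_coeff, 3)
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knot sequence must be non-decreasing")
        n_coeff = len(self.knots) - self.degree - 1
        if self.coefficients.shape != (n_coeff, 3):
            raise ValueError(
                f"expected {(n_coeff, 3)} coefficients, got {self.coefficients.shape}"
            )

    @property
    def L(self) -> float:
        return self.domain[1]

    def __call__(self, t, order: int = 0):
        return evaluate(self, t, order)


def select_degree(n: int) -> int:
    """Spline degree for an ``n``-point segment.

    ``n > 5 -> 5``; ``3 < n <= 5 -> 3``; ``n = 3 -> 2``; ``n = 2 -> 1``.
    Degree 4 is never produced.
    """
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if n > 5:
        return 5
    if n > 3:
        return 3
    if n == 3:
        return 2
    return 1


def fit_segment(seg: SegmentPath, degree: int | None = None) -> BSplineCurve:
    """Interpolating spline through all points of ``seg``.

    Parameter values are the cumulative chord lengths of the points, so the
    domain is ``[0, seg.L]`` in micrometres.  Zero smoothing: the curve
    passes through every trace point.  ``degree`` overrides the point-count
    rule (e.g. forcing degree 1 reproduces a piecewise-linear trace, for
    which curvature and torsion vanish identically).
    """
    u = seg.chord_parameters()
    if np.any(np.diff(u) <= 0):
        raise DegenerateSegmentError("degenerate segment: coincident points")
    k = select_degree(seg.n_points) if degree is None else degree
    if not 1 <= k < seg.n_points:
        raise ValueError(f"degree {k} invalid for {seg.n_points} points")
    pts = seg.points
    (t, c, k), _ = splprep([pts[:, 0], pts[:, 1], pts[:, 2]], u=u, s=0, k=k)
    return BSplineCurve(
        degree=k,
        knots=np.asarray(t),
        coefficients=np.stack(c, axis=1),
        domain=(float(u[0]), float(u[-1])),
    )


_DOMAIN_TOL = 1e-9


def evaluate(curve: BSplineCurve, t, order: int = 0):
    """Position (``order=0``) or derivative vector of the curve at ``t``.

    Derivatives are with respect to the chord-length parameter and computed
    with the closed-form basis recurrences.  ``t`` outside ``[0, L]`` (up to
    a 1e-9 tolerance) raises :class:`DomainError`; there is no extrapolation.
    """
    if not 0 <= order <= 3:
        raise ValueError("order must be in 0..3")
    ta = np.asarray(t, dtype=float)
    scalar = ta.ndim == 0
    ta = np.atleast_1d(ta).astype(float)
    lo, hi = curve.domain
    if np.any(ta < lo - _DOMAIN_TOL) or np.any(ta > hi + _DOMAIN_TOL):
        raise DomainError(
            f"parameter outside domain [{lo}, {hi}]"
        )
    ta = np.clip(ta, lo, hi)
    D = _deriv_matrix(curve.degree, curve.knots, ta, order)
    vals = D @ curve.coefficients
    return vals[0] if scalar else vals
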