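"""M-spline and I-spline basis construction for hazard modelling.

M-splines are nonnegative polynomial spline basis functions, each normalized
to integrate to one over the basis support.  A convex combination
``sum_i p_i b_i(t)`` scaled by a positive factor therefore yields a smooth,
positive hazard function.  I-splines are the running integrals of M-splines
and build the cumulative hazard.

The basis here is the standard one obtained from B-splines on a clamped knot
vector: with B-splines ``B_i`` of order ``k = degree + 1`` (which sum to one),
the M-spline is ``b_i(t) = k * B_i(t) / (knots[i+k] - knots[i])``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "MSplineBasis",
    "InvalidSpecificationError",
    "InsufficientEventsError",
    "place_knots",
    "eval_msplines",
    "eval_isplines",
    "constant_hazard_coefs",
]


class InvalidSpecificationError(ValueError):
    """Raised when a basis or model specification is internally inconsistent."""


class InsufficientEventsError(ValueError):
    """Raised when data contain too few uncensored events for the request."""


@dataclass(frozen=True)
class MSplineBasis:
    """A cubic (by default) M-spline basis on ``[lower, upper]``.

    Parameters
    ----------
    degree
        Polynomial degree of each piece (cubic = 3).
    knots
        Full nondecreasing knot vector with the boundary knots repeated
        ``degree + 1`` times (a clamped vector).  Times are in years.
    """

    degree: int
    knots: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if self.degree < 1:
            raise InvalidSpecificationError("degree must be >= 1")
        if knots.ndim != 1 or knots.size < 2 * (self.degree + 1):
            raise InvalidSpecificationError(
                "knot vector must contain each boundary knot degree+1 times"
            )
        if np.any(np.diff(knots) < 0):
            raise InvalidSpecificationError("knots must be nondecreasing")
        k = self.degree + 1
        if not (np.all(knots[:k] == knots[0]) and np.all(knots[-k:] == knots[-1])):
            raise InvalidSpecificationError(
                "boundary knots must have multiplicity degree+1"
            )
        if knots[0] < 0:
            raise InvalidSpecificationError("lower boundary must be >= 0")
        if not knots[0] < knots[-1]:
            raise InvalidSpecificationError("lower boundary must be < upper")

    @classmethod
    def from_internal_knots(
        cls,
        internal_knots: np.ndarray | list[float],
        lower: float,
        upper: float,
        degree: int = 3,
    ) -> "MSplineBasis":
        internal = np.sort(np.asarray(internal_knots, dtype=float))
        if internal.size and (internal[0] <= lower or internal[-1] >= upper):
            raise InvalidSpecificationError(
                "internal knots must lie strictly inside (lower, upper)"
            )
        full = np.concatenate(
            [np.full(degree + 1, float(lower)), internal, np.full(degree + 1, float(upper))]
        )
        return cls(degree=degree, knots=full)

    @property
    def lower(self) -> float:
        return float(self.knots[0])

    @property
    def upper(self) -> float:
        return float(self.knots[-1])

    @property
    def internal_knots(self) -> np.ndarray:
        k = self.degree + 1
        return self.knots[k:-k]

    @property
    def n_basis(self) -> int:
        """Number of basis functions = internal knots + degree + 1."""
        return self.knots.size - (self.degree + 1)


def place_knots(
    uncensored_times: np.ndarray | list[float],
    df: int,
    lower: float = 0.0,
    upper: float | None = None,
    degree: int = 3,
) -> MSplineBasis:
    """Build a basis with ``df`` functions, internal knots at event quantiles.

    With ``m = df - degree - 1`` internal knots, these sit at the
    ``i / (m + 1)`` empirical quantiles (type-7) of the uncensored event
    times, clipped to the open interval ``(lower, upper)``.  Tied quantiles
    collapse to a single knot with a warning, reducing ``df``.

    Parameters
    ----------
    uncensored_times
        Observed (uncensored) event times, years.
    df
        Requested number of basis functions.
    lower, upper
        Boundary knots; ``upper`` defaults to the maximum supplied time.
    """
    times = np.asarray(uncensored_times, dtype=float)
    if df < degree + 1:
        raise InvalidSpecificationError(
            f"df={df} is below the minimum degree+1={degree + 1}"
        )
    m = df - degree - 1
    if upper is None:
        if times.size == 0:
            raise InsufficientEventsError("no times supplied to set the upper boundary")
        upper = float(times.max())
    if not upper > lower:
        raise InvalidSpecificationError("upper must exceed lower")
    if m == 0:
        return MSplineBasis.from_internal_knots([], lower, upper, degree)
    if times.size == 0:
        raise InsufficientEventsError(
            f"{m} internal knots requested but no uncensored events available"
        )
    probs = np.arange(1, m + 1) / (m + 1)
    internal = np.quantile(times, probs)  # type-7 linear interpolation
    eps = 1e-8 * (upper - lower)
    internal = np.clip(internal, lower + eps, upper - eps)
    unique = np.unique(internal)
    if unique.size < internal.size:
        warnings.warn(
            "duplicate internal knots collapsed; basis dimension reduced from "
            f"{df} to {unique.size + degree + 1}",
            stacklevel=2,
        )
    return MSplineBasis.from_internal_knots(unique, lower, upper, degree)


def _mspline_scale(basis: MSplineBasis) -> np.ndarray:
    """Per-function factors converting B-splines to unit-integral M-splines."""
    k = basis.degree + 1
    spans = basis.knots[k:] - basis.knots[:-k]
    return k / spans


def eval_msplines(basis: MSplineBasis, t: np.ndarray | list[float]) -> np.ndarray:
    """Evaluate all M-spline basis functions at times ``t``.

    Returns a ``[len(t), n_basis]`` matrix; rows for times outside
    ``[lower, upper]`` are zero.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    out = np.zeros((t.size, basis.n_basis))
    inside = (t >= basis.lower) & (t <= basis.upper)
    if np.any(inside):
        design = BSpline.design_matrix(
            t[inside], basis.knots, basis.degree, extrapolate=False
        ).toarray()
        out[inside] = design * _mspline_scale(basis)
    return out


def eval_isplines(basis: MSplineBasis, t: np.ndarray | list[float]) -> np.ndarray:
    """Evaluate I-splines ``I_i(t) = int_lower^t b_i(u) du``.

    Each column runs monotonically from 0 at ``lower`` to 1 at ``upper``;
    values are clamped to those limits outside the support.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    tc = np.clip(t, basis.lower, basis.upper)
    scale = _mspline_scale(basis)
    n = basis.n_basis
    out = np.empty((t.size, n))
    for i in range(n):
        c = np.zeros(n)
        c[i] = scale[i]
        anti = BSpline(basis.knots, c, basis.degree, extrapolate=False).antiderivative()
        out[:, i] = anti(tc) - anti(basis.lower)
    # guard round-off at the boundaries
    return np.clip(out, 0.0, None)


def constant_hazard_coefs(basis: MSplineBasis) -> np.ndarray:
    """Coefficient simplex making ``sum_i p_i b_i(t)`` constant in t.

    Because each B-spline family forms a partition of unity,
    ``p_i proportional to knots[i+degree+1] - knots[i]`` flattens the
    weighted M-spline sum exactly.  These are the prior means of the
    spline-coefficient model (a constant-hazard centring).
    """
    k = basis.degree + 1
    spans = basis.knots[k:] - basis.knots[:-k]
    return spans / spans.sum()
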