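"""Restricted cubic spline (RCS) bases for continuous vital signs.

Systolic blood pressure and heart rate enter the multivariable risk models
through a restricted cubic spline: a piecewise-cubic function of the raw
measurement that is constrained to be linear beyond its boundary knots, so
that predictions do not explode for extreme vitals.  With ``k`` knots the
basis has ``k - 1`` columns: the raw value itself plus ``k - 2`` nonlinear
"spline basis function" (SBF) columns.

Knots are placed at percentiles of the observed distribution, computed once
on the model-development sample and then frozen: a prediction model must be
fully specified before it is validated or charted, so downstream code always
re-uses the stored knots rather than recomputing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "DegenerateInputError", "compute_knots", "rcs_basis"]


class DegenerateInputError(ValueError):
    """Raised when a variable has too few distinct values to place knots."""


#: Percentile schemes for knot placement, keyed by name.  ``equal`` places
#: k knots at the k equally spaced interior percentiles 100*i/(k+1); the
#: ``outer`` scheme is the conventional 5/35/65/95 placement for 4 knots
#: (and its generalisation 5 / equally-spaced / 95 otherwise).
KNOT_SCHEMES = ("equal", "outer")


def _scheme_percentiles(n_knots: int, scheme: str) -> np.ndarray:
    if scheme == "equal":
        return 100.0 * np.arange(1, n_knots + 1) / (n_knots + 1)
    if scheme == "outer":
        return np.linspace(5.0, 95.0, n_knots)
    raise ValueError(f"unknown knot scheme {scheme!r}; expected one of {KNOT_SCHEMES}")


@dataclass(frozen=True)
class SplineBasis:
    """A frozen restricted-cubic-spline basis.

    Parameters
    ----------
    knots
        Strictly increasing knot locations on the scale of the raw variable.
    variable
        Optional name of the variable the knots were computed on; used in
        error messages and model-file serialisation.
    """

    knots: tuple[float, ...]
    variable: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("a restricted cubic spline needs at least 3 knots")
        if not np.all(np.diff(k) > 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def basis_dimension(self) -> int:
        """Number of basis columns: one linear plus ``n_knots - 2`` nonlinear."""
        return len(self.knots) - 1


def compute_knots(
    values, n_knots: int = 4, scheme: str = "equal", variable: str = ""
) -> SplineBasis:
    """Place spline knots at percentiles of the observed, non-missing values.

    The default scheme puts 4 knots at the 20th/40th/60th/80th percentiles
    (equally spaced interior percentiles).  The conventional outer-percentile
    placement (5/35/65/95) is available as ``scheme="outer"``.

    Raises
    ------
    DegenerateInputError
        If, after dropping missing values, fewer than ``n_knots`` distinct
        values remain or the resulting knots are not strictly increasing.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    name = variable or "values"
    if np.unique(x).size < n_knots:
        raise DegenerateInputError(
            f"cannot place {n_knots} knots on {name!r}: "
            f"only {np.unique(x).size} distinct finite values"
        )
    pct = _scheme_percentiles(n_knots, scheme)
    knots = np.percentile(x, pct)
    if not np.all(np.diff(knots) > 0):
        raise DegenerateInputError(
            f"knot percentiles of {name!r} are not strictly increasing: {knots}"
        )
    return SplineBasis(knots=tuple(float(t) for t in knots), variable=variable)


def rcs_basis(x, basis: SplineBasis) -> np.ndarray:
    """Evaluate the restricted truncated-power cubic basis at ``x``.

    Returns an ``(n, k - 1)`` matrix whose first column is ``x`` itself and
    whose remaining columns are the restricted cubic terms

    .. math::

        B_j(x) = \\frac{(x-t_j)_+^3
                  - (x-t_{k-1})_+^3 \\, (t_k-t_j)/(t_k-t_{k-1})
                  + (x-t_k)_+^3 \\, (t_{k-1}-t_j)/(t_k-t_{k-1})}
                 {(t_k-t_1)^2}

    for interior knots :math:`t_j`, :math:`j = 1..k-2`.  The division by the
    squared knot range keeps the nonlinear coefficients on a scale comparable
    with the linear one.  The restriction makes the spline linear (second
    derivative zero) below the first and above the last knot; evaluation
    outside the knot range is therefore valid linear extrapolation.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    t = np.asarray(basis.knots, dtype=float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def cube(v: np.ndarray) -> np.ndarray:
        return np.where(v > 0, v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        num = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(num / scale)
    out = np.column_stack(cols)
    return out[0] if scalar else out
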