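"""Natural cubic spline basis for gestational age.

The gestational-age trend f(GA) is modelled as a natural cubic spline:
piecewise cubic, twice continuously differentiable, and constrained to be
linear beyond its boundary knots.  Linearity outside the boundary matters
here because charts extend a week or two past the bulk of the delivery
measurements, and a linear tail is the only defensible extrapolation for
weight gain.

The basis is parameterised in *cardinal* form: with nodes
``t_0 < t_1 < ... < t_df`` (the two boundary knots plus ``df - 1`` interior
knots), basis function ``k`` (k = 1..df) is the unique natural cubic spline
interpolating the unit vector ``e_k`` on the nodes.  The function attached
to ``t_0`` is dropped, so the basis spans the natural-spline space modulo
constants and carries no constant column — the model supplies its own
intercept.  A convenient side effect is that every basis function vanishes
at the lower boundary knot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline


class SplineSpecError(ValueError):
    """Invalid spline specification."""


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline basis specification.

    Parameters
    ----------
    df
        Degrees of freedom (number of basis columns, excluding the
        intercept).  ``df = len(interior_knots) + 1``.
    interior_knots
        Strictly increasing knot locations in weeks, strictly inside the
        boundary knots.
    boundary_knots
        ``(low, high)`` in weeks; the spline is linear outside this range.
    """

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise SplineSpecError("boundary knots must satisfy low < high")
        interior = tuple(float(k) for k in self.interior_knots)
        if len(interior) != self.df - 1:
            raise SplineSpecError(
                f"df={self.df} requires {self.df - 1} interior knots, "
                f"got {len(interior)}"
            )
        knots = (lo, *interior, hi)
        if any(a >= b for a, b in zip(knots, knots[1:])):
            raise SplineSpecError(f"knots must be strictly increasing: {knots}")
        object.__setattr__(self, "interior_knots", interior)
        object.__setattr__(self, "boundary_knots", (float(lo), float(hi)))

    @property
    def nodes(self) -> np.ndarray:
        """All knots, boundary included, in increasing order."""
        lo, hi = self.boundary_knots
        return np.array([lo, *self.interior_knots, hi])

    def to_json(self) -> str:
        return json.dumps(
            {
                "df": self.df,
                "interior_knots": list(self.interior_knots),
                "boundary_knots": list(self.boundary_knots),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplineSpec":
        d = json.loads(text)
        return cls(
            df=int(d["df"]),
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
        )


def build_spec(ga_values: Sequence[float], df: int = 5) -> SplineSpec:
    """Place knots from observed gestational ages.

    Boundary knots sit at the min/max of ``ga_values``; the ``df - 1``
    interior knots sit at equally spaced quantiles (for df=5: the
    20/40/60/80% quantiles).  Standard practice when only the degrees of
    freedom are prescribed.
    """
    ga = np.asarray(ga_values, dtype=float)
    if df < 1:
        raise SplineSpecError("df must be >= 1")
    distinct = np.unique(ga)
    if distinct.size < df + 2:
        raise SplineSpecError(
            f"need at least {df + 2} distinct gestational ages for df={df}, "
            f"got {distinct.size}"
        )
    lo, hi = float(ga.min()), float(ga.max())
    probs = np.arange(1, df) / df
    interior = tuple(float(q) for q in np.quantile(ga, probs))
    # quantile ties would collapse knots; nudge into the open interval
    interior = tuple(np.clip(interior, lo + 1e-9, hi - 1e-9))
    return SplineSpec(df=df, interior_knots=interior, boundary_knots=(lo, hi))


def evaluate_basis(spec: SplineSpec, ga) -> np.ndarray:
    """Evaluate the natural cubic basis at gestational ages.

    Returns an array of shape ``(len(ga), spec.df)`` (or ``(spec.df,)`` for
    scalar input).  Values outside the boundary knots are linearly
    extrapolated from the boundary value and slope, so the second
    derivative is identically zero there.
    """
    ga_arr = np.atleast_1d(np.asarray(ga, dtype=float))
    nodes = spec.nodes
    lo, hi = spec.boundary_knots
    out = np.empty((ga_arr.size, spec.df))

    inside = (ga_arr >= lo) & (ga_arr <= hi)
    below = ga_arr < lo
    above = ga_arr > hi

    for k in range(1, spec.df + 1):
        unit = np.zeros(nodes.size)
        unit[k] = 1.0
        if nodes.size >= 3:
            cs = CubicSpline(nodes, unit, bc_type="natural")
            col = np.empty(ga_arr.size)
            col[inside] = cs(ga_arr[inside])
            if below.any():
                col[below] = cs(lo) + cs(lo, 1) * (ga_arr[below] - lo)
            if above.any():
                col[above] = cs(hi) + cs(hi, 1) * (ga_arr[above] - hi)
        else:
            # df=1: two nodes, natural spline is the straight line through them
            col = (ga_arr - nodes[0]) / (nodes[1] - nodes[0])
        out[:, k - 1] = col
    if np.isscalar(ga) or np.ndim(ga) == 0:
        return out[0]
    return out
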