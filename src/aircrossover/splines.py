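"""Natural cubic spline bases for nonlinear confounder adjustment and
concentration-response modelling.

The basis is the truncated-power natural cubic spline: piecewise cubic,
twice continuously differentiable, and constrained to be *linear* beyond the
boundary knots.  With K knots the basis spans K-1 free columns (the model's
stratum-wise conditioning absorbs the constant), so "degrees of freedom = 4"
means 5 knots: two boundary knots and three interior knots.

By default knots are placed from the data: boundary knots at the 1st/99th
percentiles and interior knots at equally spaced quantiles in between (the
25th/50th/75th percentiles for df = 4).  The covariate is standardised
before the cubic terms are formed, which keeps the design well conditioned;
the standardisation constants are frozen in the spec so a fitted basis can
be evaluated at new points (e.g. along a concentration grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "natural_spline_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout (data units) for a natural cubic spline basis."""

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if any(k <= lo or k >= hi for k in self.interior_knots):
            raise ValueError("boundary knots must strictly contain interior knots")
        knots = self.all_knots
        if len(set(knots)) != len(knots):
            raise ValueError("duplicate knots")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def all_knots(self) -> tuple[float, ...]:
        return tuple(sorted((self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1])))

    @property
    def df(self) -> int:
        return len(self.all_knots) - 1

    @classmethod
    def from_data(cls, x, df: int = 4) -> "SplineSpec":
        """Quantile knot rule: boundary at the 1st/99th percentiles, df - 1
        interior knots at equally spaced quantiles between the quart
        positions i/df, i = 1..df-1 (25/50/75% for df = 4)."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < df + 1:
            raise ValueError("not enough data points to place knots")
        if df < 2:
            raise ValueError("df must be >= 2")
        lo, hi = np.percentile(x, [1.0, 99.0])
        qs = np.percentile(x, 100.0 * np.arange(1, df) / df)
        if not lo < hi:
            raise ValueError("degenerate covariate: 1st and 99th percentiles equal")
        # Nudge interior knots strictly inside the boundary if quantiles tie.
        qs = np.clip(qs, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        if len(np.unique(qs)) != len(qs):
            raise ValueError("duplicate knots (covariate too discrete for this df)")
        center = float(np.median(x))
        scale = float(np.std(x)) or 1.0
        return cls(tuple(float(q) for q in qs), (float(lo), float(hi)), center, scale)

    def basis(self, x) -> np.ndarray:
        """Evaluate the df-column basis at ``x`` (linear extrapolation
        beyond the boundary knots, as the natural constraint implies)."""
        return natural_spline_basis(x, self)


def natural_spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Truncated-power natural cubic spline basis matrix (n × df).

    Columns: the (standardised) covariate itself, then the K-2 natural
    cubic terms d_k(x) - d_{K-2}(x) with
    d_k(x) = [(x-ξ_k)_+^3 - (x-ξ_{K-1})_+^3] / (ξ_{K-1} - ξ_k)
    over the standardised knots ξ_0 < ... < ξ_{K-1}.
    """
    x = np.asarray(x, dtype=float)
    z = (x - spec.center) / spec.scale
    knots = (np.asarray(spec.all_knots) - spec.center) / spec.scale
    K = knots.size

    def pos3(u):
        return np.where(u > 0, u, 0.0) ** 3

    last = pos3(z - knots[-1])

    def d(k):
        return (pos3(z - knots[k]) - last) / (knots[-1] - knots[k])

    d_pen = d(K - 2)
    cols = [z] + [d(k) - d_pen for k in range(K - 2)]
    return np.stack(cols, axis=-1)
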