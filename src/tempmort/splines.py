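"""Restricted (natural) cubic spline bases for covariate adjustment.

Harrell's parameterization: with knots t_1 < ... < t_k the basis has
k−1 columns — the linear term plus k−2 nonlinear terms

    S_j(x) = [ (x−t_j)_+^3
               − (x−t_{k−1})_+^3 (t_k−t_j)/(t_k−t_{k−1})
               + (x−t_k)_+^3 (t_{k−1}−t_j)/(t_k−t_{k−1}) ] / (t_k−t_1)^2

which is linear beyond the terminal knots with continuous first and
second derivatives everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineError", "SplineBasis", "default_knot_percentiles", "rcs_basis"]


class SplineError(ValueError):
    pass


# Conventional percentile placements (Harrell 2015, table 2.3).
_KNOT_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
    6: (5.0, 23.0, 41.0, 59.0, 77.0, 95.0),
    7: (2.5, 18.33, 34.17, 50.0, 65.83, 81.67, 97.5),
}


def default_knot_percentiles(n_knots: int) -> tuple[float, ...]:
    if n_knots in _KNOT_PERCENTILES:
        return _KNOT_PERCENTILES[n_knots]
    # equally spaced in probability with 5%/95% terminals
    return tuple(np.linspace(5.0, 95.0, n_knots))


@dataclass(frozen=True)
class SplineBasis:
    """Knot locations plus the transform producing the design columns."""

    knots: tuple[float, ...]

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        """Evaluate the k−1 design columns (linear term first) at x."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(self.knots)
        k = len(t)
        denom = (t[-1] - t[0]) ** 2
        cols = [x]
        for j in range(k - 2):
            term = (
                np.clip(x - t[j], 0.0, None) ** 3
                - np.clip(x - t[k - 2], 0.0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[k - 2])
                + np.clip(x - t[-1], 0.0, None) ** 3 * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
            )
            cols.append(term / denom)
        return np.column_stack(cols)

    def column_names(self, name: str) -> list[str]:
        return [f"rcs({name})1"] + [f"rcs({name}){j + 2}" for j in range(len(self.knots) - 2)]


def rcs_basis(
    x,
    n_knots: int = 4,
    knots: tuple[float, ...] | None = None,
) -> tuple[SplineBasis, np.ndarray]:
    """Restricted cubic spline basis with percentile-placed knots.

    Parameters
    ----------
    x
        Sample used both for knot placement and for the returned design
        columns.
    n_knots
        Number of knots (>= 3); ignored when explicit ``knots`` given.
    knots
        Explicit knot locations (must be strictly increasing).

    Returns
    -------
    (SplineBasis, design) where design has ``n_knots − 1`` columns, the
    first being x itself.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots < 3:
            raise SplineError("a restricted cubic spline needs at least 3 knots")
        if len(np.unique(x)) < n_knots:
            raise SplineError(
                f"need at least {n_knots} distinct values to place {n_knots} knots"
            )
        pct = default_knot_percentiles(n_knots)
        knots = tuple(np.percentile(x, pct))
        if len(np.unique(knots)) < n_knots:
            raise SplineError(
                f"percentile knots are not distinct (heavily tied data): {knots}"
            )
    else:
        knots = tuple(float(t) for t in knots)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise SplineError(f"explicit knots must be >= 3 and strictly increasing: {knots}")
    basis = SplineBasis(knots)
    return basis, basis.transform(x)
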