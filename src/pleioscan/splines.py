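"""Restricted cubic spline basis (natural spline, linear beyond the boundary
knots), in the standard truncated-power parameterization with the usual
quantile-based knot placement."""

from __future__ import annotations

import numpy as np

from ._errors import DataError

KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def default_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    if n_knots not in KNOT_QUANTILES:
        raise DataError(f"unsupported knot count {n_knots}; choose from {sorted(KNOT_QUANTILES)}")
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x[~np.isnan(x)], KNOT_QUANTILES[n_knots])
    if np.unique(knots).size < n_knots:
        raise DataError("degenerate knots: too few distinct covariate values")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Columns: x itself plus k-2 restricted cubic terms (k = len(knots))."""
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    k = knots.size
    if k < 3:
        raise DataError("rcs_basis needs at least 3 knots")
    t1, t_km1, t_k = knots[0], knots[-2], knots[-1]
    scale = (t_k - t1) ** 2

    def pos3(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - t_km1) * (t_k - tj) / (t_k - t_km1)
            + pos3(x - t_k) * (t_km1 - tj) / (t_k - t_km1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)
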