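"""Natural cubic spline basis for formulas.

Provides ``ns(x, df)`` usable inside patsy formulas.  Internal knots are placed
at equally spaced quantiles of the training data and boundary knots at the
observed range, so the spanned function space matches the conventional
natural-spline regression setup: ``df`` basis columns (intercept excluded),
linear extrapolation beyond the boundary knots.
"""

from __future__ import annotations

import numpy as np
from patsy import stateful_transform


class NaturalSpline:
    """Stateful natural cubic spline transform (truncated power basis).

    With boundary knots ``b0 < b1`` and internal knots ``k_1 < ... < k_m`` the
    basis is ``x`` together with ``d_j(x) - d_{m}(x)`` for ``j = 0..m-1``
    where ``d_j`` are the usual scaled truncated cubic differences; the
    quadratic and cubic terms cancel outside the boundary knots, so the fit is
    linear there.
    """

    def __init__(self) -> None:
        self._knots: np.ndarray | None = None

    def memorize_chunk(self, x, df=3, knots=None, boundary_knots=None):
        x = np.asarray(x, dtype=float)
        if knots is not None:
            inner = np.sort(np.asarray(knots, dtype=float))
        else:
            if df < 1:
                raise ValueError("ns requires df >= 1")
            probs = np.linspace(0, 1, df + 1)[1:-1]
            inner = np.quantile(x[~np.isnan(x)], probs) if len(probs) else np.array([])
        if boundary_knots is not None:
            lo, hi = boundary_knots
        else:
            lo, hi = np.nanmin(x), np.nanmax(x)
        self._knots = np.concatenate([[lo], inner, [hi]])

    def memorize_finish(self):
        pass

    def transform(self, x, df=3, knots=None, boundary_knots=None):
        x = np.asarray(x, dtype=float)
        knots_all = self._knots
        assert knots_all is not None
        K = len(knots_all)

        scale = (knots_all[-1] - knots_all[0]) ** 2  # keep columns O(range)

        def d(j):
            num = np.clip(x - knots_all[j], 0, None) ** 3 - np.clip(
                x - knots_all[K - 1], 0, None
            ) ** 3
            return num / (knots_all[K - 1] - knots_all[j]) / scale

        cols = [x]
        d_last = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - d_last)
        return np.column_stack(cols)


ns = stateful_transform(NaturalSpline)
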