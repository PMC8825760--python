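"""LOESS smoothing of the crude pseudotime.

Averaging discretized orderings leaves a step-like, locally noisy curve.
The final step regresses the crude pseudotime (response) on its own
ranking (predictor) with local polynomial regression and rescales the fit
to [0, 1].  The LOESS here is the classical one: for each target point,
fit a weighted least-squares polynomial of degree 1 or 2 over the
``q = ceil(span * n)`` nearest neighbours in the predictor, with tri-cube
weights ``w(u) = (1 - |u|^3)^3`` on distances scaled by the window radius.
Boundary windows are the usual asymmetric nearest-neighbour windows; there
are no robustness (bisquare) iterations.  Every point is fitted exactly up
to n = 50,000; above that the fit is evaluated on an even 5,000-point rank
grid and interpolated linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = ["LoessParams", "loess_fit", "smooth_pseudotime"]

_EXACT_FIT_MAX_N = 50_000
_GRID_SIZE = 5_000


@dataclass(frozen=True)
class LoessParams:
    """span: fraction of points per local window; degree: local polynomial."""

    span: float = 0.1
    degree: int = 2

    def __post_init__(self):
        if not (0.0 < self.span <= 1.0):
            raise InvalidParameterError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (1, 2):
            raise InvalidParameterError(f"degree must be 1 or 2, got {self.degree}")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.abs(u) ** 3) ** 3
    w[np.abs(u) >= 1.0] = 0.0
    return w


def _fit_at_targets(
    xs: np.ndarray, ys: np.ndarray, targets: np.ndarray, q: int, degree: int
) -> np.ndarray:
    """WLS polynomial fit over the q nearest neighbours of each target.

    ``xs``/``ys`` must be sorted by ``xs`` and ``targets`` ascending; the
    q-nearest window of a target is then contiguous and its start is
    non-decreasing across targets, so a single sliding pointer finds it.
    """
    n = xs.size
    out = np.empty(targets.size)
    lo = 0
    for i, x0 in enumerate(targets):
        # slide right while the point entering is strictly nearer than the
        # one leaving (ties keep the leftmost window — deterministic)
        while lo + q < n and xs[lo + q] - x0 < x0 - xs[lo]:
            lo += 1
        hi = lo + q
        xw = xs[lo:hi] - x0
        d = np.abs(xw)
        dmax = d.max()
        if dmax == 0.0:
            w = np.ones_like(d)
        else:
            w = _tricube(d / dmax)
            # guard against an all-zero window when every neighbour sits on
            # the boundary (cannot happen with distinct predictors, q >= 2)
            if not np.any(w > 0):
                w = np.ones_like(d)
        scale = dmax if dmax > 0 else 1.0
        design = np.vander(xw / scale, N=degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ys[lo:hi] * sw, rcond=None)
        out[i] = coef[0]
    return out


def loess_fit(x, y, params: LoessParams | None = None) -> np.ndarray:
    """Fitted LOESS values at every ``x``.

    Parameters
    ----------
    x, y
        Predictor and response vectors of equal length.
    params
        Span and polynomial degree; defaults ``span=0.1, degree=2``.
    """
    params = params or LoessParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D vectors of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite values in LOESS input")
    n = x.size
    q = int(np.ceil(params.span * n))
    if q < params.degree + 2:
        raise InvalidParameterError(
            f"window of {q} points is too small for degree {params.degree}; "
            f"increase span (need ceil(span*n) >= {params.degree + 2})"
        )
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted_sorted = _fit_at_targets(xs, ys, xs, q, params.degree)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def smooth_pseudotime(
    crude, params: LoessParams | None = None, tie_key=None
) -> np.ndarray:
    """Smooth a crude pseudotime against its ranking; rescale to [0, 1].

    The predictor is the ordinal rank of the crude values, the response
    the crude values themselves.  Rank ties are broken by ``tie_key``
    (e.g. a canonical per-cell ordering) when given, otherwise by stable
    input position; ordinal ranks keep the predictor strictly increasing,
    which local quadratic fits require.
    """
    params = params or LoessParams()
    values = np.asarray(getattr(crude, "values", crude), dtype=float)
    if values.ndim != 1:
        raise InvalidInputError("crude pseudotime must be a 1-D vector")
    if values.size < params.degree + 2:
        raise InvalidInputError(
            f"need at least {params.degree + 2} cells, got {values.size}"
        )
    if np.all(values == values[0]):
        raise DegenerateInputError("crude pseudotime is constant; no ordering exists")
    if tie_key is not None:
        order = np.lexsort((np.asarray(tie_key), values))
    else:
        order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size)
    ranks[order] = np.arange(values.size, dtype=float)

    n = values.size
    q = int(np.ceil(params.span * n))
    if q < params.degree + 2:
        raise InvalidParameterError(
            f"span {params.span} gives a {q}-point window; need "
            f">= {params.degree + 2} points"
        )
    xs, ys = ranks[order], values[order]
    if n <= _EXACT_FIT_MAX_N:
        fitted_sorted = _fit_at_targets(xs, ys, xs, q, params.degree)
    else:
        grid = np.linspace(xs[0], xs[-1], _GRID_SIZE)
        on_grid = _fit_at_targets(xs, ys, grid, q, params.degree)
        fitted_sorted = np.interp(xs, grid, on_grid)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    lo, hi = fitted.min(), fitted.max()
    if hi == lo:
        raise DegenerateInputError("smoothed pseudotime collapsed to a constant")
    return (fitted - lo) / (hi - lo)
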