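"""Four-parameter log-logistic (LL.4, Hill-type) dose-response modelling.

The LL.4 curve is

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with slope ``b`` (negative for a rising incidence curve), lower asymptote
``c``, upper asymptote ``d`` (proportions, ``0 <= c < d <= 1``) and
inflection dose ``e`` (f(e) = (c+d)/2).  Curves are fitted by (optionally
weighted) least squares on per-dose affected fractions, and relative
effective concentrations ECp are extracted analytically:

    EC_p = e * exp(ln((100 - p) / p) / b)

so that f(EC_p) = c + (p/100)(d - c).  "Relative" means p percent of the
fitted (c, d) span, the convention used by standard dose-response software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["LL4Params", "ECEstimate", "FitResult", "ll4", "fit_ll4", "ec_p"]


@dataclass(frozen=True)
class LL4Params:
    """Parameters of a four-parameter log-logistic curve."""

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.c < self.d <= 1.0):
            raise ValueError(
                f"asymptotes must satisfy 0 <= c < d <= 1, got c={self.c}, d={self.d}"
            )
        if not self.e > 0:
            raise ValueError(f"inflection dose e must be positive, got e={self.e}")


@dataclass(frozen=True)
class ECEstimate:
    """A relative effective concentration: the dose giving p% of the (c, d) span."""

    p: float
    dose: float
    extrapolated: bool = False


@dataclass(frozen=True)
class FitResult:
    params: LL4Params | None
    rss: float
    converged: bool
    message: str = ""


def ll4(x, params: LL4Params):
    """Evaluate the LL.4 curve at dose(s) ``x`` (must be strictly positive)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("doses must be strictly positive")
    val = params.c + (params.d - params.c) / (
        1.0 + np.exp(params.b * (np.log(x) - math.log(params.e)))
    )
    return float(val) if np.isscalar(x) or x.ndim == 0 else val


def ec_p(params: LL4Params, p: float, tested_range: tuple[float, float] | None = None) -> ECEstimate:
    """Relative ECp: the dose at which the curve attains c + (p/100)(d - c).

    Parameters
    ----------
    params
        Fitted curve.  ``b`` must be nonzero.
    p
        Effect percent, strictly between 0 and 100.  p=50 returns ``e``.
    tested_range
        Optional (low, high) tested dose range; when given, the estimate is
        flagged ``extrapolated`` if the dose falls outside it.
    """
    if not 0 < p < 100:
        raise ValueError(f"effect percent must be in (0, 100), got {p}")
    if params.b == 0:
        raise ValueError("slope b = 0: ECp undefined (flat curve)")
    dose = params.e * math.exp(math.log((100.0 - p) / p) / params.b)
    extrapolated = False
    if tested_range is not None:
        lo, hi = tested_range
        extrapolated = not (lo <= dose <= hi)
    return ECEstimate(p=p, dose=dose, extrapolated=extrapolated)


# multi-start slope grid; e ranges over the tested doses
_B_STARTS = (-4.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 4.0)


def _residuals(theta, log_x, y, sqrt_w):
    b, c, d, log_e = theta
    # clamp the exponent so steep slopes saturate instead of overflowing
    arg = np.clip(b * (log_x - log_e), -60.0, 60.0)
    pred = c + (d - c) / (1.0 + np.exp(arg))
    return sqrt_w * (y - pred)


def fit_ll4(
    doses,
    proportions,
    weights=None,
    n_refine: int = 5,
    tol: float = 1e-8,
) -> FitResult:
    """Least-squares LL.4 fit to per-dose affected fractions.

    Minimizes sum_i w_i (y_i - f(x_i))^2 over b, c, d, e subject to the box
    constraints 0 <= c, d <= 1 (with c < d checked on the solution) and
    e > 0 (optimized on the log scale).  A grid of starting points (slope in
    ``_B_STARTS``, inflection over every tested dose, asymptotes at the
    observed min/max) is scored by the objective and the ``n_refine`` best
    are polished; the best polished solution is returned, which guarantees
    the returned objective is no worse than any start.

    Degenerate inputs (constant response) are reported as non-converged,
    never silently fitted.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and proportions must have equal length")
    if np.any(x <= 0):
        raise ValueError("doses must be strictly positive")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct doses to fit 4 parameters")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    sqrt_w = np.sqrt(w)

    if np.ptp(y) < 1e-9:
        return FitResult(
            params=None,
            rss=float(np.sum(w * (y - y.mean()) ** 2)),
            converged=False,
            message="constant response: curve parameters are unidentifiable",
        )

    log_x = np.log(x)
    c0 = float(np.clip(y.min(), 0.0, 1.0))
    d0 = float(np.clip(y.max(), 0.0, 1.0))
    if d0 <= c0:
        c0, d0 = max(0.0, d0 - 1e-3), min(1.0, c0 + 1e-3)

    starts = [
        np.array([b, c0, d0, le])
        for b in _B_STARTS
        for le in np.unique(log_x)
    ]
    scores = [float(np.sum(_residuals(t, log_x, y, sqrt_w) ** 2)) for t in starts]
    order = np.argsort(scores, kind="stable")[: max(1, n_refine)]

    lb = np.array([-50.0, 0.0, 0.0, log_x.min() - math.log(100.0)])
    ub = np.array([50.0, 1.0, 1.0, log_x.max() + math.log(100.0)])

    best = None
    best_rss = math.inf
    for idx in order:
        t0 = np.clip(starts[idx], lb, ub)
        try:
            sol = least_squares(
                _residuals,
                t0,
                args=(log_x, y, sqrt_w),
                bounds=(lb, ub),
                xtol=tol,
                ftol=tol,
                gtol=tol,
            )
        except Exception:  # pragma: no cover - scipy failure on odd input
            continue
        rss = float(np.sum(sol.fun**2))
        # status 0 = budget exhausted; still usable when the fit is already
        # essentially exact (a perfectly steep curve has an unbounded slope
        # direction the optimizer keeps chasing)
        exact = rss <= 1e-10 * max(1.0, float(np.sum(w * y**2)))
        if (sol.success or (sol.status == 0 and exact)) and rss < best_rss:
            best, best_rss = sol, rss

    if best is None:
        return FitResult(
            params=None,
            rss=math.inf,
            converged=False,
            message="least-squares optimization failed from every start",
        )

    b, c, d, log_e = best.x
    if d <= c:
        return FitResult(
            params=None,
            rss=best_rss,
            converged=False,
            message="degenerate solution: upper asymptote not above lower",
        )
    params = LL4Params(b=float(b), c=float(c), d=float(d), e=float(math.exp(log_e)))
    return FitResult(params=params, rss=best_rss, converged=True, message="converged")
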