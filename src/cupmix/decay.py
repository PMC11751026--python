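"""Exponential distance-decay fits of spray-drift gradients.

Per-sample compound counts (or concentrations) decline with distance from
the field margin. The model is

    y = a * exp(b * x) + c

with ``a`` the amplitude at the margin, ``b`` the decay rate (1/m; more
negative = faster decay) and ``c`` a *fixed* background level, never
estimated: by convention it is the mean response of the in-field subset
(sampled at -20 m inside the crop, mapped to distance 0, as the in-field
level is taken to represent the field-margin source strength). Only
``(a, b)`` are free, fitted by damped (Levenberg-Marquardt) least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

DISTANCE_M = {"in_field": 0.0, "m1": 1.0, "m5": 5.0, "m20": 20.0}


def map_distance(distance_class: str) -> float:
    """Metres from the field margin for a distance class (in-field -> 0)."""
    try:
        return DISTANCE_M[distance_class]
    except KeyError:
        raise KeyError(
            f"unknown distance class {distance_class!r}; expected one of "
            f"{sorted(DISTANCE_M)}") from None


@dataclass(frozen=True)
class ExpFitResult:
    """Fitted exponential gradient with diagnostics."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool
    n_obs: int
    warnings: tuple[str, ...] = ()

    def predict(self, x) -> np.ndarray | float:
        return predict(self, x)


def fit_exponential(
    x,
    y,
    c: float | None = None,
    include_infield: bool = True,
    b0: float = -0.1,
    max_iter: int = 200,
) -> ExpFitResult:
    """Fit ``y = a*exp(b*x) + c`` with fixed background ``c``.

    Parameters
    ----------
    x, y
        Distances (m) and responses. At least two distinct non-zero
        distances are required, and — when ``c`` is not supplied — at least
        one observation at x = 0 to set the background.
    c
        Fixed background. ``None`` (default) applies the in-field-mean rule:
        c = mean of the y values at x = 0.
    include_infield
        Whether the x = 0 observations enter the residual sum (default) or
        serve only to set ``c``.
    b0
        Initial decay rate. The amplitude is initialised from the spread
        a0 = max(mean(y|x=0) - mean(y|x=x_max), 1e-3).

    Notes
    -----
    ``b`` is unconstrained; fits with b > 0 (growth with distance) or a <= 0
    are returned but flagged in ``warnings``. A degenerate all-equal response
    leaves the amplitude unidentifiable and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.ptp(y) == 0:
        raise ValueError("all responses identical: amplitude unidentifiable")
    at0 = x == 0
    if c is None:
        if not at0.any():
            raise ValueError("no x = 0 observations to fix the background c")
        c = float(y[at0].mean())
    nonzero_x = np.unique(x[~at0])
    if nonzero_x.size < 2:
        raise ValueError("need >= 2 distinct non-zero distances")

    if include_infield:
        xf, yf = x, y
    else:
        xf, yf = x[~at0], y[~at0]

    y0_mean = float(y[at0].mean()) if at0.any() else float(yf.max())
    far_mean = float(y[x == x.max()].mean())
    a0 = max(y0_mean - far_mean, 1e-3)

    def residuals(theta):
        a, b = theta
        return a * np.exp(np.clip(b * xf, -700, 700)) + c - yf

    sol = least_squares(residuals, x0=[a0, b0], method="lm",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=max_iter * 10)
    a_hat, b_hat = map(float, sol.x)
    warnings = []
    if b_hat > 0:
        warnings.append("fitted b > 0: response grows with distance")
    if a_hat <= 0:
        warnings.append("fitted a <= 0: no positive margin excess over background")
    return ExpFitResult(a=a_hat, b=b_hat, c=float(c),
                        rss=float(2.0 * sol.cost),
                        converged=bool(sol.success and np.isfinite(sol.x).all()),
                        n_obs=int(xf.size), warnings=tuple(warnings))


def predict(fit: ExpFitResult, x) -> np.ndarray | float:
    """Expected response a*exp(b*x) + c at distance x (metres)."""
    xa = np.asarray(x, dtype=float)
    out = fit.a * np.exp(fit.b * xa) + fit.c
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def distance_observations(table, matrix: str, system: str | None = None,
                          statistic: str = "n_cups_detected"):
    """Per-sample (distance in m, CUP count) observations for one matrix.

    Pools all months and replicate sites of one management system (or all
    systems when ``system`` is None), as the fits are intended to describe
    the year-round gradient.
    """
    from .summary import summarize_samples

    sub = table.subset(matrix=matrix)
    if system is not None:
        sub = sub.subset(system=system)
    summ = summarize_samples(sub).reset_index()
    x = summ["distance_class"].map(DISTANCE_M).to_numpy(float)
    y = summ[statistic].to_numpy(float)
    return x, y


def fit_distance_decay(table, matrix: str, system: str | None = None,
                       statistic: str = "n_cups_detected",
                       c: float | None = None,
                       include_infield: bool = True) -> ExpFitResult:
    """Convenience: pooled per-sample counts vs. distance, then fit."""
    x, y = distance_observations(table, matrix, system, statistic)
    return fit_exponential(x, y, c=c, include_infield=include_infield)
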