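"""Annual-course modelling: loess smoothing, KL divergence, peak detection.

The seasonal statistic of interest is the per-sample count of detected
compounds, averaged per month over the pooled replicate sites of one
(management system, matrix, distance class). The annual course is smoothed
with a locally weighted polynomial regression (loess; tricube weights,
degree 2 by default, span selected by leave-one-out cross-validation), the
smooths of two systems are normalised to probability curves over the month
grid and compared by the Kullback-Leibler divergence in bits,

    KL(P||Q) = sum_i P_i * log2(P_i / Q_i) = H(P, Q) - H(P),

and seasonal extrema are located by a running-extremum delta-threshold
detector applied to the residuals of a linear trend fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .residue_io import ResidueTable

EPSILON_DEFAULT = 1e-6
DELTA_DEFAULT = 0.3
SPAN_GRID_DEFAULT = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class MonthlySeries:
    """A statistic on the month grid (0 = first February .. 12 = last)."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.shape != values.shape or grid.ndim != 1:
            raise ValueError("grid and values must be 1-D and equal length")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class SmoothedSeries:
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int = 2
    cv_score: float | None = None


@dataclass(frozen=True)
class ProbabilityCurve:
    grid: np.ndarray
    p: np.ndarray
    epsilon: float = EPSILON_DEFAULT

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if np.any(p <= 0):
            raise ValueError("probabilities must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class Peak:
    position: int
    value: float
    kind: str  # "maximum" | "minimum"


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    delta: float

    def maxima(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.kind == "maximum")

    def minima(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.kind == "minimum")


def monthly_series(table: ResidueTable, matrix: str, system: str,
                   distance_class: str = "in_field",
                   statistic: str = "n_cups_detected") -> MonthlySeries:
    """Per-month mean of a per-sample statistic, pooled over replicate sites."""
    from .summary import summarize_samples

    sub = table.subset(matrix=matrix, system=system,
                       distance_class=distance_class)
    summ = summarize_samples(sub).reset_index()
    if summ.empty:
        raise ValueError(
            f"no samples for matrix={matrix!r}, system={system!r}, "
            f"distance_class={distance_class!r}")
    means = summ.groupby("month_index")[statistic].mean().sort_index()
    return MonthlySeries(means.index.to_numpy(float), means.to_numpy(float))


def _loess_window(n: int, span: float, degree: int) -> int:
    k = int(np.ceil(span * n))
    return min(max(k, 3, degree + 1), n)


def _loess_at(x: np.ndarray, y: np.ndarray, x0: float, k: int,
              degree: int) -> float:
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:k]
    xs, ys, ds = x[idx], y[idx], d[idx]
    h = ds.max()
    if h == 0:
        return float(ys.mean())
    w = (1.0 - np.clip(ds / h, 0.0, 1.0) ** 3) ** 3
    if (w > 0).sum() <= degree:   # boundary weights vanish; drop the degree
        degree = max((w > 0).sum() - 1, 0)
    sw = np.sqrt(w)
    X = np.vander(xs - x0, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
    return float(beta[0])


def fit_loess(series: MonthlySeries, span: float, degree: int = 2) -> SmoothedSeries:
    """Tricube-weighted local polynomial regression evaluated on the grid.

    ``span`` is the fraction of points in the local window (window of at
    least 3 points required); ``degree`` 1 (locally linear) or 2 (locally
    quadratic, the default, matching the classical loess smoother).
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = len(series.grid)
    if n < 4:
        raise ValueError("need at least 4 points to smooth")
    if int(np.ceil(span * n)) < 3:
        raise ValueError(f"span {span} yields a window below 3 points")
    k = _loess_window(n, span, degree)
    fitted = np.array([
        _loess_at(series.grid, series.values, x0, k, degree)
        for x0 in series.grid
    ])
    return SmoothedSeries(series.grid, fitted, span=span, degree=degree)


def select_span_cv(series: MonthlySeries, candidate_spans: Sequence[float],
                   degree: int = 2) -> float:
    """Leave-one-out cross-validated span selection.

    Returns the candidate minimising mean squared leave-one-out prediction
    error; ties are broken towards the *largest* (smoothest) span.
    Candidates whose window is infeasible are skipped; if none is feasible a
    ``ValueError`` is raised.
    """
    if len(candidate_spans) < 2:
        raise ValueError("need at least 2 candidate spans")
    x, y = series.grid, series.values
    n = len(x)
    best_span, best_score = None, np.inf
    for span in sorted(candidate_spans):
        if not (0.0 < span <= 1.0) or int(np.ceil(span * (n - 1))) < 3:
            continue
        k = _loess_window(n - 1, span, degree)
        if k <= degree:
            continue
        errs = []
        for i in range(n):
            xs = np.delete(x, i)
            ys = np.delete(y, i)
            pred = _loess_at(xs, ys, x[i], k, degree)
            errs.append((pred - y[i]) ** 2)
        score = float(np.mean(errs))
        if score <= best_score + 1e-12:  # ties -> larger span (ascending loop)
            best_span, best_score = span, min(score, best_score)
    if best_span is None:
        raise ValueError("no feasible candidate span")
    return best_span


def detrend_linear(series: MonthlySeries) -> MonthlySeries:
    """Residuals of an ordinary least-squares line of value on month."""
    if len(series.grid) < 3:
        raise ValueError("need at least 3 points to detrend")
    if np.ptp(series.grid) == 0:
        raise ValueError("degenerate grid")
    coef = np.polyfit(series.grid, series.values, 1)
    residuals = series.values - np.polyval(coef, series.grid)
    return MonthlySeries(series.grid, residuals)


def detect_peaks(values: Sequence[float], delta: float = DELTA_DEFAULT) -> PeakSet:
    """Running-extremum delta-threshold peak detector.

    A single forward pass tracks the current maximum and minimum candidates;
    when the series moves more than ``delta`` away from a candidate, that
    candidate is emitted as an extremum (position and value recorded) and
    the search direction flips, so emitted kinds alternate. A trailing
    candidate that the series never moves ``delta`` away from remains
    pending and is not emitted.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    v = np.asarray(values, dtype=float)
    peaks: list[Peak] = []
    if v.size == 0:
        return PeakSet((), delta)
    mx, mn = v[0], v[0]
    mx_pos = mn_pos = 0
    look_for_max = True
    for i, val in enumerate(v):
        if val > mx:
            mx, mx_pos = val, i
        if val < mn:
            mn, mn_pos = val, i
        if look_for_max:
            if val < mx - delta:
                peaks.append(Peak(mx_pos, float(mx), "maximum"))
                mn, mn_pos = val, i
                look_for_max = False
        else:
            if val > mn + delta:
                peaks.append(Peak(mn_pos, float(mn), "minimum"))
                mx, mx_pos = val, i
                look_for_max = True
    return PeakSet(tuple(peaks), delta)


def to_probability(curve: SmoothedSeries,
                   epsilon: float = EPSILON_DEFAULT) -> ProbabilityCurve:
    """Normalise a smooth to a probability curve over the month grid.

    Fitted values are floored at ``epsilon`` (negative excursions of the
    smooth are clipped) and divided by their sum, so the result lives on the
    epsilon-floored simplex required by the KL divergence.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    f = np.asarray(curve.fitted, dtype=float)
    if np.all(f <= 0):
        raise ValueError("all fitted values <= 0: cannot normalise")
    floored = np.maximum(f, epsilon)
    return ProbabilityCurve(curve.grid, floored / floored.sum(), epsilon)


def kl_divergence(P: ProbabilityCurve, Q: ProbabilityCurve) -> float:
    """Kullback-Leibler divergence KL(P||Q) in bits; >= 0, asymmetric."""
    if P.p.shape != Q.p.shape or not np.array_equal(P.grid, Q.grid):
        raise ValueError("probability curves live on different grids")
    return float(np.sum(P.p * np.log2(P.p / Q.p)))


def compare_systems(series_by_system: dict[str, MonthlySeries],
                    span: float | None = None,
                    candidate_spans: Sequence[float] = SPAN_GRID_DEFAULT,
                    degree: int = 2,
                    epsilon: float = EPSILON_DEFAULT) -> pd.DataFrame:
    """Pairwise KL matrix between the smoothed annual courses of systems.

    Each series is loess-fitted (span cross-validated per series unless a
    fixed ``span`` is given), normalised, and compared for every ordered
    pair. The diagonal is identically 0.
    """
    if len(series_by_system) < 2:
        raise ValueError("need at least 2 systems to compare")
    curves = {}
    for name, series in series_by_system.items():
        s = span if span is not None else select_span_cv(
            series, candidate_spans, degree)
        curves[name] = to_probability(fit_loess(series, s, degree), epsilon)
    names = list(curves)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for p_name in names:
        for q_name in names:
            if p_name != q_name:
                mat.loc[p_name, q_name] = kl_divergence(
                    curves[p_name], curves[q_name])
    return mat
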