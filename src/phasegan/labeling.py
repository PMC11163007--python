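"""Phase labeling across a concentration-ordered series of spectra.

Two procedures assign sol/gel labels to a plate sweep from a scalar summary
feature per well:

* sigmoid-inflection labeling — fit a 4-parameter logistic to the feature
  sequence; wells before the inflection point are "before" (solution), wells
  after it are "after" (gel).  Used for thermogelling sweeps where the
  feature saturates on both sides of the transition.
* two-line-intersection labeling — fit ordinary least-squares lines to the
  two segments around every candidate breakpoint, pick the breakpoint with
  minimal total residual sum of squares, and place the transition at the
  intersection of the two best-fit lines.  Used for sweeps where the feature
  changes slope rather than saturating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import SpectralDataset

logger = logging.getLogger(__name__)

__all__ = ["LabeledSeries", "series_feature", "label_by_sigmoid_inflection",
           "label_by_two_line_intersection"]

BEFORE = "before"
AFTER = "after"


@dataclass
class LabeledSeries:
    """A labeled concentration series: two contiguous blocks of wells.

    Wells with index < ``transition_index`` are labeled ``"before"`` and the
    rest ``"after"``; labels are never interleaved.
    """

    feature: np.ndarray
    labels: list[str]
    transition_index: int
    fit_diagnostics: dict

    def __post_init__(self) -> None:
        expected = [BEFORE if i < self.transition_index else AFTER
                    for i in range(len(self.feature))]
        if self.labels != expected:
            raise ValueError("labels must form contiguous before/after blocks")


_REDUCERS = {
    "min": lambda v: v.min(axis=1),
    "max": lambda v: v.max(axis=1),
    "mean": lambda v: v.mean(axis=1),
}


def series_feature(dataset: SpectralDataset, reducer: str = "value_at",
                   index: int | None = None) -> np.ndarray:
    """One scalar summary per spectrum, order preserved.

    ``reducer`` is one of ``"value_at"`` (value at a fixed measurement
    position), ``"min"``, ``"max"``, ``"mean"``.  The default is the value
    at the peak center — the position of the phase-angle dip, auto-detected
    as the argmin of the across-well mean spectrum when no ``index`` is
    given — because that scalar responds linearly to the sol-gel morphing
    of the curve, which the extremal reducers distort.
    """
    values = dataset.values
    if reducer == "value_at":
        if index is None:
            index = int(np.argmin(values.mean(axis=0)))
        if not 0 <= index < values.shape[1]:
            raise ValueError("index out of range")
        return values[:, index].copy()
    if reducer not in _REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}")
    return _REDUCERS[reducer](values)


def _logistic(x, a, b, x0, s):
    return a + (b - a) / (1.0 + np.exp(-(x - x0) / s))


def label_by_sigmoid_inflection(feature, max_restarts: int = 5) -> LabeledSeries:
    """Label a series by the inflection of a fitted 4-parameter logistic.

    f(x) = a + (b - a) / (1 + exp(-(x - x0)/s)) is fitted by least squares
    over well index x = 0..N-1; the transition index is the smallest index
    strictly greater than the inflection x0.  Initialization: a, b from the
    early/late plateaus, x0 at the steepest finite difference, s = N/10;
    up to ``max_restarts`` jittered restarts.
    """
    y = np.asarray(feature, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 points for a sigmoid fit")
    x = np.arange(n, dtype=float)
    spread = y.max() - y.min()
    if spread <= 1e-12 * max(1.0, abs(y).max()):
        raise ValueError("constant feature: sigmoid fit is non-identifiable")

    a0 = float(np.mean(y[: max(3, n // 10)]))
    b0 = float(np.mean(y[-max(3, n // 10):]))
    x0_init = float(np.argmax(np.abs(np.diff(y))) + 0.5)
    s0 = n / 10.0

    def residuals(p):
        return _logistic(x, *p) - y

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = [a0, b0, x0_init, s0]
        else:
            p0 = [a0, b0,
                  float(np.clip(x0_init + rng.normal(0, n / 8), 0, n - 1)),
                  s0 * float(np.exp(rng.normal(0, 0.5)))]
        try:
            fit = least_squares(residuals, p0,
                                bounds=([-np.inf, -np.inf, -n, 1e-6],
                                        [np.inf, np.inf, 2.0 * n, 10.0 * n]))
        except Exception:  # noqa: BLE001 - restart on any solver failure
            continue
        rss = float(np.sum(fit.fun ** 2))
        if best is None or rss < best[1]:
            best = (fit, rss)
        if rss <= 1e-10 * max(1.0, float(np.sum(y ** 2))):
            break
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge after restarts")
    fit, rss = best
    a, b, x0, s = (float(v) for v in fit.x)
    if abs(b - a) <= 1e-9 * max(1.0, spread):
        raise ValueError("degenerate sigmoid fit: no transition amplitude")
    # snap an inflection that is numerically an integer before applying the
    # "smallest index strictly greater than x0" rule
    x0_snapped = round(x0) if abs(x0 - round(x0)) < 1e-6 else x0
    transition = int(math.floor(x0_snapped)) + 1
    transition = int(np.clip(transition, 0, n))
    labels = [BEFORE if i < transition else AFTER for i in range(n)]
    diag = {"a": a, "b": b, "x0": x0, "s": s, "rss": rss, "n_points": n}
    return LabeledSeries(y, labels, transition, diag)


def label_by_two_line_intersection(feature, min_segment: int = 3) -> LabeledSeries:
    """Label a series at the intersection of two best-fit regression lines.

    Every breakpoint k splitting the series into segments of at least
    ``min_segment`` points is scored by the total RSS of independent OLS
    lines on [0..k-1] and [k..N-1]; ties break to the smallest k.  The
    transition index is the ceiling of the two lines' intersection abscissa
    (the transition well belongs to the post-transition phase).  If the best
    lines are parallel or intersect outside the observed range, the
    breakpoint itself is used as the transition (with a warning).
    """
    y = np.asarray(feature, dtype=float)
    n = y.size
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} points")
    x = np.arange(n, dtype=float)

    def ols(xs, ys):
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        return slope, intercept, float(np.sum(resid ** 2))

    best_k, best = None, None
    for k in range(min_segment, n - min_segment + 1):
        m1, c1, r1 = ols(x[:k], y[:k])
        m2, c2, r2 = ols(x[k:], y[k:])
        rss = r1 + r2
        if best is None or rss < best[4] - 1e-12 * max(1.0, abs(best[4])):
            best_k, best = k, (m1, c1, m2, c2, rss)
    m1, c1, m2, c2, rss = best
    scale = max(abs(m1), abs(m2), 1e-12)
    diag = {"breakpoint": best_k, "slope_left": m1, "intercept_left": c1,
            "slope_right": m2, "intercept_right": c2, "rss": rss, "n_points": n}
    if abs(m1 - m2) <= 1e-9 * scale:
        logger.warning("parallel best-fit lines; falling back to breakpoint %d", best_k)
        transition = best_k
        diag["intersection"] = None
    else:
        x_star = (c2 - c1) / (m1 - m2)
        if not 0.0 <= x_star <= n - 1:
            logger.warning("line intersection %.2f outside range; using breakpoint %d",
                           x_star, best_k)
            transition = best_k
            diag["intersection"] = float(x_star)
        else:
            transition = int(math.ceil(x_star))
            diag["intersection"] = float(x_star)
    labels = [BEFORE if i < transition else AFTER for i in range(n)]
    return LabeledSeries(y, labels, transition, diag)
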