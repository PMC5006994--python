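"""Storage-time trendline models for plasma quality markers.

Marker abundance as a function of hours of whole-blood storage at 25 °C is
modelled by one of three two-parameter trendlines:

* power        y = a * x**b        (fit by OLS on ln x vs ln y)
* linear       y = a * x + b       (ordinary least squares)
* logarithmic  y = a * ln(x) + b   (OLS on ln x)

R² is always computed in the original y space (1 − SS_res / SS_tot), so the
three kinds are comparable and :func:`select_trendline` can pick the best one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

KINDS = ("linear", "logarithmic", "power")


@dataclass
class TrendlineFit:
    """One fitted trendline: kind, coefficients a and b, R², point count."""

    kind: str
    a: float
    b: float
    r2: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


def evaluate_trendline(fit: TrendlineFit, hours) -> np.ndarray | float:
    """Trendline value at the given storage time(s) in hours.

    Power and logarithmic kinds require hours > 0 (ln 0 is undefined).
    """
    x = np.asarray(hours, dtype=float)
    if fit.kind in ("power", "logarithmic") and np.any(x <= 0):
        raise ValueError(f"{fit.kind} trendline requires hours > 0")
    if fit.kind == "linear":
        y = fit.a * x + fit.b
    elif fit.kind == "logarithmic":
        y = fit.a * np.log(x) + fit.b
    else:
        y = fit.a * np.power(x, fit.b)
    return float(y) if np.isscalar(hours) else y


def _r2_original_space(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def fit_trendline(hours, nla, kind: str) -> TrendlineFit:
    """Least-squares fit of one trendline kind.

    Points violating the kind's positivity requirements (x ≤ 0 for power and
    logarithmic; y ≤ 0 for power) are excluded with a warning; fewer than
    three surviving points is an error.
    """
    x = np.asarray(hours, dtype=float)
    y = np.asarray(nla, dtype=float)
    if x.shape != y.shape:
        raise ValueError("hours and nla must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if kind in ("power", "logarithmic"):
        keep &= x > 0
    if kind == "power":
        keep &= y > 0
    if keep.sum() < x.size:
        log.warning("fit_trendline(%s): excluded %d inadmissible point(s)",
                    kind, int(x.size - keep.sum()))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"{kind} fit needs >= 3 admissible points, got {x.size}")

    if kind == "linear":
        a, b = np.polyfit(x, y, 1)
    elif kind == "logarithmic":
        a, b = np.polyfit(np.log(x), y, 1)
    else:
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        a, b = math.exp(intercept), slope
    fit = TrendlineFit(kind, float(a), float(b), n_points=int(x.size))
    fit.r2 = _r2_original_space(y, np.asarray(evaluate_trendline(fit, x)))
    return fit


def select_trendline(hours, nla) -> TrendlineFit:
    """Fit all admissible kinds and return the one with the highest R²
    (original y space).  Exact ties break toward linear, then logarithmic,
    then power."""
    best: TrendlineFit | None = None
    for kind in KINDS:
        try:
            fit = fit_trendline(hours, nla, kind)
        except ValueError:
            continue
        if best is None or fit.r2 > best.r2 + 1e-12:
            best = fit
    if best is None:
        raise ValueError("no trendline kind is admissible for these points")
    return best
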