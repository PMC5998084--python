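"""Per-series and per-pixel linear NPP trend estimation with F-test grading.

The inter-annual trend of a pixel's NPP series is summarised by the slope
of the least-squares line

    theta_slope = (n * sum(i * y_i) - sum(i) * sum(y_i))
                  / (n * sum(i^2) - (sum(i))^2),

with the index i running over observation rank 1..n by default (the six
observation years are unevenly spaced; calendar-year spacing is available
by passing an explicit ``time_index``).  Significance comes from the
regression F statistic with (1, n - 2) degrees of freedom and slopes are
graded into five classes:

    slope < 0, p < 0.01          extremely significant decrease
    slope < 0, 0.01 <= p < 0.05  significant decrease
    p >= 0.05                    no significant change
    slope > 0, 0.01 <= p < 0.05  significant increase
    slope > 0, p < 0.01          extremely significant increase
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrendResult",
    "TrendMap",
    "fit_trend",
    "classify_trend",
    "trend_map",
    "CLASSES",
    "INVALID_CLASS",
]

CLASSES = (
    "ext_sig_decrease",
    "sig_decrease",
    "no_change",
    "sig_increase",
    "ext_sig_increase",
)
INVALID_CLASS = "invalid"
_CLASS_CODE = {name: i for i, name in enumerate(CLASSES)}
_CLASS_CODE[INVALID_CLASS] = -1


@dataclass
class TrendResult:
    slope: float        # response units per time step
    intercept: float
    p_value: float      # NaN when undefined (n = 2)
    klass: str | None
    n: int


@dataclass
class TrendMap:
    slope_grid: np.ndarray
    p_grid: np.ndarray
    class_grid: np.ndarray          # integer codes; -1 marks invalid pixels
    class_area_pct: dict[str, float]
    classes: tuple[str, ...] = CLASSES


def classify_trend(slope: float, p_value: float) -> str:
    """Grade a (slope, p) pair into one of the five significance classes.

    Boundaries follow the half-open intervals: p = 0.05 is "no change",
    p = 0.01 falls in the "significant" (not "extremely") class.
    """
    if not (np.isfinite(slope) and np.isfinite(p_value)):
        raise ValueError(f"invalid inputs to classify_trend: slope={slope}, p={p_value}")
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p_value must lie in [0, 1], got {p_value}")
    if p_value >= 0.05 or slope == 0.0:
        return "no_change"
    if slope < 0:
        return "ext_sig_decrease" if p_value < 0.01 else "sig_decrease"
    return "ext_sig_increase" if p_value < 0.01 else "sig_increase"


def fit_trend(values, time_index=None) -> TrendResult:
    """Least-squares trend of one NPP series with F-test significance.

    ``time_index`` defaults to observation rank 1..n.  With n = 2 the
    slope is defined but the p-value is undefined (NaN) and no class is
    assigned.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need at least 2 values in one series")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    n = len(y)
    if time_index is None:
        t = np.arange(1, n + 1, dtype=float)
    else:
        t = np.asarray(time_index, dtype=float)
        if len(t) != n:
            raise ValueError("time_index length must match values")
        if np.any(np.diff(t) <= 0):
            if np.all(t == t[0]):
                raise ValueError("degenerate design: all time_index values identical")
            raise ValueError("time_index must be strictly increasing")

    denom = n * np.sum(t * t) - np.sum(t) ** 2
    slope = float((n * np.sum(t * y) - np.sum(t) * np.sum(y)) / denom)
    intercept = float(np.mean(y) - slope * np.mean(t))

    if n == 2:
        return TrendResult(slope=slope, intercept=intercept,
                           p_value=float("nan"), klass=None, n=n)

    resid = y - (intercept + slope * t)
    sse = float(resid @ resid)
    ssr = slope ** 2 * denom / n   # regression sum of squares
    if sse <= 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        f = ssr / (sse / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
    return TrendResult(slope=slope, intercept=intercept, p_value=p,
                       klass=classify_trend(slope, p), n=n)


def trend_map(stack, mask=None, cell_area: float = 1.0) -> TrendMap:
    """Per-pixel trend fit over a gridded NPP stack.

    ``stack`` has shape (n_years, H, W); ``mask`` selects valid grassland
    pixels.  Pixels with non-finite values get the sentinel class and are
    excluded from the area percentages, which are computed over valid
    pixels only and sum to 100.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (n_years, H, W)")
    n = stack.shape[0]
    if n < 3:
        raise ValueError("need at least 3 layers for a graded trend map")
    H, W = stack.shape[1:]
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError("mask shape must match grid shape")
    if not mask.any():
        raise ValueError("empty mask: zero valid pixels")

    t = np.arange(1, n + 1, dtype=float)
    finite = np.all(np.isfinite(stack), axis=0)
    valid = mask & finite

    tbar = t.mean()
    denom = n * np.sum(t * t) - np.sum(t) ** 2
    sum_y = stack.sum(axis=0)
    sum_ty = np.tensordot(t, stack, axes=(0, 0))
    with np.errstate(invalid="ignore"):
        slope = (n * sum_ty - np.sum(t) * sum_y) / denom
        intercept = sum_y / n - slope * tbar
        fitted = intercept[None] + slope[None] * t[:, None, None]
        sse = np.sum((stack - fitted) ** 2, axis=0)
        ssr = slope ** 2 * denom / n
        f = np.where(sse > 0, ssr / np.where(sse > 0, sse / (n - 2), 1.0), np.inf)
    p = stats.f.sf(f, 1, n - 2)
    p = np.where(sse > 0, p, np.where(slope != 0, 0.0, 1.0))

    codes = np.full((H, W), _CLASS_CODE[INVALID_CLASS], dtype=int)
    sig_ext = p < 0.01
    sig = (p >= 0.01) & (p < 0.05)
    dn, up = slope < 0, slope > 0
    codes[valid & (p >= 0.05)] = _CLASS_CODE["no_change"]
    codes[valid & (slope == 0)] = _CLASS_CODE["no_change"]
    codes[valid & up & sig] = _CLASS_CODE["sig_increase"]
    codes[valid & up & sig_ext] = _CLASS_CODE["ext_sig_increase"]
    codes[valid & dn & sig] = _CLASS_CODE["sig_decrease"]
    codes[valid & dn & sig_ext] = _CLASS_CODE["ext_sig_decrease"]

    n_valid = int(valid.sum())
    pct = {name: 100.0 * float(np.sum(codes == _CLASS_CODE[name])) / n_valid
           for name in CLASSES}

    slope = np.where(finite, slope, np.nan)
    p = np.where(finite, p, np.nan)
    return TrendMap(slope_grid=slope, p_grid=p, class_grid=codes,
                    class_area_pct=pct)
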