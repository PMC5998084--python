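"""NPP totals, change rates, and land-use-conversion change accounting.

Total NPP change between two dates decomposes additively over land-use
transition classes: pixels that stay grassland (G-G) contribute their NPP
difference, pixels converted into grassland (O-G) are credited their full
end-date NPP, and pixels converted out of grassland (G-O) are debited
their full start-date NPP.  By construction

    delta_total = delta_retained + delta_in + delta_out

holds exactly, where delta_total is total grassland NPP at the end date
minus total grassland NPP at the start date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NPPSummary",
    "ChangeDecomposition",
    "summarize_npp",
    "percent_change",
    "annual_rate",
    "decompose_change",
]

GRASS = "grassland"
KNOWN_CODES = {"grassland", "other"}


@dataclass
class NPPSummary:
    year: float
    total_npp: float   # sum of value * area (units carried through unchanged)
    mean_npp: float    # gC m^-2, area-weighted
    area: float        # km^2


def summarize_npp(data, area_weights=None) -> list[NPPSummary]:
    """Area-weighted total and mean NPP per year.

    ``data`` is either a panel DataFrame with columns ``year``, ``npp``
    and optionally ``area``, or a gridded stack of shape (n_years, ...)
    with per-pixel ``area_weights`` (scalar or array).  Totals are
    Sum(value * area); means are totals divided by total area.
    """
    if isinstance(data, pd.DataFrame):
        df = data
        if area_weights is not None:
            area = np.broadcast_to(np.asarray(area_weights, dtype=float), len(df))
        elif "area" in df.columns:
            area = df["area"].to_numpy(dtype=float)
        else:
            area = np.ones(len(df))
        if np.any(area <= 0):
            raise ValueError("areas must be positive")
        out = []
        tmp = df.assign(_area=area, _mass=df["npp"].to_numpy(dtype=float) * area)
        for year, grp in tmp.groupby("year", sort=True):
            total = float(grp["_mass"].sum())
            a = float(grp["_area"].sum())
            out.append(NPPSummary(year=float(year), total_npp=total,
                                  mean_npp=total / a, area=a))
        return out

    stack = np.asarray(data, dtype=float)
    if area_weights is None:
        raise ValueError("gridded input requires area weights")
    area = np.broadcast_to(np.asarray(area_weights, dtype=float), stack.shape[1:])
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    total_area = float(area.sum())
    out = []
    for k in range(stack.shape[0]):
        total = float(np.sum(stack[k] * area))
        out.append(NPPSummary(year=float(k), total_npp=total,
                              mean_npp=total / total_area, area=total_area))
    return out


def percent_change(mean_start: float, mean_end: float) -> float:
    """Percent increase from start to end: 100 * (end - start) / start."""
    if mean_start <= 0:
        raise ValueError(f"mean_start must be positive, got {mean_start}")
    return 100.0 * (mean_end - mean_start) / mean_start


def annual_rate(pct_change: float, n_years: float, convention: str = "arithmetic") -> float:
    """Average annual growth rate implied by a total percent change.

    ``arithmetic`` divides the total change by the number of years;
    ``geometric`` compounds: 100 * ((1 + pct/100)^(1/n) - 1).  Both are
    exposed because reported summary rates are frequently computed with
    either convention.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if convention == "arithmetic":
        return pct_change / n_years
    if convention == "geometric":
        return 100.0 * ((1.0 + pct_change / 100.0) ** (1.0 / n_years) - 1.0)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class ChangeDecomposition:
    delta_total: float
    delta_retained: float  # G-G: sum(end - start)
    delta_in: float        # O-G: sum(end)
    delta_out: float       # G-O: -sum(start)
    shares: dict[str, float]  # each component as % of |delta_total|


def decompose_change(npp_start, npp_end, landuse_start, landuse_end,
                     area=1.0) -> ChangeDecomposition:
    """Decompose total grassland NPP change over land-use transitions."""
    s = np.asarray(npp_start, dtype=float)
    e = np.asarray(npp_end, dtype=float)
    lu_s = np.asarray(landuse_start).astype(str)
    lu_e = np.asarray(landuse_end).astype(str)
    if not (s.shape == e.shape == lu_s.shape == lu_e.shape):
        raise ValueError("all grids must be congruent")
    unknown = (set(np.unique(lu_s)) | set(np.unique(lu_e))) - KNOWN_CODES
    if unknown:
        raise ValueError(f"unknown land-use codes: {sorted(unknown)}")
    a = np.broadcast_to(np.asarray(area, dtype=float), s.shape)

    grass_s = lu_s == GRASS
    grass_e = lu_e == GRASS
    retained = grass_s & grass_e
    conv_in = ~grass_s & grass_e
    conv_out = grass_s & ~grass_e

    d_ret = float(np.sum((e - s)[retained] * a[retained]))
    d_in = float(np.sum(e[conv_in] * a[conv_in]))
    d_out = -float(np.sum(s[conv_out] * a[conv_out]))
    d_total = d_ret + d_in + d_out

    if d_total != 0.0:
        shares = {
            "retained": 100.0 * d_ret / abs(d_total),
            "in": 100.0 * d_in / abs(d_total),
            "out": 100.0 * d_out / abs(d_total),
        }
    else:
        shares = {"retained": float("nan"), "in": float("nan"), "out": float("nan")}
    return ChangeDecomposition(delta_total=d_total, delta_retained=d_ret,
                               delta_in=d_in, delta_out=d_out, shares=shares)
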