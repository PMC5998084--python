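"""Synthetic multilevel panels and gridded NPP stacks with known truth.

The generator emulates the statistical structure of a nested alpine-plateau landscape: 18
counties containing ~1,800 small watersheds, each observed in six
unevenly spaced calendar years (1988, 1995, 2000, 2005, 2008, 2012),
with grassland NPP generated on the log scale from a quadratic time
trend, covariate fixed effects applied to standardized covariates,
county- and watershed-level random effects, and i.i.d. Gaussian
residuals.  All true parameters and the exact random-effect draws are
returned alongside the data so downstream estimators can be checked by
direct parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mlm import eval_effect_column

__all__ = [
    "SyntheticConfig",
    "TrueValues",
    "SyntheticGrid",
    "generate_panel",
    "generate_grid",
    "true_values",
    "COVARIATE_SDS",
    "COVARIATE_MEANS",
    "DEFAULT_FIXED_EFFECTS",
]

# Covariate scale (one standard deviation) per reference descriptive
# statistics for this landscape; the generator draws raw covariates at these SDs and applies
# fixed effects to their z-scores, so coefficients are "per SD" throughout.
COVARIATE_SDS: dict[str, float] = {
    "precipitation": 158.5,   # mm
    "temperature": 2.28,      # degC
    "sunlight": 201.05,       # h
    "grassland_pct": 23.99,   # %
    "dem": 395.18,            # m
    "slope": 5.8,             # deg
    "soil_k": 37.17,          # %
    "soil_n": 0.17,           # %
    "soil_p": 0.01,           # %
    "d2water": 28.12,         # km
    "d2highway": 196.65,      # km
    "d2village": 55.76,       # km
    "gdp": 149.0,             # million CNY
    "hpd": 30.6,              # thousand people / km^2 (taken at face value)
    "meat": 2.66,             # thousand tons
}

# Means are free knobs (the model consumes z-scores, so they are
# immaterial to recovery); plausible alpine-plateau values are used.
COVARIATE_MEANS: dict[str, float] = {
    "precipitation": 450.0, "temperature": -2.0, "sunlight": 2550.0,
    "grassland_pct": 60.0, "dem": 4300.0, "slope": 12.0,
    "soil_k": 40.0, "soil_n": 0.3, "soil_p": 0.05,
    "d2water": 40.0, "d2highway": 250.0, "d2village": 80.0,
    "gdp": 300.0, "hpd": 20.0, "meat": 5.0,
}

# Covariates that vary by watershed and year (climate + grassland cover),
# by county and year (socioeconomic), or are fixed watershed traits.
TIME_VARYING_WATERSHED = ("precipitation", "temperature", "sunlight", "grassland_pct")
TIME_VARYING_COUNTY = ("gdp", "hpd", "meat")
WATERSHED_CONSTANT = ("dem", "slope", "soil_k", "soil_n", "soil_p",
                      "d2water", "d2highway", "d2village")

# Generative fixed effects (per-SD scale for covariates).  The quadratic
# time trend and the socioeconomic/grassland coefficients follow the
# reported standardized estimates; the remaining coefficients are chosen
# to realize the reported sign pattern (hump-shaped climate response,
# negative time x precipitation, positive time x temperature, negative
# topography, positive soil fertility).
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 5.135,
    "T": -0.000,
    "T2": 0.001,
    "precipitation": 0.20, "temperature": 0.15, "sunlight": 0.05,
    "precipitation^2": -0.05, "temperature^2": -0.04, "sunlight^2": 0.01,
    "grassland_pct": 0.033,
    "T:grassland_pct": -0.003,
    "grassland_type[ASAM]": 0.40, "grassland_type[DG]": -1.50,
    "grassland_type[MDW]": 0.30,
    "T:grassland_type[ASAM]": 0.002, "T:grassland_type[DG]": 0.004,
    "T:grassland_type[MDW]": -0.005,
    "nnr": 0.04, "T:nnr": -0.002,
    "dem": -0.05, "slope": -0.03,
    "soil_n": 0.04, "soil_p": 0.02, "soil_k": 0.03,
    "d2water": -0.02, "d2highway": -0.01, "d2village": -0.01,
    "gdp": -0.093, "hpd": -0.299, "meat": 0.146,
    "T:precipitation": -0.008, "T:temperature": 0.008, "T:sunlight": 0.001,
    "grassland_pct:gdp": -0.021, "grassland_pct:hpd": -0.009,
    "grassland_pct:meat": 0.006,
}

# Grassland-type mix: meadow (MDW) is rare, alpine/sub-alpine grassland
# and meadow dominate, desert grassland is a minor class.
DEFAULT_TYPE_PROBS = {"ASAG": 0.45, "ASAM": 0.42, "DG": 0.12, "MDW": 0.01}
DEFAULT_NNR_PROBS = {"outside": 0.45, "core": 0.20, "buffer": 0.15, "trial": 0.20}


def _as_cov(x, name: str) -> np.ndarray:
    m = np.atleast_2d(np.asarray(x, dtype=float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(m)) < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return m


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for the multilevel panel generator."""

    n_counties: int = 18
    watersheds_per_county: int | Sequence[int] = 100
    obs_years: Sequence[int] = (1988, 1995, 2000, 2005, 2008, 2012)
    time_origin: float = 1988.0
    fixed_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    sigma2_resid: float = 0.160
    # 2x2 (intercept, time-slope) covariances; with random_slopes=False only
    # the [0, 0] intercept variance is used.
    tau_watershed: object = field(
        default_factory=lambda: np.array([[1.781, 0.0], [0.0, 0.002]]))
    tau_county: object = field(
        default_factory=lambda: np.array([[1.354, 0.0], [0.0, 0.001]]))
    random_slopes: bool = True
    covariate_means: Mapping[str, float] = field(
        default_factory=lambda: dict(COVARIATE_MEANS))
    covariate_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(COVARIATE_SDS))
    grassland_type_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROBS))
    nnr_zone_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NNR_PROBS))
    missing_rate: float = 0.022
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise ValueError("n_counties must be positive")
        years = list(self.obs_years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("obs_years must be strictly increasing")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.sigma2_resid < 0:
            raise ValueError("sigma2_resid must be non-negative")
        self.tau_watershed = _as_cov(self.tau_watershed, "tau_watershed")
        self.tau_county = _as_cov(self.tau_county, "tau_county")

    def watershed_counts(self) -> list[int]:
        wpc = self.watersheds_per_county
        if np.isscalar(wpc):
            return [int(wpc)] * self.n_counties
        counts = [int(c) for c in wpc]
        if len(counts) != self.n_counties:
            raise ValueError("per-county watershed list length must equal n_counties")
        return counts

    def tau(self, level: str) -> np.ndarray:
        full = self.tau_watershed if level == "watershed" else self.tau_county
        return full if self.random_slopes else full[:1, :1]


@dataclass
class TrueValues:
    """Generative parameters named exactly as FitResult reports them."""

    fixed_effects: dict[str, float]
    sigma2: float
    tau_watershed: np.ndarray
    tau_county: np.ndarray
    icc_watershed: float
    icc_county: float
    county_effects: pd.DataFrame | None = None
    watershed_effects: pd.DataFrame | None = None


def true_values(config: SyntheticConfig) -> TrueValues:
    """Return the generative parameters in estimator naming, without data."""
    tw = config.tau("watershed")
    tc = config.tau("county")
    s2 = config.sigma2_resid
    denom = s2 + tw[0, 0] + tc[0, 0]
    return TrueValues(
        fixed_effects=dict(config.fixed_effects),
        sigma2=s2, tau_watershed=tw, tau_county=tc,
        icc_watershed=tw[0, 0] / denom if denom > 0 else 0.0,
        icc_county=tc[0, 0] / denom if denom > 0 else 0.0,
    )


def generate_panel(config: SyntheticConfig) -> tuple[pd.DataFrame, TrueValues]:
    """Simulate one long-format watershed-by-year panel.

    The response is built on the log scale as fixed linear predictor
    (evaluated on standardized covariates) + county draw + watershed draw
    + residual, then exponentiated to NPP.  Identical config (including
    ``seed``) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.watershed_counts()
    years = np.asarray(list(config.obs_years), dtype=float)
    n_years = len(years)
    n_ws = int(sum(counts))
    county_of_ws = np.repeat(np.arange(config.n_counties), counts)

    ws_labels = np.array([f"W{i + 1:05d}" for i in range(n_ws)])
    county_labels = np.array([f"C{j + 1:02d}" for j in range(config.n_counties)])

    # long-format index: watershed-major, year-minor
    ws_idx = np.repeat(np.arange(n_ws), n_years)
    year_col = np.tile(years, n_ws)
    county_idx = county_of_ws[ws_idx]
    n_rows = n_ws * n_years

    df = pd.DataFrame({
        "watershed_id": ws_labels[ws_idx],
        "county_id": county_labels[county_idx],
        "year": year_col,
    })

    means, sds = config.covariate_means, config.covariate_sds
    for cov in TIME_VARYING_WATERSHED:
        df[cov] = rng.normal(means[cov], sds[cov], size=n_rows)
    for cov in WATERSHED_CONSTANT:
        per_ws = rng.normal(means[cov], sds[cov], size=n_ws)
        df[cov] = per_ws[ws_idx]
    for cov in TIME_VARYING_COUNTY:
        per_cy = rng.normal(means[cov], sds[cov],
                            size=(config.n_counties, n_years))
        df[cov] = per_cy[county_idx, np.tile(np.arange(n_years), n_ws)]

    tp = config.grassland_type_probs
    gt_levels = list(tp)
    gt_per_ws = rng.choice(gt_levels, size=n_ws,
                           p=np.asarray([tp[k] for k in gt_levels]) / sum(tp.values()))
    df["grassland_type"] = gt_per_ws[ws_idx]
    zp = config.nnr_zone_probs
    zone_levels = list(zp)
    zone_per_ws = rng.choice(zone_levels, size=n_ws,
                             p=np.asarray([zp[k] for k in zone_levels]) / sum(zp.values()))
    df["nnr_zone"] = zone_per_ws[ws_idx]
    df["nnr"] = (df["nnr_zone"] != "outside").astype(float)

    # fixed linear predictor on z-scored covariates
    zdf = df.copy()
    for cov, sd in sds.items():
        if cov in zdf.columns:
            zdf[cov] = (zdf[cov] - means[cov]) / sd
    lp = np.zeros(n_rows)
    for name, coef in config.fixed_effects.items():
        if coef == 0.0:
            continue
        lp += coef * eval_effect_column(zdf, name, config.time_origin)

    # random effects
    tau_w = config.tau("watershed")
    tau_c = config.tau("county")
    q_w, q_c = tau_w.shape[0], tau_c.shape[0]
    u_w = rng.multivariate_normal(np.zeros(q_w), tau_w, size=n_ws,
                                  method="eigh")
    u_c = rng.multivariate_normal(np.zeros(q_c), tau_c, size=config.n_counties,
                                  method="eigh")
    T = (year_col - config.time_origin)
    Z = np.column_stack([np.ones(n_rows), T])
    lp += (Z[:, :q_w] * u_w[ws_idx]).sum(axis=1)
    lp += (Z[:, :q_c] * u_c[county_idx]).sum(axis=1)

    eps = (rng.normal(0.0, np.sqrt(config.sigma2_resid), size=n_rows)
           if config.sigma2_resid > 0 else np.zeros(n_rows))
    df["npp"] = np.exp(lp + eps)

    if config.missing_rate > 0:
        keep = rng.random(n_rows) >= config.missing_rate
        df = df.loc[keep].reset_index(drop=True)

    tv = true_values(config)
    tv.watershed_effects = pd.DataFrame(
        u_w, columns=["intercept", "T"][:q_w]).assign(
        watershed_id=ws_labels, county_id=county_labels[county_of_ws])
    tv.county_effects = pd.DataFrame(
        u_c, columns=["intercept", "T"][:q_c]).assign(county_id=county_labels)
    cols = (["watershed_id", "county_id", "year", "npp"]
            + list(TIME_VARYING_WATERSHED) + list(WATERSHED_CONSTANT)
            + list(TIME_VARYING_COUNTY) + ["grassland_type", "nnr_zone", "nnr"])
    return df[cols], tv


# ---------------------------------------------------------------------------
# Gridded fixture: NPP stacks and land-use layers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGrid:
    """Per-year NPP rasters plus start/end land-use layers with known truth."""

    npp_stack: np.ndarray          # (n_years, H, W)
    landuse_start: np.ndarray      # (H, W) of {"grassland", "other"}
    landuse_end: np.ndarray
    true_slope_field: np.ndarray   # (H, W)
    cell_area: float = 1.0         # km^2

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        shape = self.npp_stack.shape[1:]
        for layer in (self.landuse_start, self.landuse_end, self.true_slope_field):
            if layer.shape != shape:
                raise ValueError("all grid layers must share one shape")


def generate_grid(
    shape: tuple[int, int],
    trend_params: Mapping | None = None,
    conversion_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SyntheticGrid:
    """Simulate a per-pixel NPP time series with land-use transitions.

    ``trend_params`` keys: ``intercept`` (scalar or field), ``slope``
    (scalar, field, or ``(low, high)`` uniform range), ``noise_sd``
    (>= 0), ``n_years``, ``cell_area``.  Pixel series are
    ``intercept + slope * t + N(0, noise_sd)`` over steps t = 1..n_years.

    ``conversion_fractions`` gives the pixel fractions of the transition
    classes ``retained`` (grass to grass), ``in`` (other to grass) and
    ``out`` (grass to other); the remainder stays non-grassland in both
    layers.  Fractions are realized exactly up to integer rounding.
    """
    H, W = int(shape[0]), int(shape[1])
    if H <= 0 or W <= 0:
        raise ValueError("grid shape must be positive")
    tp = dict(trend_params or {})
    n_years = int(tp.get("n_years", 6))
    noise_sd = float(tp.get("noise_sd", 10.0))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def _field(value, default):
        v = tp.get(value, default)
        if isinstance(v, tuple) and len(v) == 2:
            return rng.uniform(v[0], v[1], size=(H, W))
        return np.broadcast_to(np.asarray(v, dtype=float), (H, W)).copy()

    intercept = _field("intercept", 250.0)
    slope = _field("slope", 2.0)

    t = np.arange(1, n_years + 1, dtype=float)
    stack = intercept[None] + slope[None] * t[:, None, None]
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)

    cf = dict(conversion_fractions or {})
    for key, val in cf.items():
        if key not in ("retained", "in", "out"):
            raise ValueError(f"unknown conversion class {key!r}")
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"conversion fraction {key!r}={val} outside [0, 1]")
    if sum(cf.values()) > 1.0 + 1e-12:
        raise ValueError("conversion fractions must sum to at most 1")
    f_ret = cf.get("retained", 1.0 - cf.get("in", 0.0) - cf.get("out", 0.0))

    n_pix = H * W
    n_ret = int(round(f_ret * n_pix))
    n_in = int(round(cf.get("in", 0.0) * n_pix))
    n_out = int(round(cf.get("out", 0.0) * n_pix))
    n_ret = min(n_ret, n_pix)
    n_in = min(n_in, n_pix - n_ret)
    n_out = min(n_out, n_pix - n_ret - n_in)

    perm = rng.permutation(n_pix)
    start = np.full(n_pix, "other", dtype=object)
    end = np.full(n_pix, "other", dtype=object)
    ret_idx = perm[:n_ret]
    in_idx = perm[n_ret:n_ret + n_in]
    out_idx = perm[n_ret + n_in:n_ret + n_in + n_out]
    start[ret_idx] = "grassland"
    end[ret_idx] = "grassland"
    end[in_idx] = "grassland"
    start[out_idx] = "grassland"

    return SyntheticGrid(
        npp_stack=stack,
        landuse_start=start.reshape(H, W).astype(str),
        landuse_end=end.reshape(H, W).astype(str),
        true_slope_field=slope,
        cell_area=float(tp.get("cell_area", 1.0)),
    )
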