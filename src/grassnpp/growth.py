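"""The growth-model ladder: null model, unconditional and conditional
three-level growth models, ICC decomposition, and variance-explained
comparisons.

Model ladder (cumulative, each step adds terms to the previous one):

    null  — fixed intercept only; random intercepts at watershed and
            county level (the "empty" two-random-level model).
    1     — unconditional growth: fixed {1, T, T^2} with T = year - 1988.
    2     — + climate mains and quadratics (precipitation, temperature,
            sunlight, each standardized).
    3     — + grassland cover and type: grassland_pct, grassland-type
            dummies (reference ASAG), NNR dummy, and their T interactions.
    4     — + watershed traits: topography (dem, slope), soil fertility
            (N, P, K), location (distances to water/highway/village).
    5     — + county socioeconomic mains (GDP, HPD, meat production).
    6     — + cross-level interactions: T x climate and
            grassland_pct x socioeconomic.

Covariates enter standardized (z-scores against declared SDs), so every
coefficient reads as the proportional change in NPP per one-SD change in
the covariate.  The intraclass correlations use intercept variances only:

    ICC_watershed = tau_w00 / (sigma2 + tau_w00 + tau_c00)
    ICC_county    = tau_c00 / (sigma2 + tau_w00 + tau_c00)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .mlm import FitResult, ModelSpec, build_design, fit_lmm
from .synthetic import COVARIATE_SDS

__all__ = [
    "ICCDecomposition",
    "standardize",
    "destandardize",
    "null_model",
    "unconditional_growth",
    "conditional_growth",
    "icc",
    "icc_from_components",
    "variance_shares",
    "LADDER",
]

CLIMATE = ("precipitation", "temperature", "sunlight")
SOCIO = ("gdp", "hpd", "meat")

# cumulative term additions per conditional step
LADDER: dict[int, tuple[str, ...]] = {
    2: tuple(CLIMATE) + tuple(f"{c}^2" for c in CLIMATE),
    3: ("grassland_pct", "C(grassland_type)", "nnr",
        "T:grassland_pct", "T:C(grassland_type)", "T:nnr"),
    4: ("dem", "slope", "soil_n", "soil_p", "soil_k",
        "d2water", "d2highway", "d2village"),
    5: SOCIO,
    6: ("T:precipitation", "T:temperature", "T:sunlight",
        "grassland_pct:gdp", "grassland_pct:hpd", "grassland_pct:meat"),
}


def _terms_for_step(step: int, ladder: Mapping[int, tuple[str, ...]]) -> list[str]:
    terms = ["1", "T", "T2"]
    for k in range(2, step + 1):
        terms.extend(ladder[k])
    return terms


def standardize(
    panel: pd.DataFrame,
    sd_table: Mapping[str, float] | None = None,
    mean_table: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Z-score covariates and log the response; record the transform.

    Covariates named in ``sd_table`` (default: the reference SD table) are
    replaced by (x - mean) / SD; means default to the sample mean.  The
    response is log-transformed into a ``log_npp`` column; time and IDs
    are left untouched.  The applied (mean, sd) pairs are stored in
    ``df.attrs["standardization"]`` for back-conversion.
    """
    sds = dict(sd_table) if sd_table is not None else dict(COVARIATE_SDS)
    out = panel.copy()
    record: dict[str, tuple[float, float]] = {}
    for col, sd in sds.items():
        if col not in out.columns:
            continue
        if sd <= 0:
            raise ValueError(f"zero or negative SD for covariate {col!r}")
        mean = (float(mean_table[col]) if mean_table and col in mean_table
                else float(out[col].mean()))
        out[col] = (out[col] - mean) / sd
        record[col] = (mean, float(sd))
    if "npp" in out.columns and "log_npp" not in out.columns:
        if (out["npp"].dropna() <= 0).any():
            raise ValueError("npp must be positive to take logs")
        out["log_npp"] = np.log(out["npp"])
    out.attrs["standardization"] = record
    return out


def destandardize(panel: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`standardize` using the recorded transform."""
    record = panel.attrs.get("standardization")
    if not record:
        raise ValueError("panel carries no standardization record")
    out = panel.copy()
    for col, (mean, sd) in record.items():
        out[col] = out[col] * sd + mean
    out.attrs["standardization"] = {}
    return out


def _spec(fixed_terms, random_slopes=False) -> ModelSpec:
    rt = ("intercept", "T") if random_slopes else ("intercept",)
    return ModelSpec(
        fixed_terms=tuple(fixed_terms),
        random_watershed=rt, random_county=rt,
        categorical_refs={"grassland_type": "ASAG"},
    )


def null_model(panel: pd.DataFrame, method: str = "ML") -> FitResult:
    """Empty model: fixed intercept, random intercepts at both levels."""
    dm = build_design(panel, _spec(["1"]))
    return fit_lmm(dm, method=method)


def unconditional_growth(panel: pd.DataFrame, method: str = "ML",
                         random_slopes: bool = False) -> FitResult:
    """Quadratic growth model with no covariates (Model 1)."""
    years = panel["year"].dropna().unique()
    if len(years) < 3:
        raise ValueError("need at least 3 distinct time points for a quadratic trend")
    dm = build_design(panel, _spec(["1", "T", "T2"], random_slopes))
    return fit_lmm(dm, method=method)


def conditional_growth(panel: pd.DataFrame, step: int, method: str = "ML",
                       random_slopes: bool = False,
                       ladder: Mapping[int, tuple[str, ...]] | None = None) -> FitResult:
    """Stepwise conditional growth model (Models 2..6).

    The default term ladder follows the climate -> grassland -> watershed
    traits -> socioeconomic -> interactions ordering; pass ``ladder`` to
    override the per-step term lists.
    """
    if step not in (2, 3, 4, 5, 6):
        raise ValueError(f"step must be in 2..6, got {step}")
    ladder = dict(LADDER if ladder is None else ladder)
    dm = build_design(panel, _spec(_terms_for_step(step, ladder), random_slopes))
    return fit_lmm(dm, method=method)


@dataclass
class ICCDecomposition:
    icc_watershed: float
    icc_county: float
    residual_share: float
    components_used: dict[str, float]


def icc_from_components(sigma2: float, tau_watershed: float,
                        tau_county: float) -> ICCDecomposition:
    """ICC decomposition from explicit intercept variance components."""
    for nm, v in (("sigma2", sigma2), ("tau_watershed", tau_watershed),
                  ("tau_county", tau_county)):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"variance component {nm} must be finite and >= 0")
    denom = sigma2 + tau_watershed + tau_county
    if denom <= 0:
        raise ValueError("total variance must be positive")
    return ICCDecomposition(
        icc_watershed=tau_watershed / denom,
        icc_county=tau_county / denom,
        residual_share=sigma2 / denom,
        components_used={"sigma2": sigma2, "tau_watershed": tau_watershed,
                         "tau_county": tau_county},
    )


def icc(fit: FitResult) -> ICCDecomposition:
    """ICC decomposition of a fit, using intercept variances only.

    Slope variances (when random slopes were fitted) are deliberately
    excluded: the decomposition is defined on the intercept components.
    """
    vc = fit.vc
    if vc.tau_watershed is None or vc.tau_county is None:
        raise ValueError("fit lacks intercept variance at one of the levels")
    return icc_from_components(vc.sigma2, vc.intercept_variance("watershed"),
                               vc.intercept_variance("county"))


def variance_shares(fit_a: FitResult, fit_b: FitResult) -> dict[str, float]:
    """Proportional reduction of each variance component from fit_a to fit_b.

    Returns (comp_a - comp_b) / comp_a for the residual ("within-group")
    variance and each level's intercept ("between-group") variance.
    """
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("variance comparison requires fits on the same rows")
    out = {}
    pairs = {
        "within_group": (fit_a.vc.sigma2, fit_b.vc.sigma2),
        "between_watershed": (fit_a.vc.intercept_variance("watershed"),
                              fit_b.vc.intercept_variance("watershed")),
        "between_county": (fit_a.vc.intercept_variance("county"),
                           fit_b.vc.intercept_variance("county")),
    }
    for nm, (a, b) in pairs.items():
        out[nm] = (a - b) / a if a > 0 else float("nan")
    return out
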