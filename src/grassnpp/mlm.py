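"""Gaussian linear mixed models with two nested random-effect levels.

The estimator targets the three-level longitudinal design used throughout
this package: repeated observations (level 1) nested in watersheds
(level 2) nested in counties (level 3).  Writing ``y`` for the response
(log-NPP), the marginal model is

    y = X beta + Z_c u_c + Z_w u_w + eps,
    u_c ~ N(0, tau_c),  u_w ~ N(0, tau_w),  eps ~ N(0, sigma2 I),

with independent county effects ``u_c`` (one vector per county),
watershed effects ``u_w`` (one per watershed) and i.i.d. residuals.
Each level carries either a random intercept or a random
intercept-plus-time-slope pair with unstructured covariance.

Estimation maximises the profiled (RE)ML log-likelihood over the
variance-ratio matrices Gamma_l = tau_l / sigma2, parameterised through a
log-Cholesky factor so that positive semi-definiteness is automatic and
the tau -> 0 boundary is reached smoothly.  Fixed effects come from GLS at
the optimum; sigma2 is profiled out in closed form.  The marginal
covariance is block diagonal by county, so all linear algebra is done
per county block with dense Cholesky factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

logger = logging.getLogger("grassnpp")

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "VarianceComponents",
    "FitResult",
    "LRTestResult",
    "build_design",
    "fit_lmm",
    "fixed_effects_at",
    "loglik_at",
    "lr_test",
    "predict_trajectory",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Model specification and term algebra
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative description of one growth model.

    ``fixed_terms`` is an ordered list of term strings:

    * ``"1"`` — intercept (always prepended if absent);
    * ``"T"`` / ``"T2"`` — time and time squared, where
      ``T = (year - time_origin) / time_scale``;
    * a column name — numeric main effect (columns are used as-is, so
      standardize beforehand if standardized coefficients are wanted);
    * ``"name^2"`` — quadratic of a numeric column;
    * ``"C(name)"`` — categorical expanded to dummies against the
      reference level declared in ``categorical_refs``;
    * ``"a:b"`` — product interaction of any two factors above.

    ``random_watershed`` / ``random_county`` are ``("intercept",)`` or
    ``("intercept", "T")``.
    """

    fixed_terms: Sequence[str] = ("1", "T", "T2")
    random_watershed: Sequence[str] = ("intercept",)
    random_county: Sequence[str] = ("intercept",)
    response: str = "log_npp"
    time_origin: float = 1988.0
    time_scale: float = 1.0
    categorical_refs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        terms = list(self.fixed_terms)
        if "1" not in terms:
            terms.insert(0, "1")
        if "T2" in terms and "T" not in terms:
            raise ValueError("fixed term 'T2' requires 'T' in the model")
        self.fixed_terms = tuple(terms)
        for rt in (self.random_watershed, self.random_county):
            if tuple(rt) not in ((), ("intercept",), ("intercept", "T")):
                raise ValueError(
                    f"random terms must be ('intercept',) or ('intercept','T'), got {rt!r}"
                )


def _time_column(df: pd.DataFrame, origin: float, scale: float) -> np.ndarray:
    return (df["year"].to_numpy(dtype=float) - origin) / scale


def _expand_term(term: str, cat_levels: Mapping[str, tuple[list, str]]) -> list[str]:
    """Expand one term into fully-resolved column names.

    Categorical factors multiply out: ``T:C(gt)`` with levels A (ref), B, C
    becomes ``["T:gt[B]", "T:gt[C]"]``.
    """
    names_per_factor: list[list[str]] = []
    for factor in term.split(":"):
        factor = factor.strip()
        if factor.startswith("C(") and factor.endswith(")"):
            col = factor[2:-1]
            if col not in cat_levels:
                raise KeyError(f"categorical term {factor!r} not resolvable")
            levels, ref = cat_levels[col]
            names_per_factor.append([f"{col}[{lev}]" for lev in levels if lev != ref])
        elif factor == "1":
            names_per_factor.append(["intercept"])
        else:
            names_per_factor.append([factor])
    out = names_per_factor[0]
    for extra in names_per_factor[1:]:
        out = [f"{a}:{b}" for a in out for b in extra]
    # normalise "intercept:x" back to "x"
    return [":".join(p for p in n.split(":") if p != "intercept") or "intercept" for n in out]


def eval_effect_column(
    df: pd.DataFrame,
    name: str,
    time_origin: float = 1988.0,
    time_scale: float = 1.0,
) -> np.ndarray:
    """Evaluate one fully-resolved design column name on a data frame.

    Recognised atoms: ``intercept``, ``T``, ``T2``, ``col``, ``col^2``,
    ``col[level]`` (dummy indicator); atoms joined by ``:`` multiply.
    This single evaluator is shared by the design builder, the synthetic
    generator and the trajectory predictor, so coefficient names line up
    across all three.
    """
    out = np.ones(len(df))
    for atom in name.split(":"):
        if atom == "intercept":
            continue
        if atom == "T":
            out = out * _time_column(df, time_origin, time_scale)
        elif atom in ("T2", "T^2"):
            out = out * _time_column(df, time_origin, time_scale) ** 2
        elif atom.endswith("^2"):
            out = out * df[atom[:-2]].to_numpy(dtype=float) ** 2
        elif "[" in atom and atom.endswith("]"):
            col, lev = atom[:-1].split("[", 1)
            out = out * (df[col].astype(str) == lev).to_numpy(dtype=float)
        else:
            out = out * df[atom].to_numpy(dtype=float)
    return out


def _base_columns(name: str) -> set[str]:
    """Data-frame columns a resolved design-column name depends on."""
    cols: set[str] = set()
    for atom in name.split(":"):
        if atom in ("intercept",):
            continue
        if atom in ("T", "T2", "T^2"):
            cols.add("year")
        elif atom.endswith("^2"):
            cols.add(atom[:-2])
        elif "[" in atom:
            cols.add(atom.split("[", 1)[0])
        else:
            cols.add(atom)
    return cols


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Numeric design for :func:`fit_lmm`, sorted by county then watershed."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    watershed: np.ndarray          # integer codes, 0..n_watersheds-1
    county: np.ndarray             # integer codes, 0..n_counties-1
    Z_watershed: np.ndarray | None # n x q_w random design (None = no level)
    Z_county: np.ndarray | None
    watershed_ids: list            # code -> original label
    county_ids: list
    n_dropped: int = 0
    spec: ModelSpec | None = None
    cat_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X and y row counts disagree")
        for Z in (self.Z_watershed, self.Z_county):
            if Z is not None and Z.shape[0] != n:
                raise ValueError("random-effect design row count disagrees with y")
        # strict nesting: every watershed under exactly one county
        mapping: dict[int, int] = {}
        for w, c in zip(self.watershed, self.county):
            if mapping.setdefault(int(w), int(c)) != int(c):
                raise ValueError(
                    f"nesting violation: watershed {self.watershed_ids[int(w)]!r} "
                    "appears under two counties"
                )

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_watersheds(self) -> int:
        return len(self.watershed_ids)

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @classmethod
    def from_arrays(
        cls,
        y,
        X,
        watershed,
        county,
        x_names=None,
        random_watershed: Sequence[str] = ("intercept",),
        random_county: Sequence[str] = ("intercept",),
        time: np.ndarray | None = None,
    ) -> "DesignMatrices":
        """Build a design directly from arrays (mainly for tests/oracles)."""
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if x_names is None:
            x_names = [f"x{i}" for i in range(X.shape[1])]
        w_ids, w_codes = np.unique(np.asarray(watershed), return_inverse=True)
        c_ids, c_codes = np.unique(np.asarray(county), return_inverse=True)
        order = np.lexsort((w_codes, c_codes))

        def _z(terms):
            if not terms:
                return None
            cols = [np.ones(len(y))]
            if "T" in terms:
                if time is None:
                    raise ValueError("random slope requested but no time array given")
                cols.append(np.asarray(time, dtype=float))
            return np.column_stack(cols)[order]

        return cls(
            y=y[order], X=X[order], x_names=list(x_names),
            watershed=w_codes[order], county=c_codes[order],
            Z_watershed=_z(tuple(random_watershed)),
            Z_county=_z(tuple(random_county)),
            watershed_ids=list(w_ids), county_ids=list(c_ids),
        )


def build_design(panel: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Construct fixed- and random-effect design matrices from a panel.

    Rows with a missing value in the response or in any required column
    are dropped (the count is logged).  Columns are ordered exactly as the
    spec's term list, with categorical terms expanded against their
    declared reference level.
    """
    df = panel

    # resolve categorical levels once, in sorted order, reference first
    cat_levels: dict[str, tuple[list, str]] = {}
    for term in spec.fixed_terms:
        for factor in term.split(":"):
            factor = factor.strip()
            if factor.startswith("C(") and factor.endswith(")"):
                col = factor[2:-1]
                if col not in df.columns:
                    raise KeyError(f"term {factor!r} not resolvable: no column {col!r}")
                levels = sorted(df[col].dropna().astype(str).unique().tolist())
                ref = spec.categorical_refs.get(col, levels[0])
                if ref not in levels:
                    raise ValueError(f"reference level {ref!r} absent from column {col!r}")
                cat_levels[col] = (levels, ref)

    names: list[str] = []
    for term in spec.fixed_terms:
        for nm in _expand_term(term, cat_levels):
            if nm not in names:
                names.append(nm)

    needed: set[str] = set()
    for nm in names:
        needed |= _base_columns(nm)
    for col in sorted(needed):
        if col not in df.columns:
            raise KeyError(f"term referencing column {col!r} not resolvable in panel")

    if spec.response == "log_npp" and "log_npp" not in df.columns:
        if (df["npp"].dropna() <= 0).any():
            raise ValueError("npp must be positive to take logs")
        df = df.assign(log_npp=np.log(df["npp"].to_numpy(dtype=float)))
    y_col = spec.response

    required = sorted(needed | {y_col, "watershed_id", "county_id", "year"})
    keep = df[required].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing data", n_dropped)
    df = df.loc[keep]

    X = np.column_stack(
        [eval_effect_column(df, nm, spec.time_origin, spec.time_scale) for nm in names]
    )
    y = df[y_col].to_numpy(dtype=float)

    w_ids, w_codes = np.unique(df["watershed_id"].to_numpy(), return_inverse=True)
    c_ids, c_codes = np.unique(df["county_id"].to_numpy(), return_inverse=True)
    order = np.lexsort((w_codes, c_codes))

    T = _time_column(df, spec.time_origin, spec.time_scale)

    def _z(terms):
        terms = tuple(terms)
        if not terms:
            return None
        cols = [np.ones(len(df))]
        if "T" in terms:
            cols.append(T)
        return np.column_stack(cols)[order]

    return DesignMatrices(
        y=y[order], X=X[order], x_names=names,
        watershed=w_codes[order], county=c_codes[order],
        Z_watershed=_z(spec.random_watershed), Z_county=_z(spec.random_county),
        watershed_ids=list(w_ids), county_ids=list(c_ids),
        n_dropped=n_dropped, spec=spec, cat_levels=cat_levels,
    )


# ---------------------------------------------------------------------------
# Variance components and results
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2: float
    tau_watershed: np.ndarray | None   # q_w x q_w covariance, None if level absent
    tau_county: np.ndarray | None

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        for nm in ("tau_watershed", "tau_county"):
            tau = getattr(self, nm)
            if tau is None:
                continue
            tau = np.atleast_2d(np.asarray(tau, dtype=float))
            if not np.allclose(tau, tau.T):
                raise ValueError(f"{nm} must be symmetric")
            if np.min(np.linalg.eigvalsh(tau)) < -1e-10:
                raise ValueError(f"{nm} must be positive semi-definite")
            setattr(self, nm, tau)

    def intercept_variance(self, level: str) -> float:
        tau = getattr(self, f"tau_{level}")
        return 0.0 if tau is None else float(tau[0, 0])


@dataclass
class FitResult:
    """Mixed-model fit: fixed effects, variance components, fit statistics."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    vc: VarianceComponents
    loglik: float
    aic: float
    n_obs: int
    n_watersheds: int
    n_counties: int
    method: str
    converged: bool
    blups: dict[str, dict]
    n_params_fixed: int
    n_params_variance: int
    spec: ModelSpec | None = None
    cat_levels: dict = field(default_factory=dict)
    x_names: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def to_dict(self) -> dict:
        vc = self.vc
        return {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "t_values": self.t_values,
            "variance_components": {
                "sigma2": vc.sigma2,
                "tau_watershed": None if vc.tau_watershed is None else vc.tau_watershed.tolist(),
                "tau_county": None if vc.tau_county is None else vc.tau_county.tolist(),
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_watersheds": self.n_watersheds,
            "n_counties": self.n_counties,
            "method": self.method,
            "converged": self.converged,
            "aic_convention": "AIC = -2*loglik + 2*(p_fixed + n_variance_params); "
            "variance params include sigma2",
            "t_convention": "asymptotic z (no denominator-df correction)",
        }


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _theta_dim(q: int) -> int:
    return q * (q + 1) // 2


def _gamma_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Relative covariance Gamma = L L' from log-Cholesky parameters."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(np.clip(theta[k], -20.0, 20.0))
            else:
                L[i, j] = theta[k]
            k += 1
    return L @ L.T


class _Blocks:
    """Per-county block structure precomputed from a design."""

    def __init__(self, dm: DesignMatrices):
        self.dm = dm
        self.q_w = 0 if dm.Z_watershed is None else dm.Z_watershed.shape[1]
        self.q_c = 0 if dm.Z_county is None else dm.Z_county.shape[1]
        self.blocks: list[dict] = []
        county = dm.county
        bounds = np.flatnonzero(np.diff(county)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(county)]])
        for s, e in zip(starts, ends):
            blk = {"sl": slice(int(s), int(e)), "county": int(county[s])}
            if self.q_c:
                blk["Zc"] = dm.Z_county[s:e]
            if self.q_w:
                ws = dm.watershed[s:e]
                wb = np.flatnonzero(np.diff(ws)) + 1
                ws_starts = np.concatenate([[0], wb])
                ws_ends = np.concatenate([wb, [e - s]])
                blk["ws"] = [
                    (slice(int(a), int(b)), dm.Z_watershed[s + a : s + b], int(ws[a]))
                    for a, b in zip(ws_starts, ws_ends)
                ]
            self.blocks.append(blk)

    def whiten(self, Gw: np.ndarray | None, Gc: np.ndarray | None):
        """Cholesky-whiten [X y] per block under V* = I + Z Gamma Z'.

        Returns (logdet V*, XtX, Xty, yty, cholesky factors per block).
        """
        dm = self.dm
        p = dm.X.shape[1]
        logdet = 0.0
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        chols = []
        for blk in self.blocks:
            sl = blk["sl"]
            nj = sl.stop - sl.start
            V = np.eye(nj)
            if Gc is not None:
                Zc = blk["Zc"]
                V += Zc @ Gc @ Zc.T
            if Gw is not None:
                for wsl, Zw, _ in blk["ws"]:
                    V[wsl, wsl] += Zw @ Gw @ Zw.T
            C = np.linalg.cholesky(V)
            logdet += 2.0 * float(np.sum(np.log(np.diag(C))))
            A = solve_triangular(C, np.column_stack([dm.X[sl], dm.y[sl]]), lower=True)
            Xw, yw = A[:, :p], A[:, p]
            XtX += Xw.T @ Xw
            Xty += Xw.T @ yw
            yty += float(yw @ yw)
            chols.append(C)
        return logdet, XtX, Xty, yty, chols


def _profiled_neg2ll(theta, blocks: _Blocks, method: str, return_full=False):
    q_w, q_c = blocks.q_w, blocks.q_c
    d_w = _theta_dim(q_w)
    Gw = _gamma_from_theta(theta[:d_w], q_w) if q_w else None
    Gc = _gamma_from_theta(theta[d_w:], q_c) if q_c else None
    dm = blocks.dm
    n, p = dm.X.shape
    logdet, XtX, Xty, yty, chols = blocks.whiten(Gw, Gc)
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        return np.inf if not return_full else None
    rss = max(yty - 2.0 * beta @ Xty + beta @ XtX @ beta, 1e-300)
    if method == "ML":
        sigma2 = rss / n
        neg2ll = n * (_LOG2PI + np.log(sigma2)) + logdet + n
    else:  # REML
        sigma2 = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        neg2ll = (n - p) * (_LOG2PI + np.log(sigma2)) + logdet + logdet_xtx + (n - p)
    if not return_full:
        return neg2ll
    return {
        "neg2ll": neg2ll, "beta": beta, "sigma2": sigma2,
        "Gw": Gw, "Gc": Gc, "XtX": XtX, "chols": chols, "logdet": logdet,
    }


def _start_theta(blocks: _Blocks) -> np.ndarray:
    """Moment-based starting values for the variance ratios.

    A crude nested ANOVA on OLS residuals: within-watershed variance as
    the residual scale, variances of watershed and county residual means
    as the between-level components.
    """
    dm = blocks.dm
    beta, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
    r = dm.y - dm.X @ beta
    rs = pd.Series(r)
    within = rs.groupby(dm.watershed).transform("mean")
    s2 = float(np.var(r - within)) or float(np.var(r)) or 1.0
    w_means = rs.groupby(dm.watershed).mean()
    c_means = rs.groupby(dm.county).mean()
    var_c = float(np.var(c_means)) if len(c_means) > 1 else 0.0
    var_w = max(float(np.var(w_means)) - var_c, 0.0)
    theta = []
    for q, v in ((blocks.q_w, var_w), (blocks.q_c, var_c)):
        if q == 0:
            continue
        ratio = max(v / s2, 1e-3)
        block = [0.0] * _theta_dim(q)
        block[0] = 0.5 * np.log(ratio)
        if q == 2:
            block[2] = -2.0  # small starting slope variance
        theta.extend(block)
    return np.asarray(theta)


def fit_lmm(
    dm: DesignMatrices,
    method: str = "ML",
    opts: Mapping | None = None,
) -> FitResult:
    """Fit the nested mixed model by maximising the profiled (RE)ML likelihood.

    Deterministic given the data and options: fixed moment-based starting
    values, Nelder-Mead on the profiled deviance followed by a BFGS
    polish, no randomness anywhere.  Non-convergence is reported through
    ``converged``, never silently ignored.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    opts = dict(opts or {})

    n, p = dm.X.shape
    if p >= n:
        raise ValueError(f"p={p} fixed-effect columns for only n={n} observations")

    # identically-zero columns carry no information: fit without them and
    # report a zero coefficient, rather than failing the rank check
    zero_cols = [j for j in range(p) if not dm.X[:, j].any()]
    if zero_cols:
        keep = [j for j in range(p) if j not in zero_cols]
        sub = DesignMatrices(
            y=dm.y, X=dm.X[:, keep], x_names=[dm.x_names[j] for j in keep],
            watershed=dm.watershed, county=dm.county,
            Z_watershed=dm.Z_watershed, Z_county=dm.Z_county,
            watershed_ids=dm.watershed_ids, county_ids=dm.county_ids,
            n_dropped=dm.n_dropped, spec=dm.spec, cat_levels=dm.cat_levels,
        )
        fit = fit_lmm(sub, method=method, opts=opts)
        for j in zero_cols:
            nm = dm.x_names[j]
            fit.coefficients[nm] = 0.0
            fit.std_errors[nm] = float("nan")
            fit.t_values[nm] = float("nan")
        fit.x_names = list(dm.x_names)
        fit.coefficients = {nm: fit.coefficients[nm] for nm in dm.x_names}
        fit.std_errors = {nm: fit.std_errors[nm] for nm in dm.x_names}
        fit.t_values = {nm: fit.t_values[nm] for nm in dm.x_names}
        return fit

    rank = np.linalg.matrix_rank(dm.X)
    if rank < p:
        # name the offending columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(dm.X)
        bad = [dm.x_names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")
    if dm.Z_watershed is not None and dm.n_watersheds < 2:
        raise ValueError("need >= 2 watersheds for a watershed random level")
    if dm.Z_county is not None and dm.n_counties < 2:
        raise ValueError("need >= 2 counties for a county random level")
    if dm.Z_watershed is None and dm.Z_county is None:
        raise ValueError("at least one random level is required; use OLS otherwise")

    blocks = _Blocks(dm)
    x0 = _start_theta(blocks)
    fun = lambda th: _profiled_neg2ll(th, blocks, method)

    res = optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={
            "xatol": opts.get("xatol", 1e-8),
            "fatol": opts.get("fatol", 1e-10),
            "maxiter": opts.get("maxiter", 400 * (len(x0) + 1)),
            "maxfev": opts.get("maxfev", 400 * (len(x0) + 1)),
        },
    )
    polish = optimize.minimize(fun, res.x, method="BFGS",
                               options={"gtol": opts.get("gtol", 1e-7)})
    if polish.fun < res.fun:
        res = polish
    converged = bool(np.isfinite(res.fun)) and (res.success or polish.success
                                                or abs(polish.fun - res.fun) < 1e-6)
    if not converged:
        logger.warning("fit_lmm: optimizer did not report convergence (%s)", res.message)

    full = _profiled_neg2ll(res.x, blocks, method, return_full=True)
    beta, sigma2 = full["beta"], full["sigma2"]
    cov_beta = sigma2 * np.linalg.inv(full["XtX"])
    se = np.sqrt(np.diag(cov_beta))
    tau_w = None if full["Gw"] is None else sigma2 * full["Gw"]
    tau_c = None if full["Gc"] is None else sigma2 * full["Gc"]
    vc = VarianceComponents(sigma2=float(sigma2), tau_watershed=tau_w, tau_county=tau_c)

    loglik = -0.5 * float(full["neg2ll"])
    n_var = len(res.x) + 1  # free variance parameters incl. sigma2
    aic = -2.0 * loglik + 2.0 * (p + n_var)

    blups = _blups(blocks, full, dm)

    names = dm.x_names
    return FitResult(
        coefficients=dict(zip(names, map(float, beta))),
        std_errors=dict(zip(names, map(float, se))),
        t_values=dict(zip(names, map(float, beta / se))),
        vc=vc, loglik=loglik, aic=float(aic),
        n_obs=n, n_watersheds=dm.n_watersheds, n_counties=dm.n_counties,
        method=method, converged=converged, blups=blups,
        n_params_fixed=p, n_params_variance=n_var,
        spec=dm.spec, cat_levels=dict(dm.cat_levels), x_names=list(names),
        n_dropped=dm.n_dropped,
    )


def _blups(blocks: _Blocks, full: dict, dm: DesignMatrices) -> dict:
    """Best linear unbiased predictors: u_hat = Gamma Z' V*^{-1} r per group."""
    r = dm.y - dm.X @ full["beta"]
    Gw, Gc = full["Gw"], full["Gc"]
    out: dict[str, dict] = {"watershed": {}, "county": {}}
    for blk, C in zip(blocks.blocks, full["chols"]):
        sl = blk["sl"]
        vinv_r = solve_triangular(
            C.T, solve_triangular(C, r[sl], lower=True), lower=False
        )
        if Gc is not None:
            u = Gc @ (blk["Zc"].T @ vinv_r)
            out["county"][dm.county_ids[blk["county"]]] = u.tolist()
        if Gw is not None:
            for wsl, Zw, wcode in blk["ws"]:
                u = Gw @ (Zw.T @ vinv_r[wsl])
                out["watershed"][dm.watershed_ids[wcode]] = u.tolist()
    return out


def fixed_effects_at(dm: DesignMatrices, vc: VarianceComponents) -> np.ndarray:
    """GLS fixed effects at given variance components (method-independent)."""
    blocks = _Blocks(dm)
    s2 = vc.sigma2
    if s2 <= 0:
        raise ValueError("sigma2 must be positive for GLS")
    Gw = None if vc.tau_watershed is None else vc.tau_watershed / s2
    Gc = None if vc.tau_county is None else vc.tau_county / s2
    _, XtX, Xty, _, _ = blocks.whiten(Gw, Gc)
    return np.linalg.solve(XtX, Xty)


def loglik_at(dm: DesignMatrices, vc: VarianceComponents, beta) -> float:
    """Exact Gaussian log-density of y at explicit components and fixed effects."""
    beta = np.asarray(beta, dtype=float)
    s2 = vc.sigma2
    if s2 <= 0:
        # degenerate residual variance only valid if data fit exactly; reject
        raise ValueError("sigma2 must be positive to evaluate the log-likelihood")
    blocks = _Blocks(dm)
    Gw = None if vc.tau_watershed is None else vc.tau_watershed / s2
    Gc = None if vc.tau_county is None else vc.tau_county / s2
    r = dm.y - dm.X @ beta
    n = len(r)
    quad = 0.0
    logdet = 0.0
    for blk in blocks.blocks:
        sl = blk["sl"]
        nj = sl.stop - sl.start
        V = np.eye(nj)
        if Gc is not None:
            V += blk["Zc"] @ Gc @ blk["Zc"].T
        if Gw is not None:
            for wsl, Zw, _ in blk["ws"]:
                V[wsl, wsl] += Zw @ Gw @ Zw.T
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise ValueError("marginal covariance is not positive definite") from exc
        logdet += 2.0 * float(np.sum(np.log(np.diag(C))))
        z = solve_triangular(C, r[sl], lower=True)
        quad += float(z @ z)
    return -0.5 * (n * (_LOG2PI + np.log(s2)) + logdet + quad / s2)


@dataclass
class LRTestResult:
    chi2: float
    df: int
    p_value: float
    note: str = (
        "If the reduced model sets a variance component to zero, the null "
        "lies on the parameter-space boundary and the chi-squared reference "
        "distribution is conservative."
    )


def lr_test(fit_full: FitResult, fit_reduced: FitResult) -> LRTestResult:
    """Likelihood-ratio test of nested fits: chi2 = 2 (ll_full - ll_reduced)."""
    if fit_full.method == "REML" or fit_reduced.method == "REML":
        if fit_full.x_names != fit_reduced.x_names:
            raise ValueError(
                "REML likelihoods are not comparable across different fixed parts"
            )
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("LR test requires fits on identical rows")
    df = (fit_full.n_params_fixed + fit_full.n_params_variance) - (
        fit_reduced.n_params_fixed + fit_reduced.n_params_variance
    )
    chi2 = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 == 0 else 0.0)
    return LRTestResult(chi2=float(chi2), df=int(df), p_value=p)


def predict_trajectory(
    fit: FitResult,
    covariate_profile: Mapping[str, object],
    time_grid: Sequence[float],
    group: tuple[str, object] | None = None,
) -> pd.DataFrame:
    """Predicted log-NPP curve over calendar years at a covariate profile.

    With ``group=None`` the curve is the population-level fixed-effects
    prediction; ``group=("watershed", id)`` or ``("county", id)`` adds the
    group's BLUP.  The returned frame flags which was used.
    """
    if fit.spec is None:
        raise ValueError("fit carries no model spec; cannot rebuild design rows")
    spec = fit.spec
    df = pd.DataFrame({"year": np.asarray(time_grid, dtype=float)})
    for key, val in covariate_profile.items():
        df[key] = val
    for nm in fit.x_names:
        for col in _base_columns(nm):
            if col not in df.columns:
                raise KeyError(f"covariate profile missing model term column {col!r}")
    X = np.column_stack(
        [eval_effect_column(df, nm, spec.time_origin, spec.time_scale)
         for nm in fit.x_names]
    )
    beta = np.array([fit.coefficients[nm] for nm in fit.x_names])
    pred = X @ beta
    level = "population"
    if group is not None:
        lvl, gid = group
        u = np.asarray(fit.blups[lvl][gid])
        T = (df["year"].to_numpy() - spec.time_origin) / spec.time_scale
        Zcols = np.column_stack([np.ones(len(df)), T])[:, : len(u)]
        pred = pred + Zcols @ u
        level = f"{lvl}:{gid}"
    return pd.DataFrame({"year": df["year"], "log_npp": pred, "level": level})
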