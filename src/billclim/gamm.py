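"""Gaussian additive mixed model with a 2D spatial smooth and a year
random intercept, fit by REML.

Model
-----
    SA_i = x_i'β + f(lat_i, lon_i) + u_{year(i)} + ε_i,
    u_year ~ N(0, σ²_year),   ε ~ N(0, σ²),

where f is a low-rank thin-plate regression spline (eigen-truncation of
the full thin-plate spline, radial kernel r²·log r, null space spanned
by {1, lat, lon}).  The penalized part of the smooth is recast as a
random-effect block with i.i.d. coefficients, so REML jointly estimates
the residual variance, the year-intercept variance and the smoothing
variance (equivalently the smoothing parameter λ = σ²/σ²_smooth).

The REML criterion is profiled over σ²: with V0(γ) = I + γ_s Z_s Z_s' +
γ_y Z_y Z_y' and γ the variance ratios, we minimise

    (n − p)·log(y'P0 y) + log|V0| + log|X'V0⁻¹X|

over ρ = log γ, using Woodbury identities so each evaluation costs
O(n·q²) for q random-effect columns.  Two optimizer starts guard
against local optima; a variance ratio pinned at the box boundary is
flagged in the fit metadata.

Coefficient covariance is the usual Bayesian posterior covariance of
the penalized fit, σ²·(C'C + D)⁻¹, whose fixed-effect block equals the
GLS covariance.  Effective degrees of freedom are diagonal elements of
(C'C + D)⁻¹C'C; the reported smooth edf adds the 3 null-space
dimensions (the constant is shared with the model intercept, so the
design carries only centered lat/lon as unpenalized columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from . import morphometry
from .climate_covariates import haversine_km

__all__ = [
    "ModelSpec",
    "TPSBasis",
    "thinplate_basis",
    "Designs",
    "build_design",
    "FitResult",
    "fit_gamm",
    "fit_model",
    "predict_with_ci",
    "wald_tests",
    "smooth_edf",
    "r2_nakagawa",
    "r2_from_components",
    "morans_i",
    "MoranResult",
    "gvif",
    "refit_alternative_bodysize",
    "bergmann_test",
]

FIXED_TERMS = (
    "rel_min_temp",
    "rel_max_temp",
    "mean_temp",
    "rel_min_temp:mean_temp",
    "rel_max_temp:mean_temp",
    "temp_sd",
    "recent_precip",
    "rel_min_temp:recent_precip",
    "rel_max_temp:recent_precip",
    "month",
    "subspecies_thurberi",
    "BODYSIZE",  # placeholder, replaced by tarsus_mm or wing_chord_mm
    "sex_male",
)


class RankDeficientError(ValueError):
    """Fixed design is not of full column rank."""


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: fixed terms per the SA regression, a 2D thin-plate
    smooth of (lat, lon) with basis dimension `k`, and a year random
    intercept.  `bodysize` switches the body-size proxy column."""

    bodysize: str = "tarsus"  # "tarsus" | "wing"
    k: int = 30
    standardize: bool = False

    @property
    def bodysize_column(self) -> str:
        if self.bodysize == "tarsus":
            return "tarsus_mm"
        if self.bodysize == "wing":
            return "wing_chord_mm"
        raise ValueError("bodysize must be 'tarsus' or 'wing'")

    @property
    def fixed_names(self) -> list[str]:
        return ["intercept"] + [
            self.bodysize_column if t == "BODYSIZE" else t for t in FIXED_TERMS
        ]


# ---------------------------------------------------------------------------
# thin-plate regression spline
# ---------------------------------------------------------------------------


def _tps_eta(r: np.ndarray) -> np.ndarray:
    """Radial kernel r²·log(r) for the 2D thin-plate spline; η(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


@dataclass
class TPSBasis:
    """Low-rank thin-plate regression spline basis over (lat, lon).

    Attributes
    ----------
    basis : (n, k) ndarray — penalized columns first, then the null-space
        columns [1, lat, lon].
    penalty : (k, k) PSD ndarray, exactly zero on the null-space block.
    null_dim : 3.
    Z_mixed : (n, k-3) penalized block reparametrized so its penalty is
        the identity (for the mixed-model form).
    """

    knots: np.ndarray  # (n, 2)
    k: int
    Uk: np.ndarray  # (n, k-3) eigenvectors (constraint absorbed): knots -> delta map
    pen_eigvals: np.ndarray  # (k-3,) penalty eigenvalues in mixed coords ( = 1 after reparam)
    basis: np.ndarray
    penalty: np.ndarray
    Z_mixed: np.ndarray
    _mixed_map: np.ndarray  # (n, k-3): delta = _mixed_map @ b_s
    null_dim: int = 3

    def predict_penalized(self, points: np.ndarray) -> np.ndarray:
        """Mixed-form penalized basis evaluated at new (lat, lon) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = degree_distance_matrix(pts, self.knots)
        return _tps_eta(d) @ self._mixed_map


def degree_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance in degree space (isotropic smooth)."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def thinplate_basis(lat, lon, k: int) -> TPSBasis:
    """Construct a rank-`k` thin-plate regression spline basis.

    `k` counts the total basis dimension including the 3 null-space
    functions {1, lat, lon}.  The penalized space is the span of the
    k−3 leading eigenvectors (by |eigenvalue|) of the radial-kernel
    matrix over all data points, with the polynomial orthogonality
    constraint absorbed.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    pts = np.column_stack([lat, lon])
    n = len(pts)
    n_distinct = len(np.unique(pts.round(12), axis=0))
    if k < 4:
        raise ValueError("k must be at least 4 (null space has dimension 3)")
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct locations for k={k}; reduce k to <= {n_distinct}"
        )
    E = _tps_eta(degree_distance_matrix(pts, pts))
    T = np.column_stack([np.ones(n), lat, lon])
    evals, evecs = linalg.eigh(E)
    # keep k leading eigenvectors; absorbing the 3 polynomial-orthogonality
    # constraints leaves k-3 penalized columns, plus the 3 null functions = k
    order = np.argsort(np.abs(evals))[::-1][:k]
    Uk = evecs[:, order]
    lam = evals[order]
    # absorb T'δ = 0: δ = Uk δk, constraint (T'Uk) δk = 0
    M = T.T @ Uk  # 3 x k
    q, _ = linalg.qr(M.T, mode="full")
    Z = q[:, 3:]  # k x (k-3), columns spanning null(M)
    Xpen = (Uk * lam) @ Z
    S = Z.T @ (Z * lam[:, None])
    S = (S + S.T) / 2.0
    # reparametrize so the penalty is the identity
    w, P = linalg.eigh(S)
    floor = max(w.max(), 1.0) * 1e-12
    w = np.maximum(w, floor)
    scale = 1.0 / np.sqrt(w)
    Z_mixed = Xpen @ (P * scale)
    mixed_map = Uk @ (Z @ (P * scale))
    basis = np.column_stack([Xpen, T])
    kk = Xpen.shape[1]
    penalty = np.zeros((kk + 3, kk + 3))
    penalty[:kk, :kk] = S
    return TPSBasis(
        knots=pts,
        k=k,
        Uk=Uk,
        pen_eigvals=np.ones(Z_mixed.shape[1]),
        basis=basis,
        penalty=penalty,
        Z_mixed=Z_mixed,
        _mixed_map=mixed_map,
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class Designs:
    """Model matrices: fixed block X, unpenalized smooth null columns
    (centered lat/lon), mixed-form penalized smooth block, and the year
    random-intercept indicator matrix."""

    X: np.ndarray
    fixed_names: list[str]
    tps: TPSBasis
    smooth_null: np.ndarray  # (n, 2) centered lat, lon
    centroid: tuple[float, float]
    Z_year: np.ndarray
    year_levels: np.ndarray
    frame: pd.DataFrame
    spec: ModelSpec
    scales: np.ndarray | None = None  # per-column standardization, if used


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = linalg.qr(X / norms, mode="economic", pivoting=True)
    tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps * 100
    rank = int(np.sum(np.abs(np.diag(R)) > tol))
    return [names[j] for j in piv[rank:]]


def build_design(
    covariates: pd.DataFrame,
    specimens: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> Designs:
    """Assemble fixed, smooth and random design matrices.

    Treatment coding: subspecies reference is pinosus, sex reference is
    female.  Interactions are elementwise products of the stored
    covariate columns; covariates enter in raw units unless
    ``spec.standardize`` is set.
    """
    spec = spec or ModelSpec()
    df = specimens.merge(covariates, left_on="catalog_id", right_on="key", how="inner")
    if len(df) < len(specimens):
        missing = set(specimens["catalog_id"]) - set(df["catalog_id"])
        raise ValueError(f"no covariates for specimens: {sorted(missing)[:5]} ...")
    n = len(df)
    if df["year"].nunique() < 2:
        raise ValueError("need at least 2 collection-year levels for the year random effect")
    body = spec.bodysize_column
    if body not in df.columns or df[body].isna().any():
        raise ValueError(f"body-size column {body!r} missing or incomplete")
    cols = {
        "intercept": np.ones(n),
        "rel_min_temp": df["rel_min_temp"].to_numpy(float),
        "rel_max_temp": df["rel_max_temp"].to_numpy(float),
        "mean_temp": df["mean_temp"].to_numpy(float),
        "temp_sd": df["temp_sd"].to_numpy(float),
        "recent_precip": df["recent_precip"].to_numpy(float),
        "month": df["month"].to_numpy(float),
        "subspecies_thurberi": (df["subspecies"] == "thurberi").to_numpy(float),
        body: df[body].to_numpy(float),
        "sex_male": (df["sex"] == "male").to_numpy(float),
    }
    cols["rel_min_temp:mean_temp"] = cols["rel_min_temp"] * cols["mean_temp"]
    cols["rel_max_temp:mean_temp"] = cols["rel_max_temp"] * cols["mean_temp"]
    cols["rel_min_temp:recent_precip"] = cols["rel_min_temp"] * cols["recent_precip"]
    cols["rel_max_temp:recent_precip"] = cols["rel_max_temp"] * cols["recent_precip"]
    names = spec.fixed_names
    X = np.column_stack([cols[nm] for nm in names])
    scales = None
    if spec.standardize:
        scales = X.std(axis=0, ddof=1)
        scales[0] = 1.0
        scales[scales == 0] = 1.0
        X = X / scales
    aliased = _find_aliased(X, names)
    if aliased:
        raise RankDeficientError(f"fixed design is rank deficient; aliased columns: {aliased}")
    lat = df["decimal_latitude"].to_numpy(float)
    lon = df["decimal_longitude"].to_numpy(float)
    tps = thinplate_basis(lat, lon, spec.k)
    centroid = (float(lat.mean()), float(lon.mean()))
    smooth_null = np.column_stack([lat - centroid[0], lon - centroid[1]])
    year_levels, year_idx = np.unique(df["year"].to_numpy(int), return_inverse=True)
    Z_year = np.zeros((n, len(year_levels)))
    Z_year[np.arange(n), year_idx] = 1.0
    return Designs(
        X=X,
        fixed_names=list(names),
        tps=tps,
        smooth_null=smooth_null,
        centroid=centroid,
        Z_year=Z_year,
        year_levels=year_levels,
        frame=df,
        spec=spec,
        scales=scales,
    )


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    designs: Designs
    y: np.ndarray
    coef: np.ndarray  # full coefficient vector [fixed | lat,lon | smooth | year]
    coef_names: list[str]
    cov: np.ndarray  # sigma2 * (C'C + D)^-1
    n_fixed: int  # columns in X (14)
    n_unpen: int  # fixed + null-space columns (16)
    n_smooth: int
    sigma2_resid: float
    sigma2_year: float
    sigma2_smooth: float
    lambda_smooth: float
    gamma: tuple[float, float]
    edf_by_col: np.ndarray
    edf_smooth: float
    edf_total: float
    df_resid: float
    fitted: np.ndarray
    residuals: np.ndarray
    ranef_year: pd.Series
    reml_criterion: float
    n_iter: int
    converged: bool
    boundary: dict
    trace: list

    # convenient views ---------------------------------------------------
    @property
    def coef_fixed(self) -> pd.Series:
        return pd.Series(self.coef[: self.n_fixed], index=self.designs.fixed_names)

    @property
    def se_fixed(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov)[: self.n_fixed])
        return pd.Series(se, index=self.designs.fixed_names)

    @property
    def sd_year(self) -> float:
        return float(np.sqrt(self.sigma2_year))

    @property
    def sd_resid(self) -> float:
        return float(np.sqrt(self.sigma2_resid))

    def smooth_slice(self) -> slice:
        """Columns of the smooth block (null lat/lon + penalized)."""
        return slice(self.n_fixed, self.n_fixed + 2 + self.n_smooth)


def _reml_criterion(gam, blocks, cache):
    """Profiled −2·REML (up to an additive constant) at variance ratios gam."""
    FtF, Fty, yty, ZtZ, ZtF, Zty, n, p = cache
    q = ZtZ.shape[0]
    if q == 0:
        XtViX, XtViy, yty_v, logdetV0 = FtF, Fty, yty, 0.0
    else:
        g = np.concatenate([np.full(b, v) for b, v in blocks if b > 0])
        gh = np.sqrt(g)
        W = np.eye(q) + (gh[:, None] * ZtZ * gh[None, :])
        cW, low = linalg.cho_factor(W, lower=True)
        logdetV0 = 2.0 * np.sum(np.log(np.diag(cW)))
        AF = gh[:, None] * ZtF
        Ay = gh * Zty
        WiAF = linalg.cho_solve((cW, low), AF)
        WiAy = linalg.cho_solve((cW, low), Ay)
        XtViX = FtF - AF.T @ WiAF
        XtViy = Fty - AF.T @ WiAy
        yty_v = yty - Ay @ WiAy
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, None
    try:
        beta = linalg.solve(XtViX, XtViy, assume_a="pos")
    except linalg.LinAlgError:
        beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
    quad = max(yty_v - XtViy @ beta, 1e-300)
    crit = (n - p) * np.log(quad) + logdetV0 + logdet_xvx
    return crit, quad


def fit_gamm(
    designs: Designs,
    response: np.ndarray,
    fix_gamma_smooth: float | None = None,
    fix_gamma_year: float | None = None,
    n_starts: int = 2,
    maxiter: int = 400,
) -> FitResult:
    """Fit the GAMM by (profiled) REML.

    ``fix_gamma_*`` pin a variance ratio γ = σ²_component/σ²_resid
    instead of estimating it; 0 removes the component (γ_smooth = 0 is
    the infinite-penalty limit, leaving only the smooth's null space).
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    F = np.column_stack([designs.X, designs.smooth_null])
    p = F.shape[1]
    Zs = designs.tps.Z_mixed
    Zy = designs.Z_year
    qs, qy = Zs.shape[1], Zy.shape[1]
    if n <= p:
        raise ValueError("need more observations than unpenalized columns")
    if np.var(y) == 0:
        raise ValueError("response has zero variance: degenerate fit")

    free = []  # indices into (gamma_s, gamma_y) being optimized
    if fix_gamma_smooth is None:
        free.append(0)
    if fix_gamma_year is None:
        free.append(1)

    LOG_LO, LOG_HI = np.log(1e-8), np.log(1e8)

    def gammas_from(rho_free):
        g = [fix_gamma_smooth, fix_gamma_year]
        for slot, r in zip(free, np.atleast_1d(rho_free)):
            g[slot] = float(np.exp(np.clip(r, LOG_LO, LOG_HI)))
        return tuple(g)

    def make_cache(gs_on, gy_on):
        parts = []
        if gs_on:
            parts.append(Zs)
        if gy_on:
            parts.append(Zy)
        Z = np.column_stack(parts) if parts else np.zeros((n, 0))
        return (
            F.T @ F,
            F.T @ y,
            float(y @ y),
            Z.T @ Z,
            Z.T @ F,
            Z.T @ y,
            n,
            p,
        ), Z

    trace: list[float] = []

    def active_blocks(g):
        return [(qs if g[0] > 0 else 0, g[0]), (qy if g[1] > 0 else 0, g[1])]

    if free:
        cache_full, _ = make_cache(
            fix_gamma_smooth is None or (fix_gamma_smooth or 0) > 0,
            fix_gamma_year is None or (fix_gamma_year or 0) > 0,
        )

        def obj(rho_free):
            g = gammas_from(rho_free)
            crit, _ = _reml_criterion(g, active_blocks(g), cache_full)
            trace.append(crit)
            return crit

        # the profiled criterion can be extremely flat in log-gamma with a
        # shallow interior minimum; seed the simplex search from the best
        # points of a coarse grid instead of trusting a single descent path
        grid_pts = np.array([-8.0, -5.0, -3.0, -1.0, 0.0, 1.0, 3.0, 6.0])
        if len(free) == 1:
            cand = grid_pts[:, None]
        else:
            gx, gy = np.meshgrid(grid_pts, grid_pts, indexing="ij")
            cand = np.column_stack([gx.ravel(), gy.ravel()])
        vals = np.array([obj(c) for c in cand])
        order = np.argsort(vals)
        starts = [cand[i] for i in order[: max(1, n_starts)]]
        best = None
        nit = 0
        for s0 in starts:
            res = optimize.minimize(
                obj, s0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
            )
            nit += res.nit
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed to find a finite optimum", trace)
        gamma = gammas_from(best.x)
        converged = bool(best.success or best.fun <= min(trace) + 1e-6)
        n_iter = nit
    else:
        gamma = (float(fix_gamma_smooth), float(fix_gamma_year))
        converged, n_iter = True, 0

    boundary = {
        "smooth": fix_gamma_smooth is None and not (1e-7 < gamma[0] < 1e7),
        "year": fix_gamma_year is None and not (1e-7 < gamma[1] < 1e7),
    }
    if any(boundary.values()):
        warnings.warn(f"variance ratio at boundary: {boundary}", RuntimeWarning)

    cache_full, _ = make_cache(gamma[0] > 0, gamma[1] > 0)
    crit, quad = _reml_criterion(gamma, active_blocks(gamma), cache_full)
    if quad is None:
        raise ConvergenceError("REML criterion not finite at the optimum", trace)
    sigma2 = quad / (n - p)

    # penalized augmented solve for coefficients, covariance and edf
    C = np.column_stack([F, Zs, Zy])
    names = (
        list(designs.fixed_names)
        + ["s(lat)", "s(lon)"]
        + [f"s_pen_{i}" for i in range(qs)]
        + [f"year_{yv}" for yv in designs.year_levels]
    )
    pen = np.concatenate(
        [
            np.zeros(p),
            np.full(qs, 1.0 / gamma[0] if gamma[0] > 0 else np.inf),
            np.full(qy, 1.0 / gamma[1] if gamma[1] > 0 else np.inf),
        ]
    )
    keep = ~np.isinf(pen)
    Ck = C[:, keep]
    CtC = Ck.T @ Ck
    H = CtC + np.diag(pen[keep])
    try:
        cH = linalg.cho_factor(H, lower=True)
        Hinv = linalg.cho_solve(cH, np.eye(H.shape[0]))
    except linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
    coef_k = Hinv @ (Ck.T @ y)
    coef = np.zeros(C.shape[1])
    coef[keep] = coef_k
    cov = np.zeros((C.shape[1], C.shape[1]))
    cov[np.ix_(keep, keep)] = sigma2 * Hinv
    edf_k = np.einsum("ij,ji->i", Hinv, CtC)
    edf = np.zeros(C.shape[1])
    edf[keep] = edf_k
    sm = slice(p, p + qs)
    edf_smooth_val = 3.0 + float(edf[sm].sum())
    edf_total = float(edf.sum())
    fitted = C @ coef
    residuals = y - fitted
    ranef = pd.Series(coef[p + qs :], index=designs.year_levels, name="year_effect")
    return FitResult(
        designs=designs,
        y=y,
        coef=coef,
        coef_names=names,
        cov=cov,
        n_fixed=designs.X.shape[1],
        n_unpen=p,
        n_smooth=qs,
        sigma2_resid=float(sigma2),
        sigma2_year=float(gamma[1] * sigma2),
        sigma2_smooth=float(gamma[0] * sigma2),
        lambda_smooth=float(1.0 / gamma[0]) if gamma[0] > 0 else np.inf,
        gamma=gamma,
        edf_by_col=edf,
        edf_smooth=edf_smooth_val,
        edf_total=edf_total,
        df_resid=float(n - edf_total),
        fitted=fitted,
        residuals=residuals,
        ranef_year=ranef,
        reml_criterion=float(crit),
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
        trace=trace,
    )


def fit_model(
    covariates: pd.DataFrame,
    specimens: pd.DataFrame,
    spec: ModelSpec | None = None,
    response: np.ndarray | None = None,
    **fit_kwargs,
) -> FitResult:
    """Build the design and fit; the response defaults to bill surface
    area computed from the specimen bill measurements."""
    spec = spec or ModelSpec()
    designs = build_design(covariates, specimens, spec)
    if response is None:
        df = designs.frame
        response = morphometry.bill_surface_area(
            df["bill_length_mm"].to_numpy(float),
            df["bill_width_mm"].to_numpy(float),
            df["bill_depth_mm"].to_numpy(float),
        )
    return fit_gamm(designs, response, **fit_kwargs)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _design_rows(fit: FitResult, rows: pd.DataFrame, lat: float, lon: float) -> np.ndarray:
    """Full design matrix for new covariate points (year effects at 0,
    smooth evaluated at a single (lat, lon))."""
    d = fit.designs
    m = len(rows)
    vals = {c: rows[c].to_numpy(float) for c in rows.columns}
    vals["intercept"] = np.ones(m)
    vals["rel_min_temp:mean_temp"] = vals["rel_min_temp"] * vals["mean_temp"]
    vals["rel_max_temp:mean_temp"] = vals["rel_max_temp"] * vals["mean_temp"]
    vals["rel_min_temp:recent_precip"] = vals["rel_min_temp"] * vals["recent_precip"]
    vals["rel_max_temp:recent_precip"] = vals["rel_max_temp"] * vals["recent_precip"]
    X = np.column_stack([vals[nm] for nm in d.fixed_names])
    if d.scales is not None:
        X = X / d.scales
    null = np.tile([lat - d.centroid[0], lon - d.centroid[1]], (m, 1))
    zs = np.tile(d.tps.predict_penalized(np.array([[lat, lon]]))[0], (m, 1))
    zy = np.zeros((m, len(d.year_levels)))
    return np.column_stack([X, null, zs, zy])


def predict_with_ci(
    fit: FitResult,
    rows: pd.DataFrame,
    lat: float | None = None,
    lon: float | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predict SA (fixed + smooth, random effects at 0) with pointwise CI.

    `rows` must carry the covariate and factor columns used by the fixed
    design; `lat`/`lon` default to the data centroid (the smooth is then
    evaluated at the centroid).  The CI is the delta-method interval on
    the linear predictor from the coefficient covariance.
    """
    d = fit.designs
    if lat is None or lon is None:
        lat, lon = d.centroid
    z = stats.norm.ppf(0.5 + level / 2.0)
    M = _design_rows(fit, rows, lat, lon)
    mean = M @ fit.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", M, fit.cov, M), 0.0))
    return pd.DataFrame({"fit": mean, "se": se, "lo": mean - z * se, "hi": mean + z * se})


# ---------------------------------------------------------------------------
# inference & diagnostics
# ---------------------------------------------------------------------------


def wald_tests(fit: FitResult) -> pd.DataFrame:
    """Coefficient table: estimate, SE, t, p for fixed terms, and an
    approximate F test for the smooth.

    t = estimate/SE with residual df = n − total edf (fixed + smooth +
    random trace); the smooth row tests all smooth coefficients jointly
    against their covariance (statistic/edf ~ F(edf, df_resid))."""
    est = fit.coef_fixed
    se = fit.se_fixed
    t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    rows = pd.DataFrame(
        {"term": est.index, "estimate": est.values, "se": se.values, "statistic": t.values,
         "stat_type": "t", "df": np.nan, "p": p}
    )
    sl = fit.smooth_slice()
    beta_s = fit.coef[sl]
    V_s = fit.cov[sl.start : sl.stop, sl.start : sl.stop]
    Vinv = np.linalg.pinv(V_s, rcond=1e-10, hermitian=True)
    stat = float(beta_s @ Vinv @ beta_s)
    fstat = stat / fit.edf_smooth
    pf = float(stats.f.sf(fstat, fit.edf_smooth, fit.df_resid))
    smooth_row = pd.DataFrame(
        {"term": ["s(latitude,longitude)"], "estimate": [np.nan], "se": [np.nan],
         "statistic": [fstat], "stat_type": "F", "df": [fit.edf_smooth], "p": [pf]}
    )
    return pd.concat([rows, smooth_row], ignore_index=True)


def smooth_edf(fit: FitResult) -> float:
    """Effective degrees of freedom of the spatial smooth (null space of
    {1, lat, lon} counts 3; plus the trace over the penalized block)."""
    return fit.edf_smooth


def r2_from_components(var_fixed: float, var_year: float, var_resid: float) -> tuple[float, float]:
    tot = var_fixed + var_year + var_resid
    return var_fixed / tot, (var_fixed + var_year) / tot


def r2_nakagawa(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional R² for the mixed model.

    The 'fixed' predictor includes the smooth contribution (evaluated at
    the data); marginal R² = var(fixed predictor) / (var(fixed) +
    σ²_year + σ²_resid), conditional adds σ²_year to the numerator."""
    d = fit.designs
    p, qs = fit.n_unpen, fit.n_smooth
    eta_fixed = (
        np.column_stack([d.X, d.smooth_null]) @ fit.coef[:p]
        + d.tps.Z_mixed @ fit.coef[p : p + qs]
    )
    var_f = float(np.var(eta_fixed, ddof=1))
    return r2_from_components(var_f, fit.sigma2_year, fit.sigma2_resid)


@dataclass
class MoranResult:
    I: float
    expected: float
    sd: float
    z: float
    p: float
    p_permutation: float | None = None
    n: int = 0
    weight_sum: float = 0.0


def morans_i(
    residuals: np.ndarray,
    lats: np.ndarray | None = None,
    lons: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    variance: str = "randomization",
    permutations: int = 0,
    rng: np.random.Generator | None = None,
    coincident_cap: float | None = None,
) -> MoranResult:
    """Moran's I with inverse great-circle-distance weights.

    I = (n/W)·ΣΣ w_ij (x_i−x̄)(x_j−x̄) / Σ(x_i−x̄)².  The diagonal is
    zero and weights are not row-standardized.  The analytic two-sided p
    uses the normal approximation with the expectation −1/(n−1) and the
    `variance` convention ('randomization' or 'normality'); an optional
    permutation p is computed by shuffling residuals.
    Coincident points (zero distance) get their weight capped at the
    largest finite weight (or `coincident_cap`), with a warning.
    """
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("residuals have zero variance")
    if weights is None:
        if lats is None or lons is None:
            raise ValueError("provide coords or a weight matrix")
        la = np.asarray(lats, float)
        lo = np.asarray(lons, float)
        d = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
        with np.errstate(divide="ignore"):
            W = 1.0 / d
        np.fill_diagonal(W, 0.0)
        if np.isinf(W).any():
            cap = coincident_cap if coincident_cap is not None else W[np.isfinite(W)].max()
            warnings.warn("coincident points: capping infinite weights", RuntimeWarning)
            W[np.isinf(W)] = cap
    else:
        W = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(W, 0.0)
    S0 = W.sum()
    if S0 <= 0:
        raise ValueError("weight matrix sums to zero")
    xc = x - x.mean()
    denom = float(xc @ xc)
    num = float(xc @ W @ xc)
    I = n / S0 * num / denom
    EI = -1.0 / (n - 1)
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    if variance == "normality":
        VI = (n * n * S1 - n * S2 + 3 * S0 * S0) / (S0 * S0 * (n * n - 1)) - EI * EI
    elif variance == "randomization":
        m2 = (xc**2).mean()
        m4 = (xc**4).mean()
        b2 = m4 / (m2 * m2)
        A = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
        B = b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0)
        VI = (A - B) / ((n - 1) * (n - 2) * (n - 3) * S0 * S0) - EI * EI
    else:
        raise ValueError("variance must be 'randomization' or 'normality'")
    sd = float(np.sqrt(max(VI, 1e-300)))
    z = (I - EI) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    p_perm = None
    if permutations > 0:
        rng = rng or np.random.default_rng(0)
        count = 0
        for _ in range(permutations):
            xs = rng.permutation(xc)
            Ip = n / S0 * float(xs @ W @ xs) / denom
            if abs(Ip - EI) >= abs(I - EI):
                count += 1
        p_perm = (count + 1) / (permutations + 1)
    return MoranResult(I=float(I), expected=EI, sd=sd, z=float(z), p=p,
                       p_permutation=p_perm, n=n, weight_sum=float(S0))


def gvif(
    X: np.ndarray,
    names: list[str],
    terms: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Generalized variance inflation factors.

    For a term with columns J, GVIF = det(R_JJ)·det(R_rest)/det(R) on
    the correlation matrix R of the non-intercept columns; a one-column
    term reduces to the classical VIF.  Also reports GVIF^(1/(2·df))."""
    X = np.asarray(X, dtype=float)
    keep = [j for j, nm in enumerate(names) if nm != "intercept"]
    sub = X[:, keep]
    if np.linalg.matrix_rank(sub - sub.mean(axis=0)) < sub.shape[1]:
        raise RankDeficientError("design is rank deficient after centering; GVIF undefined")
    R = np.corrcoef(sub, rowvar=False)
    name_map = {names[j]: i for i, j in enumerate(keep)}
    if terms is None:
        terms = {names[j]: [names[j]] for j in keep}
    rows = []
    for term, cols in terms.items():
        J = [name_map[c] for c in cols]
        notJ = [i for i in range(len(keep)) if i not in J]
        detR = np.linalg.det(R)
        det1 = np.linalg.det(R[np.ix_(J, J)])
        det2 = np.linalg.det(R[np.ix_(notJ, notJ)]) if notJ else 1.0
        g = det1 * det2 / detR
        df = len(J)
        rows.append({"term": term, "df": df, "gvif": g, "gvif_scaled": g ** (1.0 / (2 * df))})
    return pd.DataFrame(rows)


def refit_alternative_bodysize(
    covariates: pd.DataFrame,
    specimens: pd.DataFrame,
    spec: ModelSpec | None = None,
    **fit_kwargs,
) -> FitResult:
    """Refit the SA model with wing chord replacing tarsus length."""
    base = spec or ModelSpec()
    alt = ModelSpec(bodysize="wing", k=base.k, standardize=base.standardize)
    return fit_model(covariates, specimens, alt, **fit_kwargs)


def bergmann_test(
    covariates: pd.DataFrame,
    specimens: pd.DataFrame,
    spec: ModelSpec | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Bergmann's-rule check: body size ~ mean temperature, with the same
    spatial smooth and year random intercept.  Returns a Wald table in
    the same schema as :func:`wald_tests` (intercept, mean_temp, smooth)."""
    spec = spec or ModelSpec()
    designs = build_design(covariates, specimens, spec)
    df = designs.frame
    y = df[spec.bodysize_column].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), df["mean_temp"].to_numpy(float)])
    small = Designs(
        X=X,
        fixed_names=["intercept", "mean_temp"],
        tps=designs.tps,
        smooth_null=designs.smooth_null,
        centroid=designs.centroid,
        Z_year=designs.Z_year,
        year_levels=designs.year_levels,
        frame=df,
        spec=spec,
    )
    fit = fit_gamm(small, y, **fit_kwargs)
    return wald_tests(fit)
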