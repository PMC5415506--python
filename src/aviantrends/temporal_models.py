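"""Per-species temporal trend models for wing length and plumage colour.

The estimation protocol for each species and trait is:

1. fit a Gaussian linear mixed model of the trait on decade of collection,
   sex and altitude (plus season and season-squared for colour, tracking
   post-molt feather abrasion), with a subspecies random intercept;
2. rasterize the residuals on a geographic grid and compute a residual
   autocovariate (RAC) — the mean residual of the eight neighbouring cells
   — then refit with RAC as an extra covariate to absorb residual spatial
   autocorrelation;
3. optionally compare, by ML/AIC, a homoscedastic residual against
   sex-stratified residual variances and keep the richer structure only
   when it improves AIC by more than 2;
4. screen for nonlinearity with a penalized cubic spline on year of
   collection (a GAMM); effective degrees of freedom (EDF) near 1 indicate
   a linear trend, above 3 a clearly nonlinear one.

The decade coefficient divided by 10 is the per-year slope reported as a
:class:`TemporalEffect`; Moran's I and a lag-1 residual autocorrelation
check are provided as diagnostics.

The mixed model (one random intercept, optional per-stratum residual
variances) is estimated by direct REML/ML maximization of the marginal
Gaussian likelihood; the homoscedastic case is cross-checked against
statsmodels' MixedLM in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

__all__ = [
    "ModelSpec",
    "LmmFit",
    "TemporalEffect",
    "RacField",
    "GammFit",
    "fit_lmm",
    "compute_rac",
    "select_variance_structure",
    "extract_effect",
    "morans_i",
    "residual_acf",
    "fit_gamm",
    "fit_species_trait",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure of one per-species trait model.

    Colour models carry season + season^2 terms; size models do not.
    ``heteroscedastic`` switches on per-stratum residual variances (strata
    default to sex).  ``rac_cell`` is the RAC raster cell size in degrees.
    """

    response: str
    include_season: bool = False
    heteroscedastic: bool = False
    strata: str = "sex"
    random_effect: str = "subspecies"
    rac_cell: float = 1.0
    center_decade: bool = True

    @classmethod
    def wing(cls, **kw) -> "ModelSpec":
        return cls(response="wing_length", include_season=False, **kw)

    @classmethod
    def colour(cls, response: str = "pc1", **kw) -> "ModelSpec":
        return cls(response=response, include_season=True, **kw)


@dataclass
class LmmFit:
    """A fitted Gaussian mixed model (REML or ML)."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    df: int
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    fitted: np.ndarray
    loglik: float
    aic: float
    method: str
    sigma_u: float
    sigma_e: np.ndarray
    n_obs: int
    spec: ModelSpec

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])


@dataclass(frozen=True)
class TemporalEffect:
    """Per-species, per-trait linear temporal effect on the per-year scale."""

    species: str
    trait: str
    beta: float
    se: float
    df: int
    t: float
    p: float
    edf: float = float("nan")

    @property
    def nonlinear(self) -> bool:
        return self.edf > 3


@dataclass(frozen=True)
class RacField:
    """Residual autocovariate values aligned with the input specimens."""

    cell: float
    values: np.ndarray


# ---------------------------------------------------------------------------
# design matrices


def _sex_code(sex: pd.Series) -> np.ndarray:
    allowed = {"male", "female"}
    vals = sex.astype(str).str.lower()
    bad = set(vals) - allowed
    if bad:
        raise ValueError(f"unknown sex codes {sorted(bad)}; expected male/female")
    return (vals == "male").to_numpy(float)


def _build_design(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    decade = frame["decade"].to_numpy(float) / 10.0  # decade units, not years
    if spec.center_decade:
        decade = decade - decade.mean()
    cols.append(decade)
    names.append("decade")
    cols.append(_sex_code(frame["sex"]))
    names.append("sex")
    cols.append(frame["altitude"].to_numpy(float))
    names.append("altitude")
    if "rac" in frame.columns:
        cols.append(frame["rac"].to_numpy(float))
        names.append("rac")
    if spec.include_season:
        season = frame["season"].to_numpy(float)
        if np.any(~np.isfinite(season)):
            raise ValueError("season missing for some specimens in a colour model")
        sc = season - season.mean()  # centre before squaring to cut collinearity
        cols.append(sc)
        names.append("season")
        cols.append(sc**2)
        names.append("season2")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, names)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    return x, names


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    return [names[i] for i in np.where(diag < tol)[0]]


def _standardize(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Scale non-constant columns to unit sd (fitting aid only)."""
    scale = np.ones(x.shape[1])
    xs = x.copy()
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        sd = x[:, j].std()
        if sd > 0:
            scale[j] = sd
            xs[:, j] = x[:, j] / sd
    return xs, scale


# ---------------------------------------------------------------------------
# mixed-model likelihood


def _v_solve(
    arr: np.ndarray,
    var_e: np.ndarray,
    groups: np.ndarray | None,
    sigma_u2: float,
) -> np.ndarray:
    """V^{-1} @ arr for V = diag(var_e) + sigma_u2 * Z Z' (Woodbury).

    The random-intercept indicator Z has disjoint columns, so the inner
    q x q system is diagonal and the solve is O(n) per column.
    """
    w = 1.0 / var_e
    out = (arr.T * w).T
    if groups is not None and sigma_u2 > 0:
        q = groups.max() + 1
        g = np.bincount(groups, weights=w, minlength=q)
        m = 1.0 / sigma_u2 + g
        if arr.ndim == 1:
            s = np.bincount(groups, weights=out, minlength=q)
            out = out - w * (s / m)[groups]
        else:
            for j in range(arr.shape[1]):
                s = np.bincount(groups, weights=out[:, j], minlength=q)
                out[:, j] = out[:, j] - w * (s / m)[groups]
    return out


def _v_logdet(
    var_e: np.ndarray, groups: np.ndarray | None, sigma_u2: float
) -> float:
    logdet = float(np.log(var_e).sum())
    if groups is not None and sigma_u2 > 0:
        q = groups.max() + 1
        g = np.bincount(groups, weights=1.0 / var_e, minlength=q)
        logdet += float(np.log1p(sigma_u2 * g).sum())
    return logdet


def _neg_loglik(
    logpars: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    z_groups: np.ndarray | None,
    strata_idx: np.ndarray,
    n_strata: int,
    method: str,
) -> float:
    n, p = x.shape
    has_re = z_groups is not None
    sigma_u2 = np.exp(2 * logpars[0]) if has_re else 0.0
    sig_e = np.exp(logpars[1:] if has_re else logpars)
    var_e = sig_e[strata_idx] ** 2 if n_strata > 1 else np.full(n, sig_e[0] ** 2)
    if np.any(~np.isfinite(var_e)) or np.any(var_e <= 0):
        return 1e12

    logdet_v = _v_logdet(var_e, z_groups, sigma_u2)
    vi_x = _v_solve(x, var_e, z_groups, sigma_u2)
    vi_y = _v_solve(y, var_e, z_groups, sigma_u2)
    xtvx = x.T @ vi_x
    try:
        beta = np.linalg.solve(xtvx, x.T @ vi_y)
    except np.linalg.LinAlgError:
        return 1e12
    r = y - x @ beta
    quad = float(r @ _v_solve(r, var_e, z_groups, sigma_u2))
    if method == "reml":
        _, logdet_xtvx = np.linalg.slogdet(xtvx)
        ll = -0.5 * (logdet_v + logdet_xtvx + quad + (n - p) * np.log(2 * np.pi))
    else:
        ll = -0.5 * (logdet_v + quad + n * np.log(2 * np.pi))
    return -ll


def fit_lmm(
    frame: pd.DataFrame,
    spec: ModelSpec,
    method: str = "reml",
) -> LmmFit:
    """Fit the mixed model defined by ``spec`` on a per-species frame.

    A subspecies random intercept is included when the frame has at least
    two subspecies levels (otherwise it is dropped with a warning).
    Continuous predictors are standardized internally for optimizer
    stability and coefficients reported on the original scales.  Wald
    t-statistics use df = n_obs − n_fixed_coefficients.
    """
    frame = frame.reset_index(drop=True)
    y = frame[spec.response].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"missing values in response {spec.response!r}")
    x, names = _build_design(frame, spec)
    xs, scale = _standardize(x, names)
    n, p = x.shape

    groups = None
    if spec.random_effect in frame.columns:
        codes = pd.factorize(frame[spec.random_effect].astype(str))[0]
        if codes.max() >= 1:
            groups = codes
        else:
            warnings.warn(
                f"only one {spec.random_effect} level: random intercept dropped",
                stacklevel=2,
            )
    strata_idx = np.zeros(n, dtype=int)
    n_strata = 1
    if spec.heteroscedastic:
        strata_idx = pd.factorize(frame[spec.strata].astype(str))[0]
        n_strata = strata_idx.max() + 1

    resid0 = y - xs @ np.linalg.lstsq(xs, y, rcond=None)[0]
    s0 = np.log(max(resid0.std(), 1e-6))
    start = ([s0 - 1.0] if groups is not None else []) + [s0] * n_strata
    res = optimize.minimize(
        _neg_loglik,
        np.array(start),
        args=(y, xs, groups, strata_idx, n_strata, method),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    logpars = res.x
    loglik = -float(res.fun)

    has_re = groups is not None
    sigma_u = float(np.exp(logpars[0])) if has_re else 0.0
    sig_e = np.exp(logpars[1:] if has_re else logpars)
    var_e = sig_e[strata_idx] ** 2 if n_strata > 1 else np.full(n, sig_e[0] ** 2)
    vi_x = _v_solve(xs, var_e, groups, sigma_u**2)
    xtvx = xs.T @ vi_x
    beta_s = np.linalg.solve(xtvx, xs.T @ _v_solve(y, var_e, groups, sigma_u**2))
    cov_s = np.linalg.inv(xtvx)
    beta = beta_s / scale
    se = np.sqrt(np.diag(cov_s)) / scale
    fitted = x @ beta
    resid = y - fitted
    df = n - p
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    n_varpar = (1 if has_re else 0) + n_strata
    aic = -2 * loglik + 2 * (p + n_varpar)
    return LmmFit(
        terms=names,
        beta=beta,
        se=se,
        df=df,
        tvalues=tvals,
        pvalues=pvals,
        resid=resid,
        fitted=fitted,
        loglik=loglik,
        aic=aic,
        method=method,
        sigma_u=sigma_u,
        sigma_e=np.asarray(sig_e, float),
        n_obs=n,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# spatial correction and diagnostics


def compute_rac(
    residuals: np.ndarray,
    latitude: np.ndarray,
    longitude: np.ndarray,
    cell: float = 1.0,
) -> RacField:
    """Residual autocovariate: neighbourhood mean of rasterized residuals.

    Residuals are averaged within cells of a ``cell``-degree grid; each
    specimen's RAC is the mean value of the up-to-8 neighbouring occupied
    cells (queen neighbourhood, focal cell excluded).  Specimens whose
    neighbourhood is entirely empty get RAC = 0.
    """
    residuals = np.asarray(residuals, float)
    ix = np.floor(np.asarray(longitude, float) / cell).astype(int)
    iy = np.floor(np.asarray(latitude, float) / cell).astype(int)
    cell_sum: dict[tuple[int, int], float] = {}
    cell_n: dict[tuple[int, int], int] = {}
    for cx, cy, r in zip(ix, iy, residuals):
        cell_sum[(cx, cy)] = cell_sum.get((cx, cy), 0.0) + r
        cell_n[(cx, cy)] = cell_n.get((cx, cy), 0) + 1
    cell_mean = {k: cell_sum[k] / cell_n[k] for k in cell_sum}
    if len(cell_mean) == 1:
        warnings.warn("all specimens fall in one raster cell: RAC is all zero",
                      stacklevel=2)

    values = np.zeros(residuals.size)
    for i, (cx, cy) in enumerate(zip(ix, iy)):
        neigh = [
            cell_mean[(cx + dx, cy + dy)]
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0) and (cx + dx, cy + dy) in cell_mean
        ]
        values[i] = np.mean(neigh) if neigh else 0.0
    return RacField(cell=cell, values=values)


def morans_i(
    residuals: np.ndarray,
    latitude: np.ndarray | None = None,
    longitude: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Moran's I with row-standardized weights.

    Weights default to inverse Euclidean distance between specimen
    locations; a precomputed (e.g. rook/queen contiguity) weight matrix can
    be passed instead.  Under spatial independence E[I] = -1/(n-1).
    """
    z = np.asarray(residuals, float)
    z = z - z.mean()
    n = z.size
    if weights is None:
        if latitude is None or longitude is None:
            raise ValueError("provide either locations or a weight matrix")
        pts = np.column_stack([np.asarray(latitude, float), np.asarray(longitude, float)])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        w[~np.isfinite(w)] = 0.0
    else:
        w = np.asarray(weights, float).copy()
        np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    w = w / rs
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero residual variance: Moran's I undefined")
    return float((z @ w @ z) / denom)


def residual_acf(residuals: np.ndarray, year: np.ndarray) -> float:
    """Lag-1 autocorrelation of year-mean residuals.

    Residuals are averaged per collection year, ordered, and the Pearson
    correlation of consecutive values returned.
    """
    frame = pd.DataFrame({"r": np.asarray(residuals, float), "year": np.asarray(year)})
    series = frame.groupby("year")["r"].mean().sort_index().to_numpy()
    if series.size < 3:
        raise ValueError("need at least three distinct years")
    a, b = series[:-1], series[1:]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant residual series: autocorrelation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# variance structure selection


def select_variance_structure(
    frame: pd.DataFrame, spec: ModelSpec
) -> tuple[ModelSpec, dict[str, float]]:
    """Choose between homoscedastic and per-stratum residual variances.

    Both variants are fitted by maximum likelihood; the per-stratum model
    is adopted only when its AIC undercuts the homoscedastic one by more
    than 2 (ties keep the simpler model).
    """
    homo = fit_lmm(frame, replace(spec, heteroscedastic=False), method="ml")
    strat = fit_lmm(frame, replace(spec, heteroscedastic=True), method="ml")
    aics = {"homoscedastic": homo.aic, "per_stratum": strat.aic}
    chosen = replace(spec, heteroscedastic=(homo.aic - strat.aic > 2.0))
    return chosen, aics


def extract_effect(fit: LmmFit, trait: str, species: str = "", edf: float = float("nan")) -> TemporalEffect:
    """Per-year temporal effect from the decade coefficient (beta/10)."""
    j = fit.terms.index("decade")
    return TemporalEffect(
        species=species,
        trait=trait,
        beta=float(fit.beta[j]) / 10.0,
        se=float(fit.se[j]) / 10.0,
        df=fit.df,
        t=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]),
        edf=edf,
    )


# ---------------------------------------------------------------------------
# GAMM nonlinearity screen


@dataclass
class GammFit:
    """Penalized-spline fit of a trait against year with linear covariates."""

    edf: float
    lambda_: float
    year: np.ndarray
    smooth: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray
    sigma2: float
    reml: float

    def year_linear_slope(self) -> float:
        """Slope of the best line through the fitted smooth (per year)."""
        return float(np.polyfit(self.year, self.smooth, 1)[0])


def _bspline_basis(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = x.min(), x.max()
    span = hi - lo if hi > lo else 1.0
    lo -= 1e-3 * span
    hi += 1e-3 * span
    n_interior = k - 4
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    basis = interpolate.BSpline.design_matrix(x, knots, 3).toarray()
    return basis, knots


def _curvature_penalty(knots: np.ndarray, k: int) -> np.ndarray:
    """Exact integrated-squared-second-derivative penalty for the basis.

    B'' of a cubic B-spline is piecewise linear, so two-point Gauss
    quadrature per knot span integrates the products exactly.  The penalty
    null space is then exactly the straight lines the basis can represent,
    which is what makes the infinite-penalty limit reproduce a linear fit.
    """
    d2 = interpolate.BSpline(knots, np.eye(k), 3).derivative(2)
    nodes, weights = np.polynomial.legendre.leggauss(2)
    s = np.zeros((k, k))
    for a, b in zip(knots[3:-4], knots[4:-3]):
        if b <= a:
            continue
        half = 0.5 * (b - a)
        pts = 0.5 * (a + b) + half * nodes
        vals = d2(pts)  # (2, k)
        s += half * (vals * weights[:, None]).T @ vals
    return s


def fit_gamm(
    frame: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    lambda_: float | None = None,
) -> GammFit:
    """Penalized cubic regression spline on year of collection.

    The trait is modelled with the same parametric covariates as the LMM
    (sex, altitude, RAC, season terms) but year — not decade — enters
    through a cubic B-spline with ``k`` basis functions under a
    second-order difference penalty; the subspecies intercepts enter as a
    ridge-penalized block (the mixed-model form of a random intercept).
    The smoothing parameter is chosen by REML unless ``lambda_`` is given.
    EDF is the trace of the influence matrix over the smooth's columns;
    as the penalty grows the smooth collapses to its unpenalized null
    space, a straight line in year (EDF -> 1).
    """
    frame = frame.reset_index(drop=True)
    year = frame["year"].to_numpy(float)
    if np.unique(year).size < 15:
        raise ValueError("GAMM needs at least 15 distinct collection years")
    y = frame[spec.response].to_numpy(float)

    # parametric block: LMM design minus the decade column
    x_full, names = _build_design(frame, spec)
    keep = [j for j, nm in enumerate(names) if nm != "decade"]
    x_par = x_full[:, keep]
    x_par, _ = _standardize(x_par, [names[j] for j in keep])
    p_par = x_par.shape[1]

    basis, knots = _bspline_basis(year, k)
    con = basis.sum(axis=0)  # sum-to-zero constraint keeps intercept identifiable
    q_full, _ = np.linalg.qr(con.reshape(-1, 1), mode="complete")
    q = q_full[:, 1:]  # orthonormal basis of the constraint null space
    z = basis @ q

    pen = _curvature_penalty(knots, k)
    # rescale so the smoothing parameter is dimensionless in year units
    pen = pen / max(np.abs(pen).max(), 1e-300)
    s_tilde = q.T @ pen @ q
    eig = np.linalg.eigvalsh(s_tilde)
    pos = eig[eig > eig.max() * 1e-10]
    rank_s = pos.size
    logdet_s_tilde = float(np.log(pos).sum())

    groups = None
    if spec.random_effect in frame.columns:
        codes = pd.factorize(frame[spec.random_effect].astype(str))[0]
        if codes.max() >= 1:
            groups = np.eye(codes.max() + 1)[codes]
    q_re = 0 if groups is None else groups.shape[1]

    blocks = [x_par, z] + ([groups] if groups is not None else [])
    c = np.column_stack(blocks)
    m = c.shape[1]
    n = len(y)
    smooth_cols = slice(p_par, p_par + z.shape[1])
    re_cols = slice(p_par + z.shape[1], m)

    ctc = c.T @ c
    cty = c.T @ y

    def penalty(loglam: float, logtau: float) -> np.ndarray:
        s = np.zeros((m, m))
        s[smooth_cols, smooth_cols] += np.exp(loglam) * s_tilde
        if q_re:
            s[re_cols, re_cols] += np.exp(logtau) * np.eye(q_re)
        return s

    def neg_reml(pars: np.ndarray) -> float:
        loglam = pars[0]
        logtau = pars[1] if q_re else 0.0
        s = penalty(loglam, logtau)
        a = ctc + s
        try:
            cf = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            return 1e12
        theta = np.linalg.solve(a, cty)
        rss_pen = float(y @ y - 2 * theta @ cty + theta @ ctc @ theta + theta @ s @ theta)
        rank_total = rank_s + q_re
        nbar = n - (m - rank_total)
        sigma2 = max(rss_pen / nbar, 1e-300)
        logdet_a = 2 * np.log(np.diag(cf)).sum()
        logdet_s = rank_s * loglam + logdet_s_tilde + (q_re * logtau if q_re else 0.0)
        return 0.5 * (nbar * (np.log(2 * np.pi * sigma2) + 1) + logdet_a - logdet_s)

    lam_bounds = (-12.0, 25.0)
    tau_bounds = (-12.0, 18.0)

    def best_tau(loglam: float) -> float:
        if not q_re:
            return 0.0
        r = optimize.minimize_scalar(
            lambda lt: neg_reml(np.array([loglam, lt])),
            bounds=tau_bounds, method="bounded",
            options={"xatol": 1e-5},
        )
        return float(r.x)

    if lambda_ is not None:
        # cap: far beyond any data scale, yet small enough that float noise
        # in the penalty's null space cannot swamp C'C
        loglam = min(np.log(lambda_), 22.0) if np.isfinite(lambda_) else 22.0
    else:
        # profile the random-effect variance out and search the smoothing
        # parameter on a bounded grid refined by Brent; the bounds keep the
        # criterion away from the numerically degenerate extremes
        grid = np.linspace(*lam_bounds, 16)
        profile = [neg_reml(np.array([g, best_tau(g)])) for g in grid]
        g0 = grid[int(np.argmin(profile))]
        r = optimize.minimize_scalar(
            lambda g: neg_reml(np.array([g, best_tau(g)])),
            bounds=(max(lam_bounds[0], g0 - 2.5), min(lam_bounds[1], g0 + 2.5)),
            method="bounded", options={"xatol": 1e-4},
        )
        loglam = float(r.x)
    pars = np.array([loglam, best_tau(loglam)] if q_re else [loglam])

    loglam = pars[0]
    logtau = pars[1] if q_re else 0.0
    s = penalty(loglam, logtau)
    a = ctc + s
    theta = np.linalg.solve(a, cty)
    f_mat = np.linalg.solve(a, ctc)  # influence of data on coefficients
    # the constrained basis still contains the unpenalized linear-in-year
    # direction, so a pure line scores EDF = 1 and penalty -> inf gives 1.
    edf_smooth = float(np.trace(f_mat[smooth_cols, smooth_cols]))
    fitted = c @ theta
    smooth_part = z @ theta[smooth_cols]
    rank_total = rank_s + q_re
    nbar = n - (m - rank_total)
    rss_pen = float((y - fitted) @ (y - fitted) + theta @ s @ theta)
    return GammFit(
        edf=edf_smooth,
        lambda_=float(np.exp(loglam)),
        year=year,
        smooth=smooth_part,
        fitted=fitted,
        resid=y - fitted,
        sigma2=rss_pen / nbar,
        reml=-neg_reml(pars),
    )


# ---------------------------------------------------------------------------
# full per-species protocol


def fit_species_trait(
    frame: pd.DataFrame,
    spec: ModelSpec,
    species: str = "",
    select_variance: bool = True,
    gamm: bool = True,
) -> tuple[TemporalEffect, LmmFit]:
    """Two-stage RAC protocol for one species and trait.

    First-pass model without RAC supplies residuals for
    :func:`compute_rac`; the model is then refit with the RAC covariate,
    optionally with AIC-based variance-structure selection, and screened
    for nonlinearity with the GAMM.  Returns the per-year effect and the
    final fit.
    """
    base = frame.drop(columns=["rac"], errors="ignore").reset_index(drop=True)
    first = fit_lmm(base, spec)
    rac = compute_rac(
        first.resid,
        base["latitude"].to_numpy(float),
        base["longitude"].to_numpy(float),
        cell=spec.rac_cell,
    )
    with_rac = base.assign(rac=rac.values)
    final_spec = spec
    if select_variance:
        final_spec, _ = select_variance_structure(with_rac, spec)
    fit = fit_lmm(with_rac, final_spec)
    edf = float("nan")
    if gamm:
        try:
            edf = fit_gamm(with_rac, final_spec).edf
        except ValueError as exc:
            warnings.warn(f"{species}: GAMM skipped ({exc})", stacklevel=2)
    trait = "wing_length" if spec.response == "wing_length" else "colour"
    return extract_effect(fit, trait, species=species, edf=edf), fit
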