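"""Abiotic cue summaries and mixed-model inference of phenological timing.

The question this module answers: which summary of a plot's soil
microclimate best predicts when activity starts, peaks and ends there?
Soil temperature is measured at two depths -- 1 cm (near-surface) and
25 cm (the shallowest depth at which diapausing ground-nesting bees sit)
-- together with volumetric soil-moisture content, repeatedly over the
February--May measurement campaign.  Per plot we reduce each channel to
seasonal min/max/mean, then regress phenophase dates on those summaries
with linear mixed models:

    date_ij = beta0 + beta_T * T_j + beta_M * M_j + beta_TM * T_j M_j
              + u_site(i) + eps_ij,   u ~ N(0, var_site), eps ~ N(0, var_resid)

i.e. a random intercept per site with a fixed mean.  Candidate models are
compared with AICc; the selection runs in two stages: first the seven
single-predictor models (six temperature summaries + mean moisture)
against the intercept-only null, then -- for the winning temperature
summary T* -- the nested sequence T*, T* + M, T* + M + T*:M.

Likelihoods, and hence AICc, come from full maximum likelihood (not
REML) so they are comparable across fixed-effect structures; a REML
switch is exposed for benchmarking against software whose mixed-model
default is REML.  The solver profiles the likelihood over the variance
ratio var_site/var_resid with closed-form GLS coefficients at each step.
Reported standard errors use the REML variance estimates with the
Kenward-Roger small-sample adjustment -- with a handful of sites and a
few dozen plots the naive ML covariance is noticeably anticonservative.
Fit quality is reported as marginal and conditional R2 (variance
partitioning: fixed effects alone vs fixed plus site effects).  Slopes
are estimated on the raw measurement scale (degrees C, VWC fraction);
interaction models are additionally summarised by the marginal slope at
the sample mean of the other covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABIOTIC_COLUMNS",
    "SUMMARY_COLUMNS",
    "TEMPERATURE_LABELS",
    "STAGE1_LABELS",
    "PREDICTOR_COLUMN",
    "ModelSpec",
    "ModelFit",
    "summarize_abiotic",
    "build_candidate_grid",
    "fit_lmm",
    "aicc",
    "rank_models",
    "r2_glmm",
    "marginal_slope",
    "run_cue_analysis",
    "DEFAULT_WINDOW",
]

logger = logging.getLogger(__name__)

#: raw abiotic record columns
ABIOTIC_COLUMNS = ("site", "plot", "doy", "temp_1cm", "temp_25cm", "moisture")

#: per-plot seasonal summary columns
SUMMARY_COLUMNS = ("t1_min", "t1_max", "t1_ave", "t25_min", "t25_max", "t25_ave", "m_ave")

#: Feb 1 .. May 31 in day-of-year (non-leap)
DEFAULT_WINDOW = (32, 151)

# model labels: depth-first temperature summaries plus mean moisture
TEMPERATURE_LABELS = ("T1_min", "T1_max", "T1_ave", "T25_min", "T25_max", "T25_ave")
STAGE1_LABELS = ("null", "M_ave") + TEMPERATURE_LABELS

PREDICTOR_COLUMN = {
    "M_ave": "m_ave",
    "T1_min": "t1_min",
    "T1_max": "t1_max",
    "T1_ave": "t1_ave",
    "T25_min": "t25_min",
    "T25_max": "t25_max",
    "T25_ave": "t25_ave",
}

PHENOPHASES = ("start", "peak", "end")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate timing model.

    ``temp`` names a summary column (t1_min .. t25_ave) or is None;
    ``moisture`` adds m_ave; ``interaction`` adds the T*M product and is
    only legal when both main effects are present.  The intercept is
    always included.
    """

    label: str
    temp: str | None = None
    moisture: bool = False
    interaction: bool = False

    def __post_init__(self) -> None:
        if self.interaction and not (self.temp and self.moisture):
            raise ValueError("interaction requires both temperature and moisture terms")

    @property
    def coef_names(self) -> tuple[str, ...]:
        names = ["intercept"]
        if self.temp:
            names.append(self.temp)
        if self.moisture:
            names.append("m_ave")
        if self.interaction:
            names.append(f"{self.temp}:m_ave")
        return tuple(names)

    @property
    def n_fixed(self) -> int:
        return len(self.coef_names)

    def design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        if self.temp:
            cols.append(data[self.temp].to_numpy(dtype=float))
        if self.moisture:
            cols.append(data["m_ave"].to_numpy(dtype=float))
        if self.interaction:
            cols.append(
                data[self.temp].to_numpy(dtype=float) * data["m_ave"].to_numpy(dtype=float)
            )
        return np.column_stack(cols)


@dataclass(frozen=True)
class ModelFit:
    """A fitted random-intercept timing model."""

    spec: ModelSpec
    response: str
    coef_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    var_site: float
    var_resid: float
    loglik: float
    n: int
    k: int
    aicc: float
    r2m: float
    r2c: float
    singular: bool = False
    reml: bool = False

    def coef(self, name: str) -> float:
        return float(self.beta[self.coef_names.index(name)])


def summarize_abiotic(
    records: pd.DataFrame, window: tuple[int, int] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Seasonal min/max/mean temperatures and mean moisture per plot.

    ``records`` carries one row per (site, plot, doy) measurement with
    columns temp_1cm, temp_25cm (degrees C) and moisture (VWC fraction).
    Only rows with doy inside the closed ``window`` (default Feb 1--May 31)
    contribute; a plot with fewer than two in-window records is an error.

    Returns a DataFrame with one row per plot: site, plot, t1_min, t1_max,
    t1_ave, t25_min, t25_max, t25_ave, m_ave.
    """
    missing = set(ABIOTIC_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"abiotic table missing columns: {sorted(missing)}")
    vals = records[["temp_1cm", "temp_25cm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite temperature in abiotic records")
    m = records["moisture"].to_numpy(dtype=float)
    if np.any(m < 0) or np.any(m > 1) or not np.all(np.isfinite(m)):
        raise ValueError("moisture outside [0, 1]")

    lo, hi = window
    inwin = records[(records["doy"] >= lo) & (records["doy"] <= hi)]
    rows = []
    for (site, plot), g in records.groupby(["site", "plot"], sort=True):
        gw = inwin[(inwin["site"] == site) & (inwin["plot"] == plot)]
        if len(gw) < 2:
            raise ValueError(
                f"plot {plot} at site {site}: {len(gw)} abiotic records in window "
                f"[{lo}, {hi}], need >=2"
            )
        t1 = gw["temp_1cm"].to_numpy(dtype=float)
        t25 = gw["temp_25cm"].to_numpy(dtype=float)
        mo = gw["moisture"].to_numpy(dtype=float)
        rows.append(
            {
                "site": site,
                "plot": plot,
                "t1_min": t1.min(),
                "t1_max": t1.max(),
                "t1_ave": t1.mean(),
                "t25_min": t25.min(),
                "t25_max": t25.max(),
                "t25_ave": t25.mean(),
                "m_ave": mo.mean(),
            }
        )
    return pd.DataFrame(rows, columns=["site", "plot", *SUMMARY_COLUMNS])


def build_candidate_grid(stage: int = 1, best_temp: str | None = None) -> list[ModelSpec]:
    """Candidate model sets for the two selection stages.

    Stage 1: null, mean moisture, and the six temperature summaries as
    single predictors (8 models).  Stage 2: given the winning temperature
    summary, the nested sequence T*, T* + M, T* + M + T*:M (3 models).
    """
    if stage == 1:
        specs = [ModelSpec("null"), ModelSpec("M_ave", moisture=True)]
        for label in TEMPERATURE_LABELS:
            specs.append(ModelSpec(label, temp=PREDICTOR_COLUMN[label]))
        return specs
    if stage == 2:
        if best_temp is None:
            raise ValueError("stage 2 requires the winning temperature summary")
        col = PREDICTOR_COLUMN.get(best_temp, best_temp)
        if col not in SUMMARY_COLUMNS:
            raise ValueError(f"unknown temperature summary {best_temp!r}")
        label = next(k for k, v in PREDICTOR_COLUMN.items() if v == col)
        return [
            ModelSpec(label, temp=col),
            ModelSpec(f"{label}+M", temp=col, moisture=True),
            ModelSpec(f"{label}+M+{label}:M", temp=col, moisture=True, interaction=True),
        ]
    raise ValueError("stage must be 1 or 2")


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _variance_r2(
    X: np.ndarray, beta: np.ndarray, var_site: float, var_resid: float
) -> tuple[float, float]:
    """Variance-partitioning R2 for a random-intercept model."""
    eta = X @ beta
    var_fixed = float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0
    denom = var_fixed + var_site + var_resid
    if denom <= 0:
        raise ValueError("degenerate model: total variance is zero")
    r2m = var_fixed / denom
    r2c = (var_fixed + var_site) / denom
    return r2m, r2c


def _ols_ml(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Closed-form ML linear fit: beta, se, sigma2_ml, loglik.

    The likelihood uses the ML residual variance (RSS/n); the standard
    errors use the unbiased RSS/(n - p) as usual.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * rss / max(n - p, 1))
    return beta, se, sigma2, float(loglik)


# --- random-intercept solver: profile likelihood over lambda = var_site/var_resid


def _profile_eval(
    lam: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray, reml: bool
) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood at variance ratio ``lam``; returns
    (loglik, beta_gls, sigma2_hat)."""
    n, p = X.shape
    V = np.eye(n) + lam * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    C = X.T @ Vinv @ X
    beta = np.linalg.solve(C, X.T @ Vinv @ y)
    r = y - X @ beta
    q = float(r @ Vinv @ r)
    sign, logdet_v = np.linalg.slogdet(V)
    if reml:
        dof = n - p
        sigma2 = q / dof
        sign_c, logdet_c = np.linalg.slogdet(C)
        # floor keeps a perfectly-fitting (degenerate) model finite-loggable
        ll = -0.5 * (dof * (np.log(2.0 * np.pi * max(sigma2, 1e-300)) + 1.0)
                     + logdet_v + logdet_c)
    else:
        sigma2 = q / n
        ll = -0.5 * (n * (np.log(2.0 * np.pi * max(sigma2, 1e-300)) + 1.0) + logdet_v)
    return float(ll), beta, sigma2


def _profile_maximize(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, reml: bool, tol: float = 1e-8
) -> tuple[float, float, np.ndarray, float]:
    """Maximize the profile likelihood over lam >= 0.

    Coarse log-spaced grid (lam = 0 included) followed by golden-section
    refinement to ``tol`` on the log-likelihood.  Returns (lam, loglik,
    beta, sigma2).
    """
    grid = np.concatenate([[0.0], np.logspace(-4.0, 3.0, 43)])
    lls = np.array([_profile_eval(l, y, X, Z, reml)[0] for l in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if i == len(grid) - 1:
        hi = grid[-1] * 10.0
    # golden-section on [lo, hi]
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc = _profile_eval(c, y, X, Z, reml)[0]
    fd = _profile_eval(d, y, X, Z, reml)[0]
    for _ in range(200):
        if abs(fc - fd) < tol and abs(b - a) < 1e-10 + 1e-6 * max(1.0, a):
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = _profile_eval(c, y, X, Z, reml)[0]
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = _profile_eval(d, y, X, Z, reml)[0]
    lam = c if fc >= fd else d
    cand = [(lls[0], 0.0)]  # always reconsider the boundary
    ll_lam, beta, sigma2 = _profile_eval(lam, y, X, Z, reml)
    cand.append((ll_lam, lam))
    ll_best, lam_best = max(cand)
    if lam_best != lam:
        ll_best, beta, sigma2 = _profile_eval(lam_best, y, X, Z, reml)
    return float(lam_best), float(ll_best), beta, float(sigma2)


def _kr_covariance(
    X: np.ndarray, Z: np.ndarray, sigma2: float, tau2: float
) -> np.ndarray:
    """Kenward-Roger adjusted covariance of the GLS fixed effects.

    V = sigma2 * I + tau2 * Z Z' is linear in theta = (sigma2, tau2), so
    the second-derivative term of the adjustment vanishes.  W is the
    inverse expected REML information of theta.
    """
    n = X.shape[0]
    G = [np.eye(n), Z @ Z.T]
    V = sigma2 * G[0] + tau2 * G[1]
    Vinv = np.linalg.inv(V)
    phi = np.linalg.inv(X.T @ Vinv @ X)
    Pstar = Vinv - Vinv @ X @ phi @ X.T @ Vinv
    info = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            info[i, j] = 0.5 * np.trace(Pstar @ G[i] @ Pstar @ G[j])
    W = np.linalg.pinv(info)
    P = [-(X.T @ Vinv @ Gi @ Vinv @ X) for Gi in G]
    Q = [[X.T @ Vinv @ G[i] @ Vinv @ G[j] @ Vinv @ X for j in range(2)] for i in range(2)]
    mid = np.zeros_like(phi)
    for i in range(2):
        for j in range(2):
            mid += W[i, j] * (Q[i][j] - P[i] @ phi @ P[j])
    return phi + 2.0 * phi @ mid @ phi


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    response: str,
    reml: bool = False,
    constrain_site_variance: bool = False,
) -> ModelFit:
    """Fit one candidate timing model with a random intercept per site.

    ``data`` carries one row per plot: the response column (a phenophase
    DOY), the abiotic summary columns, and ``site``.  The likelihood is
    profiled over the variance ratio var_site/var_resid with closed-form
    GLS coefficients at each step (tolerance 1e-8 on the log-likelihood).
    Maximum likelihood is the default so AICc is comparable across
    fixed-effect structures; pass ``reml=True`` only for benchmarking.
    Standard errors always come from the REML variance estimates with the
    Kenward-Roger small-sample adjustment, the usual remedy when the
    number of sites is small.  With a single site, or with
    ``constrain_site_variance=True``, the site variance is fixed at zero
    and the fit reduces to the closed-form ML linear regression.

    A site variance estimated at the zero boundary is reported as
    var_site=0 with ``singular=True``, not as an error.
    """
    needed = [response]
    if spec.temp:
        needed.append(spec.temp)
    if spec.moisture:
        needed.append("m_ave")
    sub = data.dropna(subset=needed)
    if len(sub) < len(data):
        logger.warning(
            "%s ~ %s: dropped %d plot(s) with missing values",
            response,
            spec.label,
            len(data) - len(sub),
        )
    y = sub[response].to_numpy(dtype=float)
    X = spec.design_matrix(sub)
    n, p = X.shape
    k = p + 2  # fixed coefficients + site and residual variances
    if n <= p + 2:
        raise ValueError(f"{spec.label}: only {n} plots for {p} fixed coefficients")
    sites = sub["site"].to_numpy()
    n_sites = len(np.unique(sites))

    singular = False
    if constrain_site_variance or n_sites == 1:
        beta, se, sigma2, loglik = _ols_ml(y, X)
        var_site, var_resid = 0.0, sigma2
        singular = True
    else:
        # site indicator matrix for the random intercept
        _, site_idx = np.unique(sites, return_inverse=True)
        Z = np.zeros((n, n_sites))
        Z[np.arange(n), site_idx] = 1.0
        try:
            lam, loglik, beta, var_resid = _profile_maximize(y, X, Z, reml=reml)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"{spec.label} ~ {response}: mixed-model fit failed "
                f"(n={n}, sites={n_sites}): {err}"
            ) from err
        var_site = lam * var_resid
        if var_site < 1e-8 * max(var_resid, 1.0):
            var_site = 0.0
            singular = True
        # SEs: REML variance estimates + Kenward-Roger adjustment
        lam_r, _, _, sigma2_r = _profile_maximize(y, X, Z, reml=True)
        cov_adj = _kr_covariance(X, Z, sigma2_r, lam_r * sigma2_r)
        se = np.sqrt(np.clip(np.diag(cov_adj), 0.0, None))

    r2m, r2c = _variance_r2(X, beta, var_site, var_resid)
    return ModelFit(
        spec=spec,
        response=response,
        coef_names=spec.coef_names,
        beta=beta,
        se=se,
        var_site=var_site,
        var_resid=var_resid,
        loglik=loglik,
        n=n,
        k=k,
        aicc=aicc(loglik, k, n),
        r2m=r2m,
        r2c=r2c,
        singular=singular,
        reml=reml,
    )


def r2_glmm(fit: ModelFit, data: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R2 by variance partitioning.

    r2m = var_fixed / (var_fixed + var_site + var_resid);
    r2c = (var_fixed + var_site) / (same denominator), where var_fixed is
    the sample variance of the fixed-effect linear predictor across plots.
    """
    needed = [fit.response]
    if fit.spec.temp:
        needed.append(fit.spec.temp)
    if fit.spec.moisture:
        needed.append("m_ave")
    sub = data.dropna(subset=[c for c in needed if c in data.columns])
    X = fit.spec.design_matrix(sub)
    return _variance_r2(X, fit.beta, fit.var_site, fit.var_resid)


def rank_models(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Rank fits by AICc; delta_aicc relative to the best; co_best flags
    every model within 1 AICc unit of the winner."""
    if not fits:
        raise ValueError("rank_models: no fits")
    responses = {f.response for f in fits}
    if len(responses) > 1:
        raise ValueError(f"rank_models: mixed responses {sorted(responses)}")
    rows = [
        {
            "model": f.spec.label,
            "aicc": f.aicc,
            "loglik": f.loglik,
            "k": f.k,
            "n": f.n,
            "r2m": f.r2m,
            "r2c": f.r2c,
            "singular": f.singular,
        }
        for f in fits
    ]
    tab = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["co_best"] = tab["delta_aicc"] < 1.0
    return tab


def marginal_slope(fit: ModelFit, data: pd.DataFrame) -> dict[str, float]:
    """Slopes of an interaction model at the sample mean of the other covariate.

    For the model date ~ T + M + T:M the temperature marginal slope is
    beta_T + beta_TM * mean(M) (days per degree C at average moisture), and
    symmetrically for moisture at the mean temperature.
    """
    if not fit.spec.interaction:
        if fit.spec.temp and fit.spec.moisture:
            return {
                "temperature": fit.coef(fit.spec.temp),
                "moisture": fit.coef("m_ave"),
            }
        raise ValueError("marginal_slope requires a model with T and M terms")
    sub = data.dropna(subset=[c for c in (fit.response, "m_ave", fit.spec.temp) if c])
    mean_m = float(sub["m_ave"].mean())
    mean_t = float(sub[fit.spec.temp].mean())
    b_tm = fit.coef(f"{fit.spec.temp}:m_ave")
    return {
        "temperature": fit.coef(fit.spec.temp) + b_tm * mean_m,
        "moisture": fit.coef("m_ave") + b_tm * mean_t,
    }


def _fit_rows(
    fit: ModelFit, role: str, phenophase: str, stage: int, delta: float
) -> list[dict]:
    rows = []
    for name, est, se in zip(fit.coef_names, fit.beta, fit.se):
        rows.append(
            {
                "role": role,
                "phenophase": phenophase,
                "stage": stage,
                "model": fit.spec.label,
                "terms": "+".join(fit.coef_names[1:]) or "1",
                "aicc": fit.aicc,
                "delta_aicc": delta,
                "r2m": fit.r2m,
                "r2c": fit.r2c,
                "coef_name": name,
                "estimate": float(est),
                "se": float(se),
                "var_site": fit.var_site,
                "var_resid": fit.var_resid,
                "n": fit.n,
                "k": fit.k,
                "singular": fit.singular,
            }
        )
    return rows


def run_cue_analysis(
    phenology: pd.DataFrame,
    abiotic_summaries: pd.DataFrame,
    reml: bool = False,
    roles: Iterable[str] = ("bee", "flower"),
    phenophases: Iterable[str] = PHENOPHASES,
) -> dict[str, pd.DataFrame]:
    """Two-stage AICc selection of abiotic timing cues for every role and phenophase.

    ``phenology`` is the per-plot table from the metrics stage (columns
    site, plot, role, start_doy, peak_doy, end_doy, ...);
    ``abiotic_summaries`` comes from :func:`summarize_abiotic`.  Plots with
    no abiotic summary are dropped with a warning, never imputed.

    Returns ``{"models": tidy per-coefficient table, "marginal_slopes":
    per-interaction-model slopes at covariate means}``.
    """
    model_rows: list[dict] = []
    slope_rows: list[dict] = []
    for role in roles:
        pheno_role = phenology[phenology["role"] == role]
        if pheno_role.empty:
            logger.warning("no %s plots in phenology table; skipped", role)
            continue
        data = pheno_role.merge(abiotic_summaries, on=["site", "plot"], how="left")
        n_missing = data[list(SUMMARY_COLUMNS)].isna().any(axis=1).sum()
        if n_missing:
            logger.warning(
                "%s: %d plot(s) lack abiotic summaries; excluded from model fits",
                role,
                n_missing,
            )
            data = data.dropna(subset=list(SUMMARY_COLUMNS))
        for phase in phenophases:
            response = f"{phase}_doy"
            stage1 = [
                fit_lmm(s, data, response, reml=reml) for s in build_candidate_grid(1)
            ]
            ranking = rank_models(stage1)
            by_label = {f.spec.label: f for f in stage1}
            for _, row in ranking.iterrows():
                model_rows.extend(
                    _fit_rows(by_label[row["model"]], role, phase, 1, row["delta_aicc"])
                )
            # best temperature summary carried into stage 2 (ties resolved
            # by lower AICc; co-best set recorded in stage-1 delta column)
            temp_rank = ranking[ranking["model"].isin(TEMPERATURE_LABELS)]
            best_temp_label = temp_rank["model"].iloc[0]
            stage2 = [
                fit_lmm(s, data, response, reml=reml)
                for s in build_candidate_grid(2, best_temp=best_temp_label)
            ]
            rank2 = rank_models(stage2)
            by_label2 = {f.spec.label: f for f in stage2}
            for _, row in rank2.iterrows():
                model_rows.extend(
                    _fit_rows(by_label2[row["model"]], role, phase, 2, row["delta_aicc"])
                )
            inter_fit = stage2[-1]
            slopes = marginal_slope(inter_fit, data)
            slope_rows.append(
                {
                    "role": role,
                    "phenophase": phase,
                    "model": inter_fit.spec.label,
                    "temperature_summary": best_temp_label,
                    "temp_slope_days_per_degC": slopes["temperature"],
                    "moisture_slope_days_per_vwc": slopes["moisture"],
                }
            )
    models = pd.DataFrame(model_rows)
    slopes_tab = pd.DataFrame(
        slope_rows,
        columns=[
            "role",
            "phenophase",
            "model",
            "temperature_summary",
            "temp_slope_days_per_degC",
            "moisture_slope_days_per_vwc",
        ],
    )
    return {"models": models, "marginal_slopes": slopes_tab}
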