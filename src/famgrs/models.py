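"""Family-aware rate models for risk-allele burden.

The response is a per-individual risk-allele count with an offset of
log(2 * n_nonmissing), so every model below describes the *rate* of risk
alleles per observed allele slot and the familial-longevity coefficient
beta has the interpretation exp(beta) = ratio of expected risk-allele rates
between longevity members and married-in controls.

Four model families are provided:

* ``fit_poisson_glmm`` — Poisson log-link mixed model with a Gaussian random
  intercept per family, fit by maximum likelihood with adaptive
  Gauss-Hermite quadrature (the primary model; inference by LRT).
* ``fit_poisson_glm`` — ordinary Poisson GLM ignoring family correlation.
* ``fit_poisson_gee`` — marginal Poisson model with exchangeable working
  correlation and a robust sandwich covariance.
* ``fit_lmm_kinship`` — linear mixed model on the rate count/(2 n) with
  covariance sigma_g^2 * 2*Phi + sigma_e^2 * I (Phi the kinship matrix),
  fit by spectral-decomposition REML.

Because the random intercept is constant within a family, the Poisson GLMM
likelihood depends on the data only through three per-family scalars
(sum of counts, sum of exp(fixed linear predictor), sum of y*eta minus
log-factorials), which makes the quadrature exact-in-structure and fast
even for thousands of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FitResult",
    "prepare_model_frame",
    "fit_poisson_glmm",
    "fit_poisson_glm",
    "fit_poisson_gee",
    "fit_lmm_kinship",
    "run_analysis_suite",
    "rate_ratio_report",
]

LONGEVITY = "longevity_member"


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: model family, adjustment covariates, grouping, offset."""

    model: str = "poisson_glmm"
    covariates: tuple[str, ...] = ()
    grouping: str = "family_id"
    offset_column: str = "offset"
    alpha: float = 0.05
    n_quad: int = 9  # adaptive Gauss-Hermite nodes (1 = Laplace)

    def __post_init__(self) -> None:
        allowed = {"poisson_glmm", "poisson_glm", "poisson_gee", "lmm_kinship"}
        if self.model not in allowed:
            raise ValueError(f"model must be one of {sorted(allowed)}")
        bad = set(self.covariates) - {"sex", "generation"}
        if bad:
            raise ValueError(f"unsupported covariates: {sorted(bad)}")


@dataclass
class FitResult:
    """Coefficients and inference for one model fit.

    ``beta`` is on the log-rate scale for the Poisson models and on the rate
    scale for the kinship LMM.  ``p_lrt`` is the likelihood-ratio p-value for
    the longevity coefficient (NaN where no likelihood exists, i.e. GEE);
    ``p_wald`` the corresponding Wald p-value.  ``rate_ratio`` is
    exp(beta_longevity) for Poisson models.
    """

    model: str
    beta: dict[str, float]
    se: dict[str, float]
    z_stat: dict[str, float]
    p_lrt: float
    p_wald: float
    rate_ratio: float
    converged: bool
    n_obs: int
    n_families: int
    loglik: float = np.nan
    loglik_reduced: float = np.nan
    extra: dict = field(default_factory=dict)

    @property
    def lrt_stat(self) -> float:
        return 2.0 * (self.loglik - self.loglik_reduced)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def prepare_model_frame(grs_table: pd.DataFrame, individuals: pd.DataFrame) -> pd.DataFrame:
    """Join GRS records to pedigree roles, keeping modelling columns only."""
    cols = ["individual_id", "family_id", "sex", "generation", LONGEVITY]
    joined = grs_table.merge(individuals[cols], on="individual_id", how="inner", validate="one_to_one")
    if len(joined) != len(grs_table):
        missing = set(grs_table["individual_id"]) - set(individuals["individual_id"])
        raise ValueError(f"GRS records without pedigree entry: {sorted(missing)[:5]}")
    return joined


def _design(data: pd.DataFrame, covariates: Sequence[str], include_longevity: bool = True):
    """Intercept + longevity indicator + requested adjustment covariates."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    if include_longevity:
        cols[LONGEVITY] = data[LONGEVITY].to_numpy(dtype=float)
    for cov in covariates:
        if cov == "sex":
            cols["sex_M"] = (data["sex"] == "M").to_numpy(dtype=float)
        elif cov == "generation":
            cols["generation2"] = (data["generation"] == 2).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an aliased column for a useful message
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"singular design: column {names[j]!r} is aliased")
    return X, names


def _check_counts(y: np.ndarray) -> None:
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")


# ---------------------------------------------------------------------------
# Poisson GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


class _GlmmWork:
    """Per-dataset sufficient statistics for the random-intercept Poisson GLMM."""

    def __init__(self, y, X, offset, fam_codes, n_fam, n_quad):
        self.y = y
        self.X = X
        self.offset = offset
        self.fam = fam_codes
        self.n_fam = n_fam
        self.S = np.bincount(fam_codes, weights=y, minlength=n_fam)  # sum of counts
        self.lgam = np.bincount(fam_codes, weights=gammaln(y + 1.0), minlength=n_fam)
        z, w = hermgauss(n_quad)
        self.z = z
        self.logw = np.log(w)

    def _family_terms(self, beta):
        eta = self.X @ beta + self.offset
        with np.errstate(over="ignore"):
            B = np.bincount(self.fam, weights=np.exp(eta), minlength=self.n_fam)
        C = np.bincount(self.fam, weights=self.y * eta, minlength=self.n_fam) - self.lgam
        return B, C

    def loglik(self, beta, sigma):
        """Marginal log-likelihood, integrating the family intercepts."""
        B, C = self._family_terms(beta)
        if not np.all(np.isfinite(B)):  # optimizer excursion; reject softly
            return -1e300
        if sigma < 1e-8:
            return float(np.sum(C - B))
        inv_var = 1.0 / (sigma * sigma)
        # mode of h(u) = C + S*u - B*e^u - u^2/(2 sigma^2), per family (Newton)
        u = np.zeros(self.n_fam)
        for _ in range(60):
            Beu = B * np.exp(u)
            grad = self.S - Beu - u * inv_var
            hess = Beu + inv_var
            step = grad / hess
            np.clip(step, -2.0, 2.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-11:
                break
        Beu = B * np.exp(u)
        tau = 1.0 / np.sqrt(Beu + inv_var)
        # adaptive nodes u_k = u_hat + sqrt(2) tau z_k
        uk = u[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]
        h = (
            C[:, None]
            + self.S[:, None] * uk
            - B[:, None] * np.exp(uk)
            - 0.5 * uk * uk * inv_var
        )
        log_terms = self.logw[None, :] + self.z[None, :] ** 2 + h
        per_fam = (
            logsumexp(log_terms, axis=1)
            + 0.5 * np.log(2.0)
            + np.log(tau)
            - np.log(sigma)
            - 0.5 * np.log(2.0 * np.pi)
        )
        return float(np.sum(per_fam))


def _maximize_glmm(
    work: _GlmmWork, p: int, start: np.ndarray | None = None, fix_sigma: float | None = None
):
    """Maximize the marginal likelihood over (beta, sigma >= 0)."""

    if fix_sigma is not None:

        def neg_b(beta):
            return -work.loglik(beta, fix_sigma)

        glm = sm.GLM(work.y, work.X, family=sm.families.Poisson(), offset=work.offset)
        res = optimize.minimize(
            neg_b, glm.fit().params, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-10},
        )
        res.x = np.concatenate([res.x, [fix_sigma]])
        return res

    def neg(params):
        return -work.loglik(params[:p], params[p])

    if start is None:
        glm = sm.GLM(work.y, work.X, family=sm.families.Poisson(), offset=work.offset)
        beta0 = glm.fit().params
        start = np.concatenate([beta0, [0.1]])
    bounds = [(None, None)] * p + [(1e-9, 20.0)]
    res = optimize.minimize(
        neg, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success:
        # line searches on finite-difference gradients occasionally abort near
        # the sigma ~ 0 boundary; polish with a derivative-free pass
        res2 = optimize.minimize(
            neg, res.x, method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res2.fun <= res.fun:
            res = res2
    return res


def _numeric_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H, f0


def fit_poisson_glmm(
    data: pd.DataFrame, spec: ModelSpec | None = None, fix_sigma: float | None = None
) -> FitResult:
    """Poisson random-intercept model by adaptive Gauss-Hermite ML.

    Maximizes the marginal likelihood over the fixed effects and the
    random-intercept SD (bounded at zero), with the default 9 quadrature
    nodes; standard errors come from the observed information (numerical
    Hessian) and the longevity coefficient is tested both by LRT against the
    model without it (chi-square, 1 df) and by Wald.

    ``fix_sigma`` pins the random-intercept SD instead of estimating it
    (``fix_sigma=0`` reduces the model to the plain Poisson GLM).
    """
    spec = spec or ModelSpec()
    y = data["count"].to_numpy(dtype=float)
    _check_counts(y)
    offset = data[spec.offset_column].to_numpy(dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    fam_codes, fams = pd.factorize(data[spec.grouping])
    if len(fams) < 2:
        raise ValueError("need at least 2 families")

    X, names = _design(data, spec.covariates, include_longevity=True)
    p = X.shape[1]
    work = _GlmmWork(y, X, offset, fam_codes, len(fams), spec.n_quad)
    res = _maximize_glmm(work, p, fix_sigma=fix_sigma)
    beta_hat, sigma_hat = res.x[:p], res.x[p]
    ll_full = -res.fun

    # reduced model (no longevity indicator) for the LRT
    Xr, _ = _design(data, spec.covariates, include_longevity=False)
    work_r = _GlmmWork(y, Xr, offset, fam_codes, len(fams), spec.n_quad)
    res_r = _maximize_glmm(work_r, Xr.shape[1], fix_sigma=fix_sigma)
    ll_red = -res_r.fun
    lrt = max(0.0, 2.0 * (ll_full - ll_red))
    p_lrt = float(stats.chi2.sf(lrt, df=1))

    # observed-information SEs
    if fix_sigma is not None:
        # sigma pinned: information over beta only
        H, _ = _numeric_hessian(lambda par: -work.loglik(par, fix_sigma), res.x[:p])
    else:
        H, _ = _numeric_hessian(lambda par: -work.loglik(par[:p], max(par[p], 1e-9)), res.x)
    se = np.full(p, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        try:
            cov_b = np.linalg.inv(H[:p, :p])
            d = np.diag(cov_b)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

    beta = dict(zip(names, beta_hat))
    se_map = dict(zip(names, se))
    z = {k: beta[k] / se_map[k] if se_map[k] and np.isfinite(se_map[k]) else np.nan for k in names}
    zl = z.get(LONGEVITY, np.nan)
    return FitResult(
        model="poisson_glmm",
        beta=beta,
        se=se_map,
        z_stat=z,
        p_lrt=p_lrt,
        p_wald=float(2 * stats.norm.sf(abs(zl))) if np.isfinite(zl) else np.nan,
        rate_ratio=float(np.exp(beta.get(LONGEVITY, np.nan))),
        converged=bool(res.success and res_r.success),
        n_obs=len(y),
        n_families=len(fams),
        loglik=ll_full,
        loglik_reduced=ll_red,
        extra={"sigma_u": float(sigma_hat), "n_quad": spec.n_quad},
    )


def glmm_loglik(
    data: pd.DataFrame,
    beta: Sequence[float],
    sigma: float,
    spec: ModelSpec | None = None,
) -> float:
    """Marginal GLMM log-likelihood at given parameters (for diagnostics)."""
    spec = spec or ModelSpec()
    y = data["count"].to_numpy(dtype=float)
    offset = data[spec.offset_column].to_numpy(dtype=float)
    fam_codes, fams = pd.factorize(data[spec.grouping])
    X, _ = _design(data, spec.covariates, include_longevity=True)
    work = _GlmmWork(y, X, offset, fam_codes, len(fams), spec.n_quad)
    return work.loglik(np.asarray(beta, dtype=float), float(sigma))


# ---------------------------------------------------------------------------
# Poisson GLM and GEE (statsmodels)
# ---------------------------------------------------------------------------


def fit_poisson_glm(data: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Ordinary Poisson GLM with offset, ignoring within-family correlation."""
    spec = spec or ModelSpec(model="poisson_glm")
    y = data["count"].to_numpy(dtype=float)
    _check_counts(y)
    offset = data[spec.offset_column].to_numpy(dtype=float)
    X, names = _design(data, spec.covariates, include_longevity=True)
    fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    Xr, _ = _design(data, spec.covariates, include_longevity=False)
    fit_r = sm.GLM(y, Xr, family=sm.families.Poisson(), offset=offset).fit()
    lrt = max(0.0, 2.0 * (fit.llf - fit_r.llf))
    beta = dict(zip(names, fit.params))
    se = dict(zip(names, fit.bse))
    z = {k: beta[k] / se[k] for k in names}
    return FitResult(
        model="poisson_glm",
        beta=beta,
        se=se,
        z_stat=z,
        p_lrt=float(stats.chi2.sf(lrt, df=1)),
        p_wald=float(2 * stats.norm.sf(abs(z[LONGEVITY]))),
        rate_ratio=float(np.exp(beta[LONGEVITY])),
        converged=bool(fit.converged),
        n_obs=len(y),
        n_families=int(data[spec.grouping].nunique()),
        loglik=float(fit.llf),
        loglik_reduced=float(fit_r.llf),
    )


def fit_poisson_gee(data: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Marginal Poisson model: exchangeable working correlation, sandwich SEs."""
    spec = spec or ModelSpec(model="poisson_gee")
    y = data["count"].to_numpy(dtype=float)
    _check_counts(y)
    offset = data[spec.offset_column].to_numpy(dtype=float)
    groups = data[spec.grouping].to_numpy()
    if len(np.unique(groups)) == 0:
        raise ValueError("no families in data")
    X, names = _design(data, spec.covariates, include_longevity=True)
    model = sm.GEE(
        y,
        X,
        groups=groups,
        family=sm.families.Poisson(),
        cov_struct=sm.cov_struct.Exchangeable(),
        offset=offset,
    )
    fit = model.fit()  # robust (sandwich) covariance is the default
    beta = dict(zip(names, fit.params))
    se = dict(zip(names, fit.bse))
    z = {k: beta[k] / se[k] for k in names}
    return FitResult(
        model="poisson_gee",
        beta=beta,
        se=se,
        z_stat=z,
        p_lrt=np.nan,
        p_wald=float(2 * stats.norm.sf(abs(z[LONGEVITY]))),
        rate_ratio=float(np.exp(beta[LONGEVITY])),
        converged=bool(getattr(fit, "converged", True)),
        n_obs=len(y),
        n_families=int(len(np.unique(groups))),
        extra={"working_dep": float(model.cov_struct.dep_params)},
    )


# ---------------------------------------------------------------------------
# kinship LMM (spectral REML)
# ---------------------------------------------------------------------------


def fit_lmm_kinship(
    data: pd.DataFrame,
    kinship: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> FitResult:
    """Linear mixed model for the risk-allele rate with kinship covariance.

    Models count/(2 * n_nonmissing) as approximately Gaussian with
    Var = sigma_g^2 * 2*Phi + sigma_e^2 * I.  The additive relationship
    matrix 2*Phi is eigendecomposed once; REML then profiles to a
    one-dimensional search over the variance ratio.  Inference for the
    longevity coefficient is Wald.
    """
    spec = spec or ModelSpec(model="lmm_kinship")
    ids = list(data["individual_id"])
    if not set(ids) <= set(kinship.index):
        missing = sorted(set(ids) - set(kinship.index))
        raise ValueError(f"individuals missing from kinship matrix: {missing[:5]}")
    y = (data["count"] / (2.0 * data["n_nonmissing"])).to_numpy(dtype=float)
    X, names = _design(data, spec.covariates, include_longevity=True)
    n, p = X.shape

    A = 2.0 * kinship.loc[ids, ids].to_numpy()
    svals, U = np.linalg.eigh(A)
    svals = np.clip(svals, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    def reml_neg(log_delta: float):
        delta = np.exp(log_delta)
        d = svals + delta
        Xw = Xs / d[:, None]
        XtX = Xs.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ ys)
        resid = ys - Xs @ beta
        rss = float(resid @ (resid / d))
        sg2 = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        ll = -0.5 * ((n - p) * np.log(sg2) + np.sum(np.log(d)) + logdet_xtx + (n - p))
        return -ll, beta, sg2, XtX

    grid = np.linspace(-10.0, 10.0, 41)
    vals = [reml_neg(g)[0] for g in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    opt = optimize.minimize_scalar(
        lambda g: reml_neg(g)[0], bounds=(lo, hi), method="bounded"
    )
    neg_ll, beta_hat, sg2, XtX = reml_neg(opt.x)
    delta = float(np.exp(opt.x))
    cov_beta = sg2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))

    beta = dict(zip(names, beta_hat))
    se_map = dict(zip(names, se))
    z = {kk: beta[kk] / se_map[kk] for kk in names}
    return FitResult(
        model="lmm_kinship",
        beta=beta,
        se=se_map,
        z_stat=z,
        p_lrt=np.nan,
        p_wald=float(2 * stats.norm.sf(abs(z[LONGEVITY]))),
        rate_ratio=np.nan,  # beta is on the rate (not log) scale here
        converged=bool(opt.success),
        n_obs=n,
        n_families=int(data[spec.grouping].nunique()),
        loglik=-neg_ll,
        extra={"sigma_g2": float(sg2), "sigma_e2": float(sg2 * delta), "delta": delta},
    )


# ---------------------------------------------------------------------------
# analysis suite and reporting
# ---------------------------------------------------------------------------

_FITTERS = {
    "poisson_glmm": fit_poisson_glmm,
    "poisson_glm": fit_poisson_glm,
    "poisson_gee": fit_poisson_gee,
}

STRATA = ("generation1", "generation2", "both")


def _stratum_frame(data: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "generation1":
        return data[data["generation"] == 1]
    if stratum == "generation2":
        return data[data["generation"] == 2]
    if stratum == "both":
        return data
    raise ValueError(f"unknown stratum {stratum!r}")


def run_analysis_suite(
    individuals: pd.DataFrame,
    grs_tables: dict[str, pd.DataFrame],
    models: Sequence[str] = ("poisson_glmm",),
    strata: Sequence[str] = STRATA,
    kinship: pd.DataFrame | None = None,
    n_quad: int = 9,
) -> pd.DataFrame:
    """Crude and sex-adjusted fits per disease group, stratum and model.

    Generation-specific strata adjust for sex; the pooled stratum adjusts
    for sex and generation (age is never included: it is collinear with the
    longevity indicator by design of the study).  Output is one row per fit
    in a publication-style layout.
    """
    rows = []
    for group, grs in grs_tables.items():
        data_all = prepare_model_frame(grs, individuals)
        for stratum in strata:
            data = _stratum_frame(data_all, stratum)
            if len(data) == 0:
                import warnings

                warnings.warn(f"empty stratum {stratum} for {group}; skipped")
                continue
            adj: tuple[str, ...] = ("sex", "generation") if stratum == "both" else ("sex",)
            for model in models:
                for covs in ((), adj):
                    spec = ModelSpec(model=model, covariates=covs, n_quad=n_quad)
                    if model == "lmm_kinship":
                        if kinship is None:
                            raise ValueError("lmm_kinship requested but no kinship matrix given")
                        fit = fit_lmm_kinship(data, kinship, spec)
                    else:
                        fit = _FITTERS[model](data, spec)
                    b = fit.beta.get(LONGEVITY, np.nan)
                    rows.append(
                        {
                            "data_stratum": stratum,
                            "disease_group": group,
                            "model": model,
                            "covariates": "+".join(covs) if covs else "crude",
                            "beta": b,
                            "se": fit.se.get(LONGEVITY, np.nan),
                            "z": fit.z_stat.get(LONGEVITY, np.nan),
                            "p_lrt": fit.p_lrt,
                            "p_wald": fit.p_wald,
                            "rate_ratio": fit.rate_ratio,
                            "n": fit.n_obs,
                            "n_families": fit.n_families,
                            "converged": fit.converged,
                        }
                    )
    return pd.DataFrame(rows)


def rate_ratio_report(beta: float) -> tuple[float, float]:
    """Translate a log-scale coefficient into (rate ratio, percent fewer).

    The rate ratio is exp(beta); ``percent_fewer`` is 100*(1 - exp(beta))
    rounded to two decimals for display, i.e. the percentage by which
    longevity members' expected risk-allele count falls short of controls'.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    rr = float(np.exp(beta))
    return rr, round(100.0 * (1.0 - rr), 2)
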