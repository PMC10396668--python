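"""Model fitting and selection: count GLMs, backward stepwise elimination,
likelihood-ratio tests, dispersion and collinearity diagnostics, NB mixed
models, and permutation-tested linear regressions.

The modelling strategy mirrors a conventional count-regression workflow:

* individual fitness (offspring counts per female-year) — Poisson and
  negative-binomial (NB2) log-link GLMs, reduced by backward stepwise
  elimination of the least significant predictor until all retained
  predictors satisfy p < alpha (default 0.05), with AIC recorded at each
  step; final Poisson and NB fits compared by likelihood-ratio test;
  Pearson dispersion and GVIF reported as diagnostics;
* repeated measures — NB random-intercept mixed model with female identity
  as the grouping factor, compared to the fixed-only model by LRT;
* population-level responses (13 annual points) — single-predictor ordinary
  least squares with permutation p-values (response shuffled, slope
  recomputed) because the homoskedasticity assumption fails at n = 13.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._nbglmm import fit_nb_glmm_core

__all__ = [
    "ModelResult",
    "StepwiseTrace",
    "PermutationResult",
    "SingularDesignError",
    "fit_count_glm",
    "backward_stepwise",
    "likelihood_ratio_test",
    "gvif",
    "fit_nb_mixed",
    "fit_lm",
    "permutation_pvalue",
    "predict_effect",
]

Z975 = stats.norm.ppf(0.975)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (or a predictor is constant)."""


@dataclass
class ModelResult:
    """Container for one fitted model.

    ``params`` has one row per fixed-effect term (index = term name,
    'const' first) with columns estimate, se, stat, p.  ``theta`` is the NB
    size parameter (1/alpha); ``dispersion_ratio`` is Pearson chi^2 over
    residual df.  ``gvif`` is filled by :func:`gvif` for multi-predictor
    final models.
    """

    family: str
    response: str
    params: pd.DataFrame
    n: int
    k_params: int
    loglik: float
    aic: float
    converged: bool = True
    singular: bool = False
    theta: float | None = None
    theta_se: float | None = None
    re_sd: float | None = None
    dispersion_ratio: float | None = None
    adj_r2: float | None = None
    gvif: dict[str, float] | None = None
    x_means: pd.Series | None = field(default=None, repr=False)
    cov_params: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.params.loc[term, "estimate"]
        se = self.params.loc[term, "se"]
        return (float(est - z * se), float(est + z * se))


@dataclass
class StepwiseTrace:
    """Record of one backward-stepwise run: (removed_term, p_at_removal,
    aic_after) per step, plus the final model."""

    steps: list[tuple[str, float, float]]
    final: ModelResult
    all_removed: bool = False


@dataclass
class PermutationResult:
    observed_coefficient: float
    n_permutations: int
    permuted_p: float
    seed: int | None
    statistic: str = "coef"


def _design(y, X) -> tuple[np.ndarray, pd.DataFrame]:
    """Listwise-delete missing rows, add a constant, check rank."""
    if isinstance(X, pd.Series):
        X = X.to_frame()
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    ok = y.notna() & X.notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"listwise deletion dropped {dropped} rows", stacklevel=3)
    y, X = y[ok], X[ok]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    return y.to_numpy(), design


def _params_frame(names, est, se) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    stat = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {"estimate": est, "se": se, "stat": stat, "p": p}, index=list(names)
    )


def fit_count_glm(y, X, family: str = "negbin") -> ModelResult:
    """Log-link count GLM by maximum likelihood.

    ``family`` is 'poisson' or 'negbin' (NB2; theta = 1/alpha estimated
    jointly by ML, and AIC counts it as a parameter).  Wald z tests per
    coefficient; Pearson chi^2 / residual df reported as the dispersion
    diagnostic.
    """
    if family not in ("poisson", "negbin"):
        raise ValueError(f"family must be 'poisson' or 'negbin', got {family!r}")
    yv, design = _design(y, X)
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError("count response must be nonnegative integers")
    n, k = design.shape
    names = list(design.columns)
    Xmat = design.to_numpy()
    if yv.sum() == 0:
        # the log-link MLE pushes the mean to the boundary (mu -> 0);
        # report the degenerate fit honestly instead of iterating forever
        warnings.warn(
            "response is identically zero: log-link mean lies on the boundary",
            stacklevel=2,
        )
        params = _params_frame(names, np.full(k, -np.inf), np.full(k, np.nan))
        params.loc["const", "estimate"] = -np.inf
        return ModelResult(
            family=family, response="y", params=params, n=n, k_params=k,
            loglik=0.0, aic=2.0 * k, converged=False, singular=True,
            theta=None, dispersion_ratio=np.nan,
            x_means=design.drop(columns="const").mean(),
            cov_params=pd.DataFrame(
                np.full((k, k), np.nan), index=names, columns=names
            ),
        )

    if family == "poisson":
        res = sm.GLM(yv, Xmat, family=sm.families.Poisson()).fit()
        mu = res.mu
        pearson = float(np.sum((yv - mu) ** 2 / mu))
        params = _params_frame(names, res.params, res.bse)
        theta = theta_se = None
        loglik, aic, kp = float(res.llf), float(res.aic), k
        cov = res.cov_params()
        conv = bool(res.converged)
    else:
        model = sm.NegativeBinomial(yv, Xmat, loglike_method="nb2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
                conv = bool(res.mle_retvals.get("converged", True))
            except Exception:
                res = model.fit(disp=0, method="bfgs", maxiter=500)
                conv = bool(res.mle_retvals.get("converged", True))
        alpha = float(res.params[-1])
        alpha = max(alpha, 1e-12)
        mu = np.exp(Xmat @ res.params[:-1])
        pearson = float(np.sum((yv - mu) ** 2 / (mu + alpha * mu**2)))
        params = _params_frame(names, res.params[:-1], res.bse[:-1])
        theta = 1.0 / alpha
        alpha_se = float(res.bse[-1])
        # delta method: se(theta) = se(alpha)/alpha^2
        theta_se = alpha_se / alpha**2 if np.isfinite(alpha_se) else None
        loglik, aic, kp = float(res.llf), float(res.aic), k + 1
        try:
            cov = np.asarray(res.cov_params())[:k, :k]
        except (ValueError, np.linalg.LinAlgError):
            cov = np.full((k, k), np.nan)
            conv = False

    return ModelResult(
        family=family,
        response="y",
        params=params,
        n=n,
        k_params=kp,
        loglik=loglik,
        aic=aic,
        converged=conv,
        theta=theta,
        theta_se=theta_se,
        dispersion_ratio=pearson / (n - k) if n > k else np.nan,
        x_means=pd.DataFrame(design).drop(columns="const").mean(),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
    )


def backward_stepwise(
    y, X, family: str = "negbin", alpha: float = 0.05,
    fitter=None,
) -> StepwiseTrace:
    """Backward stepwise elimination on Wald p-values.

    Refit after removing the single largest-p predictor while any predictor
    has p >= alpha; the intercept is never removed; AIC is recorded at each
    step (selection itself is p-driven).  Ties within 1e-12 remove the
    later column for deterministic builds.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    fit = fitter if fitter is not None else (
        lambda yy, XX: fit_count_glm(yy, XX, family=family)
    )
    cols = list(X.columns)
    steps: list[tuple[str, float, float]] = []
    model = fit(y, X[cols])
    while cols:
        pvals = model.params.drop(index="const")["p"]
        worst_p = float(pvals.max())
        if worst_p < alpha:
            break
        # tie rule: among terms within 1e-12 of the max, drop the LATER column
        tied = [c for c in cols if pvals[c] >= worst_p - 1e-12]
        drop = max(tied, key=cols.index)
        cols.remove(drop)
        if not cols:
            model = fit(y, X[[]])
            steps.append((drop, worst_p, model.aic))
            warnings.warn(
                "all predictors removed; final model is intercept-only",
                stacklevel=2,
            )
            return StepwiseTrace(steps=steps, final=model, all_removed=True)
        model = fit(y, X[cols])
        steps.append((drop, worst_p, model.aic))
    return StepwiseTrace(steps=steps, final=model)


def likelihood_ratio_test(
    model_a: ModelResult, model_b: ModelResult, *, boundary_correction: bool = False
) -> tuple[float, int, float]:
    """LRT of nested models: 2*(ll_b - ll_a) ~ chi^2 with df = parameter
    difference (df = 1 for Poisson vs NB: the dispersion parameter).

    ``boundary_correction`` halves the p-value for a parameter tested on
    the boundary of its space (variance component or NB dispersion).
    """
    if model_a.n != model_b.n:
        raise ValueError("models fit to different numbers of observations")
    if model_b.k_params < model_a.k_params:
        model_a, model_b = model_b, model_a
    df = model_b.k_params - model_a.k_params
    stat = 2.0 * (model_b.loglik - model_a.loglik)
    if df == 0:
        return (float(stat), 0, 1.0)
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    if boundary_correction:
        p /= 2.0
    return (float(stat), df, p)


def gvif(X, term_groups: dict[str, list[str]] | None = None) -> dict[str, float]:
    """Generalized variance inflation factors from the predictor correlation
    matrix: GVIF_j = det(R_j) * det(R_-j) / det(R).  Reduces to the
    classical VIF 1/(1 - R_j^2) for single-column terms.
    """
    X = pd.DataFrame(X).astype(float)
    if term_groups is None:
        term_groups = {c: [c] for c in X.columns}
    if len(term_groups) < 2:
        raise ValueError("GVIF needs at least 2 terms")
    if (X.std(ddof=1) == 0).any():
        raise SingularDesignError("constant predictor column")
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    det_R = np.linalg.det(R)
    if det_R < 1e-12:
        raise SingularDesignError("singular predictor correlation matrix")
    cols = list(X.columns)
    out = {}
    for term, members in term_groups.items():
        idx = [cols.index(c) for c in members]
        rest = [i for i in range(len(cols)) if i not in idx]
        det_j = np.linalg.det(R[np.ix_(idx, idx)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)])
        out[term] = float(det_j * det_rest / det_R)
    return out


def fit_nb_mixed(y, X, group_ids, n_quad: int = 25) -> ModelResult:
    """NB2 mixed model with a Gaussian random intercept per group (female ID).

    Marginal ML via Gauss-Hermite quadrature.  The converged flag is
    honest: optimizer failure, an unidentifiable (ridge) likelihood, or a
    boundary fit (random-intercept SD ~ 0 -> ``singular``) are reported as
    such, mirroring the convergence failures expected when most groups are
    observed only once.
    """
    Xdf = pd.DataFrame(X).astype(float).reset_index(drop=True)
    yser = pd.Series(np.asarray(y, dtype=float))
    g = np.asarray(group_ids)
    if not (len(g) == len(Xdf) == len(yser)):
        raise ValueError("y, X and group_ids must align")
    ok = (yser.notna() & Xdf.notna().all(axis=1)).to_numpy()
    if (~ok).any():
        warnings.warn(f"listwise deletion dropped {int((~ok).sum())} rows",
                      stacklevel=2)
    yv, design = _design(yser[ok], Xdf.loc[ok])
    codes = pd.factorize(g[ok])[0]
    start = fit_count_glm(yv, design.drop(columns="const"), family="negbin")
    raw = fit_nb_glmm_core(
        yv,
        design.to_numpy(),
        codes,
        start_beta=start.params["estimate"].to_numpy(),
        start_log_alpha=float(np.log(1.0 / start.theta)) if start.theta else 0.0,
        n_quad=n_quad,
    )
    # boundary fits: the random intercept adds (numerically) nothing beyond
    # the fixed-only model, its SD collapsed toward zero, or the NB
    # dispersion ran to the Poisson boundary (alpha -> 0), leaving sigma^2
    # and alpha on an unidentifiable ridge
    if raw["sigma"] < 1e-2 or (raw["loglik"] - start.loglik) < 1e-4:
        raw["singular"] = True
    if raw["alpha"] < 2e-3:
        raw["singular"] = True
        raw["converged"] = False
    names = list(design.columns)
    p = len(names)
    se = np.sqrt(np.diag(raw["cov"])[:p]) if np.isfinite(raw["cov"]).all() else np.full(p, np.nan)
    params = _params_frame(names, raw["beta"], se)
    kp = p + 2  # beta + alpha + sigma
    cov = raw["cov"][:p, :p] if np.isfinite(raw["cov"]).all() else np.full((p, p), np.nan)
    return ModelResult(
        family="negbin_mixed",
        response="y",
        params=params,
        n=len(yv),
        k_params=kp,
        loglik=raw["loglik"],
        aic=2 * kp - 2 * raw["loglik"],
        converged=raw["converged"],
        singular=raw["singular"],
        theta=1.0 / raw["alpha"],
        re_sd=raw["sigma"],
        x_means=design.drop(columns="const").mean(),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
    )


def fit_lm(y, x, response: str = "y") -> ModelResult:
    """Ordinary least squares of y on one (or more) predictors, with
    t statistics and adjusted R^2."""
    yv, design = _design(y, x)
    if design.shape[0] < 3:
        raise ValueError("need at least 3 complete pairs")
    res = sm.OLS(yv, design).fit()
    names = list(design.columns)
    est, se = res.params, res.bse
    stat = res.tvalues
    p = res.pvalues
    params = pd.DataFrame(
        {"estimate": est, "se": se, "stat": stat, "p": p}, index=names
    )
    return ModelResult(
        family="gaussian",
        response=response,
        params=params,
        n=int(res.nobs),
        k_params=design.shape[1] + 1,  # + error variance
        loglik=float(res.llf),
        aic=float(res.aic),
        adj_r2=float(res.rsquared_adj),
        x_means=design.drop(columns="const").mean(),
        cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
    )


def permutation_pvalue(
    y, x, n_perm: int = 1000, seed: int | None = None, statistic: str = "coef"
) -> PermutationResult:
    """Monte-Carlo permutation p-value for a simple regression slope.

    The response is shuffled ``n_perm`` times and the slope (or its t
    statistic) recomputed; the two-sided add-one estimate is
    p = (1 + #{|b_perm| >= |b_obs|}) / (1 + n_perm), which is never zero.
    """
    if statistic not in ("coef", "t"):
        raise ValueError("statistic must be 'coef' or 't'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise SingularDesignError("constant x")
    rng = np.random.default_rng(seed)
    perm = np.stack([rng.permutation(y) for _ in range(n_perm)])  # (B, n)
    yc_obs = y - y.mean()
    b_obs = float(yc_obs @ xc) / denom
    b_perm = (perm - perm.mean(axis=1, keepdims=True)) @ xc / denom

    if statistic == "coef":
        s_obs, s_perm = b_obs, b_perm
    else:
        ssy = float(yc_obs @ yc_obs)

        def tstat(b):
            sse = np.maximum(ssy - b**2 * denom, 1e-300)
            return b / np.sqrt(sse / (n - 2) / denom)

        s_obs, s_perm = tstat(b_obs), tstat(b_perm)
    exceed = int(np.sum(np.abs(s_perm) >= np.abs(s_obs) - 1e-12))
    return PermutationResult(
        observed_coefficient=b_obs,
        n_permutations=n_perm,
        permuted_p=(1 + exceed) / (1 + n_perm),
        seed=seed,
        statistic=statistic,
    )


def predict_effect(
    model: ModelResult, focal_term: str, grid, level: float = 0.95
) -> pd.DataFrame:
    """Response-scale predictions over a grid of the focal predictor, with
    non-focal predictors held at their sample means and a Wald CI.
    """
    if not model.converged:
        raise ValueError("model did not converge; refusing to predict")
    if focal_term != "const" and focal_term not in model.terms:
        raise ValueError(f"focal term {focal_term!r} not in model")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    names = list(model.params.index)
    Xg = np.empty((grid.size, len(names)))
    for j, name in enumerate(names):
        if name == "const":
            Xg[:, j] = 1.0
        elif name == focal_term:
            Xg[:, j] = grid
        else:
            Xg[:, j] = float(model.x_means[name])
    beta = model.params["estimate"].to_numpy()
    cov = model.cov_params.to_numpy()
    eta = Xg @ beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = eta - z * se_eta, eta + z * se_eta
    if model.family in ("poisson", "negbin", "negbin_mixed"):
        eta, lo, hi = np.exp(eta), np.exp(lo), np.exp(hi)
    return pd.DataFrame(
        {focal_term: grid, "predicted": eta, "ci_lo": lo, "ci_hi": hi}
    )
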