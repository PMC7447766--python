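"""Mixed-effect models of cognitive status and test performance.

``fit_ordinal_mixed`` maximizes the marginal likelihood of a
proportional-odds cumulative-logit model with a subject-level Gaussian
random intercept,

    P(Y_ij <= k | b_i) = logistic(alpha_k - x_ij' beta - b_i),
    b_i ~ N(0, sigma_b^2),

integrating the random effect by non-adaptive Gauss-Hermite quadrature.
A single beta is shared across cut-points (proportional odds).  Wald z
statistics and two-sided p values are reported per coefficient, with
odds ratios exp(beta) and 95% CIs exp(beta +/- 1.96 se).

``fit_linear_mixed`` is a random-intercept linear mixed model of a
cognitive test score, fitted by maximum likelihood via statsmodels
MixedLM behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess

DEFAULT_STATUS_COVARIATES = [
    "age_years",
    "disease_duration_years",
    "sex",
    "apoe4",
    "gba",
    "mapt_h1",
    "ledd_mg",
    "gds15",
    "education_years",
    "site",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class MixedFit:
    kind: str  # "ordinal" | "linear"
    covariates: list[str]
    params: pd.Series  # fixed-effect coefficients
    se: pd.Series
    thresholds: np.ndarray | None  # ordinal cut-points (ascending), else None
    intercept: float | None  # linear intercept, else None
    sigma_b: float
    loglik: float
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def or_table(self) -> pd.DataFrame:
        """Table of coefficients, ORs, 95% CIs, and Wald p values."""
        rows = []
        for name in self.params.index:
            orv, lo, hi = or_from_coef(self.params[name], self.se[name])
            rows.append(
                {
                    "covariate": name,
                    "coef": self.params[name],
                    "se": self.se[name],
                    "or": orv,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.pvalues[name],
                }
            )
        return pd.DataFrame(rows)


def or_from_coef(coef: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(coef) with Wald 95% CI exp(coef -/+ 1.96 se)."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    return float(np.exp(coef)), float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction p_c = min(1, m * p); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def build_design(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix; 'site' expands to treatment-coded dummies."""
    parts = []
    for c in covariates:
        if c == "site":
            d = pd.get_dummies(table["site"].astype(int), prefix="site", drop_first=True)
            parts.append(d.astype(float))
        else:
            parts.append(table[[c]].astype(float))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in covariates {bad}; impute first")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # name the culprits via the R diagonal of a QR on the centred design
        Z = X.to_numpy(float) - X.to_numpy(float).mean(axis=0)
        _, rr = np.linalg.qr(Z)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * 1e-8 if diag.size else 0.0
        bad = [X.columns[j] for j in range(len(diag)) if diag[j] <= tol]
        raise ValueError(f"singular design; collinear columns include {bad or list(X.columns)}")


def _ordinal_nll_factory(X, y, group_idx, n_groups, n_quad, K):
    """Vectorized negative marginal log-likelihood over (beta, alpha, log sigma)."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    order = np.argsort(group_idx, kind="stable")
    Xs = X[order]
    ys = y[order]
    gs = group_idx[order]
    boundaries = np.searchsorted(gs, np.arange(n_groups))
    p = X.shape[1]

    def unpack(theta):
        beta = theta[:p]
        a1 = theta[p]
        gaps = np.exp(theta[p + 1 : p + K - 1])
        alphas = a1 + np.concatenate([[0.0], np.cumsum(gaps)])
        sigma = np.exp(theta[-1])
        return beta, alphas, sigma

    def nll(theta):
        beta, alphas, sigma = unpack(theta)
        eta = Xs @ beta  # (N,)
        b = np.sqrt(2.0) * sigma * nodes  # (Q,)
        u = eta[None, :] + b[:, None]  # (Q, N)
        # P(Y <= k) = logistic(alpha_k - u); category probs by differencing
        cum = expit(alphas[:, None, None] - u[None, :, :])  # (K-1, Q, N)
        probs = np.empty((K, u.shape[0], u.shape[1]))
        probs[0] = cum[0]
        for k in range(1, K - 1):
            probs[k] = cum[k] - cum[k - 1]
        probs[K - 1] = 1.0 - cum[K - 2]
        np.clip(probs, 1e-300, None, out=probs)
        logp = np.log(probs[ys, :, np.arange(len(ys))]).T  # (Q, N)
        per_group = np.add.reduceat(logp, boundaries, axis=1)  # (Q, G)
        ll = logsumexp(per_group + log_w[:, None], axis=0).sum()
        return -ll

    return nll, unpack


def fit_ordinal_mixed(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "status",
    group: str = "subject_id",
    n_quad: int = 21,
    maxiter: int = 500,
) -> MixedFit:
    """ML fit of the proportional-odds random-intercept model.

    Covariates are standardized internally for optimization and the
    estimates mapped back to the raw scale, so coefficients keep their
    per-unit (e.g. per-year) interpretation.
    """
    if covariates is None:
        covariates = DEFAULT_STATUS_COVARIATES
    if n_quad < 1 or n_quad % 2 == 0:
        raise ValueError("n_quad must be a positive odd integer")
    y_raw = table[outcome].to_numpy()
    levels = np.unique(y_raw)
    if len(levels) < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 observed levels")
    K = len(levels)
    y = np.searchsorted(levels, y_raw)
    Xdf = build_design(table, covariates)
    _check_full_rank(Xdf)
    names = list(Xdf.columns)
    X = Xdf.to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    groups, group_idx = np.unique(table[group].to_numpy(), return_inverse=True)
    nll, unpack = _ordinal_nll_factory(Z, y, group_idx, len(groups), n_quad, K)

    p = Z.shape[1]
    cum = np.cumsum(np.bincount(y, minlength=K))[:-1] / len(y)
    a0 = np.log(cum / (1 - cum))
    theta0 = np.concatenate(
        [np.zeros(p), [a0[0]], np.log(np.maximum(np.diff(a0), 1e-2)), [np.log(0.5)]]
    )
    res = optimize.minimize(nll, theta0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6})
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead", options={"maxiter": 4000})
        if res2.fun < res.fun:
            res = res2
        if nll(res.x) > nll(theta0):
            raise ConvergenceError("ordinal mixed model failed to converge", trace=res)

    beta_z, alphas_z, sigma = unpack(res.x)
    beta = beta_z / sd
    alphas = alphas_z + float(beta_z @ (mu / sd))

    H = approx_hess(res.x, nll)
    warns: list[str] = []
    try:
        cov = np.linalg.inv(H)
        var_bz = np.diag(cov)[:p]
        if np.any(var_bz < 0):
            raise np.linalg.LinAlgError
        se = np.sqrt(var_bz) / sd
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.abs(np.diag(cov))[:p]) / sd
        warns.append("hessian not positive definite; SEs from pseudo-inverse (possible separation)")
    if np.any(np.abs(beta_z) > 15):
        warns.append("inflated-SE flag: extreme coefficient suggests separation")

    return MixedFit(
        kind="ordinal",
        covariates=names,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        thresholds=alphas,
        intercept=None,
        sigma_b=float(sigma),
        loglik=float(-res.fun),
        converged=bool(res.success or np.linalg.norm(res.jac if hasattr(res, "jac") else 0) <= 1e-2),
        warnings=warns,
    )


def predict_status_proba(fit: MixedFit, new_rows: pd.DataFrame) -> np.ndarray:
    """Per-class probabilities for new rows with the random intercept at 0.

    Returns an (n, K) array (columns NCI, MCI, PDD) summing to 1.
    """
    if fit.kind != "ordinal":
        raise ValueError("probabilities require an ordinal fit")
    # Recover the original covariate list (site dummies come from 'site').
    base_covs = []
    for c in fit.covariates:
        if c.startswith("site_"):
            if "site" not in base_covs:
                base_covs.append("site")
        else:
            base_covs.append(c)
    missing = [c for c in base_covs if c not in new_rows.columns]
    if missing:
        raise ValueError(f"new rows lack covariates {missing}")
    X = build_design(new_rows, base_covs)
    X = X.reindex(columns=fit.covariates, fill_value=0.0)
    eta = X.to_numpy(float) @ fit.params.to_numpy()
    cum = expit(fit.thresholds[None, :] - eta[:, None])  # (n, K-1)
    K = cum.shape[1] + 1
    probs = np.empty((len(eta), K))
    probs[:, 0] = cum[:, 0]
    for k in range(1, K - 1):
        probs[:, k] = cum[:, k] - cum[:, k - 1]
    probs[:, K - 1] = 1.0 - cum[:, K - 2]
    return probs


def fit_linear_mixed(
    table: pd.DataFrame,
    test_name: str,
    covariates: list[str] | None = None,
    group: str = "subject_id",
) -> MixedFit:
    """Random-intercept linear mixed model of one test score (ML fit)."""
    if covariates is None:
        covariates = [c for c in DEFAULT_STATUS_COVARIATES]
    data = table.dropna(subset=[test_name]).copy()
    yv = data[test_name].astype(float)
    if yv.notna().sum() < 10:
        raise ValueError(f"test column {test_name!r} needs >= 10 observed values")
    X = build_design(data, covariates)
    _check_full_rank(X)
    # standardize for optimizer conditioning; map estimates back below
    A = X.to_numpy(float)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    exog = np.column_stack([np.ones(len(X)), (A - mu) / sd])
    names = ["intercept"] + list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(yv.to_numpy(), exog, groups=data[group].to_numpy())
        try:
            res = model.fit(reml=False, method="lbfgs")
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="cg")
    scale = np.concatenate([[1.0], sd])
    params = pd.Series(res.fe_params / scale, index=names)
    se = pd.Series(res.bse_fe / scale, index=names)
    params["intercept"] -= float(np.sum(params.iloc[1:].to_numpy() * mu))
    sigma_b = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
    return MixedFit(
        kind="linear",
        covariates=list(X.columns),
        params=params.drop("intercept"),
        se=se.drop("intercept"),
        thresholds=None,
        intercept=float(params["intercept"]),
        sigma_b=sigma_b,
        loglik=float(res.llf),
        converged=bool(res.converged),
    )


def genotype_test_associations(
    table: pd.DataFrame,
    genotype_cols: tuple[str, ...] = ("apoe4", "gba", "mapt_h1"),
    adjusters: tuple[str, ...] = (
        "age_years",
        "ledd_mg",
        "gds15",
        "disease_duration_years",
        "sex",
        "site",
        "education_years",
    ),
    tests: list[str] | None = None,
) -> pd.DataFrame:
    """Genotype effects on each cognitive test with Bonferroni correction.

    One linear mixed model per test; the Bonferroni factor is the number
    of tests analysed.
    """
    from .cohort import TEST_COLUMNS

    tests = TEST_COLUMNS if tests is None else tests
    covs = list(genotype_cols) + list(adjusters)
    rows = []
    for t in tests:
        fit = fit_linear_mixed(table, t, covs)
        for g in genotype_cols:
            rows.append(
                {
                    "test": t,
                    "genotype": g,
                    "coef": fit.params[g],
                    "se": fit.se[g],
                    "ci_low": fit.params[g] - 1.96 * fit.se[g],
                    "ci_high": fit.params[g] + 1.96 * fit.se[g],
                    "p": fit.pvalues[g],
                    "random_intercept_sd": fit.sigma_b,
                }
            )
    out = pd.DataFrame(rows)
    out["p_corrected"] = np.nan
    for g in out["genotype"].unique():
        sel = out["genotype"] == g
        out.loc[sel, "p_corrected"] = bonferroni(out.loc[sel, "p"].to_numpy(), m=len(tests))
    return out
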