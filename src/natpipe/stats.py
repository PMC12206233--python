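"""Resilience statistics: beta mixed models, moderation, Johnson-Neyman.

NAT values are fractions strictly inside (0, 1) observed repeatedly per
participant (once per network density), so the first-stage model is a
generalized linear mixed model with a beta response and logit link,

    y_ij | u_i ~ Beta(mu_ij * phi, (1 - mu_ij) * phi),
    logit(mu_ij) = x_ij' b + u_i,      u_i ~ N(0, sigma_u^2),

with a participant random intercept u_i and precision phi. The marginal
likelihood integrates u_i out by Gauss-Hermite quadrature and is maximized
directly; standard errors come from the numerical Hessian at the optimum
(Wald inference). No installed Python package fits this family with random
effects, so the estimator lives here; its contract is parameter recovery on
data simulated from the same model (see the test suite).

The second stage regresses composite behavior on per-network mean NAT with
a lifestyle moderator (OLS with interaction), and the Johnson-Neyman
technique solves analytically for the moderator values where the
conditional NAT slope b1 + b3*w crosses the Wald significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm, t as t_dist
import statsmodels.formula.api as smf
from statsmodels.tools.numdiff import approx_hess1

from .errors import ContractError, DomainError, NotConvergedError

_EPS = 1e-6        # boundary nudge for responses touching 0/1
_MU_CLIP = 1e-10


# ---------------------------------------------------------------------------
# Beta GLMM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLMMSpec:
    """Design of the NAT mixed model.

    Default fixed effects mirror the reporting layout: putaminal DaT, PA,
    education, age, sex (female reference), network density, and two
    scanning-sequence contrasts against sequence 1 — eight slopes plus the
    intercept — with a per-participant random intercept.
    """

    response: str = "nat"
    group: str = "participant"
    include_sequence: bool = True
    quadrature_points: int = 21

    @property
    def slope_names(self) -> tuple:
        names = ["dat", "pa", "education", "age", "sex(f<m)", "density"]
        if self.include_sequence:
            names += ["seq(1<2)", "seq(1<3)"]
        return tuple(names)


def glmm_design(df: pd.DataFrame, spec: GLMMSpec = GLMMSpec()):
    """Build (X, names, y, groups) for the beta mixed model.

    Columns required: response, group, dat, pa, education, age, sex
    ("f"/"m"), density, sequence (1/2/3). Sequence contrasts use level 1
    as reference; a contrast with no observations is rejected (drop the
    sequence term instead, as in subgroup sensitivity analyses).
    """
    cols = [spec.response, spec.group, "dat", "pa", "education", "age",
            "sex", "density"] + (["sequence"] if spec.include_sequence else [])
    missing = set(cols) - set(df.columns)
    if missing:
        raise ContractError(f"model frame lacks columns: {sorted(missing)}")
    data = df.dropna(subset=cols).copy()
    parts = [
        np.ones(len(data)),
        data["dat"].to_numpy(float),
        data["pa"].to_numpy(float),
        data["education"].to_numpy(float),
        data["age"].to_numpy(float),
        (data["sex"] == "m").to_numpy(float),
        data["density"].to_numpy(float),
    ]
    names = ["intercept"] + list(spec.slope_names)
    if spec.include_sequence:
        for level in (2, 3):
            col = (data["sequence"] == level).to_numpy(float)
            if col.sum() == 0:
                raise ContractError(
                    f"no observations with sequence {level}; "
                    "drop the sequence term (include_sequence=False)"
                )
            parts.append(col)
    X = np.column_stack(parts)
    y = data[spec.response].to_numpy(float)
    groups = data[spec.group].to_numpy()
    return X, names, y, groups


def _beta_logpdf(y, mu, phi):
    return (
        gammaln(phi)
        - gammaln(mu * phi)
        - gammaln((1 - mu) * phi)
        + (mu * phi - 1) * np.log(y)
        + ((1 - mu) * phi - 1) * np.log1p(-y)
    )


class _MarginalLikelihood:
    """Negative marginal log-likelihood with Gauss-Hermite integration."""

    def __init__(self, X, y, groups, n_quad):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g = np.asarray(groups)[order]
        change = np.r_[True, g[1:] != g[:-1]]
        self.starts = np.flatnonzero(change)
        self.n_groups = len(self.starts)
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self.nodes = nodes * np.sqrt(2.0)
        self.log_w = np.log(weights) - 0.5 * np.log(np.pi)
        self.p = X.shape[1]

    def __call__(self, params):
        beta = params[: self.p]
        phi = np.exp(params[self.p])
        sigma = np.exp(params[self.p + 1])
        eta = self.X @ beta
        mu = expit(eta[:, None] + sigma * self.nodes[None, :])
        mu = np.clip(mu, _MU_CLIP, 1 - _MU_CLIP)
        ll_obs = _beta_logpdf(self.y[:, None], mu, phi)
        ll_group = np.add.reduceat(ll_obs, self.starts, axis=0)
        ll = logsumexp(ll_group + self.log_w[None, :], axis=1)
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(ll.sum())


@dataclass(frozen=True)
class GLMMFit:
    """Beta-GLMM estimates: coefficient table plus dispersion components."""

    table: pd.DataFrame          # estimate, se, z, p, ci_low, ci_high
    phi: float
    sigma_u: float
    loglik: float
    pseudo_r2: float
    converged: bool
    n_obs: int
    n_groups: int

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "estimate"])


def _fit_marginal(X, y, groups, n_quad, x0=None):
    nll = _MarginalLikelihood(X, y, groups, n_quad)
    p = X.shape[1]
    if x0 is None:
        z = np.log(np.clip(y, _EPS, 1 - _EPS) / np.clip(1 - y, _EPS, 1 - _EPS))
        beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta0
        mu0 = np.clip(expit(X @ beta0), 0.05, 0.95)
        v = max(np.var(y - expit(X @ beta0)), 1e-6)
        phi0 = max(float(np.mean(mu0 * (1 - mu0)) / v - 1), 2.0)
        sigma0 = max(float(np.std(resid)) * 0.5, 0.05)
        x0 = np.r_[beta0, np.log(phi0), np.log(sigma0)]
    opt = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
    return nll, opt


def fit_beta_glmm(df: pd.DataFrame, spec: GLMMSpec = GLMMSpec()) -> GLMMFit:
    """Fit the logit-link beta mixed model by marginal maximum likelihood.

    Responses touching 0 or 1 are nudged into (eps, 1 - eps) with a
    warning (the beta density is undefined at the boundary). The reported
    explained-variance statistic is a deviance-based pseudo-R-squared,
    1 - D_model / D_null, each deviance taken against the saturated model
    at the respective fit's precision.
    """
    X, names, y, groups = glmm_design(df, spec)
    _, counts = np.unique(groups, return_counts=True)
    if counts.min() < 2:
        raise ContractError("every participant needs at least 2 observations")
    if np.any((y <= 0) | (y >= 1)):
        warnings.warn("responses at the 0/1 boundary nudged into (0, 1)",
                      stacklevel=2)
        y = np.clip(y, _EPS, 1 - _EPS)

    # standardize the slope columns for optimization (covariates live on very
    # different scales); estimates and covariance are mapped back afterwards
    p_fix = X.shape[1]
    m = X.mean(axis=0)
    s = X.std(axis=0)
    m[0], s[0] = 0.0, 1.0
    s[s == 0] = 1.0
    Xs = (X - m) / s
    Xs[:, 0] = 1.0
    T = np.diag(1.0 / s)
    T[0, 1:] = -m[1:] / s[1:]
    T[0, 0] = 1.0

    nll, opt = _fit_marginal(Xs, y, groups, spec.quadrature_points)
    if not opt.success:  # polish once from the incumbent
        nll, opt = _fit_marginal(Xs, y, groups, spec.quadrature_points,
                                 x0=opt.x)
    params_s = opt.x
    converged = bool(opt.success)
    if not converged:
        raise NotConvergedError(f"beta GLMM did not converge: {opt.message}")

    hess = approx_hess1(params_s, nll)
    jac = np.eye(len(params_s))
    jac[:p_fix, :p_fix] = T
    try:
        cov = jac @ np.linalg.inv(hess) @ jac.T
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(len(params_s), np.nan)
        converged = False
    params = params_s.copy()
    params[:p_fix] = T @ params_s[:p_fix]
    est = params[:p_fix]
    se = se_all[:p_fix]
    zval = est / se
    pval = 2 * norm.sf(np.abs(zval))
    ci = 1.959963984540054 * se
    table = pd.DataFrame(
        {"estimate": est, "se": se, "z": zval, "p": pval,
         "ci_low": est - ci, "ci_high": est + ci},
        index=names,
    )

    phi = float(np.exp(params[p_fix]))
    ll_model = -opt.fun
    # explained deviance at the fitted precision: saturated model has mu = y,
    # the null is an intercept-only beta regression (no random intercept), so
    # participant-level structure counts as explained variance
    mu_sat = np.clip(y, _MU_CLIP, 1 - _MU_CLIP)
    ll_sat = float(_beta_logpdf(y, mu_sat, phi).sum())
    null = minimize_scalar(
        lambda b0: -float(_beta_logpdf(y, expit(np.full_like(y, b0)), phi).sum()),
        bounds=(-10, 10), method="bounded",
    )
    ll_null = -null.fun
    d_model = 2 * (ll_sat - ll_model)
    d_null = 2 * (ll_sat - ll_null)
    pseudo_r2 = float(np.clip(1 - d_model / d_null, 0, 1)) if d_null > 0 else np.nan

    return GLMMFit(
        table=table, phi=phi, sigma_u=float(np.exp(params[p_fix + 1])),
        loglik=ll_model, pseudo_r2=pseudo_r2, converged=converged,
        n_obs=len(y), n_groups=len(counts),
    )


def simulate_beta_glmm(X: np.ndarray, beta: np.ndarray, phi: float,
                       sigma_u: float, groups: np.ndarray, rng) -> np.ndarray:
    """Draw responses from the beta mixed model (for recovery studies)."""
    uniq, inv = np.unique(groups, return_inverse=True)
    u = rng.normal(0.0, sigma_u, size=len(uniq))
    mu = expit(X @ np.asarray(beta, float) + u[inv])
    mu = np.clip(mu, _MU_CLIP, 1 - _MU_CLIP)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return np.clip(y, _EPS, 1 - _EPS)


# ---------------------------------------------------------------------------
# Moderation models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModerationFit:
    """OLS interaction model with the covariance needed for Johnson-Neyman."""

    outcome: str
    predictor: str
    moderator: str
    table: pd.DataFrame
    cov: pd.DataFrame
    df_resid: float
    fvalue: float
    f_pvalue: float
    n_obs: int
    moderator_range: tuple
    predictor_term: str = field(repr=False, default="")
    interaction_term: str = field(repr=False, default="")

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])


def fit_moderation(df: pd.DataFrame, outcome: str, predictor: str = "nat",
                   moderator: str = "pa",
                   controls=("education", "dat", "age", "sex", "sequence"),
                   ) -> ModerationFit:
    """OLS moderation model: outcome ~ predictor * moderator + controls.

    Complete cases only (a missing outcome simply drops that participant).
    ``sex`` enters with female reference and ``sequence`` as contrasts
    against level 1. Rank deficiency is rejected with the offending columns
    named; a constant moderator is the canonical offender.
    """
    terms = [f"{predictor} * {moderator}"]
    for c in controls:
        if c == "sex":
            terms.append("C(sex, Treatment('f'))")
        elif c == "sequence":
            terms.append("C(sequence, Treatment(1))")
        else:
            terms.append(c)
    formula = f"{outcome} ~ " + " + ".join(terms)
    used = {outcome, predictor, moderator} | {c for c in controls}
    data = df.dropna(subset=[c for c in used if c in df.columns])
    if len(data) == 0:
        raise ContractError("no complete cases for the moderation model")

    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        r = np.abs(np.diag(np.linalg.qr(exog, mode="r")))
        bad = [model.exog_names[i] for i in np.flatnonzero(r < 1e-8 * r.max())]
        raise DomainError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    res = model.fit()
    ci = res.conf_int()
    table = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "t": res.tvalues,
         "p": res.pvalues, "ci_low": ci[0], "ci_high": ci[1]}
    )
    interaction = f"{predictor}:{moderator}"
    if interaction not in res.params.index:
        interaction = f"{moderator}:{predictor}"
    w = data[moderator].to_numpy(float)
    return ModerationFit(
        outcome=outcome, predictor=predictor, moderator=moderator,
        table=table, cov=res.cov_params(), df_resid=float(res.df_resid),
        fvalue=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        n_obs=int(res.nobs), moderator_range=(float(w.min()), float(w.max())),
        predictor_term=predictor, interaction_term=interaction,
    )


# ---------------------------------------------------------------------------
# Johnson-Neyman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JNRegion:
    """Moderator ranges where the conditional predictor effect is significant.

    ``regions`` lists (lower, upper, direction) intervals within the
    observed moderator range; ``status`` is "everywhere", "nowhere" or
    "partial". At each interior boundary the conditional-effect t-statistic
    equals the two-sided critical value exactly.
    """

    boundaries: tuple
    regions: tuple
    status: str
    alpha: float
    t_crit: float
    df: float
    b1: float
    b3: float
    v11: float
    v13: float
    v33: float
    moderator_range: tuple

    def conditional_effect(self, w):
        """Conditional predictor slope and its SE at moderator value(s) w."""
        w = np.asarray(w, float)
        est = self.b1 + self.b3 * w
        se = np.sqrt(self.v11 + 2 * w * self.v13 + w ** 2 * self.v33)
        return est, se

    def t_stat(self, w):
        est, se = self.conditional_effect(w)
        return est / se


def johnson_neyman(fit: ModerationFit, alpha: float = 0.05,
                   moderator_range: tuple | None = None) -> JNRegion:
    """Analytic Johnson-Neyman significance regions for the moderation fit.

    Solves |(b1 + b3 w) / SE(w)| = t_crit, a quadratic in w, and reports the
    sub-intervals of the observed moderator range where the conditional
    effect of the predictor is significant at level ``alpha``. With a zero
    interaction the conditional effect is flat and the answer is all-or-
    nothing depending on the main effect's t-statistic.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    b1 = fit.coef(fit.predictor_term)
    b3 = fit.coef(fit.interaction_term)
    v11 = float(fit.cov.loc[fit.predictor_term, fit.predictor_term])
    v13 = float(fit.cov.loc[fit.predictor_term, fit.interaction_term])
    v33 = float(fit.cov.loc[fit.interaction_term, fit.interaction_term])
    t_crit = float(t_dist.ppf(1 - alpha / 2, fit.df_resid))
    lo, hi = moderator_range if moderator_range is not None else fit.moderator_range
    if not lo < hi:
        raise DomainError("moderator range must be non-degenerate")

    # significant where f(w) = (b1 + b3 w)^2 - t^2 SE^2(w) > 0
    a = b3 ** 2 - t_crit ** 2 * v33
    b = 2 * (b1 * b3 - t_crit ** 2 * v13)
    c = b1 ** 2 - t_crit ** 2 * v11

    def f(w):
        return (b1 + b3 * w) ** 2 - t_crit ** 2 * (v11 + 2 * w * v13 + w ** 2 * v33)

    roots = []
    scale = max(abs(a), abs(b), abs(c), 1e-300)
    if abs(a) > 1e-14 * scale:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    elif abs(b) > 1e-14 * scale:
        roots = [-c / b]

    interior = [r for r in roots if lo < r < hi]
    points = [lo] + sorted(interior) + [hi]
    regions = []
    for left, right in zip(points[:-1], points[1:]):
        mid = 0.5 * (left + right)
        if f(mid) > 0:
            direction = 1 if b1 + b3 * mid > 0 else -1
            regions.append((left, right, direction))
    if not regions:
        status = "nowhere"
    elif len(regions) == 1 and regions[0][0] == lo and regions[0][1] == hi:
        status = "everywhere"
    else:
        status = "partial"
    return JNRegion(
        boundaries=tuple(interior), regions=tuple(regions), status=status,
        alpha=alpha, t_crit=t_crit, df=fit.df_resid,
        b1=b1, b3=b3, v11=v11, v13=v13, v33=v33, moderator_range=(lo, hi),
    )
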