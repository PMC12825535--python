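"""Four-way effect decomposition for a rare time-to-event outcome.

The total effect of an exposure A on the excess-relative-risk (ERR) scale is
decomposed into controlled direct effect (CDE), reference interaction
(INTref), mediated interaction (INTmed) and pure indirect effect (PIE),
following the regression-based approach for survival outcomes with a
normally distributed continuous mediator M and an exposure-mediator product
term:

    mediator model:  M = beta0 + beta1*A + beta2'C + eps,  eps ~ N(0, sigma2)
    outcome model:   log h(t) = log h0(t) + theta1*A + theta2*M
                                 + theta3*A*M + theta4'C

Under the rare-outcome approximation (hazard ratio ~ risk ratio), with
g(a, m) = exp(theta1*a + theta2*m + theta3*a*m) and the closed-form normal
expectation

    Q(a, a') = exp(theta1*a) * exp((theta2 + theta3*a) * mu(a')
                                   + 0.5*(theta2 + theta3*a)^2 * sigma2),
    mu(a') = beta0 + beta1*a' + beta2'c,

the four components (normalized by D = Q(a*, a*)) are

    te      = [Q(a,a)  - Q(a*,a*)] / D
    cde     = [g(a,m*) - g(a*,m*)] / D
    int_ref = [Q(a,a*) - Q(a*,a*) - g(a,m*) + g(a*,m*)] / D
    int_med = [Q(a,a)  - Q(a*,a) - Q(a,a*) + Q(a*,a*)] / D
    pie     = [Q(a*,a) - Q(a*,a*)] / D

and satisfy cde + int_ref + int_med + pie = te exactly.  Note that on this
additive ERR scale the interaction components do not vanish when theta3 = 0:
a log-linear hazard with no product term still carries additive-scale
interaction, and at theta3 = 0 the components reduce to
int_med = (e^{theta1*da} - 1)(e^{theta2*beta1*da} - 1) and
int_ref = (e^{theta1*da} - 1)(1 - e^{theta2*(m* - mu(a*)) - theta2^2*sigma2/2}).
They do vanish exactly when beta1 = 0 (no exposure->mediator path kills
pie and int_med) or when theta1 = 0 (kills cde and both interactions only if
additionally m*, sigma2 terms align) — the additivity identity holds always.

Uncertainty is by seeded nonparametric bootstrap (percentile intervals,
refitting both models per resample) by default, with a delta-method variant
using a numerical Jacobian for parity with the Stata implementation of this
decomposition.  Mediation is called significant when both TE and PIE have
p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxError, CoxFit, fit_cox
from .design import DEFAULT_COVARIATES, design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FourWaySpec",
    "FourWayResult",
    "ModelPair",
    "four_way_components",
    "encode_exposure",
    "fit_models",
    "decompose",
    "exposure_associations",
    "screen_mediators",
    "pca_aggregate",
    "mediate_via_pca",
]

_COMPONENTS = ("te", "cde", "int_ref", "int_med", "pie")


def four_way_components(
    beta0: float,
    beta1: float,
    sigma2: float,
    theta1: float,
    theta2: float,
    theta3: float,
    a: float = 1.0,
    a_star: float = 0.0,
    m_star: float = 0.0,
    cov_term: float = 0.0,
) -> dict[str, float]:
    """Closed-form four-way components on the ERR scale.

    ``cov_term`` is beta2'c, the mediator-model covariate contribution at the
    chosen covariate level c.
    """

    def mu(ap):
        return beta0 + beta1 * ap + cov_term

    def g(aa, m):
        return np.exp(theta1 * aa + theta2 * m + theta3 * aa * m)

    def Q(aa, ap):
        s = theta2 + theta3 * aa
        return np.exp(theta1 * aa) * np.exp(s * mu(ap) + 0.5 * s**2 * sigma2)

    D = Q(a_star, a_star)
    te = (Q(a, a) - Q(a_star, a_star)) / D
    cde = (g(a, m_star) - g(a_star, m_star)) / D
    int_ref = (Q(a, a_star) - Q(a_star, a_star) - g(a, m_star) + g(a_star, m_star)) / D
    # grouped so the beta1=0 limit cancels exactly in floating point
    int_med = ((Q(a, a) - Q(a, a_star)) - (Q(a_star, a) - Q(a_star, a_star))) / D
    pie = (Q(a_star, a) - Q(a_star, a_star)) / D
    return {
        "te": float(te),
        "cde": float(cde),
        "int_ref": float(int_ref),
        "int_med": float(int_med),
        "pie": float(pie),
    }


@dataclass
class FourWaySpec:
    a: float = 1.0
    a_star: float = 0.0
    m_star: float | None = None  # default: marginal sample mean of the mediator
    covariate_level: np.ndarray | None = None  # default: sample means of the design
    ci_method: str = "bootstrap"  # or "delta"
    n_boot: int = 500
    seed: int = 0

    def validate(self):
        if self.a == self.a_star:
            raise ValueError("index and reference exposure levels must differ")
        if self.ci_method not in ("bootstrap", "delta"):
            raise ValueError("ci_method must be 'bootstrap' or 'delta'")


@dataclass
class ModelPair:
    """Fitted mediator (OLS) and outcome (Cox) models plus the data used."""

    exposure: str
    mediator: str
    covariates: list[str]
    beta0: float
    beta1: float
    beta_cov: np.ndarray
    sigma2: float
    theta1: float
    theta2: float
    theta3: float
    theta_cov: np.ndarray
    ols_cov: np.ndarray  # covariance of (beta0, beta1, beta_cov...)
    sigma2_var: float
    cox_fit: CoxFit
    A: np.ndarray
    M: np.ndarray
    C: np.ndarray
    cov_names: list[str]
    time: np.ndarray
    event: np.ndarray

    @property
    def n(self) -> int:
        return self.A.size

    @property
    def event_fraction(self) -> float:
        return float(np.mean(self.event))


@dataclass
class FourWayResult:
    exposure: str
    mediator: str
    estimates: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    proportion_mediated: float | None
    proportion_mediated_ci: tuple | None
    total_mediated: float | None  # (pie + int_med) / te, "including interaction"
    significant: bool
    ci_method: str = "bootstrap"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in _COMPONENTS:
            rows.append(
                {
                    "component": comp,
                    "estimate": self.estimates[comp],
                    "se": self.se.get(comp, np.nan),
                    "ci_low": self.ci_low.get(comp, np.nan),
                    "ci_high": self.ci_high.get(comp, np.nan),
                    "p": self.p.get(comp, np.nan),
                }
            )
        out = pd.DataFrame(rows)
        out.insert(0, "mediator", self.mediator)
        out.insert(0, "exposure", self.exposure)
        return out


def encode_exposure(cohort: pd.DataFrame, exposure: str, kind: str | None = None):
    """Numeric exposure vector: standardized continuous or 0/1 binary.

    'bmi' is standardized to mean 0 / SD 1; 'smoking' maps ever/current to 1
    and never to 0.  Other columns are standardized when ``kind`` is
    'continuous' and used as-is when 'binary'.
    """
    col = cohort[exposure]
    if kind is None:
        kind = "binary" if exposure == "smoking" or col.dtype == object else "continuous"
    if kind == "binary":
        if col.dtype == object:
            vals = col.isin(["ever", "current", "ever/current", "yes", "1"]).astype(float)
        else:
            vals = col.astype(float)
        uniq = set(np.unique(vals))
        if not uniq <= {0.0, 1.0}:
            raise ValueError(f"binary exposure {exposure!r} is not 0/1")
        return vals.to_numpy(), "binary"
    x = col.astype(float)
    return ((x - x.mean()) / x.std(ddof=1)).to_numpy(), "continuous"


def fit_models(
    cohort: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: list[str] | None = None,
    matrix: pd.DataFrame | None = None,
    exposure_kind: str | None = None,
) -> ModelPair:
    """Fit the mediator OLS and the interaction Cox model.

    The mediator is taken from ``matrix`` when given, otherwise from the
    cohort table.  Warns (does not fail) if the event fraction exceeds 5%,
    where the hazard-ratio ~ risk-ratio approximation degrades.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    covariates = [c for c in covariates if c != exposure]  # exposure is modelled, not adjusted for
    A, _ = encode_exposure(cohort, exposure, exposure_kind)
    if matrix is not None and mediator in matrix.columns:
        M = matrix.loc[cohort.index, mediator].to_numpy(float)
    else:
        M = cohort[mediator].to_numpy(float)
    if np.std(M) == 0:
        raise ValueError(f"mediator {mediator!r} is constant")
    D = design_matrix(cohort, covariates)
    C = D.to_numpy(float)
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)

    # mediator model (OLS with intercept)
    Xm = np.column_stack([np.ones(len(A)), A, C])
    bm, res_ss, rank, _ = np.linalg.lstsq(Xm, M, rcond=None)
    if rank < Xm.shape[1]:
        raise CoxError("singular mediator-model design")
    resid = M - Xm @ bm
    dof = len(A) - Xm.shape[1]
    sigma2 = float(resid @ resid / dof)
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    ols_cov = sigma2 * XtX_inv
    sigma2_var = 2.0 * sigma2**2 / dof

    # outcome model (Cox with product term)
    Xo = np.column_stack([A, M, A * M, C])
    fit = fit_cox(Xo, time, event, names=["A", "M", "A:M"] + D.columns.tolist())
    if not fit.converged:
        raise CoxError("outcome Cox model did not converge")

    frac = float(np.mean(event))
    if frac > 0.05:
        warnings.warn(
            f"event fraction {frac:.1%} exceeds 5%; the rare-outcome "
            "hazard-ratio ~ risk-ratio approximation may be poor",
            stacklevel=2,
        )
    return ModelPair(
        exposure=exposure,
        mediator=mediator,
        covariates=covariates,
        beta0=float(bm[0]),
        beta1=float(bm[1]),
        beta_cov=bm[2:],
        sigma2=sigma2,
        theta1=float(fit.coef[0]),
        theta2=float(fit.coef[1]),
        theta3=float(fit.coef[2]),
        theta_cov=fit.coef[3:],
        ols_cov=ols_cov,
        sigma2_var=sigma2_var,
        cox_fit=fit,
        A=A,
        M=M,
        C=C,
        cov_names=D.columns.tolist(),
        time=time,
        event=event,
    )


def _components_from_pair(models: ModelPair, spec: FourWaySpec, m_star, c_level):
    cov_term = float(models.beta_cov @ c_level) if models.beta_cov.size else 0.0
    return four_way_components(
        beta0=models.beta0,
        beta1=models.beta1,
        sigma2=models.sigma2,
        theta1=models.theta1,
        theta2=models.theta2,
        theta3=models.theta3,
        a=spec.a,
        a_star=spec.a_star,
        m_star=m_star,
        cov_term=cov_term,
    )


def _refit_components(models, spec, m_star, c_level, idx, cox_init):
    """Refit both models on a bootstrap index vector; return components."""
    A, M, C = models.A[idx], models.M[idx], models.C[idx]
    Xm = np.column_stack([np.ones(idx.size), A, C])
    bm, *_ = np.linalg.lstsq(Xm, M, rcond=None)
    resid = M - Xm @ bm
    sigma2 = float(resid @ resid / (idx.size - Xm.shape[1]))
    Xo = np.column_stack([A, M, A * M, C])
    fit = fit_cox(Xo, models.time[idx], models.event[idx], init=cox_init, tol=1e-6)
    cov_term = float(bm[2:] @ c_level) if bm.size > 2 else 0.0
    return four_way_components(
        beta0=float(bm[0]),
        beta1=float(bm[1]),
        sigma2=sigma2,
        theta1=float(fit.coef[0]),
        theta2=float(fit.coef[1]),
        theta3=float(fit.coef[2]),
        a=spec.a,
        a_star=spec.a_star,
        m_star=m_star,
        cov_term=cov_term,
    )


def decompose(models: ModelPair, spec: FourWaySpec | None = None) -> FourWayResult:
    """Point estimates and uncertainty for the four-way decomposition."""
    spec = spec or FourWaySpec()
    spec.validate()
    m_star = float(np.mean(models.M)) if spec.m_star is None else float(spec.m_star)
    c_level = (
        models.C.mean(axis=0)
        if spec.covariate_level is None
        else np.asarray(spec.covariate_level, dtype=float)
    )
    est = _components_from_pair(models, spec, m_star, c_level)

    if spec.ci_method == "bootstrap":
        rng = np.random.default_rng(spec.seed)
        cox_init = models.cox_fit.coef
        draws = {k: [] for k in _COMPONENTS}
        prop_draws = []
        n_fail = 0
        for _ in range(spec.n_boot):
            idx = rng.integers(0, models.n, models.n)
            if models.event[idx].sum() < 2:
                n_fail += 1
                continue
            try:
                comp = _refit_components(models, spec, m_star, c_level, idx, cox_init)
            except (CoxError, np.linalg.LinAlgError):
                n_fail += 1
                continue
            for k in _COMPONENTS:
                draws[k].append(comp[k])
            if comp["te"] != 0:
                prop_draws.append(comp["pie"] / comp["te"])
        if n_fail:
            logger.info("decompose: %d/%d bootstrap resamples failed", n_fail, spec.n_boot)
        se, lo, hi, pvals = {}, {}, {}, {}
        for k in _COMPONENTS:
            arr = np.asarray(draws[k])
            se[k] = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
            lo[k], hi[k] = (
                (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
                if arr.size > 1
                else (np.nan, np.nan)
            )
            pvals[k] = (
                float(2.0 * stats.norm.sf(abs(est[k]) / se[k]))
                if se[k] and np.isfinite(se[k]) and se[k] > 0
                else np.nan
            )
        prop_ci = (
            (float(np.percentile(prop_draws, 2.5)), float(np.percentile(prop_draws, 97.5)))
            if len(prop_draws) > 1
            else None
        )
    else:  # delta method via numerical Jacobian
        params = np.r_[
            models.beta0, models.beta1, models.beta_cov, models.sigma2,
            models.theta1, models.theta2, models.theta3,
        ]
        k_ols = 2 + models.beta_cov.size
        Sigma = np.zeros((params.size, params.size))
        Sigma[:k_ols, :k_ols] = models.ols_cov
        Sigma[k_ols, k_ols] = models.sigma2_var
        Sigma[k_ols + 1 :, k_ols + 1 :] = models.cox_fit.cov[:3, :3]

        def comp_vec(p):
            cov_term = float(p[2:k_ols] @ c_level) if k_ols > 2 else 0.0
            c = four_way_components(
                beta0=p[0], beta1=p[1], sigma2=max(p[k_ols], 1e-12),
                theta1=p[k_ols + 1], theta2=p[k_ols + 2], theta3=p[k_ols + 3],
                a=spec.a, a_star=spec.a_star, m_star=m_star, cov_term=cov_term,
            )
            return np.array([c[k] for k in _COMPONENTS])

        eps = 1e-6
        J = np.zeros((len(_COMPONENTS), params.size))
        base = comp_vec(params)
        for j in range(params.size):
            dp = params.copy()
            h = eps * max(1.0, abs(params[j]))
            dp[j] += h
            J[:, j] = (comp_vec(dp) - base) / h
        var = J @ Sigma @ J.T
        se = {k: float(np.sqrt(max(var[i, i], 0.0))) for i, k in enumerate(_COMPONENTS)}
        lo = {k: est[k] - 1.96 * se[k] for k in _COMPONENTS}
        hi = {k: est[k] + 1.96 * se[k] for k in _COMPONENTS}
        pvals = {
            k: float(2.0 * stats.norm.sf(abs(est[k]) / se[k])) if se[k] > 0 else np.nan
            for k in _COMPONENTS
        }
        prop_ci = None

    if abs(est["te"]) < np.finfo(float).eps:
        logger.warning("decompose: total effect ~ 0; proportion mediated undefined")
        prop = None
        total_med = None
    else:
        prop = est["pie"] / est["te"]
        total_med = (est["pie"] + est["int_med"]) / est["te"]
    significant = bool(
        np.isfinite(pvals.get("te", np.nan))
        and np.isfinite(pvals.get("pie", np.nan))
        and pvals["te"] < 0.05
        and pvals["pie"] < 0.05
    )
    return FourWayResult(
        exposure=models.exposure,
        mediator=models.mediator,
        estimates=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p=pvals,
        proportion_mediated=prop,
        proportion_mediated_ci=prop_ci,
        total_mediated=total_med,
        significant=significant,
        ci_method=spec.ci_method,
    )


def exposure_associations(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    exposure_kind: str | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted OLS of each protein on the exposure (beta, se, p)."""
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    covariates = [c for c in covariates if c != exposure]
    A, _ = encode_exposure(cohort, exposure, exposure_kind)
    C = design_matrix(cohort, covariates).to_numpy(float)
    X = np.column_stack([np.ones(len(A)), A, C])
    Y = matrix.loc[cohort.index].to_numpy(float)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    dof = len(A) - X.shape[1]
    s2 = (resid**2).sum(axis=0) / dof
    XtX_inv_11 = np.linalg.inv(X.T @ X)[1, 1]
    se = np.sqrt(s2 * XtX_inv_11)
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return pd.DataFrame({"beta": beta, "se": se, "p": p}, index=matrix.columns)


def screen_mediators(
    exposure_p: pd.Series, outcome_p: pd.Series, alpha: float = 0.05
) -> list[str]:
    """Mediator candidates: significant in both legs (exposure->protein and
    protein->outcome) at ``alpha`` each."""
    shared = exposure_p.index.intersection(outcome_p.index)
    ok = (exposure_p.loc[shared] < alpha) & (outcome_p.loc[shared] < alpha)
    return shared[ok].tolist()


def filter_interaction_mediators(
    results: list[FourWayResult], alpha: float = 0.05
) -> list[FourWayResult]:
    """Optionally drop mediators whose mediated interaction is significant.

    A significant INTmed means the exposure effect transmitted through the
    mediator depends on exposure level, which muddies a pure-indirect-effect
    reading; some analyses exclude such mediators before aggregation.  Off
    by default — call explicitly to apply it.
    """
    kept = []
    for r in results:
        p_int = r.p.get("int_med", np.nan)
        if np.isfinite(p_int) and p_int < alpha:
            logger.info(
                "filter_interaction_mediators: dropping %s (INTmed p=%.3g)",
                r.mediator, p_int,
            )
            continue
        kept.append(r)
    return kept


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    retained: list[str]
    excluded: list[str] = field(default_factory=list)


def pca_aggregate(
    mediator_matrix: pd.DataFrame,
    results: list[FourWayResult] | None = None,
) -> PCAResult:
    """PCA of candidate mediators after the opposing-sign exclusion.

    Mediators whose PIE and CDE point estimates disagree in sign are dropped
    (their direct and indirect pathways oppose, so a shared component would
    conflate them).  Columns are standardized; components with correlation-
    scale eigenvalue > 1 are retained (Kaiser criterion; if none passes, the
    first component is kept with a warning).  Scores are standardized to
    SD 1; loadings are eigenvectors scaled by sqrt(eigenvalue).
    """
    excluded = []
    cols = list(mediator_matrix.columns)
    if results:
        by_med = {r.mediator: r for r in results}
        keep = []
        for c in cols:
            r = by_med.get(c)
            if r is not None and np.sign(r.estimates["pie"]) != np.sign(r.estimates["cde"]):
                excluded.append(c)
            else:
                keep.append(c)
        cols = keep
    if len(cols) < 2:
        raise ValueError("need >= 2 mediators after the opposing-sign exclusion")
    X = mediator_matrix[cols].to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Xs, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_keep = int(np.sum(eigval > 1.0))
    if n_keep == 0:
        logger.warning("pca_aggregate: no component passes Kaiser; retaining the first")
        n_keep = 1
    comp_names = [f"PC{i + 1}" for i in range(n_keep)]
    scores = Xs @ eigvec[:, :n_keep]
    scores = scores / scores.std(axis=0, ddof=1)
    loadings = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    return PCAResult(
        scores=pd.DataFrame(scores, index=mediator_matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_names),
        eigenvalues=eigval,
        retained=comp_names,
        excluded=excluded,
    )


def mediate_via_pca(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    spec: FourWaySpec | None = None,
    exposure_kind: str | None = None,
):
    """Four-way decomposition with each retained PCA score as the mediator.

    Returns ``(results, combined_proportion)``.  With a single retained
    component this is exactly :func:`decompose` on that score.  With several
    the combined proportion sums the component PIEs over the mean TE — an
    approximation (the decomposition is nonlinear even for orthogonal
    scores), flagged as such.
    """
    work = cohort.join(scores)
    results = []
    for comp in scores.columns:
        models = fit_models(work, exposure, comp, covariates, exposure_kind=exposure_kind)
        results.append(decompose(models, spec))
    tes = [r.estimates["te"] for r in results]
    pies = [r.estimates["pie"] for r in results]
    if len(results) == 1:
        combined = results[0].proportion_mediated
    else:
        logger.warning(
            "mediate_via_pca: combining %d components by PIE summation (approximate)",
            len(results),
        )
        mean_te = float(np.mean(tes))
        combined = float(np.sum(pies) / mean_te) if mean_te != 0 else None
    return results, combined
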