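"""Clinical, protein, combined and single-marker Cox risk models.

The clinical model is chosen by bidirectional stepwise search minimizing the
partial-likelihood AIC over the nine baseline covariates; the protein model
applies LASSO-penalized Cox regression to the FDR-significant scan hits with
the penalty chosen by cross-validated partial-likelihood deviance
(Verweij–van Houwelingen), then refits the surviving proteins unpenalized;
the combined model runs the stepwise search over the union of both models'
features.  Evaluation is derivation-fit / replication-evaluate: models are
frozen after fitting, and `evaluate` only computes linear predictors.

Reported metrics: Harrell's C-index with bootstrap CI, IPCW time-dependent
cumulative/dynamic AUC on a 2–10-year horizon grid, integrated
discrimination improvement (IDI) versus a reference model at the 10-year
horizon, a paired-bootstrap C-index comparison p-value, and a Youden-optimal
risk cutoff with Kaplan-Meier log-rank split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from ._cox import CoxError, breslow_cumhaz, cox_loglik, cumhaz_at, fit_cox
from .design import DEFAULT_COVARIATES, covariate_blocks, design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "ModelEval",
    "fit_clinical",
    "fit_protein",
    "fit_combined",
    "evaluate",
    "evaluate_single_marker",
    "youden_cutoff",
]


@dataclass
class RiskModel:
    """A frozen Cox risk model: selected features and their coefficients.

    ``features`` are original cohort/protein names; ``coef`` lives on the
    expanded design columns.  Protein columns are standardized with the
    training-set mean/SD stored in ``scaling``.
    """

    kind: str  # clinical | protein | combined | single
    features: list[str]
    coef: pd.Series
    scaling: dict[str, tuple[float, float]]
    baseline: tuple[np.ndarray, np.ndarray]
    train_time: np.ndarray
    train_event: np.ndarray
    trace: list = field(default_factory=list)

    def _design(self, cohort: pd.DataFrame, matrix: pd.DataFrame | None) -> pd.DataFrame:
        cov_feats = [f for f in self.features if matrix is None or f not in matrix.columns]
        cov_feats = [f for f in cov_feats if f in cohort.columns or "[" not in f]
        parts = []
        if cov_feats:
            parts.append(design_matrix(cohort, cov_feats))
        if matrix is not None:
            prots = [f for f in self.features if f in matrix.columns]
            if prots:
                P = matrix.loc[cohort.index, prots].astype(float).copy()
                for p in prots:
                    mu, sd = self.scaling[p]
                    P[p] = (P[p] - mu) / sd
                parts.append(P)
        D = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)
        return D.reindex(columns=self.coef.index, fill_value=0.0)

    def linear_predictor(self, cohort: pd.DataFrame, matrix: pd.DataFrame | None = None):
        """Linear predictor on new data; never refits."""
        D = self._design(cohort, matrix)
        return pd.Series(D.to_numpy() @ self.coef.to_numpy(), index=cohort.index)

    def risk_at(self, horizon: float, lp: pd.Series) -> pd.Series:
        """Absolute risk by ``horizon`` years from the Breslow baseline."""
        H0 = cumhaz_at(*self.baseline, horizon)
        with np.errstate(over="ignore"):
            return 1.0 - np.exp(-H0 * np.exp(lp))


@dataclass
class ModelEval:
    c_index: float
    c_index_ci: tuple
    td_auc: dict[int, float]
    idi: float | None = None
    idi_p: float | None = None
    c_index_vs_reference_p: float | None = None
    km_cutoff: float | None = None
    logrank_p: float | None = None


def _freeze(kind, features, coef_series, scaling, X, time, event, trace) -> RiskModel:
    baseline = breslow_cumhaz(X, time, event, coef_series.to_numpy())
    return RiskModel(
        kind=kind,
        features=list(features),
        coef=coef_series,
        scaling=scaling,
        baseline=baseline,
        train_time=time,
        train_event=event,
        trace=trace,
    )


def _drop_collinear(D: pd.DataFrame) -> pd.DataFrame:
    """Drop later columns that are linearly dependent on earlier ones."""
    X = D.to_numpy(float)
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear column %s", D.columns[j])
    return D.iloc[:, keep]


def _stepwise_aic(cohort, candidates, blocks, time, event, extra: pd.DataFrame | None):
    """Bidirectional stepwise search from the full model, minimizing AIC.

    ``candidates`` are unit names; covariates enter/leave as whole dummy
    blocks, protein columns (provided via ``extra``) individually.
    """

    def build(sel):
        parts = []
        cov = [c for c in sel if c in blocks]
        for c in cov:
            parts.append(design_matrix(cohort, [c]))
        prots = [c for c in sel if c not in blocks]
        if prots:
            parts.append(extra[prots])
        if not parts:
            return None
        return _drop_collinear(pd.concat(parts, axis=1))

    def aic(sel):
        D = build(sel)
        if D is None or D.shape[1] == 0:
            # null model: partial likelihood at beta=0 with no covariates
            return 2.0 * 0.0 - 2.0 * cox_loglik(
                np.zeros((len(cohort), 1)), time, event, [0.0]
            ), None
        fit = fit_cox(D.to_numpy(), time, event)
        return -2.0 * fit.loglik + 2.0 * D.shape[1], (D, fit)

    selected = list(candidates)
    best_aic, best_fit = aic(selected)
    trace = [("start", tuple(selected), best_aic)]
    improved = True
    while improved:
        improved = False
        moves = [("drop", c) for c in selected] + [
            ("add", c) for c in candidates if c not in selected
        ]
        best_move = None
        for action, c in moves:
            trial = [x for x in selected if x != c] if action == "drop" else selected + [c]
            try:
                a, fit = aic(trial)
            except (CoxError, np.linalg.LinAlgError):
                continue
            if a < best_aic - 1e-9:
                best_aic, best_move, best_fit = a, (action, c, trial), fit
        if best_move is not None:
            action, c, selected = best_move
            trace.append((action, c, best_aic))
            improved = True
    return selected, best_fit, best_aic, trace


def fit_clinical(
    cohort: pd.DataFrame, candidates: list[str] | None = None
) -> RiskModel:
    """Stepwise-AIC Cox model over clinical covariates."""
    candidates = list(DEFAULT_COVARIATES if candidates is None else candidates)
    blocks = covariate_blocks(cohort, candidates)
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    selected, fitpack, best_aic, trace = _stepwise_aic(
        cohort, candidates, blocks, time, event, extra=None
    )
    if fitpack is None:
        logger.warning("fit_clinical: no candidate improves over the null model")
        empty = pd.Series(dtype=float)
        return _freeze("clinical", [], empty, {}, np.zeros((len(cohort), 0)), time, event, trace)
    D, fit = fitpack
    coef = pd.Series(fit.coef, index=D.columns)
    return _freeze("clinical", selected, coef, {}, D.to_numpy(), time, event, trace)


def _cv_deviance(X, time, event, alphas, folds, seed, l1_ratio=1.0):
    """Verweij-van Houwelingen CV partial-likelihood deviance per alpha."""
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    y = Surv.from_arrays(event.astype(bool), time)
    dev = np.zeros(len(alphas))
    count = np.zeros(len(alphas), dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    n_folds_run = 0
    for tr, _ in kf.split(X):
        if event[tr].sum() < 2 or event.sum() - event[tr].sum() < 1:
            continue
        n_folds_run += 1
        net = CoxnetSurvivalAnalysis(alphas=alphas, l1_ratio=l1_ratio, fit_baseline_model=False)
        net.fit(X[tr], y[tr])
        # the path may stop early on a fold; align columns by fitted alphas
        for col, a in enumerate(net.alphas_):
            j = int(np.argmin(np.abs(alphas - a)))
            beta = net.coef_[:, col]
            ll_all = cox_loglik(X, time, event, beta)
            ll_tr = cox_loglik(X[tr], time[tr], event[tr], beta)
            dev[j] += -2.0 * (ll_all - ll_tr)
            count[j] += 1
    # only penalties evaluated in every completed fold are comparable
    dev[count < n_folds_run] = np.inf
    return dev


def fit_protein(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    fdr_hits: list[str],
    cv_folds: int = 10,
    seed: int = 0,
) -> RiskModel:
    """LASSO-Cox over FDR hits, lambda at minimum CV deviance, then an
    unpenalized refit of the nonzero-coefficient proteins."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    hits = [p for p in fdr_hits if p in matrix.columns]
    if not hits:
        raise ValueError("no FDR hits available for the protein model")
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    P = matrix.loc[cohort.index, hits].astype(float)
    scaling = {p: (float(P[p].mean()), float(P[p].std(ddof=1))) for p in hits}
    X = ((P - P.mean()) / P.std(ddof=1)).to_numpy()

    y = Surv.from_arrays(event.astype(bool), time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=50, fit_baseline_model=False)
    path.fit(X, y)
    alphas = path.alphas_
    dev = _cv_deviance(X, time, event, alphas, cv_folds, seed)
    j_min = int(np.argmin(dev))
    beta = path.coef_[:, j_min]
    nz = np.flatnonzero(beta)
    j = j_min
    while nz.size == 0 and j + 1 < len(alphas):
        j += 1  # one step down the path toward weaker penalty
        beta = path.coef_[:, j]
        nz = np.flatnonzero(beta)
        logger.warning("fit_protein: empty model at lambda_min; stepping down the path")
    if nz.size == 0:
        raise CoxError("LASSO shrank every coefficient to zero along the path")
    chosen = [hits[i] for i in nz]
    Xf = X[:, nz]
    refit = fit_cox(Xf, time, event, names=chosen)
    coef = pd.Series(refit.coef, index=chosen)
    trace = [{"alphas": alphas.tolist(), "cv_deviance": dev.tolist(), "lambda_index": j}]
    model = _freeze("protein", chosen, coef, {p: scaling[p] for p in chosen}, Xf, time, event, trace)
    return model


def fit_combined(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    clinical: RiskModel,
    protein: RiskModel,
) -> RiskModel:
    """Stepwise-AIC Cox over the union of the two models' features."""
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    cov_feats = [f for f in clinical.features]
    prot_feats = [f for f in protein.features if f in matrix.columns]
    if not cov_feats and not prot_feats:
        raise ValueError("both component models are empty")
    blocks = covariate_blocks(cohort, cov_feats) if cov_feats else {}
    P = matrix.loc[cohort.index, prot_feats].astype(float)
    for p in prot_feats:
        mu, sd = protein.scaling[p]
        P[p] = (P[p] - mu) / sd
    candidates = cov_feats + prot_feats
    selected, fitpack, best_aic, trace = _stepwise_aic(
        cohort, candidates, blocks, time, event, extra=P
    )
    if fitpack is None:
        logger.warning("fit_combined: stepwise kept nothing")
        empty = pd.Series(dtype=float)
        return _freeze("combined", [], empty, {}, np.zeros((len(cohort), 0)), time, event, trace)
    D, fit = fitpack
    coef = pd.Series(fit.coef, index=D.columns)
    scaling = {p: protein.scaling[p] for p in prot_feats if p in D.columns}
    # features = selected units (covariates by name, proteins by column)
    return _freeze("combined", selected, coef, scaling, D.to_numpy(), time, event, trace)


def _harrell_c(time, event, score):
    c = concordance_index_censored(event.astype(bool), time, score)[0]
    return float(c)


def _boot_c(time, event, score, n_boot, rng):
    n = time.size
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if event[idx].sum() == 0:
            continue
        try:
            out.append(_harrell_c(time[idx], event[idx], score[idx]))
        except ValueError:
            continue
    return np.asarray(out)


def _idi(risk_model, risk_ref, status):
    """Discrimination-slope difference between model and reference risks."""
    slope_m = risk_model[status == 1].mean() - risk_model[status == 0].mean()
    slope_r = risk_ref[status == 1].mean() - risk_ref[status == 0].mean()
    return float(slope_m - slope_r)


def youden_cutoff(risk: np.ndarray, status: np.ndarray) -> float:
    """Risk cutoff maximizing sensitivity + specificity - 1."""
    order = np.argsort(risk)
    r, s = risk[order], status[order]
    pos, neg = s.sum(), (1 - s).sum()
    # candidate cutoffs between consecutive distinct risks
    uniq = np.unique(r)
    best_j, best_cut = -np.inf, uniq[0]
    for cut in uniq:
        pred = risk > cut
        sens = (pred & (status == 1)).sum() / max(pos, 1)
        spec = ((~pred) & (status == 0)).sum() / max(neg, 1)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut = j, float(cut)
    return best_cut


def _horizon_status(time, event, horizon):
    """1 = event by horizon, 0 = event-free at horizon, -1 = censored early."""
    status = np.full(time.size, -1)
    status[(event == 1) & (time <= horizon)] = 1
    status[time >= horizon] = np.where(
        (event[time >= horizon] == 1) & (time[time >= horizon] <= horizon), 1, 0
    )
    return status


def evaluate(
    model: RiskModel,
    cohort: pd.DataFrame,
    matrix: pd.DataFrame | None = None,
    horizons: range | list = range(2, 11),
    reference: RiskModel | None = None,
    ref_matrix_needed: bool = True,
    idi_horizon: float = 10.0,
    cutoff: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> ModelEval:
    """Evaluate a frozen model on an evaluation split (no refitting).

    ``cutoff``, if given, is a pre-computed Youden risk cutoff (e.g. from
    the derivation split via :func:`youden_cutoff`); the KM log-rank test
    then splits this cohort at that cutoff.  When ``cutoff`` is None it is
    computed here at the ``idi_horizon``.
    """
    rng = np.random.default_rng(seed)
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    lp = model.linear_predictor(cohort, matrix).to_numpy()

    c = _harrell_c(time, event, lp)
    cboot = _boot_c(time, event, lp, n_boot, rng)
    c_ci = (
        (float(np.percentile(cboot, 2.5)), float(np.percentile(cboot, 97.5)))
        if cboot.size > 1
        else (np.nan, np.nan)
    )

    surv_train = Surv.from_arrays(model.train_event.astype(bool), model.train_time)
    surv_test = Surv.from_arrays(event.astype(bool), time)
    td = {}
    tmax = time[event == 0].max() if (event == 0).any() else time.max()
    for h in horizons:
        has_events = ((event == 1) & (time <= h)).any()
        at_risk = (time > h).any()
        if not has_events or not at_risk or h >= tmax:
            logger.warning("evaluate: horizon %s y undefined; reported as missing", h)
            td[int(h)] = float("nan")
            continue
        try:
            auc, _ = cumulative_dynamic_auc(surv_train, surv_test, lp, [float(h)])
            td[int(h)] = float(auc[0])
        except ValueError as exc:
            logger.warning("evaluate: td-AUC at %s y failed: %s", h, exc)
            td[int(h)] = float("nan")

    idi = idi_p = comp_p = None
    risk = model.risk_at(idi_horizon, pd.Series(lp, index=cohort.index)).to_numpy()
    status = _horizon_status(time, event, idi_horizon)
    usable = status >= 0
    if reference is not None:
        lp_ref = reference.linear_predictor(
            cohort, matrix if ref_matrix_needed else None
        ).to_numpy()
        risk_ref = reference.risk_at(idi_horizon, pd.Series(lp_ref, index=cohort.index)).to_numpy()
        if usable.sum() and status[usable].sum() > 0:
            idi = _idi(risk[usable], risk_ref[usable], status[usable])
            # bootstrap p for IDI and paired C-index difference
            idis, cdiffs = [], []
            n = time.size
            for _ in range(n_boot):
                idx = rng.integers(0, n, n)
                if event[idx].sum() == 0:
                    continue
                st = status[idx]
                us = st >= 0
                if us.sum() and st[us].sum() > 0 and (st[us] == 0).sum() > 0:
                    idis.append(_idi(risk[idx][us], risk_ref[idx][us], st[us]))
                try:
                    cdiffs.append(
                        _harrell_c(time[idx], event[idx], lp[idx])
                        - _harrell_c(time[idx], event[idx], lp_ref[idx])
                    )
                except ValueError:
                    continue
            if len(idis) > 1:
                arr = np.asarray(idis)
                frac = min(np.mean(arr <= 0), np.mean(arr >= 0))
                idi_p = float(min(1.0, 2.0 * max(frac, 1.0 / len(arr))))
            if len(cdiffs) > 1:
                arr = np.asarray(cdiffs)
                frac = min(np.mean(arr <= 0), np.mean(arr >= 0))
                comp_p = float(min(1.0, 2.0 * max(frac, 1.0 / len(arr))))

    km_cut = logrank_p = None
    if usable.sum() and status[usable].sum() > 0 and (status[usable] == 0).sum() > 0:
        km_cut = cutoff if cutoff is not None else youden_cutoff(risk[usable], status[usable])
        hi = risk > km_cut
        if hi.any() and (~hi).any():
            from lifelines.statistics import logrank_test

            lr = logrank_test(time[hi], time[~hi], event[hi], event[~hi])
            logrank_p = float(lr.p_value)
    return ModelEval(
        c_index=c,
        c_index_ci=c_ci,
        td_auc=td,
        idi=idi,
        idi_p=idi_p,
        c_index_vs_reference_p=comp_p,
        km_cutoff=km_cut,
        logrank_p=logrank_p,
    )


def fit_single_marker(cohort: pd.DataFrame, matrix: pd.DataFrame, protein: str) -> RiskModel:
    """Univariate Cox model on one standardized protein."""
    if protein not in matrix.columns:
        raise KeyError(f"protein {protein!r} not in matrix")
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    v = matrix.loc[cohort.index, protein].to_numpy(float)
    mu, sd = float(v.mean()), float(v.std(ddof=1))
    x = ((v - mu) / sd)[:, None]
    fit = fit_cox(x, time, event, names=[protein])
    coef = pd.Series(fit.coef, index=[protein])
    return _freeze("single", [protein], coef, {protein: (mu, sd)}, x, time, event, [])


def evaluate_single_marker(
    protein: str,
    cohort_train: pd.DataFrame,
    matrix_train: pd.DataFrame,
    cohort_eval: pd.DataFrame | None = None,
    matrix_eval: pd.DataFrame | None = None,
    **eval_kwargs,
):
    """Fit a univariate protein model and evaluate it (ModelEval).

    If no evaluation split is given the training split is evaluated
    (apparent performance).
    """
    model = fit_single_marker(cohort_train, matrix_train, protein)
    if cohort_eval is None:
        cohort_eval, matrix_eval = cohort_train, matrix_train
    ev = evaluate(model, cohort_eval, matrix_eval, **eval_kwargs)
    return model, ev
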