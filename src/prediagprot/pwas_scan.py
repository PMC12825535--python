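"""Proteome-wide Cox proportional-hazards association scan.

Each protein enters its own Cox model (standardized to SD 1 within the
analysis set) alongside the nine baseline adjustment covariates.  Wald
statistics, Bonferroni flags against a declared family size, BH-FDR
q-values, and a correlation-based Schoenfeld proportional-hazards check are
reported per protein.  Sensitivity variants re-run the scan after excluding
cases diagnosed within a lead-time window (reverse causation) or with extra
adjustment covariates (e.g. serum creatinine).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._cox import CoxError, fit_cox, schoenfeld_residuals
from .design import DEFAULT_COVARIATES, design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "scan",
    "ph_check",
    "sensitivity_exclude_early",
    "sensitivity_adjust",
    "bonferroni_threshold",
]


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    return alpha / family_size


def ph_check(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    term: int = 0,
    threshold: float = 0.01,
):
    """Schoenfeld-residual proportional-hazards test for one model term.

    Correlates the term's Schoenfeld residuals with the rank of the event
    times; the p-value is the exact t-test on the Pearson correlation.
    Returns ``(p, violated)``; with fewer than three events the test is
    indeterminate and ``(nan, False)`` is returned.
    """
    times, resid = schoenfeld_residuals(X, time, event, beta)
    d = times.size
    if d < 3:
        return float("nan"), False
    r = resid[:, term]
    tr = stats.rankdata(times)
    if np.std(r) == 0 or np.std(tr) == 0:
        return float("nan"), False
    corr = float(np.corrcoef(r, tr)[0, 1])
    if not np.isfinite(corr):
        return float("nan"), False
    corr = min(max(corr, -1.0), 1.0)
    tstat = corr * np.sqrt((d - 2) / max(1.0 - corr**2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(tstat), d - 2))
    return p, p < threshold


def scan(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    family_size: int | None = None,
    ph_threshold: float = 0.01,
    compute_ph: bool = True,
) -> pd.DataFrame:
    """One Cox fit per protein; returns a ScanResult table.

    Columns: protein, log_hr, se, hr, ci_low, ci_high, p, fdr_q,
    bonferroni_sig, schoenfeld_p, ph_violation, n_events, converged.
    Hazard ratios are per SD of NPX within the analysis set.  The Bonferroni
    threshold uses ``family_size`` if declared (e.g. 2911 to reproduce the
    full-panel threshold), otherwise the number of proteins tested.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    matrix = matrix.loc[cohort.index]
    C = design_matrix(cohort, covariates).to_numpy()
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events in analysis set")
    if matrix.shape[1] == 0:
        raise ValueError("no proteins to scan")

    # warm start: covariate-only fit shared across proteins
    if C.shape[1]:
        base = fit_cox(C, time, event)
        init0 = np.r_[0.0, base.coef]
    else:
        init0 = np.zeros(1)

    rows = []
    for prot in matrix.columns:
        v = matrix[prot].to_numpy(float)
        rec = {"protein": prot, "n_events": int(event.sum())}
        sd = v.std(ddof=1)
        try:
            if not np.isfinite(v).all():
                raise CoxError("missing values in protein column")
            if sd == 0:
                raise CoxError("constant protein")
            x = (v - v.mean()) / sd
            X = np.column_stack([x, C])
            fit = fit_cox(X, time, event, init=init0)
            b, se = fit.coef[0], fit.se[0]
            rec.update(
                log_hr=b,
                se=se,
                hr=np.exp(b),
                ci_low=np.exp(b - 1.959963984540054 * se),
                ci_high=np.exp(b + 1.959963984540054 * se),
                p=float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan,
                converged=fit.converged,
            )
            if compute_ph:
                sp, viol = ph_check(X, time, event, fit.coef, term=0, threshold=ph_threshold)
            else:
                sp, viol = np.nan, False
            rec.update(schoenfeld_p=sp, ph_violation=viol)
        except (CoxError, np.linalg.LinAlgError) as exc:
            logger.warning("scan: fit failed for %s: %s", prot, exc)
            rec.update(
                log_hr=np.nan, se=np.nan, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                p=np.nan, converged=False, schoenfeld_p=np.nan, ph_violation=False,
            )
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("protein", drop=False)
    out.index.name = None

    m = family_size if family_size is not None else int(out["p"].notna().sum())
    thresh = bonferroni_threshold(alpha, m)
    out["bonferroni_sig"] = out["p"] < thresh
    out["fdr_q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr_q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out.attrs["alpha"] = alpha
    out.attrs["family_size"] = m
    out.attrs["bonferroni_threshold"] = thresh
    return out


def sensitivity_exclude_early(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    covariates: list[str] | None = None,
    min_lead: float = 2.0,
    **scan_kwargs,
) -> pd.DataFrame:
    """Re-scan after removing cases diagnosed within ``min_lead`` years.

    Participants with an event at lead time < ``min_lead`` are removed
    entirely; the multiplicity family defaults to the full protein count so
    thresholds match the primary scan.
    """
    is_early = (cohort["event"] == 1) & (cohort["lead_time"] < min_lead)
    kept = cohort[~is_early]
    if (kept["event"] == 1).sum() == 0:
        raise ValueError("no cases remain after early-case exclusion")
    scan_kwargs.setdefault("family_size", matrix.shape[1])
    return scan(kept, matrix.loc[kept.index], covariates, **scan_kwargs)


def sensitivity_adjust(
    cohort: pd.DataFrame,
    matrix: pd.DataFrame,
    extra_covariates: list[str],
    covariates: list[str] | None = None,
    **scan_kwargs,
) -> pd.DataFrame:
    """Scan with an augmented covariate set (e.g. serum creatinine)."""
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    missing = [c for c in extra_covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"extra covariates not in cohort: {missing}")
    return scan(cohort, matrix, covariates + list(extra_covariates), **scan_kwargs)
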