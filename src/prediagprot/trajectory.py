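"""Pre-diagnostic trajectory reconstruction from baseline-only measurements.

With a single blood draw per participant, the time from draw to diagnosis
(lead time) serves as a surrogate progression axis: cases sampled at
different lead times trace out a population-level trajectory.  The stages
are: match each case to 10 event-free controls on sex (exact) and baseline
age (nearest); residualize NPX on covariates fitted on controls only;
convert case values to z-scores against each case's own matched controls;
smooth (lead time, z) points per protein with degree-1 LOESS on a common
grid; call abnormality-threshold crossings; and cluster the smoothed curves
(Chebyshev distance + complete linkage, with a k-means sensitivity check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
import statsmodels.api as sm

from .design import DEFAULT_COVARIATES, design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedSet",
    "match_controls",
    "residualize",
    "zscore_cases",
    "default_grid",
    "fit_loess",
    "build_trajectories",
    "call_abnormal",
    "cluster_trajectories",
]

ABNORMAL_Z = 0.45  # z-score above which a protein is considered abnormally elevated


@dataclass
class MatchedSet:
    case_id: str
    control_ids: list[str]
    case_age: float
    case_sex: str


def match_controls(cohort: pd.DataFrame, ratio: int = 10, seed: int = 0):
    """Match each case to ``ratio`` event-free controls by age and sex.

    Sex is matched exactly; controls are taken nearest in baseline age,
    without replacement across cases, processing cases in a seeded random
    order (ties in age broken by a seeded shuffle).  If the pool runs short
    a smaller set is returned and logged.
    """
    rng = np.random.default_rng(seed)
    cases = cohort[cohort["event"] == 1]
    controls = cohort[cohort["event"] == 0]
    order = rng.permutation(len(cases))
    used: set = set()
    sets = []
    for idx in order:
        case = cases.iloc[idx]
        pool = controls[(controls["sex"] == case["sex"]) & (~controls.index.isin(used))]
        if pool.empty:
            logger.warning("match_controls: no controls left for case %s", case.name)
            sets.append(MatchedSet(case.name, [], case["age"], case["sex"]))
            continue
        agediff = (pool["age"] - case["age"]).abs().to_numpy()
        tiebreak = rng.permutation(len(pool))
        chosen = pool.index.to_numpy()[np.lexsort((tiebreak, agediff))][:ratio]
        if chosen.size < ratio:
            logger.warning(
                "match_controls: only %d controls for case %s", chosen.size, case.name
            )
        used.update(chosen)
        sets.append(MatchedSet(case.name, list(chosen), case["age"], case["sex"]))
    # restore cohort case order for determinism of downstream iteration
    pos = {cid: i for i, cid in enumerate(cases.index)}
    sets.sort(key=lambda s: pos[s.case_id])
    return sets


def residualize(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Remove covariate effects from NPX, fitting on controls only.

    Per protein, an OLS of NPX on covariates (plus intercept) is fitted on
    event-free participants; residuals ``observed - predicted`` are returned
    for everyone, so case-specific signal is not absorbed into the fit.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    D = design_matrix(cohort.loc[matrix.index], covariates)
    X = np.column_stack([np.ones(len(D)), D.to_numpy()])
    names = ["intercept"] + D.columns.tolist()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular covariate design; collinear columns: {bad}")
    ctrl = (cohort.loc[matrix.index, "event"] == 0).to_numpy()
    Y = matrix.to_numpy(float)
    B, *_ = np.linalg.lstsq(X[ctrl], Y[ctrl], rcond=None)
    resid = Y - X @ B
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def zscore_cases(adjusted: pd.DataFrame, matched: list[MatchedSet]) -> pd.DataFrame:
    """Case z-scores against each case's own matched controls.

    ``z = (case - mean(controls)) / sd(controls)`` with the n-1 denominator.
    A zero control SD yields NaN for that case/protein and is logged.
    """
    rows = {}
    for mset in matched:
        if len(mset.control_ids) < 2:
            logger.warning("zscore_cases: <2 controls for case %s; skipped", mset.case_id)
            continue
        ctrl = adjusted.loc[mset.control_ids]
        mu = ctrl.mean(axis=0)
        sd = ctrl.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "zscore_cases: zero control SD for case %s in %d proteins",
                mset.case_id,
                int(zero.sum()),
            )
            sd = sd.replace(0.0, np.nan)
        rows[mset.case_id] = (adjusted.loc[mset.case_id] - mu) / sd
    return pd.DataFrame(rows).T


def default_grid(step: float = 0.25, max_years: float = 15.0) -> np.ndarray:
    """Lead-time grid, descending from ``max_years`` to 0."""
    return np.round(np.arange(max_years, -step / 2, -step), 10)


def fit_loess(
    lead_times,
    z,
    span: float = 0.75,
    grid: np.ndarray | None = None,
    min_points: int = 10,
) -> pd.Series:
    """Degree-1 LOESS curve of z against lead time on a common grid.

    Local linear regression with tricube weights; predictions are restricted
    to the observed lead-time range (no extrapolation).  If the span window
    would hold fewer than ~4 points it is widened and logged.
    """
    lt = np.asarray(lead_times, dtype=float)
    zz = np.asarray(z, dtype=float)
    keep = np.isfinite(lt) & np.isfinite(zz)
    lt, zz = lt[keep], zz[keep]
    if lt.size < min_points:
        raise ValueError(f"need >= {min_points} points for LOESS, got {lt.size}")
    if grid is None:
        grid = default_grid()
    span_eff = span
    if span * lt.size < 4:
        span_eff = min(1.0, 4 / lt.size)
        logger.info("fit_loess: widened span %.2f -> %.2f", span, span_eff)
    inside = (grid >= lt.min()) & (grid <= lt.max())
    xvals = np.sort(grid[inside])  # lowess wants ascending xvals
    fitted = sm.nonparametric.lowess(
        zz, lt, frac=span_eff, it=0, xvals=xvals, is_sorted=False
    )
    curve = pd.Series(fitted, index=xvals).reindex(np.sort(grid[inside])[::-1])
    curve.index.name = "lead_time"
    return curve


def build_trajectories(
    zmat: pd.DataFrame,
    lead_times: pd.Series,
    span: float = 0.75,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """LOESS curves for every protein on the identical grid (grid x proteins)."""
    lt = lead_times.loc[zmat.index]
    curves = {}
    for prot in zmat.columns:
        curves[prot] = fit_loess(lt, zmat[prot], span=span, grid=grid)
    return pd.DataFrame(curves)


def call_abnormal(curve: pd.Series, threshold: float = ABNORMAL_Z) -> dict:
    """Threshold crossings and the earliest sustained abnormality onset.

    ``curve`` is indexed by lead time descending toward 0.  Crossings are
    the maximal grid intervals with ``z > threshold`` as ``(start, end)``
    lead times (start > end).  The sustained onset is the start of the final
    exceedance run only if that run persists to the end of the grid (i.e.
    up to diagnosis); otherwise ``None``.
    """
    lead = curve.index.to_numpy(float)
    above = curve.to_numpy(float) > threshold
    crossings = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            crossings.append((float(lead[i]), float(lead[j])))
            i = j + 1
        else:
            i += 1
    onset = None
    if crossings and above[-1]:
        onset = crossings[-1][0]
    return {"crossings": crossings, "onset": onset}


def chebyshev_distance(curve_a: pd.Series, curve_b: pd.Series) -> float:
    """Maximum absolute difference between two curves on their shared grid."""
    return float(np.max(np.abs(curve_a.to_numpy() - curve_b.to_numpy())))


@dataclass
class ClusterResult:
    labels: pd.Series
    method: str
    linkage_matrix: np.ndarray | None = None
    centroids: np.ndarray | None = None


def cluster_trajectories(
    curves: pd.DataFrame,
    k: int = 4,
    method: str = "hierarchical",
    seed: int = 0,
) -> ClusterResult:
    """Cluster trajectory curves into ``k`` groups.

    ``hierarchical``: Chebyshev (maximum) distance between curves, complete
    linkage, tree cut at ``k`` — deterministic, with distance ties resolved
    by input order.  ``kmeans``: Lloyd's algorithm on the raw prediction
    vectors with a seeded 10-start initialization.
    """
    if curves.shape[1] < k:
        raise ValueError(f"need >= {k} curves to form {k} clusters")
    V = curves.to_numpy(float).T  # proteins x grid
    if method == "hierarchical":
        Z = linkage(pdist(V, metric="chebyshev"), method="complete")
        labels = fcluster(Z, t=k, criterion="maxclust")
        return ClusterResult(
            labels=pd.Series(labels, index=curves.columns), method=method, linkage_matrix=Z
        )
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(V) + 1
        return ClusterResult(
            labels=pd.Series(labels, index=curves.columns),
            method=method,
            centroids=km.cluster_centers_,
        )
    raise ValueError(f"unknown clustering method: {method!r}")
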