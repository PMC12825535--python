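"""Cohort exclusions, protein missingness filter, kNN imputation, 80/20 split.

The imputation follows the gene-wise k-nearest-neighbour scheme of the R
``impute`` package: neighbours are *proteins* (variables), distances are
root-mean-square differences over rows where both proteins are observed, and
a missing cell is filled with the average of the k nearest proteins' values
in that row.  A protein with no overlapping observations with any peer falls
back to its own observed mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import DEFAULT_COVARIATES

logger = logging.getLogger(__name__)

__all__ = ["apply_exclusions", "filter_proteins", "knn_impute", "split_cohort"]


def apply_exclusions(
    cohort: pd.DataFrame, required_covariates: list[str] | None = None
):
    """Drop prior-cancer participants, then rows missing any covariate.

    The cascade is order-dependent: a row failing both rules counts only in
    the first step.  Returns ``(filtered_cohort, log)`` where ``log`` is a
    list of ``{"step", "removed"}`` records in cascade order.
    """
    required = list(DEFAULT_COVARIATES if required_covariates is None else required_covariates)
    log = []
    out = cohort
    if "prior_cancer" in out.columns:
        keep = out["prior_cancer"].fillna(0).astype(int) == 0
        log.append({"step": "prior_cancer", "removed": int((~keep).sum())})
        out = out[keep]
    complete = out[required].notna().all(axis=1)
    log.append({"step": "missing_covariates", "removed": int((~complete).sum())})
    out = out[complete]
    if out.empty:
        raise ValueError("exclusion cascade removed every participant")
    return out.copy(), log


def filter_proteins(matrix: pd.DataFrame, max_missing: float = 0.20) -> pd.DataFrame:
    """Drop proteins missing in strictly more than ``max_missing`` of rows.

    A protein missing in exactly ``max_missing`` of rows is retained; column
    order is preserved.
    """
    frac = matrix.isna().mean(axis=0)
    keep = frac.index[frac.to_numpy() <= max_missing]
    dropped = matrix.shape[1] - len(keep)
    if dropped:
        logger.info("filter_proteins: dropped %d of %d proteins", dropped, matrix.shape[1])
    return matrix.loc[:, keep]


def _protein_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete RMS distance between protein columns.

    Pairs with no common observed row get distance +inf.
    """
    obs = ~np.isnan(X)
    F = np.where(obs, X, 0.0)
    O = obs.astype(float)
    counts = O.T @ O
    sq = (F**2).T @ O  # sum over common rows of x_p^2 (rows where q observed)
    cross = F.T @ F
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (sq + sq.T - 2.0 * cross) / counts
        d = np.sqrt(np.clip(msd, 0.0, None))
    d[counts == 0] = np.inf
    return d


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Protein-wise kNN imputation (see module docstring).

    Deterministic given the input; observed cells are left untouched.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    out = X.copy()
    if not np.isnan(X).any():
        return matrix.copy()
    dist = _protein_distances(X)
    np.fill_diagonal(dist, np.inf)
    col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    grand_mean = np.nanmean(X)
    obs = ~np.isnan(X)
    for j in range(p):
        miss_rows = np.flatnonzero(~obs[:, j])
        if miss_rows.size == 0:
            continue
        order = np.argsort(dist[j], kind="stable")
        finite = order[np.isfinite(dist[j, order])]
        if finite.size == 0:
            fallback = col_means[j] if np.isfinite(col_means[j]) else grand_mean
            logger.warning(
                "knn_impute: protein %s has no complete peers; using its mean",
                matrix.columns[j],
            )
            out[miss_rows, j] = fallback
            continue
        for i in miss_rows:
            donors = finite[obs[i, finite]][:k]
            if donors.size == 0:
                fallback = col_means[j] if np.isfinite(col_means[j]) else grand_mean
                out[i, j] = fallback
            else:
                out[i, j] = X[i, donors].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def split_cohort(cohort: pd.DataFrame, frac: float = 0.80, seed: int = 0):
    """Simple random derivation/replication split of participant ids.

    The derivation set holds ``floor(frac * N)`` participants; the split is
    unstratified, disjoint and exhaustive, and reproducible from ``seed``.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    ids = cohort.index.to_numpy()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_deriv = int(np.floor(frac * len(ids)))
    deriv = ids[np.sort(perm[:n_deriv])]
    repl = ids[np.sort(perm[n_deriv:])]
    return deriv, repl
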