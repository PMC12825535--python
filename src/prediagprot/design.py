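"""Covariate design-matrix construction shared across pipeline stages.

The cohort table keeps covariates in their natural types (strings for sex,
ethnicity, smoking, alcohol; floats and 0/1 flags elsewhere); every model
stage converts them to a numeric design through :func:`design_matrix` so all
stages agree on the encoding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The nine baseline adjustment covariates used throughout the pipeline.
DEFAULT_COVARIATES = [
    "age",
    "sex",
    "ethnicity",
    "deprivation_index",
    "smoking",
    "alcohol",
    "bmi",
    "hypertension",
    "diabetes",
]

CATEGORICAL = {"sex", "ethnicity", "smoking", "alcohol"}


def design_matrix(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) for ``covariates``.

    Categorical covariates are expanded to treatment-coded indicators with
    the alphabetically first level as reference, named ``var[level]``.
    If ``columns`` is given, the output is reindexed to exactly those columns
    (absent indicator levels filled with 0) so a design built on one split
    can be reproduced on another.
    """
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise KeyError(f"covariates not in cohort: {missing}")
    parts = []
    for cov in covariates:
        col = cohort[cov]
        if cov in CATEGORICAL or col.dtype == object:
            levels = sorted(col.dropna().astype(str).unique())
            for level in levels[1:]:
                parts.append(
                    (col.astype(str) == level).astype(float).rename(f"{cov}[{level}]")
                )
        else:
            parts.append(col.astype(float).rename(cov))
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)
    if columns is not None:
        out = out.reindex(columns=list(columns), fill_value=0.0)
    return out


def covariate_blocks(cohort: pd.DataFrame, covariates: list[str]) -> dict[str, list[str]]:
    """Map each covariate to its design-matrix column names."""
    blocks = {}
    for cov in covariates:
        cols = design_matrix(cohort, [cov]).columns.tolist()
        blocks[cov] = cols
    return blocks


def standardize(x: pd.Series | np.ndarray) -> np.ndarray:
    """Center to mean 0, scale to SD 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd
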