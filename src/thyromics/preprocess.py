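"""Intensity preprocessing: run-day median rescaling, missingness filter, log10.

The order mirrors the measurement workflow: platform drift is removed by
dividing each feature by its median within every acquisition run day, features
with too many missing values are dropped (strictly less than 40% missing are
kept), and the remaining raw intensities are log10-transformed for the
mixed-model screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["runday_normalize", "missingness_filter", "log10_transform"]

logger = logging.getLogger(__name__)


def runday_normalize(matrix: pd.DataFrame, run_days) -> pd.DataFrame:
    """Rescale each feature by its median within every run day.

    Parameters
    ----------
    matrix : DataFrame
        Raw-scale intensities, samples x features, NaN = missing.
    run_days : Series or array-like
        Run-day label per sample, aligned with ``matrix`` rows.

    After rescaling, every feature's per-run-day median equals 1 wherever it
    is defined.  A run day in which a feature has no observed value (or a
    zero median, which cannot be divided out) leaves those cells missing.
    """
    run_days = pd.Series(np.asarray(run_days), index=matrix.index)
    medians = matrix.groupby(run_days, observed=True).median()
    aligned = medians.reindex(run_days.to_numpy()).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        values = matrix.to_numpy(dtype=float) / aligned
    zero_median = aligned == 0
    if zero_median.any():
        n_cells = int(zero_median.sum())
        logger.warning("run-day median of 0 for %d cells; set to missing", n_cells)
        values[zero_median] = np.nan
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def missingness_filter(matrix: pd.DataFrame, threshold: float = 0.40):
    """Keep features with strictly less than ``threshold`` missing values.

    Returns the filtered matrix together with the kept-feature list.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        logger.warning("missingness_filter received an empty matrix")
        return matrix.copy(), list(matrix.columns)
    frac_missing = matrix.isna().mean(axis=0)
    kept = list(matrix.columns[frac_missing < threshold])
    logger.info("missingness filter kept %d of %d features", len(kept), matrix.shape[1])
    return matrix[kept], kept


def log10_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Base-10 logarithm of all positive values; non-positive become missing."""
    values = matrix.to_numpy(dtype=float).copy()
    nonpos = ~np.isnan(values) & (values <= 0)
    if nonpos.any():
        logger.warning("%d non-positive intensities set to missing before log10",
                       int(nonpos.sum()))
        values[nonpos] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log10(values)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
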