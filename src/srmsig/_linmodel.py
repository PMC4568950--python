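"""Additive two-way fixed-effects least squares on long-format data.

Shared by standard-protein summarization (peptide + run) and protein-level
summarization (peptide + subject).  On balanced complete data the per-column
summaries reduce to per-column means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def additive_summaries(
    y: np.ndarray, rows: np.ndarray, cols: np.ndarray, col_levels=None
) -> pd.Series:
    """Fit ``y ~ intercept + row_effect + col_effect`` by least squares on
    observed cells and return one summary per column level.

    The summary for column *c* is the model prediction at *c* averaged over
    all row levels (intercept + col effect + mean row effect), i.e. the
    column abundance on a common row basis.  Columns with no observed cell
    get NaN.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    rows = np.asarray(rows)[ok]
    cols = np.asarray(cols)[ok]
    if col_levels is None:
        col_levels = pd.unique(np.asarray(cols))
    col_levels = list(col_levels)
    if y.size == 0:
        return pd.Series(np.nan, index=col_levels, dtype=float)

    row_levels, row_idx = np.unique(rows, return_inverse=True)
    obs_col_levels, col_idx = np.unique(cols, return_inverse=True)
    n, r, c = y.size, len(row_levels), len(obs_col_levels)

    if r == 1:
        # single row level: summary is the per-column mean
        sums = np.bincount(col_idx, weights=y, minlength=c)
        counts = np.bincount(col_idx, minlength=c)
        means = pd.Series(sums / counts, index=obs_col_levels)
        return means.reindex(col_levels)

    # dummy coding, first level of each factor dropped
    X = np.zeros((n, 1 + (r - 1) + (c - 1)))
    X[:, 0] = 1.0
    for i in range(n):
        if row_idx[i] > 0:
            X[i, row_idx[i]] = 1.0
        if col_idx[i] > 0:
            X[i, r - 1 + col_idx[i]] = 1.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept = beta[0]
    row_eff = np.concatenate([[0.0], beta[1:r]])
    col_eff = np.concatenate([[0.0], beta[r:]])
    summaries = intercept + row_eff.mean() + col_eff
    out = pd.Series(summaries, index=obs_col_levels, dtype=float)
    return out.reindex(col_levels)
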