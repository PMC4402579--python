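"""Sample filtering and between-sample quantile normalization.

Both expression matrices are reduced to their shared, fully observed
sample set and then quantile-normalized independently, so that every
sample (column) carries the identical empirical distribution: the
across-sample mean of the order statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def drop_incomplete_samples(
    matrix: pd.DataFrame, partner: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to the shared samples with no missing data.

    A sample is kept only if it is present in both matrices and has no
    missing value in either.  Both returned matrices share an identical
    ordered sample set (order of ``matrix``'s columns).

    Raises
    ------
    ValueError
        If no sample survives the intersection and completeness filter.
    """
    common = [s for s in matrix.columns if s in set(partner.columns)]
    if not common:
        raise ValueError("matrices share no sample IDs")
    complete = [
        s
        for s in common
        if not matrix[s].isna().any() and not partner[s].isna().any()
    ]
    if not complete:
        raise ValueError("no shared sample is complete in both matrices")
    return matrix[complete], partner[complete]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization.

    Each column is mapped onto the reference distribution given by the
    across-column mean of order statistics.  Ties within a column receive
    the mean of the reference values spanned by the tied ranks, so the
    map is well defined and rank-preserving.

    Raises
    ------
    ValueError
        If the matrix has fewer than 2 features or fewer than 2 samples,
        or contains missing values.
    """
    values = matrix.to_numpy(dtype=float)
    n_features, n_samples = values.shape
    if n_features < 2:
        raise ValueError("quantile normalization needs at least 2 features")
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; filter samples first")

    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        normalized = reference.copy()
        # ties: average the reference values over each tied span
        sorted_col = col[order]
        span_start = 0
        for i in range(1, n_features + 1):
            if i == n_features or sorted_col[i] != sorted_col[span_start]:
                if i - span_start > 1:
                    normalized[span_start:i] = reference[span_start:i].mean()
                span_start = i
        out[order, j] = normalized
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
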