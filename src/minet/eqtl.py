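"""cis eQTL mapping between miRNA and gene expression.

For every miRNA-gene pair whose genomic loci lie within a cis window
(default 1 Mb, minimal interval distance, inclusive), gene expression is
regressed on miRNA expression with a simple linear model
``y = a + b x + e`` and the slope tested with a two-sided t test on
n - 2 degrees of freedom.  Benjamini-Hochberg FDR is applied jointly
across all tested cis pairs and pairs below the FDR cutoff become the
seed eQTLs of the downstream network expansion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_WINDOW = 1_000_000
DEFAULT_FDR = 0.01

EQTL_COLUMNS = ["mirna_id", "gene_id", "beta", "t_stat", "p_value", "fdr", "is_seed"]


def cis_pairs(
    mirnas: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> list[tuple[str, str]]:
    """Enumerate miRNA-gene pairs within ``window`` bp of each other.

    ``mirnas`` and ``genes`` are BED-like frames (chrom/start/end/name,
    0-based half-open).  Distance is the minimal gap between the two
    intervals (0 when they overlap), compared inclusively; strand is
    ignored.  Pairs on different chromosomes are never emitted.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    for frame, label in ((mirnas, "miRNA"), (genes, "gene")):
        if frame["name"].duplicated().any():
            dup = frame.loc[frame["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate {label} feature ID: {dup!r}")

    pairs: list[tuple[str, str]] = []
    for chrom, msub in mirnas.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        ms, me = msub["start"].to_numpy()[:, None], msub["end"].to_numpy()[:, None]
        gs, ge = gsub["start"].to_numpy()[None, :], gsub["end"].to_numpy()[None, :]
        gap = np.maximum(0, np.maximum(gs - me, ms - ge))
        rows, cols = np.nonzero(gap <= window)
        mnames = msub["name"].to_numpy()
        gnames = gsub["name"].to_numpy()
        pairs.extend((mnames[r], gnames[c]) for r, c in zip(rows, cols))
    return pairs


def fit_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple linear regression of y on x; returns (beta, t, p).

    Closed-form OLS slope with intercept; two-sided p from the Student-t
    survival function on n - 2 df.  A perfect fit yields p = 0 by
    convention (the t statistic is +/- inf).

    Raises
    ------
    ValueError
        If n < 3 or x is constant (undefined slope test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need matched vectors with at least 3 observations")
    if x.min() == x.max():
        raise ValueError("constant predictor: slope undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    rss = float(resid @ resid)
    df = n - 2
    if rss == 0.0:
        t_stat = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
    else:
        se = np.sqrt(rss / df / sxx)
        t_stat = beta / se
    p_value = float(2.0 * stats.t.sf(abs(t_stat), df)) if np.isfinite(t_stat) else 0.0
    if t_stat == 0.0:
        p_value = 1.0
    return beta, float(t_stat), p_value


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compute_pair_stats(
    mirna: pd.DataFrame, gene: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Vectorized per-pair OLS over an explicit pair list.

    Equivalent to calling :func:`fit_pair` on every pair; implemented
    through correlation identities for speed.  Pairs whose miRNA or gene
    has constant expression are skipped with a warning.
    """
    if list(mirna.columns) != list(gene.columns):
        raise ValueError("matrices must share an identical ordered sample set")
    n = mirna.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")

    x = mirna.to_numpy(dtype=float)
    y = gene.to_numpy(dtype=float)
    x_const = x.min(axis=1) == x.max(axis=1)
    y_const = y.min(axis=1) == y.max(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))

    midx = {fid: i for i, fid in enumerate(mirna.index)}
    gidx = {fid: i for i, fid in enumerate(gene.index)}
    kept, skipped = [], 0
    for m, g in pairs:
        if x_const[midx[m]] or y_const[gidx[g]]:
            skipped += 1
        else:
            kept.append((midx[m], gidx[g], m, g))
    if skipped:
        warnings.warn(f"skipped {skipped} pair(s) with constant expression")
    if not kept:
        return pd.DataFrame(columns=EQTL_COLUMNS[:5])

    mi = np.array([k[0] for k in kept])
    gi = np.array([k[1] for k in kept])
    r = np.einsum("ij,ij->i", xc[mi], yc[gi]) / (sx[mi] * sy[gi])
    r = np.clip(r, -1.0, 1.0)
    beta = r * sy[gi] / sx[mi]
    df = n - 2
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    p = np.where(np.isfinite(t_stat), p, 0.0)
    return pd.DataFrame(
        {
            "mirna_id": [k[2] for k in kept],
            "gene_id": [k[3] for k in kept],
            "beta": beta,
            "t_stat": t_stat,
            "p_value": p,
        }
    )


def call_eqtls(
    mirna: pd.DataFrame,
    gene: pd.DataFrame,
    mirna_coords: pd.DataFrame,
    gene_coords: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    fdr_cutoff: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Full cis eQTL scan: pair enumeration, per-pair OLS, joint BH-FDR.

    Returns the full association table (one row per tested pair) with an
    ``is_seed`` flag marking pairs with fdr < ``fdr_cutoff``.  Only
    features present in both the expression matrix and the coordinate
    file are tested.
    """
    mcoords = mirna_coords[mirna_coords["name"].isin(set(mirna.index))]
    gcoords = gene_coords[gene_coords["name"].isin(set(gene.index))]
    pairs = cis_pairs(mcoords, gcoords, window)
    if not pairs:
        warnings.warn("no cis pairs within the window; empty eQTL table")
        return pd.DataFrame(columns=EQTL_COLUMNS)
    table = compute_pair_stats(mirna, gene, pairs)
    if table.empty:
        return pd.DataFrame(columns=EQTL_COLUMNS)
    # the t test can underflow to p = 0 for extreme signal; clamp into
    # BH's (0, 1] domain at the smallest positive double
    table["fdr"] = bh_fdr(np.maximum(table["p_value"].to_numpy(), 5e-324))
    table["is_seed"] = table["fdr"] < fdr_cutoff
    return table.reset_index(drop=True)
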