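"""Two-graph-guided multitask Lasso (MtLasso2G).

Estimates the coefficient matrix B (J miRNAs x K genes) linking miRNA
expression X (n x J) to gene expression Y (n x K) by minimizing

    ||Y - X B||_F^2
    + lambda * ||B||_1
    + gamma1 * sum_{(m,l) in E_gene}  w_ml  sum_j |B[j,m] - sign(r_ml) B[j,l]|
    + gamma2 * sum_{(f,g) in E_mirna} w_fg  sum_k |B[f,k] - sign(r_fg) B[g,k]|

where E_gene / E_mirna are thresholded Pearson co-expression graphs
over genes and miRNAs, w = |r| and the sign makes the fusion coherent
with the direction of co-expression: positively correlated features are
pushed toward equal coefficients, negatively correlated ones toward
equal magnitude with opposite sign.

The solver is FISTA on the smooth surrogate obtained by Nesterov (Huber)
smoothing of both fusion terms, with the l1 term handled exactly by
soft-thresholding and a monotone restart so the recorded (surrogate)
objective never increases.  Nonzero entries of the fitted B are the
multitask eQTLs; the co-expression edges among features and labels that
participate in them are the association subnetworks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CorrelationGraph:
    """Thresholded signed Pearson co-expression graph.

    Edges are stored as parallel index arrays into ``nodes``; each edge
    carries the underlying correlation r, with weight |r| and sign(r).
    """

    nodes: list[str]
    edges_i: np.ndarray  # int indices into nodes
    edges_j: np.ndarray
    r: np.ndarray  # Pearson correlation per edge

    @property
    def weight(self) -> np.ndarray:
        return np.abs(self.r)

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.r)

    @property
    def n_edges(self) -> int:
        return int(self.r.size)

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [
            (self.nodes[i], self.nodes[j], float(rv))
            for i, j, rv in zip(self.edges_i, self.edges_j, self.r)
        ]


@dataclass
class MtLassoConfig:
    """Hyperparameters of the fused multitask fit.

    ``lam``/``gamma1``/``gamma2`` weight the l1, gene-graph-fusion and
    miRNA-graph-fusion penalties on the standardized scale.  With the
    string "auto" (the default) they are selected jointly by k-fold
    cross-validated prediction error over the log-grid
    ``cv_lambda_grid`` x lambda_max by ``cv_gamma_ratios`` x lambda,
    with the one-SE rule resolving statistically indistinguishable fits
    toward the sparser model (larger lambda, then smaller gamma).
    ``smoothing_mu`` is the Huber smoothing width of the fusion terms.
    ``nonzero_eps`` (default ``nonzero_rel`` = 0.1 x max|B|) separates
    identified eQTLs from the halo of small coefficients that smoothed
    fusion and correlated-predictor over-selection leave on
    co-expression neighbours of true effects (a thresholded-lasso
    post-step).
    """

    lam: float | str = "auto"
    gamma1: float | str = "auto"
    gamma2: float | str = "auto"
    corr_threshold: float = 0.7
    smoothing_mu: float = 1e-3
    max_iter: int = 2000
    tol: float = 1e-8
    nonzero_eps: float | None = None
    nonzero_rel: float = 0.1
    cv_folds: int = 5
    cv_lambda_grid: tuple[float, ...] = (0.5, 0.3, 0.2, 0.1)
    cv_gamma_ratios: tuple[float, ...] = (0.02, 0.1, 0.5)
    cv_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lam", "gamma1", "gamma2"):
            value = getattr(self, name)
            if isinstance(value, str):
                if value != "auto":
                    raise ValueError(f"{name} must be a number or 'auto'")
            elif value < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tol <= 0 or self.smoothing_mu <= 0:
            raise ValueError("tol and smoothing_mu must be positive")
        if not 0 <= self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in [0, 1]")


def build_correlation_graph(
    matrix: pd.DataFrame, threshold: float
) -> CorrelationGraph:
    """Thresholded Pearson graph over the features (rows) of a matrix.

    An edge joins every feature pair with |r| >= threshold; constant
    features cannot carry a correlation and are excluded with a warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    values = matrix.to_numpy(dtype=float)
    constant = values.min(axis=1) == values.max(axis=1)
    if constant.any():
        warnings.warn(
            f"excluded {int(constant.sum())} constant feature(s) from the graph"
        )
    nodes = list(matrix.index)
    keep = np.flatnonzero(~constant)
    if keep.size < 2:
        return CorrelationGraph(nodes, np.empty(0, int), np.empty(0, int), np.empty(0))
    corr = np.corrcoef(values[keep])
    iu, ju = np.triu_indices(keep.size, k=1)
    mask = np.abs(corr[iu, ju]) >= threshold
    return CorrelationGraph(
        nodes=nodes,
        edges_i=keep[iu[mask]],
        edges_j=keep[ju[mask]],
        r=corr[iu, ju][mask],
    )


def _difference_operator(graph: CorrelationGraph) -> np.ndarray:
    """E x V matrix D with rows w_e * (1_i - sign(r_e) 1_j).

    The fusion penalty over coefficients indexed by the graph's nodes is
    then the entrywise l1 norm of D applied along that axis.
    """
    d = np.zeros((graph.n_edges, len(graph.nodes)))
    if graph.n_edges:
        rows = np.arange(graph.n_edges)
        d[rows, graph.edges_i] = graph.weight
        d[rows, graph.edges_j] = -graph.sign * graph.weight
    return d


def _huber(z: np.ndarray, mu: float) -> float:
    a = np.abs(z)
    return float(np.sum(np.where(a <= mu, z**2 / (2 * mu), a - mu / 2)))


def objective(
    b: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    g_gene: CorrelationGraph | None,
    g_mirna: CorrelationGraph | None,
    lam: float,
    gamma1: float,
    gamma2: float,
) -> dict[str, float]:
    """Exact (unsmoothed) penalized objective, term by term.

    ``b`` is J x K, ``x`` n x J, ``y`` n x K.  The gene graph must be
    defined over the K labels and the miRNA graph over the J features.
    Returns the four terms and their total.
    """
    b = np.asarray(b, dtype=float)
    j_dim, k_dim = b.shape
    if x.shape[1] != j_dim or y.shape[1] != k_dim or x.shape[0] != y.shape[0]:
        raise ValueError("dimension mismatch between B, X and Y")
    resid = y - x @ b
    terms = {
        "rss": float(np.sum(resid**2)),
        "l1": float(lam * np.sum(np.abs(b))),
        "gene_fusion": 0.0,
        "mirna_fusion": 0.0,
    }
    if g_gene is not None and gamma1 > 0 and g_gene.n_edges:
        if len(g_gene.nodes) != k_dim:
            raise ValueError("gene graph nodes do not match the K labels")
        d1 = _difference_operator(g_gene)
        terms["gene_fusion"] = float(gamma1 * np.sum(np.abs(b @ d1.T)))
    if g_mirna is not None and gamma2 > 0 and g_mirna.n_edges:
        if len(g_mirna.nodes) != j_dim:
            raise ValueError("miRNA graph nodes do not match the J features")
        d2 = _difference_operator(g_mirna)
        terms["mirna_fusion"] = float(gamma2 * np.sum(np.abs(d2 @ b)))
    terms["total"] = sum(terms.values())
    return terms


def _zscore(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, keepdims=True)
    sd[sd == 0.0] = 1.0  # constant columns stay zero after centering
    return centered / sd


def lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest l1 weight at which the all-zero matrix is optimal
    (gamma = 0): 2 * max |X^T Y|."""
    return float(2.0 * np.max(np.abs(x.T @ y)))


def _fista(
    x: np.ndarray,
    y: np.ndarray,
    d1: np.ndarray | None,
    d2: np.ndarray | None,
    lam: float,
    gamma1: float,
    gamma2: float,
    mu: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[float]]:
    """Monotone FISTA on the Huber-smoothed objective.

    Returns the iterate and the recorded surrogate-objective sequence
    (smoothed fusion terms + exact RSS and l1), which is non-increasing
    by construction of the restart rule.
    """
    n, j_dim = x.shape
    k_dim = y.shape[1]
    xtx = x.T @ x
    xty = x.T @ y

    lipschitz = 2.0 * float(np.linalg.norm(xtx, 2))
    if d1 is not None and gamma1 > 0:
        lipschitz += gamma1 * float(np.linalg.norm(d1, 2)) ** 2 / mu
    if d2 is not None and gamma2 > 0:
        lipschitz += gamma2 * float(np.linalg.norm(d2, 2)) ** 2 / mu
    lipschitz = max(lipschitz, 1e-12)

    def smooth_grad(b: np.ndarray) -> np.ndarray:
        grad = 2.0 * (xtx @ b - xty)
        if d1 is not None and gamma1 > 0:
            z = b @ d1.T
            grad += gamma1 * np.clip(z / mu, -1.0, 1.0) @ d1
        if d2 is not None and gamma2 > 0:
            z = d2 @ b
            grad += gamma2 * d2.T @ np.clip(z / mu, -1.0, 1.0)
        return grad

    def surrogate(b: np.ndarray) -> float:
        value = float(np.sum((y - x @ b) ** 2)) + lam * float(np.sum(np.abs(b)))
        if d1 is not None and gamma1 > 0:
            value += gamma1 * _huber(b @ d1.T, mu)
        if d2 is not None and gamma2 > 0:
            value += gamma2 * _huber(d2 @ b, mu)
        return value

    b = np.zeros((j_dim, k_dim))
    z = b.copy()
    t = 1.0
    trace = [surrogate(b)]
    for _ in range(max_iter):
        candidate = z - smooth_grad(z) / lipschitz
        candidate = np.sign(candidate) * np.maximum(np.abs(candidate) - lam / lipschitz, 0.0)
        f_candidate = surrogate(candidate)
        if f_candidate > trace[-1]:
            # monotone restart: re-step from the best iterate
            z = b.copy()
            t = 1.0
            candidate = z - smooth_grad(z) / lipschitz
            candidate = np.sign(candidate) * np.maximum(
                np.abs(candidate) - lam / lipschitz, 0.0
            )
            f_candidate = surrogate(candidate)
            if f_candidate > trace[-1]:
                break  # at numerical stationarity
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t**2)) / 2.0
        z = candidate + ((t - 1.0) / t_next) * (candidate - b)
        b = candidate
        t = t_next
        previous = trace[-1]
        trace.append(f_candidate)
        denom = max(abs(previous), 1e-12)
        if abs(previous - f_candidate) / denom < tol:
            break
    else:
        warnings.warn(
            f"fused multitask fit hit max_iter={max_iter}; "
            f"final objective {trace[-1]:.6g}"
        )
    return b, trace


def fit(
    x_matrix: pd.DataFrame,
    y_matrix: pd.DataFrame,
    cfg: MtLassoConfig,
    g_gene: CorrelationGraph | None = None,
    g_mirna: CorrelationGraph | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit the fused multitask model on feature x sample matrices.

    ``x_matrix`` holds the J miRNAs, ``y_matrix`` the K genes, both
    features x samples with an identical ordered sample set.  Columns
    (features) are z-scored internally and coefficients are reported on
    the standardized scale.  Graphs default to thresholded Pearson
    graphs built from each matrix at ``cfg.corr_threshold``.

    Returns (B as a J x K DataFrame, info dict with the hyperparameters
    used and the recorded objective trace).
    """
    if list(x_matrix.columns) != list(y_matrix.columns):
        raise ValueError("matrices must share an identical ordered sample set")
    if x_matrix.isna().any().any() or y_matrix.isna().any().any():
        raise ValueError("expression matrices contain NaN")

    if g_gene is None:
        g_gene = build_correlation_graph(y_matrix, cfg.corr_threshold)
    if g_mirna is None:
        g_mirna = build_correlation_graph(x_matrix, cfg.corr_threshold)
    if list(g_gene.nodes) != list(y_matrix.index):
        raise ValueError("gene graph nodes must match the gene matrix features")
    if list(g_mirna.nodes) != list(x_matrix.index):
        raise ValueError("miRNA graph nodes must match the miRNA matrix features")

    x = _zscore(x_matrix.to_numpy(dtype=float).T)  # n x J
    y = _zscore(y_matrix.to_numpy(dtype=float).T)  # n x K

    cfg = _resolve_hyperparameters(x, y, cfg, g_gene, g_mirna)
    d1 = _difference_operator(g_gene) if g_gene.n_edges else None
    d2 = _difference_operator(g_mirna) if g_mirna.n_edges else None
    b, trace = _fista(
        x,
        y,
        d1,
        d2,
        cfg.lam,
        cfg.gamma1,
        cfg.gamma2,
        cfg.smoothing_mu,
        cfg.max_iter,
        cfg.tol,
    )
    b_frame = pd.DataFrame(b, index=x_matrix.index, columns=y_matrix.index)
    info = {
        "lam": cfg.lam,
        "gamma1": cfg.gamma1,
        "gamma2": cfg.gamma2,
        "objective_trace": trace,
        "n_iter": len(trace) - 1,
        "final_objective": trace[-1],
    }
    return b_frame, info


def _resolve_hyperparameters(
    x: np.ndarray,
    y: np.ndarray,
    cfg: MtLassoConfig,
    g_gene: CorrelationGraph,
    g_mirna: CorrelationGraph,
) -> MtLassoConfig:
    if any(getattr(cfg, name) == "auto" for name in ("lam", "gamma1", "gamma2")):
        lam, gamma = select_hyperparameters(x, y, cfg, g_gene, g_mirna)
    else:
        lam = gamma = None
    lam = float(cfg.lam) if cfg.lam != "auto" else lam
    gamma1 = float(cfg.gamma1) if cfg.gamma1 != "auto" else gamma
    gamma2 = float(cfg.gamma2) if cfg.gamma2 != "auto" else gamma
    return replace(cfg, lam=lam, gamma1=gamma1, gamma2=gamma2)


def select_hyperparameters(
    x: np.ndarray,
    y: np.ndarray,
    cfg: MtLassoConfig,
    g_gene: CorrelationGraph | None = None,
    g_mirna: CorrelationGraph | None = None,
) -> tuple[float, float]:
    """Joint (lambda, gamma) selection by k-fold CV with the one-SE rule.

    Candidates are the grid ``cv_lambda_grid`` x lambda_max crossed with
    ``cv_gamma_ratios`` x lambda (gamma1 = gamma2 during the search).
    Mean held-out squared prediction error is computed per candidate;
    among candidates within one standard error of the minimum, the
    sparsest wins: largest lambda first, smallest gamma second.
    """
    n = x.shape[0]
    folds = min(cfg.cv_folds, n)
    rng = np.random.default_rng(cfg.cv_seed)
    assignment = rng.permutation(n) % folds
    lmax = lambda_max(x, y)
    candidates = [
        (frac * lmax, ratio * frac * lmax)
        for frac in sorted(cfg.cv_lambda_grid, reverse=True)
        for ratio in sorted(cfg.cv_gamma_ratios)
    ]
    d1 = (
        _difference_operator(g_gene)
        if g_gene is not None and g_gene.n_edges
        else None
    )
    d2 = (
        _difference_operator(g_mirna)
        if g_mirna is not None and g_mirna.n_edges
        else None
    )

    mean_err, se_err = [], []
    for lam, gamma in candidates:
        fold_errors = []
        for fold in range(folds):
            train, test = assignment != fold, assignment == fold
            b, _ = _fista(
                x[train],
                y[train],
                d1,
                d2,
                lam,
                gamma,
                gamma,
                cfg.smoothing_mu,
                cfg.max_iter,
                cfg.tol,
            )
            resid = y[test] - x[test] @ b
            fold_errors.append(float(np.mean(resid**2)))
        fold_errors = np.asarray(fold_errors)
        mean_err.append(fold_errors.mean())
        se_err.append(fold_errors.std(ddof=1) / np.sqrt(folds) if folds > 1 else 0.0)

    mean_err = np.asarray(mean_err)
    best = int(np.argmin(mean_err))
    cutoff = mean_err[best] + se_err[best]
    # candidates are ordered sparsest-first: lambda descending, gamma ascending
    for i, (lam, gamma) in enumerate(candidates):
        if mean_err[i] <= cutoff:
            logger.info("selected lambda=%.4g gamma=%.4g by CV", lam, gamma)
            return lam, gamma
    return candidates[best]


def extract_eqtls(b_matrix: pd.DataFrame, cfg: MtLassoConfig) -> pd.DataFrame:
    """Nonzero coefficients as (mirna_id, gene_id, coefficient) rows.

    Entries with |b| > nonzero_eps are reported, sorted by |coefficient|
    descending.  The default cutoff is ``nonzero_rel`` x max|b|: the
    smoothed fusion penalties leave a halo of small but genuinely
    nonzero coefficients on co-expression neighbours of true effects,
    so "nonzero" in the eQTL sense means clear of that halo, not merely
    clear of floating-point zero.  Set ``nonzero_eps`` explicitly (e.g.
    0.0) to report every numerically nonzero entry.
    """
    values = b_matrix.to_numpy(dtype=float)
    max_abs = float(np.max(np.abs(values))) if values.size else 0.0
    eps = cfg.nonzero_eps if cfg.nonzero_eps is not None else cfg.nonzero_rel * max_abs
    rows, cols = np.nonzero(np.abs(values) > eps)
    table = pd.DataFrame(
        {
            "mirna_id": [str(b_matrix.index[r]) for r in rows],
            "gene_id": [str(b_matrix.columns[c]) for c in cols],
            "coefficient": values[rows, cols],
        }
    )
    table = table.reindex(
        table["coefficient"].abs().sort_values(ascending=False, kind="stable").index
    )
    return table.reset_index(drop=True)


def association_subnetworks(
    b_matrix: pd.DataFrame,
    g_gene: CorrelationGraph,
    g_mirna: CorrelationGraph,
    cfg: MtLassoConfig,
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]]]:
    """Correlation edges around the perturbed miRNAs and genes.

    A feature/label is perturbed when it participates in at least one
    extracted eQTL.  The gene subnetwork is the correlations AMONG the
    perturbed genes (both endpoints perturbed); the miRNA subnetwork
    keeps every correlation edge touching a perturbed miRNA, so it can
    introduce correlated partners that carry no eQTL themselves —
    mirroring the asymmetric integration rules downstream.  Returns
    (miRNA edges, gene edges) as (a, b, r) triples.
    """
    eqtls = extract_eqtls(b_matrix, cfg)
    perturbed_mirnas = set(eqtls["mirna_id"])
    perturbed_genes = set(eqtls["gene_id"])
    mirna_edges = [
        e
        for e in g_mirna.edge_list()
        if e[0] in perturbed_mirnas or e[1] in perturbed_mirnas
    ]
    gene_edges = [
        e for e in g_gene.edge_list() if e[0] in perturbed_genes and e[1] in perturbed_genes
    ]
    return mirna_edges, gene_edges
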