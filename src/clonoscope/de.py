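"""Normalization, benign-subset gating, and differential expression.

The DE test is a logistic-regression likelihood-ratio test: for each gene,
the model logit P(group) = b0 + b1 * expression is compared against the
intercept-only model (1 df, chi-squared). P-values are Bonferroni-corrected
over the genes actually tested; a gene is called differentially expressed
when the adjusted p-value clears alpha AND the natural-log fold change
clears the threshold (0.3 for within-clone comparisons, 0.25 for
cluster/microenvironment comparisons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import chi2

from .io import CountMatrix
from .clonotypes import CloneAssignment

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
PROB_CLAMP = 1e-10
MAX_IRLS_ITER = 100
IRLS_TOL = 1e-12


@dataclass(frozen=True)
class DEThresholds:
    min_abs_logfc: float = 0.3
    alpha: float = 0.05
    min_pct: float = 0.1

    def __post_init__(self):
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 <= self.min_pct <= 1.0):
            raise ValueError("min_pct must lie in [0, 1]")


#: threshold presets: clone comparisons use |logFC| > 0.3, microenvironment
#: (per-cluster) comparisons use |logFC| > 0.25
CLONE_THRESHOLDS = DEThresholds(min_abs_logfc=0.3)
MICROENV_THRESHOLDS = DEThresholds(min_abs_logfc=0.25)


@dataclass
class DEResult:
    gene: str
    logfc: float
    p: float
    p_adj: float
    pct_a: float
    pct_b: float

    @property
    def direction(self) -> str:
        return "up" if self.logfc > 0 else "down"


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Attach the log-normalized view: ln(1 + scale * count / library size).

    All-zero cells are dropped with a warning (their library size is
    undefined). Returns a CountMatrix; the input is returned unchanged when
    no cells are dropped apart from gaining `.normalized`.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    libsize = np.asarray(counts.counts.sum(axis=0)).ravel().astype(float)
    keep = libsize > 0
    if not keep.all():
        n_drop = int((~keep).sum())
        logger.warning("dropping %d all-zero cells before normalization", n_drop)
        sub = counts.counts[:, keep]
        counts = CountMatrix(
            genes=list(counts.genes),
            cells=[c for c, k in zip(counts.cells, keep) if k],
            counts=sp.csr_matrix(sub),
        )
        libsize = libsize[keep]
    norm = sp.csc_matrix(counts.counts, dtype=float, copy=True)
    inv = scale / libsize
    norm.data *= np.repeat(inv, np.diff(norm.indptr))
    np.log1p(norm.data, out=norm.data)
    counts.normalized = sp.csr_matrix(norm)
    return counts


def gate_subsets(
    norm: CountMatrix,
    assignments: list[CloneAssignment],
    cd4: str = "CD4",
    cd8a: str = "CD8A",
    foxp3: str = "FOXP3",
) -> list[CloneAssignment]:
    """Fill the subset field of clone assignments by marker gating.

    Dominant-clone cells are malignant regardless of markers. Among
    polyclonal TCR+ cells, precedence is: FOXP3+ regulatory, then CD8A+
    FOXP3- cytotoxic, then CD4+ FOXP3- helper, else other. Cells without a
    TCR stay ungated (subset=None kept as "other" for no_tcr cells is NOT
    applied; they are left out of the benign subsets).
    """
    for name, sym in (("cd4", cd4), ("cd8a", cd8a), ("foxp3", foxp3)):
        if not norm.has_gene(sym):
            raise ValueError(f"gating gene for {name} ({sym!r}) not present in matrix")
    cd4_v = norm.gene_row(cd4, normalized=True)
    cd8_v = norm.gene_row(cd8a, normalized=True)
    fox_v = norm.gene_row(foxp3, normalized=True)
    pos = {c: i for i, c in enumerate(norm.cells)}
    for a in assignments:
        i = pos.get(a.cell_id)
        if a.clonality == "dominant":
            a.subset = "malignant"
        elif a.clonality == "polyclonal":
            if i is None:
                a.subset = "other"
            elif fox_v[i] > 0:
                a.subset = "regulatory"
            elif cd8_v[i] > 0:
                a.subset = "cytotoxic"
            elif cd4_v[i] > 0:
                a.subset = "helper"
            else:
                a.subset = "other"
        else:
            a.subset = None
    return assignments


def _null_loglik(y: np.ndarray) -> float:
    p0 = min(max(y.mean(), PROB_CLAMP), 1 - PROB_CLAMP)
    return float(y.sum() * np.log(p0) + (len(y) - y.sum()) * np.log(1 - p0))


def lr_test(expr: np.ndarray, labels: np.ndarray) -> float:
    """Likelihood-ratio p-value for logistic regression of labels on expr.

    Fit by IRLS (max 100 iterations, fitted probabilities clamped to
    [1e-10, 1 - 1e-10]); compared against the intercept-only model with one
    degree of freedom. Constant expression carries no information: p = 1.
    """
    y = np.asarray(labels, dtype=float).ravel()
    x = np.asarray(expr, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("expr and labels must have the same length")
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    uniq = np.unique(y)
    if not np.array_equal(uniq, [0.0, 1.0]):
        if uniq.size == 1:
            raise ValueError("labels contain a single class")
        raise ValueError("labels must be binary 0/1")
    if np.ptp(x) == 0.0:
        return 1.0

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll1 = -np.inf
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta
        mu = np.clip(expit(eta), PROB_CLAMP, 1 - PROB_CLAMP)
        w = mu * (1 - mu)
        # 2x2 normal equations for the Newton step
        Xw = X * w[:, None]
        H = X.T @ Xw
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < IRLS_TOL:
            break
    eta = X @ beta
    mu = np.clip(expit(eta), PROB_CLAMP, 1 - PROB_CLAMP)
    ll1 = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
    stat = max(0.0, 2.0 * (ll1 - _null_loglik(y)))
    return float(max(chi2.sf(stat, df=1), P_FLOOR))


def log_fold_change(
    norm: CountMatrix, cells_a: np.ndarray, cells_b: np.ndarray, pseudo: float = 1.0
) -> np.ndarray:
    """Per-gene natural-log fold change of expm1-means (group a minus b).

    logfc[g] = ln(mean_a(expm1(norm)) + pseudo) - ln(mean_b(expm1(norm)) + pseudo)
    """
    a_idx = np.asarray(cells_a)
    b_idx = np.asarray(cells_b)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    mat = norm.normalized
    if mat is None:
        raise ValueError("matrix has no normalized view; call log_normalize first")
    mean_a = _expm1_mean(mat, a_idx)
    mean_b = _expm1_mean(mat, b_idx)
    return np.log(mean_a + pseudo) - np.log(mean_b + pseudo)


def _expm1_mean(mat: sp.csr_matrix, cols: np.ndarray) -> np.ndarray:
    sub = sp.csc_matrix(mat[:, cols])
    sub = sub.copy()
    np.expm1(sub.data, out=sub.data)
    return np.asarray(sub.sum(axis=1)).ravel() / len(cols)


def _pct_expressed(mat: sp.csr_matrix, cols: np.ndarray) -> np.ndarray:
    sub = mat[:, cols]
    return np.asarray((sub > 0).sum(axis=1)).ravel() / len(cols)


def de_genes(
    norm: CountMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    thresholds: DEThresholds = CLONE_THRESHOLDS,
) -> list[DEResult]:
    """Differentially expressed genes between two disjoint cell groups.

    Only genes expressed (count > 0) in at least min_pct of either group are
    tested; Bonferroni multiplies by the number tested. Returns the genes
    with p_adj < alpha and |logfc| > min_abs_logfc, sorted by p_adj
    ascending then |logfc| descending.
    """
    a_idx = np.asarray(cells_a, dtype=int)
    b_idx = np.asarray(cells_b, dtype=int)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups must be disjoint")
    mat = norm.normalized
    if mat is None:
        raise ValueError("matrix has no normalized view; call log_normalize first")

    pct_a = _pct_expressed(mat, a_idx)
    pct_b = _pct_expressed(mat, b_idx)
    tested = np.nonzero(np.maximum(pct_a, pct_b) >= thresholds.min_pct)[0]
    n_tested = tested.size
    if n_tested == 0:
        return []

    logfc = log_fold_change(norm, a_idx, b_idx)
    labels = np.concatenate([np.ones(a_idx.size), np.zeros(b_idx.size)])
    cols = np.concatenate([a_idx, b_idx])
    expr_block = np.asarray(mat[np.ix_(tested, cols)].todense())

    results: list[DEResult] = []
    for row, g_i in enumerate(tested):
        p = lr_test(expr_block[row], labels)
        p_adj = min(1.0, p * n_tested)
        if p_adj < thresholds.alpha and abs(logfc[g_i]) > thresholds.min_abs_logfc:
            results.append(
                DEResult(
                    gene=norm.genes[g_i],
                    logfc=float(logfc[g_i]),
                    p=p,
                    p_adj=p_adj,
                    pct_a=float(pct_a[g_i]),
                    pct_b=float(pct_b[g_i]),
                )
            )
    results.sort(key=lambda r: (r.p_adj, -abs(r.logfc), r.gene))
    return results


def deg_count_per_cluster(
    norm: CountMatrix,
    metadata,
    condition_a: set[str] | str,
    condition_b: set[str] | str,
    thresholds: DEThresholds = MICROENV_THRESHOLDS,
    cluster_col: str = "cluster",
) -> dict[str, int]:
    """Number of DEGs between two lesion-class conditions within each cluster.

    Clusters lacking cells in either condition are absent from the result
    (not reported as zero).
    """
    if isinstance(condition_a, str):
        condition_a = {condition_a}
    if isinstance(condition_b, str):
        condition_b = {condition_b}
    pos = {c: i for i, c in enumerate(norm.cells)}
    meta = metadata[metadata["cell_id"].isin(pos)]
    out: dict[str, int] = {}
    for cluster, grp in meta.groupby(cluster_col, sort=True):
        a = np.array([pos[c] for c in grp.loc[grp["lesion_class"].isin(condition_a), "cell_id"]])
        b = np.array([pos[c] for c in grp.loc[grp["lesion_class"].isin(condition_b), "cell_id"]])
        if a.size == 0 or b.size == 0:
            continue
        out[str(cluster)] = len(de_genes(norm, a, b, thresholds))
    return out


def de_to_frame(results: list[DEResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "logFC": r.logfc,
                "p": r.p,
                "p_adj": r.p_adj,
                "pct_a": r.pct_a,
                "pct_b": r.pct_b,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=["gene", "logFC", "p", "p_adj", "pct_a", "pct_b", "direction"],
    )
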