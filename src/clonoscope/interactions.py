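"""Ligand-receptor interaction scoring with a cluster-permutation null.

The interaction score for pair R between ligand cluster X and receptor
cluster Y is the arithmetic mean of the two cluster means of normalized
expression, I_R(X,Y) = (mean_X(ligand) + mean_Y(receptor)) / 2, evaluated
only when the ligand is detected in at least min_frac of X and the receptor
in at least min_frac of Y. The null shuffles cluster labels over all cells
(cluster sizes preserved); the empirical p uses the add-one estimator so it
is never exactly zero. Multiple testing is handled with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LigandReceptorPair:
    pair_id: str
    ligand_gene: str
    receptor_gene: str

    def __post_init__(self):
        if not self.ligand_gene or not self.receptor_gene:
            raise ValueError("ligand and receptor genes must be non-empty")


def read_pairs(path: str | Path) -> list[LigandReceptorPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["pair_id", "ligand_gene", "receptor_gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"pair list {path} missing columns: {missing}")
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise FormatError(f"duplicate pair_id {dup!r}")
    return [
        LigandReceptorPair(r.pair_id, r.ligand_gene.upper(), r.receptor_gene.upper())
        for r in df.itertuples(index=False)
    ]


def bundled_pairs_path() -> Path:
    return Path(__file__).parent / "data" / "pairs_demo.tsv"


def interaction_score(
    norm: CountMatrix,
    clusters: pd.Series | dict,
    pair: LigandReceptorPair,
    cluster_x: str,
    cluster_y: str,
    min_frac: float = 0.1,
) -> float | None:
    """I_R(X,Y); None when the pair fails the expression-fraction filter."""
    labels = _labels_array(norm, clusters)
    x_mask = labels == cluster_x
    y_mask = labels == cluster_y
    if not x_mask.any() or not y_mask.any():
        raise ValueError(f"empty cluster: {cluster_x if not x_mask.any() else cluster_y!r}")
    lig = norm.gene_row(pair.ligand_gene, normalized=True)
    rec = norm.gene_row(pair.receptor_gene, normalized=True)
    if (lig[x_mask] > 0).mean() < min_frac or (rec[y_mask] > 0).mean() < min_frac:
        return None
    return float((lig[x_mask].mean() + rec[y_mask].mean()) / 2.0)


def _labels_array(norm: CountMatrix, clusters) -> np.ndarray:
    if isinstance(clusters, pd.Series):
        return np.asarray(clusters.reindex(norm.cells))
    if isinstance(clusters, dict):
        return np.asarray([clusters[c] for c in norm.cells])
    arr = np.asarray(clusters)
    if arr.shape[0] != norm.n_cells:
        raise ValueError("cluster labels must cover every cell")
    return arr


def permutation_test(
    norm: CountMatrix,
    clusters,
    pair: LigandReceptorPair,
    cluster_x: str,
    cluster_y: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_frac: float = 0.1,
) -> tuple[float | None, float | None]:
    """(score, empirical p) for one pair and one ordered cluster pair.

    p = (1 + #{permuted score >= observed}) / (1 + n_perm); labels are
    shuffled over all cells, preserving cluster sizes. Returns (None, None)
    when the pair is filtered out.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    score = interaction_score(norm, clusters, pair, cluster_x, cluster_y, min_frac)
    if score is None:
        return None, None
    labels = _labels_array(norm, clusters)
    lig = norm.gene_row(pair.ligand_gene, normalized=True)
    rec = norm.gene_row(pair.receptor_gene, normalized=True)
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pl = labels[perm]
        x_mask = pl == cluster_x
        y_mask = pl == cluster_y
        s = (lig[x_mask].mean() + rec[y_mask].mean()) / 2.0
        if s >= score:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return score, float(p)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def score_interactions(
    norm: CountMatrix,
    clusters,
    pairs: list[LigandReceptorPair],
    cluster_pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Score all (pair, X, Y) combinations within one sample.

    One shared set of label permutations is used for every combination (the
    usual convention of permutation-based interaction tools); BH q-values
    are computed over all evaluated combinations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = _labels_array(norm, clusters)
    names = sorted(pd.unique(labels))
    if cluster_pairs is None:
        cluster_pairs = [(x, y) for x in names for y in names if x != y]

    genes_needed = sorted({p.ligand_gene for p in pairs} | {p.receptor_gene for p in pairs})
    for g in genes_needed:
        if not norm.has_gene(g):
            raise ValueError(f"interaction gene {g!r} not present in matrix")
    expr = {g: norm.gene_row(g, normalized=True) for g in genes_needed}

    # observed cluster means and expressed fractions
    masks = {c: labels == c for c in names}
    mean_obs = {(g, c): expr[g][m].mean() for g in genes_needed for c, m in masks.items()}
    frac_obs = {(g, c): (expr[g][m] > 0).mean() for g in genes_needed for c, m in masks.items()}

    combos = []
    for pair in pairs:
        for x, y in cluster_pairs:
            if frac_obs[(pair.ligand_gene, x)] >= min_frac and frac_obs[(pair.receptor_gene, y)] >= min_frac:
                score = (mean_obs[(pair.ligand_gene, x)] + mean_obs[(pair.receptor_gene, y)]) / 2.0
                combos.append([pair, x, y, score, 0])
    if not combos:
        return pd.DataFrame(
            columns=["pair_id", "ligand_gene", "receptor_gene", "cluster_x", "cluster_y", "score", "p_emp", "q_fdr"]
        )

    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    E = np.vstack([expr[g] for g in genes_needed])  # genes_needed x cells
    g_row = {g: i for i, g in enumerate(genes_needed)}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pl = labels[perm]
        pm = {c: (pl == c) for c in names}
        means = {c: E[:, pm[c]].mean(axis=1) for c in names}
        for combo in combos:
            pair, x, y, score, _ = combo
            s = (means[x][g_row[pair.ligand_gene]] + means[y][g_row[pair.receptor_gene]]) / 2.0
            if s >= score:
                combo[4] += 1

    rows = []
    for pair, x, y, score, n_ge in combos:
        rows.append(
            {
                "pair_id": pair.pair_id,
                "ligand_gene": pair.ligand_gene,
                "receptor_gene": pair.receptor_gene,
                "cluster_x": x,
                "cluster_y": y,
                "score": float(score),
                "p_emp": (1 + n_ge) / (1 + n_perm),
            }
        )
    df = pd.DataFrame(rows)
    df["q_fdr"] = fdr_bh(df["p_emp"].to_numpy())
    return df


def interaction_deltas(
    scores_by_sample: dict[str, pd.DataFrame],
    sample_pairs: list[tuple[str, str, str]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Between-lesion score differences per patient.

    sample_pairs: (patient_id, palpable_sample, patch_sample). The delta
    (palpable minus patch) is reported for combinations significant
    (q <= threshold) in at least one of the two samples and evaluated in
    both.
    """
    key_cols = ["pair_id", "ligand_gene", "receptor_gene", "cluster_x", "cluster_y"]
    rows = []
    for patient, palpable, patch in sample_pairs:
        if palpable not in scores_by_sample or patch not in scores_by_sample:
            raise ValueError(f"unmatched sample pairing for patient {patient!r}")
        a = scores_by_sample[palpable].set_index(key_cols)
        b = scores_by_sample[patch].set_index(key_cols)
        common = a.index.intersection(b.index)
        for key in common:
            qa, qb = a.at[key, "q_fdr"], b.at[key, "q_fdr"]
            if min(qa, qb) > q_threshold:
                continue
            rows.append(
                dict(
                    zip(key_cols, key),
                    patient_id=patient,
                    score_palpable=float(a.at[key, "score"]),
                    score_patch=float(b.at[key, "score"]),
                    delta=float(a.at[key, "score"] - b.at[key, "score"]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=key_cols + ["patient_id", "score_palpable", "score_patch", "delta"],
    )
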