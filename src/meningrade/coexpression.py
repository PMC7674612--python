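"""Weighted gene co-expression network stage.

Soft-thresholded (unsigned) Pearson adjacency, topological overlap,
average-linkage hierarchical clustering with a dynamic tree cut into gene
modules, module meta-genes (first principal component of the module's
standardized expression, sign-fixed), and grade-wise meta-gene
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import MergedCohort

__all__ = [
    "Adjacency",
    "TOMMatrix",
    "soft_threshold_adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_metagene",
    "MetaGeneMatrix",
    "compare_metagenes_by_grade",
]


@dataclass(frozen=True)
class Adjacency:
    """Symmetric gene x gene adjacency a_ij = |r_ij|^beta in [0, 1]."""

    matrix: pd.DataFrame
    beta: float

    def __post_init__(self):
        a = self.matrix.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        if self.beta < 1:
            raise ValueError("soft power beta must be >= 1")


@dataclass(frozen=True)
class TOMMatrix:
    """Topological overlap t_ij and per-gene connectivity k_i."""

    matrix: pd.DataFrame
    connectivity: pd.Series


@dataclass(frozen=True)
class MetaGeneMatrix:
    """Module x sample meta-gene scores with per-module variance explained.

    Each meta-gene is the first principal component of its module's
    gene-standardized submatrix, scaled to unit sample variance and
    sign-oriented to correlate positively with the module's mean
    expression profile.
    """

    scores: pd.DataFrame  # modules x samples
    variance_explained: pd.Series


def soft_threshold_adjacency(cohort: MergedCohort, beta: float = 6.0) -> Adjacency:
    """Unsigned adjacency a_ij = |pearson(x_i, x_j)|^beta, diagonal 1.

    Zero-variance genes get zero correlation to everything (warning).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = cohort.expression.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s); correlations set to 0")
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(flat, 1.0, sd * np.sqrt(X.shape[1]))
    Z = Xc / denom[:, None]
    r = Z @ Z.T
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    genes = cohort.expression.index
    return Adjacency(matrix=pd.DataFrame(a, index=genes, columns=genes), beta=beta)


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float | None:
    """R^2 of log10 p(k) vs log10 k over equal-width connectivity bins."""
    k = connectivity[connectivity > 0]
    if len(np.unique(np.round(k, 12))) < n_bins:
        return None
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return None
    r = np.corrcoef(log_k, log_p)[0, 1]
    return float(r * r)


def pick_soft_threshold(
    cohort: MergedCohort,
    candidate_powers: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12),
    r2_target: float = 0.80,
    default_beta: float = 6.0,
) -> float:
    """Smallest power whose scale-free topology fit R^2 >= target.

    Falls back to the power with maximal R^2 when none reaches the
    target, and to ``default_beta`` when connectivities are too
    degenerate to bin (fewer than 10 distinct values).
    """
    if not len(candidate_powers):
        raise ValueError("candidate_powers must be non-empty")
    fits: dict[float, float] = {}
    for beta in candidate_powers:
        adj = soft_threshold_adjacency(cohort, beta=beta)
        a = adj.matrix.to_numpy()
        k = a.sum(axis=1) - 1.0
        r2 = _scale_free_r2(k)
        if r2 is None:
            continue
        fits[beta] = r2
        if r2 >= r2_target:
            return float(beta)
    if not fits:
        warnings.warn(
            "connectivity distribution too degenerate for a scale-free fit; "
            f"falling back to beta={default_beta}"
        )
        return float(default_beta)
    return float(max(fits, key=fits.get))


def topological_overlap(adj: Adjacency) -> TOMMatrix:
    """t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), t_ii = 1.

    l_ij sums shared-neighbor adjacency products over u != i, j and
    k_i is the connectivity of gene i (row sum without the diagonal).
    """
    a = adj.matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # A @ A counts u over everything; remove the u == i and u == j terms
    l = a @ a  # l[i, j] includes no u==i/u==j term since diag(a)=0
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 1e-12, num / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    genes = adj.matrix.index
    return TOMMatrix(
        matrix=pd.DataFrame(t, index=genes, columns=genes),
        connectivity=pd.Series(k, index=genes, name="connectivity"),
    )


def _subtree_split(
    d: np.ndarray, members: np.ndarray, min_module_size: int, gap: float
) -> list[np.ndarray] | None:
    """Try to split one cluster at its top merge; None if no valid split."""
    sub = d[np.ix_(members, members)]
    Z = hierarchy.linkage(squareform(sub, checks=False), method="average")
    # children of the root merge
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    left = members[labels == 1]
    right = members[labels == 2]
    if min(len(left), len(right)) < min_module_size:
        return None
    # split only if the children are mutually distant relative to the
    # looser child's internal scatter
    intra = []
    for child in (left, right):
        csub = d[np.ix_(child, child)]
        intra.append(csub[np.triu_indices(len(child), k=1)].mean())
    inter = d[np.ix_(left, right)].mean()
    if inter - max(intra) < gap:
        return None
    return [left, right]


def detect_modules(
    tom: TOMMatrix, min_module_size: int = 30, deep_split: int = 3
) -> pd.Series:
    """Cut the TOM dendrogram into gene modules (label 0 = unassigned).

    Average-linkage clustering on dissimilarity 1 - t, followed by a
    dynamic (branch-wise) cut: candidate modules are the maximal
    subtrees of at least ``min_module_size`` genes that hang distinctly
    below their attachment point (attachment height minus subtree top
    height >= a gap that shrinks as ``deep_split`` grows, so higher
    values split more aggressively). Candidates at least twice the size
    floor are recursively split at their top merge while both children
    clear ``min_module_size`` and the same gap criterion. Finally a
    cohesion filter sends incoherent candidates to the grey label 0: the
    mean dissimilarity to non-members (1.0 when a candidate spans all
    genes) must exceed the mean internal dissimilarity by the gap. When
    no subtree qualifies, the whole tree is assessed as a single
    cluster; a matrix that really is one tight module comes back as a
    single module with a warning.
    """
    if not 0 <= deep_split <= 3:
        raise ValueError("deep_split must be in {0, 1, 2, 3}")
    t = tom.matrix.to_numpy(dtype=float)
    genes = tom.matrix.index
    n = len(genes)
    if n < 2:
        return pd.Series(np.zeros(n, dtype=int), index=genes, name="module")
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    root = hierarchy.to_tree(Z)

    gap = 0.20 - 0.05 * deep_split  # smaller gap => deeper splitting

    def leaves(node) -> np.ndarray:
        return np.asarray(node.pre_order(lambda x: x.id), dtype=int)

    # maximal branches hanging >= gap below their attachment point
    candidates: list[np.ndarray] = []
    stack = [(root.left, root.dist), (root.right, root.dist)]
    while stack:
        node, parent_h = stack.pop()
        if node is None or node.get_count() < min_module_size:
            continue
        if parent_h - node.dist >= gap:
            candidates.append(leaves(node))
        else:
            stack.append((node.left, node.dist))
            stack.append((node.right, node.dist))
    if not candidates:
        candidates = [np.arange(n)]

    final: list[np.ndarray] = []
    while candidates:
        members = candidates.pop()
        if len(members) >= 2 * min_module_size:
            split = _subtree_split(d, members, min_module_size, gap)
            if split is not None:
                candidates.extend(split)
                continue
        final.append(members)

    labels = np.zeros(n, dtype=int)
    kept = []
    for members in final:
        if len(members) < min_module_size:
            continue
        outside = np.setdiff1d(np.arange(n), members)
        sub = d[np.ix_(members, members)]
        intra = sub[np.triu_indices(len(members), k=1)].mean()
        separation = d[np.ix_(members, outside)].mean() if len(outside) else 1.0
        if separation - intra < gap:  # no tighter than its surroundings
            continue
        kept.append(members)
    # stable module numbering: by first gene position
    kept.sort(key=lambda m: m.min())
    for mod, members in enumerate(kept, start=1):
        labels[members] = mod
    if len(kept) == 1 and len(kept[0]) == n:
        warnings.warn("all genes fall in a single module")
    return pd.Series(labels, index=genes, name="module")


def module_metagene(cohort: MergedCohort, partition: pd.Series) -> MetaGeneMatrix:
    """First-principal-component meta-gene per module.

    Genes are standardized across samples before the PCA; the score
    vector is scaled to unit sample variance (ddof=1) and its sign is
    fixed so it correlates positively with the module's mean standardized
    profile. Label-0 (grey) genes are ignored. Modules of a single gene
    fall back to that gene's standardized profile with a warning.
    """
    X = cohort.expression
    modules = sorted(m for m in partition.unique() if m != 0)
    if not modules:
        raise ValueError("partition contains no modules")
    scores = {}
    varexp = {}
    for m in modules:
        genes = partition.index[partition == m]
        sub = X.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        subz = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if len(genes) == 1:
            warnings.warn(f"module {m} has a single gene; meta-gene is its profile")
            vec = subz[0]
            ve = 1.0
        else:
            u, s, vt = np.linalg.svd(subz, full_matrices=False)
            vec = vt[0]
            ve = float(s[0] ** 2 / (s**2).sum())
        mean_profile = subz.mean(axis=0)
        if np.dot(vec, mean_profile) < 0:
            vec = -vec
        v = vec.std(ddof=1)
        if v > 0:
            vec = (vec - vec.mean()) / v
        scores[f"M{m}"] = vec
        varexp[f"M{m}"] = ve
    frame = pd.DataFrame(scores, index=X.columns).T
    return MetaGeneMatrix(
        scores=frame,
        variance_explained=pd.Series(varexp, name="variance_explained"),
    )


def compare_metagenes_by_grade(
    metagenes: MetaGeneMatrix,
    grades: pd.Series,
    pair: tuple[int, int] = (1, 3),
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney comparison of each module's meta-gene between grades.

    Effect is the difference of group medians, second grade of ``pair``
    minus the first; significance flag at p <= p_threshold.
    """
    ga, gb = pair
    a = grades.index[grades == ga]
    b = grades.index[grades == gb]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"grades {pair} need >= 2 samples each")
    rows = []
    for mod in metagenes.scores.index:
        xa = metagenes.scores.loc[mod, a].to_numpy(dtype=float)
        xb = metagenes.scores.loc[mod, b].to_numpy(dtype=float)
        p = float(stats.mannwhitneyu(xb, xa, alternative="two-sided").pvalue)
        rows.append(
            {
                "module": mod,
                "median_diff": float(np.median(xb) - np.median(xa)),
                "p_value": p,
                "significant": p <= p_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("module")
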