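"""Fuzzy C-means reclassification of grade 2 meningiomas.

The core procedure: soft-cluster all samples in a feature space built
from grade-1-vs-3-discriminating features (module meta-genes and/or
single genes), orient the two clusters by the ratio of grade 3 to grade
1 tumors in the high-membership tails, score the separation of grades 1
and 3 with a prevalence-balanced sigmoidal cost

    C = (1/N1) sum_{i in S1} sigmoid(alpha (P_i - 0.5))
      + (1/N3) sum_{j in S3} sigmoid(alpha (0.5 - P_j))

where P_k is the membership of sample k in the grade-3-enriched cluster,
select features greedily (forward and backward) under that cost, and
finally call grade 2 samples grade-1-like / intermediate / grade-3-like
by thresholding P_k at 0.20 / 0.80.

Grade 2 samples take part in the clustering fit but never enter the
cost, so the signature is trained without any grade-2 input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .coexpression import MetaGeneMatrix
from .diffexpr import DEResult
from .preprocess import MergedCohort

__all__ = [
    "FeatureSet",
    "MembershipResult",
    "ReclassificationReport",
    "SignatureSelection",
    "build_feature_pool",
    "fcm_cluster",
    "cluster_polarity",
    "grade3_membership",
    "separation_cost",
    "forward_select",
    "backward_eliminate",
    "select_signature",
    "reclassify_grade2",
]

DEFAULT_ALPHAS = (1.0, 5.0, 10.0, 100.0)
DEFAULT_THRESHOLD = 0.80


@dataclass(frozen=True)
class FeatureSet:
    """Ordered candidate features with a standardized sample x feature matrix."""

    feature_ids: tuple[str, ...]
    matrix: pd.DataFrame  # samples x features, z-scored per feature

    def subset(self, ids: tuple[str, ...] | list[str]) -> "FeatureSet":
        ids = tuple(ids)
        return FeatureSet(feature_ids=ids, matrix=self.matrix[list(ids)])

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass
class MembershipResult:
    """FCM fit: memberships, centroids, diagnostics, and cluster polarity."""

    membership: pd.DataFrame  # samples x 2, rows sum to 1
    centroids: np.ndarray  # 2 x n_features
    fuzzifier: float
    objective: float
    n_iter: int
    converged: bool
    #: objective value after each centroid update (non-increasing)
    objective_trace: tuple[float, ...] = ()
    grade3_cluster: int | None = None  # set by cluster_polarity

    @property
    def polarity(self) -> str | None:
        if self.grade3_cluster is None:
            return None
        return f"cluster{self.grade3_cluster}_is_grade3"


@dataclass(frozen=True)
class ReclassificationReport:
    """Grade-2 labels plus the memberships and settings that produced them."""

    labels: pd.Series  # grade-2 samples -> label
    p_grade3: pd.Series  # all samples
    threshold: float
    counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class SignatureSelection:
    """Outcome of feature selection over the alpha grid, both directions."""

    cost_curves: pd.DataFrame  # direction, alpha, n_features, features, cost
    best_features: tuple[str, ...]
    best_direction: str
    reporting_alpha: float
    best_cost: float
    result: MembershipResult


def build_feature_pool(
    cohort: MergedCohort,
    metagenes: MetaGeneMatrix | None,
    module_comparison: pd.DataFrame | None,
    de_result: DEResult | None,
    max_genes: int = 20,
) -> FeatureSet:
    """Assemble the candidate pool from grade-1-vs-3-significant features.

    Module meta-genes flagged significant in ``module_comparison`` enter
    as ``module:<id>``; DE-significant genes enter as ``gene:<id>``,
    capped at the ``max_genes`` largest absolute fold changes. Features
    are z-scored across all samples.
    """
    columns: dict[str, np.ndarray] = {}
    if metagenes is not None and module_comparison is not None:
        for mod in module_comparison.index[module_comparison["significant"]]:
            columns[f"module:{mod}"] = metagenes.scores.loc[mod].to_numpy(dtype=float)
    if de_result is not None:
        sig = de_result.table.loc[de_result.significant]
        top = sig.reindex(sig["log2_fc"].abs().sort_values(ascending=False).index)
        for gene in top.index[:max_genes]:
            columns[f"gene:{gene}"] = cohort.expression.loc[gene].to_numpy(dtype=float)
    if not columns:
        raise ValueError("candidate feature pool is empty")
    frame = pd.DataFrame(columns, index=cohort.expression.columns)
    frame = (frame - frame.mean()) / frame.std(ddof=0).replace(0.0, 1.0)
    return FeatureSet(feature_ids=tuple(frame.columns), matrix=frame)


def fcm_cluster(
    features: FeatureSet,
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 10,
    seed: int = 0,
) -> MembershipResult:
    """Standard fuzzy C-means with Euclidean distance.

    Alternates centroid updates c_j = sum_k u_jk^m x_k / sum_k u_jk^m and
    membership updates u_jk = 1 / sum_l (d_jk / d_lk)^(2/(m-1)) until the
    largest membership change drops below ``tol``. Memberships are
    initialized from the seeded generator; the best of ``n_restarts``
    runs by the FCM objective is returned. A sample coincident with a
    centroid gets hard membership to it.
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = features.matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < n_clusters:
        raise ValueError("need at least n_clusters samples")
    rng = np.random.default_rng(seed)
    expo = 1.0 / (fuzzifier - 1.0)
    best: MembershipResult | None = None
    for _ in range(max(1, n_restarts)):
        U = rng.random((n, n_clusters)) + 1e-3
        U /= U.sum(axis=1, keepdims=True)
        converged = False
        it = 0
        trace: list[float] = []
        for it in range(1, max_iter + 1):
            Um = U**fuzzifier
            C = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
            trace.append(float((Um * d2).sum()))
            coincident = d2 < 1e-24
            with np.errstate(divide="ignore", invalid="ignore"):
                inv = d2 ** (-expo)
                U_new = inv / inv.sum(axis=1, keepdims=True)
            hit = coincident.any(axis=1)
            if hit.any():
                U_new[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
            delta = np.abs(U_new - U).max()
            U = U_new
            if delta < tol:
                converged = True
                break
        Um = U**fuzzifier
        C = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        objective = float((Um * d2).sum())
        if not converged:
            warnings.warn("FCM did not converge within max_iter")
        cand = MembershipResult(
            membership=pd.DataFrame(
                U, index=features.matrix.index, columns=list(range(n_clusters))
            ),
            centroids=C,
            fuzzifier=fuzzifier,
            objective=objective,
            n_iter=it,
            converged=converged,
            objective_trace=tuple(trace),
        )
        if best is None or objective < best.objective:
            best = cand
    return best


def cluster_polarity(
    result: MembershipResult,
    grades: pd.Series,
    hard_threshold: float = DEFAULT_THRESHOLD,
) -> MembershipResult:
    """Decide which cluster is grade-3-enriched and record it.

    Among samples with membership >= ``hard_threshold`` to a cluster,
    the grade-3 : grade-1 ratio is computed with a +0.5 continuity guard
    on both counts; the cluster with the larger ratio is grade-3
    enriched. If neither tail contains any grade 1 or 3 sample the
    polarity falls back to comparing the clusters' median memberships of
    grade-3 vs grade-1 samples (warning logged).
    """
    grades = grades.loc[result.membership.index]
    U = result.membership
    ratios = []
    any_graded = False
    for j in U.columns:
        tail = U.index[U[j] >= hard_threshold]
        g = grades.loc[tail]
        n3 = int((g == 3).sum())
        n1 = int((g == 1).sum())
        if n1 + n3 > 0:
            any_graded = True
        ratios.append((n3 + 0.5) / (n1 + 0.5))
    if any_graded:
        grade3_cluster = int(np.argmax(ratios))
    else:
        warnings.warn(
            "no grade 1/3 samples in either membership tail; "
            "polarity from median memberships"
        )
        scores = []
        for j in U.columns:
            g3 = U.loc[grades == 3, j]
            g1 = U.loc[grades == 1, j]
            s3 = float(g3.median()) if len(g3) else None
            s1 = float(g1.median()) if len(g1) else None
            if s3 is not None and s1 is not None:
                scores.append(s3 - s1)
            elif s3 is not None:
                scores.append(s3)
            elif s1 is not None:
                scores.append(-s1)
            else:
                raise ValueError("no grade 1 or grade 3 samples; cannot set polarity")
        grade3_cluster = int(np.argmax(scores))
    result.grade3_cluster = grade3_cluster
    return result


def grade3_membership(result: MembershipResult) -> pd.Series:
    """P_k: membership of the grade-3-enriched cluster, per sample."""
    if result.grade3_cluster is None:
        raise ValueError("polarity not set; run cluster_polarity first")
    p = result.membership[result.grade3_cluster].copy()
    p.name = "p_grade3"
    return p


def separation_cost(p_grade3: pd.Series, grades: pd.Series, alpha: float) -> float:
    """Balanced sigmoidal separation cost of grades 1 and 3.

    Grade 2 samples (and any other grade) are excluded from the sum;
    lower is better; C = 1 exactly when every membership is 0.5 and
    C is confined to (0, 2).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    grades = grades.loc[p_grade3.index]
    p1 = p_grade3[grades == 1].to_numpy(dtype=float)
    p3 = p_grade3[grades == 3].to_numpy(dtype=float)
    if len(p1) == 0:
        raise ValueError("no grade 1 samples; cost undefined")
    if len(p3) == 0:
        raise ValueError("no grade 3 samples; cost undefined")
    c1 = expit(alpha * (p1 - 0.5)).mean()
    c3 = expit(alpha * (0.5 - p3)).mean()
    return float(c1 + c3)


def _evaluate(
    pool: FeatureSet,
    ids: tuple[str, ...],
    grades: pd.Series,
    alpha: float,
    fcm_kwargs: dict,
    seed: int,
) -> tuple[float, MembershipResult]:
    sub = pool.subset(ids)
    result = fcm_cluster(sub, seed=seed, **fcm_kwargs)
    result = cluster_polarity(result, grades)
    return separation_cost(grade3_membership(result), grades, alpha), result


def forward_select(
    pool: FeatureSet,
    grades: pd.Series,
    alpha: float,
    fcm_kwargs: dict | None = None,
    seed: int = 0,
    min_improvement: float = 1e-6,
) -> tuple[tuple[str, ...], float]:
    """Greedy forward selection under the separation cost.

    Starts empty and repeatedly adds the feature minimizing C (the FCM
    fit is re-run per candidate with the same seed), stopping when the
    best improvement falls below ``min_improvement`` or the pool is
    exhausted. Ties break toward the earliest pool position.
    """
    if len(pool) == 0:
        raise ValueError("feature pool is empty")
    fcm_kwargs = fcm_kwargs or {}
    selected: tuple[str, ...] = ()
    best_cost = np.inf
    remaining = list(pool.feature_ids)
    while remaining:
        costs = [
            _evaluate(pool, selected + (f,), grades, alpha, fcm_kwargs, seed)[0]
            for f in remaining
        ]
        i = int(np.argmin(costs))
        if best_cost - costs[i] < min_improvement and selected:
            break
        if costs[i] < best_cost:
            best_cost = costs[i]
            selected = selected + (remaining.pop(i),)
        else:
            break
    return selected, float(best_cost)


def backward_eliminate(
    pool: FeatureSet,
    grades: pd.Series,
    alpha: float,
    fcm_kwargs: dict | None = None,
    seed: int = 0,
    min_improvement: float = 1e-6,
) -> tuple[tuple[str, ...], float]:
    """Greedy backward elimination under the separation cost.

    Starts with the full pool and repeatedly drops the feature whose
    removal minimizes C, stopping when no removal improves by at least
    ``min_improvement``.
    """
    if len(pool) == 0:
        raise ValueError("feature pool is empty")
    fcm_kwargs = fcm_kwargs or {}
    selected = tuple(pool.feature_ids)
    best_cost, _ = _evaluate(pool, selected, grades, alpha, fcm_kwargs, seed)
    while len(selected) > 1:
        candidates = [
            tuple(f for f in selected if f != drop) for drop in selected
        ]
        costs = [
            _evaluate(pool, ids, grades, alpha, fcm_kwargs, seed)[0]
            for ids in candidates
        ]
        i = int(np.argmin(costs))
        if best_cost - costs[i] < min_improvement:
            break
        best_cost = costs[i]
        selected = candidates[i]
    return selected, float(best_cost)


def select_signature(
    pool: FeatureSet,
    grades: pd.Series,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    reporting_alpha: float = 10.0,
    fcm_kwargs: dict | None = None,
    seed: int = 0,
) -> SignatureSelection:
    """Run forward and backward selection across the alpha grid.

    All cost curves are recorded; the final signature is the
    (direction, feature set) with minimal cost at ``reporting_alpha``
    (ties break toward forward selection). The returned result carries a
    fresh, polarity-oriented FCM fit on the winning features.
    """
    fcm_kwargs = fcm_kwargs or {}
    rows = []
    best: tuple[float, str, tuple[str, ...]] | None = None
    for direction, fn in (("forward", forward_select), ("backward", backward_eliminate)):
        for alpha in alphas:
            feats, cost = fn(pool, grades, alpha, fcm_kwargs=fcm_kwargs, seed=seed)
            rows.append(
                {
                    "direction": direction,
                    "alpha": alpha,
                    "n_features": len(feats),
                    "features": ";".join(feats),
                    "cost": cost,
                }
            )
            if alpha == reporting_alpha:
                if best is None or cost < best[0]:
                    best = (cost, direction, feats)
    if best is None:
        raise ValueError("reporting_alpha must be one of alphas")
    cost, direction, feats = best
    final_cost, result = _evaluate(pool, feats, grades, reporting_alpha, fcm_kwargs, seed)
    return SignatureSelection(
        cost_curves=pd.DataFrame(rows),
        best_features=feats,
        best_direction=direction,
        reporting_alpha=reporting_alpha,
        best_cost=final_cost,
        result=result,
    )


def reclassify_grade2(
    result: MembershipResult,
    grades: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> ReclassificationReport:
    """Label grade 2 samples by thresholding P_k.

    grade3_like iff P >= threshold, grade1_like iff P <= 1 - threshold,
    intermediate otherwise (a sample satisfying both — only possible at
    threshold 0.5 with P exactly 0.5 — is intermediate). Grade 1 and 3
    samples are untouched.
    """
    p = grade3_membership(result)
    grades = grades.loc[p.index]
    g2 = p.index[grades == 2]
    if len(g2) == 0:
        warnings.warn("no grade 2 samples to reclassify")
    labels = {}
    eps = 1e-12  # boundary values (e.g. P exactly 0.20) are inclusive
    for s in g2:
        hi = p[s] >= threshold - eps
        lo = p[s] <= (1.0 - threshold) + eps
        if hi and not lo:
            labels[s] = "grade3_like"
        elif lo and not hi:
            labels[s] = "grade1_like"
        else:
            labels[s] = "intermediate"
    labels = pd.Series(labels, dtype=object, name="label").reindex(g2)
    counts = {
        k: int((labels == k).sum())
        for k in ("grade1_like", "intermediate", "grade3_like")
    }
    return ReclassificationReport(
        labels=labels, p_grade3=p, threshold=threshold, counts=counts
    )
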