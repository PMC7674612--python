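"""Per-study normalization, multi-study merging and batch correction.

Pipeline order is fixed: log2 transform -> quantile normalization (per
study) -> merge on the gene intersection -> global standardization ->
empirical-Bayes batch adjustment (ComBat). Inputs are assumed to be
processed expression matrices (probe-level background correction happens
upstream of deposited series matrices and is out of scope here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyExpression",
    "MergedCohort",
    "log2_transform",
    "quantile_normalize",
    "intersect_and_merge",
    "global_scale",
    "combat_adjust",
    "preprocess_cohort",
]

VALID_RECURRENCE = frozenset({"yes", "no", "unknown"})


@dataclass(frozen=True)
class StudyExpression:
    """One study's gene x sample expression matrix.

    ``scale`` flags whether intensities are linear or already log2.
    """

    study_id: str
    expression: pd.DataFrame  # genes x samples
    scale: str = "linear"  # {"linear", "log2"}

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.expression.index.has_duplicates:
            dup = self.expression.index[self.expression.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in study {self.study_id!r}")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite values in study {self.study_id!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns


@dataclass(frozen=True)
class MergedCohort:
    """Merged gene x sample matrix with per-sample batch/grade/recurrence.

    ``metadata`` is indexed by sample id, aligned with ``expression``
    columns, and carries columns study_id, who_grade, recurrence.
    """

    expression: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame

    def __post_init__(self):
        if not self.expression.columns.equals(self.metadata.index):
            raise ValueError("expression columns and metadata index must align")
        bad = set(self.metadata["recurrence"]) - VALID_RECURRENCE
        if bad:
            raise ValueError(f"invalid recurrence values: {sorted(bad)}")

    @property
    def batch(self) -> pd.Series:
        return self.metadata["study_id"]

    @property
    def grade(self) -> pd.Series:
        return self.metadata["who_grade"]

    @property
    def recurrence(self) -> pd.Series:
        return self.metadata["recurrence"]

    def samples_of_grade(self, grade: int) -> pd.Index:
        return self.metadata.index[self.metadata["who_grade"] == grade]


def log2_transform(study: StudyExpression) -> StudyExpression:
    """Apply ``x -> log2(x + 1)`` to a linear-scale study.

    Studies already flagged log2 pass through unchanged. The +1 offset
    keeps zeros finite (RNA-seq counts).
    """
    if study.scale == "log2":
        return study
    values = study.expression.to_numpy(dtype=float)
    if (values <= -1).any():
        raise ValueError(
            f"study {study.study_id!r} has values <= -1; log2(x+1) undefined"
        )
    transformed = pd.DataFrame(
        np.log2(values + 1.0), index=study.expression.index, columns=study.expression.columns
    )
    return replace(study, expression=transformed, scale="log2")


def quantile_normalize(study: StudyExpression) -> StudyExpression:
    """Force every sample onto the mean empirical distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; within-sample ranks are preserved, and ties receive the
    mean of their tied reference positions. A single-sample study is
    returned unchanged with a warning (nothing to normalize against).
    """
    X = study.expression
    if X.shape[1] < 2:
        warnings.warn(
            f"study {study.study_id!r} has a single sample; quantile normalization skipped"
        )
        return study
    values = X.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        # average ranks so tied inputs get the mean of their tied
        # reference quantiles
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(len(col))
        ranks[order] = np.arange(len(col))
        mapped = reference[ranks.astype(int)]
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=mapped)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return replace(
        study, expression=pd.DataFrame(out, index=X.index, columns=X.columns)
    )


def intersect_and_merge(
    studies: list[StudyExpression], metadata: pd.DataFrame
) -> MergedCohort:
    """Merge studies on the intersection of their gene sets.

    Rows are the shared genes sorted lexicographically; columns are the
    studies' samples concatenated in input order; each sample's batch
    label is its study_id.
    """
    if not studies:
        raise ValueError("no studies to merge")
    for s in studies:
        if s.scale != "log2":
            raise ValueError(f"study {s.study_id!r} is not log2-scaled; transform first")
    shared = studies[0].gene_ids
    for s in studies[1:]:
        shared = shared.intersection(s.gene_ids)
    if len(shared) == 0:
        raise ValueError("gene-set intersection across studies is empty")
    shared = shared.sort_values()
    expr = pd.concat([s.expression.loc[shared] for s in studies], axis=1)
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} across studies")
    missing = expr.columns.difference(metadata.index)
    if len(missing):
        raise ValueError(f"sample {missing[0]!r} missing from metadata")
    meta = metadata.loc[expr.columns].copy()
    # the batch label downstream is the study of origin
    study_of = {}
    for s in studies:
        for sid in s.sample_ids:
            study_of[sid] = s.study_id
    meta["study_id"] = [study_of[c] for c in expr.columns]
    return MergedCohort(expression=expr, metadata=meta)


def global_scale(cohort: MergedCohort) -> MergedCohort:
    """Standardize the whole matrix to grand mean 0 and grand sd 1.

    Population (ddof=0) standard deviation over all entries; the choice
    is immaterial at cohort size but fixed for reproducibility.
    """
    values = cohort.expression.to_numpy(dtype=float)
    mean = values.mean()
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("grand standard deviation is zero; cannot scale")
    scaled = pd.DataFrame(
        (values - mean) / sd,
        index=cohort.expression.index,
        columns=cohort.expression.columns,
    )
    return replace(cohort, expression=scaled)


def combat_adjust(cohort: MergedCohort) -> MergedCohort:
    """Remove per-batch location-scale effects with parametric ComBat.

    Per-gene additive and multiplicative batch effects are estimated,
    shrunk toward batch-level priors by empirical Bayes (normal prior on
    the additive effect, inverse-gamma on the multiplicative one), and
    removed. No covariates are protected. Delegates to scanpy's ComBat
    (imported lazily; the import is slow).
    """
    batches = cohort.batch
    counts = batches.value_counts()
    if len(counts) < 2:
        raise ValueError("combat_adjust requires >= 2 batches")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"batch {small.index[0]!r} has {int(small.iloc[0])} sample(s); need >= 2 per batch"
        )
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        cohort.expression.to_numpy(dtype=float).T,
        obs=pd.DataFrame({"batch": batches.astype(str).values}, index=cohort.expression.columns.astype(str)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    adjusted = pd.DataFrame(
        np.asarray(adata.X).T,
        index=cohort.expression.index,
        columns=cohort.expression.columns,
    )
    return replace(cohort, expression=adjusted)


def preprocess_cohort(
    studies: list[StudyExpression],
    metadata: pd.DataFrame,
    quantile: bool = True,
    batch_correct: bool = True,
) -> MergedCohort:
    """Full preprocessing chain: log2 -> quantile -> merge -> scale -> ComBat."""
    normed = []
    for s in studies:
        s = log2_transform(s)
        if quantile:
            s = quantile_normalize(s)
        normed.append(s)
    cohort = global_scale(intersect_and_merge(normed, metadata))
    if batch_correct:
        cohort = combat_adjust(cohort)
    return cohort
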