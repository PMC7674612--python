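"""Single-gene differential expression between WHO grades.

Fold change in log2 space is the difference of group means (grade 3 minus
grade 1); significance by two-sample Welch t-test (Mann-Whitney U
available as an option). A gene is called up/down when |log2 FC| >= 1.5
and p <= 1e-4 (configurable thresholds, defaulting to the study design's
fixed rule, with no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MergedCohort

__all__ = ["DEResult", "log2_fold_change", "de_test"]

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class DEResult:
    """Per-gene log2 fold change, p-value and direction flag."""

    table: pd.DataFrame  # columns: log2_fc, p_value, direction
    fc_threshold: float
    p_threshold: float
    test: str

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "ns"]


def log2_fold_change(
    cohort: MergedCohort, grade_a: int = 1, grade_b: int = 3
) -> pd.Series:
    """Per-gene mean(grade_b) - mean(grade_a) in log2 space."""
    a = cohort.samples_of_grade(grade_a)
    b = cohort.samples_of_grade(grade_b)
    if len(a) == 0:
        raise ValueError(f"no samples of grade {grade_a}")
    if len(b) == 0:
        raise ValueError(f"no samples of grade {grade_b}")
    fc = cohort.expression[b].mean(axis=1) - cohort.expression[a].mean(axis=1)
    fc.name = "log2_fc"
    return fc


def de_test(
    cohort: MergedCohort,
    grades: tuple[int, int] = (1, 3),
    test: str = "welch",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> DEResult:
    """Differential expression between two grades.

    ``test`` is "welch" (unequal-variance t) or "mannwhitney". Genes with
    zero variance in both groups get p = 1 and direction "ns". Direction
    is "up" iff log2_fc >= +fc_threshold and p <= p_threshold, "down" iff
    log2_fc <= -fc_threshold and p <= p_threshold, otherwise "ns".
    """
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    grade_a, grade_b = grades
    a = cohort.samples_of_grade(grade_a)
    b = cohort.samples_of_grade(grade_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per grade for testing")
    Xa = cohort.expression[a].to_numpy(dtype=float)
    Xb = cohort.expression[b].to_numpy(dtype=float)
    fc = Xb.mean(axis=1) - Xa.mean(axis=1)

    degenerate = (Xa.std(axis=1) == 0) & (Xb.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "welch":
            p = stats.ttest_ind(Xb, Xa, axis=1, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(Xb, Xa, axis=1, alternative="two-sided").pvalue
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)

    direction = np.full(len(fc), "ns", dtype=object)
    direction[(fc >= fc_threshold) & (p <= p_threshold)] = "up"
    direction[(fc <= -fc_threshold) & (p <= p_threshold)] = "down"
    table = pd.DataFrame(
        {"log2_fc": fc, "p_value": p, "direction": direction},
        index=cohort.expression.index,
    )
    return DEResult(
        table=table, fc_threshold=fc_threshold, p_threshold=p_threshold, test=test
    )
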