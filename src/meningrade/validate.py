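"""Recurrence and biological-concordance validation of the reclassification.

Compares recurrence rates between groups (2x2 contingency tables,
chi-square with optional Yates correction, Fisher's exact as a
diagnostic) and quantifies shared biology between matched groups through
the correlation of per-module median meta-gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import MetaGeneMatrix

__all__ = [
    "RecurrenceTable",
    "ConcordanceResult",
    "recurrence_table",
    "chi_square_test",
    "fisher_exact_test",
    "recurrence_rate",
    "module_concordance",
    "differential_concordance",
]


@dataclass(frozen=True)
class RecurrenceTable:
    """2x2 contingency of recurrence by group; unknowns already dropped."""

    counts: pd.DataFrame  # index: (group_a, group_b); columns: recurred, not_recurred

    def as_array(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-module group medians and their Pearson correlation."""

    medians: pd.DataFrame  # modules x groups
    rho: float
    rho_p_value: float
    per_module: pd.DataFrame  # p_value, significant per module


def recurrence_table(
    labels: pd.Series,
    recurrence: pd.Series,
    group_a: str,
    group_b: str,
) -> RecurrenceTable:
    """Tabulate recurred / not recurred for two disjoint label groups.

    Samples with unknown recurrence are excluded; a group left empty
    after exclusion is an error.
    """
    recurrence = recurrence.loc[labels.index]
    bad = set(recurrence.unique()) - {"yes", "no", "unknown"}
    if bad:
        raise ValueError(f"invalid recurrence values: {sorted(bad)}")
    rows = {}
    for group in (group_a, group_b):
        members = labels.index[labels == group]
        rec = recurrence.loc[members]
        known = rec[rec != "unknown"]
        if len(known) == 0:
            raise ValueError(
                f"group {group!r} has no samples with known recurrence"
            )
        rows[group] = {
            "recurred": int((known == "yes").sum()),
            "not_recurred": int((known == "no").sum()),
        }
    return RecurrenceTable(counts=pd.DataFrame(rows).T[["recurred", "not_recurred"]])


def chi_square_test(
    table: RecurrenceTable | np.ndarray,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1.

    Optional Yates continuity correction. A zero marginal makes the test
    undefined; then (0.0, 1.0) is returned with a warning.
    """
    counts = table.as_array() if isinstance(table, RecurrenceTable) else np.asarray(table, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("chi_square_test expects a 2x2 table")
    if counts.sum() < 1:
        raise ValueError("table total must be >= 1")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        warnings.warn("zero marginal; chi-square undefined, returning p = 1")
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(counts, correction=continuity_correction)
    return float(stat), float(p)


def fisher_exact_test(table: RecurrenceTable | np.ndarray) -> tuple[float, float]:
    """Fisher's exact test (diagnostic for small expected counts)."""
    counts = table.as_array() if isinstance(table, RecurrenceTable) else np.asarray(table, dtype=float)
    odds, p = stats.fisher_exact(counts)
    return float(odds), float(p)


def recurrence_rate(recurred: int, total: int) -> tuple[float, int]:
    """Recurrence percentage of a table row: (unrounded, rounded)."""
    if total <= 0:
        raise ValueError("row total must be > 0")
    pct = 100.0 * recurred / total
    return pct, int(round(pct))


def _group_medians(
    metagenes: MetaGeneMatrix, groups: dict[str, pd.Index]
) -> pd.DataFrame:
    out = {}
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = metagenes.scores[list(members)].median(axis=1)
    return pd.DataFrame(out)


def module_concordance(
    metagenes: MetaGeneMatrix,
    group_a: tuple[str, pd.Index],
    group_b: tuple[str, pd.Index],
    p_threshold: float = 0.05,
) -> ConcordanceResult:
    """Concordance of per-module median meta-gene expression of two groups.

    Pearson rho across modules of the two median vectors; per-module
    Mann-Whitney flags at ``p_threshold``. Needs >= 3 modules (rho is
    unstable below that).
    """
    name_a, idx_a = group_a
    name_b, idx_b = group_b
    if metagenes.scores.shape[0] < 3:
        raise ValueError("need >= 3 modules for a stable correlation")
    medians = _group_medians(metagenes, {name_a: idx_a, name_b: idx_b})
    rho, p = stats.pearsonr(medians[name_a], medians[name_b])
    per_module = []
    for mod in metagenes.scores.index:
        xa = metagenes.scores.loc[mod, list(idx_a)].to_numpy(dtype=float)
        xb = metagenes.scores.loc[mod, list(idx_b)].to_numpy(dtype=float)
        mp = float(stats.mannwhitneyu(xb, xa, alternative="two-sided").pvalue)
        per_module.append({"module": mod, "p_value": mp, "significant": mp <= p_threshold})
    return ConcordanceResult(
        medians=medians,
        rho=float(rho),
        rho_p_value=float(p),
        per_module=pd.DataFrame(per_module).set_index("module"),
    )


def differential_concordance(
    metagenes: MetaGeneMatrix,
    grade1: pd.Index,
    grade3: pd.Index,
    grade1_like: pd.Index,
    grade3_like: pd.Index,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Compare grade-3-minus-grade-1 separation with its grade-2 analogue.

    Per module: Delta_grades = median(G3) - median(G1) and Delta_like =
    median(grade3_like) - median(grade1_like), each with a Mann-Whitney
    significance flag; the result also carries the Pearson rho of the two
    difference vectors (DataFrame attrs "rho", "rho_p_value") and a
    per-module classification in {both, grades_only, like_only, neither}.
    """
    medians = _group_medians(
        metagenes,
        {"g1": grade1, "g3": grade3, "g1like": grade1_like, "g3like": grade3_like},
    )
    rows = []
    for mod in metagenes.scores.index:
        x1 = metagenes.scores.loc[mod, list(grade1)].to_numpy(dtype=float)
        x3 = metagenes.scores.loc[mod, list(grade3)].to_numpy(dtype=float)
        y1 = metagenes.scores.loc[mod, list(grade1_like)].to_numpy(dtype=float)
        y3 = metagenes.scores.loc[mod, list(grade3_like)].to_numpy(dtype=float)
        p_grades = float(stats.mannwhitneyu(x3, x1, alternative="two-sided").pvalue)
        p_like = float(stats.mannwhitneyu(y3, y1, alternative="two-sided").pvalue)
        sig_g = p_grades <= p_threshold
        sig_l = p_like <= p_threshold
        if sig_g and sig_l:
            cls = "both"
        elif sig_g:
            cls = "grades_only"
        elif sig_l:
            cls = "like_only"
        else:
            cls = "neither"
        rows.append(
            {
                "module": mod,
                "delta_grades": medians.loc[mod, "g3"] - medians.loc[mod, "g1"],
                "delta_like": medians.loc[mod, "g3like"] - medians.loc[mod, "g1like"],
                "p_grades": p_grades,
                "p_like": p_like,
                "classification": cls,
            }
        )
    out = pd.DataFrame(rows).set_index("module")
    if len(out) >= 3:
        rho, p = stats.pearsonr(out["delta_grades"], out["delta_like"])
    else:
        raise ValueError("need >= 3 modules for a stable correlation")
    out.attrs["rho"] = float(rho)
    out.attrs["rho_p_value"] = float(p)
    return out
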