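"""End-to-end pipeline orchestration.

Runs the stages in their fixed order — preprocess -> differential
expression -> co-expression network -> fuzzy reclassification ->
validation — writing every artifact as a TSV/JSON under a run directory.
All randomness flows from a single master seed: each stage draws its own
child seed from ``numpy.random.SeedSequence(master_seed).spawn``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .coexpression import (
    compare_metagenes_by_grade,
    detect_modules,
    module_metagene,
    pick_soft_threshold,
    soft_threshold_adjacency,
    topological_overlap,
)
from .diffexpr import de_test
from .preprocess import MergedCohort, StudyExpression, preprocess_cohort
from .reclassify import (
    FeatureSet,
    build_feature_pool,
    cluster_polarity,
    fcm_cluster,
    grade3_membership,
    reclassify_grade2,
    select_signature,
)
from .synthetic import SynthConfig, simulate_cohort
from .validate import (
    chi_square_test,
    differential_concordance,
    fisher_exact_test,
    module_concordance,
    recurrence_rate,
    recurrence_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_to_dir", "load_studies"]


@dataclass
class PipelineConfig:
    """All stage parameters with the study design's defaults.

    Thresholds default to the published rule set: |log2 FC| >= 1.5 with
    p <= 1e-4 for single genes, Mann-Whitney p <= 0.05 for module
    meta-genes, membership cutoff 0.80 for reclassification, alpha grid
    {1, 5, 10, 100} for the separation cost.
    """

    # differential expression
    fc_threshold: float = 1.5
    de_p_threshold: float = 1e-4
    de_test: str = "welch"
    # network
    beta: float | None = None  # None = pick by scale-free fit
    min_module_size: int = 30
    deep_split: int = 3
    module_p_threshold: float = 0.05
    # reclassification
    alphas: tuple[float, ...] = (1.0, 5.0, 10.0, 100.0)
    reporting_alpha: float = 10.0
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    fcm_restarts: int = 10
    membership_threshold: float = 0.80
    max_single_genes: int = 20
    # validation
    continuity_correction: bool = False
    # orchestration
    master_seed: int = 0
    quantile: bool = True
    batch_correct: bool = True

    def fcm_kwargs(self) -> dict:
        return {
            "fuzzifier": self.fuzzifier,
            "tol": self.fcm_tol,
            "max_iter": self.fcm_max_iter,
            "n_restarts": self.fcm_restarts,
        }


def _child_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master_seed).spawn(n)]


def simulate_to_dir(config: SynthConfig, out_dir: str | Path) -> None:
    """Run the generator and write its study/metadata/truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    studies, metadata, truth = simulate_cohort(config)
    for s in studies:
        mio.write_expression_tsv(s.expression, out / f"expression_{s.study_id}.tsv")
    mio.write_metadata_tsv(metadata, out / "metadata.tsv")
    truth.latent_class.to_frame().to_csv(out / "truth.tsv", sep="\t", index_label="sample_id")


def load_studies(in_dir: str | Path, scale: str = "log2") -> tuple[list[StudyExpression], pd.DataFrame]:
    """Load every ``expression_<study>.tsv`` plus ``metadata.tsv`` from a directory."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("expression_*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no expression_*.tsv files in {in_dir}")
    studies = [
        mio.read_study_tsv(p, study_id=p.stem.removeprefix("expression_"), scale=scale)
        for p in paths
    ]
    metadata = mio.read_metadata_tsv(in_dir / "metadata.tsv")
    return studies, metadata


def run_pipeline(
    studies: list[StudyExpression],
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    saved_signature: dict | None = None,
) -> dict:
    """Execute all stages and return a machine-readable summary.

    When the cohort has no grade 3 samples (an external validation
    cohort), a previously saved signature must be supplied; its feature
    list is applied without re-training and polarity falls back to the
    grade-1 memberships.
    """
    config = config or PipelineConfig()
    seeds = _child_seeds(config.master_seed, 4)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", asdict(config))

    cohort = preprocess_cohort(
        studies, metadata, quantile=config.quantile, batch_correct=config.batch_correct
    )
    if out is not None:
        mio.write_expression_tsv(cohort.expression, out / "merged_expression.tsv")
        mio.write_metadata_tsv(cohort.metadata, out / "merged_metadata.tsv")

    grades = cohort.grade
    have_grade3 = (grades == 3).any()
    if not have_grade3 and saved_signature is None:
        raise ValueError(
            "cohort has no grade 3 samples; supply a saved signature to apply"
        )

    summary: dict = {"n_samples": int(cohort.expression.shape[1]),
                     "n_genes": int(cohort.expression.shape[0])}

    # --- network stage (always: meta-genes are needed for validation) ---
    beta = config.beta
    if beta is None:
        beta = pick_soft_threshold(cohort)
    adjacency = soft_threshold_adjacency(cohort, beta=beta)
    tom = topological_overlap(adjacency)
    partition = detect_modules(
        tom, min_module_size=config.min_module_size, deep_split=config.deep_split
    )
    summary["beta"] = float(beta)
    summary["n_modules"] = int(partition[partition > 0].nunique())
    if summary["n_modules"] == 0:
        raise RuntimeError("no co-expression modules detected")
    metagenes = module_metagene(cohort, partition)
    if out is not None:
        partition.to_frame().to_csv(out / "modules.tsv", sep="\t", index_label="gene_id")
        metagenes.scores.to_csv(out / "metagenes.tsv", sep="\t", index_label="module")

    if saved_signature is None:
        # --- training mode: DE, module comparison, feature selection ---
        de = de_test(
            cohort,
            grades=(1, 3),
            test=config.de_test,
            fc_threshold=config.fc_threshold,
            p_threshold=config.de_p_threshold,
        )
        comparison = compare_metagenes_by_grade(
            metagenes, grades, pair=(1, 3), p_threshold=config.module_p_threshold
        )
        if out is not None:
            de.table.to_csv(out / "diffexpr.tsv", sep="\t", index_label="gene_id")
            comparison.to_csv(out / "module_grade_comparison.tsv", sep="\t")
        pool = build_feature_pool(
            cohort, metagenes, comparison, de, max_genes=config.max_single_genes
        )
        selection = select_signature(
            pool,
            grades,
            alphas=config.alphas,
            reporting_alpha=config.reporting_alpha,
            fcm_kwargs=config.fcm_kwargs(),
            seed=seeds[0],
        )
        result = selection.result
        # carry the gene membership of every selected module so the
        # signature can be applied to an external cohort
        module_genes = {}
        for f in selection.best_features:
            kind, _, name = f.partition(":")
            if kind == "module":
                mod = int(name.removeprefix("M"))
                module_genes[name] = list(partition.index[partition == mod])
        summary["signature"] = {
            "features": list(selection.best_features),
            "direction": selection.best_direction,
            "alpha": selection.reporting_alpha,
            "cost": selection.best_cost,
            "modules": module_genes,
        }
        if out is not None:
            selection.cost_curves.to_csv(out / "cost_curves.tsv", sep="\t", index=False)
            (out / "signature.json").write_text(json.dumps(summary["signature"], indent=2))
    else:
        # --- application mode: reuse the saved feature list; module
        # meta-genes are recomputed from the saved gene memberships ---
        features = saved_signature["features"]
        saved_modules = saved_signature.get("modules", {})
        cols = {}
        for f in features:
            kind, _, name = f.partition(":")
            if kind == "module":
                genes = [g for g in saved_modules.get(name, ())
                         if g in cohort.expression.index]
                if len(genes) < 2:
                    raise ValueError(
                        f"saved signature module {name!r} has <2 genes in this cohort"
                    )
                saved_part = pd.Series(0, index=cohort.expression.index)
                saved_part.loc[genes] = 1
                mg = module_metagene(cohort, saved_part)
                cols[f] = mg.scores.iloc[0].to_numpy(dtype=float)
            else:
                if name not in cohort.expression.index:
                    raise ValueError(f"saved signature gene {name!r} not in this cohort")
                cols[f] = cohort.expression.loc[name].to_numpy(dtype=float)
        frame = pd.DataFrame(cols, index=cohort.expression.columns)
        frame = (frame - frame.mean()) / frame.std(ddof=0).replace(0.0, 1.0)
        fs = FeatureSet(feature_ids=tuple(frame.columns), matrix=frame)
        result = fcm_cluster(fs, seed=seeds[0], **config.fcm_kwargs())
        result = cluster_polarity(result, grades)
        summary["signature"] = dict(saved_signature)

    report = reclassify_grade2(result, grades, threshold=config.membership_threshold)
    summary["reclassification"] = dict(report.counts)
    summary["grade2_labels"] = {str(k): str(v) for k, v in report.labels.items()}
    n_g2 = int(sum(report.counts.values()))
    summary["fraction_reclassified"] = (
        float((report.counts["grade1_like"] + report.counts["grade3_like"]) / n_g2)
        if n_g2
        else float("nan")
    )
    if out is not None:
        pd.DataFrame(
            {
                "p_grade3": report.p_grade3,
                "label": report.labels.reindex(report.p_grade3.index),
            }
        ).to_csv(out / "membership.tsv", sep="\t", index_label="sample_id", na_rep="NA")

    # --- validation stage ---
    labels = pd.Series("", index=grades.index, dtype=object)
    labels[grades == 1] = "grade1"
    labels[grades == 3] = "grade3"
    labels.update(report.labels)
    validation: dict = {}
    try:
        table = recurrence_table(labels, cohort.recurrence, "grade3_like", "grade1_like")
        stat, p = chi_square_test(table, continuity_correction=config.continuity_correction)
        _, fisher_p = fisher_exact_test(table)
        r3 = recurrence_rate(*table.counts.loc["grade3_like"].pipe(lambda r: (r["recurred"], r.sum())))
        r1 = recurrence_rate(*table.counts.loc["grade1_like"].pipe(lambda r: (r["recurred"], r.sum())))
        validation["recurrence"] = {
            "table": table.counts.to_dict(),
            "chi2": stat,
            "p_value": p,
            "fisher_p_value": fisher_p,
            "rate_grade3_like_pct": r3[0],
            "rate_grade1_like_pct": r1[0],
        }
        if out is not None:
            table.counts.to_csv(out / "recurrence_table.tsv", sep="\t", index_label="group")
    except ValueError as exc:
        warnings.warn(f"recurrence validation skipped: {exc}")
        validation["recurrence"] = {"skipped": str(exc)}

    groups = {name: labels.index[labels == name] for name in
              ("grade1", "grade3", "grade1_like", "grade3_like")}
    if all(len(v) for v in groups.values()) and metagenes.scores.shape[0] >= 3:
        conc1 = module_concordance(
            metagenes, ("grade1", groups["grade1"]), ("grade1_like", groups["grade1_like"])
        )
        conc3 = module_concordance(
            metagenes, ("grade3", groups["grade3"]), ("grade3_like", groups["grade3_like"])
        )
        diff = differential_concordance(
            metagenes, groups["grade1"], groups["grade3"],
            groups["grade1_like"], groups["grade3_like"],
        )
        validation["concordance"] = {
            "rho_grade1_vs_grade1_like": conc1.rho,
            "rho_grade3_vs_grade3_like": conc3.rho,
            "rho_differential": diff.attrs["rho"],
        }
        if out is not None:
            diff.to_csv(out / "differential_concordance.tsv", sep="\t")
    else:
        validation["concordance"] = {"skipped": "a group is empty or too few modules"}
    summary["validation"] = validation

    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
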