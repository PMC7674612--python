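"""Synthetic multi-study meningioma cohort generator.

Emulates the statistical structure of a multi-study expression
meta-analysis: several studies (batches) with additive and multiplicative
batch effects, planted co-expressed gene modules driven by a latent
per-sample activity (a linear factor model, the implicit model behind
module eigengene summarization), grade-dependent module activity, WHO
grade 2 samples drawn as a mixture of three latent states (grade-1-like,
intermediate, grade-3-like), and recurrence outcomes whose probability
depends on the latent state.

All randomness flows from ``SynthConfig.seed`` through a single
``numpy.random.Generator``; identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import StudyExpression

__all__ = [
    "SynthConfig",
    "LatentTruth",
    "SynthConfigError",
    "simulate_cohort",
    "truth_summary",
    "LATENT_CLASSES",
]

#: Latent classes, ordered benign -> malignant.
LATENT_CLASSES = ("G1", "G2_1like", "G2_int", "G2_3like", "G3")

#: WHO grade implied by each latent class.
_CLASS_GRADE = {"G1": 1, "G2_1like": 2, "G2_int": 2, "G2_3like": 2, "G3": 3}

#: recurrence_probs key for each latent class.
_CLASS_RECUR_KEY = {
    "G1": "grade1",
    "G2_1like": "grade1_like",
    "G2_int": "intermediate",
    "G2_3like": "grade3_like",
    "G3": "grade3",
}


class SynthConfigError(ValueError):
    """Raised when a SynthConfig violates one of its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort shape of the six-study meningioma
    meta-analysis: 129 / 46 / 37 samples of WHO grades 1 / 2 / 3 spread
    over 6 studies, grade-2 samples split 13:12:21 into grade-1-like,
    intermediate and grade-3-like latent states, and recurrence
    probabilities of 0.17 (grade 1), 0.05 (grade-1-like), 0.25
    (intermediate), 0.75 (grade-3-like) and 0.85 (grade 3), with ~46% of
    recurrence labels masked to "unknown".
    """

    n_genes: int = 600
    module_sizes: tuple[int, ...] = (60, 50, 40, 40, 30)
    n_background_genes: int = 380
    samples_per_grade: tuple[int, int, int] = (129, 46, 37)
    grade2_mixture: tuple[float, float, float] = (13 / 46, 12 / 46, 21 / 46)
    #: per-module mean latent activity for (grade 1, grade 3); the
    #: intermediate grade-2 state sits at the midpoint.
    module_effects: tuple[tuple[float, float], ...] = (
        (-1.0, 1.0),
        (1.0, -1.0),
        (-0.8, 0.8),
        (0.6, -0.6),
        (0.0, 0.0),
    )
    within_module_loading: float = 0.9
    #: sd of the per-sample latent activity around its class mean.
    activity_sd: float = 0.5
    noise_sd: float = 0.3
    n_batches: int = 6
    batch_shift_sd: float = 0.3
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    recurrence_probs: dict[str, float] = field(
        default_factory=lambda: {
            "grade1": 0.17,
            "grade1_like": 0.05,
            "intermediate": 0.25,
            "grade3_like": 0.75,
            "grade3": 0.85,
        }
    )
    recurrence_missing_frac: float = 97 / 212
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`SynthConfigError` naming the violated invariant."""
        if sum(self.module_sizes) + self.n_background_genes != self.n_genes:
            raise SynthConfigError(
                "sum(module_sizes) + n_background_genes must equal n_genes "
                f"({sum(self.module_sizes)} + {self.n_background_genes} != {self.n_genes})"
            )
        if abs(sum(self.grade2_mixture) - 1.0) > 1e-9:
            raise SynthConfigError("grade2_mixture must sum to 1 within 1e-9")
        if any(p < 0 or p > 1 for p in self.grade2_mixture):
            raise SynthConfigError("grade2_mixture fractions must lie in [0, 1]")
        for key in ("grade1", "grade1_like", "intermediate", "grade3_like", "grade3"):
            if key not in self.recurrence_probs:
                raise SynthConfigError(f"recurrence_probs missing key {key!r}")
            p = self.recurrence_probs[key]
            if not 0.0 <= p <= 1.0:
                raise SynthConfigError(f"recurrence_probs[{key!r}]={p} not in [0, 1]")
        if not 0.0 <= self.recurrence_missing_frac <= 1.0:
            raise SynthConfigError("recurrence_missing_frac must lie in [0, 1]")
        if len(self.module_effects) != len(self.module_sizes):
            raise SynthConfigError("module_effects must have one entry per planted module")
        if not 0.0 < self.within_module_loading <= 1.0:
            raise SynthConfigError("within_module_loading must lie in (0, 1]")
        if self.noise_sd < 0 or self.activity_sd < 0 or self.batch_shift_sd < 0:
            raise SynthConfigError("standard deviations must be non-negative")
        if self.n_batches < 1:
            raise SynthConfigError("n_batches must be >= 1")
        lo, hi = self.batch_scale_range
        if not 0 < lo <= hi:
            raise SynthConfigError("batch_scale_range must satisfy 0 < lo <= hi")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatentTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    #: per-sample latent class, indexed by sample id.
    latent_class: pd.Series
    #: per-gene planted module id (0 = background), indexed by gene id.
    gene_module: pd.Series
    #: per-sample per-module latent activity (samples x modules).
    activity: pd.DataFrame


def _class_activity_mean(config: SynthConfig, module: int, cls: str) -> float:
    g1, g3 = config.module_effects[module]
    mid = 0.5 * (g1 + g3)
    return {
        "G1": g1,
        "G2_1like": g1,
        "G2_int": mid,
        "G2_3like": g3,
        "G3": g3,
    }[cls]


def _draw_latent_classes(config: SynthConfig, rng: np.random.Generator) -> list[str]:
    n1, n2, n3 = config.samples_per_grade
    classes = ["G1"] * n1
    # deterministic proportional split of the grade-2 mixture (largest
    # remainder), then the order is shuffled with the cohort rng
    targets = np.array(config.grade2_mixture) * n2
    counts = np.floor(targets).astype(int)
    for _ in range(n2 - counts.sum()):
        counts[int(np.argmax(targets - counts))] += 1
    g2 = (
        ["G2_1like"] * counts[0]
        + ["G2_int"] * counts[1]
        + ["G2_3like"] * counts[2]
    )
    rng.shuffle(g2)
    classes += g2 + ["G3"] * n3
    return classes


def simulate_cohort(
    config: SynthConfig | None = None,
) -> tuple[list[StudyExpression], pd.DataFrame, LatentTruth]:
    """Simulate a multi-study cohort.

    Expression of gene g (in module m) in sample s:

        x[g, s] = scale[b, g] * (loading * activity[s, m] + eps) + shift[b, g]

    with b the study/batch of s, ``eps ~ N(0, noise_sd)``, per-batch
    per-gene additive shift ``~ N(0, batch_shift_sd)`` and multiplicative
    scale ``~ U(batch_scale_range)`` — the location-scale model that the
    empirical-Bayes batch adjustment removes. Background genes carry no
    activity term. Values are on a log2-like scale, so the returned
    studies are flagged ``scale="log2"``.

    Returns
    -------
    studies : list of StudyExpression, one per batch.
    metadata : DataFrame indexed by sample_id with columns
        study_id, who_grade, recurrence (yes/no/unknown).
    truth : LatentTruth
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = _draw_latent_classes(config, rng)
    n_samples = len(classes)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    grades = np.array([_CLASS_GRADE[c] for c in classes])

    n_modules = len(config.module_sizes)
    gene_ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    gene_module = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        gene_module[pos : pos + size] = m
        pos += size

    # round-robin batch assignment within each grade: every grade present
    # in >= min(n_batches, count) batches
    batch_of = np.empty(n_samples, dtype=int)
    for g in (1, 2, 3):
        idx = np.flatnonzero(grades == g)
        batch_of[idx] = np.arange(len(idx)) % config.n_batches

    # latent activity: class mean + individual variation
    activity = np.empty((n_samples, n_modules))
    for m in range(n_modules):
        means = np.array([_class_activity_mean(config, m, c) for c in classes])
        activity[:, m] = means + rng.normal(0.0, config.activity_sd, n_samples)

    loading = config.within_module_loading
    signal = np.zeros((config.n_genes, n_samples))
    for m in range(1, n_modules + 1):
        rows = gene_module == m
        signal[rows, :] = loading * activity[:, m - 1][None, :]

    noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    shift = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes))
    lo, hi = config.batch_scale_range
    scale = rng.uniform(lo, hi, size=(config.n_batches, config.n_genes))

    expr = signal + noise
    for b in range(config.n_batches):
        cols = batch_of == b
        expr[:, cols] = expr[:, cols] * scale[b][:, None] + shift[b][:, None]

    recur_p = np.array(
        [config.recurrence_probs[_CLASS_RECUR_KEY[c]] for c in classes]
    )
    recurred = rng.random(n_samples) < recur_p
    missing = rng.random(n_samples) < config.recurrence_missing_frac
    recurrence = np.where(missing, "unknown", np.where(recurred, "yes", "no"))

    study_ids = [f"study{b + 1}" for b in range(config.n_batches)]
    studies = []
    for b, sid in enumerate(study_ids):
        cols = np.flatnonzero(batch_of == b)
        studies.append(
            StudyExpression(
                study_id=sid,
                expression=pd.DataFrame(
                    expr[:, cols],
                    index=pd.Index(gene_ids, name="gene_id"),
                    columns=[sample_ids[i] for i in cols],
                ),
                scale="log2",
            )
        )

    metadata = pd.DataFrame(
        {
            "study_id": [study_ids[b] for b in batch_of],
            "who_grade": grades,
            "recurrence": recurrence,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = LatentTruth(
        latent_class=pd.Series(classes, index=metadata.index, name="latent_class"),
        gene_module=pd.Series(gene_module, index=pd.Index(gene_ids, name="gene_id"), name="module"),
        activity=pd.DataFrame(
            activity,
            index=metadata.index,
            columns=[f"M{m + 1}" for m in range(n_modules)],
        ),
    )
    return studies, metadata, truth


def truth_summary(truth: LatentTruth, metadata: pd.DataFrame) -> pd.DataFrame:
    """Latent-class counts and per-class recurrence rates.

    Rates are computed over samples with known recurrence; a class with
    no known-recurrence samples gets rate NaN.
    """
    rows = []
    for cls in LATENT_CLASSES:
        mask = truth.latent_class == cls
        rec = metadata.loc[mask.values, "recurrence"]
        known = rec[rec != "unknown"]
        rate = float((known == "yes").mean()) if len(known) else float("nan")
        rows.append(
            {
                "latent_class": cls,
                "n": int(mask.sum()),
                "n_known_recurrence": int(len(known)),
                "recurrence_rate": rate,
            }
        )
    return pd.DataFrame(rows).set_index("latent_class")
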