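# meningrade

Transcriptomic reclassification of WHO grade 2 meningiomas into
"grade-1-like" and "grade-3-like" subgroups.

WHO grade 1 (indolent) and grade 3 (aggressive) meningiomas behave
fairly homogeneously, but grade 2 tumors — 20–30% of all meningiomas —
are clinically heterogeneous, with a ~50% five-year recurrence rate that
histology cannot decompose. `meningrade` implements, as a reusable and
tested pipeline, a transcriptomic route out of that heterogeneity: learn
a gene-expression signature that separates grades 1 and 3, then read off
where each grade 2 tumor falls between those two poles.

The pipeline, aimed at computational biologists working with multi-study
bulk expression data:

1. **Preprocess** — per-study log2 transform and quantile normalization,
   merge on the shared gene set, global standardization to mean 0 / sd 1,
   and empirical-Bayes batch correction (ComBat) across studies.
2. **Differential expression** — per-gene log2 fold change
   FC = mean(grade 3) − mean(grade 1) with Welch *t* (or Mann–Whitney)
   p-values; significant when |FC| ≥ 1.5 and p ≤ 10⁻⁴.
3. **Co-expression network** — unsigned weighted network
   a<sub>ij</sub> = |cor(x<sub>i</sub>, x<sub>j</sub>)|<sup>β</sup>,
   topological overlap matrix
   t<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>) / (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),
   average-linkage clustering of 1 − t with a dynamic branch cut into
   gene modules, and one **meta-gene** per module (sign-fixed first
   principal component of the module's expression).
4. **Reclassify** — fuzzy C-means soft clustering of all samples in a
   feature space of grade-1-vs-3-discriminating meta-genes and single
   genes. The two clusters are oriented by the grade-3 : grade-1 ratio in
   the ≥80%-membership tails, and the separation of grades 1 and 3 is
   scored with a prevalence-balanced sigmoidal cost

   C = (1/N₁) Σ_{i∈S₁} 1/(1+e^{−α(P_i−0.5)}) + (1/N₃) Σ_{j∈S₃} 1/(1+e^{−α(0.5−P_j)})

   where P_k is the membership of sample k in the grade-3-enriched
   cluster and α ∈ {1, 5, 10, 100}. Features are chosen by greedy
   forward selection and backward elimination under C (grade 2 samples
   are clustered but never enter C). Grade 2 tumors are then labelled
   grade-3-like (P ≥ 0.8), grade-1-like (P ≤ 0.2) or intermediate.
5. **Validate** — recurrence contingency tables (chi-square, optional
   Yates correction, Fisher's exact as a diagnostic) and biological
   concordance: Pearson correlation of per-module median meta-gene
   expression between each grade-2 subgroup and its adjacent grade.

Because the original GEO cohorts are external, the package ships a
first-class **synthetic cohort generator**: a linear factor model with
planted co-expressed modules whose latent activity depends on grade,
grade 2 drawn as a mixture of grade-1-like / intermediate / grade-3-like
latent states, per-study location-scale batch effects, and recurrence
outcomes tied to the latent state. Every stage is tested end-to-end
against that ground truth.

## Worked example

```bash
meningrade simulate --seed 1 --out data/
meningrade run --in data/ --out runs/demo --seed 1
```

or, equivalently, in Python:

```python
from meningrade import SynthConfig, simulate_cohort, PipelineConfig, run_pipeline

studies, metadata, truth = simulate_cohort(SynthConfig(seed=1))
summary = run_pipeline(studies, metadata, PipelineConfig(master_seed=1),
                       out_dir="runs/demo")
```

On the default synthetic cohort (212 samples: 129 / 46 / 37 of grades
1 / 2 / 3 across six studies) this prints a summary like:

```json
{
  "n_samples": 212, "n_genes": 600, "n_modules": 4,
  "signature": {"features": ["module:M2", "module:M1"],
                "direction": "forward", "alpha": 10.0,
                "cost": 0.0197},
  "reclassification": {"grade1_like": 13, "intermediate": 13,
                       "grade3_like": 20},
  "fraction_reclassified": 0.717,
  "validation": {
    "recurrence": {"chi2": 4.87, "p_value": 0.027,
                   "rate_grade3_like_pct": 66.7,
                   "rate_grade1_like_pct": 14.3},
    "concordance": {"rho_grade1_vs_grade1_like": 0.954,
                    "rho_grade3_vs_grade3_like": 0.990,
                    "rho_differential": 0.989}
  }
}
```

Reading it: feature selection kept two module meta-genes (meta-genes
beat single genes under the cost C, here C ≈ 0.02 at α = 10, i.e. nearly
perfect grade 1 vs 3 separation); 33 of 46 grade 2 samples (72%) were
confidently reassigned; the reassigned subgroups recur at very different
rates (67% vs 14% among samples with known recurrence); and each
subgroup's module-level expression profile correlates strongly with its
adjacent grade (ρ ≥ 0.95) — the signal planted by the generator,
recovered end to end. Run directories additionally contain every
intermediate artifact as TSV (merged matrix, DE table, module
assignment, meta-genes, cost curves per α and direction, per-sample
memberships, contingency tables).

A cohort without grade 3 tumors (the external-validation situation) can
be pushed through a previously trained signature instead of re-training:

```bash
meningrade run --in validation_data/ --out runs/val \
    --signature runs/demo/signature.json
```

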