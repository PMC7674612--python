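# Methods

This note documents the models and procedures implemented in
`meningrade`, the assumptions behind them, the parameters that matter,
and the places where the design was genuinely open.

## The scientific procedure

The pipeline treats tumor-grade reclassification as a semi-supervised
problem: grades 1 and 3 define two well-separated biological poles, and
grade 2 samples are located between them. Concretely, a two-centroid
fuzzy C-means (FCM) model is fitted to *all* samples in a feature space
built from grade-1-vs-3-discriminating features; only the grade 1 and
grade 3 samples are used to score — and hence select — the feature
space; and each grade 2 sample is then labelled by its membership P_k in
the grade-3-enriched cluster. This "train on the poles, read off the
middle" design means grade 2 samples influence the centroids (they are
part of the clustered population) but never the signature choice.

### Preprocessing

Per-study matrices are log2(x+1)-transformed (the +1 offset keeps
RNA-seq zeros finite; for data already in log space the transform is
skipped), quantile-normalized within study (each sample's sorted values
are replaced by the across-sample mean of sorted values; ties receive
the mean of their tied reference quantiles), merged on the
lexicographically sorted intersection of gene sets, standardized to
grand mean 0 / grand sd 1 (population sd; the choice is immaterial at
cohort size but fixed for reproducibility), and batch-corrected with
parametric empirical-Bayes ComBat (scanpy's implementation of the
standard location-scale model; no covariates are protected). The order
log2 → quantile is an assumption — platform processing pipelines differ
on it — and is fixed here for determinism.

A note on ComBat and idempotence: the EB posterior removes a
prior-weighted *fraction* of each batch's residual location/scale
effect, so re-running ComBat on already-adjusted data still moves values
slightly (≈0.03 RMS at 20-sample batches on standardized data);
successive passes contract geometrically. The tests assert this
contraction rather than exact idempotence, which no EB formulation
provides.

### Differential expression

FC_g = mean(grade 3) − mean(grade 1) in log2 space; Welch's
unequal-variance t-test by default (Mann–Whitney U as an option — the
study design names both without assigning them). Significance uses the
fixed rule |FC| ≥ 1.5 and p ≤ 10⁻⁴ with no multiple-testing correction;
the thresholds are configuration values and change only the flags, never
the statistics.

### Co-expression network and modules

Unsigned weighted network a_ij = |cor|^β. β is either fixed by the user
or chosen as the smallest candidate power whose scale-free topology fit
reaches R² ≥ 0.80 (log10 frequency vs log10 connectivity over 10 bins),
falling back to the best-fitting power, or to β = 6 when the
connectivity distribution is too degenerate to bin. The topological
overlap matrix is

    t_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,  k_i = Σ_{u≠i} a_iu,

verified in the tests against a brute-force triple loop.

**Dynamic branch cut.** Modules are cut from the average-linkage
dendrogram of 1 − t by branch detection rather than a fixed-height cut:
with several hundred uncorrelated background genes, the upper 1% of
merge heights sits at the very top of the tree and any static cut there
returns a single blob. Instead:

1. *candidates* are the maximal subtrees with ≥ `min_module_size` genes
   that hang at least `gap` below their attachment height;
2. candidates at least twice the size floor are recursively split at
   their top merge while both children clear the size floor and the mean
   inter-child dissimilarity exceeds the looser child's internal scatter
   by `gap`;
3. a cohesion filter sends to the grey label (module 0) any candidate
   whose mean dissimilarity to non-members does not exceed its internal
   mean by `gap` (for a candidate spanning all genes the external
   reference is the maximal dissimilarity 1, so an all-noise matrix goes
   entirely grey while a genuinely one-module matrix survives, with a
   warning).

`gap = 0.20 − 0.05·deep_split`, `deep_split ∈ {0..3}`, default 3. The
default is deliberately the most aggressive setting: modules whose
activities are all driven by grade are mutually correlated, and at
looser gaps they merge into one super-module. On planted data, branch
attachment gaps of real modules measure 0.06–0.12 against ≤ 0.02 for
noise branches, so gap = 0.05 separates the two regimes cleanly;
`min_module_size` defaults to 30.

**Meta-genes.** Per module, genes are standardized across samples and
the first principal component score vector is taken as the module's
meta-gene, scaled to unit sample variance. PCA sign is arbitrary, so the
sign is fixed by positive correlation with the module's mean
standardized profile — without this, downstream grade comparisons and
concordance correlations would flip at random. The fraction of variance
explained by the first component is recorded; on planted one-factor
modules it approaches 1 and always dominates the second component.

### Fuzzy C-means and the balanced cost

Standard FCM with Euclidean distance on z-scored features: centroid
update c_j = Σ u_jk^m x_k / Σ u_jk^m, membership update
u_jk = 1/Σ_l (d_jk/d_lk)^{2/(m−1)}, fuzzifier m = 2, tolerance 10⁻⁶ on
the largest membership change, ≤300 iterations, best of 10 seeded
restarts by the objective Σ u^m d². A sample coincident with a centroid
receives hard membership. The objective trace is exposed and is
non-increasing (alternating minimization). The fuzzifier, distance,
initialization and restart policy were not specified by the study; these
choices favor reproducibility and are all configurable.

Cluster polarity: among samples with membership ≥ 0.80 to a cluster, the
grade-3 : grade-1 count ratio is computed with a +0.5 continuity guard
on both counts (the raw ratio is undefined when a tail holds no grade 1
samples); the larger ratio marks the grade-3-enriched cluster. If
neither tail contains any grade 1/3 sample, polarity falls back to
comparing median memberships of grade 3 vs grade 1 samples — and, in a
cohort with no grade 3 tumors at all, to the grade 1 samples alone
(the cluster avoided by grade 1 is taken as grade-3-enriched).

The separation cost weights grades 1 and 3 equally regardless of their
prevalence; C ∈ (0, 2), C = 1 exactly at uniform memberships, and for
perfectly separated equal-size groups C = 2/(1+e^{α/2}). Greedy forward
selection and backward elimination both run at every α in {1, 5, 10,
100}; all cost curves are recorded, and the reported signature is the
best (direction, feature set) at the reporting α (default 10 — the
study never states which α produced its final model, so this is a
configurable choice). Ties break toward the earliest pool position;
improvements below 10⁻⁶ stop the search. The single-gene candidate list
is capped at the 20 largest |FC| among DE-significant genes (the
original DE pool had six genes; an uncapped synthetic pool would be
hundreds and would only slow the greedy search).

Applying a trained signature to an external cohort (e.g. one with no
grade 3 samples) re-uses the saved module *gene lists* — meta-genes are
recomputed on the new cohort from those genes — rather than re-detecting
modules, since module numbering is not portable across cohorts.

### Validation

Recurrence is compared between groups on the samples with known status
(unknowns excluded); the 2×2 table is tested with Pearson's chi-square
(df = 1), the Yates-corrected variant is exposed (default off; the
headline bound holds under both), and Fisher's exact test is attached as
a diagnostic because expected counts in tables of this size drop
below 5. Biological concordance between a grade-2 subgroup and its
adjacent grade is the Pearson correlation across modules of per-group
median meta-gene expression (≥3 modules required), with per-module
Mann–Whitney flags at p ≤ 0.05; the differential variant correlates the
module-wise contrast median(G3) − median(G1) with
median(grade-3-like) − median(grade-1-like).

## The synthetic cohort generator

The generator is the package's test bed and encodes the structure the
method assumes. Expression of gene g (module m) in sample s of batch b:

    x_gs = scale_bg · (λ · a_sm + ε_gs) + shift_bg

with factor loading λ = 0.9, noise ε ~ N(0, 0.3²), per-batch per-gene
shift ~ N(0, 0.3²) and scale ~ U(0.8, 1.25) — the location-scale model
ComBat removes. Background genes carry no factor. A linear factor model
is the natural choice because it is exactly the implicit model of
first-PC meta-gene summarization. Per-sample activity a_sm is its latent
class's mean effect plus N(0, 0.5²) individual variation; the
intermediate grade-2 state sits at the midpoint of the grade 1 and
grade 3 effects (a "true biological intermediate").

Defaults mirror the published cohort shape: 129/46/37 samples of grades
1/2/3 over 6 studies (every grade present in ≥2 studies by round-robin
assignment); grade 2 mixed 13:12:21 into grade-1-like : intermediate :
grade-3-like; recurrence Bernoulli with probabilities 0.17 (grade 1),
0.05 (grade-1-like), 0.25 (intermediate), 0.75 (grade-3-like), 0.85
(grade 3); 97/212 ≈ 46% of recurrence labels masked to "unknown". The
gene dimension is scaled to desk size — 600 genes with five planted
modules of 60/50/40/40/30 genes (one of them carrying no grade effect,
as a null) — chosen so that network construction, module detection and
repeated FCM feature selection run in seconds per cohort while leaving
hundreds of background genes to stress module detection. Matrices are
emitted on a log2-like scale (the studies are flagged `log2`), so batch
effects are additive in the space where ComBat operates.

What the generator does **not** emulate: probe-level microarray
artifacts, platform-specific intensity distributions, count noise,
gene-gene correlation beyond the planted factors, censored follow-up
times, or annotation errors. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes when that structure is
present — not that the original clinical findings re-derive from raw
GEO data. In particular, the original 29 modules, the 61- and 121-gene
signature modules, and the exact 34-of-46 reclassification depend on
external accessions and unstated network parameters and are out of
scope here.

## Numerical and degenerate-input conventions

* All randomness descends from one master seed via
  `numpy.random.SeedSequence.spawn`; no stage touches global state, and
  identical configs reproduce bit-identical artifacts.
* Zero-variance genes: correlations set to 0 with a warning (network);
  p = 1 and "ns" (differential expression).
* Single-sample studies skip quantile normalization with a warning;
  single-gene modules use the gene's standardized profile as meta-gene.
* TOM denominators below 10⁻¹² map to overlap 0; entries are clipped
  to [0, 1].
* Reclassification thresholds are inclusive with a 10⁻¹² guard so that
  P exactly 0.20/0.80 is labelled, not left intermediate; at a
  degenerate threshold of 0.5 only P exactly 0.5 is intermediate.
* Zero-marginal contingency tables return (statistic 0, p 1) with a
  warning instead of failing.
* TSV dialect is fixed: tab-separated, UTF-8, '.' decimal, "NA" for
  missing; floats round-trip exactly (`float_precision="round_trip"` on
  read). A GEO-series-matrix-like dialect ('!'-comment lines) is
  accepted on input; duplicate gene ids keep the first row with a
  warning, duplicate sample ids are an error.

## Known limitations

* The branch-cut gap schedule is calibrated on TOM dissimilarities of
  the unsigned |cor|^β network; signed networks or very small β would
  shift the natural gap scale.
* ComBat is applied without covariate protection; with strongly
  grade-imbalanced batches some grade signal is attenuated along with
  the batch effect.
* The balanced cost is optimized greedily; neither direction guarantees
  the globally optimal feature subset.
* Recurrence is treated as a binary endpoint; time-to-recurrence
  modeling is out of scope.
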