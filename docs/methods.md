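# Methods

## The problem

Super-SILAC proteomics quantifies each patient sample against a common
heavy-labelled standard spiked in at 1:1. When the standard is assembled from
cell lines it misses part of the tissue proteome — notably secreted and
extracellular-matrix proteins — so a purely ratio-based analysis silently
drops exactly the proteins that often distinguish tumor subtypes. This
package implements a hybrid quantification that falls back to label-free
comparison for those proteins, followed by the matrix conditioning,
unsupervised analysis, enrichment and supervised panel selection needed to
classify two closely related tumor subtypes from the resulting protein
profiles.

## Synthetic cohort generator

Because the workflow is meant to be testable without patient data, the
generator produces peptide-level cohorts with the statistical structure the
analysis assumes:

- **Cohort design.** Two subtypes, 13 + 7 samples by default, mirroring a
  typical unbalanced cell-of-origin cohort. Default 1,000 proteins (a
  full-scale tissue proteome is ~6,000–9,000 protein groups; tests and the
  acceptance runs use 200–2,000 so everything completes in seconds to
  minutes).
- **Abundance model.** Per-protein base abundance is log10-normal, mean 7.0
  (a typical MS intensity scale) with spread `abundance_sd_log10` (default
  1.0, so the cohort spans several orders of magnitude). A fraction
  `frac_differential` of proteins receives a signed log2 fold change drawn
  uniformly from `log2fc_range` in subtype B.
- **Peptides.** Each protein yields 1 + Poisson(mean − 1) peptides (default
  mean 4). Each peptide has a log10-normal response factor (sd 0.5) shared
  across samples — peptide ionization efficiency varies much more than
  biological abundance between samples, which is exactly why the
  ratio-of-ratios design helps.
- **Channels.** Light intensity = sample abundance × response × noise; heavy
  intensity = subtype-free base abundance × response × noise (the standard is
  the same material in every sample), present only for the
  `frac_in_standard` fraction of proteins (default 0.8). Multiplicative
  noise is log-normal with coefficient of variation `noise_cv` (default 0.1,
  a realistic MS1 feature-level precision).
- **Detection (MNAR).** A peptide feature — the co-eluting light/heavy
  isotope pair — is detected as a unit with probability
  logistic((log10 intensity − midpoint) × slope), driven by the light
  intensity (defaults: midpoint 6.0, slope 2.0, i.e. features below ~10⁶
  counts are mostly lost). Detecting the pair as a unit rather than each
  channel independently reflects how SILAC feature detection behaves and
  keeps heavy-channel missingness attributable to standard membership; a
  `detection_slope` of 0 disables missingness entirely. Consequence: the set
  of proteins quantifiable only by the hybrid fallback coincides with the
  standard-absent set.
- **RNG discipline.** One `numpy` Generator seeded from `seed`, consumed in
  a fixed order (protein-level draws, then per-protein peptide draws, then
  per-peptide sample draws). Adding proteins or samples therefore changes
  subsequent draws; this is documented, not avoided.

What the generator does **not** emulate: retention time and charge states,
peptide identification errors, shared (razor) peptides across protein groups,
correlated biological covariation between proteins, batch effects, and
mixing-ratio error of the spike-in (light:heavy is exactly 1:1 in
expectation). Passing tests on these cohorts therefore demonstrates
correctness of the algorithms under the stated statistical model, not
robustness to every artefact of real FFPE data.

The annotation generator emits uniform random categories plus one planted
category enriched for the differential set (a known positive control) and an
"extracellular-like" category collecting the standard-absent proteins,
mimicking the real situation where the hybrid gain concentrates in
secreted/ECM categories.

## Hybrid quantification

Peptide pair rule (per peptide feature, per sample pair): ratio of SILAC
ratios when both samples have light and heavy; light ratio when both have
light but a heavy is missing; otherwise the peptide abstains. Mixed pools are
allowed — for one protein and sample pair, some peptides may contribute
SILAC ratio-of-ratios and others light ratios; the pairwise summary is the
**median** of all contributing peptide log2 ratios, kept when supported by at
least `min_ratio_count` peptides (default 1). The median is a deliberate,
robust simplification of the maximal-ratio-extraction step of the label-free
algorithm this scheme generalizes; exact bit-equivalence with that software
is not claimed.

Profile reconstruction solves the unweighted least-squares system
x_a − x_b = r(a,b) per connected component via a dense solve with an
appended mean-zero gauge row (the gradient of the gauge term vanishes at any
least-squares solution, so it selects the mean-zero representative without
perturbing the fit). Support counts are retained for a future weighted mode.
Anchoring: `sum_of_light` (default) rescales each component profile so its
total linear intensity equals the protein's total observed light intensity —
presentation only, since the algorithm defines relative intensities;
`geometric_mean_one` pins the mean log2 profile to 0 and is used when light
totals are unavailable (e.g. reconstructing from a bare ratio set).
Between-sample normalization is deliberately **not** part of quantification;
it happens downstream in width normalization, so quantification stays a pure
within-protein operation.

## Matrix conditioning

Fixed order: filter → impute → normalize.

- **Filter**: keep proteins with ≥ ceil(fraction × n_samples) valid values;
  0.75 × 20 ⇒ 15 (ceiling rounding, consistent with that worked value).
- **Impute**: per sample (columns), draws from
  Normal(m_j − downshift·s_j, (width·s_j)²), defaults width 0.3 and
  downshift 1.0; per-sample scope because the downshift mimics each run's
  detection limit, a per-run property. Sample sd uses ddof = 1. Observed
  cells are never modified (bitwise).
- **Width normalization**: subtract the sample median, divide by the sample
  IQR (Q3 − Q1, linear-interpolation quantiles); the common target IQR is 1.
  Zero IQR raises an error naming the sample.

## Unsupervised analysis

PCA treats samples as observations and proteins as variables, centers each
protein across samples, and decomposes by SVD. Sign convention: each loading
column is flipped so its largest-magnitude entry is positive, making results
deterministic. The best separating component pair maximizes the absolute
two-sample t statistic of scores between labels — an automated stand-in for
the manual choice of a separating pair on real cohorts (where, e.g.,
components 1 and 4 may carry the subtype contrast; such component indices
are data-set-specific and not reproducible synthetically).

Hierarchical clustering uses Pearson correlation distance (1 − r) with
average linkage — the standard heatmap choice; both are overridable. Constant profiles make the
distance undefined and raise an error naming the offending row. The subtype
split check cuts the sample dendrogram into exactly two clusters and demands
the bipartition equal the label bipartition.

## Enrichment

Fisher exact tests are two-sided by hypergeometric enumeration (the SciPy
implementation, verified in the test suite against an independent full
enumeration to 1e-12 for all tables with total ≤ 30). BH correction is the
standard step-up with monotonicity; significance cutoff 0.05.

"Associated with a component" is defined as |loading| above the 90th
percentile of that component's |loadings| (configurable) — there is no
standard formalization of component membership, so this is a documented
interpretation, as is the enrichment factor (in-category fraction among
associated proteins over the overall in-category fraction).

The 1D score s = 2U/(m(n−m)) − 1 uses mid-ranks for ties; the Mann–Whitney p
is exact when the larger group has ≤ 25 members and the values are tie-free,
and normal-approximated with tie correction otherwise. The 2D mode scores
both dimensions separately and combines significance conservatively as
min(1, 2·min(p_x, p_y)) before BH across categories — the two-dimensional
test combination is another under-specified point, resolved simply and
flagged here.

## Supervised panel selection

The moderated statistic d = (mean_A − mean_B)/(se + s0) uses the pooled
two-sample standard error; s0 (default 0.1, a conventional choice on
log2-scale data) damps low-variance features so larger fold changes rank
better. Parametric p-values come from a Student reference
with n_A + n_B − 2 df applied to |d| — exact at s0 = 0, a conventional
plug-in otherwise — and a permutation mode is provided for SAM-style
inference. Ranking sorts by ascending p with ties broken by |fold change|
then stable ID order.

Cross-validation: stratified random 90% training draws (stratification
prevents single-class held-out sets in an unbalanced 13-vs-7 cohort — a
documented deviation from plain random sampling), 1,000 repetitions by
default, feature ranking and SVM training on the training split only. The
per-k mean error pools misclassified held-out predictions over all
repetitions; optimal k is the smallest k attaining the minimum (parsimony).
Both the full-data top-k panel and per-feature CV selection frequencies are
reported, since a published panel may be finalized by either route. The
linear SVM uses soft-margin cost C = 1; note that on width-normalized data a
single feature's scale is small, so k = 1 fits can degenerate to the
majority-class solution — the error curve makes this visible rather than
hiding it.

Clustering-loss cutoff: scanning k upward (default every rank to 50, then
steps of 10), the cutoff is the largest k such that the two-cluster split is
correct at every scanned k′ ≤ k. For k ≤ 2 correlation distance is undefined
(one feature) or degenerate (two features leave one degree of freedom after
per-sample centering), so those scan points use Euclidean average linkage.
The statistic is intentionally strict — a single small-k failure ends the
scan — which makes it conservative and, on noisy cohorts, highly variable;
this mirrors its role as a rough "how deep does the signal reach" cutoff
rather than a precise estimator.

## Pipeline

`run_pipeline` executes simulate → quantify → preprocess → PCA → enrichment →
classify, serializing every stage artifact (TSV/JSON) for inspectability and
restartability. Stage seeds derive from the global seed plus fixed per-stage
offsets, so one seed reproduces a run byte-for-byte. Validation distinguishes
fatal schema errors (unknown samples in the label file, non-positive
intensities) from warnings (zero catalog overlap).

## Problem sizes

Unit tests run cohorts of 40–300 proteins; the end-to-end acceptance checks
use a 2,000-protein, 20-sample cohort with 50 planted differential proteins
and 100 cross-validation repetitions, and verify the quantification engine
against dense least-squares oracles on 500 random small instances. These
sizes were chosen so the full suite exercises every stage at meaningful
scale while completing in well under an hour on a single core.

## Known limitations

- The pairwise-ratio summary (median) and unweighted least squares are
  simplifications of the cited label-free reconstruction; no delayed
  normalization is performed.
- Protein groups are taken as given; no shared-peptide reassignment.
- Imputation supports only the downshifted-Gaussian family; no kNN or
  minimum-value variants.
- Two classes only; no multiclass extension, kernel search or survival
  analysis.
- Enrichment treats categories as flat sets; no ontology-graph propagation.
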