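# Methods

`ithfish` quantifies intratumor heterogeneity from single-cell in situ
measurements of HER2-positive breast tumors — combined immunofluorescence
(ER and HER2 protein) and FISH (*HER2* gene copies, centromere 17) scored
per tumor cell — and relates heterogeneity and its change under neoadjuvant
therapy to clinical outcome. This note documents the models, conventions and
numerical choices, and what the synthetic cohorts do and do not establish.

## Cell classification

Each cell carries two adjusted fluorescence intensities on a 12-bit scale
(0–4095) and the total *HER2* probe pixel area within its nucleus. The
package assumes background/perinuclear adjustment happened upstream in the
image-analysis pipeline that produced the table; the `intensities_adjusted`
provenance flag records this assumption.

* **Phenotype (4-way):** HER2+ iff HER2 intensity > 300; ER+ iff ER
  intensity > 50. Positivity is *strictly greater* than the cutoff. The
  published ranges state only that the thresholds "define" positive cells;
  strict inequality is the convention that makes the pixel bands below
  (inclusive upper bounds on the lower class) internally consistent, and it
  is echoed into every run report.
* **Genotype (3-way):** norm ≤ 63 px (~up to 3 gene copies), gain 64–200 px
  (~3–6 copies), amp > 200 px (> 6 copies), from total probe area.
* **Combined (12-way):** the phenotype × genotype pair; its marginals equal
  the 4-way and 3-way counts by construction (tested).

Patient-level ER status uses the clinical 1% rule on pre-treatment cells:
ER+ iff ≥ 1% of cells are ER-positive (the negative class is defined by
< 1%, so the cutoff is inclusive). ER strata are negative < 1%, low [1, 10]%,
intermediate (10, 50]%, high > 50%; the printed ranges overlap at 10 and 50,
and the lower-inclusive/upper-inclusive resolution is exposed in the run
report.

## Diversity indices

Per (patient, timepoint) sample, the composition over a category system
(4/3/12-way, or the 3 spatial patterns) is the vector of class fractions.

* **Shannon index** `SI = −Σ f_i log2 f_i` (bits; 0·log 0 := 0). Base 2 is
  used throughout: the reported group-mean SI of 1.2 for a 3-category system
  exceeds ln(3) ≈ 1.10 and is only attainable in bits.
* **Kullback–Leibler clonal shift** `K-L = Σ P_i log2(P_i/Q_i)` with P the
  pre-treatment and Q the post-treatment composition, i.e. D(pre ‖ post).
  Empty categories certainly occur (many tumors lack entire classes); when
  either vector has a zero and `epsilon > 0` (default 1e-6), the affected
  vector receives an additive epsilon pseudo-fraction and is renormalized.
  With `epsilon = 0`, a category with Q_i = 0 < P_i raises an
  infinite-divergence error telling the caller to smooth.
* **Median split:** patients strictly above the cohort median K-L are
  `KL_high`, the rest `KL_low`; ties at the median go low (deterministic).
  An all-identical cohort triggers a degenerate-split warning.

## Composition clustering

Agglomerative clustering of per-sample fraction vectors, Ward linkage on
Euclidean distances, tree cut at k = 3 by default — the published analyses
report three groups per system but name neither linkage nor metric, and Ward
on fractions is the conventional default. k, linkage and metric are config
options; an optional centred-log-ratio transform (pseudo-count 1e-6) is
provided for a compositional-geometry variant but is off by default because
the reference analysis clusters raw fractions. Cluster ids are relabeled
contiguously in input order, which makes results order-invariant up to label
permutation (tested by shuffling). A forced 3-cut of a single unstructured
archetype still reaches silhouette ≈ 0.3–0.45 (convex cuts of unimodal
scatter always score moderately), so k is documented as an analyst choice;
the test suite checks the *contrast* with genuinely separated archetypes
(silhouette ≈ 0.88) rather than a small absolute value.

## Intranuclear spatial patterns

Cell-level labels (cluster / scatter / mix) are aggregated per sample into
frequencies; the sample class is the pattern reaching the 70% majority
cutoff (inclusive: 70 of 100 scored cells qualifies), else `heterogeneous`.
The scoring convention is 100 cells per biopsy; with fewer labeled cells all
available ones are used and `n_scored` records the shortfall. Frequencies
map to ternary coordinates by the barycentric transform with pure patterns
at the triangle corners (cluster at the origin, scatter at (1,0), mix at the
apex) — a bijection from the 2-simplex, inverted in a property test.

`classify_spot_pattern` scores a pattern from spot centroids via
single-linkage grouping at 1.5 spot-diameter units: one group holding ≥ 80%
of spots (and more than 2) → cluster; no group above 2 spots → scatter; else
mix. The reference study scored patterns visually; this classifier exists so
synthetic nuclei with known patterns are machine-scorable and makes no claim
of fidelity to human scoring.

## Outcome statistics

Two-sided throughout. Per-sample biomarker means (mean probe area as the
copy-number proxy, cent17, per-cell area/cent17 ratio over cells with a
positive count — skipped cells are counted — and both intensities) are
compared between patient groups by Welch's t-test or the Wilcoxon rank-sum
test; both are offered because the source analysis uses both. Fisher's exact
test: 2×2 exactly via the hypergeometric distribution (scipy); r×c by a
seeded Monte Carlo permutation of the margins with the add-one estimator
(no installed package provides the exact network algorithm), validated
against full enumeration on small tables. Kaplan–Meier, the log-rank test
and univariate Cox regression (Efron tie handling, Wald 95% CI) delegate to
lifelines. Monotone-likelihood Cox cases (constant covariate, no events, a
binary covariate with all events in one group) raise a non-identifiability
error rather than returning a diverged estimate. No multiple-testing
correction is applied by default (matching the reference analysis); a
Benjamini–Hochberg switch exists for the five-marker panel.

## Synthetic cohorts

Samples are subclone mixtures. Each subclone fixes intensity locations
(log-normal draws with log-sd 0.5, clipped to [0, 4095]; medians 1200/80 for
HER2±, 400/12 for ER±, placing ~0.2–0.4% of cells across the intensity
threshold), a pixel-area band (normal truncated at zero, centres 30/130/400
px with sds 10/21/60 so each band edge sits ~3.3 sd out: crossings occur at
a few per thousand cells but do not distort compositions), a spatial-pattern
propensity (amplified subclones cluster-heavy, normal-CN subclones
scatter-heavy) and Poisson(2) cent17 counts with 5% missing. Survival is
exponential (mean 60 months disease-free, 90 months overall at baseline)
scaled by the planted hazard multiplier, with administrative censoring at
the time giving 30% censoring under baseline hazard. All randomness flows
from one integer seed; equal seeds give byte-identical cohorts.

Scenario presets are the study conditions for the tests:

* `homogeneous_amp` — one HER2+/ER+ amplified subclone (degenerate mixture).
* `three_archetypes` — 36 patients in three groups whose phenotype-mixture
  centroids are (0.85, 0.05, 0.05, 0.05), (0.05, 0.85, 0.05, 0.05) and the
  uniform (0.25, …); Dirichlet concentration 150 controls within-group
  scatter. The uniform archetype is the high-entropy group.
* `kl_contrast` — 40 patients; pre-treatment genotype fractions drawn
  Dirichlet (concentration 60) around (0.5, 0.3, 0.2) floored at 0.02; the
  post-treatment composition lies on the segment from the pre vector toward
  an amp-takeover direction, with the mixing weight solved by scalar root
  finding so the planted divergence is hit to machine precision (1 bit for
  half the cohort, 0.05 bit for the other half). The direction ladder
  (0.05, 0.15, 0.80) → (0.02, 0.08, 0.90) → (0.01, 0.01, 0.98) uses the
  mildest direction that can reach the target: near-vertex targets leave
  tiny post-treatment masses whose small counts dominate the variance of the
  estimated divergence. Low-shift patients carry a 3× hazard, mirroring the
  clinical observation that static clonal composition under therapy
  accompanies worse outcome.
* `null_no_shift` — pre and post identical; every true K-L is exactly 0.

What the generator does **not** emulate: spatial correlation between
neighboring cells, image-to-image batch effects within a biopsy, intensity
dependence on copy number, non-proportional hazards, or informative
censoring. Passing recovery tests therefore demonstrates correctness of the
estimators and the pipeline plumbing under the stated model, not robustness
to those real-data features.

## Numerical notes and known limitations

* The plug-in K-L estimator at N cells has bias ≈ (M−1)/(2N ln 2) and, for a
  1-bit shift, standard deviation ≈ 0.03 bits at N = 10⁴ (delta method:
  Var ≈ Var_P[log2(P/Q)]/N + Σ P_i²/Q_i/(N ln²2)). Recovery tests
  therefore bound the *mean* error over ≥ 20 independent cohorts (observed
  ≲ 0.01 bits per planted level) rather than every single draw at the high
  level; single-draw bounds hold at the 0.05-bit level and for composition
  fractions (≤ 0.03 at 10⁴ cells).
* Problem sizes in the simulation suites (20 seeds × 10⁴ cells for recovery,
  100 cohorts of 40 patients × 300 cells for effect recovery, 100/500
  replicates for Cox coverage and log-rank calibration) were chosen as the
  smallest sizes at which the targeted properties are statistically stable.
* File round-trips are byte-exact: numeric columns are validated with the
  tolerant pandas parser but converted with numpy's correctly rounded one.
* Multiple images per biopsy are pooled into one (patient, timepoint)
  sample; `image_id` is kept for audit only. Samples with fewer than 50
  cells (configurable) are excluded with a per-sample report, since sparse
  post-therapy biopsies yield unstable fractions.
* The ratio HER2 CN / cent17 uses per-cell probe area over spot count;
  cells with missing or zero cent17 are excluded and counted. Whether this
  matches the reference pipeline's per-cell handling is unknowable from the
  published description.
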