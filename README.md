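# ithfish

Single-cell intratumor-heterogeneity analysis for HER2-positive breast
tumors, from quantified in situ measurements: combined immunofluorescence
(ER, HER2 protein) and FISH (*HER2* gene copies, centromere 17) scored per
tumor cell.

Tumors are mixtures of cell subpopulations that differ in receptor
expression and *HER2* copy number, and both the degree of that mixing and
its change under neoadjuvant therapy carry prognostic information. `ithfish`
turns a per-cell measurement table into those quantities:

* **Classification** — each cell into 4 phenotypes (HER2±/ER±, intensity
  thresholds 300 and 50 on the 12-bit scale), 3 genotypes by *HER2* probe
  pixel area (norm ≤ 63 px, gain 64–200 px, amp > 200 px) and the 12-way
  combined class; patient ER status by the clinical 1%-positive rule with
  negative/low/intermediate/high strata.
* **Diversity** — per-sample composition vectors; within-sample
  heterogeneity as the Shannon index `SI = −Σ f_i log2 f_i` (bits);
  treatment-induced clonal shift as the Kullback–Leibler divergence
  `K-L = Σ P_i log2(P_i/Q_i)` between pre-treatment (P) and post-treatment
  (Q) compositions, with the cohort split at the median K-L into
  KL-high/KL-low groups.
* **Clustering** — Ward hierarchical clustering of composition vectors into
  phenotype (P), genotype (G) and combined (PG) tumor groups.
* **Spatial patterns** — intranuclear *HER2* signal patterns (cluster /
  scatter / mix) aggregated per sample by a 70% majority rule, with ternary
  plot coordinates.
* **Outcome statistics** — Welch / Wilcoxon biomarker comparisons, Fisher's
  exact test, Kaplan–Meier curves, log-rank tests and univariate Cox
  regression (via lifelines).
* **Synthetic cohorts** — a generator with planted ground truth (subclone
  mixtures, exact planted K-L targets, hazard multipliers) so every stage is
  verifiable end to end.

## Worked example

Simulate a 40-patient cohort in which half the patients undergo a large
clonal shift under therapy (planted K-L = 1 bit) and half a negligible one
(0.05 bit), with a 3× death hazard planted on the low-shift group, then run
the full analysis:

```python
from ithfish.pipeline import run_pipeline

res = run_pipeline(
    {"scenario": {"name": "kl_contrast"}, "seed": 42, "systems": ["genotype3"]},
    out_dir="demo_out",
)
print(res.summary["clonal_shift"])
print(res.summary["survival"])
print(res.summary["cox_kl_continuous"])
```

prints

```
{'system': 'genotype3', 'n_paired_patients': 40, 'kl_median_bits': 0.4848952266118102,
 'kl_max_bits': 1.642340705581974, 'n_high': 20, 'n_low': 20, 'degenerate_split': False}
{'endpoint': 'os', 'logrank_stat': 6.496510218676096, 'logrank_p': 0.010808644176026274}
{'hr': 0.44668750118281103, 'ci': [0.2164999107400702, 0.9216157319921449],
 'p': 0.02919401210404588}
```

Reading: the 40 estimated K-L indices split 20/20 at the cohort median of
0.48 bits, exactly separating the two planted groups. Overall survival
differs between the recovered KL-high and KL-low groups (log-rank
p ≈ 0.011), and treating the K-L index as a continuous covariate gives a
Cox hazard ratio of 0.45 per bit (95% CI 0.22–0.92): *larger* clonal shifts
under therapy go with *lower* hazard, i.e. the planted effect — tumors whose
composition does not respond carry the excess risk — is recovered with the
correct direction. `demo_out/` additionally contains the per-cell
classification table, composition and Shannon tables, cluster assignments
with linkage records, spatial profiles with ternary coordinates, the
per-patient delta table sorted by decreasing K-L, `summary.json` and a
plain-text report echoing every threshold and convention in force.

The same pipeline runs from the shell:

```sh
ithfish run --scenario kl_contrast --seed 42 --out demo_out
ithfish scenarios            # list synthetic presets
ithfish simulate --scenario three_archetypes --out sim_out
```

Real data enter through a YAML config pointing at per-cell and per-patient
CSV/TSV tables (column-name mapping supported; see
`ithfish.cohort.read_cells`).

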