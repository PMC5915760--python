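# endoprot

Label-free quantitative (LFQ) proteomics analysis of
endometriosis-associated ovarian carcinomas, packaged as a tested,
reusable pipeline. It takes a MaxQuant-style `proteinGroups.txt` matrix
for a cohort of clear cell carcinoma (CC), endometrioid carcinoma (EC),
endometriosis (EMT) and benign endometrium (END) tissues and carries it
through:

1. **Preprocessing** — ≥2-unique-peptide filtering, decoy/contaminant
   removal, log2 transform, and missing-not-at-random imputation: each
   missing cell in sample *j* is drawn from
   N(μⱼ − 1.0·σⱼ, (0.3·σⱼ)²), where μⱼ, σⱼ are the observed mean and SD
   of that sample column (the Gaussian down-shift model of low-signal
   values).
2. **QC** — inter-patient Pearson correlation, within-cohort outlier
   flagging, housekeeping-protein stability.
3. **Multivariate structure** — PCA by SVD on centered log2 values;
   average-linkage hierarchical clustering under Euclidean distance on
   z-scored rows.
4. **Differential testing** — one-way ANOVA with Benjamini–Hochberg
   control; empirical-Bayes moderated t statistics with the variance
   prior (d₀, s₀²) estimated by digamma/trigamma moment matching on log
   sample variances, t = Δx̄ / √(s̃²(1/n₁+1/n₂)),
   s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀+d df; and the S0 volcano rule
   t_S0 = Δx̄/(se + S0).
5. **Disease-marker calling** — for each progression transition
   (END→EMT, EMT→cancer), a one-sided moderated test with the control
   cohort's variance replaced by its conservative chi-square
   upper-confidence bound (n−1)s²/χ²_γ(n−1); the one-sided p-values feed
   the two-group mixture model: z = Φ⁻¹(1−p),
   lfdr(z) = π₀·f₀(z)/f̂(z) with f̂ a Gaussian-kernel density estimate and
   π₀ from the right-boundary histogram rule; the posterior of elevation
   is 1 − lfdr on the right tail. Proteins are labelled by which
   transitions clear a posterior threshold τ: pattern **A** (both — a
   progressive increase END→EMT→cancer), **B** (only END→EMT), **C**
   (only EMT→cancer); the union is the disease-marker set.
6. **Signatures and enrichment** — direction concordance of external
   gene signatures with protein fold changes, signature-based cohort
   discrimination (2-cut clustering + adjusted Rand index), and
   hypergeometric over-representation against local GMT gene sets.

A synthetic-cohort generator (`endoprot.simulate`) reproduces the study
design — 21 samples in unbalanced cohorts 6/7/3/5, log-normal
intensities, progressive effect patterns, housekeeping proteins, and
logistic intensity-dependent dropout emitted as zero intensities — with
full ground truth, so every stage is testable without any download.

## Worked example

The numbered drivers under `analysis/` run the whole study on one seeded
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py
python analysis/03_multivariate.py
python analysis/04_differential.py
python analysis/05_disease_markers.py
python analysis/06_signatures.py
```

Output of the run at seed 1:

```
cohort: 21 samples, 5000 protein groups
missing (zero-intensity) cells: 12.3%
filter report: {'input': 5000, 'removed_low_peptides': 267, ... 'survivors': 4733}
within-cohort correlation floors: {'CC': 0.847, 'EC': 0.847, 'EMT': 0.841, 'END': 0.828}
flagged outliers: none
housekeeping median log2 SD: 0.746 (simulated residual SD 0.7)
PC1/PC2 explained variance: 16.5% / 5.2%
2-cluster ARI vs cancer/control labels: 1.000
CC vs EMT/END: 127 proteins at BH FDR 0.01 (of 4733)
EC vs EMT/END: 142 proteins at BH FDR 0.01 (of 4733)
CC: pi0 = (1.00, 1.00); 41 markers (A/B/C = 0/13/28)
  vs ground truth: sensitivity 0.15, FDP 0.00
signature discrimination ARI: cancer vs control 1.00, EMT vs END -0.06
```

Reading this: 4733 of 5000 simulated protein groups survive the
two-peptide filter; patients correlate at r ≥ 0.83 within each cohort
(no outlier falls below the 0.75 flag threshold); unsupervised
clustering separates tumours from benign tissue perfectly (ARI 1.0)
while a cancer-shift signature cannot separate EMT from END (ARI ≈ 0);
ANOVA at FDR 0.01 enriches ~127 CC-variable proteins; and the posterior
marker procedure calls 41 CC markers with zero false discoveries — at a
0.9 posterior cutoff it is highly conservative, recovering ~15% of the
300 proteins that truly carry a progressive pattern (see
`docs/methods.md` on the power of the local-fdr threshold at this
design size).

Alternatively, `endoprot.pipeline.run_pipeline(PipelineConfig(...))`
executes all stages from one (optionally YAML) configuration with a
single seed and writes a JSON manifest; real MaxQuant exports enter
through `protein_groups=` / `annotation=` paths instead of the
simulation block.

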