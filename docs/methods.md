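# Methods

## Data model

The pipeline operates on a protein-group × sample matrix of MaxLFQ-style
intensities (arbitrary units) in the MaxQuant `proteinGroups.txt`
dialect. Zero intensity means "not quantified in this run"; the pipeline
treats those cells as missing-not-at-random, because LFQ dropout
concentrates near the detection limit. Samples belong to one of four
cohorts: clear cell carcinoma (CC), endometrioid carcinoma (EC),
endometriosis (EMT) and benign endometrium (END); the presumed disease
progression is END → EMT → carcinoma, with each carcinoma subtype
analyzed separately.

## Preprocessing

* **Filtering.** Groups with fewer than 2 unique peptides, decoy
  (reverse) hits and contaminants are removed; the filter report records
  counts per criterion.
* **Imputation.** Per sample column with observed mean μ and sample SD
  σ (n−1 denominator), each missing cell is an independent draw from
  N(μ − downshift·σ, (width·σ)²). Defaults `width = 0.3`,
  `downshift = 1.0` (fractions of the observed SD) are the parameters
  the tissue study used; the common alternative down-shift of 1.8 is a
  configuration away. Imputation is per column rather than whole-matrix
  because per-run sensitivity differs; observed cells are never touched
  (asserted bitwise in the tests).
* **z-scoring** for clustering uses the population SD (divide by n),
  matching common heatmap tooling; the choice is configurable and
  invisible to clustering topology.

## Quality control

Pairwise Pearson correlation between samples, either on the complete
imputed matrix (default) or restricted per pair to cells observed in
both samples (deterministic, imputation-free mode). A sample is flagged
as an outlier when its *best* within-cohort correlation falls strictly
below a threshold (default 0.75, between the ~0.80 within-cohort floor a
healthy cohort shows and the ≤0.72 of a genuinely discordant sample);
singleton cohorts are never flagged. Flagged samples are only excluded
downstream when explicitly requested — exclusion is a judgement call.

## Differential testing

* **ANOVA.** One-way fixed-effects F across the named cohorts (3 groups
  for "cancer vs EMT/END"; a pooled 2-group mode exists), with
  Benjamini–Hochberg step-up control (default FDR 0.01). Proteins
  constant across all samples get F = 0, p = 1.
* **Moderated t.** The variance prior (d₀, s₀²) is fitted by moment
  matching on log sample variances: with z = log s² and residual df d,
  e = z − ψ(d/2) + log(d/2) has variance ψ′(d/2) + ψ′(d₀/2); the excess
  of var(e) over the sampling term is inverted through ψ′ (Newton, rel.
  tol 1e−8) to give d₀, and mean(e) gives s₀². Zero or negative excess
  dispersion returns d₀ = ∞ (complete shrinkage; the t reduces to a
  z-test against s₀²). The moderated statistic uses
  s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀+d degrees of freedom; infinite df is
  capped at 1e7 for tail evaluation.
* **S0 volcano rule.** t_S0 = Δ/(se + S0) with p-values from the t
  distribution on the unmodified df and BH at the configured FDR
  (defaults FDR 0.05, S0 = 1). The analytic construction is used rather
  than permutation FDR: it is deterministic and matches the curve-based
  significance boundary closely. Note that S0 = 1 (one log2 unit added
  to the SE) is a strict rule at this design size: with n = (6, 3) even
  a 3-log2-unit shift does not clear BH, which is consistent with the
  small concordant-and-significant counts this kind of analysis reports.

## Disease-marker procedure

For each adjacent transition (END→EMT, EMT→cancer):

1. **Conservative control model.** The earlier (control) cohort's
   per-protein variance is replaced by the upper bound of its (1−γ)
   chi-square confidence interval, (n−1)s²/χ²_γ(n−1), γ = 0.25 by
   default. This never deflates the variance (γ ≤ 0.5 enforced) and
   demonstrably reduces the null false-positive rate; the inflation is
   substantial at these cohort sizes (×2.08 at n = 5, ×3.48 at n = 3).
2. **One-sided moderated test** of elevation in the later cohort, the
   control variance entering the pooled estimate.
3. **Right-boundary π₀.** The p-value histogram (20 bins) is scanned
   left to right; the first bin whose density is ≤ the tail estimator
   #{p > λ}/(m(1−λ)) computed at its right edge selects λ*, and
   π₀ = π₀(λ*) clipped to [0, 1]. On exactly uniform p-values this
   returns 1.0; concentrating p-mass near 0 can only lower it.
4. **Two-group model.** z = Φ⁻¹(1−p); the marginal f̂ is a Gaussian KDE
   with Silverman bandwidth 0.9·min(SD, IQR/1.34)·m^(−1/5);
   lfdr = clip(π₀f₀(z)/f̂(z), 0, 1) with f₀ the standard normal
   (default) or a normal fitted to the central half of z (median
   location, IQR/1.349 scale; empirical-null mode). The posterior of
   elevation is 1 − lfdr for z > 0 and 0 otherwise. p-values exactly at
   0 or 1 are clamped to [1/(m+1), m/(m+1)] with a warning.
5. **Pattern classification** at posterior threshold τ (default 0.9):
   A = both transitions elevated, B = only the first, C = only the
   second; markers = A ∪ B ∪ C. The source analysis states no numeric
   cutoff; 0.9 is a conventional high-confidence level and is exposed as
   a parameter.

**Power at this design size.** A posterior threshold of 0.9 means
lfdr ≤ 0.1, which the two-group model only grants deep in the right
tail. At effect 2.0 log2 units, residual SD 0.7 and cohorts (6, 3, 5),
the per-transition noncentrality is ≈3.9 while the lfdr = 0.1 crossing
sits near z ≈ 3.4 even for an oracle fit with known π₀ and known
marginal — an intrinsic per-transition detection ceiling of ≈0.7, which
the conservative variance inflation lowers further (realized marker
sensitivity ≈0.15–0.2 at τ = 0.9, with false-discovery proportion ≈0).
The procedure is deliberately specific rather than sensitive; lowering τ
or γ trades in the other direction.

## Synthetic cohort generator

Emulates: 21 samples in cohorts 6/7/3/5 (the study's Table-1 design),
per-protein log2 baselines ~ N(25, 2²), within-cohort residual SD 0.7,
progressive patterns on 2% of proteins each (A: +e at EMT, +2e at
cancer; B: +e at EMT with a cancer ceiling; C: +e at cancer only;
e = 2.0 log2 units by default), 50 housekeeping proteins with equal
means everywhere, and dropout acting on the realized noisy value with
P(missing|x) = logistic(α − βx), α = 21.9, β = 1.0 — calibrated so a
protein one SD below the mean intensity drops out ~25% of the time,
giving ~12% missing cells overall (the study does not report its missing
rate; these are documented defaults, not fitted values). Intensities are
exported on the raw scale (2^x, 0 = missing) through the same
`proteinGroups` dialect the real input uses, so the full preprocessing
path is exercised.

Not emulated: peptide-level evidence, retention time or spectra,
correlated protein modules, batch effects beyond an optional additive
shift, cohort-specific variance differences, and biological covariance
between markers. Passing tests therefore demonstrate the statistical
machinery under the assumed generative model, not robustness to every
artefact of real tissue data.

## Numerical and determinism choices

* One pipeline seed; each randomized stage draws from a named substream
  (seed, CRC32 of stage name), so adding stages never changes another
  stage's draws. Identical config + seed ⇒ byte-identical outputs.
* Hierarchical clustering: Euclidean distance with average linkage
  (UPGMA, the tool-of-record default; single/complete/ward available);
  k-cluster extraction removes the k−1 highest merges.
* PCA signs are fixed by making the largest-magnitude loading positive.
* BH is the statsmodels step-up implementation, cross-checked against a
  brute-force oracle; ORA is the scipy hypergeometric tail,
  cross-checked against combinatorial enumeration.
* Gene → protein mapping is case-insensitive exact symbol matching;
  multi-mapping resolves to the group with the highest mean abundance.

## Problem sizes used in tests and the acceptance run

The acceptance script simulates one 5000-protein, 21-sample cohort
(≈8 s end to end). Test-suite simulations use 250–2000 proteins per
replicate: marker-recovery statistics aggregate 25 replicates at 2000
proteins, null calibration pools 200 replicates at 250 proteins, and the
discrimination asymmetry takes medians over 10 replicates at 500
proteins — sizes at which every quantity under test has comfortably
converged while the full suite stays fast.

## Known limitations

* The marker procedure's sensitivity at τ = 0.9 is intrinsically limited
  at this cohort size (see above); reported marker sets should be read
  as high-precision shortlists.
* The KDE-based lfdr is unstable in extreme tails with very few
  proteins (<~500); π₀ estimation refuses to run below 50 p-values.
* Only two-group and one-way designs are supported; no permutation FDR;
  no GO-graph handling beyond flat gene sets.
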