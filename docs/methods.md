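# Methods

## Pipeline model

The method estimates a sample-level ancestry representation from methylation
array data alone. Its premise: the beta value of a CpG probe whose
interrogated site overlaps a common SNP (distance 0, MAF ≥ 0.05) is partly
determined by the local genotype, so a PCA over many such probes recovers
population structure — provided nuisance variation is removed first.

Stages, in fixed order:

1. **Probe selection.** All probes with SNP distance ≤ 0 bp and MAF ≥ 0.05
   (inclusive) from the array's annotation, in annotation order. For EPIC v1
   the probe must additionally be listed by at least one published
   annotation source (`source_flags` non-empty), reflecting how that array's
   SNP-overlap lists are curated. The realized probe counts on real
   annotations (≈7300 for 450K, ≈3600 for EPIC v1, ≈2700 for EPIC v2) depend
   on annotation versions and are treated as documentation, not contract.
2. **Detection-p masking.** Entries with detection p > 1e-16 are set missing
   in both channels. The aggressive threshold reflects that SNP-probe signal
   is strong when present; a liberal threshold would let background noise
   into the PCA.
3. **Probe filters.** Strict rules: a probe is dropped when the share of
   samples with bead count < 3 exceeds 5 %, or (otherwise) when its missing
   share exceeds 10 %. A probe failing both is booked once, under the
   bead-count reason, so the filter report partitions removals exactly.
4. **Quantile normalization** of meth and unmeth intensities separately,
   stratified by probe chemistry (type I green / type I red / type II),
   since the two assay designs have different intensity distributions and
   joint normalization would distort both. Reference = mean of order
   statistics; with missing values each sample's sorted vector is
   interpolated onto a common quantile grid before averaging; ties receive
   the mean of the reference values their rank span covers; missing entries
   re-inserted. `strata="joint"` is available for comparison.
5. **Beta values**: β = M/(M+U+100). The 100 AU offset (ecosystem
   convention) stabilizes low-intensity ratios and keeps β < 1.
6. **Imputation** by k nearest probes (k = 5): donors ranked by mean squared
   difference over mutually observed samples, imputed value = mean of the
   k nearest donors observed at that sample, clipped to [0, 1]. Entirely
   deterministic; a fully missing probe is an error (the call-rate filter
   prevents it).
7. **Residualization.** Design X = [intercept, sex (0/1), age, cell-type
   PCs, 10 control-probe PCs]. Control-probe intensities are log2(x+1)
   transformed and per-probe standardized before their PCA so a few bright
   probe classes cannot dominate the technical axes; cell-type proportions
   are centered (rank ≤ K−1 on the simplex; default number of cell PCs
   min(K−1, 6), configurable because cohorts differ). Constant columns
   (single-sex cohorts) are dropped with a warning rather than failing.
   Per probe, OLS residuals via the design's QR factorization —
   mathematically identical to per-probe regression fits but one matrix
   product for all probes; residuals are exactly orthogonal to every design
   column.
8. **Genotype augmentation.** rs-probe betas are trimodal; the default
   caller thresholds at 0.25 / 0.75 with an inclusive heterozygote band,
   encoding calls as 0 / 0.5 / 1 (half dosage) so the genotype block lives
   on the same numeric scale as beta residuals and cannot dominate the
   unscaled PCA. A 3-cluster 1-D k-means caller (centers initialized at
   0.05/0.5/0.95, deterministic) is available as `caller="kmeans"`.
   rs probes with call rate < 0.9 are dropped; remaining no-calls take the
   probe's mean call.
9. **PCA**: column-centered SVD without variance scaling (residual
   magnitudes are meaningful); scores U·S; sign fixed so each component's
   largest-magnitude entry is positive (backend-independent results).
   Explained variance = S²/ΣS² over all components. Scores min–max scaled
   to [0, 1] per component by default (`scale=False` to disable), applied
   over the analyzed samples for cross-variant comparability.

Variants: `raw` stops after stage 6 (PCA of betas), `residualized` after 7,
`augmented` runs all stages.

## Evaluation battery

All clustering metrics use the first three min–max-scaled PCs with Euclidean
distance. Silhouette s(i) = (b−a)/max(a,b) with singleton clusters scored 0
(scikit-learn's convention; verified against a brute-force pairwise oracle
in the tests). Centroids are coordinate-wise means; cluster density = mean
distance to own centroid; separation = centroid–centroid distances.
PC–group association uses one-way ANOVA when per-group Shapiro–Wilk and
median-centered Levene checks all exceed α = 0.05 (conventional choice; the
switch rule itself is the contract), otherwise Kruskal–Wallis; groups too
small for the checks fall back to Kruskal–Wallis. Correlations with
genotype-derived PCs are absolute Pearson values over the 3×3 grid; constant
vectors yield missing entries excluded from the mean. Partial R² for
predictor sets A, B: (SSE(B) − SSE(A∪B))/SSE(B) and symmetrically, with
SSE from OLS including an intercept. Confounding of adjustment factors with
ancestry is tested per factor by one-way ANOVA, or — with repeated samples —
a likelihood-ratio test between random-intercept mixed models with and
without the group predictor, both fitted by maximum likelihood (REML
log-likelihoods are not comparable across fixed-effect changes); singular
fits are reported missing. The genomic inflation factor is
λ = median(χ²₁(1−p)) / 0.4549 from per-probe EWAS p-values, where the EWAS
regresses M-values (log2 β/(1−β), β clipped to [1e-6, 1−1e-6]) on
[intercept, phenotype, covariates] with a two-sided t-test on the phenotype
coefficient, vectorized across probes.

## Synthetic cohorts

The generator produces every input the pipeline consumes, with ground truth:

- **Population structure.** Ancestral allele frequencies ~ U(0.1, 0.9);
  group frequencies from the Balding–Nichols Beta parameterisation with
  divergence `fst` (default 0.3, a deliberately strong two-population
  split); genotypes Binomial(2, p) per individual. SNP-probe beta means
  track genotype/2 shrunk toward 0.5 by a per-probe attenuation
  ~ U(0.6, 0.9) — perfect genotype–methylation coupling would make recovery
  trivially easy.
- **Technical structure.** `n_tech_factors` axes: a binary batch (optionally
  correlated with ancestry via `batch_ancestry_cor`) plus continuous factors
  emulating slide/position/scanner drift. Each factor loads coherently on
  all CpG probes (N(0,1)·`batch_effect`) and, on the log scale, on all
  control probes — so control-probe PCs can recover the technical span,
  which is exactly the method's assumption.
- **Biology.** Sex and age per individual; cell proportions Dirichlet(5) with
  an optional group shift; small per-probe loadings for each.
- **Arrays.** Intensities are drawn so that M/(M+U+100) reproduces the
  generating beta exactly (total intensity lognormal around 10⁴ AU);
  rs-probe betas are trimodal around 0.05/0.5/0.95 (σ = 0.03) from an
  independent genotype draw; detection p-values are tiny except a
  `missing_rate` fraction; bead counts Poisson(12) with occasional lows.
  Repeats share genotypes, sex and age and differ by technical factors and
  noise. All draws flow from one seed through a fixed seed-sequence split
  per stage, so outputs are bit-identical per seed.
- **Reference PCs.** The "genotyping PCs" used by the evaluation are the
  top-3 PCs of the true individual-level genotype matrix, broadcast to
  samples (so repeats share them exactly).

Scenario presets: `clean` (randomized design, weak technical effects);
`batch_confounded` (batch_effect 0.4 across 4 technical factors — sized so
the technical span, not ancestry, owns the top raw-beta variance axes, the
regime this scenario exists to represent); `covariate_correlated`
(batch and cell composition partially aligned with ancestry, the regime
where residualization removes true signal); `repeats` (2 groups × 10
individuals × 3 samples, batch_effect 0.3 so repeats of one individual
scatter technically). Default cohort size is 2 groups × 30 individuals with
800 SNP probes, 1200 other probes, 120 control probes and 59 rs probes
(the EPIC arrays carry 59 rs probes) — sizes chosen so every end-to-end
experiment runs in seconds on one CPU while keeping n_features ≫ n_samples
as on real arrays.

What the generator does **not** emulate: linkage disequilibrium between
probes, genomic coordinates, probe-specific detection chemistry, admixed
individuals (group labels are discrete), cell-type deconvolution error
structure, and dye-bias beyond what probe-type-stratified normalization
absorbs. Passing tests therefore demonstrate correctness of the machinery
and qualitative behaviour under the assumed generative model, not
cohort-specific performance on real data.

## The EWAS practical example

The inflation experiment assigns a binary phenotype with different case
rates per ancestry group (0.75 vs 0.25), mirroring a stratified case–control
design, and runs the EWAS over all simulated probes with base covariates
[sex, age, 4 cell-type PCs, 5 control-probe PCs] plus 0 / 2 / 5 / 10
ancestry PCs. The base design mirrors practice: the part of the ancestry
axis lying in the covariate span is handled by those covariates, the
orthogonal part by the ancestry PCs (which, being built from residualized
features, are orthogonal to the design by construction). The "optimal" PC
count is the one in {2, 5} with λ closest to 1, the rule practitioners apply.
Because λ at a fixed seed has sampling noise of a few percent, the
over-adjustment comparison (10 PCs vs optimum) is asserted on the mean
|λ−1| pooled over six seeds. The null calibration uses single-group cohorts:
with two groups of 30, even a randomly assigned phenotype chance-correlates
with ancestry (|r| ≈ 0.13), which is genuine confounding, not a null.

## Numerical choices and edge cases

- Rank checks use singular values against `max(shape)·eps·s₁`; requesting
  more PCs than the rank is an error, never silent padding.
- Min–max scaling of a constant score column is an error naming the PC.
- Quantile-normalization strata with < 2 probes pass through with a warning.
- Genotype entries are validated to {0, 0.5, 1, NaN}; detection p-values to
  [0, 1]; cell proportions to the simplex within 1e-6.
- The imputer accepts a `seed` argument for interface uniformity but is
  fully deterministic.
- I/O round-trips are lossless to ≥ 12 significant digits (`%.17g`).

## Known limitations

- Residualizing against p covariates at n samples removes an expected ~p/n
  of any fixed direction's variance by chance; at n = 60 with 14 covariates
  this measurably attenuates the ancestry axis (PC1–truth correlations
  ≈ 0.8–0.95 rather than ≈ 1). This is a property of the method at small n,
  visible in the experiments, not an implementation artifact.
- The threshold genotype caller assumes well-separated trimodal clusters;
  arrays with shifted cluster positions would need the k-means caller or
  adjusted thresholds.
- Mixed-model LRT p-values are asymptotic; at 20 individuals the empirical
  type-I rate sits near the upper end of the acceptable band.
- No projection of new samples onto fixed loadings; PCs are cohort-specific.
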