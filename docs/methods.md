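# Methods

## Statistical model

### Differential methylation

Methylation beta values are modeled on the beta scale as the response:
for probe *g* and sample *i*,

    β_gi = α_g + Δ_g · case_i + γ_gᵀ c_i + ε_gi,   ε_gi ~ N(0, σ²_g)

where `case_i` is the case indicator and `c_i` the estimated leukocyte
fractions (one cell type dropped, since fractions sum to one and would
otherwise make the design singular). `Δ_g` is the cell-adjusted
case-control beta difference. Although some descriptions of this class of
workflow phrase the regression with beta as predictor and the label as
response, the implemented (and conventional) formulation treats beta as
the response; the case coefficient is the quantity of interest either way.

Per-probe residual variances are unstable at episignature sample sizes
(tens of cases), so they are shrunk by empirical Bayes under a scaled
inverse-χ² prior `σ²_g ~ s₀²·d₀/χ²_{d₀}`. The prior is estimated by
moment matching on `z_g = log s²_g`: with residual df `d_g`,
`Var(z) − ψ′(d_g/2)` estimates `ψ′(d₀/2)` (inverted by Newton iteration on
the trigamma function, relative tolerance 1e-8), and `s₀²` comes from the
mean equation `E[z] = log s₀² + (ψ(d_g/2) − log(d_g/2)) − (ψ(d₀/2) −
log(d₀/2))`. When the observed dispersion of `z` does not exceed
`ψ′(d_g/2)`, the probes are consistent with one common variance and
`d₀ = +∞`. Posterior variances are `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`;
the moderated statistic `t_g = Δ_g/(s̃_g√v_g)` has `d₀+d_g` degrees of
freedom (normal reference when `d₀ = ∞`). `d₀ = 0` is the no-shrinkage
limit and reproduces the ordinary t-test exactly — used as an oracle in
the tests, which also cross-check the estimator against Bioconductor
limma's `squeezeVar` on simulated variances. Two edge conventions differ
from naive intuition: when all observed `s²` are identical the estimate
`s₀²` is the bias-corrected value `s²·(d_g/2)/exp(ψ(d_g/2))`, not `s²`
itself (the mean equation corrects the negative bias of `log s²`).

Multiple testing uses the Benjamini-Hochberg step-up (statsmodels
implementation behind the package's function surface, verified against a
literal step-up enumeration). DMP significance downstream is
`adj_p < 0.05` with no additional effect-size floor.

### Probe-set selection

Candidates are ranked by adjusted p (ties: larger `|Δβ|` first, then probe
id). The cutoff grid defaults to adjusted-p thresholds
`(1e-12, 1e-8, 1e-4, 0.05)` — "varying the cutoff on the top p-values" —
and also accepts integer entries as top-N sizes. Each candidate set is
pruned greedily in rank order, dropping any probe with `|Pearson r| > 0.9`
to an already-retained one, then scored by the mean silhouette width of
the case/control labelling under Euclidean distance (chosen as the
"best clustering" criterion; the original selection metric is not
specified in this literature beyond "best clustering"). The
highest-scoring set wins; exact ties go to the smaller set. A best score
below 0.25 flags the selection as non-significant — null cohorts score
near 0, genuinely planted signatures well above 0.5. Per-probe importance
is additionally reported as the direction-folded Mann-Whitney AUC,
`max(A, 1−A)`.

Note that mean silhouette is only asymptotically invariant to duplicating
samples (each duplicate contributes a zero self-distance to the
intra-cluster mean, an O(1/n) effect); the tests assert near-invariance.

### Classification (MVP score)

A linear-kernel SVM (C = 1, inverse-class-frequency weights) is trained on
the selected probes. The training composition follows the episignature
convention: cases vs their matched controls plus a seeded, per-cohort
stratified 75 % of all remaining samples (unmatched controls and
other-disorder cohorts, all labeled 0, so the classifier learns
specificity against both health and other signatures); the remaining 25 %
is the test set. Decision values are mapped to [0, 1] by Platt sigmoid
calibration — a logistic fit on the training decision values — recorded in
the model metadata; the mapping is monotone, so a more case-like profile
never lowers the score. 0.5 is the classification threshold for
cross-validation accuracy; 0.75 is reported separately as the descriptive
"high score" bound for affected cases.

Both cross-validation protocols (leave-one-out over cases; 20 rounds of
leave-25 %-out over cases jointly with their matched controls) re-run
matching, differential methylation, probe selection and training on the
retained samples only. Each round records its training-id hash so the
no-leakage property is directly assertable.

### Annotation and comparison

CpG-island context uses the standard geometry: island if the probe's CpG
lies inside an island, shore within 0–2 kb of an island boundary, shelf
within 2–4 kb, open sea otherwise (precedence island > shore > shelf;
distances on the same chromosome only). Gene context is strand-aware:
promoter 0–1 kb upstream of the TSS, promoter+ 1–5 kb; UTRs and CDS from
BED12 thick coordinates; intron inside the span but outside exons;
intergenic iff nothing else applies. Multi-gene overlaps keep all
memberships; summary percentages use the single-label precedence
promoter > promoter+ > 5′UTR > CDS > 3′UTR > intron > intergenic.

A DMR is ≥ 5 probes, consecutive in the position-sorted manifest with no
intervening non-significant probe, spanning ≤ 1,000 bp (max − min
position); overlapping qualifying windows merge into maximal regions. The
caller is verified against exhaustive window enumeration.

Cohort comparison takes each cohort's top-n DMPs (n = min(#significant,
500)) and median case-minus-control difference profile. The overlap matrix
entry (y, x) is the percentage of y's probes also in x's set —
deliberately asymmetric. The cohort tree clusters median-difference
profiles (Euclidean, complete linkage) over the union of all top sets,
with per-cohort node size (#DMPs) and color value (global mean methylation
difference, case-minus-control beta scale).

## The synthetic cohort generator

The generator emulates what an EPIC blood study measures, with known
truth. Defaults are the study conditions: 24 discovery + 5 validation
cases, a 200-sample control pool, two other-disorder cohorts of 20
(standing in for a reference database of known episignatures), 10,000
probes, a planted 296-probe case signature with 98.6 % hypomethylated
probes, mean beta-shift 0.10, logit-scale noise sd 0.15, six leukocyte
types with a neutrophil-dominated Dirichlet composition (α ≈ 18, 4.5, 2.4,
1.5, 2.4, 1.2), two batches (logit shift sd 0.1), 3 % SNP-overlap, 3 %
cross-reactive and 3 % sex-chromosome probes, and a 1e-4 per-entry
detection-failure rate (chosen so that total filter loss lands near the
~11 % typical of EPIC QC; the original pool sizes and noise levels are not
published, and were fixed once at values a methylation analyst would call
realistic).

Generative order per probe/sample: bimodal baseline mixture (≈ 45 %
unmethylated, 45 % methylated, 10 % intermediate); cell-informative probes
(20 %) take the fraction-weighted mix of the cell reference profiles;
additive batch shift on the logit scale; for affected samples, the planted
beta-scale shift (clipped to [0.001, 0.999]); logit-normal noise; clipping
again. Effects are applied on the logit scale except the planted delta,
which stays in beta units so the effect-size knob matches how such effects
are reported. Per-probe planted magnitudes are uniform on
[0.5δ, 1.5δ]. Planted probes are drawn from clean autosomal,
non-cell-informative probes and given mid-range baselines (hypo: 0.30–0.85;
hyper: 0.15–0.70) so the shift survives clipping — consistent with
episignature CpGs sitting at intermediate methylation, and with discovery
operating on post-QC probes. Sex and batch rotate over samples in a
balanced design (as a matched study aims for), so exact-matching strata in
the control pool cannot starve; ages are random. Each simulation stage
draws from its own RNG stream derived from the seed, so adding a stage
never perturbs earlier draws.

What the generator does **not** emulate: real EPIC probe-level annotation
and probe-type chemistry, genotype-driven SNP artifacts, age-related
methylation drift, sex-specific autosomal effects, and correlated probe
blocks beyond CGI-clustered placement. Passing tests therefore demonstrate
that the statistics recover what the generative model plants — not that
the pipeline's numbers would match any particular patient cohort.

## Numerical and operational choices

- Matching: greedy nearest-age within exact (sex, batch, array) strata,
  cases in sample-id order, age ties broken by control id; errors rather
  than relaxes when a case cannot be matched. Default ratio 4:1.
- Deconvolution: SLSQP on the simplex (ftol 1e-14), gradient supplied;
  rank-deficient references are rejected naming the collinear cell types.
  On noiseless mixtures the solution is exact to ~1e-6; truth recovery on
  the default cohort is RMSE ≈ 0.004.
- PCA outlier screen: top-3 axes, robust criterion median ± 3·1.4826·MAD
  per axis; it warns and records but never drops samples. At desk scale
  (10⁴ probes) the planted signature and batch structure dominate the top
  axes, so whole groups can be flagged — informational only; at real scale
  (~10⁶ probes, subtle effects) the same screen isolates individual
  technical outliers.
- Hierarchical clustering delegates to scipy's complete linkage; its
  deterministic merge order is accepted as the tie-break rule. Newick
  export writes branch lengths as parent-minus-child merge heights.
- Classical MDS truncates negative eigenvalues at zero; coordinates are
  deterministic up to sign.
- Tables are written with 15-significant-digit floats (round trips below
  1e-12); every output embeds the configuration hash (sha-256 over the
  config minus the output path) so byte-identical reproduction is
  checkable from the output manifest. Timings live only in the log.
- Test and acceptance problem sizes (10,000 probes, 269 samples, 20 CV
  rounds, 50,000-probe variance simulations) were chosen so the full suite
  completes in a few minutes on one CPU while keeping every estimate's
  sampling error far from the asserted margins.

## Known limitations

- Normalization, background correction and IDAT-level QC are upstream of
  this package's entry point (it consumes beta matrices).
- The variance prior assumes a single scaled inverse-χ² across probes; no
  robustification against variance outliers, no intensity-dependent trend.
- Reference-based deconvolution only; no reference-free correction for
  unknown cell types.
- The silhouette selection criterion is one defensible reading of "best
  clustering"; alternatives (e.g. cluster purity) are not implemented.
- The comparison module fabricates stand-in cohorts via the generator;
  real cross-disorder comparisons require externally supplied signature
  files (`episig compare --signatures DIR`).
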