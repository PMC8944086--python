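# Methods

This note documents the models implemented in `methage`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Data model and preprocessing

Methylation travels as a probes × samples matrix of beta values (fraction
methylated, in [0,1]) or M-values, M = log2(β/(1−β)), with betas clipped to
[1e−6, 1−1e−6] before the logit so boundary values stay finite; inside the
clip range the conversion is exactly invertible. M-values are the modelling
scale (variance more homogeneous across the range); betas are the
interpretation and entropy scale.

Probe filtering removes (i) probes whose detection p-value exceeds the
threshold (default 0.01) in more than a configurable fraction of samples —
the default fraction is 0, i.e. a failure in any sample removes the probe,
the strictest reading; (ii) sex-chromosome probes; (iii) SNP-overlapping
probes. Filtering is idempotent and order-preserving. Coordinates are
1-based, hg19 labels carried as metadata only.

Cross-dataset aggregation uses parametric empirical-Bayes ComBat on
M-values: per-probe batch means and variances are shrunk toward normal /
inverse-gamma priors (moment-matched, priors with n−1 denominators as in the
reference R implementation) and divided out, protected covariates estimated
jointly and retained. Only the parametric form is implemented. Two
properties deserve a caveat: exact equalization of per-batch probe means and
exact grand-mean preservation hold when per-probe batch effects are
homogeneous (the shrinkage target equals every effect); under noisy
per-probe effects both hold only approximately, which is inherent to
empirical Bayes, not an implementation artifact. A cross-check against
scanpy's independent ComBat implementation agrees to within the two
codebases' prior-moment conventions.

## Epigenetic clock

The age transform is log-linear below `adult_age` (default 20 years) and
linear above, continuous at the knee. Prediction is a linear model on clock
probe betas followed by the inverse transform. Clock probes missing after
filtering are dropped from the linear predictor without re-normalization
(with a warning and count) — the same convention as running a published
clock on a detection-filtered array. Training uses cross-validated
elastic-net regression in transformed-age space.

Calibration of clock-probe betas to a reference cohort is per-probe quantile
matching on the rank grid (rank−1)/(n−1) with linear interpolation: monotone
(ranking preserved), the identity when input equals the reference, and it
restores affine distortions exactly. It is a stand-in for array-calibration
procedures that operate on raw intensities, which are out of scope here;
it is off by default for synthetic data, which is already on the model
scale.

## Methylation entropy

Marker-level HME uses natural log with the 0·log 0 := 0 convention (no
clipping), so fully ordered profiles score exactly 0 — the base cancels
through the log(1/2) normalizer. Because the formula is a per-marker
average, the global value equals the probe-count-weighted mean of stratum
values, which the tests assert as an algebraic identity. The read-level
haplotype entropy uses base 2, under which two pure patterns over 4 CpGs at
50/50 score exactly 0.25. The two statistics agree on ordered profiles but
are not interchangeable: marker-level HME sees only marginal methylation
fractions, not the co-occurrence structure of reads.

## Association scans

The DMP scan is a vectorized per-probe F-test between probe ~ covariate and
the intercept-only model; categorical covariates are dummy-coded, constant
probes get F = 0, p = 1 by convention. Multiplicity is Bonferroni (the
adjusted p is reported as the q-value; no FDR for DMPs), DMP at q < 0.1
strictly. The scan is invariant to affine rescaling of the covariate.

Functional methylation tests promoter CpGs (|TSS distance| ≤ 1500 bp)
against their gene's expression by Spearman correlation; ties get average
ranks, the p-value is the t-approximation for n ≥ 10 and exact permutation
below. The multiplicity default is Benjamini–Hochberg with a Bonferroni
switch (the appropriate procedure for this scan is a judgment call; BH is
the field default for correlation screens). A pair is functional when
q < 0.05 and ρ < −0.3 strictly. Probes annotated to several genes are
tested once per gene.

Gene-set enrichment is the upper-tail hypergeometric test per set with
Bonferroni adjustment, significant at adjusted p ≤ 0.1; sets and queries are
intersected with the supplied universe first.

## Molecular state

Copy-number log ratios are log2((meth+unmeth)/reference), median-centered
per sample (the exact within-sample normalization of combined intensities
is underdetermined; median-centering is the default). CBS is the recursive
maximal circular-arc statistic with a within-segment permutation reference
(defaults alpha = 0.01, 1000 permutations, minimum width 3, seeded); no
hybrid p-value speedups. Segments tile each chromosome exactly.

CDKN2A homozygous deletion: two-component Gaussian mixture on per-sample
CDKN2A probe means; HD = posterior > 0.5 for the lower component, with a
merge guard — if the component means are closer than one pooled standard
deviation the mixture is treated as degenerate and no HD is called.

Purity is the least-squares coefficient of β_obs = w·β_tumor + (1−w)·β_normal
over informative probes (reference difference > 0.3), clipped to [0,1]. The
reference profiles are explicit inputs.

MGMT-STP27: probability = inverse-logit(b₀ + b₁·M₁ + b₂·M₂) on the two
probe M-values; methylated iff probability ≥ 0.358 (the boundary counts as
methylated). The model coefficients are not bundled — they are a required
configuration input; synthetic runs use generator-known coefficients.

G-CIMP-style clustering is Ward/Euclidean on the most variable probes, cut
at k = 2, flagging the hypermethylated cluster. Subtype assignment
(MES / RTK I / RTK II) is nearest-centroid with ties broken in the fixed
label order MES, RTK_I, RTK_II — a deliberate surrogate for external
random-forest classifiers, which are out of scope.

## Outcome statistics

ADONIS partitions the squared Euclidean distance matrix (SS_total = Σd²/n)
by the grouping, with the permutation p-value (1+b)/(1+B) over freely
shuffled labels; on univariate data its R² equals one-way ANOVA R² exactly.
Variation partitioning fits the seven redundancy models over three
explanatory blocks and derives the Venn fractions by inclusion–exclusion;
adjusted (Ezekiel) R² is the primary currency, raw R² is also reported, and
negative shared fractions under collinearity are reported, not clipped.
Wald tests use the HC3 sandwich covariance
(X'X)⁻¹X'diag(e²/(1−h)²)X(X'X)⁻¹ with an F reference; the two-way table
(classification, study/batch, interaction) jointly tests each term group.
Cox models use lifelines with Efron tie handling and exactly the terms
treatment, MGMT, covariate, treatment × MGMT; non-convergence falls back to
a lightly ridged refit flagged as such. The CMH test drops zero-margin
strata with a warning; continuity correction is off by default.

## Synthetic cohorts

The generator's defaults are the study conditions: acceleration mean 36.8
years, SD 24 years (the GBM-cohort scale), subtype proportions ≈ 30/20/50
for MES/RTK I/RTK II with shifts (−7.7, −3.3, +6.5 years) making RTK II the
most accelerated; ages uniform on 30–85; purity uniform on 0.31–0.99; MGMT
states ≈ 50/50; survival exponential proportional-hazards with baseline
rate 0.5/year, censoring 0.15/year, log-HRs −0.3 (treatment), +0.1 (MGMT),
−1.0 (interaction) and −0.0147 per acceleration year (HR ≈ 0.985); clonal
chr7 gain (+0.58) and chr10 loss (−1.0) plus CDKN2A deletion (log2 0.1) in
half the samples. One pseudo-random stream per logical block (annotation,
clock, survival, CNV, …) derives from the master seed, so enlarging one
block never perturbs another, and identical seeds give bit-identical
cohorts.

Probe baselines follow island context — bimodal near 0/1 in promoter
islands, intermediate in open sea — which reproduces the stratum entropy
ranking (promoter islands lowest). Clock probes are constructed as
β = c_j + u_j·F(age+accel) with the generating clock defined to invert this
exactly, so a noiseless, single-batch, unit-purity configuration yields
exact DNAm-age recovery. Planted DMPs carry a beta-scale slope of 0.004 per
covariate year (sign random); all other probes have generating slope
exactly 0. Functional CpGs share a latent per-sample signal with their
gene's expression, with the noise weight chosen analytically (including the
attenuation from measurement noise) to hit the target Spearman ρ = −0.5.
Noise is added on the logit scale and back-transformed, keeping betas in
[0,1] without truncation while preserving monotone signals; batch
location/scale shifts also act on the logit scale.

Deliberate idealizations: purity mixing acts on a dedicated informative
probe block (the synthetic normal-brain profile equals the tumor baseline
elsewhere), and the MGMT / CDKN2A / purity blocks are exempt from batch
shifts and extra noise so their generating scales stay interpretable. Real
purity contamination attenuates every probe, real batch effects spare
nothing, and real 450k betas are more bimodal genome-wide than these
baselines (the synthetic global HME runs higher than typical cohort
values). Consequently, passing tests demonstrate that each method recovers
the structure it models under controlled conditions — not that it is robust
to the full entanglement of purity, batch and subtype effects in real
tumors. No read-level data, IDAT intensities, or realistic co-methylation
(beyond block structure) are simulated.

## Problem sizes and numerics

Test cohorts use 900–5,050 probes and 40–300 samples — large enough that
the planted effects are identifiable at realistic effect sizes, small
enough for quick iteration. Replicated checks (Cox recovery, calibration
nulls) use 100–500 replicates chosen so the Monte-Carlo error is well
inside the asserted bands. Permutation counts: 199–500 for CBS and ADONIS
in tests (1000 is the CBS production default). Degenerate inputs are
handled by convention rather than error where a convention exists (constant
probes in scans, merged mixture components, zero-margin strata); genuinely
uninterpretable inputs (empty universe, constant covariate, no events)
raise.

## Known limitations

- ComBat is parametric-only; non-parametric priors are not implemented.
- The published 353-probe clock coefficients are not bundled; users supply
  their own coefficient CSV for real data.
- MGMT-STP27 coefficients likewise are a user input; only the cutoff is
  fixed.
- CBS computes the full O(n²) arc statistic per permutation — fine for
  array-scale chromosomes, not tuned for millions of markers.
- The read-level "randomly organized" entropy scenario has no closed-form
  target under either formula and is not asserted anywhere.
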