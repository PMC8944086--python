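# methage

DNA-methylation analysis of IDH-wild-type glioblastoma (GBM) cohorts:
epigenetic-clock DNAm age and age acceleration, methylation entropy by
genomic stratum, differential- and functional-methylation scans, MGMT-STP27
promoter classification, copy-number and purity metrics, and the
multivariate / survival statistics that tie them to outcome. Every analysis
runs end-to-end on a seeded synthetic 450k-style cohort generator with a
ground-truth record, so the whole pipeline is testable without any data
download.

The package is aimed at methylation analysts and methods developers who want
the building blocks of a tumor-methylome study as reusable, tested Python
functions rather than a one-off script collection.

## The quantities at the core

**DNAm age and acceleration.** A Horvath-style clock predicts a transformed
age from clock-CpG betas,

```
F(a) = log(a+1) − log(adult_age+1)        a ≤ adult_age
F(a) = (a − adult_age) / (adult_age+1)    a > adult_age
```

with DNAm age = F⁻¹(intercept + Σⱼ βⱼ·coefⱼ) and age acceleration
Accel = DNAm age − chronological age (years). In GBM the acceleration is
typically tens of years.

**Methylation entropy (HME).** Each CpG is a two-state system with
methylated probability p (the beta value):

```
HME = Σᵢ [ (1−pᵢ)·log(1−pᵢ) + pᵢ·log(pᵢ) ] / (N·log ½),   0·log 0 := 0
```

HME is 0 for fully ordered profiles (betas at 0/1) and 1 at maximal disorder
(betas at 0.5). It is computed globally and within the 12 strata formed by
the six CpG-island relations × promoter status. A read-level companion,
H = −(1/n_CpG)·Σₖ fₖ·log₂ fₖ over haplotype-pattern frequencies, reproduces
the classical worked example: two pure 4-CpG patterns at 50/50 give 0.25.

**Scans and state calls.** DMPs are probes with a significant linear-model
F-test against a covariate (Bonferroni q < 0.1); functional CpGs are
promoter probes (|TSS distance| ≤ 1500 bp) whose betas correlate negatively
with their gene's expression (Spearman ρ < −0.3, q < 0.05); MGMT status is
the two-probe (cg12434587, cg12981137) logistic model with the 0.358
probability cutoff; copy number is segmented by circular binary segmentation
of intensity log2 ratios; CDKN2A homozygous deletion is a two-component
Gaussian mixture on probe means; purity is the least-squares tumor/normal
mixing weight. Outcome statistics include PCA, permutation MANOVA (ADONIS),
three-block variation partitioning, HC3-sandwich Wald F-tests and Cox models
with a treatment × MGMT interaction.

## Worked example

```python
from methage.clock import predict_dnam_age, age_acceleration
from methage.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_samples=120, n_probes=1500,
                                      noise_sd=0.05,
                                      batch_labels={"one": (0.0, 1.0)}, seed=2))
dnam  = predict_dnam_age(cohort.betas, cohort.truth.clock)
accel = age_acceleration(dnam, cohort.samples["age"])
print(dnam.mean(), accel.mean())
```

Running `python examples/02_clock_age_acceleration.py` (the same analysis
with diagnostics) prints:

```
mean chronological age:  58.55 y
mean DNAm age:           95.21 y
mean acceleration:       36.65 y
Spearman r (predicted vs true DNAm age): 0.999
max abs prediction error: 2.09 y
```

The cohort's DNAm age exceeds patient age by ~37 years on average — the
tumor age-acceleration signal the generator plants — and the clock reads it
through the measurement noise almost perfectly. The other scripts in
`examples/` walk through entropy strata, the DMP/functional scans, copy
number + MGMT + purity, and the survival interaction model, each printing
the numbers it computes and what they mean.

A thin CLI wraps the pipeline: `methage run --config cfg.yaml` executes
generate → filter → ComBat → clock → entropy → scans → molecular state →
statistics and writes TSV report tables plus a JSON summary and run log;
`methage simulate`, `methage entropy`, `methage dmp`, `methage clock-predict`
and `methage mgmt` expose single stages on fixture files.

## Layout

```
src/methage/        preprocess, clock, entropy, association, genomic_state,
                    stats_outcome, synthetic, pipeline, cli
examples/           one narrative script per capability
docs/methods.md     models, assumptions, parameter choices, limitations
tests/              unit + property tests, acceptance suite
```
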