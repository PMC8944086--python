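"""Copy-number segmentation, CDKN2A deletion calls, purity and MGMT status.

Copy number comes from combined methylated+unmethylated probe intensities
(log2 ratio to a reference, CBS segmentation); CDKN2A homozygous deletions
are a two-component mixture on per-sample probe means; purity is the
least-squares tumor/normal mixing weight; MGMT status is the two-probe
logistic classifier at the 0.358 probability cutoff.
"""

import pandas as pd

from methage.genomic_state import (
    cdkn2a_hd_call,
    copy_number_logratio,
    estimate_purity,
    mgmt_stp27,
    segment_genome,
)
from methage.preprocess import beta_to_m
from methage.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_samples=60, n_probes=1500, seed=5))
truth = cohort.truth

lr = copy_number_logratio(cohort.intensities, truth.intensity_reference)
sample = truth.hd_samples[0]
ann = cohort.annotation.table
segs = segment_genome(lr[sample], ann[["chromosome", "position"]], n_perm=200, seed=0)
print(f"sample {sample}: {len(segs)} segments")
for s in segs:
    if abs(s.mean) > 0.3:
        print(f"  chr{s.chromosome}:{s.start}-{s.end}  mean log2 {s.mean:+.2f}  ({s.n_probes} probes)")

cdkn2a = ann.index[ann["gene"] == "CDKN2A"]
calls = cdkn2a_hd_call(lr.loc[cdkn2a].mean(axis=0))
agree = (calls["hd"] == truth.samples["hd"]).mean()
print(f"\nCDKN2A HD calls match planted truth in {agree:.0%} of samples")

purity = estimate_purity(cohort.betas, truth.tumor_reference, truth.normal_reference)
err = (purity - truth.samples["purity"]).abs().max()
print(f"purity estimates within {err:.3f} of truth (range {purity.min():.2f}-{purity.max():.2f})")

mgmt = mgmt_stp27(beta_to_m(cohort.betas.values), truth.mgmt_coefficients)
print(f"MGMT methylated: {(mgmt['status'] == 'M').sum()}/{len(mgmt)} "
      f"(agreement with truth {(mgmt['status'] == cohort.samples['mgmt_status']).mean():.0%})")
# The chr7 gain / chr10 loss pattern plus focal CDKN2A loss is the classic
# GBM copy-number portrait the generator plants.
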