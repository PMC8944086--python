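"""Methylation entropy (HME) at marker level, per genomic stratum, and per read haplotype.

HME treats each CpG marker as a two-state system: methylated with probability
p (the beta value) and unmethylated with probability 1 - p.  The normalized
Shannon entropy over N markers,

    HME = sum_i [ (1-p_i) log(1-p_i) + p_i log(p_i) ] / (N log(1/2)),

ranges from 0 (every marker fully ordered, beta in {0, 1}) to 1 (every marker
at 0.5).  The normalizing constant log(1/2) makes the logarithm base cancel;
natural log is used.  A read-level companion computes the per-CpG-normalized
base-2 entropy of methylation haplotype (read pattern) frequencies, the
formulation under which 50% methylation split between fully methylated and
fully unmethylated alleles over 4 CpGs scores 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ISLAND_RELATIONS, MethylationMatrix, ProbeAnnotation

__all__ = ["hme", "hme_by_stratum", "read_haplotype_entropy", "EntropyTable", "STRATA"]

#: The 12 strata: island relation x promoter status.
STRATA = tuple(
    f"{rel}.{loc}" for rel in ISLAND_RELATIONS for loc in ("promoter", "non_promoter")
)

_LOG_HALF = np.log(0.5)


def _xlogx(p: np.ndarray) -> np.ndarray:
    # p*log(p) with the 0*log0 := 0 convention (no clipping)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def hme(betas) -> float:
    """Normalized methylation entropy of a vector of methylation fractions.

    Parameters
    ----------
    betas
        Methylation fractions in [0, 1], at least one marker.

    Returns
    -------
    float in [0, 1]; 0 iff every value is exactly 0 or 1, 1 iff all are 0.5.
    """
    p = np.asarray(betas, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("hme requires at least one marker")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("betas must lie in [0, 1]")
    terms = _xlogx(p) + _xlogx(1.0 - p)
    return float(terms.sum() / (p.size * _LOG_HALF)) + 0.0  # avoid -0.0


@dataclass
class EntropyTable:
    """Per-sample HME by stratum plus the global value.

    ``by_stratum`` is samples x 12 strata (NaN where a stratum is empty),
    ``global_hme`` one value per sample, ``counts`` the probe count per stratum.
    """

    by_stratum: pd.DataFrame
    global_hme: pd.Series
    counts: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return self.by_stratum.assign(global_hme=self.global_hme)


def hme_by_stratum(m: MethylationMatrix, ann: ProbeAnnotation) -> EntropyTable:
    """HME per sample within each of the 12 island x promoter strata and globally.

    Empty strata yield NaN, not zero.  Requires beta scale and annotation
    coverage of every probe in the matrix.
    """
    if m.scale != "beta":
        raise ValueError("hme_by_stratum expects beta values")
    if not ann.covers(m.probe_ids):
        raise KeyError("annotation does not cover all matrix probes")
    tab = ann.table.loc[m.probe_ids]
    vals = m.values.to_numpy(dtype=float)
    terms = _xlogx(vals) + _xlogx(1.0 - vals)  # probes x samples

    rel = tab["island_relation"].to_numpy()
    prom = tab["is_promoter"].to_numpy(dtype=bool)
    out = {}
    counts = {}
    for stratum in STRATA:
        rel_name, loc = stratum.rsplit(".", 1)
        mask = (rel == rel_name) & (prom if loc == "promoter" else ~prom)
        n = int(mask.sum())
        counts[stratum] = n
        out[stratum] = (
            terms[mask].sum(axis=0) / (n * _LOG_HALF) if n else np.full(m.n_samples, np.nan)
        )
    by_stratum = pd.DataFrame(out, index=m.sample_ids)
    global_hme = pd.Series(
        terms.sum(axis=0) / (m.n_probes * _LOG_HALF), index=m.sample_ids, name="global_hme"
    )
    return EntropyTable(by_stratum, global_hme, pd.Series(counts))


def read_haplotype_entropy(pattern_frequencies, n_cpgs: int) -> float:
    """Per-CpG-normalized base-2 entropy of read methylation-pattern frequencies.

    H = -(1/n_cpgs) * sum_k f_k log2 f_k, with 0*log0 := 0.  Frequencies must
    sum to 1 (tolerance 1e-9).  Two pure patterns at 50/50 over 4 CpGs give
    exactly 0.25; the uniform distribution over all 2^n patterns gives 1.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    if isinstance(pattern_frequencies, dict):
        f = np.asarray(list(pattern_frequencies.values()), dtype=float)
    else:
        f = np.asarray(pattern_frequencies, dtype=float).ravel()
    if f.size == 0 or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("pattern frequencies must sum to 1")
    if (f < 0).any():
        raise ValueError("pattern frequencies must be non-negative")
    pos = f > 0
    return float(-(f[pos] * np.log2(f[pos])).sum() / n_cpgs)
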