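"""Methylome-wide association scans and gene-set enrichment.

Three scans mirror a standard 450k tumor-cohort workflow:

- :func:`dmp_scan` — per-probe linear-model F-test of methylation against a
  covariate of interest (age, age acceleration, or a categorical subtype),
  Bonferroni-adjusted; a probe is a differentially methylated position (DMP)
  at adjusted q < 0.1.
- :func:`functional_scan` — Spearman correlation of promoter-CpG methylation
  (within 1500 bp of the TSS) against the expression of the annotated gene;
  functional methylation is a significantly negative correlation
  (q < 0.05 and rho < -0.3).
- :func:`hypergeom_gsea` — upper-tail hypergeometric over-representation of a
  query gene list in gene-set collections, Bonferroni-adjusted at 0.1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MethylationMatrix

__all__ = ["dmp_scan", "functional_scan", "hypergeom_gsea", "bonferroni", "read_gmt"]


def bonferroni(p: np.ndarray) -> np.ndarray:
    """Bonferroni-adjusted p-values, q = min(1, p * m)."""
    p = np.asarray(p, dtype=float)
    return np.minimum(1.0, p * p.size)


def _design(covariate, index) -> np.ndarray:
    """Intercept + covariate columns (dummies for categoricals, drop-first)."""
    if isinstance(covariate, pd.DataFrame):
        cov = covariate.reindex(index)
    else:
        cov = pd.Series(covariate, index=index) if not isinstance(covariate, pd.Series) \
            else covariate.reindex(index)
        cov = cov.to_frame("x")
    cols = []
    for name in cov.columns:
        c = cov[name]
        if c.dtype == object or isinstance(c.dtype, pd.CategoricalDtype):
            cols.append(pd.get_dummies(c, drop_first=True, dtype=float))
        else:
            cols.append(c.astype(float).to_frame(name))
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    if X.shape[1] == 0 or np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate: F-test is undefined")
    return np.hstack([np.ones((X.shape[0], 1)), X])


def dmp_scan(
    m: MethylationMatrix,
    covariate,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-probe F-test of the model probe ~ covariate vs the intercept-only null.

    Vectorized across probes.  The covariate may be continuous (a Series or
    array) or categorical (object/category dtype, dummy-coded); a DataFrame
    supplies several columns jointly.  Returns a DataFrame indexed by probe
    with columns ``F``, ``p``, ``q`` (Bonferroni), ``is_dmp`` (q <
    ``q_threshold``) and ``direction`` (sign of the first slope; 0 for
    multi-column designs where a single direction is undefined).

    Constant probes get F = 0, p = 1 by convention.
    """
    X = _design(covariate, m.sample_ids)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} samples for {k - 1} covariate terms")
    Y = m.values.to_numpy(dtype=float).T  # samples x probes

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss1 = (resid**2).sum(axis=0)
    centered = Y - Y.mean(axis=0, keepdims=True)
    rss0 = (centered**2).sum(axis=0)

    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    const = np.ptp(Y, axis=0) == 0
    F = np.where(const | ~np.isfinite(F) | (F < 0), 0.0, F)
    p = np.where(const, 1.0, stats.f.sf(F, df1, df2))
    q = bonferroni(p)

    direction = np.sign(coef[1]) if k == 2 else np.zeros(Y.shape[1])
    return pd.DataFrame(
        {
            "F": F,
            "p": p,
            "q": q,
            "is_dmp": q < q_threshold,
            "direction": np.where(const, 0.0, direction),
        },
        index=m.probe_ids,
    )


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    base = np.arange(1, n + 1, dtype=float)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = stats.pearsonr(base, base[list(perm)]).statistic
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def functional_scan(
    beta: MethylationMatrix,
    expression: pd.DataFrame,
    probe_gene: pd.Series,
    q_threshold: float = 0.05,
    rho_threshold: float = -0.3,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Spearman scan of promoter-CpG betas against their genes' expression.

    ``expression`` is genes x samples (already normalized); ``probe_gene``
    maps probe id -> gene symbol (probes annotated to several genes appear
    once per gene, i.e. supply a Series with repeated index entries).
    Requires >= 10 shared samples.  Multiple testing uses Benjamini-Hochberg
    by default (``adjust="bonferroni"`` to switch).  A probe-gene pair is
    functional when q < ``q_threshold`` and rho < ``rho_threshold``.

    Pairs whose gene is absent from the expression matrix are skipped; the
    count is available via ``result.attrs["n_skipped"]``.
    """
    shared = beta.sample_ids.intersection(expression.columns)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared samples")
    B = beta.to_beta().values[list(shared)]
    E = expression[list(shared)]
    n = len(shared)

    rows = []
    n_skipped = 0
    for probe, gene in probe_gene.items():
        if probe not in B.index:
            continue
        if gene not in E.index:
            n_skipped += 1
            continue
        x = B.loc[probe].to_numpy(dtype=float)
        y = E.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p = 0.0, 1.0
        elif n < 10:  # unreachable under the precondition; kept for direct calls
            rho = stats.spearmanr(x, y).statistic
            p = _spearman_exact_p(rho, n)
        else:
            res = stats.spearmanr(x, y)
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append((probe, gene, rho, p))
    out = pd.DataFrame(rows, columns=["probe_id", "gene", "rho", "p"])
    if len(out):
        if adjust == "bonferroni":
            out["q"] = bonferroni(out["p"].to_numpy())
        else:
            out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
        out["is_functional"] = (out["q"] < q_threshold) & (out["rho"] < rho_threshold)
    else:
        out["q"] = pd.Series(dtype=float)
        out["is_functional"] = pd.Series(dtype=bool)
    out.attrs["n_skipped"] = n_skipped
    return out.set_index("probe_id")


def hypergeom_gsea(
    query,
    gene_sets: dict,
    universe,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per gene set, Bonferroni-adjusted.

    For a universe of M genes, a set of K genes and a query of size N with
    overlap k, p = P(X >= k) under the hypergeometric null.  Sets are
    significant at Bonferroni-adjusted p <= ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    M, N = len(universe), len(query)

    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        k = len(genes & query)
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    out["p_adj"] = bonferroni(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    out["significant"] = out["p_adj"] <= alpha
    if N == 0:
        out["significant"] = False
    return out.sort_values("p")


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file: name, description, genes... per line."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
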