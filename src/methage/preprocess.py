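"""Core data model, matrix I/O, probe filtering, beta/M conversion and batch adjustment.

The data model mirrors the Illumina 450k world: a probes x samples matrix of
beta values (fraction methylated, in [0, 1]) or M-values (log2 odds), a probe
annotation manifest carrying genomic coordinates and CpG-island context, and a
per-sample clinical sheet.  Everything downstream (clock, entropy, association
scans, molecular-state calls) consumes these three objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ISLAND_RELATIONS",
    "MethylationMatrix",
    "ProbeAnnotation",
    "FilterReport",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "combat_adjust",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "read_sample_sheet",
]

#: The six 450k CpG-island context categories.
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})

#: Clip bound for beta -> M conversion; keeps M-values finite at beta in {0, 1}.
BETA_EPS = 1e-6

#: Promoter definition: within this many bp of the transcription start site.
TSS_PROMOTER_WINDOW = 1500


def beta_to_m(beta, eps: float = BETA_EPS):
    """Convert beta values to M-values, M = log2(beta / (1 - beta)).

    Betas are clipped to [eps, 1 - eps] first so boundary values map to
    finite M-values.  Inside the clip range the conversion is exactly
    invertible by :func:`m_to_beta`.
    """
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    x = np.asarray(m, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp2(-x)), np.exp2(x) / (1.0 + np.exp2(x)))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


@dataclass
class MethylationMatrix:
    """A probes x samples methylation matrix with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
    scale
        Either ``"beta"`` (fractions in [0, 1]) or ``"m"`` (log2 odds).
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ValueError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids in methylation matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in methylation matrix")
        if self.scale == "beta" and self.values.size:
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("beta-tagged values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_m(self, eps: float = BETA_EPS) -> "MethylationMatrix":
        if self.scale == "m":
            return self
        return MethylationMatrix(beta_to_m(self.values, eps=eps), scale="m")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        return MethylationMatrix(m_to_beta(self.values), scale="beta")

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[probe_ids], scale=self.scale)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(sample_ids)], scale=self.scale)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation plus optional detection p-values.

    ``table`` is indexed by probe id with columns:

    - ``chromosome`` (hg19 labels, carried as metadata only),
    - ``position`` (1-based bp),
    - ``island_relation`` (one of :data:`ISLAND_RELATIONS`),
    - ``gene`` (symbol, empty string when intergenic),
    - ``tss_distance`` (signed bp to the nearest TSS),
    - ``is_promoter`` (|tss_distance| <= 1500),
    - ``is_snp_probe``, ``is_sex_chromosome``.

    ``detection_p`` is an optional probes x samples DataFrame of detection
    p-values from the array scanner.
    """

    table: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        tab = self.table
        if tab.index.has_duplicates:
            raise ValueError("duplicate probe ids in annotation")
        if "position" in tab.columns and len(tab) and (tab["position"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        if "island_relation" in tab.columns and len(tab):
            bad = set(tab["island_relation"].unique()) - set(ISLAND_RELATIONS)
            if bad:
                raise ValueError(f"unknown island relations: {sorted(bad)}")
        if "is_promoter" not in tab.columns and "tss_distance" in tab.columns:
            self.table = tab.assign(
                is_promoter=tab["tss_distance"].abs() <= TSS_PROMOTER_WINDOW
            )
        if "is_sex_chromosome" not in self.table.columns and "chromosome" in tab.columns:
            self.table = self.table.assign(
                is_sex_chromosome=self.table["chromosome"].astype(str).isin(SEX_CHROMOSOMES)
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def covers(self, probe_ids) -> bool:
        return pd.Index(probe_ids).isin(self.table.index).all()


@dataclass
class FilterReport:
    """Counts of probes removed by each filtering rule (rules may overlap)."""

    n_input: int
    n_detection: int
    n_sex: int
    n_snp: int
    n_removed: int
    n_retained: int


def filter_probes(
    m: MethylationMatrix,
    ann: ProbeAnnotation,
    p_thresh: float = 0.01,
    max_fail_fraction: float = 0.0,
    drop_sex: bool = True,
    drop_snp: bool = True,
) -> tuple[MethylationMatrix, FilterReport]:
    """Remove probes failing detection, sex-chromosome or SNP rules.

    A probe fails the detection rule when its detection p-value exceeds
    ``p_thresh`` in more than ``max_fail_fraction`` of samples.  The default
    (0.0) removes a probe failing in any sample, the strictest reading.
    Probe order of the retained set is preserved.
    """
    missing = m.probe_ids.difference(ann.probe_ids)
    if len(missing):
        raise KeyError(
            f"{len(missing)} probes missing annotation, e.g. {list(missing[:5])}"
        )
    tab = ann.table.loc[m.probe_ids]

    fail_det = pd.Series(False, index=m.probe_ids)
    if ann.detection_p is not None and m.n_samples:
        det = ann.detection_p.reindex(index=m.probe_ids, columns=m.sample_ids)
        frac = (det > p_thresh).mean(axis=1)
        fail_det = frac > max_fail_fraction

    fail_sex = (
        tab["is_sex_chromosome"].astype(bool)
        if drop_sex and "is_sex_chromosome" in tab.columns
        else pd.Series(False, index=m.probe_ids)
    )
    fail_snp = (
        tab["is_snp_probe"].astype(bool)
        if drop_snp and "is_snp_probe" in tab.columns
        else pd.Series(False, index=m.probe_ids)
    )

    drop = fail_det | fail_sex | fail_snp
    keep = m.probe_ids[~drop.to_numpy()]
    report = FilterReport(
        n_input=m.n_probes,
        n_detection=int(fail_det.sum()),
        n_sex=int(fail_sex.sum()),
        n_snp=int(fail_snp.sum()),
        n_removed=int(drop.sum()),
        n_retained=len(keep),
    )
    return m.subset_probes(keep), report


def _combat_it_sol(sdat: np.ndarray, g_hat, d_hat, g_bar, t2, a_prior, b_prior,
                   conv: float = 1e-4):
    # standard parametric EB iteration for per-batch location/scale effects
    n = np.sum(~np.isnan(sdat), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old)) / (np.max(np.abs(g_old)) + 1e-12),
            np.max(np.abs(d_new - d_old)) / (np.max(np.abs(d_old)) + 1e-12),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    m: MethylationMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> MethylationMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    Per-probe batch means and variances are shrunk toward their across-probe
    priors (normal for means, inverse gamma for variances) and divided out,
    while effects of ``covariates`` (protected biological covariates, one
    column per term, numeric) are estimated jointly and retained.  Typically
    run on M-values.

    Raises if any batch has fewer than two samples.
    """
    batch = batch.reindex(m.sample_ids)
    if batch.isna().any():
        raise KeyError("batch labels missing for some samples")
    levels = pd.unique(batch)
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with <2 samples: {small}")
    if len(levels) == 1:
        return MethylationMatrix(m.values.copy(), scale=m.scale)

    Y = m.values.to_numpy(dtype=float)  # probes x samples
    n_probes, n_samples = Y.shape
    onehot = pd.get_dummies(batch).loc[m.sample_ids, levels].to_numpy(dtype=float)
    n_batch = onehot.shape[1]
    design = onehot
    if covariates is not None:
        cov = covariates.reindex(m.sample_ids).to_numpy(dtype=float)
        design = np.hstack([onehot, cov])

    # probe-wise least squares (shared design): B is (n_params x n_probes)
    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    batch_sizes = onehot.sum(axis=0)
    grand_mean = (batch_sizes / n_samples) @ B_hat[:n_batch]  # per probe
    resid = Y.T - design @ B_hat
    var_pooled = np.mean(resid**2, axis=0)  # per probe (ML, as in sva)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = grand_mean[None, :] + (design[:, n_batch:] @ B_hat[n_batch:]
                                        if design.shape[1] > n_batch else 0.0)
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # samples x probes

    bayes = np.zeros_like(Z)
    for j in range(n_batch):
        mask = onehot[:, j] == 1
        Zb = Z[mask]  # samples_in_batch x probes
        g_hat = Zb.mean(axis=0)
        d_hat = Zb.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        # moment-matched inverse-gamma hyperpriors
        m_d, v_d = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * v_d + m_d**2) / v_d if v_d > 0 else 2.0
        b_prior = (m_d * v_d + m_d**3) / v_d if v_d > 0 else 1.0
        g_star, d_star = _combat_it_sol(Zb.T, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        bayes[mask] = (Zb - g_star[None, :]) / np.sqrt(d_star)[None, :]

    adjusted = bayes * np.sqrt(var_pooled)[None, :] + stand_mean
    out = pd.DataFrame(adjusted.T, index=m.probe_ids, columns=m.sample_ids)
    if m.scale == "beta":
        out = out.clip(0.0, 1.0)
    return MethylationMatrix(out, scale=m.scale)


# ---------------------------------------------------------------------------
# Text I/O.  Matrices travel as TSV with probe rows and sample columns; the
# manifest is a CSV tolerant of stock 450k column names.

_MANIFEST_ALIASES = {
    "IlmnID": "probe_id",
    "Name": "probe_id",
    "CHR": "chromosome",
    "MAPINFO": "position",
    "Relation_to_UCSC_CpG_Island": "island_relation",
    "UCSC_RefGene_Name": "gene",
    "UCSC_RefGene_Group": "gene_region",
}
_ISLAND_ALIASES = {"": "OpenSea", "OpenSea": "OpenSea", "Open Sea": "OpenSea"}


def read_matrix(path, scale: str = "beta") -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MethylationMatrix(df, scale=scale)


def write_matrix(m: MethylationMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", float_format="%.10g")


def read_manifest(path, detection_p_path=None) -> ProbeAnnotation:
    """Read a probe manifest CSV, accepting Illumina 450k column names."""
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in _MANIFEST_ALIASES.items() if k in df.columns})
    if "probe_id" not in df.columns:
        raise ValueError("manifest must contain a probe id column (IlmnID/Name/probe_id)")
    df = df.set_index("probe_id")
    if "island_relation" in df.columns:
        df["island_relation"] = (
            df["island_relation"].fillna("OpenSea").replace(_ISLAND_ALIASES)
        )
    for col in ("is_snp_probe", "is_sex_chromosome", "is_promoter"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    det = None
    if detection_p_path is not None:
        det = pd.read_csv(detection_p_path, sep="\t", index_col=0)
    return ProbeAnnotation(df, detection_p=det)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the per-sample clinical sheet (TSV indexed by sample_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "age" in df.columns and len(df) and (df["age"] <= 0).any():
        warnings.warn("sample sheet contains non-positive ages")
    return df
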