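"""Sample-level molecular state from 450k data.

Copy-number log-ratios from combined methylated + unmethylated intensities,
circular binary segmentation (CBS), CDKN2A homozygous-deletion calling by a
two-component Gaussian mixture, methylation-based tumor purity, the two-probe
MGMT-STP27 promoter-methylation classifier, Ward clustering for the G-CIMP
phenotype, and a nearest-centroid surrogate for methylation-subtype
classification (MES / RTK I / RTK II).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import expit, logit
from sklearn.mixture import GaussianMixture

from .preprocess import MethylationMatrix

__all__ = [
    "IntensityPair",
    "Segment",
    "MgmtCall",
    "MGMT_PROBES",
    "MGMT_CUTOFF",
    "copy_number_logratio",
    "cbs_segment",
    "segment_genome",
    "cdkn2a_hd_call",
    "estimate_purity",
    "mgmt_stp27",
    "gcimp_cluster",
    "nearest_centroid_subtype",
    "SUBTYPES",
    "segments_to_bed",
]

#: The two CpG probes feeding the MGMT-STP27 logistic model.
MGMT_PROBES = ("cg12434587", "cg12981137")

#: Probability cutoff for calling the MGMT promoter methylated.
MGMT_CUTOFF = 0.358

#: Fixed subtype label order; also the tie-break order for nearest-centroid.
SUBTYPES = ("MES", "RTK_I", "RTK_II")


@dataclass
class IntensityPair:
    """Methylated and unmethylated signal intensities, probes x samples."""

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth must share probes and samples")
        for df in (self.meth, self.unmeth):
            if df.size and df.to_numpy(dtype=float).min() < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def total(self) -> pd.DataFrame:
        return self.meth + self.unmeth


@dataclass
class Segment:
    """A copy-number segment, 1-based inclusive coordinates."""

    chromosome: str
    start: int
    end: int
    mean: float
    n_probes: int
    p_value: float


def copy_number_logratio(
    intensities: IntensityPair, reference: pd.Series
) -> pd.DataFrame:
    """Per-probe log2 ratio of total intensity to a reference profile.

    lr = log2((meth + unmeth) / reference_total), median-centered per sample.
    Probes with non-positive total (in the sample or the reference) are
    masked as NaN before centering.
    """
    total = intensities.total
    ref = reference.reindex(total.index)
    if ref.isna().any():
        raise KeyError("reference profile does not cover all probes")
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(total.to_numpy(dtype=float) / ref.to_numpy(dtype=float)[:, None])
    lr[~np.isfinite(lr)] = np.nan
    lr = pd.DataFrame(lr, index=total.index, columns=total.columns)
    return lr - lr.median(axis=0)


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Max standardized circular arc statistic over all arcs (i, j], i < j.

    The statistic compares the mean of the arc against the mean of its
    complement, standardized by the segment standard deviation.
    """
    n = x.size
    s = np.concatenate([[0.0], np.cumsum(x)])
    tot = s[-1]
    sd = x.std()
    if sd == 0:
        return 0.0, 0, n
    i = np.arange(n + 1)
    # arc sums S[j]-S[i] for all i<j via broadcasting
    arc = s[None, :] - s[:, None]  # arc[i, j] = sum x[i:j]
    k = i[None, :] - i[:, None]
    valid = (k > 0) & (k < n)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = arc / k - (tot - arc) / (n - k)
        z = np.abs(diff) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    z[~valid] = -np.inf
    flat = np.argmax(z)
    bi, bj = np.unravel_index(flat, z.shape)
    return float(z[bi, bj]), int(bi), int(bj)


def _cbs_split(x, rng, alpha, n_perm, min_width):
    """Return accepted split points within x, or None."""
    n = x.size
    if n < 2 * min_width:
        return None
    obs, i, j = _max_arc_stat(x)
    if obs == 0.0:
        return None
    exceed = 0
    for _ in range(n_perm):
        t, _, _ = _max_arc_stat(rng.permutation(x))
        if t >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    if p >= alpha:
        return None
    # clamp the arc to respect min_width at the outer edges
    cuts = [c for c in (i, j) if min_width <= c <= n - min_width]
    if not cuts:
        return None
    return sorted(set(cuts)), p


def cbs_segment(
    logratios,
    positions=None,
    chromosome: str = "1",
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> list[Segment]:
    """Circular binary segmentation of one chromosome's ordered log-ratios.

    Recursively tests the maximal circular-arc statistic against a
    permutation reference (within the segment under test); a split is
    accepted when the permutation p-value is below ``alpha``.  Deterministic
    given ``seed``.  Returned segments tile the probe positions exactly.
    """
    x = np.asarray(logratios, dtype=float)
    keep = np.isfinite(x)
    x = x[keep]
    n = x.size
    if positions is None:
        positions = np.arange(1, n + 1)
    else:
        positions = np.asarray(positions)[keep]
    if n == 0:
        return []
    rng = np.random.default_rng(seed)

    boundaries = [0, n]
    p_at = {}
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        res = _cbs_split(x[lo:hi], rng, alpha, n_perm, min_width)
        if res is None:
            continue
        cuts, p = res
        new = [lo + c for c in cuts]
        for c in new:
            if c not in boundaries:
                boundaries.append(c)
                p_at[c] = p
        pieces = sorted({lo, hi, *new})
        for a, b in zip(pieces[:-1], pieces[1:]):
            if (a, b) != (lo, hi):
                stack.append((a, b))
    boundaries = sorted(set(boundaries))

    segments = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        segments.append(
            Segment(
                chromosome=str(chromosome),
                start=int(positions[a]),
                end=int(positions[b - 1]),
                mean=float(x[a:b].mean()),
                n_probes=b - a,
                p_value=float(p_at.get(a, np.nan)),
            )
        )
    return segments


def segment_genome(
    logratios: pd.Series,
    annotation: pd.DataFrame,
    **kwargs,
) -> list[Segment]:
    """Run :func:`cbs_segment` per chromosome (annotation: chromosome, position)."""
    ann = annotation.loc[logratios.index]
    out = []
    for chrom, idx in ann.groupby("chromosome", sort=False).groups.items():
        sub = ann.loc[idx].sort_values("position")
        out.extend(
            cbs_segment(
                logratios.loc[sub.index].to_numpy(),
                positions=sub["position"].to_numpy(),
                chromosome=str(chrom),
                **kwargs,
            )
        )
    return out


def segments_to_bed(segments: list[Segment], path) -> None:
    """Write segments as BED (0-based half-open) with mean log2 ratio as score."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{s.mean:.4f}\t{s.n_probes}\n")


def cdkn2a_hd_call(
    cn_means: pd.Series, min_samples: int = 20, separation_sd: float = 1.0
) -> pd.DataFrame:
    """Call CDKN2A homozygous deletion from per-sample copy-number probe means.

    A two-component Gaussian mixture is fit to the sample means; samples with
    posterior > 0.5 for the lower-mean component are HD.  When the component
    means are closer than ``separation_sd`` pooled standard deviations the
    mixture is considered degenerate and no HD is called.
    """
    x = cn_means.to_numpy(dtype=float).reshape(-1, 1)
    if x.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if np.ptp(x) == 0:
        warnings.warn("all copy-number means identical; no HD called")
        return pd.DataFrame(
            {"hd": False, "posterior_hd": 0.0}, index=cn_means.index
        )
    gmm = GaussianMixture(n_components=2, n_init=5, random_state=0)
    gmm.fit(x)
    means = gmm.means_.ravel()
    pooled_sd = float(np.sqrt(gmm.covariances_.ravel().mean()))
    lower = int(np.argmin(means))
    if abs(means[0] - means[1]) < separation_sd * pooled_sd:
        return pd.DataFrame({"hd": False, "posterior_hd": 0.0}, index=cn_means.index)
    post = gmm.predict_proba(x)[:, lower]
    return pd.DataFrame({"hd": post > 0.5, "posterior_hd": post}, index=cn_means.index)


def estimate_purity(
    betas: MethylationMatrix,
    tumor_reference: pd.Series,
    normal_reference: pd.Series,
    min_diff: float = 0.3,
    min_probes: int = 50,
) -> pd.Series:
    """Tumor purity as the least-squares tumor/normal mixing weight.

    Over probes where the tumor and normal reference profiles differ by more
    than ``min_diff`` (the informative probes), solve
    beta_obs = w * beta_tumor + (1 - w) * beta_normal for w per sample and
    clip to [0, 1].
    """
    t = tumor_reference.reindex(betas.probe_ids)
    n = normal_reference.reindex(betas.probe_ids)
    diff = (t - n).to_numpy(dtype=float)
    informative = np.abs(diff) > min_diff
    if informative.sum() < min_probes:
        raise ValueError(
            f"only {int(informative.sum())} informative probes (< {min_probes})"
        )
    d = diff[informative]
    obs = betas.to_beta().values.to_numpy(dtype=float)[informative]
    resid = obs - n.to_numpy(dtype=float)[informative, None]
    w = (d @ resid) / (d @ d)
    return pd.Series(np.clip(w, 0.0, 1.0), index=betas.sample_ids, name="purity")


def mgmt_stp27(
    m_values: pd.DataFrame,
    coefficients,
    cutoff: float = MGMT_CUTOFF,
    probes=MGMT_PROBES,
) -> pd.DataFrame:
    """MGMT promoter classification from the two STP27 probe M-values.

    ``coefficients`` is (intercept, slope1, slope2) for the logistic model on
    the two probe M-values (in ``probes`` order).  probability =
    expit(b0 + b1*M1 + b2*M2); score = logit(probability); status "M"
    (methylated) when probability >= ``cutoff``, else "U".  The model's
    published coefficient values are a user-supplied input.
    """
    for p in probes:
        if p not in m_values.index:
            raise KeyError(f"missing MGMT probe {p}")
    b0, b1, b2 = (float(c) for c in coefficients)
    m1 = m_values.loc[probes[0]].to_numpy(dtype=float)
    m2 = m_values.loc[probes[1]].to_numpy(dtype=float)
    lin = b0 + b1 * m1 + b2 * m2
    prob = expit(lin)
    return pd.DataFrame(
        {
            "score": lin,
            "probability": prob,
            "status": np.where(prob >= cutoff, "M", "U"),
        },
        index=m_values.columns,
    )


def gcimp_cluster(
    m: MethylationMatrix, k: int = 2, n_top_var: int = 1000
) -> pd.DataFrame:
    """Ward/Euclidean hierarchical clustering; flags the high-methylation cluster.

    Samples are clustered on the ``n_top_var`` most variable probes; the
    cluster with the highest mean methylation over those probes is flagged as
    the G-CIMP-like (hypermethylated) group.
    """
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples")
    vals = m.values
    n_top = min(n_top_var, m.n_probes)
    top = vals.var(axis=1).nlargest(n_top).index
    X = vals.loc[top].to_numpy(dtype=float).T  # samples x probes
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    cluster_means = {c: X[labels == c].mean() for c in np.unique(labels)}
    gcimp_cluster_id = max(cluster_means, key=cluster_means.get)
    return pd.DataFrame(
        {"cluster": labels, "gcimp": labels == gcimp_cluster_id}, index=m.sample_ids
    )


def nearest_centroid_subtype(
    m: MethylationMatrix, centroids: pd.DataFrame
) -> pd.Series:
    """Assign each sample to the nearest subtype centroid (Euclidean).

    ``centroids`` is probes x subtypes; column order (default MES, RTK_I,
    RTK_II) breaks ties.  Centroid probes absent from the matrix raise.
    """
    missing = centroids.index.difference(m.probe_ids)
    if len(missing):
        raise KeyError(f"{len(missing)} centroid probes missing from matrix")
    X = m.values.loc[centroids.index].to_numpy(dtype=float)  # probes x samples
    C = centroids.to_numpy(dtype=float)  # probes x subtypes
    d2 = ((X[:, :, None] - C[:, None, :]) ** 2).sum(axis=0)  # samples x subtypes
    idx = np.argmin(d2, axis=1)  # argmin takes the first minimum: column order ties
    return pd.Series(
        np.asarray(centroids.columns)[idx], index=m.sample_ids, name="subtype"
    )
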