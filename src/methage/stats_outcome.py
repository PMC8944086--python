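"""Multivariate and outcome statistics for methylation-derived sample metrics.

PCA of sample metrics, permutation MANOVA (ADONIS) on Euclidean distances,
three-block variation partitioning with Venn fractions, heteroscedasticity-
robust (HC3) Wald F-tests, Cox proportional-hazards models with a
biomarker x treatment interaction, and the Cochran-Mantel-Haenszel test for
stratified 2x2 tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = [
    "PCAResult",
    "pca",
    "AdonisResult",
    "adonis",
    "VarPartResult",
    "variation_partition",
    "wald_hc3",
    "two_way_wald_table",
    "CoxFit",
    "cox_interaction_fit",
    "cmh_test",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # variances per component, non-increasing
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components


def pca(X: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of a samples x features table via SVD of the (centered) data.

    Eigenvalues are the per-component variances (SVD singular values squared
    over n - 1); their sum equals the total per-feature variance.
    """
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    M = X.to_numpy(dtype=float)
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, ddof=1)
        M = M / np.where(sd == 0, 1.0, sd)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        eigenvalues=eig,
        scores=pd.DataFrame(U * s, index=X.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comps),
    )


@dataclass
class AdonisResult:
    r2: float
    f: float
    p: float
    n_perm: int


def adonis(
    data,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
    is_distance: bool = False,
) -> AdonisResult:
    """Permutation MANOVA (ADONIS) of a grouping factor on Euclidean distances.

    ``data`` is samples x features (a Euclidean distance matrix is computed)
    or, with ``is_distance=True``, a precomputed square distance matrix.  The
    total sum of squares is partitioned from squared inter-point distances;
    R^2 = SS_between / SS_total and the pseudo-F is referred to the
    permutation distribution of freely-shuffled sample labels,
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    g = np.asarray(grouping)
    levels, codes = np.unique(g, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if is_distance:
        D2 = np.asarray(data, dtype=float) ** 2
    else:
        D2 = squareform(pdist(np.asarray(data, dtype=float), metric="sqeuclidean"))
    n = D2.shape[0]
    if g.size != n:
        raise ValueError("grouping length must match sample count")
    a = len(levels)

    def _partition(codes_):
        ss_total = D2.sum() / (2 * n)
        ss_within = 0.0
        for c in range(a):
            idx = np.flatnonzero(codes_ == c)
            if idx.size:
                ss_within += D2[np.ix_(idx, idx)].sum() / (2 * idx.size)
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
        return ss_between / ss_total if ss_total > 0 else 0.0, f

    r2_obs, f_obs = _partition(codes)
    rng = np.random.default_rng(seed)
    exceed = sum(
        _partition(rng.permutation(codes))[1] >= f_obs for _ in range(n_perm)
    )
    return AdonisResult(
        r2=float(r2_obs), f=float(f_obs), p=(1 + exceed) / (n_perm + 1), n_perm=n_perm
    )


def _block_design(block, index) -> np.ndarray:
    """Numeric design for one explanatory block (dummies for categoricals)."""
    if isinstance(block, pd.DataFrame):
        b = block.reindex(index)
    elif isinstance(block, pd.Series):
        b = block.reindex(index).to_frame()
    else:
        b = pd.DataFrame({"x": np.asarray(block)}, index=index)
    cols = []
    for name in b.columns:
        c = b[name]
        if c.dtype == object or isinstance(c.dtype, pd.CategoricalDtype):
            cols.append(pd.get_dummies(c, drop_first=True, dtype=float))
        else:
            cols.append(c.astype(float).to_frame(name))
    return pd.concat(cols, axis=1).to_numpy(dtype=float)


def _rda_r2(Y: np.ndarray, X: np.ndarray, adjusted: bool) -> float:
    """Redundancy R^2 of multivariate Y on design X (with intercept)."""
    n = Y.shape[0]
    X1 = np.hstack([np.ones((n, 1)), X])
    beta, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    resid = Y - X1 @ beta
    ss_tot = (Y**2).sum()  # Y is centered
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    if adjusted:
        p = np.linalg.matrix_rank(X1) - 1
        if n - p - 1 <= 0:
            return np.nan
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2


@dataclass
class VarPartResult:
    """Venn decomposition of multivariate R^2 over three explanatory blocks.

    ``fractions`` holds the 7 Venn fractions keyed by subset label
    ("A", "B", "C", "AB", "BC", "AC", "ABC") plus "residual"; negative shared
    fractions are possible with collinear blocks and are reported as-is.
    """

    labels: tuple[str, str, str]
    fractions: dict
    r2_models: dict
    adjusted: bool

    @property
    def residual(self) -> float:
        return self.fractions["residual"]


def variation_partition(
    response: pd.DataFrame,
    block_a,
    block_b,
    block_c,
    labels: tuple[str, str, str] = ("A", "B", "C"),
    adjusted: bool = True,
) -> VarPartResult:
    """Partition the variance of a multivariate response over three blocks.

    Fits the 7 redundancy models (A, B, C, AB, AC, BC, ABC) and derives the
    unique and shared fractions by inclusion-exclusion.  Adjusted (Ezekiel)
    R^2 is the default currency; ``adjusted=False`` uses raw R^2.  The
    fractions plus the residual sum to 1 exactly (raw) since residual is
    defined as 1 - R^2(ABC).
    """
    Y = response.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    idx = response.index
    A, B, C = (_block_design(b, idx) for b in (block_a, block_b, block_c))

    r2 = {
        "A": _rda_r2(Y, A, adjusted),
        "B": _rda_r2(Y, B, adjusted),
        "C": _rda_r2(Y, C, adjusted),
        "AB": _rda_r2(Y, np.hstack([A, B]), adjusted),
        "AC": _rda_r2(Y, np.hstack([A, C]), adjusted),
        "BC": _rda_r2(Y, np.hstack([B, C]), adjusted),
        "ABC": _rda_r2(Y, np.hstack([A, B, C]), adjusted),
    }
    g = (
        r2["A"] + r2["B"] + r2["C"]
        - r2["AB"] - r2["AC"] - r2["BC"]
        + r2["ABC"]
    )
    fractions = {
        "A": r2["ABC"] - r2["BC"],
        "B": r2["ABC"] - r2["AC"],
        "C": r2["ABC"] - r2["AB"],
        "AB": r2["A"] + r2["B"] - r2["AB"] - g,
        "BC": r2["B"] + r2["C"] - r2["BC"] - g,
        "AC": r2["A"] + r2["C"] - r2["AC"] - g,
        "ABC": g,
        "residual": 1.0 - r2["ABC"],
    }
    return VarPartResult(labels=labels, fractions=fractions, r2_models=r2, adjusted=adjusted)


def wald_hc3(response, design: pd.DataFrame, terms) -> tuple[float, float]:
    """Wald F-test of the joint null on ``terms`` with HC3 sandwich covariance.

    ``design`` is the samples x terms model matrix (an intercept is added);
    ``terms`` names the columns tested jointly.  The coefficient covariance
    is (X'X)^-1 X' diag(e_i^2 / (1 - h_ii)^2) X (X'X)^-1; the statistic is
    referred to an F distribution with (q, n - p) degrees of freedom.
    """
    y = np.asarray(response, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design is rank deficient")
    hat = X.to_numpy() @ np.linalg.pinv(X.to_numpy())
    if np.any(np.diag(hat) >= 1 - 1e-12):
        raise ValueError("saturated design point (leverage 1): HC3 undefined")
    fit = sm.OLS(y, X).fit(cov_type="HC3")
    terms = [terms] if isinstance(terms, str) else list(terms)
    R = np.zeros((len(terms), X.shape[1]))
    for i, t in enumerate(terms):
        R[i, X.columns.get_loc(t)] = 1.0
    res = fit.wald_test(R, use_f=True, scalar=True)
    return float(res.statistic), float(res.pvalue)


def two_way_wald_table(
    response, factor_a: pd.Series, factor_b: pd.Series,
    names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """HC3 Wald F-tests for a two-way model: A, B, and A x B term groups.

    Builds the dummy-coded model response ~ A + B + A:B and jointly tests
    each term group, mirroring a per-characteristic row of a cohort Wald
    table (F-value, Pr(>F) per column).
    """
    idx = factor_a.index
    da = pd.get_dummies(factor_a, drop_first=True, dtype=float).add_prefix(f"{names[0]}_")
    db = pd.get_dummies(factor_b.reindex(idx), drop_first=True, dtype=float).add_prefix(
        f"{names[1]}_"
    )
    inter = pd.DataFrame(
        {
            f"{ca}:{cb}": da[ca] * db[cb]
            for ca in da.columns
            for cb in db.columns
        },
        index=idx,
    )
    design = pd.concat([da, db, inter], axis=1)
    rows = []
    for label, cols in (
        (names[0], list(da.columns)),
        (names[1], list(db.columns)),
        (f"{names[0]} x {names[1]}", list(inter.columns)),
    ):
        f, p = wald_hc3(response, design, cols)
        rows.append((label, f, p))
    return pd.DataFrame(rows, columns=["term", "F", "Pr(>F)"]).set_index("term")


@dataclass
class CoxFit:
    """Cox model summary: one row per term with HR, z and p."""

    summary: pd.DataFrame  # index: term; columns: coef, HR, se, z, p
    log_likelihood: float
    converged: bool = True

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "HR"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def cox_interaction_fit(
    time,
    event,
    treatment,
    mgmt,
    covariate,
    covariate_name: str = "covariate",
) -> CoxFit:
    """Cox model: treatment + MGMT + covariate + treatment x MGMT (Efron ties).

    ``treatment`` and ``mgmt`` are binary (0/1); ``covariate`` is the
    continuous biomarker (e.g. age acceleration in years, or an entropy
    value).  Returns hazard ratios, z-values and p-values per term; the
    interaction term carries the predictive-biomarker question.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "treatment": np.asarray(treatment, dtype=float),
            "mgmt": np.asarray(mgmt, dtype=float),
            covariate_name: np.asarray(covariate, dtype=float),
        }
    )
    df["treatment_x_mgmt"] = df["treatment"] * df["mgmt"]
    if df["event"].sum() < 10:
        raise ValueError("need at least 10 events")
    if not np.isfinite(df[covariate_name]).all():
        raise ValueError("covariate contains non-finite values")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            # retry with ridge; flags likely separation
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "HR": np.exp(s["coef"]),
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
        }
    )
    out.index.name = "term"
    return CoxFit(
        summary=out, log_likelihood=float(cph.log_likelihood_), converged=converged
    )


def cmh_test(tables, correction: bool = False) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-squared test over K stratified 2x2 tables.

    ``tables`` is a (2, 2, K) array or a list of K 2x2 arrays.  Strata with a
    zero row or column margin carry no information and are skipped with a
    warning.  Continuity correction is off by default.  Returns (statistic,
    p) with p from chi-squared(1).
    """
    if isinstance(tables, np.ndarray) and tables.ndim == 3 and tables.shape[:2] == (2, 2):
        strata = [tables[:, :, k].astype(float) for k in range(tables.shape[2])]
    else:
        strata = [np.asarray(t, dtype=float) for t in tables]
    if any(t.shape != (2, 2) for t in strata):
        raise ValueError("each stratum must be a 2x2 table")
    if (np.asarray(strata) < 0).any():
        raise ValueError("counts must be non-negative")
    kept = []
    for t in strata:
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn("stratum with a zero margin skipped")
            continue
        kept.append(t)
    if not kept:
        raise ValueError("no informative strata")
    st = StratifiedTable(kept)
    res = st.test_null_odds(correction=correction)
    return float(res.statistic), float(res.pvalue)
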