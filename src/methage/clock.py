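"""Epigenetic-clock DNAm age: age transform, prediction, training, calibration, acceleration.

A Horvath-style clock is a penalized linear model on clock-CpG beta values
predicting a piecewise-transformed age: logarithmic below ``adult_age``
(default 20 years) and linear above,

    F(a) = log(a + 1) - log(adult_age + 1)    for a <= adult_age
    F(a) = (a - adult_age) / (adult_age + 1)  for a >  adult_age.

DNAm age is the inverse transform of the linear predictor; age acceleration
is DNAm age minus chronological age, in years.  In tumors the acceleration is
typically large and positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import ElasticNetCV

from .preprocess import MethylationMatrix

__all__ = [
    "ClockModel",
    "age_transform",
    "inverse_age_transform",
    "predict_dnam_age",
    "age_acceleration",
    "calibrate_betas",
    "train_clock",
]

DEFAULT_ADULT_AGE = 20.0


def age_transform(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Piecewise log-linear transform of age in years; continuous at adult_age."""
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1):
        raise ValueError("age must be > -1")
    out = np.where(
        a <= adult_age,
        np.log(a + 1.0) - np.log(adult_age + 1.0),
        (a - adult_age) / (adult_age + 1.0),
    )
    return float(out) if np.isscalar(age) else out


def inverse_age_transform(t, adult_age: float = DEFAULT_ADULT_AGE):
    """Exact inverse of :func:`age_transform`."""
    x = np.asarray(t, dtype=float)
    out = np.where(
        x <= 0,
        np.exp(x + np.log(adult_age + 1.0)) - 1.0,
        x * (adult_age + 1.0) + adult_age,
    )
    return float(out) if np.isscalar(t) else out


@dataclass
class ClockModel:
    """Intercept + per-probe beta-scale coefficients in transformed-age units."""

    intercept: float
    coefficients: pd.Series  # indexed by probe id
    adult_age: float = DEFAULT_ADULT_AGE

    def __post_init__(self) -> None:
        if self.coefficients.index.has_duplicates:
            raise ValueError("duplicate probe ids in clock coefficients")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.coefficients.index

    def to_csv(self, path) -> None:
        rows = pd.concat(
            [pd.Series({"(Intercept)": self.intercept}), self.coefficients]
        )
        rows.rename_axis("probe_id").rename("coefficient").to_csv(path)

    @classmethod
    def from_csv(cls, path, adult_age: float = DEFAULT_ADULT_AGE) -> "ClockModel":
        s = pd.read_csv(path, index_col=0)["coefficient"]
        return cls(float(s.pop("(Intercept)")), s, adult_age=adult_age)


def predict_dnam_age(
    m: MethylationMatrix,
    clock: ClockModel,
    missing: str = "drop",
) -> pd.Series:
    """DNAm age in years for every sample.

    The linear predictor is intercept + sum(coef * beta) over the clock probes
    present in the matrix, inverse-transformed to years.  Probes absent from
    the matrix are dropped from the sum without re-normalization, with a
    warning reporting the count (``missing="drop"``, the default, matching
    the practice of running a clock on a detection-filtered array);
    ``missing="error"`` raises instead.
    """
    beta = m.to_beta().values
    present = clock.probe_ids.intersection(beta.index)
    n_missing = len(clock.probe_ids) - len(present)
    if len(present) == 0:
        raise KeyError("no clock probes present in matrix")
    if n_missing:
        if missing == "error":
            raise KeyError(f"{n_missing} clock probes missing from matrix")
        warnings.warn(
            f"{n_missing}/{len(clock.probe_ids)} clock probes missing; "
            "dropped from the linear predictor"
        )
    coefs = clock.coefficients.loc[present]
    lin = clock.intercept + coefs.to_numpy() @ beta.loc[present].to_numpy(dtype=float)
    return pd.Series(
        inverse_age_transform(lin, clock.adult_age), index=m.sample_ids, name="dnam_age"
    )


def age_acceleration(dnam_age, age):
    """DNAm age minus chronological age, in years."""
    if isinstance(dnam_age, pd.Series) and isinstance(age, pd.Series):
        return (dnam_age - age.reindex(dnam_age.index)).rename("acceleration")
    return np.asarray(dnam_age, dtype=float) - np.asarray(age, dtype=float)


def calibrate_betas(
    m: MethylationMatrix, reference: MethylationMatrix
) -> MethylationMatrix:
    """Per-probe quantile matching of clock-probe betas to a reference cohort.

    For each probe shared with the reference, sample values are replaced by
    the reference quantile at their empirical rank (grid (rank-1)/(n-1),
    linear interpolation).  The map is monotone, so within-probe sample
    ranking is preserved; when the input equals the reference it is the
    identity.  Constant probes cannot be rank-calibrated and are left
    unchanged with a warning.  Probes absent from the reference pass through.
    """
    beta = m.to_beta().values.copy()
    ref = reference.to_beta().values
    n = beta.shape[1]
    skipped = []
    for probe in beta.index.intersection(ref.index):
        x = beta.loc[probe].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped.append(probe)
            continue
        q = (rankdata(x, method="average") - 1.0) / max(n - 1, 1)
        beta.loc[probe] = np.quantile(ref.loc[probe].to_numpy(dtype=float), q)
    if skipped:
        warnings.warn(f"{len(skipped)} constant probes skipped in calibration")
    return MethylationMatrix(beta, scale="beta")


def train_clock(
    betas: pd.DataFrame,
    ages,
    l1_ratio: float = 0.5,
    alphas=None,
    cv: int = 5,
    seed: int = 0,
    adult_age: float = DEFAULT_ADULT_AGE,
) -> ClockModel:
    """Fit an elastic-net clock in transformed-age space.

    ``betas`` is probes x samples; ``ages`` chronological (or DNAm) ages in
    years.  The penalty is selected by cross-validation over ``alphas`` (an
    automatic grid when None).  Deterministic given ``seed``.
    """
    ages = np.asarray(ages, dtype=float)
    if betas.shape[1] != ages.size:
        raise ValueError("ages length must match sample count")
    if betas.shape[1] < 20:
        raise ValueError("need at least 20 samples to train a clock")
    if np.ptp(ages) == 0:
        raise ValueError("constant ages: nothing to fit")
    y = age_transform(ages, adult_age)
    X = betas.to_numpy(dtype=float).T
    kwargs = {} if alphas is None else {"alphas": alphas}
    model = ElasticNetCV(
        l1_ratio=l1_ratio, cv=cv, random_state=seed, max_iter=50000, **kwargs
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coefs = pd.Series(model.coef_, index=betas.index)
    return ClockModel(float(model.intercept_), coefs[coefs != 0.0], adult_age=adult_age)
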