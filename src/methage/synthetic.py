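"""Seeded synthetic 450k-style GBM cohorts with ground truth.

The generator emulates the statistical structure a methylation-cohort
analysis assumes, at desk scale: beta values with CpG-island-context
baselines (bimodal in promoter islands, intermediate in open sea), an age
signal on clock probes plus a large tumor "age acceleration", three
methylation subtypes with probe-signature shifts, promoter CpGs negatively
coupled to expression, batch location/scale shifts on the logit scale,
planted copy-number segments including CDKN2A homozygous deletions, purity
mixing with a synthetic normal-brain profile on a dedicated informative
probe block, and proportional-hazards survival with an MGMT x treatment
interaction.  Every draw comes from named child streams of one master seed,
so the same config and seed reproduce the cohort bit for bit and adding
probes does not perturb the survival draws.

The accompanying :class:`TruthRecord` carries everything a test oracle
needs: planted flags and slopes, the generating clock, reference profiles,
breakpoints, and per-sample latent state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clock import ClockModel, age_transform
from .genomic_state import MGMT_PROBES, SUBTYPES, IntensityPair
from .preprocess import (
    ISLAND_RELATIONS,
    MethylationMatrix,
    ProbeAnnotation,
    beta_to_m,
    m_to_beta,
)

__all__ = [
    "CohortConfig",
    "SurvivalParams",
    "CnvParams",
    "TruthRecord",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_survival",
    "write_fixtures",
    "read_fixtures",
]

_STREAMS = (
    "annotation", "baseline", "clock", "covariates", "dmp", "functional",
    "expression", "subtype", "noise", "batch", "survival", "cnv", "purity",
    "mgmt",
)


@dataclass
class SurvivalParams:
    """Exponential proportional-hazards survival model, rates per year."""

    baseline_rate: float = 0.5
    log_hr_treatment: float = -0.3
    log_hr_mgmt: float = 0.1
    log_hr_interaction: float = -1.0
    log_hr_accel_per_year: float = -0.0147
    censoring_rate: float = 0.15


@dataclass
class CnvParams:
    """Planted copy-number state: clonal segments plus CDKN2A deletions."""

    cdkn2a_hd_fraction: float = 0.5
    #: (chromosome, start, end, log2 ratio), applied to every sample.
    segment_spec: list = field(
        default_factory=lambda: [
            ("7", 1, 159_000_000, 0.58),     # chr7 gain, log2(3/2)
            ("10", 1, 135_000_000, -1.0),    # chr10 loss
        ]
    )


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults emulate a GBM trial cohort.

    Acceleration defaults follow the published GBM picture (mean ~36.8 years,
    sd ~24 years, RTK II highest); purity spans 0.31-0.99; subtype
    proportions roughly MES 30% / RTK I 20% / RTK II 50%.
    """

    n_samples: int = 200
    n_probes: int = 5000
    n_clock_probes: int = 60
    subtype_proportions: dict = field(
        default_factory=lambda: {"MES": 0.3, "RTK_I": 0.2, "RTK_II": 0.5}
    )
    age_range: tuple = (30.0, 85.0)
    accel_mean: float = 36.8
    accel_sd: float = 24.0
    accel_subtype_shift: dict = field(
        default_factory=lambda: {"MES": -7.7, "RTK_I": -3.3, "RTK_II": 6.5}
    )
    n_dmp_age: int = 30
    n_dmp_accel: int = 50
    dmp_slope: float = 0.004  # beta units per year
    n_functional: int = 20
    expression_coupling: float = -0.5
    n_subtype_signature: int = 150
    n_purity_informative: int = 100
    n_cdkn2a_probes: int = 20
    batch_labels: dict = field(
        default_factory=lambda: {"batchA": (0.0, 1.0), "batchB": (0.3, 1.0)}
    )
    noise_sd: float = 0.2  # logit-scale
    functional_signal_sd: float = 0.12  # beta-scale spread of functional CpGs
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    cnv_params: CnvParams = field(default_factory=CnvParams)
    purity_range: tuple = (0.31, 0.99)
    seed: int = 0

    def validate(self) -> None:
        props = np.array(list(self.subtype_proportions.values()), dtype=float)
        if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("subtype_proportions must be a simplex")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for name in ("n_probes", "n_clock_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clock_probes > self.n_probes:
            raise ValueError("n_clock_probes must not exceed n_probes")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ValueError("age_range must satisfy 0 < min < max")
        sp = self.survival_params
        if sp.baseline_rate <= 0 or sp.censoring_rate <= 0:
            raise ValueError("survival rates must be positive")
        plo, phi = self.purity_range
        if not (0 <= plo <= phi <= 1):
            raise ValueError("purity_range must lie within [0, 1]")
        reserved = (
            self.n_clock_probes + self.n_dmp_age + self.n_dmp_accel
            + self.n_functional + self.n_subtype_signature
            + self.n_purity_informative + self.n_cdkn2a_probes + len(MGMT_PROBES)
        )
        if reserved > self.n_probes:
            raise ValueError(
                f"probe blocks require {reserved} probes but n_probes={self.n_probes}"
            )


@dataclass
class TruthRecord:
    """Generator ground truth used as the test oracle."""

    samples: pd.DataFrame  # acceleration, subtype, mgmt, purity, log_hazard, hd
    probes: pd.DataFrame  # is_clock, is_age_dmp, is_accel_dmp, is_functional, slope
    breakpoints: list  # (chromosome, start, end, log2ratio)
    hd_samples: list
    clock: ClockModel
    mgmt_coefficients: tuple
    tumor_reference: pd.Series
    normal_reference: pd.Series
    intensity_reference: pd.Series
    subtype_centroids: pd.DataFrame

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for chrom, start, end, _ in self.breakpoints:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans = sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping planted segments on {chrom}")

    def to_json(self, path) -> None:
        payload = {
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "probes": self.probes.reset_index().to_dict(orient="list"),
            "breakpoints": [list(b) for b in self.breakpoints],
            "hd_samples": list(self.hd_samples),
            "clock": {
                "intercept": self.clock.intercept,
                "coefficients": self.clock.coefficients.to_dict(),
                "adult_age": self.clock.adult_age,
            },
            "mgmt_coefficients": list(self.mgmt_coefficients),
            "tumor_reference": self.tumor_reference.to_dict(),
            "normal_reference": self.normal_reference.to_dict(),
            "intensity_reference": self.intensity_reference.to_dict(),
            "subtype_centroids": self.subtype_centroids.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        samples = pd.DataFrame(d["samples"]).set_index("sample_id")
        probes = pd.DataFrame(d["probes"]).set_index("probe_id")
        return cls(
            samples=samples,
            probes=probes,
            breakpoints=[tuple(b) for b in d["breakpoints"]],
            hd_samples=d["hd_samples"],
            clock=ClockModel(
                d["clock"]["intercept"],
                pd.Series(d["clock"]["coefficients"]),
                adult_age=d["clock"]["adult_age"],
            ),
            mgmt_coefficients=tuple(d["mgmt_coefficients"]),
            tumor_reference=pd.Series(d["tumor_reference"]),
            normal_reference=pd.Series(d["normal_reference"]),
            intensity_reference=pd.Series(d["intensity_reference"]),
            subtype_centroids=pd.DataFrame(d["subtype_centroids"]),
        )


@dataclass
class SyntheticCohort:
    betas: MethylationMatrix
    annotation: ProbeAnnotation
    samples: pd.DataFrame
    expression: pd.DataFrame
    intensities: IntensityPair
    truth: TruthRecord


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def simulate_survival(
    treatment, mgmt, accel, params: SurvivalParams, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (time_years, event, log_hazard) from the exponential PH model.

    The linear predictor is log_hr_treatment * trt + log_hr_mgmt * mgmt +
    log_hr_interaction * trt * mgmt + log_hr_accel_per_year * accel; event
    times are exponential with rate baseline_rate * exp(lp), censoring times
    exponential with the censoring rate.
    """
    trt = np.asarray(treatment, dtype=float)
    mg = np.asarray(mgmt, dtype=float)
    ac = np.asarray(accel, dtype=float)
    lp = (
        params.log_hr_treatment * trt
        + params.log_hr_mgmt * mg
        + params.log_hr_interaction * trt * mg
        + params.log_hr_accel_per_year * ac
    )
    rate = params.baseline_rate * np.exp(lp)
    n = trt.size
    t_event = rng.exponential(1.0, size=n) / np.where(rate > 0, rate, 1.0)
    t_cens = rng.exponential(1.0 / params.censoring_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event, lp


def _baseline_betas(rel, prom, rng) -> np.ndarray:
    """Per-probe baseline beta by island context: bimodal in (promoter) islands,
    intermediate in open sea."""
    n = rel.size
    base = np.empty(n)
    for i in range(n):
        r, p = rel[i], prom[i]
        if r == "Island" and p:
            base[i] = rng.beta(2, 30) if rng.random() < 0.5 else rng.beta(30, 2)
        elif r == "Island":
            base[i] = rng.beta(2, 10) if rng.random() < 0.5 else rng.beta(10, 2)
        elif r in ("N_Shore", "S_Shore", "N_Shelf", "S_Shelf"):
            base[i] = rng.beta(3, 4) if rng.random() < 0.5 else rng.beta(4, 3)
        else:  # open sea: intermediate methylation, high entropy
            base[i] = rng.beta(8, 6)
    return np.clip(base, 0.01, 0.99)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort plus its :class:`TruthRecord`.

    Identical config and seed produce bit-identical outputs.
    """
    config.validate()
    cfg = config
    rngs = _streams(cfg.seed)
    n, p = cfg.n_samples, cfg.n_probes

    probe_ids = [f"cg{i:08d}" for i in range(p)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # ---- probe blocks (disjoint, deterministic layout) ------------------
    cursor = 0

    def take(k):
        nonlocal cursor
        out = np.arange(cursor, cursor + k)
        cursor += k
        return out

    idx_clock = take(cfg.n_clock_probes)
    idx_age = take(cfg.n_dmp_age)
    idx_accel = take(cfg.n_dmp_accel)
    idx_func = take(cfg.n_functional)
    idx_sig = take(cfg.n_subtype_signature)
    idx_pur = take(cfg.n_purity_informative)
    idx_cdkn2a = take(cfg.n_cdkn2a_probes)
    idx_mgmt = take(len(MGMT_PROBES))
    idx_bg = np.arange(cursor, p)
    for local, name in zip(idx_mgmt, MGMT_PROBES):
        probe_ids[local] = name

    # ---- annotation -----------------------------------------------------
    rng_ann = rngs["annotation"]
    chrom = rng_ann.choice([str(c) for c in range(1, 23)], size=p)
    chrom[idx_cdkn2a] = "9"
    chrom[idx_mgmt] = "10"
    # a slice of background probes sits on sex chromosomes / SNPs
    n_sex = max(1, len(idx_bg) // 50) if len(idx_bg) else 0
    n_snp = max(1, len(idx_bg) // 50) if len(idx_bg) else 0
    sex_probes = idx_bg[:n_sex]
    snp_probes = idx_bg[n_sex:n_sex + n_snp]
    chrom[sex_probes] = rng_ann.choice(["X", "Y"], size=n_sex)

    position = np.zeros(p, dtype=int)
    for c in np.unique(chrom):
        mask = chrom == c
        k = int(mask.sum())
        # strictly increasing positions via cumulative random gaps
        gaps = rng_ann.integers(1, max(2, 200_000_000 // (k + 1)), size=k)
        position[mask] = np.cumsum(gaps)
    position[idx_cdkn2a] = np.sort(
        rng_ann.choice(np.arange(21_967_000, 21_995_000), size=len(idx_cdkn2a), replace=False)
    )
    position[idx_mgmt] = [131_265_000, 131_265_500]

    island = rng_ann.choice(ISLAND_RELATIONS, size=p)
    tss = rng_ann.integers(-200_000, 200_000, size=p)
    promoter_draw = rng_ann.random(p) < 0.5
    tss = np.where(promoter_draw, rng_ann.integers(-1500, 1501, size=p), tss)
    tss = np.where(~promoter_draw & (np.abs(tss) <= 1500), 1501, tss)
    tss[idx_func] = rng_ann.integers(-1500, 1501, size=len(idx_func))
    is_promoter = np.abs(tss) <= 1500

    gene = np.array([""] * p, dtype=object)
    gene[is_promoter] = [f"GENE{i:05d}" for i in np.flatnonzero(is_promoter)]
    gene[idx_func] = [f"FGENE{k:04d}" for k in range(len(idx_func))]
    gene[idx_cdkn2a] = "CDKN2A"
    gene[idx_mgmt] = "MGMT"

    is_snp = np.zeros(p, dtype=bool)
    is_snp[snp_probes] = True
    is_sex = np.isin(chrom, ["X", "Y"])

    ann_table = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": position,
            "island_relation": island,
            "gene": gene,
            "tss_distance": tss,
            "is_promoter": is_promoter,
            "is_snp_probe": is_snp,
            "is_sex_chromosome": is_sex,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # detection p-values: clean except rare failures on background probes
    rng_noise = rngs["noise"]
    det = rng_noise.uniform(0, 0.005, size=(p, n))
    if len(idx_bg) and n:
        n_fail = max(1, len(idx_bg) // 100)
        fail_probes = rng_noise.choice(idx_bg, size=n_fail, replace=False)
        det[fail_probes, rng_noise.integers(0, n, size=n_fail)] = 0.02
    detection_p = pd.DataFrame(det, index=ann_table.index, columns=sample_ids)

    # ---- per-sample covariates ------------------------------------------
    rng_cov = rngs["covariates"]
    age = rng_cov.uniform(*cfg.age_range, size=n)
    sex = rng_cov.choice(["F", "M"], size=n)
    subtype = rng_cov.choice(
        list(cfg.subtype_proportions), size=n, p=list(cfg.subtype_proportions.values())
    )
    shift = np.array([cfg.accel_subtype_shift.get(s, 0.0) for s in subtype])
    accel = rng_cov.normal(cfg.accel_mean + shift, cfg.accel_sd, size=n)
    accel = np.maximum(accel, -(age - 1.0))  # keep true DNAm age above 1 year
    batch = np.array(list(cfg.batch_labels))[np.arange(n) % max(len(cfg.batch_labels), 1)]
    treatment = rng_cov.integers(0, 2, size=n)

    rng_mgmt = rngs["mgmt"]
    mgmt_state = rng_mgmt.integers(0, 2, size=n)
    purity = rngs["purity"].uniform(*cfg.purity_range, size=n)

    # ---- clean beta matrix ----------------------------------------------
    rng_base = rngs["baseline"]
    base = _baseline_betas(island, is_promoter, rng_base)
    betas = np.tile(base[:, None], (1, n)) if n else np.empty((p, 0))

    # clock probes: beta = c_j + u_j * F(age + accel); the generating clock
    # inverts this exactly (weights w_j = u_j / sum u^2, intercept -sum w c)
    rng_clock = rngs["clock"]
    u = rng_clock.choice([-1.0, 1.0], size=len(idx_clock)) * rng_clock.uniform(
        0.03, 0.06, size=len(idx_clock)
    )
    mean_shift = sum(
        cfg.subtype_proportions[s] * cfg.accel_subtype_shift.get(s, 0.0)
        for s in cfg.subtype_proportions
    )
    t_mid = age_transform(np.mean(cfg.age_range) + cfg.accel_mean + mean_shift)
    c = 0.5 - u * t_mid
    t_true = age_transform(age + accel) if n else np.empty(0)
    betas[idx_clock] = c[:, None] + u[:, None] * t_true[None, :]
    w = u / (u @ u)
    clock = ClockModel(
        intercept=-float(w @ c),
        coefficients=pd.Series(w, index=[probe_ids[i] for i in idx_clock]),
    )

    # planted DMPs: linear beta-scale slope in the covariate
    rng_dmp = rngs["dmp"]
    slope = np.zeros(p)
    base_dmp_age = rng_dmp.uniform(0.35, 0.65, size=len(idx_age))
    sgn_age = rng_dmp.choice([-1.0, 1.0], size=len(idx_age))
    slope[idx_age] = sgn_age * cfg.dmp_slope
    if n:
        betas[idx_age] = base_dmp_age[:, None] + np.outer(
            slope[idx_age], age - age.mean()
        )
    base_dmp_acc = rng_dmp.uniform(0.35, 0.65, size=len(idx_accel))
    sgn_acc = rng_dmp.choice([-1.0, 1.0], size=len(idx_accel))
    slope[idx_accel] = sgn_acc * cfg.dmp_slope
    if n:
        betas[idx_accel] = base_dmp_acc[:, None] + np.outer(
            slope[idx_accel], accel - accel.mean()
        )

    # functional promoter CpGs: per-sample latent signal feeding expression
    rng_func = rngs["functional"]
    func_base = rng_func.uniform(0.3, 0.7, size=len(idx_func))
    func_latent = rng_func.standard_normal((len(idx_func), n)) if n else np.empty(
        (len(idx_func), 0)
    )
    betas[idx_func] = func_base[:, None] + cfg.functional_signal_sd * func_latent

    # subtype signature shifts (logit scale)
    rng_sub = rngs["subtype"]
    sig_shift = rng_sub.normal(0.0, 1.2, size=(len(idx_sig), len(SUBTYPES)))
    sub_idx = {s: k for k, s in enumerate(SUBTYPES)}
    if n:
        cols = np.array([sub_idx[s] for s in subtype])
        betas[idx_sig] = expit(
            logit(np.clip(betas[idx_sig], 0.01, 0.99)) + sig_shift[:, cols]
        )
    centroids = pd.DataFrame(
        expit(logit(np.clip(base[idx_sig], 0.01, 0.99))[:, None] + sig_shift),
        index=[probe_ids[i] for i in idx_sig],
        columns=list(SUBTYPES),
    )

    # purity mixing on the informative block
    half = len(idx_pur) // 2
    t_prof = np.concatenate(
        [
            rngs["purity"].uniform(0.75, 0.95, size=half),
            rngs["purity"].uniform(0.05, 0.25, size=len(idx_pur) - half),
        ]
    )
    n_prof = np.concatenate(
        [
            rngs["purity"].uniform(0.05, 0.25, size=half),
            rngs["purity"].uniform(0.75, 0.95, size=len(idx_pur) - half),
        ]
    )
    if n:
        betas[idx_pur] = np.outer(t_prof, purity) + np.outer(n_prof, 1.0 - purity)
    tumor_ref = pd.Series(base.copy(), index=ann_table.index)
    normal_ref = pd.Series(base.copy(), index=ann_table.index)
    tumor_ref.iloc[idx_pur] = t_prof
    normal_ref.iloc[idx_pur] = n_prof

    # MGMT probe M-values by true promoter state
    mgmt_coefs = (0.0, 1.0, 1.0)
    if n:
        m1 = np.where(mgmt_state == 1, 2.5, -3.5) + rng_mgmt.normal(0, 0.5, size=n)
        m2 = np.where(mgmt_state == 1, 2.5, -3.5) + rng_mgmt.normal(0, 0.5, size=n)
        betas[idx_mgmt[0]] = m_to_beta(m1)
        betas[idx_mgmt[1]] = m_to_beta(m2)

    # batch shifts (logit scale) then logit-scale noise; MGMT, purity and
    # CDKN2A blocks stay on their generating scale
    exempt = np.zeros(p, dtype=bool)
    exempt[np.concatenate([idx_pur, idx_cdkn2a, idx_mgmt])] = True
    if n:
        lo = logit(np.clip(betas, 1e-6, 1 - 1e-6))
        locs = np.array([cfg.batch_labels[b][0] for b in batch])
        scales = np.array([cfg.batch_labels[b][1] for b in batch])
        shifted = lo * scales[None, :] + locs[None, :]
        lo = np.where(exempt[:, None], lo, shifted)
        if cfg.noise_sd > 0:
            noise = rng_noise.normal(0.0, cfg.noise_sd, size=lo.shape)
            noise[exempt] = 0.0
            lo = lo + noise
        noisy = expit(lo)
        # noiseless, unshifted probes keep exact generating values
        untouched = exempt[:, None] | (
            (cfg.noise_sd == 0)
            & np.isclose(locs, 0.0)[None, :]
            & np.isclose(scales, 1.0)[None, :]
        )
        betas = np.where(untouched, betas, noisy)
    betas = np.clip(betas, 0.0, 1.0)
    beta_df = pd.DataFrame(betas, index=ann_table.index, columns=sample_ids)

    # ---- expression ------------------------------------------------------
    rng_expr = rngs["expression"]
    rho = abs(cfg.expression_coupling)
    # account for logit-noise attenuation of the observed beta signal
    noise_beta = cfg.noise_sd * 0.25
    r_signal = cfg.functional_signal_sd / np.hypot(cfg.functional_signal_sd, noise_beta)
    lam = np.sqrt(max(r_signal**2 / rho**2 - 1.0, 0.0)) if rho > 0 else np.inf
    genes = [g for g in pd.unique(gene[is_promoter]) if g]
    expr = pd.DataFrame(
        rng_expr.standard_normal((len(genes), n)),
        index=pd.Index(genes, name="gene"),
        columns=sample_ids,
    )
    for k, gi in enumerate(idx_func):
        g = gene[gi]
        expr.loc[g] = -func_latent[k] + lam * rng_expr.standard_normal(n)
    # a handful of promoter genes are deliberately absent from expression
    absent = [g for g in genes if not g.startswith(("FGENE", "CDKN2A", "MGMT"))][: max(
        len(genes) // 50, 0
    )]
    expr = expr.drop(index=absent)

    # ---- copy number intensities ----------------------------------------
    rng_cnv = rngs["cnv"]
    ref_total = pd.Series(
        rng_cnv.lognormal(mean=np.log(3000), sigma=0.3, size=p), index=ann_table.index
    )
    lr = np.zeros((p, n))
    for chrom_s, start, end, ratio in cfg.cnv_params.segment_spec:
        mask = (chrom == str(chrom_s)) & (position >= start) & (position <= end)
        lr[mask] += ratio
    n_hd = int(round(cfg.cnv_params.cdkn2a_hd_fraction * n))
    hd_idx = rng_cnv.choice(n, size=n_hd, replace=False) if n else np.array([], int)
    hd_flag = np.zeros(n, dtype=bool)
    hd_flag[hd_idx] = True
    lr[np.ix_(idx_cdkn2a, hd_idx)] = np.log2(0.1)
    total = ref_total.to_numpy()[:, None] * np.exp2(
        lr + rng_cnv.normal(0, 0.2, size=lr.shape)
    )
    meth = pd.DataFrame(total * betas, index=ann_table.index, columns=sample_ids)
    unmeth = pd.DataFrame(total * (1 - betas), index=ann_table.index, columns=sample_ids)

    # ---- survival --------------------------------------------------------
    time_y, event, lp = simulate_survival(
        treatment, mgmt_state, accel, cfg.survival_params, rngs["survival"]
    )

    samples = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "batch": batch,
            "treatment": treatment,
            "mgmt_status": np.where(mgmt_state == 1, "M", "U"),
            "survival_time": time_y * 12.0,  # months
            "event": event,
            "subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    probes_truth = pd.DataFrame(
        {
            "is_clock": np.isin(np.arange(p), idx_clock),
            "is_age_dmp": np.isin(np.arange(p), idx_age),
            "is_accel_dmp": np.isin(np.arange(p), idx_accel),
            "is_functional": np.isin(np.arange(p), idx_func),
            "slope": slope,
        },
        index=ann_table.index,
    )
    breakpoints = [
        (str(c_), int(s_), int(e_), float(r_))
        for c_, s_, e_, r_ in cfg.cnv_params.segment_spec
    ]
    if len(idx_cdkn2a):
        breakpoints.append(
            (
                "9",
                int(position[idx_cdkn2a].min()),
                int(position[idx_cdkn2a].max()),
                float(np.log2(0.1)),
            )
        )
    truth = TruthRecord(
        samples=pd.DataFrame(
            {
                "acceleration": accel,
                "subtype": subtype,
                "mgmt": mgmt_state,
                "purity": purity,
                "log_hazard": lp,
                "hd": hd_flag,
            },
            index=samples.index,
        ),
        probes=probes_truth,
        breakpoints=breakpoints,
        hd_samples=[sample_ids[i] for i in np.sort(hd_idx)],
        clock=clock,
        mgmt_coefficients=mgmt_coefs,
        tumor_reference=tumor_ref,
        normal_reference=normal_ref,
        intensity_reference=ref_total,
        subtype_centroids=centroids,
    )
    return SyntheticCohort(
        betas=MethylationMatrix(beta_df, scale="beta"),
        annotation=ProbeAnnotation(ann_table, detection_p=detection_p),
        samples=samples,
        expression=expr,
        intensities=IntensityPair(meth, unmeth),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture I/O: everything as plain text, 450k-flavoured column names.

_MANIFEST_COLS = {
    "chromosome": "CHR",
    "position": "MAPINFO",
    "island_relation": "Relation_to_UCSC_CpG_Island",
    "gene": "UCSC_RefGene_Name",
}


def write_fixtures(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as TSV/CSV/JSON files; returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": d / "betas.tsv",
        "manifest": d / "manifest.csv",
        "samples": d / "samples.tsv",
        "expression": d / "expression.tsv",
        "meth_intensity": d / "meth_intensity.tsv",
        "unmeth_intensity": d / "unmeth_intensity.tsv",
        "detection_p": d / "detection_p.tsv",
        "truth": d / "truth.json",
    }
    fmt = "%.17g"
    cohort.betas.values.to_csv(paths["betas"], sep="\t", float_format=fmt)
    manifest = cohort.annotation.table.rename(columns=_MANIFEST_COLS)
    manifest.index.name = "IlmnID"
    manifest.to_csv(paths["manifest"])
    cohort.samples.to_csv(paths["samples"], sep="\t")
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format=fmt)
    cohort.intensities.meth.to_csv(paths["meth_intensity"], sep="\t", float_format=fmt)
    cohort.intensities.unmeth.to_csv(paths["unmeth_intensity"], sep="\t", float_format=fmt)
    if cohort.annotation.detection_p is not None:
        cohort.annotation.detection_p.to_csv(
            paths["detection_p"], sep="\t", float_format=fmt
        )
    cohort.truth.to_json(paths["truth"])
    return paths


def read_fixtures(directory) -> SyntheticCohort:
    """Read back a fixture directory written by :func:`write_fixtures`."""
    from .preprocess import read_manifest, read_sample_sheet

    d = Path(directory)
    betas = pd.read_csv(d / "betas.tsv", sep="\t", index_col=0)
    det_path = d / "detection_p.tsv"
    ann = read_manifest(d / "manifest.csv", det_path if det_path.exists() else None)
    samples = read_sample_sheet(d / "samples.tsv")
    expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    meth = pd.read_csv(d / "meth_intensity.tsv", sep="\t", index_col=0)
    unmeth = pd.read_csv(d / "unmeth_intensity.tsv", sep="\t", index_col=0)
    truth = TruthRecord.from_json(d / "truth.json")
    return SyntheticCohort(
        betas=MethylationMatrix(betas, scale="beta"),
        annotation=ann,
        samples=samples,
        expression=expr,
        intensities=IntensityPair(meth, unmeth),
        truth=truth,
    )
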