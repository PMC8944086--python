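"""End-to-end orchestration: generate/load -> preprocess -> clock -> entropy
-> association scans -> molecular state -> outcome statistics.

Produces plain-text report tables mirroring the structure of a cohort
methylation study: a per-sample baseline table (age, DNAm age, acceleration,
subtype, MGMT call, purity, entropy), DMP counts and Venn overlaps,
functional-methylation flags, a per-metric HC3 Wald table, and a Cox table
with the treatment x MGMT interaction, plus a machine-readable run log.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clock as clock_mod, entropy, genomic_state, stats_outcome
from .preprocess import MethylationMatrix, beta_to_m, combat_adjust, filter_probes
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, read_fixtures

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class Thresholds:
    detection_p: float = 0.01
    dmp_q: float = 0.1
    functional_q: float = 0.05
    functional_rho: float = -0.3
    mgmt_cutoff: float = 0.358
    gsea_alpha: float = 0.1

    def validate(self) -> None:
        for name in ("detection_p", "dmp_q", "functional_q", "gsea_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.mgmt_cutoff < 1:
            raise ValueError("mgmt_cutoff must be in (0, 1)")
        if not -1 <= self.functional_rho <= 0:
            raise ValueError("functional_rho must be in [-1, 0]")


@dataclass
class PipelineConfig:
    """Pipeline inputs: either a generator config or a fixture directory."""

    generator: CohortConfig | None = None
    input_dir: str | None = None
    output_dir: str = "methage_output"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    run_combat: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = CohortConfig(**gen)
        if thr is not None:
            cfg.thresholds = Thresholds(**thr)
        return cfg

    def validate(self) -> None:
        self.thresholds.validate()
        if self.generator is None and self.input_dir is None:
            raise ValueError("either a generator config or an input_dir is required")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict and writes all tables.

    Re-running with the same config reproduces every number.  Any stage
    failure raises :class:`PipelineError` naming the stage; outputs written
    before the failure are preserved.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - stage boundary
                _write_log(log, outdir)
                raise PipelineError(name, e) from e
            log.append({"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3)})
            return out
        return deco

    # ---- load / generate -------------------------------------------------
    @stage("load")
    def cohort() -> SyntheticCohort:
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            return generate_cohort(gen)
        return read_fixtures(config.input_dir)

    samples = cohort.samples
    truth = cohort.truth
    log[-1].update(n_samples=int(cohort.betas.n_samples), n_probes=int(cohort.betas.n_probes))

    # ---- preprocess ------------------------------------------------------
    @stage("preprocess")
    def prep():
        filtered, rep = filter_probes(
            cohort.betas, cohort.annotation, p_thresh=config.thresholds.detection_p
        )
        m = filtered.to_m()
        if config.run_combat and samples["batch"].nunique() > 1:
            m = combat_adjust(m, samples["batch"])
        return filtered, m, rep

    betas_f, mvals, filter_report = prep
    log[-1].update(dataclasses.asdict(filter_report))

    # ---- clock -----------------------------------------------------------
    @stage("clock")
    def clock_stage():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dnam = clock_mod.predict_dnam_age(betas_f, truth.clock)
        accel = clock_mod.age_acceleration(dnam, samples["age"])
        return dnam, accel

    dnam_age, accel = clock_stage

    # ---- entropy ---------------------------------------------------------
    @stage("entropy")
    def entropy_stage():
        return entropy.hme_by_stratum(betas_f, cohort.annotation)

    etab = entropy_stage

    # ---- molecular state -------------------------------------------------
    @stage("genomic_state")
    def state_stage():
        mgmt = genomic_state.mgmt_stp27(
            beta_to_m(cohort.betas.values),
            truth.mgmt_coefficients,
            cutoff=config.thresholds.mgmt_cutoff,
        )
        purity = genomic_state.estimate_purity(
            cohort.betas, truth.tumor_reference, truth.normal_reference
        )
        subtype = genomic_state.nearest_centroid_subtype(
            cohort.betas, truth.subtype_centroids
        )
        lr = genomic_state.copy_number_logratio(
            cohort.intensities, truth.intensity_reference
        )
        cdkn2a_probes = cohort.annotation.table.index[
            cohort.annotation.table["gene"] == "CDKN2A"
        ]
        hd = None
        if len(cdkn2a_probes) and cohort.betas.n_samples >= 20:
            hd = genomic_state.cdkn2a_hd_call(lr.loc[cdkn2a_probes].mean(axis=0))
        return mgmt, purity, subtype, lr, hd

    mgmt_calls, purity, subtype_calls, logratios, hd_calls = state_stage

    # ---- baseline table (per-sample summary) ----------------------------
    baseline = pd.DataFrame(
        {
            "age": samples["age"],
            "dnam_age": dnam_age,
            "acceleration": accel,
            "subtype": subtype_calls,
            "mgmt_status": mgmt_calls["status"],
            "mgmt_score": mgmt_calls["score"],
            "purity": purity,
            "global_hme": etab.global_hme,
            "hme_promoter_island": etab.by_stratum["Island.promoter"],
        }
    )
    _fmt(baseline, outdir / "baseline_table.tsv")

    # ---- association scans ----------------------------------------------
    @stage("association")
    def assoc_stage():
        q = config.thresholds.dmp_q
        dmp_age = association.dmp_scan(mvals, samples["age"], q_threshold=q)
        dmp_accel = association.dmp_scan(mvals, accel, q_threshold=q)
        if subtype_calls.nunique() > 1:
            dmp_class = association.dmp_scan(
                mvals, subtype_calls.astype(object), q_threshold=q
            )
        else:  # degenerate classification (e.g. no signature probes)
            dmp_class = dmp_age.iloc[0:0]
        probe_gene = (
            cohort.annotation.table.loc[
                cohort.annotation.table["is_promoter"]
                & (cohort.annotation.table["gene"] != ""),
                "gene",
            ]
        )
        functional = association.functional_scan(
            betas_f.subset_probes(betas_f.probe_ids.intersection(probe_gene.index)),
            cohort.expression,
            probe_gene.loc[probe_gene.index.intersection(betas_f.probe_ids)],
            q_threshold=config.thresholds.functional_q,
            rho_threshold=config.thresholds.functional_rho,
        )
        return dmp_age, dmp_accel, dmp_class, functional

    dmp_age, dmp_accel, dmp_class, functional = assoc_stage
    for name, df in (
        ("dmp_age", dmp_age), ("dmp_accel", dmp_accel), ("dmp_classification", dmp_class),
    ):
        _fmt(df[df["is_dmp"]], outdir / f"{name}.tsv")
    _fmt(functional, outdir / "functional_cpgs.tsv")

    sets = {
        "age": set(dmp_age.index[dmp_age["is_dmp"]]),
        "accel": set(dmp_accel.index[dmp_accel["is_dmp"]]),
        "classification": set(dmp_class.index[dmp_class["is_dmp"]]),
    }
    venn = {
        "age": len(sets["age"]),
        "accel": len(sets["accel"]),
        "classification": len(sets["classification"]),
        "age_and_accel": len(sets["age"] & sets["accel"]),
        "age_and_classification": len(sets["age"] & sets["classification"]),
        "accel_and_classification": len(sets["accel"] & sets["classification"]),
        "all_three": len(sets["age"] & sets["accel"] & sets["classification"]),
    }

    # ---- gene-set enrichment (synthetic collections from the manifest) ---
    @stage("gsea")
    def gsea_stage():
        ann = cohort.annotation.table
        universe = sorted(set(ann.loc[ann["gene"] != "", "gene"]))
        rng = np.random.default_rng(config.seed + 1)
        gene_sets = {
            f"SET_{i:02d}": set(rng.choice(universe, size=min(25, len(universe)), replace=False))
            for i in range(10)
        }
        accel_genes = sorted(
            set(ann.loc[ann.index.isin(sets["accel"]) & (ann["gene"] != ""), "gene"])
        )
        # one planted set built from the accelerated genes, if any
        if accel_genes:
            gene_sets["SET_ACCEL"] = set(accel_genes[:25])
        return association.hypergeom_gsea(
            accel_genes, gene_sets, universe, alpha=config.thresholds.gsea_alpha
        )

    gsea = gsea_stage
    _fmt(gsea, outdir / "gsea.tsv")

    # ---- entropy / metric statistics ------------------------------------
    @stage("stats")
    def stats_stage():
        wald_rows = []
        metrics = {
            "age": samples["age"],
            "dnam_age": dnam_age,
            "acceleration": accel,
            "purity": purity,
            "global_hme": etab.global_hme,
            "hme_promoter_island": etab.by_stratum["Island.promoter"],
        }
        two_way_ok = (
            samples["batch"].nunique() > 1
            and subtype_calls.nunique() > 1
            and not (subtype_calls.astype(str) + samples["batch"]).value_counts().lt(2).any()
        )
        for name, y in metrics.items():
            if y.isna().any():
                continue
            if two_way_ok:
                tab = stats_outcome.two_way_wald_table(
                    y, subtype_calls, samples["batch"], names=("Class", "Batch")
                )
                for term, row in tab.iterrows():
                    wald_rows.append((name, term, row["F"], row["Pr(>F)"]))
        wald = pd.DataFrame(
            wald_rows, columns=["metric", "term", "F", "Pr(>F)"]
        ).set_index(["metric", "term"])

        hme_cols = etab.by_stratum.dropna(axis=1)
        varpart = stats_outcome.variation_partition(
            hme_cols.assign(global_hme=etab.global_hme),
            samples["age"],
            accel,
            subtype_calls.astype(object),
            labels=("age", "acceleration", "classification"),
        )

        ad = (
            stats_outcome.adonis(
                hme_cols.to_numpy(), subtype_calls.to_numpy(), n_perm=99,
                seed=config.seed,
            )
            if subtype_calls.nunique() > 1
            else None
        )

        cox = None
        if samples["event"].sum() >= 10 and samples["treatment"].nunique() > 1:
            cox = stats_outcome.cox_interaction_fit(
                samples["survival_time"],
                samples["event"],
                samples["treatment"],
                (samples["mgmt_status"] == "M").astype(int),
                accel,
                covariate_name="acceleration",
            )
        return wald, varpart, ad, cox

    wald_table, varpart, adonis_res, cox_fit = stats_stage
    _fmt(wald_table, outdir / "wald_table.tsv")
    if cox_fit is not None:
        _fmt(cox_fit.summary, outdir / "cox_table.tsv")

    report = {
        "n_samples": int(cohort.betas.n_samples),
        "n_probes_input": filter_report.n_input,
        "n_probes_retained": filter_report.n_retained,
        "mean_acceleration": float(accel.mean()) if len(accel) else float("nan"),
        "dmp_counts": {k: len(v) for k, v in sets.items()},
        "venn": venn,
        "n_functional": int(functional["is_functional"].sum()) if len(functional) else 0,
        "mgmt_methylated": int((mgmt_calls["status"] == "M").sum()),
        "adonis": (
            {"r2": adonis_res.r2, "p": adonis_res.p} if adonis_res is not None else None
        ),
        "varpart": {k: float(v) for k, v in varpart.fractions.items()},
        "cox": (
            {t: {"HR": float(cox_fit.summary.loc[t, "HR"]),
                 "p": float(cox_fit.summary.loc[t, "p"])}
             for t in cox_fit.summary.index}
            if cox_fit is not None
            else None
        ),
        "thresholds": dataclasses.asdict(config.thresholds),
        "seed": config.seed,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_log(log, outdir)
    return report


def _write_log(log: list, outdir: Path) -> None:
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
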