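"""Orchestration of the full workflow under one config, with stage TSV outputs.

Order of operations: instrument selection (cis-restricted when a gene region is
configured) -> weak-instrument filtering -> harmonization -> estimation (Wald
ratio when a single instrument remains, otherwise the full suite with
fixed-effects IVW primary) -> sensitivity diagnostics -> MR-PRESSO outlier
removal and re-estimation -> random-effects fallback when heterogeneity
persists (Q p < 0.05 after outlier removal) -> optional two-step mediation.
Every stage writes a TSV under the output directory and appends to a
line-oriented run log; the summary table is assembled from the stage outputs,
never recomputed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import estimators, sensitivity
from .estimators import DEFAULT_SEED, MREstimate
from .instruments import (
    HarmonizedSet,
    InstrumentSet,
    LDMatrix,
    filter_weak,
    harmonize,
    select_cis_instruments,
    select_instruments,
)
from .mediation import MediationResult, TwoStepConfig, run_two_step
from .summary_io import read_panel

ESTIMATE_COLUMNS = [
    "method",
    "k",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "or",
    "or_low",
    "or_high",
    "intercept",
    "intercept_p",
]

MEDIATION_COLUMNS = [
    "mediator",
    "a",
    "se_a",
    "p_a",
    "b",
    "se_b",
    "p_b",
    "c",
    "se_c",
    "indirect",
    "indirect_low",
    "indirect_high",
    "direct",
    "proportion",
    "proportion_low",
    "proportion_high",
    "flags",
]


@dataclass
class RunConfig:
    """Paths, thresholds, and policy for one pipeline run."""

    exposure: str
    outcome: str
    out_dir: str
    mediators: list[str] = field(default_factory=list)
    mediator_sources: Optional[list[str]] = None
    ld: Optional[str] = None
    eqtl: Optional[str] = None
    gene_region: Optional[tuple[str, int, int]] = None  # cis selection when set
    flank_kb: float = 100.0
    binary_outcome: bool = False
    p_thresh: float = 1e-5
    window_kb: float = 10_000.0
    r2_max: float = 0.001
    f_min: float = 10.0
    alpha: float = 0.05
    presso_nsim: int = 1000
    n_boot: int = 1000
    seed: int = DEFAULT_SEED
    exclude_exposure_snps: bool = True

    def __post_init__(self) -> None:
        for name in ("p_thresh", "window_kb", "r2_max", "f_min", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "gene_region" in data and data["gene_region"] is not None:
            data["gene_region"] = tuple(data["gene_region"])
        return cls(**data)


def estimates_table(ests: list[MREstimate]) -> pd.DataFrame:
    rows = []
    for e in ests:
        orr = e.or_scale or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "method": e.method,
                "k": e.k,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pvalue": e.pvalue,
                "or": orr[0],
                "or_low": orr[1],
                "or_high": orr[2],
                "intercept": np.nan if e.intercept is None else e.intercept,
                "intercept_p": np.nan if e.intercept_p is None else e.intercept_p,
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "mediator": r.mediator,
                "a": r.a,
                "se_a": r.se_a,
                "p_a": r.p_a,
                "b": r.b,
                "se_b": r.se_b,
                "p_b": r.p_b,
                "c": r.c,
                "se_c": r.se_c,
                "indirect": r.indirect,
                "indirect_low": r.indirect_ci[0],
                "indirect_high": r.indirect_ci[1],
                "direct": r.direct,
                "proportion": r.proportion,
                "proportion_low": r.proportion_ci[0],
                "proportion_high": r.proportion_ci[1],
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=MEDIATION_COLUMNS)


def write_instruments(iset: InstrumentSet, path) -> None:
    iset.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_instruments(path, exposure_name: str = "exposure") -> InstrumentSet:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.array(df["pos"], dtype="Int64")
    if "f_stat" not in df.columns:
        df["f_stat"] = (df["beta"] / df["se"]) ** 2
    return InstrumentSet(exposure_name, df)


def write_harmonized(hset: HarmonizedSet, path) -> None:
    hset.to_frame().to_csv(path, sep="\t", index=False)


def read_harmonized(path, outcome_type: str = "quantitative") -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t")
    return HarmonizedSet.from_frame(df, outcome_type=outcome_type)


class _RunLog:
    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def __call__(self, stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with self.path.open("a") as fh:
            fh.write(f"{stamp}\t{stage}\t{message}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a report dict of outputs and the primary estimate."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")

    exposure_panel, exp_report = read_panel(config.exposure, trait_name="exposure")
    outcome_type = "binary" if config.binary_outcome else "quantitative"
    outcome_panel, out_report = read_panel(
        config.outcome, trait_name="outcome", trait_type=outcome_type
    )
    log("read", f"exposure: {exp_report.n_kept} kept, {exp_report.n_dropped} dropped")
    log("read", f"outcome: {out_report.n_kept} kept, {out_report.n_dropped} dropped")
    ld = LDMatrix.read(config.ld) if config.ld else None

    if config.gene_region is not None:
        eqtl_panel = None
        if config.eqtl:
            eqtl_panel, _ = read_panel(config.eqtl, trait_name="eqtl")
        iset = select_cis_instruments(
            exposure_panel,
            config.gene_region,
            flank_kb=config.flank_kb,
            eqtl=eqtl_panel,
            p_thresh=config.p_thresh,
            ld=ld,
            window_kb=config.window_kb,
            r2_max=config.r2_max,
        )
    else:
        iset = select_instruments(
            exposure_panel, config.p_thresh, ld, config.window_kb, config.r2_max
        )
    iset = filter_weak(iset, config.f_min)
    write_instruments(iset, out / "instruments.tsv")
    log("instruments", f"{iset.k} instruments retained")
    if iset.is_empty:
        raise RuntimeError("stage instruments: no instruments retained")

    hset = harmonize(iset, outcome_panel)
    write_harmonized(hset, out / "harmonized.tsv")
    log(
        "harmonize",
        f"{hset.k} SNPs harmonized, {len(hset.removed_palindromic)} palindromic removed",
    )
    if hset.k == 0:
        raise RuntimeError("stage harmonize: no SNPs left after harmonization")

    ests = estimators.estimate_suite(hset, n_boot=config.n_boot, seed=config.seed)
    estimates_table(ests).to_csv(out / "estimates.tsv", sep="\t", index=False, na_rep="NA")
    log("estimate", f"{len(ests)} estimator(s) on k={hset.k}")

    final_set = hset
    removed_outliers: list[str] = []
    q_p = None
    if hset.k >= 2:
        report = sensitivity.sensitivity_report(
            hset, n_sim=config.presso_nsim, seed=config.seed
        )
        q_p = report.q_p
        sens_row = {
            "q": report.q,
            "q_df": report.q_df,
            "q_p": report.q_p,
            "egger_intercept": report.egger_intercept,
            "egger_intercept_se": report.egger_intercept_se,
            "egger_intercept_p": report.egger_intercept_p,
            "presso_global_p": report.presso.global_p if report.presso else np.nan,
            "presso_outliers": ";".join(report.presso.outliers) if report.presso else "",
        }
        pd.DataFrame([sens_row]).to_csv(
            out / "sensitivity.tsv", sep="\t", index=False, na_rep="NA"
        )
        report.funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
        if report.loo is not None:
            report.loo.to_csv(out / "loo.tsv", sep="\t", index=False)
        log("sensitivity", f"Q={report.q:.4g} (p={report.q_p:.3g})")

        if report.presso and report.presso.outliers:
            removed_outliers = report.presso.outliers
            keep = [i for i, s in enumerate(hset.snp_ids) if s not in removed_outliers]
            final_set = hset.subset(keep)
            log(
                "presso",
                f"removed outliers: {', '.join(removed_outliers)}; re-estimating on k={final_set.k}",
            )
            ests = estimators.estimate_suite(
                final_set, n_boot=config.n_boot, seed=config.seed
            )
            estimates_table(ests).to_csv(
                out / "estimates_outlier_corrected.tsv", sep="\t", index=False, na_rep="NA"
            )
            if final_set.k >= 2:
                q, q_df, q_p = sensitivity.cochran_q(final_set)
                log("presso", f"post-removal Q={q:.4g} (p={q_p:.3g})")

    primary_method = "wald_ratio" if final_set.k == 1 else "ivw_fixed"
    if final_set.k >= 2 and q_p is not None and q_p < 0.05:
        primary_method = "ivw_random"
        log("policy", "heterogeneity persists (Q p < 0.05): primary switched to ivw_random")
    by_method = {e.method: e for e in ests}
    primary = by_method[primary_method]

    summary = estimates_table(ests)
    summary.insert(0, "exposure", exposure_panel.trait_name)
    summary.insert(1, "outcome", outcome_panel.trait_name)
    summary["primary"] = summary["method"] == primary_method
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, na_rep="NA")
    log("summary", f"primary method {primary_method}: beta={primary.beta:.6g}")

    n_mediation = 0
    if config.mediators:
        med_panels = []
        for p in config.mediators:
            panel, _ = read_panel(p, trait_name=Path(p).stem)
            med_panels.append(panel)
        sources = None
        if config.mediator_sources:
            sources = []
            for p in config.mediator_sources:
                panel, _ = read_panel(p, trait_name=Path(p).stem)
                sources.append(panel)
        results = run_two_step(
            iset,
            med_panels,
            outcome_panel,
            TwoStepConfig(
                p_thresh=config.p_thresh,
                window_kb=config.window_kb,
                r2_max=config.r2_max,
                f_min=config.f_min,
                alpha=config.alpha,
                seed=config.seed,
                exclude_exposure_snps=config.exclude_exposure_snps,
                ld=ld,
            ),
            mediator_instrument_sources=sources,
        )
        mediation_table(results).to_csv(out / "mediation.tsv", sep="\t", index=False)
        n_mediation = len(results)
        log("mediation", f"{len(med_panels)} mediator(s) tested, {n_mediation} result(s)")

    log("done", "pipeline complete")
    return {
        "out_dir": str(out),
        "k": final_set.k,
        "primary_method": primary_method,
        "primary_beta": primary.beta,
        "primary_ci": (primary.ci_low, primary.ci_high),
        "primary_p": primary.pvalue,
        "removed_outliers": removed_outliers,
        "n_mediation_results": n_mediation,
    }
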