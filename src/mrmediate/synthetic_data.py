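"""Three-trait GWAS summary-statistic simulator with known causal structure.

The generator emulates the two-sample setting: per-SNP true exposure effects
gamma_j; a mediator receiving a·gamma_j through the exposure plus its own
instruments delta_j; and an outcome receiving (c' + a·b)·gamma_j through the
exposure SNPs, b·delta_j through the mediator SNPs, and optional pleiotropic
offsets alpha_j on invalid SNPs (added to the outcome only, so the InSIDE
condition holds by construction). Observed betas are drawn independently per
trait around the truth with the standard summary-statistic approximation
se = 1/sqrt(2·maf·(1-maf)·n). Default sample sizes follow the study design
the pipeline targets: a large biobank exposure GWAS (n_x = 344,182), a
metabolome cohort (n_m = 8,299), and an imaging/outcome GWAS of 1e5.

SNPs are placed 20 Mb apart round-robin across 22 chromosomes so that
distance-only clumping at the default 10,000-kb window keeps independent
instruments; LD itself is not simulated (clumping with LD is exercised by
hand-built fixtures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet
from .summary_io import PANEL_COLUMNS, SummaryPanel, write_panel

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generating parameters; a fixed seed makes the output bit-reproducible."""

    k_x: int = 10  # exposure instrument count (drug-target scale)
    k_m: int = 20  # per-mediator instrument count
    n_x: float = 344_182.0  # exposure GWAS sample size
    n_m: float = 8_299.0  # mediator GWAS sample size
    n_y: float = 100_000.0  # outcome GWAS sample size
    a: float = -0.4  # exposure -> mediator
    b: float = 1.0  # mediator -> outcome
    c_prime: float = -0.9  # direct exposure -> outcome
    theta: Optional[float] = None  # total effect override (purely direct scenario)
    fraction_invalid: float = 0.0
    mean_alpha: float = 0.0
    sd_alpha: float = 0.0
    alpha_se_scaled: bool = False  # pleiotropic offsets in units of the SNP's outcome SE
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_rate: float = 0.1
    n_true_mediators: int = 1
    n_null_mediators: int = 9
    gamma_range: tuple[float, float] = (0.05, 0.15)
    delta_range: tuple[float, float] = (0.05, 0.15)
    weak_fraction: float = 0.0  # fraction of exposure SNPs given near-null gamma
    noiseless: bool = False  # n -> infinity limit (observed = true, se floor 1e-8)
    outcome_type: str = "quantitative"
    seed: int = 20240507

    def __post_init__(self) -> None:
        for name in ("fraction_invalid", "palindromic_rate", "weak_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_x, self.n_m, self.n_y) <= 0:
            raise ValueError("sample sizes must be > 0")
        if self.k_x < 1:
            raise ValueError("k_x must be >= 1")


@dataclass
class SimulationTruth:
    a: float
    b: float
    c_prime: float
    c: float  # total exposure -> outcome effect
    proportion: Optional[float]  # a*b / c; None when theta overrides the pathway
    exposure_snp_ids: list[str]
    mediator_snp_ids: dict[str, list[str]]
    invalid_snp_ids: list[str]
    gamma: dict[str, float]


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    panels: dict[str, SummaryPanel]
    truth: SimulationTruth

    @property
    def mediator_names(self) -> list[str]:
        return [n for n in self.panels if n not in ("exposure", "outcome")]

    def exposure_instruments(self) -> InstrumentSet:
        """The true exposure SNPs as an instrument set (F computed from observed data)."""
        panel = self.panels["exposure"]
        df = panel.df[panel.df["snp_id"].isin(self.truth.exposure_snp_ids)].copy()
        df = df.reset_index(drop=True)
        df["f_stat"] = (df["beta"] / df["se"]) ** 2
        return InstrumentSet(panel.trait_name, df, [(s, "kept", "simulated instrument") for s in df["snp_id"]])


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _panel_from_arrays(name, trait_type, ids, chrom, pos, ea, oa, eaf, beta, se):
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), 5e-324)
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": pd.array(pos, dtype="Int64"),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": np.nan,
        }
    )[list(PANEL_COLUMNS)]
    return SummaryPanel(name, trait_type, df)


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Draw one simulated study (exposure, mediators, outcome) under the config."""
    rng = np.random.default_rng(config.seed)
    n_med = config.n_true_mediators + config.n_null_mediators
    total = config.k_x + n_med * config.k_m

    ids = [f"rs{i + 1:06d}" for i in range(total)]
    chrom = [str((i % 22) + 1) for i in range(total)]
    pos = [(i // 22 + 1) * 20_000_000 for i in range(total)]
    pal = rng.random(total) < config.palindromic_rate
    pair_idx = rng.integers(0, 4, total)
    np_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), total)
    ea, oa = [], []
    for i in range(total):
        p = _PALINDROMIC_PAIRS[pair_idx[i]] if pal[i] else _NONPALINDROMIC_PAIRS[np_idx[i]]
        ea.append(p[0])
        oa.append(p[1])
    maf = rng.uniform(*config.maf_range, total)
    eaf = np.where(rng.random(total) < 0.5, maf, 1.0 - maf)

    # True per-SNP effects on each trait.
    gamma = np.zeros(total)
    gamma[: config.k_x] = rng.uniform(*config.gamma_range, config.k_x)
    if config.weak_fraction > 0:
        n_weak = int(round(config.weak_fraction * config.k_x))
        weak = rng.choice(config.k_x, n_weak, replace=False)
        gamma[weak] = rng.uniform(0.001, 0.01, n_weak)

    med_slices: dict[str, slice] = {}
    med_names = [f"mediator_{i + 1}" for i in range(config.n_true_mediators)] + [
        f"null_mediator_{i + 1}" for i in range(config.n_null_mediators)
    ]
    offset = config.k_x
    delta = np.zeros(total)
    for name in med_names:
        sl = slice(offset, offset + config.k_m)
        med_slices[name] = sl
        delta[sl] = rng.uniform(*config.delta_range, config.k_m)
        offset += config.k_m

    se_x = _se(maf, config.n_x)
    se_m = _se(maf, config.n_m)
    se_y = _se(maf, config.n_y)

    if config.theta is not None:
        c_total = config.theta
        proportion = None
    else:
        c_total = config.c_prime + config.a * config.b
        proportion = (config.a * config.b / c_total) if c_total != 0 else None

    true_y = np.zeros(total)
    true_y[: config.k_x] = c_total * gamma[: config.k_x]
    for name in med_names:
        if name.startswith("mediator_"):
            true_y[med_slices[name]] = config.b * delta[med_slices[name]]

    n_invalid = int(round(config.fraction_invalid * config.k_x))
    invalid_idx = (
        rng.choice(config.k_x, n_invalid, replace=False) if n_invalid else np.array([], int)
    )
    if n_invalid:
        alpha = rng.normal(config.mean_alpha, config.sd_alpha, n_invalid)
        if config.alpha_se_scaled:
            alpha = alpha * se_y[invalid_idx]
        true_y[invalid_idx] += alpha

    def observe(true, se):
        if config.noiseless:
            return true.copy(), np.full_like(se, 1e-8)
        return rng.normal(true, se), se

    obs_x, rep_x = observe(gamma, se_x)
    obs_y, rep_y = observe(true_y, se_y)

    panels = {
        "exposure": _panel_from_arrays(
            "exposure", "quantitative", ids, chrom, pos, ea, oa, eaf, obs_x, rep_x
        )
    }
    for name in med_names:
        true_m = delta.copy() * 0.0
        true_m[med_slices[name]] = delta[med_slices[name]]
        if name.startswith("mediator_"):
            true_m[: config.k_x] = config.a * gamma[: config.k_x]
        obs_m, rep_m = observe(true_m, se_m)
        panels[name] = _panel_from_arrays(
            name, "quantitative", ids, chrom, pos, ea, oa, eaf, obs_m, rep_m
        )
    panels["outcome"] = _panel_from_arrays(
        "outcome", config.outcome_type, ids, chrom, pos, ea, oa, eaf, obs_y, rep_y
    )

    truth = SimulationTruth(
        a=config.a if config.theta is None else 0.0,
        b=config.b,
        c_prime=config.c_prime if config.theta is None else config.theta,
        c=c_total,
        proportion=proportion,
        exposure_snp_ids=ids[: config.k_x],
        mediator_snp_ids={n: ids[med_slices[n]] for n in med_names},
        invalid_snp_ids=[ids[i] for i in sorted(invalid_idx)],
        gamma={ids[i]: float(gamma[i]) for i in range(config.k_x)},
    )
    return SimulatedStudy(config=config, panels=panels, truth=truth)


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Write every panel as TSV plus a truth.json record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, panel in study.panels.items():
        write_panel(panel, out / f"{name}.tsv")
    t = study.truth
    (out / "truth.json").write_text(
        json.dumps(
            {
                "a": t.a,
                "b": t.b,
                "c_prime": t.c_prime,
                "c": t.c,
                "proportion": t.proportion,
                "exposure_snp_ids": t.exposure_snp_ids,
                "mediator_snp_ids": t.mediator_snp_ids,
                "invalid_snp_ids": t.invalid_snp_ids,
                "gamma": t.gamma,
            },
            indent=2,
        )
    )


def make_fixtures(out_dir) -> None:
    """Write the small deterministic fixtures shared across module tests.

    - a 6-SNP clumping panel with an LD matrix (greedy result known by hand),
    - a 3-SNP exact-ratio panel pair (every per-SNP ratio exactly 0.2),
    - a 20-SNP planted-outlier panel pair (one SNP offset by 10 outcome SEs),
    - a noiseless mediation triple (a=0.5, b=0.6, c'=0.7, proportion 0.30),
    plus a README listing the expected values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 6-SNP clumping fixture: all on chrom 1 within one window.
    ids = [f"rs{i}" for i in range(1, 7)]
    pvals = [1e-8, 1e-6, 1e-7, 1e-9, 1e-5 / 2, 1e-10]
    z = stats.norm.isf(np.array(pvals) / 2)
    se = np.full(6, 0.01)
    beta = z * se
    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": "1",
            "pos": pd.array([1_000_000 + 50_000 * i for i in range(6)], dtype="Int64"),
            "effect_allele": ["A", "A", "G", "C", "T", "G"],
            "other_allele": ["G", "C", "A", "T", "C", "T"],
            "eaf": 0.3,
            "beta": beta,
            "se": se,
            "pvalue": pvals,
            "n": np.nan,
        }
    )
    write_panel(SummaryPanel("clump_fixture", "quantitative", df), out / "clump_panel.tsv")
    r2 = np.eye(6)
    links = {(0, 1): 0.5, (0, 2): 0.0005, (3, 4): 0.9, (5, 1): 0.3, (2, 4): 0.002}
    for (i, j), v in links.items():
        r2[i, j] = r2[j, i] = v
    ld = pd.DataFrame(r2, columns=ids)
    ld.insert(0, "snp_id", ids)
    ld.to_csv(out / "clump_ld.tsv", sep="\t", index=False)

    # 3-SNP exact-IVW pair: theta_j = 0.2 for every SNP.
    def _tiny_panel(name, betas, ses):
        d = pd.DataFrame(
            {
                "snp_id": ["rs101", "rs102", "rs103"],
                "chrom": "2",
                "pos": pd.array([1_000_000, 30_000_000, 60_000_000], dtype="Int64"),
                "effect_allele": ["A", "C", "G"],
                "other_allele": ["G", "T", "A"],
                "eaf": 0.4,
                "beta": betas,
                "se": ses,
                "pvalue": np.maximum(
                    2 * stats.norm.sf(np.abs(np.array(betas) / np.array(ses))), 5e-324
                ),
                "n": np.nan,
            }
        )
        return SummaryPanel(name, "quantitative", d)

    write_panel(_tiny_panel("exposure", [0.3, 0.4, 0.5], [0.01] * 3), out / "ivw_exact_exposure.tsv")
    write_panel(_tiny_panel("outcome", [0.06, 0.08, 0.10], [0.01] * 3), out / "ivw_exact_outcome.tsv")

    # Planted-outlier study: 19 clean SNPs + 1 with a 10-SE pleiotropic offset.
    study = simulate(
        SimulationConfig(
            k_x=20,
            n_true_mediators=0,
            n_null_mediators=0,
            k_m=0,
            theta=0.5,
            fraction_invalid=1 / 20,
            mean_alpha=10.0,
            sd_alpha=0.0,
            alpha_se_scaled=True,
            palindromic_rate=0.0,
            seed=7,
        )
    )
    write_panel(study.panels["exposure"], out / "outlier_exposure.tsv")
    write_panel(study.panels["outcome"], out / "outlier_outcome.tsv")
    (out / "outlier_truth.json").write_text(
        json.dumps({"theta": 0.5, "invalid_snp_ids": study.truth.invalid_snp_ids})
    )

    # Noiseless mediation triple: a=0.5, b=0.6, c'=0.7 -> c=1.0, proportion 0.30.
    med = simulate(
        SimulationConfig(
            a=0.5,
            b=0.6,
            c_prime=0.7,
            n_true_mediators=1,
            n_null_mediators=0,
            noiseless=True,
            palindromic_rate=0.0,
            seed=11,
        )
    )
    for name in ("exposure", "mediator_1", "outcome"):
        write_panel(med.panels[name], out / f"mediation_{name}.tsv")

    (out / "README.md").write_text(
        "# Test fixtures (deterministically regenerated)\n\n"
        "- clump_panel.tsv + clump_ld.tsv: 6 SNPs, all inside one 10,000-kb window.\n"
        "  Greedy clumping at r2 < 0.001 visits rs6 (p=1e-10), rs4 (1e-9), rs1\n"
        "  (1e-8), rs3 (1e-7), rs2 (1e-6), rs5 (5e-6) in that order and retains\n"
        "  {rs6, rs4, rs1, rs3}: rs2 falls to r2=0.3 with rs6, rs5 to r2=0.9 with\n"
        "  rs4. The unit tests re-derive this with a brute-force oracle.\n"
        "- ivw_exact_*.tsv: every per-SNP ratio equals 0.2, so IVW = 0.2 exactly and\n"
        "  Cochran's Q = 0.\n"
        "- outlier_*.tsv: true slope 0.5; the SNP listed in outlier_truth.json has a\n"
        "  pleiotropic offset of 10 outcome SEs and should be flagged by MR-PRESSO.\n"
        "- mediation_*.tsv: noiseless panels with a=0.5, b=0.6, c'=0.7; the mediated\n"
        "  proportion is exactly 0.30.\n"
    )
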