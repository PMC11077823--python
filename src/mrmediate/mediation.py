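"""Two-step MR mediation: screening, decomposition, and delta-method CIs.

Step 1 estimates the exposure's effect on each candidate mediator (a) and
screens with a Bonferroni threshold over all mediators tested. Step 2 selects
each passing mediator's own instruments, estimates its effect on the outcome
(b), and applies a second Bonferroni screen over the step-2 tests. The total
exposure->outcome effect c decomposes into an indirect effect a·b and a direct
effect c' = c - a·b; the proportion mediated is a·b/c. Standard errors for the
product and the ratio come from first-order delta expansions assuming zero
covariance between a-hat, b-hat, and c-hat (non-overlapping two-sample steps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import DEFAULT_SEED, MREstimate, Z975, ivw, wald_ratio
from .instruments import (
    HarmonizedSet,
    InstrumentSet,
    LDMatrix,
    filter_weak,
    harmonize,
    select_instruments,
)
from .summary_io import SummaryPanel


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (e.g. 0.05/1400 = 3.57e-5)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


@dataclass
class ScreenResult:
    n_tested: int
    alpha_family: float
    threshold: float
    passing: list[tuple[str, float, float]]  # (mediator, estimate, p)


def screen_mediators(
    step1: Sequence[tuple[str, MREstimate]], alpha: float = 0.05
) -> ScreenResult:
    """Bonferroni screen of step-1 exposure->mediator estimates."""
    if not step1:
        raise ValueError("no mediators to screen")
    thresh = bonferroni_threshold(alpha, len(step1))
    passing = [
        (name, est.beta, est.pvalue) for name, est in step1 if est.pvalue < thresh
    ]
    return ScreenResult(len(step1), alpha, thresh, passing)


@dataclass
class MediationResult:
    """Decomposition of a total effect through one mediator.

    indirect + direct = c holds exactly by construction, as does
    proportion = indirect/c.
    """

    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float
    se_indirect: float
    indirect_ci: tuple[float, float]
    p_indirect: float
    direct: float
    proportion: float
    se_proportion: float
    proportion_ci: tuple[float, float]
    p_a: Optional[float] = None
    p_b: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def mediate(
    a_est: MREstimate,
    b_est: MREstimate,
    c_est: MREstimate,
    include_c_uncertainty: bool = True,
    exposure: str = "",
    mediator: str = "",
    outcome: str = "",
) -> MediationResult:
    """Decompose total effect c into indirect a·b and direct c - a·b.

    se(a·b) = sqrt(a²·se_b² + b²·se_a²) (first-order delta, zero covariance).
    The proportion mediated a·b/c gets, when include_c_uncertainty is set
    (default), the full first-order delta SE
    sqrt(se_indirect²/c² + indirect²·se_c²/c⁴); otherwise c is treated as
    fixed and the SE is se_indirect/|c|. |proportion| > 1 is allowed but
    flagged as inconsistent mediation. All effects must share the additive
    (trait-unit or log-odds) scale.
    """
    a, se_a = a_est.beta, a_est.se
    b, se_b = b_est.beta, b_est.se
    c, se_c = c_est.beta, c_est.se
    if c == 0:
        raise ValueError("total effect c = 0: proportion mediated undefined")
    indirect = a * b
    se_ind = math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    if se_ind == 0:
        p_ind = 1.0 if indirect == 0 else 0.0
    else:
        p_ind = float(max(2.0 * stats.norm.sf(abs(indirect / se_ind)), 5e-324))
    direct = c - indirect
    proportion = indirect / c
    if include_c_uncertainty:
        se_prop = math.sqrt(se_ind**2 / c**2 + indirect**2 * se_c**2 / c**4)
    else:
        se_prop = se_ind / abs(c)
    flags = []
    if abs(proportion) > 1:
        flags.append("inconsistent_mediation")
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        a=a,
        se_a=se_a,
        b=b,
        se_b=se_b,
        c=c,
        se_c=se_c,
        indirect=indirect,
        se_indirect=se_ind,
        indirect_ci=(indirect - Z975 * se_ind, indirect + Z975 * se_ind),
        p_indirect=p_ind,
        direct=direct,
        proportion=proportion,
        se_proportion=se_prop,
        proportion_ci=(proportion - Z975 * se_prop, proportion + Z975 * se_prop),
        p_a=a_est.pvalue,
        p_b=b_est.pvalue,
        flags=flags,
    )


@dataclass
class TwoStepConfig:
    """Thresholds and policy for the two-step mediation pipeline."""

    p_thresh: float = 1e-5
    window_kb: float = 10_000.0
    r2_max: float = 0.001
    f_min: float = 10.0
    alpha: float = 0.05
    seed: int = DEFAULT_SEED
    include_c_uncertainty: bool = True
    # Mediator-instrument hygiene: drop the exposure's own instrument SNPs
    # and/or a genomic region (chrom, start, end, flank_kb) from step-2 selection.
    exclude_exposure_snps: bool = True
    exclude_region: Optional[tuple[str, int, int, float]] = None
    ld: Optional[LDMatrix] = None


def _estimate(hset: HarmonizedSet) -> Optional[MREstimate]:
    if hset.k == 0:
        return None
    return wald_ratio(hset) if hset.k == 1 else ivw(hset, "fixed")


def run_two_step(
    exposure_instruments: InstrumentSet,
    mediator_panels: Sequence[SummaryPanel],
    outcome_panel: SummaryPanel,
    config: Optional[TwoStepConfig] = None,
    mediator_instrument_sources: Optional[Sequence[SummaryPanel]] = None,
) -> list[MediationResult]:
    """Full two-step mediation over a set of candidate mediators.

    Step 1: harmonize the exposure instruments against every mediator panel and
    estimate a (IVW-fixed, or Wald when one SNP survives); Bonferroni-screen
    over all mediators tested. Step 2: for each passing mediator, select its own
    instruments from its instrument-source panel (same significance/clumping/
    strength rules, minus excluded SNPs), harmonize against the outcome and
    estimate b; a second Bonferroni screen over the step-2 tests sets the
    'step2_significant' flag. The total effect c comes from the exposure
    instruments against the outcome. Mediators without valid instruments are
    skipped with a warning. Returns one MediationResult per step-1-passing
    mediator.
    """
    cfg = config or TwoStepConfig()
    sources = (
        list(mediator_instrument_sources)
        if mediator_instrument_sources is not None
        else list(mediator_panels)
    )
    if len(sources) != len(mediator_panels):
        raise ValueError("one instrument source per mediator panel required")

    c_est = _estimate(harmonize(exposure_instruments, outcome_panel))
    if c_est is None:
        raise ValueError("no usable SNPs for the total exposure->outcome effect")

    step1: list[tuple[str, MREstimate]] = []
    for panel in mediator_panels:
        a_est = _estimate(harmonize(exposure_instruments, panel))
        if a_est is None:
            warnings.warn(f"mediator {panel.trait_name!r}: no harmonizable SNPs for step 1")
            continue
        step1.append((panel.trait_name, a_est))
    if not step1:
        return []
    screen = screen_mediators(step1, cfg.alpha)
    passing_names = {name for name, _, _ in screen.passing}
    a_by_name = dict(step1)
    source_by_name = {p.trait_name: s for p, s in zip(mediator_panels, sources)}

    step2: list[tuple[str, MREstimate]] = []
    for name in [n for n, _ in step1 if n in passing_names]:
        source = source_by_name[name]
        df = source.df
        mask = np.ones(len(df), dtype=bool)
        if cfg.exclude_exposure_snps:
            mask &= ~df["snp_id"].isin(exposure_instruments.snp_ids).to_numpy()
        if cfg.exclude_region is not None:
            chrom, start, end, flank_kb = cfg.exclude_region
            lo, hi = start - flank_kb * 1000.0, end + flank_kb * 1000.0
            pos = df["pos"].astype(float).to_numpy()
            in_region = (
                (df["chrom"].astype(str) == str(chrom)).to_numpy()
                & np.isfinite(pos)
                & (pos >= lo)
                & (pos <= hi)
            )
            mask &= ~in_region
        reduced = SummaryPanel(source.trait_name, source.trait_type, df[mask].reset_index(drop=True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iset = filter_weak(
                select_instruments(reduced, cfg.p_thresh, cfg.ld, cfg.window_kb, cfg.r2_max),
                cfg.f_min,
            )
        if iset.is_empty:
            warnings.warn(f"mediator {name!r}: no valid instruments; skipped")
            continue
        b_est = _estimate(harmonize(iset, outcome_panel))
        if b_est is None:
            warnings.warn(f"mediator {name!r}: no harmonizable SNPs for step 2; skipped")
            continue
        step2.append((name, b_est))

    results: list[MediationResult] = []
    if not step2:
        return results
    thresh2 = bonferroni_threshold(cfg.alpha, len(step2))
    for name, b_est in step2:
        res = mediate(
            a_by_name[name],
            b_est,
            c_est,
            include_c_uncertainty=cfg.include_c_uncertainty,
            exposure=exposure_instruments.exposure_name,
            mediator=name,
            outcome=outcome_panel.trait_name,
        )
        res.flags.append(
            "step2_significant" if b_est.pvalue < thresh2 else "step2_not_significant"
        )
        results.append(res)
    return results
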