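"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

- Cochran's Q over per-SNP ratios with IVW-fixed weights (chi-square, k-1 df).
- MR-Egger intercept test for average directional pleiotropy (t, k-2 df).
- MR-PRESSO: a simulation-based residual-sum-of-squares test. Each SNP's
  residual is measured against the leave-one-out IVW prediction; the observed
  RSS is compared with RSS values from parametric simulations under the fitted
  model, giving a global empirical p. Per-SNP empirical p-values flag outliers
  (Bonferroni over SNPs), and the IVW estimate is recomputed without them.
- Leave-one-out influence table and funnel-plot data for asymmetry inspection.

Empirical p-values use the (1 + exceedances)/(n_sim + 1) estimator so a
simulation never reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import DEFAULT_SEED, MREstimate, _ivw_core, egger, ivw, wald_ratio
from .instruments import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    n_sim: int
    outliers: list[str]
    corrected: Optional[MREstimate]
    seed: int
    outlier_p: dict[str, float] = field(default_factory=dict)


@dataclass
class SensitivityReport:
    q: float
    q_df: int
    q_p: float
    egger_intercept: Optional[float]
    egger_intercept_se: Optional[float]
    egger_intercept_p: Optional[float]
    presso: Optional[PressoResult]
    loo: Optional[pd.DataFrame]
    funnel: pd.DataFrame


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q = sum_j w_j (theta_j - theta_IVW)²; p from chi-square(k-1)."""
    if hset.k < 2:
        raise ValueError("cochran_q requires k >= 2 SNPs")
    _, _, q = _ivw_core(hset.beta_x, hset.beta_y, hset.se_y)
    df = hset.k - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """Egger intercept, its SE, and the two-sided t(k-2) p-value."""
    est = egger(hset)
    return est.intercept, est.intercept_se, est.intercept_p


def _loo_slopes(bx, by, sy):
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    num = bx * by / sy**2
    den = bx**2 / sy**2
    return (np.sum(num) - num) / (np.sum(den) - den)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = DEFAULT_SEED,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Global pleiotropy test and per-SNP outlier detection by simulation.

    Observed residuals d_j = beta_y_j - theta_(-j) * beta_x_j are weighted into
    RSS_obs = sum d_j²/se_y_j². n_sim parametric datasets are drawn with
    beta_y* ~ N(theta_(-j)·beta_x_j, se_y_j) and beta_x* ~ N(beta_x_j, se_x_j)
    and the same statistic recomputed. SNPs with per-SNP empirical p below
    outlier_alpha/k are declared outliers; when any are found the IVW-fixed
    estimate is recomputed without them.
    """
    k = hset.k
    if k < 4:
        raise ValueError("mr_presso requires k >= 4 SNPs (test unstable below)")
    bx, by, sy, sx = hset.beta_x, hset.beta_y, hset.se_y, hset.se_x
    theta_loo = _loo_slopes(bx, by, sy)
    d = by - theta_loo * bx
    rss_obs = float(np.sum(d**2 / sy**2))

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_sim, k))
    BY = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    num = BX * BY / sy**2
    den = BX**2 / sy**2
    theta_loo_sim = (num.sum(axis=1, keepdims=True) - num) / (
        den.sum(axis=1, keepdims=True) - den
    )
    D = BY - theta_loo_sim * BX
    rss_sim = np.sum(D**2 / sy**2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(D**2 >= d**2, axis=0)) / (n_sim + 1)
    thresh = outlier_alpha / k
    outlier_idx = np.flatnonzero(per_snp_p < thresh)
    outliers = [hset.snp_ids[i] for i in outlier_idx]

    corrected = None
    if len(outliers):
        keep = np.setdiff1d(np.arange(k), outlier_idx)
        reduced = hset.subset(keep)
        if reduced.k >= 2:
            corrected = ivw(reduced, "fixed")
        elif reduced.k == 1:
            corrected = wald_ratio(reduced)
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outliers=outliers,
        corrected=corrected,
        seed=seed,
        outlier_p={hset.snp_ids[i]: float(per_snp_p[i]) for i in range(k)},
    )


def leave_one_out(hset: HarmonizedSet) -> pd.DataFrame:
    """IVW-fixed estimate excluding each SNP in turn, with influence flags.

    Flags mark exclusions that change the sign of the estimate or move its
    p-value across 0.05 relative to the full-set estimate.
    """
    if hset.k < 3:
        raise ValueError("leave_one_out requires k >= 3 SNPs")
    full = ivw(hset, "fixed")
    rows = []
    for i in range(hset.k):
        keep = [j for j in range(hset.k) if j != i]
        est = ivw(hset.subset(keep), "fixed") if hset.k - 1 >= 2 else wald_ratio(
            hset.subset(keep)
        )
        rows.append(
            {
                "excluded_snp": hset.snp_ids[i],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "sign_change": np.sign(est.beta) != np.sign(full.beta),
                "p_crosses_0.05": (est.pvalue < 0.05) != (full.pvalue < 0.05),
            }
        )
    return pd.DataFrame(rows)


def funnel_data(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP (ratio, precision) pairs with IVW and Egger reference lines.

    Precision is 1/se of the per-SNP ratio (se_y/|beta_x|). Reference slopes
    are stored in DataFrame.attrs as 'ivw_beta' and (for k >= 3) 'egger_beta'.
    """
    if hset.k < 2:
        raise ValueError("funnel_data requires k >= 2 SNPs")
    theta = hset.beta_y / hset.beta_x
    se_theta = hset.se_y / np.abs(hset.beta_x)
    out = pd.DataFrame(
        {"snp_id": hset.snp_ids, "theta": theta, "precision": 1.0 / se_theta}
    )
    out.attrs["ivw_beta"] = ivw(hset, "fixed").beta
    if hset.k >= 3:
        out.attrs["egger_beta"] = egger(hset).beta
    return out


def sensitivity_report(
    hset: HarmonizedSet, n_sim: int = 1000, seed: int = DEFAULT_SEED
) -> SensitivityReport:
    """All diagnostics applicable to the set's size, bundled."""
    q, q_df, q_p = cochran_q(hset)
    if hset.k >= 3:
        intercept, i_se, i_p = egger_intercept_test(hset)
        loo = leave_one_out(hset)
    else:
        intercept = i_se = i_p = None
        loo = None
    presso = mr_presso(hset, n_sim=n_sim, seed=seed) if hset.k >= 4 else None
    return SensitivityReport(
        q=q,
        q_df=q_df,
        q_p=q_p,
        egger_intercept=intercept,
        egger_intercept_se=i_se,
        egger_intercept_p=i_p,
        presso=presso,
        loo=loo,
        funnel=funnel_data(hset),
    )
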