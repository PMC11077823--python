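"""Two-sample MR estimators over a harmonized SNP set.

Every estimator consumes per-SNP exposure effects (beta_x, se_x) and outcome
effects (beta_y, se_y) aligned to shared effect alleles and returns an
:class:`MREstimate`. The per-SNP ratio theta_j = beta_y_j / beta_x_j is the
basic quantity; estimators differ in how they pool the ratios:

- Wald ratio: the single-instrument case, first-order delta SE.
- IVW: inverse-variance weighted average with weights beta_x²/se_y²,
  equivalently weighted regression of beta_y on beta_x through the origin.
  Fixed-effects SE is (sum of weights)^{-1/2}; the multiplicative
  random-effects variant scales it by sqrt(max(1, Q/(k-1))).
- MR-Egger: weighted regression WITH an intercept after orienting all
  exposure effects positive; the intercept estimates average directional
  pleiotropy and the slope is a pleiotropy-adjusted causal effect. SEs carry a
  residual scale factor truncated below at 1 and p-values use t(k-2).
- Weighted median: cumulative-weight interpolated median of the ratios,
  consistent when valid instruments carry more than half the weight.
- Mode estimators: argmax of a normal-kernel-smoothed density of the ratios
  (weighted or uniform), robust to the largest invalid cluster.

Bootstrap SEs (median, modes) use a seeded parametric resample of both sides.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import HarmonizedSet

DEFAULT_SEED = 20240507
Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """A causal effect estimate (per unit exposure) with its uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    outcome_type: str = "quantitative"
    or_scale: Optional[tuple[float, float, float]] = None  # (OR, low, high)
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(max(2.0 * stats.norm.sf(abs(beta / se)), 5e-324))


def _finish(method, beta, se, k, outcome_type, pvalue=None, **extra) -> MREstimate:
    if pvalue is None:
        pvalue = _normal_p(beta, se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z975 * se),
        ci_high=float(beta + Z975 * se),
        pvalue=float(pvalue),
        k=int(k),
        outcome_type=outcome_type,
        **extra,
    )


def wald_ratio(hset: HarmonizedSet) -> MREstimate:
    """Single-instrument estimate beta_y/beta_x with first-order SE se_y/|beta_x|."""
    if hset.k != 1:
        raise ValueError(f"wald_ratio requires exactly 1 SNP, got {hset.k}")
    bx, by, sy = hset.beta_x[0], hset.beta_y[0], hset.se_y[0]
    if bx == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    return _finish("wald_ratio", by / bx, sy / abs(bx), 1, hset.outcome_type)


def _ivw_core(bx, by, sy):
    w = bx**2 / sy**2
    theta = by / bx
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q


def ivw(hset: HarmonizedSet, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted estimate; fixed or multiplicative random effects.

    The point estimate is identical under both effect models; the random-effects
    SE is the fixed SE scaled by sqrt(max(1, Q/(k-1))).
    """
    if hset.k < 2:
        raise ValueError("ivw requires k >= 2 SNPs; use wald_ratio for a single instrument")
    if np.any(hset.beta_x == 0):
        raise ValueError("ivw undefined when any beta_x is 0")
    if effects_model not in ("fixed", "random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    beta, se, q = _ivw_core(hset.beta_x, hset.beta_y, hset.se_y)
    if effects_model == "random":
        se *= math.sqrt(max(1.0, q / (hset.k - 1)))
    return _finish(f"ivw_{effects_model}", beta, se, hset.k, hset.outcome_type)


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger weighted regression with intercept (directional pleiotropy).

    SNPs are first oriented so every exposure beta is non-negative (both betas
    negated where needed). SEs apply a residual scale max(1, sqrt(RSS/(k-2)));
    p-values use t with k-2 df.
    """
    k = hset.k
    if k < 3:
        raise ValueError("egger requires k >= 3 SNPs (slope and intercept underdetermined)")
    sign = np.where(hset.beta_x < 0, -1.0, 1.0)
    bx = hset.beta_x * sign
    by = hset.beta_y * sign
    w = 1.0 / hset.se_y**2

    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ by)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss / (k - 2)))
    ses = np.sqrt(np.diag(xtwx_inv)) * scale
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(ses[0]), float(ses[1])
    p_slope = float(max(2.0 * stats.t.sf(abs(slope / se_slope), k - 2), 5e-324))
    p_int = float(max(2.0 * stats.t.sf(abs(intercept / se_int), k - 2), 5e-324))
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - Z975 * se_slope,
        ci_high=slope + Z975 * se_slope,
        pvalue=p_slope,
        k=k,
        outcome_type=hset.outcome_type,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=p_int,
    )


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, th))


def _parametric_boot(hset, n_boot, seed, point_fn):
    rng = np.random.default_rng(seed)
    BX = rng.normal(hset.beta_x, hset.se_x, size=(n_boot, hset.k))
    BY = rng.normal(hset.beta_y, hset.se_y, size=(n_boot, hset.k))
    ests = np.empty(n_boot)
    sy2 = hset.se_y**2
    for i in range(n_boot):
        theta = BY[i] / BX[i]
        w = BX[i] ** 2 / sy2
        ests[i] = point_fn(theta, w)
    return float(np.std(ests, ddof=1))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = DEFAULT_SEED
) -> MREstimate:
    """Weighted median of per-SNP ratios; SE from a seeded parametric bootstrap."""
    if hset.k < 3:
        raise ValueError("weighted_median requires k >= 3 SNPs")
    theta = hset.beta_y / hset.beta_x
    w = hset.beta_x**2 / hset.se_y**2
    beta = _weighted_median_point(theta, w)
    se = _parametric_boot(hset, n_boot, seed, _weighted_median_point)
    return _finish("weighted_median", beta, se, hset.k, hset.outcome_type)


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    k = len(theta)
    sd = float(np.std(theta, ddof=1))
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    h = phi * 0.9 * min(sd, mad) * k ** (-1.0 / 5.0)
    if h == 0:
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    wn = w / np.sum(w)
    dens = np.sum(
        wn[:, None] * stats.norm.pdf((grid[None, :] - theta[:, None]) / h) / h, axis=0
    )
    # np.argmax returns the first maximum; the grid ascends, so ties break
    # toward the smaller ratio.
    return float(grid[np.argmax(dens)])


def mode_estimator(
    hset: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
) -> MREstimate:
    """Kernel-density mode of per-SNP ratios (weighted or simple)."""
    if hset.k < 3:
        raise ValueError("mode estimators require k >= 3 SNPs")
    theta = hset.beta_y / hset.beta_x
    w = hset.beta_x**2 / hset.se_y**2 if weighted else np.ones(hset.k)
    beta = _mode_point(theta, w, phi)

    if weighted:
        point_fn = lambda th, ww: _mode_point(th, ww, phi)
    else:
        point_fn = lambda th, ww: _mode_point(th, np.ones_like(th), phi)
    se = _parametric_boot(hset, n_boot, seed, point_fn)
    name = "weighted_mode" if weighted else "simple_mode"
    return _finish(name, beta, se, hset.k, hset.outcome_type)


def to_or(est: MREstimate) -> MREstimate:
    """Attach the odds-ratio scale (exp of beta and CI) for a binary outcome."""
    if est.outcome_type != "binary":
        raise ValueError("odds-ratio scale only applies to binary (log-odds) outcomes")
    return dataclasses.replace(
        est,
        or_scale=(math.exp(est.beta), math.exp(est.ci_low), math.exp(est.ci_high)),
    )


def estimate_suite(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = DEFAULT_SEED
) -> list[MREstimate]:
    """All estimators applicable to the set's size, in reporting order.

    k = 1 -> Wald ratio only; k >= 2 adds IVW fixed/random; k >= 3 adds Egger,
    weighted median, and both modes. Odds-ratio scale is attached for binary
    outcomes.
    """
    if hset.k == 0:
        raise ValueError("empty harmonized set")
    out: list[MREstimate] = []
    if hset.k == 1:
        out.append(wald_ratio(hset))
    else:
        out.append(ivw(hset, "fixed"))
        out.append(ivw(hset, "random"))
        if hset.k >= 3:
            out.append(egger(hset))
            out.append(weighted_median(hset, n_boot=n_boot, seed=seed))
            out.append(mode_estimator(hset, weighted=True, n_boot=n_boot, seed=seed))
            out.append(mode_estimator(hset, weighted=False, n_boot=n_boot, seed=seed))
    if hset.outcome_type == "binary":
        out = [to_or(e) for e in out]
    return out
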