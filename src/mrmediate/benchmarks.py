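"""Replicated simulation benchmarks for estimator calibration and recovery.

Each function runs a named study scenario end to end through the public
pipeline (simulate -> harmonize -> estimate/diagnose) over many seeded
replicates and returns summary metrics. The scenarios double as the package's
reproducibility suite: the acceptance script and the test suite both call
them, with seeds derived from a single integer via numpy's SeedSequence.

Scenario conventions (the study conditions, fixed here, not tuned per run):

- Recovery scenarios use k = 50 strong instruments, a large exposure GWAS
  (n = 344,182) and an outcome GWAS of 1e5, true total effect 0.5.
- Null-calibration scenarios for Cochran's Q and the Egger intercept use an
  effectively noiseless exposure side (n_x = 1e12): chi-square(k-1) and t(k-2)
  are these statistics' reference distributions conditional on the exposure
  effects, so their calibration is checked under that model. Balanced
  pleiotropy is drawn per SNP as N(0, se_y_j) (SE-scaled), which makes the
  overdispersion exactly multiplicative — the model the scaled SEs assume.
- The planted-outlier scenario gives 1 of 20 SNPs a pleiotropic offset of
  10 outcome SEs.
- The mediation scenario uses the generator defaults: a = -0.4, b = 1.0,
  c' = -0.9, hence a true mediated proportion of 0.4/1.3 ~ 30.8%.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .estimators import MREstimate, egger, ivw
from .instruments import harmonize
from .mediation import TwoStepConfig, run_two_step, screen_mediators
from .sensitivity import cochran_q, mr_presso
from .synthetic_data import SimulationConfig, simulate


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n deterministic sub-seeds below 2**31 derived from one integer."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def _two_trait_config(seed: int, **overrides) -> SimulationConfig:
    base = dict(
        k_x=50,
        k_m=0,
        n_true_mediators=0,
        n_null_mediators=0,
        theta=0.5,
        palindromic_rate=0.0,
        seed=int(seed),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _fit_ivw(cfg: SimulationConfig) -> MREstimate:
    study = simulate(cfg)
    hset = harmonize(study.exposure_instruments(), study.panels["outcome"])
    return ivw(hset, "fixed")


def ivw_recovery(n_reps: int = 500, seed: int = 1) -> dict:
    """Bias and 95% CI coverage of fixed-effects IVW at k=50, true effect 0.5."""
    betas = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        est = _fit_ivw(_two_trait_config(s))
        betas[i] = est.beta
        covered[i] = est.ci_low <= 0.5 <= est.ci_high
    return {
        "true_theta": 0.5,
        "mean_estimate": float(betas.mean()),
        "bias": float(betas.mean() - 0.5),
        "coverage_pct": float(100.0 * covered.mean()),
        "n_reps": n_reps,
    }


def q_calibration(n_reps: int = 2000, k: int = 20, seed: int = 2) -> dict:
    """Mean of Cochran's Q under homogeneity; should be close to k-1."""
    qs = np.empty(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        study = simulate(_two_trait_config(s, k_x=k, n_x=1e12))
        hset = harmonize(study.exposure_instruments(), study.panels["outcome"])
        qs[i], _, _ = cochran_q(hset)
    return {"mean_q": float(qs.mean()), "expected": k - 1, "k": k, "n_reps": n_reps}


def egger_type1(n_reps: int = 1000, k: int = 50, seed: int = 3) -> dict:
    """Egger-intercept rejection rate at alpha=0.05 under balanced pleiotropy."""
    reject = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = _two_trait_config(
            s,
            k_x=k,
            n_x=1e12,
            fraction_invalid=1.0,
            mean_alpha=0.0,
            sd_alpha=1.0,
            alpha_se_scaled=True,
        )
        study = simulate(cfg)
        hset = harmonize(study.exposure_instruments(), study.panels["outcome"])
        reject[i] = egger(hset).intercept_p < 0.05
    return {"rejection_pct": float(100.0 * reject.mean()), "n_reps": n_reps, "k": k}


def egger_directional(n_reps: int = 200, k: int = 50, seed: int = 4) -> dict:
    """Directional pleiotropy (mean 0.05): IVW is biased, Egger nearly unbiased."""
    ivw_b = np.empty(n_reps)
    egger_b = np.empty(n_reps)
    detect = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = _two_trait_config(
            s, k_x=k, fraction_invalid=1.0, mean_alpha=0.05, sd_alpha=0.02
        )
        study = simulate(cfg)
        hset = harmonize(study.exposure_instruments(), study.panels["outcome"])
        ivw_b[i] = ivw(hset, "fixed").beta
        e = egger(hset)
        egger_b[i] = e.beta
        detect[i] = e.intercept_p < 0.05
    return {
        "true_theta": 0.5,
        "ivw_mean_bias": float(ivw_b.mean() - 0.5),
        "egger_mean_bias": float(egger_b.mean() - 0.5),
        "intercept_power_pct": float(100.0 * detect.mean()),
        "n_reps": n_reps,
    }


def presso_null(n_reps: int = 500, n_sim: int = 500, k: int = 20, seed: int = 5) -> dict:
    """MR-PRESSO global-test rejection rate at 0.05 with no pleiotropy."""
    reject = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        study = simulate(_two_trait_config(s, k_x=k))
        hset = harmonize(study.exposure_instruments(), study.panels["outcome"])
        res = mr_presso(hset, n_sim=n_sim, seed=int(s))
        reject[i] = res.global_p < 0.05
    return {"rejection_pct": float(100.0 * reject.mean()), "n_reps": n_reps, "n_sim": n_sim}


def presso_recall(n_reps: int = 200, n_sim: int = 1000, seed: int = 6) -> dict:
    """Detection of one SNP with a 10-SE pleiotropic offset among 19 clean SNPs.

    Also checks how often the outlier-corrected IVW lands closer to the truth
    than the uncorrected estimate, among replicates where the outlier was
    flagged.
    """
    flagged = np.empty(n_reps, dtype=bool)
    closer: list[bool] = []
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = _two_trait_config(
            s,
            k_x=20,
            fraction_invalid=1 / 20,
            mean_alpha=10.0,
            sd_alpha=0.0,
            alpha_se_scaled=True,
        )
        study = simulate(cfg)
        hset = harmonize(study.exposure_instruments(), study.panels["outcome"])
        res = mr_presso(hset, n_sim=n_sim, seed=int(s))
        planted = study.truth.invalid_snp_ids[0]
        flagged[i] = planted in res.outliers
        if flagged[i] and res.corrected is not None:
            uncorrected = ivw(hset, "fixed")
            closer.append(abs(res.corrected.beta - 0.5) < abs(uncorrected.beta - 0.5))
    return {
        "recall_pct": float(100.0 * flagged.mean()),
        "corrected_closer_pct": float(100.0 * np.mean(closer)) if closer else float("nan"),
        "n_reps": n_reps,
        "n_sim": n_sim,
    }


def mediation_recovery(n_reps: int = 300, seed: int = 7) -> dict:
    """Recovery of the mediated proportion under the generator defaults (~30.8%)."""
    cfg0 = SimulationConfig(n_null_mediators=0)
    true_prop = cfg0.a * cfg0.b / (cfg0.a * cfg0.b + cfg0.c_prime)
    props: list[float] = []
    covered: list[bool] = []
    max_identity_err = 0.0
    for s in _child_seeds(seed, n_reps):
        study = simulate(dataclasses.replace(cfg0, seed=int(s)))
        results = run_two_step(
            study.exposure_instruments(),
            [study.panels["mediator_1"]],
            study.panels["outcome"],
            TwoStepConfig(seed=int(s)),
        )
        if not results:
            continue
        res = results[0]
        props.append(res.proportion)
        lo, hi = res.proportion_ci
        covered.append(lo <= true_prop <= hi)
        max_identity_err = max(max_identity_err, abs(res.indirect + res.direct - res.c))
    return {
        "true_proportion_pct": float(100.0 * true_prop),
        "mean_proportion_pct": float(100.0 * np.mean(props)),
        "coverage_pct": float(100.0 * np.mean(covered)),
        "max_decomposition_error": float(max_identity_err),
        "n_results": len(props),
        "n_reps": n_reps,
    }


def two_step_screens(
    n_reps: int = 100, seed: int = 8, with_true_mediator: bool = True
) -> dict:
    """Both-screen detection of the true mediator among nulls, or all-null FWER.

    With a true mediator: fraction of replicates in which mediator_1 passes the
    step-1 Bonferroni screen and is flagged significant at step 2. All-null:
    fraction of replicates emitting no mediation result at all.
    """
    hits = np.empty(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = SimulationConfig(
            n_true_mediators=1 if with_true_mediator else 0,
            n_null_mediators=9 if with_true_mediator else 10,
            seed=int(s),
        )
        study = simulate(cfg)
        panels = [study.panels[n] for n in study.mediator_names]
        results = run_two_step(
            study.exposure_instruments(),
            panels,
            study.panels["outcome"],
            TwoStepConfig(seed=int(s)),
        )
        if with_true_mediator:
            hits[i] = any(
                r.mediator == "mediator_1" and "step2_significant" in r.flags
                for r in results
            )
        else:
            hits[i] = len(results) == 0
    key = "detection_pct" if with_true_mediator else "empty_pct"
    return {key: float(100.0 * hits.mean()), "n_reps": n_reps}


def screen_fwer(n_reps: int = 200, m: int = 1400, seed: int = 9) -> dict:
    """Family-wise error of the Bonferroni mediator screen over m null tests."""
    from scipy import stats as _st

    rng = np.random.default_rng(int(_child_seeds(seed, 1)[0]))
    any_pass = np.empty(n_reps, dtype=bool)
    for i in range(n_reps):
        z = rng.standard_normal(m)
        p = 2.0 * _st.norm.sf(np.abs(z))
        step1 = [
            (
                f"m{j}",
                MREstimate(
                    method="ivw_fixed",
                    beta=float(z[j]),
                    se=1.0,
                    ci_low=float(z[j] - 1.96),
                    ci_high=float(z[j] + 1.96),
                    pvalue=float(p[j]),
                    k=10,
                ),
            )
            for j in range(m)
        ]
        any_pass[i] = len(screen_mediators(step1, 0.05).passing) > 0
    return {"fwer_pct": float(100.0 * any_pass.mean()), "m": m, "n_reps": n_reps}
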