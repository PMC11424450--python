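"""Seeded calibration experiments exercising the whole pipeline.

Each function simulates data under a known truth, runs the relevant
stage, and returns summary rates: estimator recovery and confidence
coverage, type-I error calibration, pleiotropy-robustness of the
estimator battery, outlier detection, colocalization scenario recovery
and end-to-end screen recovery. They are the package's own evidence
that its statistics behave as advertised, and they are what the
acceptance script reports.
"""

from __future__ import annotations

import numpy as np

from .coloc import coloc_abf
from .estimators import ivw, mr_egger, weighted_median
from .screen import ScreenConfig, run_mr_screen
from .sensitivity import cochran_q, leave_one_out, mr_presso
from .simulate import (ColocSimConfig, MRSimConfig, ScreenSimConfig,
                       simulate_coloc_region, simulate_harmonized,
                       simulate_screen_panel)


def ivw_recovery(seed: int = 0, n_rep: int = 500, theta: float = 0.3,
                 j_snps: int = 50) -> dict:
    """Parameter recovery of the IVW estimator under a clean model.

    Returns the mean estimate over replicates and the empirical 95%
    confidence-interval coverage of the true effect.
    """
    ests, cover = [], 0
    for r in range(n_rep):
        cfg = MRSimConfig(j_snps=j_snps, theta=theta, seed=seed * 100_000 + r)
        h, _ = simulate_harmonized(cfg)
        fit = ivw(h)
        ests.append(fit.estimate)
        cover += fit.ci_low <= theta <= fit.ci_high
    return {
        "theta": theta,
        "mean_estimate": float(np.mean(ests)),
        "coverage": cover / n_rep,
        "n_rep": n_rep,
    }


def null_calibration(seed: int = 0, n_rep: int = 1000, j_snps: int = 10,
                     alpha: float = 0.05) -> dict:
    """Type-I error of IVW and mean Cochran's Q under the global null."""
    reject, qs = 0, []
    for r in range(n_rep):
        cfg = MRSimConfig(j_snps=j_snps, theta=0.0, seed=seed * 100_000 + r)
        h, _ = simulate_harmonized(cfg)
        reject += ivw(h).pvalue < alpha
        qs.append(cochran_q(h).q)
    return {
        "ivw_rejection_rate": reject / n_rep,
        "q_mean": float(np.mean(qs)),
        "q_df": j_snps - 1,
        "n_rep": n_rep,
    }


def presso_null_calibration(seed: int = 0, n_rep: int = 500,
                            j_snps: int = 10, n_sim: int = 200,
                            alpha: float = 0.05) -> dict:
    """Rejection rate of the MR-PRESSO global test under the null."""
    reject = 0
    for r in range(n_rep):
        cfg = MRSimConfig(j_snps=j_snps, theta=0.0, seed=seed * 100_000 + r)
        h, _ = simulate_harmonized(cfg)
        res = mr_presso(h, n_sim=n_sim, seed=seed * 100_000 + r)
        reject += res.global_pvalue < alpha
    return {"presso_rejection_rate": reject / n_rep, "n_rep": n_rep}


def pleiotropy_robustness(seed: int = 0, n_rep: int = 200,
                          j_snps: int = 100, theta: float = 0.1,
                          frac: float = 0.3) -> dict:
    """Directional pleiotropy on a fraction of instruments.

    Measures the power of the MR-Egger intercept test and how often the
    weighted median lands closer to the truth than IVW.
    """
    egger_reject, wm_closer = 0, 0
    for r in range(n_rep):
        cfg = MRSimConfig(
            j_snps=j_snps, theta=theta, pleiotropy="directional",
            pleiotropy_mean=0.12, pleiotropy_sd=0.02,
            pleiotropy_frac=frac, seed=seed * 100_000 + r,
        )
        h, truth = simulate_harmonized(cfg)
        eg = mr_egger(h)
        egger_reject += eg.intercept_pvalue < 0.05
        ivw_bias = abs(ivw(h).estimate - truth.theta)
        wm_bias = abs(weighted_median(h, n_boot=200,
                                      seed=seed * 100_000 + r).estimate
                      - truth.theta)
        wm_closer += wm_bias < ivw_bias
    return {
        "egger_intercept_power": egger_reject / n_rep,
        "wm_closer_rate": wm_closer / n_rep,
        "n_rep": n_rep,
    }


def outlier_detection(seed: int = 0, n_rep: int = 200, j_snps: int = 20,
                      shift_se: float = 10.0) -> dict:
    """Recovery of a single displaced instrument.

    One SNP's outcome beta is displaced by ``shift_se`` standard
    errors; counts how often MR-PRESSO flags exactly it and how often
    leave-one-out ranks it most influential. Instruments are drawn with
    equal variance explained (``h2_spread_decades=0``) so the raw
    estimate-shift ranking isolates the displacement rather than the
    weight of the instrument it happens to land on.
    """
    flagged, top_influence = 0, 0
    for r in range(n_rep):
        cfg = MRSimConfig(j_snps=j_snps, theta=0.2, n_outliers=1,
                          outlier_shift_se=shift_se, h2_spread_decades=0.0,
                          seed=seed * 100_000 + r)
        h, truth = simulate_harmonized(cfg)
        outlier = truth.outlier_ids[0]
        res = mr_presso(h, n_sim=1000, seed=seed * 100_000 + r)
        flagged += outlier in res.outliers
        loo = leave_one_out(h)
        full = loo.full_estimate.estimate
        shifts = (loo.rows["estimate"] - full).abs()
        top = loo.rows.loc[shifts.idxmax(), "left_out_snp"]
        top_influence += top == outlier
    return {
        "presso_flag_rate": flagged / n_rep,
        "loo_top_rate": top_influence / n_rep,
        "n_rep": n_rep,
    }


def coloc_scenario_calibration(seed: int = 0, n_h4: int = 100,
                               n_h3: int = 20, n_h0: int = 20) -> dict:
    """Recovery rates of the colocalization posteriors by scenario."""
    h4_hits = 0
    for r in range(n_h4):
        r1, r2, truth = simulate_coloc_region(
            ColocSimConfig(m_snps=100, scenario="h4", causal_z=8.0,
                           seed=seed * 100_000 + r))
        res = coloc_abf(r1, r2)
        h4_hits += res.pp["PP.H4"] > 0.8

    h3_hits = 0
    for r in range(n_h3):
        r1, r2, _ = simulate_coloc_region(
            ColocSimConfig(m_snps=200, scenario="h3", causal_z=8.0,
                           seed=seed * 100_000 + r))
        res = coloc_abf(r1, r2)
        h3_hits += max(res.pp, key=res.pp.get) == "PP.H3"

    h0_hits = 0
    for r in range(n_h0):
        r1, r2, _ = simulate_coloc_region(
            ColocSimConfig(m_snps=200, scenario="h0", seed=seed * 100_000 + r))
        res = coloc_abf(r1, r2)
        h0_hits += res.pp["PP.H0"] > 0.9
    return {
        "h4_recovery_rate": h4_hits / n_h4,
        "h3_top_rate": h3_hits / n_h3,
        "h0_recovery_rate": h0_hits / n_h0,
        "n_h4": n_h4, "n_h3": n_h3, "n_h0": n_h0,
    }


def screen_recovery(seed: int = 0, n_rep: int = 50, n_genes: int = 20,
                    theta: float = 0.4) -> dict:
    """End-to-end screen on a panel with one true causal gene.

    Counts how often exactly the causal gene is flagged candidate and
    how often its reverse-MR p-values are non-significant in both
    cohorts.
    """
    exact, reverse_clear = 0, 0
    cfg = ScreenConfig(presso_n_sim=200, wm_n_boot=200)
    for r in range(n_rep):
        panel = simulate_screen_panel(ScreenSimConfig(
            n_genes=n_genes, theta=theta, seed=seed * 100_000 + r))
        results = run_mr_screen(
            panel.genes, panel.outcome_discovery, panel.outcome_validation,
            panel.ld, cfg,
            reverse_exposure_discovery=panel.reverse_exposure_discovery,
            reverse_exposure_validation=panel.reverse_exposure_validation,
            expression_outcomes=panel.expression_outcomes,
            reverse_ld=panel.reverse_ld)
        causal = set(panel.truth["causal_genes"])
        candidates = {res.gene_id for res in results if res.candidate}
        exact += candidates == causal
        causal_res = [res for res in results if res.gene_id in causal]
        reverse_clear += all(
            res.reverse_p_discovery is not None
            and res.reverse_p_validation is not None
            and res.reverse_p_discovery >= 0.05
            and res.reverse_p_validation >= 0.05
            for res in causal_res)
    return {
        "exact_recovery_rate": exact / n_rep,
        "reverse_nonsignificant_rate": reverse_clear / n_rep,
        "n_rep": n_rep,
    }
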