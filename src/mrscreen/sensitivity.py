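"""Heterogeneity and pleiotropy diagnostics for an MR fit.

Cochran's Q measures dispersion of per-SNP Wald ratios around the IVW
estimate; MR-PRESSO detects pleiotropic outlier instruments by
comparing each SNP's residual sum of squares against a parametric null
simulation; leave-one-out refits quantify the influence of single SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, ivw
from .sumstats import HarmonizedSet


@dataclass
class QResult:
    """Cochran's Q heterogeneity statistic with chi-square p-value."""

    q: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    """MR-PRESSO global test and per-SNP outlier calls."""

    global_rss: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outliers: list[str]
    estimate_before: MRResult
    estimate_after: MRResult | None
    n_sim: int
    seed: int


@dataclass
class LeaveOneOutTable:
    """IVW refits with each instrument removed in turn.

    ``rows`` has columns left_out_snp, estimate, se, pvalue, flagged;
    a row is flagged when dropping the SNP changes the sign of the
    estimate or its significance at 0.05 relative to the full fit.
    """

    rows: pd.DataFrame
    full_estimate: MRResult


def cochran_q(h: HarmonizedSet) -> QResult:
    """Heterogeneity of Wald ratios around the IVW estimate.

    Q = Σ w_j (r_j − β̂_ivw)² with first-order weights
    w_j = β̂_exp,j²/se_out,j²; p from chi-square with J−1 df.
    """
    if h.n_snp < 2:
        raise ValueError("Cochran's Q requires >=2 instruments")
    if np.any(h.beta_exp == 0):
        raise ValueError("zero exposure beta gives an undefined ratio")
    est = ivw(h).estimate
    ratios = h.beta_out / h.beta_exp
    w = h.beta_exp**2 / h.se_out**2
    q = float(np.sum(w * (ratios - est) ** 2))
    df = h.n_snp - 1
    return QResult(q, df, float(stats.chi2.sf(q, df)))


def _loo_ivw_vec(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over the last axis."""
    num = np.sum(be * bo * w, axis=-1, keepdims=True)
    den = np.sum(be**2 * w, axis=-1, keepdims=True)
    return (num - be * bo * w) / (den - be**2 * w)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global heterogeneity test and outlier search.

    The observed global statistic is the residual sum of squares
    RSS = Σ_j (β̂_out,j − β̂_exp,j · β̂_ivw(−j))², each residual taken
    against the leave-one-out IVW fit. Its null distribution comes from
    ``n_sim`` parametric simulations redrawing both effect vectors from
    their sampling distributions under the no-pleiotropy model and
    recomputing the statistic. Empirical p-values use the
    (1 + exceedances)/(n_sim + 1) estimator; per-SNP outlier p-values
    are Bonferroni-adjusted across the J instruments and flagged below
    ``alpha``. When outliers are found, the IVW estimate is recomputed
    on the remaining SNPs.
    """
    j = h.n_snp
    if j < 4:
        raise ValueError("PRESSO requires >=4 instruments")
    be, bo = h.beta_exp, h.beta_out
    w = 1.0 / h.se_out**2

    loo = _loo_ivw_vec(be, bo, w)
    res_obs = bo - be * loo
    rss_obs = float(np.sum(res_obs**2))

    rng = np.random.default_rng(seed)
    be_sim = rng.normal(be, h.se_exp, size=(n_sim, j))
    bo_sim = rng.normal(be * loo, h.se_out, size=(n_sim, j))
    loo_sim = _loo_ivw_vec(be_sim, bo_sim, w)
    res_sim = bo_sim - be_sim * loo_sim
    rss_sim = np.sum(res_sim**2, axis=1)

    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    p_snp = (1 + np.sum(res_sim**2 >= res_obs**2, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_snp * j, 1.0)
    outlier_mask = p_adj < alpha
    outliers = [h.snp_ids[i] for i in np.flatnonzero(outlier_mask)]

    before = ivw(h)
    after = None
    if outliers and int(np.sum(~outlier_mask)) >= 1:
        after = ivw(h.subset(~outlier_mask))
    return PressoResult(
        global_rss=rss_obs, global_pvalue=float(global_p),
        outlier_pvalues=dict(zip(h.snp_ids, p_adj.tolist())),
        outliers=outliers, estimate_before=before, estimate_after=after,
        n_sim=n_sim, seed=seed,
    )


def leave_one_out(h: HarmonizedSet, alpha: float = 0.05) -> LeaveOneOutTable:
    """IVW refits dropping each SNP in turn, with influence flags."""
    if h.n_snp < 2:
        raise ValueError("leave-one-out requires >=2 instruments")
    full = ivw(h)
    full_sig = full.pvalue < alpha
    records = []
    for i in range(h.n_snp):
        mask = np.ones(h.n_snp, dtype=bool)
        mask[i] = False
        fit = ivw(h.subset(mask))
        flagged = (
            np.sign(fit.estimate) != np.sign(full.estimate)
            or (fit.pvalue < alpha) != full_sig
        )
        records.append({
            "left_out_snp": h.snp_ids[i],
            "estimate": fit.estimate,
            "se": fit.se,
            "pvalue": fit.pvalue,
            "flagged": bool(flagged),
        })
    return LeaveOneOutTable(pd.DataFrame.from_records(records), full)
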