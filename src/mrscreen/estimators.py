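"""Point estimators of the causal effect from harmonized instruments.

Given allele-aligned per-SNP effects (β̂_exp, β̂_out) the causal effect
of exposure on outcome is estimated by:

* the Wald ratio β̂_out/β̂_exp for a single instrument;
* the inverse-variance-weighted (IVW) combination

      β̂_ivw = Σ β̂_exp β̂_out / var(β̂_out)  ÷  Σ β̂_exp² / var(β̂_out),

  equivalent to a weighted regression of β̂_out on β̂_exp through the
  origin and to the inverse-variance mean of per-SNP Wald ratios;
* MR-Egger weighted regression with a free intercept, whose intercept
  tests directional horizontal pleiotropy;
* the weighted median of Wald ratios, consistent when instruments
  carrying at least half the weight are valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

Z975 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One method's causal estimate with uncertainty."""

    method: str
    estimate: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    n_snp: int


@dataclass
class EggerResult:
    """MR-Egger slope plus the pleiotropy-testing intercept."""

    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def _normal_result(method: str, estimate: float, se: float, n_snp: int) -> MRResult:
    z = estimate / se if se > 0 else np.inf * np.sign(estimate)
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return MRResult(method, float(estimate), float(se), float(min(p, 1.0)),
                    float(estimate - Z975 * se), float(estimate + Z975 * se),
                    n_snp)


def wald_ratio(h: HarmonizedSet) -> MRResult:
    """Single-instrument causal estimate β̂_out/β̂_exp.

    The standard error |se_out/β̂_exp| is the first-order delta-method
    approximation that ignores noise in the exposure effect.
    """
    if h.n_snp != 1:
        raise ValueError("wald_ratio requires exactly one SNP")
    be, bo, so = h.beta_exp[0], h.beta_out[0], h.se_out[0]
    if be == 0:
        raise ValueError("undefined ratio: exposure beta is zero")
    return _normal_result("wald", bo / be, abs(so / be), 1)


def ivw(h: HarmonizedSet, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate.

    Fixed-effect by default: se = sqrt(1/Σ β̂_exp²/var(β̂_out)). With
    ``random_effects`` the se is inflated multiplicatively by
    max(1, sqrt(Q/(J−1))) to absorb heterogeneity.
    """
    if h.n_snp == 0:
        raise ValueError("ivw requires at least one SNP")
    if h.n_snp == 1 and h.beta_exp[0] == 0:
        raise ValueError("undefined ratio: exposure beta is zero")
    w = 1.0 / h.se_out**2
    den = np.sum(h.beta_exp**2 * w)
    est = np.sum(h.beta_exp * h.beta_out * w) / den
    se = np.sqrt(1.0 / den)
    if random_effects and h.n_snp > 1:
        nz = h.beta_exp != 0
        ratios = h.beta_out[nz] / h.beta_exp[nz]
        wq = (h.beta_exp[nz] ** 2) * w[nz]
        q = np.sum(wq * (ratios - est) ** 2)
        se *= max(1.0, np.sqrt(q / (h.n_snp - 1)))
    res = _normal_result("ivw", est, se, h.n_snp)
    return res


def mr_egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Instruments are oriented so every exposure effect is nonnegative
    (flipping the signs of both betas where needed), which fixes the
    meaning of the intercept as average directional pleiotropy.
    Standard errors are scaled by max(1, sqrt(RSS_w/(J−2))) and
    p-values use a t reference with J−2 degrees of freedom.
    """
    j = h.n_snp
    if j < 3:
        raise ValueError("Egger requires >=3 instruments")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * sign
    y = h.beta_out * sign
    w = 1.0 / h.se_out**2

    sw = w.sum()
    swx = np.sum(w * x)
    swx2 = np.sum(w * x**2)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    det = sw * swx2 - swx**2
    if det <= 0:
        raise ValueError("degenerate design: no spread in exposure effects")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    rss_w = np.sum(w * resid**2)
    phi = max(1.0, rss_w / (j - 2))
    var_slope = phi * sw / det
    var_int = phi * swx2 / det

    se_slope, se_int = np.sqrt(var_slope), np.sqrt(var_int)
    tdist = stats.t(df=j - 2)
    p_slope = 2 * tdist.sf(abs(slope / se_slope)) if se_slope > 0 else 0.0
    p_int = 2 * tdist.sf(abs(intercept / se_int)) if se_int > 0 else 0.0
    tq = tdist.ppf(0.975)
    slope_res = MRResult("egger", float(slope), float(se_slope),
                         float(min(p_slope, 1.0)),
                         float(slope - tq * se_slope),
                         float(slope + tq * se_slope), j)
    return EggerResult(slope_res, float(intercept), float(se_int),
                       float(min(max(p_int, np.finfo(float).tiny), 1.0)))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios``.

    Sorts the ratios, forms normalized cumulative weights s_j, and
    linearly interpolates ratio against (s_j − w_j/2) at 0.5.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap se.

    Per-SNP Wald ratios are weighted by the inverse of their
    first-order variance, β̂_exp²/se_out². The standard error is the
    standard deviation of the estimate over ``n_boot`` resamples of
    (β̂_exp, β̂_out) from their normal sampling distributions.
    """
    j = h.n_snp
    if j < 3:
        raise ValueError("weighted median requires >=3 instruments")
    if np.any(h.beta_exp == 0):
        raise ValueError("zero exposure beta gives an undefined ratio")
    ratios = h.beta_out / h.beta_exp
    weights = h.beta_exp**2 / h.se_out**2
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    be = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, j))
    bo = rng.normal(h.beta_out, h.se_out, size=(n_boot, j))
    be = np.where(be == 0, np.finfo(float).tiny, be)
    boot_r = bo / be
    boot_w = be**2 / h.se_out**2
    boot_w = boot_w / boot_w.sum(axis=1, keepdims=True)

    order = np.argsort(boot_r, axis=1, kind="mergesort")
    rows = np.arange(n_boot)[:, None]
    rs = boot_r[rows, order]
    ws = boot_w[rows, order]
    s = np.cumsum(ws, axis=1) - 0.5 * ws
    boot_est = np.empty(n_boot)
    for b in range(n_boot):
        if 0.5 <= s[b, 0]:
            boot_est[b] = rs[b, 0]
        elif 0.5 >= s[b, -1]:
            boot_est[b] = rs[b, -1]
        else:
            boot_est[b] = np.interp(0.5, s[b], rs[b])
    se = float(np.std(boot_est, ddof=1))
    return _normal_result("weighted_median", est, se, j)
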