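"""Heterogeneity and horizontal-pleiotropy diagnostics.

Implements Cochran's Q with the I2 index around the IVW fit, Rucker's Q
around the MR-Egger fit with the 1-df Q-Q' model-selection test, the Egger
intercept test, the simulation-based MR-PRESSO global/outlier/distortion
battery, and the fixed-to-random decision rule for the IVW model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from causalmr.estimators import MREstimate, RatioEstimates, mr_egger, mr_ivw, wald_ratios
from causalmr.summary_stats import HarmonizedInstrumentSet

__all__ = [
    "HeterogeneityReport",
    "PressoResult",
    "cochran_q",
    "rucker_model_selection",
    "egger_intercept_test",
    "mr_presso",
    "decide_ivw_model",
]

#: heterogeneity gate: I2 above this percentage AND Cochran p below 0.05
I2_HETEROGENEITY_PCT = 25.0
HETEROGENEITY_P = 0.05


@dataclass
class HeterogeneityReport:
    """Q statistics around the IVW and Egger fits plus the intercept test."""

    q: float
    df_q: int
    p_q: float
    i2: float  # percentage
    q_rucker: float
    df_rucker: int
    p_rucker: float
    qq_diff: float
    p_qq: float
    egger_intercept: float
    egger_intercept_se: float
    p_intercept: float

    @property
    def heterogeneity_flag(self) -> bool:
        return self.i2 > I2_HETEROGENEITY_PCT and self.p_q < HETEROGENEITY_P

    @property
    def egger_preferred_flag(self) -> bool:
        return self.p_qq < 0.05

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["heterogeneity_flag"] = self.heterogeneity_flag
        d["egger_preferred_flag"] = self.egger_preferred_flag
        return d


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_obs: float
    global_p: float
    outlier_p: np.ndarray  # Bonferroni-adjusted, per retained variant
    outlier_ids: list[str]
    raw_estimate: MREstimate
    corrected_estimate: Optional[MREstimate]
    distortion_p: Optional[float]
    n_sim: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "outlier_ids": list(self.outlier_ids),
            "raw": self.raw_estimate.to_dict(),
            "corrected": self.corrected_estimate.to_dict() if self.corrected_estimate else None,
            "distortion_p": self.distortion_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def cochran_q(ratios: RatioEstimates) -> tuple[float, int, float, float]:
    """Cochran's Q around the IVW estimate.

    Returns (Q, df, p, I2) where p is the upper chi-square tail with k-1 df
    and I2 = max(0, (Q - df)/Q) * 100 (a percentage).
    """
    k = ratios.k
    if k < 2:
        raise ValueError("Cochran's Q requires >=2 instruments")
    w = ratios.weight
    beta = float(np.sum(w * ratios.theta) / np.sum(w))
    q = float(np.sum(w * (ratios.theta - beta) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p, i2


def rucker_model_selection(
    hset: HarmonizedInstrumentSet,
    exposure_index: int = 0,
) -> HeterogeneityReport:
    """Full Rucker framework: Q (IVW), Q' (Egger residual), and their 1-df
    difference selecting between the two models.

    Q >= Q' always (a free intercept cannot fit worse); Q - Q' referred to
    chi-square with 1 df tests whether the Egger intercept buys a
    significantly better fit.
    """
    if hset.k < 3:
        raise ValueError("Rucker framework requires >=3 instruments")
    ratios = wald_ratios(hset, exposure_index)
    q, df_q, p_q, i2 = cochran_q(ratios)
    slope, intercept = mr_egger(hset, exposure_index)
    bx = np.abs(hset.beta_x[:, exposure_index])
    by = np.sign(hset.beta_x[:, exposure_index]) * hset.beta_y
    resid = by - intercept.beta - slope.beta * bx
    q_rucker = float(np.sum(resid**2 / hset.se_y**2))
    df_rucker = hset.k - 2
    p_rucker = float(stats.chi2.sf(q_rucker, df_rucker))
    qq_diff = q - q_rucker
    p_qq = float(stats.chi2.sf(qq_diff, 1))
    return HeterogeneityReport(
        q=q,
        df_q=df_q,
        p_q=p_q,
        i2=i2,
        q_rucker=q_rucker,
        df_rucker=df_rucker,
        p_rucker=p_rucker,
        qq_diff=qq_diff,
        p_qq=p_qq,
        egger_intercept=intercept.beta,
        egger_intercept_se=intercept.se,
        p_intercept=intercept.p,
    )


def egger_intercept_test(
    hset: HarmonizedInstrumentSet,
    alpha: float = 0.05,
    exposure_index: int = 0,
) -> tuple[float, float, float, bool]:
    """Directional-pleiotropy test: returns (intercept, se, p, unbiased_flag)
    with unbiased_flag = (p > alpha), i.e. no evidence of average
    directional pleiotropy."""
    _, intercept = mr_egger(hset, exposure_index)
    return intercept.beta, intercept.se, intercept.p, intercept.p > alpha


def decide_ivw_model(report: HeterogeneityReport) -> str:
    """Fixed-to-random decision: random effects when I2 > 25% and Cochran p
    < 0.05, else fixed effects."""
    return "random" if report.heterogeneity_flag else "fixed"


def _loo_ivw(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized."""
    sw = np.sum(w)
    swt = np.sum(w * theta)
    return (swt - w * theta) / (sw - w)


def mr_presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    sig: float = 0.05,
    seed: int | None = None,
    exposure_index: int = 0,
) -> PressoResult:
    """MR-PRESSO: global test of pleiotropy via the observed residual sum of
    squares against a parametric null, per-variant outlier detection, and
    outlier-corrected re-estimation with a distortion test.

    The observed RSS sums weighted squared leave-one-out residuals
    (beta_Yj - theta_{-j} * beta_Xj)^2 / se_Yj^2. The null draws
    beta_Xj* ~ N(beta_Xj, se_Xj) and beta_Yj* ~ N(theta_{-j} beta_Xj, se_Yj)
    and recomputes the statistic; empirical p-values are floored at
    1/(n_sim+1). Outliers are variants whose Bonferroni-adjusted residual
    tail probability falls below ``sig``; the corrected estimate is the IVW
    fit without them.
    """
    k = hset.k
    if k < 4:
        raise ValueError("MR-PRESSO requires >=4 instruments")
    rng = np.random.default_rng(seed)
    bx = hset.beta_x[:, exposure_index]
    sx = hset.se_x[:, exposure_index]
    by, sy = hset.beta_y, hset.se_y
    wy = 1.0 / sy**2

    theta = by / bx
    sigma = sy / np.abs(bx)
    w = 1.0 / sigma**2
    theta_loo = _loo_ivw(theta, w)
    resid_obs = (by - theta_loo * bx) ** 2 * wy
    rss_obs = float(np.sum(resid_obs))

    # parametric null
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    theta_sim = by_sim / bx_sim
    sigma_sim = sy / np.abs(bx_sim)
    w_sim = 1.0 / sigma_sim**2
    sw = w_sim.sum(axis=1, keepdims=True)
    swt = (w_sim * theta_sim).sum(axis=1, keepdims=True)
    theta_loo_sim = (swt - w_sim * theta_sim) / (sw - w_sim)
    resid_sim = (by_sim - theta_loo_sim * bx_sim) ** 2 * wy
    rss_sim = resid_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    # per-variant outlier test, Bonferroni over k
    tail = (1 + (resid_sim >= resid_obs).sum(axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, tail * k)
    outlier_mask = adj < sig
    outlier_ids = [v for v, m in zip(hset.variant_ids, outlier_mask) if m]

    raw = mr_ivw(hset, effects="fixed", exposure_index=exposure_index)
    corrected = None
    distortion_p = None
    if outlier_ids:
        kept = hset.drop_ids(outlier_ids, "presso_outlier")
        corrected = mr_ivw(kept, effects="fixed", exposure_index=exposure_index)
        # distortion test: is the raw-vs-corrected shift larger than removing
        # an equal-sized random subset would produce?
        m = len(outlier_ids)
        if raw.beta != 0 and k - m >= 1:
            d_obs = abs(corrected.beta - raw.beta) / abs(raw.beta)
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(k, size=m, replace=False)
                keep = np.ones(k, dtype=bool)
                keep[drop] = False
                b = np.sum(w[keep] * theta[keep]) / np.sum(w[keep])
                d_null[s] = abs(b - raw.beta) / abs(raw.beta)
            distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=adj,
        outlier_ids=outlier_ids,
        raw_estimate=raw,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
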