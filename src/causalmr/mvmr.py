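"""Multivariable two-sample MR.

Joint weighted regression of SNP-outcome effects on several exposures' SNP
effects (no intercept, weights 1/se_Y^2) yields direct effects of each
exposure conditional on the others — the tool for separating horizontal
pleiotropy through a secondary trait (e.g. education) from mediation through
a downstream risk factor (e.g. BMI). Conditional instrument strength is
summarized by the Qx statistics (critical value: chi-square 0.95 quantile
with k-2 df) and residual heterogeneity by Qa (k-3 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from causalmr.estimators import MREstimate
from causalmr.summary_stats import HarmonizedInstrumentSet

__all__ = [
    "MVMRResult",
    "AttenuationReport",
    "mvmr_fit",
    "mvmr_full",
    "mvmr_instrument_strength",
    "mvmr_qa",
    "attenuation_report",
]


@dataclass
class MVMRResult:
    """Direct effects of E exposures with conditional-strength statistics."""

    exposure_labels: list[str]
    k: int
    direct_beta: np.ndarray
    direct_se: np.ndarray
    p: np.ndarray
    qx: Optional[np.ndarray] = None
    qx_critical: Optional[float] = None
    qa: Optional[float] = None
    qa_critical: Optional[float] = None

    @property
    def weak_flags(self) -> np.ndarray | None:
        if self.qx is None:
            return None
        return self.qx <= self.qx_critical

    @property
    def pleiotropy_flag(self) -> bool | None:
        if self.qa is None:
            return None
        return self.qa > self.qa_critical

    def estimate(self, exposure_index: int = 0) -> MREstimate:
        return MREstimate(
            method="mvmr_direct",
            k=self.k,
            beta=float(self.direct_beta[exposure_index]),
            se=float(self.direct_se[exposure_index]),
            p=float(self.p[exposure_index]),
        )

    def to_dict(self) -> dict:
        d = {
            "exposure_labels": list(self.exposure_labels),
            "k": self.k,
            "direct_beta": self.direct_beta.tolist(),
            "direct_se": self.direct_se.tolist(),
            "p": self.p.tolist(),
        }
        if self.qx is not None:
            d["qx"] = self.qx.tolist()
            d["qx_critical"] = self.qx_critical
            d["weak_flags"] = [bool(b) for b in self.weak_flags]
        if self.qa is not None:
            d["qa"] = self.qa
            d["qa_critical"] = self.qa_critical
            d["pleiotropy_flag"] = bool(self.pleiotropy_flag)
        return d


def mvmr_fit(hset: HarmonizedInstrumentSet) -> MVMRResult:
    """Weighted least squares of beta_Y on the k x E exposure-effect matrix,
    no intercept, weights 1/se_Y^2.

    SEs carry multiplicative overdispersion scaling floored at 1 (never
    rewarding underdispersion); p-values use the normal reference.
    """
    e = hset.n_exposures
    k = hset.k
    if e < 2:
        raise ValueError("multivariable MR requires >=2 exposures")
    if k <= e:
        raise ValueError(f"need more instruments ({k}) than exposures ({e})")
    x = hset.beta_x
    if np.linalg.matrix_rank(x) < e:
        raise ValueError("collinear exposures: effect matrix is rank-deficient")
    import statsmodels.api as sm

    w = 1.0 / hset.se_y**2
    fit = sm.WLS(hset.beta_y, x, weights=w).fit()
    coef = np.asarray(fit.params)
    resid = np.asarray(fit.resid)
    qa = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(qa / (k - e)))
    cov_unscaled = np.asarray(fit.cov_params()) / fit.scale
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    p = 2.0 * stats.norm.sf(np.abs(coef / se))
    return MVMRResult(
        exposure_labels=list(hset.exposure_labels),
        k=k,
        direct_beta=coef,
        direct_se=se,
        p=p,
    )


def mvmr_instrument_strength(
    hset: HarmonizedInstrumentSet,
    allow_general: bool = False,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Conditional instrument strength Qx per exposure.

    For exposure j, the other exposures' effects are regressed out of
    beta_Xj (weights 1/se_Xj^2, no intercept) and Qx_j is the weighted
    residual sum of squares — how much independent instrument signal
    exposure j retains. Compared against the chi-square 0.95 quantile with
    k-2 df; Qx at or below the critical value flags conditionally weak
    instruments. The two-exposure setting is the designed case; pass
    ``allow_general`` for E > 2.
    """
    e = hset.n_exposures
    k = hset.k
    if e != 2 and not allow_general:
        raise ValueError("Qx is defined for exactly 2 exposures (set allow_general for E>2)")
    if k < 3:
        raise ValueError("Qx requires >=3 instruments")
    qx = np.empty(e)
    for j in range(e):
        y = hset.beta_x[:, j]
        others = np.delete(hset.beta_x, j, axis=1)
        wj = 1.0 / hset.se_x[:, j] ** 2
        xtwx = others.T @ (wj[:, None] * others)
        xtwy = others.T @ (wj * y)
        gamma = np.linalg.solve(xtwx, xtwy)
        resid = y - others @ gamma
        qx[j] = float(np.sum(wj * resid**2))
    critical = float(stats.chi2.ppf(0.95, k - 2))
    weak = qx <= critical
    return qx, critical, weak


def mvmr_qa(hset: HarmonizedInstrumentSet, fit: MVMRResult) -> tuple[float, float, bool]:
    """Residual heterogeneity Qa of the multivariable fit against the
    chi-square 0.95 quantile with k-3 df; exceeding it indicates remaining
    heterogeneity and thus potential pleiotropy even after correction."""
    resid = hset.beta_y - hset.beta_x @ fit.direct_beta
    qa = float(np.sum(resid**2 / hset.se_y**2))
    critical = float(stats.chi2.ppf(0.95, hset.k - 3))
    return qa, critical, qa > critical


def mvmr_full(hset: HarmonizedInstrumentSet, allow_general: bool = False) -> MVMRResult:
    """Fit plus Qx/Qa statistics in one result."""
    result = mvmr_fit(hset)
    try:
        qx, qx_crit, _ = mvmr_instrument_strength(hset, allow_general=allow_general)
        result.qx = qx
        result.qx_critical = qx_crit
    except ValueError:
        pass
    result.qa, result.qa_critical, _ = mvmr_qa(hset, result)
    return result


@dataclass
class AttenuationReport:
    """Total vs direct effect of one exposure after conditioning."""

    total_beta: float
    total_or: tuple[float, float, float]
    direct_beta: float
    direct_or: tuple[float, float, float]
    absolute_attenuation: float
    proportional_attenuation: Optional[float]
    ci_overlap: bool
    label: str

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def attenuation_report(
    total: MREstimate,
    direct: MVMRResult,
    exposure_index: int = 0,
) -> AttenuationReport:
    """Compare the univariable (total) and multivariable (direct) effects.

    Proportional attenuation is 1 - direct/total on the log-odds scale
    (absent when total is zero). The label is ``independent`` when the
    direct-effect CI excludes the null, ``vertical-pleiotropy-consistent``
    when the direct effect is attenuated toward the null with the same sign,
    else ``indeterminate``.
    """
    d = direct.estimate(exposure_index)
    absolute = total.beta - d.beta
    proportional = None if total.beta == 0 else 1.0 - d.beta / total.beta
    ci_overlap = not (total.ci95[0] > d.ci95[1] or d.ci95[0] > total.ci95[1])
    excludes_null = d.ci95[0] > 0 or d.ci95[1] < 0
    attenuated = (np.sign(d.beta) == np.sign(total.beta)) and abs(d.beta) < abs(total.beta)
    if excludes_null:
        label = "independent"
    elif attenuated or d.beta == 0:
        label = "vertical-pleiotropy-consistent"
    else:
        label = "indeterminate"
    return AttenuationReport(
        total_beta=total.beta,
        total_or=total.or_view,
        direct_beta=d.beta,
        direct_or=d.or_view,
        absolute_attenuation=absolute,
        proportional_attenuation=proportional,
        ci_overlap=ci_overlap,
        label=label,
    )
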