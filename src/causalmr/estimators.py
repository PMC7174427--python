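"""Univariable two-sample MR estimators.

All estimators consume a :class:`~causalmr.summary_stats.HarmonizedInstrumentSet`
and return an :class:`MREstimate` whose ``beta`` is the causal effect on the
log-odds scale per 1 SD of exposure. Per-variant Wald ratios
theta_j = beta_Y / beta_X with first-order standard errors
sigma_j = se_Y / |beta_X| are the shared meta-analytic input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from causalmr.summary_stats import HarmonizedInstrumentSet, odds_ratio_view

__all__ = [
    "RatioEstimates",
    "MREstimate",
    "wald_ratios",
    "mr_ivw",
    "mr_egger",
    "mr_weighted_median",
    "mr_weighted_mode",
    "weighted_median",
]


@dataclass
class RatioEstimates:
    """Per-variant causal ratios and their inverse-variance weights."""

    variant_ids: list[str]
    theta: np.ndarray
    sigma: np.ndarray
    exposure_index: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("ratio SEs must be positive")

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.sigma**2

    @property
    def k(self) -> int:
        return len(self.theta)


@dataclass
class MREstimate:
    """One causal-effect estimate on the log-odds-per-SD scale."""

    method: str
    k: int
    beta: float
    se: float
    p: float
    ci95: tuple[float, float] = (np.nan, np.nan)
    seed: int | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.ci95[0]):
            z = stats.norm.ppf(0.975)
            self.ci95 = (self.beta - z * self.se, self.beta + z * self.se)

    @property
    def or_view(self) -> tuple[float, float, float]:
        or_, lo, hi = np.exp(self.beta), np.exp(self.ci95[0]), np.exp(self.ci95[1])
        return float(or_), float(lo), float(hi)

    def to_dict(self) -> dict:
        or_, lo, hi = self.or_view
        return {
            "method": self.method,
            "k": self.k,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p": self.p,
            "or": or_,
            "or_low": lo,
            "or_high": hi,
            "seed": self.seed,
        }


def _xy(hset: HarmonizedInstrumentSet, exposure_index: int, orient: bool = True):
    bx = hset.beta_x[:, exposure_index].copy()
    by = hset.beta_y.copy()
    sy = hset.se_y.copy()
    if orient:
        flip = bx < 0
        bx[flip] *= -1.0
        by[flip] *= -1.0
    return bx, by, sy


def wald_ratios(
    hset: HarmonizedInstrumentSet,
    exposure_index: int = 0,
    orient: bool = True,
) -> RatioEstimates:
    """Per-variant Wald ratios theta_j = beta_Y/beta_X with first-order SEs.

    With ``orient`` each variant is flipped so beta_X > 0 (negating beta_Y in
    tandem); theta is invariant to the joint flip but MR-Egger requires the
    positive orientation.
    """
    bx = hset.beta_x[:, exposure_index]
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise ValueError(f"beta_X is zero for variant {hset.variant_ids[zero[0]]}")
    bx, by, sy = _xy(hset, exposure_index, orient)
    return RatioEstimates(
        variant_ids=list(hset.variant_ids),
        theta=by / bx,
        sigma=sy / np.abs(bx),
        exposure_index=exposure_index,
    )


def mr_ivw(
    hset: HarmonizedInstrumentSet,
    effects: str = "fixed",
    exposure_index: int = 0,
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``fixed``: se = (sum w_j)^{-1/2}. ``random``: multiplicative
    random-effects, inflating the fixed SE by max(1, sqrt(Q/(k-1))) — the
    point estimate is identical under both models. A single instrument
    degenerates to the Wald ratio.
    """
    if effects not in ("fixed", "random"):
        raise ValueError(f"effects must be fixed|random, got {effects!r}")
    ratios = wald_ratios(hset, exposure_index)
    k = ratios.k
    if k == 0:
        raise ValueError("no instruments")
    w = ratios.weight
    beta = float(np.sum(w * ratios.theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if k == 1:
        beta, se = float(ratios.theta[0]), float(ratios.sigma[0])
        p = 2.0 * stats.norm.sf(abs(beta / se))
        return MREstimate(method="wald_single", k=1, beta=beta, se=se, p=float(p))
    if effects == "fixed":
        se = se_fixed
    else:
        q = float(np.sum(w * (ratios.theta - beta) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(method=f"ivw_{effects}", k=k, beta=beta, se=se, p=float(p))


def mr_egger(
    hset: HarmonizedInstrumentSet,
    exposure_index: int = 0,
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted LS of beta_Y on beta_X with a free
    intercept, instruments oriented to beta_X > 0.

    The slope is the causal estimate under InSIDE; the intercept estimates
    the average directional pleiotropic effect. SEs carry multiplicative
    overdispersion scaling floored at 1; p-values use t with k-2 df.
    """
    k = hset.k
    if k < 3:
        raise ValueError("Egger requires >=3 instruments")
    import statsmodels.api as sm

    bx, by, sy = _xy(hset, exposure_index, orient=True)
    w = 1.0 / sy**2
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=w).fit()
    coef = np.asarray(fit.params)
    q_prime = float(np.sum(w * np.asarray(fit.resid) ** 2))
    scale = max(1.0, np.sqrt(q_prime / (k - 2)))
    # statsmodels scales the covariance by the estimated residual variance;
    # undo that and apply overdispersion scaling floored at 1
    cov_unscaled = np.asarray(fit.cov_params()) / fit.scale
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - 2)
    tcrit = stats.t.ppf(0.975, df=k - 2)
    slope = MREstimate(
        method="egger_slope",
        k=k,
        beta=float(coef[1]),
        se=float(se[1]),
        p=float(pvals[1]),
        ci95=(float(coef[1] - tcrit * se[1]), float(coef[1] + tcrit * se[1])),
        df=k - 2,
    )
    intercept = MREstimate(
        method="egger_intercept",
        k=k,
        beta=float(coef[0]),
        se=float(se[0]),
        p=float(pvals[0]),
        ci95=(float(coef[0] - tcrit * se[0]), float(coef[0] + tcrit * se[0])),
        df=k - 2,
    )
    return slope, intercept


def weighted_median(theta: np.ndarray, weight: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized
    cumulative weights p_j = (S_j - w_j/2)/S_k at probability 0.5."""
    order = np.argsort(theta)
    th = np.asarray(theta, dtype=float)[order]
    w = np.asarray(weight, dtype=float)[order]
    s = np.cumsum(w)
    p = (s - w / 2.0) / s[-1]
    return float(np.interp(0.5, p, th))


def _bootstrap_se(estimator, ratios: RatioEstimates, nboot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(
        loc=ratios.theta, scale=ratios.sigma, size=(nboot, ratios.k)
    )
    w = ratios.weight
    ests = np.array([estimator(row, w) for row in draws])
    return float(np.std(ests, ddof=1))


def mr_weighted_median(
    hset: HarmonizedInstrumentSet,
    nboot: int = 1000,
    seed: int | None = None,
    exposure_index: int = 0,
) -> MREstimate:
    """Weighted-median estimator: consistent when instruments carrying at
    least half the weight are valid. SE by seeded parametric bootstrap
    (theta_j* ~ Normal(theta_j, sigma_j))."""
    ratios = wald_ratios(hset, exposure_index)
    if ratios.k < 2:
        raise ValueError("weighted median requires >=2 instruments")
    beta = weighted_median(ratios.theta, ratios.weight)
    se = _bootstrap_se(weighted_median, ratios, nboot, seed)
    se = max(se, 1e-300)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(
        method="weighted_median", k=ratios.k, beta=beta, se=se, p=float(p), seed=seed
    )


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    m = float(np.sum(w * x))
    return float(np.sqrt(np.sum(w * (x - m) ** 2)))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    s = np.cumsum(ws)
    p = (s - ws / 2.0) / s[-1]
    return float(np.interp(q, p, xs))


def _mode_bandwidth(theta: np.ndarray, weight: np.ndarray, phi: float) -> float:
    k = len(theta)
    sd = _weighted_sd(theta, weight)
    iqr = _weighted_quantile(theta, weight, 0.75) - _weighted_quantile(theta, weight, 0.25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * k ** (-1.0 / 5.0)


def _mode_estimate(theta: np.ndarray, weight: np.ndarray, phi: float, grid_n: int = 10_000) -> float:
    h = _mode_bandwidth(theta, weight, phi)
    if h <= 0:
        return float(theta[0])

    def neg_density(x: float) -> float:
        return -float(np.sum(weight * np.exp(-0.5 * ((x - theta) / h) ** 2)))

    grid = np.linspace(theta.min(), theta.max(), grid_n)
    dens = (weight[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(
        axis=1
    )
    i = int(np.argmax(dens))
    lo = grid[max(0, i - 1)]
    hi = grid[min(grid_n - 1, i + 1)]
    if hi <= lo:
        return float(grid[i])
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_density, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    return float(res.x)


def mr_weighted_mode(
    hset: HarmonizedInstrumentSet,
    phi: float = 1.0,
    nboot: int = 1000,
    seed: int | None = None,
    exposure_index: int = 0,
) -> MREstimate:
    """Weighted mode-based estimator: the argmax of a normal-kernel weighted
    density of the Wald ratios, consistent when the largest group of
    instruments sharing a causal estimate is valid.

    Bandwidth is the weighted modified-Silverman rule
    h = phi * 0.9 * min(sd, IQR/1.349) * k^(-1/5); the argmax is located on a
    10,000-point grid then refined to 1e-8. SE by seeded parametric
    bootstrap.
    """
    ratios = wald_ratios(hset, exposure_index)
    if ratios.k < 3:
        raise ValueError("weighted mode requires >=3 instruments")
    beta = _mode_estimate(ratios.theta, ratios.weight, phi)
    se = _bootstrap_se(lambda th, w: _mode_estimate(th, w, phi, grid_n=512), ratios, nboot, seed)
    se = max(se, 1e-300)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(
        method="weighted_mode", k=ratios.k, beta=beta, se=se, p=float(p), seed=seed
    )
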