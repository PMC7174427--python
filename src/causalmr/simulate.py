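"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the structure of a two-sample MR study of a
continuous, inverse-rank-normalized behavioural exposure (effects in SD
units; for television watching 1 SD is about 1.5 h/day) against a binary
disease outcome from a large case-control meta-analysis (effects in
log-odds). Defaults mirror that setting: exposure GWAS n = 408,815 and an
outcome study of 60,801 cases among 184,305 subjects (case fraction 0.33).

Pleiotropy scenarios cover balanced and directional horizontal pleiotropy,
InSIDE violation (pleiotropic effects correlated with instrument strength),
and outlier spikes; an optional second exposure with configurable loading on
the instrument effects supports multivariable-MR and mediation scenarios.
An LD-region simulator provides fixtures for clumping, and the
inverse-rank-normalization utility reproduces the phenotype transform that
puts exposure effects on the SD scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from causalmr.instruments import LDMatrix
from causalmr.summary_stats import AssociationTable, VariantAssociation

__all__ = [
    "PleiotropyConfig",
    "SecondExposureConfig",
    "MediatorConfig",
    "SimConfig",
    "SimulatedStudy",
    "simulate_two_sample",
    "simulate_ld_region",
    "inverse_rank_normalize",
]

# non-palindromic allele pairs only, so harmonization never drops by default
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


@dataclass(frozen=True)
class PleiotropyConfig:
    """Horizontal-pleiotropy scenario for the generator.

    kinds: ``none``; ``balanced`` (alpha_j ~ N(0, sigma_alpha^2));
    ``directional`` (alpha_j ~ N(mu_alpha, sigma_alpha^2), InSIDE holds);
    ``inside_violation`` (alpha_j correlated with the instrument effect at
    correlation ``rho``); ``outliers`` (``m`` variants receive a fixed
    pleiotropic spike of ``size`` log-odds).
    """

    kind: str = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    m: int = 0
    size: float = 0.0

    def validate(self, k: int) -> None:
        if self.kind not in ("none", "balanced", "directional", "inside_violation", "outliers"):
            raise ValueError(f"unknown pleiotropy kind: {self.kind}")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.m > k or self.m < 0:
            raise ValueError("outlier count m must lie in [0, k]")


@dataclass(frozen=True)
class SecondExposureConfig:
    """A secondary exposure measured on the same instruments (MVMR).

    Instrument effects on the secondary trait are
    b2_j = loading * b_j + N(0, spread^2); the secondary trait contributes
    ``effect_on_outcome * b2_j`` log-odds to the true outcome effect. A
    nonzero loading with a nonzero outcome effect creates mediation (or
    confounding through the secondary trait), so the univariable estimate of
    exposure 1 is theta + effect_on_outcome * loading while its direct
    effect remains theta.
    """

    label: str = "secondary"
    n_sample: float = 300_000
    loading: float = 0.5
    spread: float = 0.01
    effect_on_outcome: float = 0.0


@dataclass(frozen=True)
class MediatorConfig:
    """Latent mediator: outcome truth = theta_direct*b_j +
    theta_mediator*(mediator_on_exposure_effect*b_j). The mediator is not
    emitted as a table; the implied total effect is
    theta_direct + theta_mediator*mediator_on_exposure_effect."""

    theta_direct: float
    theta_mediator: float
    mediator_on_exposure_effect: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic two-sample MR experiment."""

    k: int = 150
    n_exp: float = 408_815
    n_out: float = 184_305
    case_fraction: float = 0.33
    theta: float = 0.365
    beta_dist: float = 0.025
    maf_range: tuple[float, float] = (0.01, 0.5)
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    mediator: Optional[MediatorConfig] = None
    second_exposure: Optional[SecondExposureConfig] = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0,1)")
        if self.beta_dist < 0:
            raise ValueError("beta_dist must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_exp <= 3 or self.n_out <= 3:
            raise ValueError("sample sizes must exceed 3")
        self.pleiotropy.validate(self.k)


@dataclass
class SimulatedStudy:
    """Generated tables plus the generative truth needed to score estimators."""

    exposure_tables: list[AssociationTable]
    outcome_table: AssociationTable
    truth: dict

    @property
    def instrument_ids(self) -> list[str]:
        return [r.variant_id for r in self.exposure_tables[0].records]


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _make_table(
    label: str,
    trait_type: str,
    ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    ea: list[str],
    oa: list[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
) -> AssociationTable:
    p = _pvals(beta, se)
    recs = [
        VariantAssociation(
            variant_id=ids[j],
            chrom=int(chrom[j]),
            pos=int(pos[j]),
            effect_allele=ea[j],
            other_allele=oa[j],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(p[j]),
            n=float(n),
        )
        for j in range(len(ids))
    ]
    return AssociationTable(trait_label=label, trait_type=trait_type, records=recs)


def simulate_two_sample(config: SimConfig) -> SimulatedStudy:
    """Generate exposure and outcome summary statistics under known truth.

    Per instrument j: maf ~ U(maf_range); true effect b_j ~ N(0, beta_dist^2)
    in SD units; se_Xj = (2 maf (1-maf) n_exp)^{-1/2}; observed
    beta_Xj ~ N(b_j, se_Xj^2). The true outcome effect is theta*b_j plus the
    pleiotropic alpha_j and any secondary-exposure/mediator contribution;
    se_Yj uses the case-fraction-scaled binary approximation
    (2 maf (1-maf) n_out cf (1-cf))^{-1/2}. p-values are normal, so
    generated records satisfy the p-z consistency invariant by construction.
    """
    config.validate()
    k = config.k
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(5)]
    rng_struct, rng_x, rng_y, rng_alpha, rng_x2 = streams

    ids = [f"rs{1000 + j}" for j in range(k)]
    chrom = 1 + (np.arange(k) % 22)
    pos = 1_000_000 + (np.arange(k) // 22) * 10_000_000 + (np.arange(k) % 22) * 137
    pair_idx = rng_struct.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    maf = rng_struct.uniform(*config.maf_range, size=k)

    b = rng_struct.normal(0.0, config.beta_dist, size=k)

    # pleiotropic effects
    pl = config.pleiotropy
    alpha = np.zeros(k)
    if pl.kind == "balanced":
        alpha = rng_alpha.normal(0.0, pl.sigma_alpha, size=k)
    elif pl.kind == "directional":
        # pleiotropic shift relative to the exposure-increasing allele:
        # estimators re-orient instruments to beta_X > 0, so a shift defined
        # in the raw allele coding would average out under orientation
        alpha = np.sign(b) * rng_alpha.normal(pl.mu_alpha, pl.sigma_alpha, size=k)
    elif pl.kind == "inside_violation":
        # redraw (b, alpha) jointly with correlation rho
        z1 = rng_alpha.standard_normal(k)
        z2 = rng_alpha.standard_normal(k)
        b = config.beta_dist * z1
        alpha = pl.sigma_alpha * (pl.rho * z1 + np.sqrt(1 - pl.rho**2) * z2)
    elif pl.kind == "outliers":
        idx = rng_alpha.choice(k, size=pl.m, replace=False)
        alpha[idx] = pl.size

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    beta_x = rng_x.normal(b, se_x)

    theta_total = config.theta
    true_y = config.theta * b + alpha
    truth: dict = {
        "theta": config.theta,
        "scenario": pl.kind,
        "seed": config.seed,
        "b": b.tolist(),
        "alpha": alpha.tolist(),
    }

    if config.mediator is not None:
        med = config.mediator
        theta_total = med.theta_direct + med.theta_mediator * med.mediator_on_exposure_effect
        true_y = med.theta_direct * b + med.theta_mediator * (
            med.mediator_on_exposure_effect * b
        ) + alpha
        truth["theta_direct"] = med.theta_direct
        truth["theta_total"] = theta_total

    exposure_tables = [
        _make_table(
            config.exposure_label, "continuous", ids, chrom, pos, ea, oa, maf,
            beta_x, se_x, config.n_exp,
        )
    ]

    if config.second_exposure is not None:
        sec = config.second_exposure
        b2 = sec.loading * b + rng_x2.normal(0.0, sec.spread, size=k)
        se_x2 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * sec.n_sample)
        beta_x2 = rng_x2.normal(b2, se_x2)
        true_y = true_y + sec.effect_on_outcome * b2
        theta_total = theta_total + sec.effect_on_outcome * sec.loading
        exposure_tables.append(
            _make_table(
                sec.label, "continuous", ids, chrom, pos, ea, oa, maf,
                beta_x2, se_x2, sec.n_sample,
            )
        )
        truth["b2"] = b2.tolist()
        truth["theta_direct"] = config.theta
        truth["theta_secondary"] = sec.effect_on_outcome

    truth["theta_total"] = theta_total

    cf = config.case_fraction
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out * cf * (1.0 - cf))
    beta_y = rng_y.normal(true_y, se_y)
    outcome_table = _make_table(
        config.outcome_label, "binary", ids, chrom, pos, ea, oa, maf,
        beta_y, se_y, config.n_out,
    )

    return SimulatedStudy(
        exposure_tables=exposure_tables,
        outcome_table=outcome_table,
        truth=truth,
    )


def simulate_ld_region(
    n_variants: int,
    n_causal: int,
    decay: float,
    n_samples: float,
    seed: int = 0,
    effect_size: float = 0.05,
    maf: float = 0.3,
    chrom: int = 1,
    spacing_bp: int = 50_000,
) -> tuple[LDMatrix, AssociationTable]:
    """One LD region for clumping fixtures.

    Pairwise r2(i,j) = exp(-decay*|i-j|) on variants spaced ``spacing_bp``
    apart. Causal effects of ``effect_size`` SD are placed at evenly spaced
    indices; marginal effects propagate through LD as the r-weighted sum of
    causal effects, then observation noise at the SE implied by
    ``n_samples`` is added.
    """
    if decay < 0:
        raise ValueError("decay must be >= 0")
    if n_causal > n_variants:
        raise ValueError("n_causal cannot exceed n_variants")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_variants)
    r2 = np.exp(-decay * np.abs(idx[:, None] - idx[None, :]))
    r2[r2 < 1e-300] = 0.0
    np.fill_diagonal(r2, 1.0)
    ids = [f"rs{50_000 + i}" for i in range(n_variants)]
    ld = LDMatrix(ids, r2)

    causal = np.zeros(n_variants)
    # interior placement keeps causal variants away from region edges
    causal_idx = np.linspace(0, n_variants - 1, n_causal + 2)[1:-1].round().astype(int)
    causal[causal_idx] = effect_size
    r = np.sqrt(r2)
    beta_marginal = r @ causal
    se = np.full(n_variants, 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_samples))
    beta_obs = rng.normal(beta_marginal, se)
    pos = 1_000_000 + idx * spacing_bp
    table = _make_table(
        "ld_region", "continuous", ids,
        np.full(n_variants, chrom), pos,
        ["A"] * n_variants, ["G"] * n_variants,
        np.full(n_variants, maf), beta_obs, se, n_samples,
    )
    return ld, table


def inverse_rank_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^{-1}((r - 3/8)/(n + 1/4)),
    with ties sharing the average rank. Output order matches input."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if np.all(x == x[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(x) + 0.25))
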