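"""Instrument construction and quality control.

Covers greedy LD clumping at a stringent r-squared threshold inside a wide
genomic window, locus definition around lead variants with cross-trait
merging, per-variant variance explained and F-statistics, the I2_GX
measurement-error index for MR-Egger, Steiger directionality filtering, and
list-based pleiotropy exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from causalmr.summary_stats import AssociationTable, HarmonizedInstrumentSet, VariantAssociation

__all__ = [
    "LDMatrix",
    "Locus",
    "SteigerResult",
    "InstrumentStrength",
    "ld_clump",
    "define_loci",
    "merge_cross_trait_loci",
    "variant_r2",
    "f_statistic",
    "WEAK_F_THRESHOLD",
    "i2_gx",
    "steiger_filter",
    "exclude_pleiotropic",
    "read_ld_matrix",
    "read_exclusion_table",
    "write_loci_bed",
]

#: F at or below this value flags a weak instrument
WEAK_F_THRESHOLD = 10.0

#: I2_GX below this fraction flags measurement-error risk in MR-Egger
I2GX_SAFE_THRESHOLD = 0.95


@dataclass
class LDMatrix:
    """Squared-correlation matrix between variants, unit diagonal."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if len(set(self.variant_ids)) != n:
            raise ValueError("duplicated variant ids in LD matrix")
        if self.r2.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r2.shape} != ({n},{n})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r2 entries must lie in [0,1]")
        self._idx = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._idx[a], self._idx[b]])
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} not in LD matrix") from None

    def __contains__(self, vid: str) -> bool:
        return vid in self._idx


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix: square TSV with an id header row, or long-format
    (id_i, id_j, r2) three-column TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 3 and set(map(str.lower, df.columns)) >= {"r2"}:
        ids = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in df.itertuples(index=False):
            mat[idx[a], idx[b]] = r2
            mat[idx[b], idx[a]] = r2
        return LDMatrix(ids, mat)
    ids = [str(c) for c in df.columns]
    return LDMatrix(ids, df.to_numpy(dtype=float))


@dataclass
class Locus:
    """A genomic region of ``flank`` bp either side of a lead variant."""

    lead: VariantAssociation
    flank: int = 1_000_000
    traits: set[str] = field(default_factory=set)

    @property
    def chrom(self) -> int:
        return self.lead.chrom

    @property
    def start(self) -> int:
        return max(1, self.lead.pos - self.flank)

    @property
    def end(self) -> int:
        return self.lead.pos + self.flank


@dataclass
class SteigerResult:
    """Directionality test for one variant."""

    variant_id: str
    r2_exposure: float
    r2_outcome: float
    z: float
    p: float
    keep: bool


@dataclass
class InstrumentStrength:
    """Per-variant and set-level instrument strength for one exposure."""

    variant_ids: list[str]
    r2: np.ndarray
    f: np.ndarray
    total_r2: float
    q_gx: float
    i2_gx: float
    k: int

    @property
    def weak_flags(self) -> np.ndarray:
        return self.f <= WEAK_F_THRESHOLD

    @property
    def i2_gx_safe(self) -> bool:
        return self.i2_gx > I2GX_SAFE_THRESHOLD


def ld_clump(
    table: AssociationTable,
    ld: LDMatrix,
    p_threshold: float = 1e-8,
    r2_max: float = 0.005,
    window_bp: int = 5_000_000,
) -> list[VariantAssociation]:
    """Greedy LD clumping into independently associated lead variants.

    Repeatedly take the most significant unremoved variant below
    ``p_threshold`` (ties broken by chrom, then pos, then id), emit it as a
    lead, and remove every variant with r2 >= ``r2_max`` within
    ``window_bp`` of it on the same chromosome. Sub-threshold variants
    never become leads and never suppress leads.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    candidates = [r for r in table.records if r.pval < p_threshold]
    missing = [r.variant_id for r in candidates if r.variant_id not in ld]
    if missing:
        raise KeyError(f"clumping candidates missing from LD matrix: {missing[:5]}")
    candidates.sort(key=lambda r: (r.pval, r.chrom, r.pos, r.variant_id))
    removed: set[str] = set()
    leads: list[VariantAssociation] = []
    for rec in candidates:
        if rec.variant_id in removed:
            continue
        leads.append(rec)
        for other in candidates:
            if other.variant_id in removed or other.variant_id == rec.variant_id:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            if ld.lookup(rec.variant_id, other.variant_id) >= r2_max:
                removed.add(other.variant_id)
        removed.add(rec.variant_id)
    return leads


def _collapse(loci: list[Locus], max_gap: int, transitive: bool) -> list[Locus]:
    """Merge same-chromosome loci whose leads are within ``max_gap`` bp.

    Transitive mode closes chains (order-invariant); single-pass mode does
    one sweep over p-sorted loci.
    """
    by_key = sorted(loci, key=lambda l: (l.lead.pval, l.chrom, l.lead.pos, l.lead.variant_id))
    if transitive:
        # union-find over the pairwise-proximity graph
        parent = list(range(len(by_key)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(by_key)):
            for j in range(i + 1, len(by_key)):
                a, b = by_key[i], by_key[j]
                if a.chrom == b.chrom and abs(a.lead.pos - b.lead.pos) <= max_gap:
                    parent[find(j)] = find(i)
        groups: dict[int, list[Locus]] = {}
        for i, loc in enumerate(by_key):
            groups.setdefault(find(i), []).append(loc)
        merged = []
        for members in groups.values():
            best = min(members, key=lambda l: (l.lead.pval, l.lead.variant_id))
            traits = set().union(*(m.traits for m in members))
            merged.append(Locus(lead=best.lead, flank=best.flank, traits=traits))
    else:
        merged = []
        for loc in by_key:
            host = next(
                (
                    m
                    for m in merged
                    if m.chrom == loc.chrom and abs(m.lead.pos - loc.lead.pos) <= max_gap
                ),
                None,
            )
            if host is None:
                merged.append(Locus(lead=loc.lead, flank=loc.flank, traits=set(loc.traits)))
            else:
                host.traits |= loc.traits
    merged.sort(key=lambda l: (l.chrom, l.lead.pos, l.lead.variant_id))
    return merged


def define_loci(
    leads: Sequence[VariantAssociation],
    flank: int = 1_000_000,
    trait: str = "",
    transitive: bool = True,
) -> list[Locus]:
    """One locus of ±``flank`` bp per lead; overlapping same-trait loci on a
    chromosome collapse to the most significant lead."""
    if not leads:
        raise ValueError("leads must be nonempty")
    loci = [Locus(lead=l, flank=flank, traits={trait} if trait else set()) for l in leads]
    # loci overlap when their leads are within 2*flank
    return _collapse(loci, max_gap=2 * flank, transitive=transitive)


def merge_cross_trait_loci(
    locus_sets: Mapping[str, list[Locus]],
    flank: int = 1_000_000,
    transitive: bool = True,
) -> list[Locus]:
    """Pool per-trait loci; leads within ``flank`` bp on a chromosome merge,
    keeping the smallest-p lead and the union of trait labels."""
    if not locus_sets:
        raise ValueError("need at least one trait")
    pooled = []
    for trait, loci in locus_sets.items():
        for loc in loci:
            pooled.append(Locus(lead=loc.lead, flank=loc.flank, traits=loc.traits | {trait}))
    return _collapse(pooled, max_gap=flank, transitive=transitive)


def variant_r2(assoc: VariantAssociation, method: str = "t_stat") -> float:
    """Proportion of trait variance explained by one variant.

    ``eaf_beta``: 2*eaf*(1-eaf)*beta^2, valid for a continuous trait whose
    beta is in SD units. ``t_stat``: t^2/(t^2+n-2) with t = beta/se, usable
    for any trait on the observed scale.
    """
    if method == "eaf_beta":
        r2 = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2
    elif method == "t_stat":
        if assoc.n <= 2:
            raise ValueError("t_stat method needs n > 2")
        t = assoc.beta / assoc.se
        r2 = t * t / (t * t + assoc.n - 2.0)
    else:
        raise ValueError(f"unknown method: {method}")
    return float(np.clip(r2, 0.0, 1.0 - 1e-12))


def _r2_from_arrays(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    t2 = (beta / se) ** 2
    return np.clip(t2 / (t2 + n - 2.0), 0.0, 1.0 - 1e-12)


def f_statistic(r2: float, n: float) -> float:
    """Instrument F-statistic, F = R^2 (n-2) / (1 - R^2).

    Values at or below :data:`WEAK_F_THRESHOLD` (10) indicate weak-instrument
    risk.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return float(r2 * (n - 2.0) / (1.0 - r2))


def i2_gx(hset: HarmonizedInstrumentSet, exposure_index: int = 0) -> InstrumentStrength:
    """Measurement-error index for MR-Egger plus per-variant strength.

    I2_GX = max(0, (Q_GX - (k-1))/Q_GX) where Q_GX is the Cochran statistic
    of the SNP-exposure effects themselves; above 0.95 the NO-Measurement-
    Error assumption is considered safe.
    """
    k = hset.k
    if k < 2:
        raise ValueError("I2_GX requires at least 2 instruments")
    bx = hset.beta_x[:, exposure_index]
    sx = hset.se_x[:, exposure_index]
    nx = hset.n_x[:, exposure_index]
    w = 1.0 / sx**2
    m = float(np.sum(w * bx) / np.sum(w))
    q_gx = float(np.sum(w * (bx - m) ** 2))
    i2 = max(0.0, (q_gx - (k - 1)) / q_gx) if q_gx > 0 else 0.0
    r2 = _r2_from_arrays(bx, sx, nx)
    f = r2 * (nx - 2.0) / (1.0 - r2)
    total = float(np.sum(r2))
    if total > 1.0:
        import warnings

        warnings.warn(f"summed per-variant r2 = {total:.3f} exceeds 1", stacklevel=2)
    return InstrumentStrength(
        variant_ids=list(hset.variant_ids),
        r2=r2,
        f=f,
        total_r2=total,
        q_gx=q_gx,
        i2_gx=float(i2),
        k=k,
    )


def steiger_filter(
    hset: HarmonizedInstrumentSet,
    alpha: float = 0.05,
    exposure_index: int = 0,
) -> tuple[HarmonizedInstrumentSet, list[SteigerResult]]:
    """Remove instruments explaining significantly more outcome than exposure
    variance (reverse-causation guard).

    Per-variant r2 uses the t-statistic approximation on each study's
    observed scale; |r| values are compared with a Fisher-z two-sample test
    (the two GWAS are non-overlapping, so samples are independent). A variant
    is removed only when r2_outcome > r2_exposure with two-sided p < alpha.
    """
    bx = hset.beta_x[:, exposure_index]
    sx = hset.se_x[:, exposure_index]
    nx = hset.n_x[:, exposure_index]
    r2_x = _r2_from_arrays(bx, sx, nx)
    r2_y = _r2_from_arrays(hset.beta_y, hset.se_y, hset.n_y)
    zx = np.arctanh(np.sqrt(r2_x))
    zy = np.arctanh(np.sqrt(r2_y))
    se_diff = np.sqrt(1.0 / (nx - 3.0) + 1.0 / (hset.n_y - 3.0))
    z = (zy - zx) / se_diff
    p = 2.0 * stats.norm.sf(np.abs(z))
    keep = ~((r2_y > r2_x) & (p < alpha))
    results = [
        SteigerResult(
            variant_id=vid,
            r2_exposure=float(r2_x[i]),
            r2_outcome=float(r2_y[i]),
            z=float(z[i]),
            p=float(p[i]),
            keep=bool(keep[i]),
        )
        for i, vid in enumerate(hset.variant_ids)
    ]
    filtered = hset.subset(keep, "steiger_removed")
    if filtered.k == 0:
        raise ValueError("Steiger filtering removed every instrument")
    return filtered, results


def read_exclusion_table(path) -> pd.DataFrame:
    """Two-column TSV (variant_id, trait) of known pleiotropic associations."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("exclusion table needs (variant_id, trait) columns")
    df.columns = ["variant_id", "trait"] + list(df.columns[2:])
    return df[["variant_id", "trait"]]


def exclude_pleiotropic(
    hset: HarmonizedInstrumentSet,
    exclusion: pd.DataFrame | Iterable[tuple[str, str]],
    ld: LDMatrix | None = None,
    r2_proxy: float = 0.8,
    traits: set[str] | str = "all",
) -> HarmonizedInstrumentSet:
    """Drop instruments listed in a pleiotropy exclusion table.

    ``traits`` restricts the exclusion to listed trait labels (e.g. only
    education) or ``"all"``. With an LD matrix, unlisted instruments in LD
    above ``r2_proxy`` with a listed variant are dropped too.
    """
    if not isinstance(exclusion, pd.DataFrame):
        exclusion = pd.DataFrame(list(exclusion), columns=["variant_id", "trait"])
    if len(exclusion) == 0:
        return hset
    if traits != "all":
        exclusion = exclusion[exclusion["trait"].isin(set(traits))]
    listed = set(exclusion["variant_id"])
    to_drop = set()
    for vid in hset.variant_ids:
        if vid in listed:
            to_drop.add(vid)
        elif ld is not None and vid in ld:
            for lv in listed:
                if lv in ld and ld.lookup(vid, lv) > r2_proxy:
                    to_drop.add(vid)
                    break
    if not to_drop:
        return hset
    return hset.drop_ids(to_drop, "pleiotropy_excluded")


def write_loci_bed(loci: Sequence[Locus], path) -> None:
    """Write loci as BED-like TSV (0-based half-open on output only)."""
    rows = [
        {
            "chrom": loc.chrom,
            "start": loc.start - 1,
            "end": loc.end,
            "lead_id": loc.lead.variant_id,
            "lead_p": loc.lead.pval,
            "traits": ",".join(sorted(loc.traits)),
        }
        for loc in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
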