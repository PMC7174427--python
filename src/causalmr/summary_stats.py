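"""GWAS summary-statistics data model, I/O, and allele harmonization.

The unit of exchange is the :class:`AssociationTable`: per-variant effect
estimates for one trait. Continuous traits carry effects in SD units of the
(inverse-rank-normalized) phenotype; binary traits carry log-odds. The
:func:`harmonize` step aligns one or more exposure tables and an outcome
table onto a common effect allele per variant, producing the
:class:`HarmonizedInstrumentSet` consumed by every estimator.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssociation",
    "AssociationTable",
    "HarmonizedInstrumentSet",
    "LoadReport",
    "read_association_table",
    "write_association_table",
    "harmonize",
    "odds_ratio_view",
    "CANONICAL_COLUMNS",
]

#: canonical on-disk column names, in canonical order
CANONICAL_COLUMNS: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = frozenset("ACGT")

#: eaf window inside which a palindromic variant's strand cannot be inferred
AMBIGUITY_WINDOW = (0.42, 0.58)


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(allele))


def _is_palindromic(ea: str, oa: str) -> bool:
    # indels are never treated as palindromic
    if len(ea) != 1 or len(oa) != 1:
        return False
    return _COMPLEMENT.get(ea) == oa


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is in SD units for continuous traits and log-odds for binary
    traits; ``se`` is its standard error; ``eaf`` the effect-allele
    frequency; ``n`` the sample size behind the estimate.
    """

    variant_id: str
    chrom: int
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        ea, oa = self.effect_allele, self.other_allele
        if ea == oa:
            problems.append("effect_allele equals other_allele")
        if not (set(ea) <= _BASES and set(oa) <= _BASES and ea and oa):
            problems.append("alleles must be non-empty strings over {A,C,G,T}")
        if not (1 <= self.chrom <= 22):
            problems.append("chrom out of range (autosomes 1-22 only)")
        if self.pos < 1:
            problems.append("pos must be >= 1")
        if not (0.0 < self.eaf < 1.0):
            problems.append("eaf out of range")
        if not (self.se > 0):
            problems.append("se must be > 0")
        if not (0.0 < self.pval <= 1.0):
            problems.append("pval out of range")
        if not (self.n > 0):
            problems.append("n must be > 0")
        return problems

    def check_p_z_consistency(self, tol_log10: float = 0.5) -> bool:
        """Warn (never error) when the p-value disagrees with 2*Phi(-|beta/se|).

        Published tables round betas, SEs and p-values heavily; a mismatch of
        up to ``tol_log10`` orders of magnitude is tolerated silently.
        """
        if self.se <= 0 or not (0 < self.pval <= 1):
            return False
        p_implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if p_implied <= 0:
            return True
        ratio = abs(math.log10(self.pval) - math.log10(p_implied))
        if ratio > tol_log10:
            warnings.warn(
                f"{self.variant_id}: reported p={self.pval:.3g} disagrees with "
                f"z-implied p={p_implied:.3g} (|dlog10|={ratio:.2f})",
                stacklevel=2,
            )
            return False
        return True

    @property
    def is_palindromic(self) -> bool:
        return _is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class AssociationTable:
    """Per-variant GWAS summary statistics for one trait."""

    trait_label: str
    trait_type: str  # "continuous" or "binary"
    records: list[VariantAssociation] = field(default_factory=list)
    build_tag: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated variant_id in table: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return (
            self.trait_label == other.trait_label
            and self.trait_type == other.trait_type
            and self.build_tag == other.build_tag
            and self.records == other.records
        )

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        idx = getattr(self, "_idx", None)
        if idx is None or len(idx) != len(self.records):
            idx = {r.variant_id: r for r in self.records}
            object.__setattr__(self, "_idx", idx)
        return idx

    def sorted(self) -> "AssociationTable":
        recs = sorted(self.records, key=lambda r: (r.chrom, r.pos, r.variant_id))
        return dataclasses.replace(self, records=recs)

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return df.rename(columns=CANONICAL_COLUMNS)


@dataclass
class LoadReport:
    """Accounting of a table load: rows read, kept, and rejected."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def rows_dropped(self) -> int:
        return len(self.dropped)


class FormatError(ValueError):
    """Structural problem with a summary-statistics file."""


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_association_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    trait_label: str = "",
    trait_type: str = "continuous",
    build_tag: str = "GRCh37",
    sep: str | None = None,
    check_p_z: bool = True,
) -> tuple[AssociationTable, LoadReport]:
    """Load summary statistics from a TSV/CSV file (optionally gzipped).

    ``dialect`` maps the nine required logical fields (``variant_id``,
    ``chrom``, ``pos``, ``effect_allele``, ``other_allele``, ``eaf``,
    ``beta``, ``se``, ``pval``, ``n``) to the file's column names; defaults
    to the canonical SNP/CHR/BP/EA/OA/EAF/BETA/SE/P/N header. Rows violating
    a record invariant are dropped with a row-indexed reason in the returned
    :class:`LoadReport`.
    """
    mapping = dict(CANONICAL_COLUMNS)
    if dialect:
        mapping.update(dialect)

    with _open_text(path) as fh:
        head = fh.readline()
    if not head.strip():
        raise FormatError(f"empty file: {path}")
    if sep is None:
        sep = "," if ("," in head and "\t" not in head) else "\t"

    df = pd.read_csv(path, sep=sep, dtype=str)
    for logical, col in mapping.items():
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")

    report = LoadReport(rows_read=len(df))
    records: list[VariantAssociation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            rec = VariantAssociation(
                variant_id=str(row_d[mapping["variant_id"]]).strip(),
                chrom=int(float(row_d[mapping["chrom"]])),
                pos=int(float(row_d[mapping["pos"]])),
                effect_allele=str(row_d[mapping["effect_allele"]]).strip().upper(),
                other_allele=str(row_d[mapping["other_allele"]]).strip().upper(),
                eaf=float(row_d[mapping["eaf"]]),
                beta=float(row_d[mapping["beta"]]),
                se=float(row_d[mapping["se"]]),
                pval=float(row_d[mapping["pval"]]),
                n=float(row_d[mapping["n"]]),
            )
        except (TypeError, ValueError) as exc:
            report.dropped.append((i, f"unparseable numeric field: {exc}"))
            continue
        problems = rec.validate()
        if problems:
            report.dropped.append((i, "; ".join(problems)))
            continue
        if check_p_z:
            rec.check_p_z_consistency()
        records.append(rec)
    report.rows_kept = len(records)
    table = AssociationTable(
        trait_label=trait_label or str(path),
        trait_type=trait_type,
        records=records,
        build_tag=build_tag,
    )
    return table, report


def write_association_table(table: AssociationTable, path) -> None:
    """Write a table as TSV with the canonical header (gzip if path ends .gz)."""
    df = table.to_frame()
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned instrument effects for E exposures and one outcome.

    Every retained variant's effects are expressed relative to the first
    exposure's effect allele. Arrays are row-aligned on ``variant_ids``;
    ``beta_x``/``se_x``/``n_x`` have shape (k, E).
    """

    exposure_labels: list[str]
    outcome_label: str
    variant_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray
    n_x: np.ndarray
    n_y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.n_x = np.atleast_2d(np.asarray(self.n_x, dtype=float))
        if self.beta_x.shape[0] != len(self.variant_ids):
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
            self.n_x = self.n_x.T
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        self.n_y = np.asarray(self.n_y, dtype=float)
        k = len(self.variant_ids)
        if len(set(self.variant_ids)) != k:
            raise ValueError("duplicated variant_id in harmonized set")
        retained = set(self.variant_ids)
        for vid, _ in self.dropped:
            if vid in retained:
                raise ValueError(f"variant {vid} both retained and dropped")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]

    def subset(self, keep: Sequence[bool] | np.ndarray, reason: str) -> "HarmonizedInstrumentSet":
        """Retain variants where ``keep`` is True; others appended to dropped."""
        keep = np.asarray(keep, dtype=bool)
        dropped = list(self.dropped)
        for vid, flag in zip(self.variant_ids, keep):
            if not flag:
                dropped.append((vid, reason))
        return HarmonizedInstrumentSet(
            exposure_labels=list(self.exposure_labels),
            outcome_label=self.outcome_label,
            variant_ids=[v for v, f in zip(self.variant_ids, keep) if f],
            beta_x=self.beta_x[keep],
            se_x=self.se_x[keep],
            beta_y=self.beta_y[keep],
            se_y=self.se_y[keep],
            eaf=self.eaf[keep],
            n_x=self.n_x[keep],
            n_y=self.n_y[keep],
            dropped=dropped,
        )

    def drop_ids(self, ids: Iterable[str], reason: str) -> "HarmonizedInstrumentSet":
        ids = set(ids)
        keep = np.array([v not in ids for v in self.variant_ids])
        return self.subset(keep, reason)


def _orient_to(ref: VariantAssociation, rec: VariantAssociation) -> tuple[float, float, str]:
    """Return (sign, eaf, status) aligning ``rec`` onto ``ref``'s effect allele.

    status is "ok" or "mismatch". Handles direct match, allele swap, strand
    flip (complement), and complement-swap.
    """
    ea, oa = rec.effect_allele, rec.other_allele
    if (ea, oa) == (ref.effect_allele, ref.other_allele):
        return 1.0, rec.eaf, "ok"
    if (ea, oa) == (ref.other_allele, ref.effect_allele):
        return -1.0, 1.0 - rec.eaf, "ok"
    cea, coa = _complement(ea), _complement(oa)
    if (cea, coa) == (ref.effect_allele, ref.other_allele):
        return 1.0, rec.eaf, "ok"
    if (cea, coa) == (ref.other_allele, ref.effect_allele):
        return -1.0, 1.0 - rec.eaf, "ok"
    return 0.0, rec.eaf, "mismatch"


def harmonize(
    exposures: Sequence[AssociationTable] | AssociationTable,
    outcome: AssociationTable,
    instrument_ids: Sequence[str],
    palindrome_policy: str = "drop_ambiguous",
    ambiguity_window: tuple[float, float] = AMBIGUITY_WINDOW,
) -> HarmonizedInstrumentSet:
    """Align instruments across exposure table(s) and the outcome table.

    All effects are oriented to the first exposure's effect allele per
    variant: an allele swap negates beta and complements eaf; a strand flip
    complements alleles first. Variants absent from any table are dropped
    (no proxy search), reason ``missing_outcome``. Palindromic (A/T, C/G)
    variants are handled per ``palindrome_policy``:

    - ``drop_ambiguous`` (default): drop when min(eaf, 1-eaf) falls in the
      ambiguity window in any table;
    - ``infer_by_eaf``: use allele frequency to resolve strand (flip sign
      when eaf sits on opposite sides of 0.5 across tables);
    - ``keep``: trust alleles at face value.
    """
    if isinstance(exposures, AssociationTable):
        exposures = [exposures]
    if not instrument_ids:
        raise ValueError("instrument list empty")
    if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindrome_policy: {palindrome_policy}")

    e = len(exposures)
    lo, hi = ambiguity_window
    ids, bx, sx, nx, by, sy, eaf_out, ny = [], [], [], [], [], [], [], []
    dropped: list[tuple[str, str]] = []

    for vid in instrument_ids:
        recs = [t.get(vid) for t in exposures]
        out_rec = outcome.get(vid)
        if any(r is None for r in recs) or out_rec is None:
            dropped.append((vid, "missing_outcome"))
            continue
        ref = recs[0]
        all_recs = recs + [out_rec]

        if ref.is_palindromic:
            if palindrome_policy == "drop_ambiguous":
                # ambiguous when eaf falls inside [lo, hi] in any table
                ambiguous = any(lo <= r.eaf <= hi for r in all_recs)
                if ambiguous:
                    dropped.append((vid, "palindromic_ambiguous"))
                    continue

        signs: list[float] = [1.0]
        eafs: list[float] = [ref.eaf]
        ok = True
        for r in all_recs[1:]:
            if ref.is_palindromic:
                # complement is indistinguishable from a swap; resolve by
                # alleles (keep/drop policies) or by frequency (infer_by_eaf)
                if palindrome_policy == "infer_by_eaf":
                    same_side = (r.eaf < 0.5) == (ref.eaf < 0.5)
                    sign, ef = (1.0, r.eaf) if same_side else (-1.0, 1.0 - r.eaf)
                else:
                    sign, ef, status = _orient_to(ref, r)
                    if status == "mismatch":
                        ok = False
                        break
                    # for palindromes a complement-swap looks like a direct
                    # match; face-value alleles decide
            else:
                sign, ef, status = _orient_to(ref, r)
                if status == "mismatch":
                    ok = False
                    break
            signs.append(sign)
            eafs.append(ef)
        if not ok:
            dropped.append((vid, "allele_mismatch"))
            continue

        ids.append(vid)
        bx.append([signs[i] * recs[i].beta for i in range(e)])
        sx.append([recs[i].se for i in range(e)])
        nx.append([recs[i].n for i in range(e)])
        by.append(signs[e] * out_rec.beta)
        sy.append(out_rec.se)
        ny.append(out_rec.n)
        eaf_out.append(ref.eaf)

    if not ids:
        raise ValueError("no harmonizable instruments")
    return HarmonizedInstrumentSet(
        exposure_labels=[t.trait_label for t in exposures],
        outcome_label=outcome.trait_label,
        variant_ids=ids,
        beta_x=np.array(bx, dtype=float),
        se_x=np.array(sx, dtype=float),
        beta_y=np.array(by, dtype=float),
        se_y=np.array(sy, dtype=float),
        eaf=np.array(eaf_out, dtype=float),
        n_x=np.array(nx, dtype=float),
        n_y=np.array(ny, dtype=float),
        dropped=dropped,
    )


def odds_ratio_view(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, CI_low, CI_high)."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if se < 0:
        raise ValueError("se must be >= 0")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
    )
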