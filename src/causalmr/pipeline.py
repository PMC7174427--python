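"""End-to-end orchestration of the MR decision logic.

For each exposure and each p-value threshold on the ladder the suite runs:
instrument selection (clumping when an LD matrix is supplied, otherwise the
threshold alone) -> harmonization -> strength QC (per-instrument F, I2_GX)
-> Steiger filtering -> IVW with the fixed/random decision rule -> MR-Egger
with the Rucker model-selection test -> weighted median and mode ->
MR-PRESSO -> pleiotropy-exclusion reruns -> multivariable MR per secondary
exposure (preceded by a univariable MR of the exposure on that secondary
trait) with an attenuation report. Every stage failure is recorded in its
cell without aborting the rest of the battery, and every estimate carries
its instrument count and seed.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from causalmr.summary_stats import (
    AssociationTable,
    HarmonizedInstrumentSet,
    harmonize,
    read_association_table,
)
from causalmr.instruments import (
    I2GX_SAFE_THRESHOLD,
    LDMatrix,
    exclude_pleiotropic,
    i2_gx,
    ld_clump,
    read_exclusion_table,
    read_ld_matrix,
    steiger_filter,
)
from causalmr.estimators import (
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    mr_weighted_mode,
)
from causalmr.diagnostics import mr_presso, rucker_model_selection
from causalmr.mvmr import attenuation_report, mvmr_full

__all__ = ["AnalysisManifest", "TableSpec", "run_mr_suite", "run_mr_suite_tables", "render_report"]

DEFAULT_LADDER = (1e-8, 5e-8, 1e-7, 1e-6, 1e-5)


@dataclass
class TableSpec:
    """Location and dialect of one summary-statistics table."""

    path: str
    label: str = ""
    trait_type: str = "continuous"
    dialect: Optional[dict] = None

    def load(self) -> AssociationTable:
        table, _ = read_association_table(
            self.path,
            dialect=self.dialect,
            trait_label=self.label or Path(self.path).stem,
            trait_type=self.trait_type,
        )
        return table


@dataclass
class AnalysisManifest:
    """Inputs, ladder, estimator settings and toggles for one suite run."""

    exposures: list[TableSpec]
    outcome: TableSpec
    secondary_exposures: list[TableSpec] = field(default_factory=list)
    ld_path: Optional[str] = None
    exclusion_path: Optional[str] = None
    thresholds: tuple[float, ...] = DEFAULT_LADDER
    nboot: int = 1000
    n_sim: int = 1000
    phi: float = 1.0
    seed: int = 0
    steiger: bool = True
    presso: bool = True
    education_trait: str = "years of education"
    out_dir: str = "mr_output"

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(set(self.thresholds)))

    def validate(self) -> None:
        if not self.exposures:
            raise ValueError("at least one exposure table required")
        for spec in [*self.exposures, self.outcome, *self.secondary_exposures]:
            if not Path(spec.path).exists():
                raise FileNotFoundError(spec.path)
        for extra in (self.ld_path, self.exclusion_path):
            if extra and not Path(extra).exists():
                raise FileNotFoundError(extra)

    @classmethod
    def from_file(cls, path) -> "AnalysisManifest":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw["exposures"] = [TableSpec(**s) for s in raw.get("exposures", [])]
        raw["outcome"] = TableSpec(**raw["outcome"])
        raw["secondary_exposures"] = [
            TableSpec(**s) for s in raw.get("secondary_exposures", [])
        ]
        if "thresholds" in raw:
            raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
        return cls(**raw)


def _cell_seed(root_seed: int, *parts: str) -> int:
    """Stable per-cell seed below 2^31 derived from the manifest seed."""
    digest = hashlib.sha256(("|".join(map(str, parts))).encode()).digest()
    return (root_seed * 1_000_003 + int.from_bytes(digest[:4], "big")) % (2**31)


def _guard(cell: dict, key: str, fn):
    """Run one stage; on failure record the error in the cell and move on."""
    try:
        cell[key] = fn()
        return cell[key]
    except Exception as exc:  # per-cell error isolation
        cell.setdefault("errors", {})[key] = f"{type(exc).__name__}: {exc}"
        return None


def _analyze_cell(
    exposure: AssociationTable,
    outcome: AssociationTable,
    threshold: float,
    *,
    ld: Optional[LDMatrix],
    exclusion: Optional[pd.DataFrame],
    secondary_tables: Sequence[AssociationTable],
    nboot: int,
    n_sim: int,
    phi: float,
    seed: int,
    steiger: bool,
    presso: bool,
    education_trait: str,
) -> dict:
    cell: dict = {"exposure": exposure.trait_label, "threshold": threshold, "seed": seed}

    if ld is not None:
        leads = ld_clump(exposure, ld, p_threshold=threshold)
        ids = [r.variant_id for r in leads]
    else:
        ids = [r.variant_id for r in exposure.records if r.pval < threshold]
    if not ids:
        cell["status"] = "insufficient instruments"
        return cell

    try:
        hset = harmonize([exposure], outcome, ids)
    except ValueError as exc:
        cell["status"] = f"insufficient instruments ({exc})"
        return cell
    cell["k_selected"] = len(ids)
    cell["k_harmonized"] = hset.k
    cell["dropped"] = list(hset.dropped)

    strength = _guard(
        cell,
        "instrument_qc",
        lambda: _qc_dict(hset),
    )

    steiger_removed = 0
    if steiger:
        def _steiger():
            nonlocal hset, steiger_removed
            filtered, results = steiger_filter(hset)
            steiger_removed = sum(1 for r in results if not r.keep)
            hset = filtered
            return {"removed": steiger_removed, "k_after": filtered.k}

        _guard(cell, "steiger", _steiger)
    cell["k_final"] = hset.k

    het = _guard(cell, "heterogeneity", lambda: rucker_model_selection(hset).to_dict())
    model = "fixed"
    if het is not None:
        model = "random" if het["heterogeneity_flag"] else "fixed"
    cell["ivw_model_decision"] = model
    _guard(cell, "ivw_fixed", lambda: mr_ivw(hset, "fixed").to_dict())
    _guard(cell, "ivw_random", lambda: mr_ivw(hset, "random").to_dict())
    cell["main_estimate"] = cell.get(f"ivw_{model}")

    def _egger():
        slope, intercept = mr_egger(hset)
        d = {"slope": slope.to_dict(), "intercept": intercept.to_dict()}
        if strength is not None and strength["i2_gx"] < I2GX_SAFE_THRESHOLD:
            d["warning"] = (
                f"I2_GX = {strength['i2_gx']:.3f} < {I2GX_SAFE_THRESHOLD}: "
                "Egger slope may be attenuated by measurement error"
            )
        return d

    _guard(cell, "egger", _egger)
    _guard(
        cell,
        "weighted_median",
        lambda: mr_weighted_median(hset, nboot=nboot, seed=_cell_seed(seed, "wm")).to_dict(),
    )
    _guard(
        cell,
        "weighted_mode",
        lambda: mr_weighted_mode(
            hset, phi=phi, nboot=nboot, seed=_cell_seed(seed, "mode")
        ).to_dict(),
    )
    if presso:
        _guard(
            cell,
            "presso",
            lambda: mr_presso(hset, n_sim=n_sim, seed=_cell_seed(seed, "presso")).to_dict(),
        )

    if exclusion is not None and len(exclusion):
        def _rerun(traits):
            sub = exclude_pleiotropic(hset, exclusion, ld=ld, traits=traits)
            d = mr_ivw(sub, model).to_dict()
            d["k_excluded"] = hset.k - sub.k
            return d

        _guard(cell, "ivw_excl_education", lambda: _rerun({education_trait}))
        _guard(cell, "ivw_excl_all_traits", lambda: _rerun("all"))

    if secondary_tables:
        cell["mvmr"] = {}
        for sec in secondary_tables:
            block: dict = {}
            cell["mvmr"][sec.trait_label] = block

            def _uni():
                # exposure -> secondary trait univariable MR; absence of this
                # association would make conditioning unnecessary
                hs = harmonize([exposure], sec, list(hset.variant_ids))
                return mr_ivw(hs, "fixed").to_dict()

            _guard(block, "exposure_on_secondary", _uni)

            def _mv():
                hs = harmonize([exposure, sec], outcome, list(hset.variant_ids))
                result = mvmr_full(hs)
                d = result.to_dict()
                total = mr_ivw(hset, model)
                d["attenuation"] = attenuation_report(total, result, 0).to_dict()
                return d

            _guard(block, "multivariable", _mv)
    return cell


def _qc_dict(hset: HarmonizedInstrumentSet) -> dict:
    s = i2_gx(hset)
    return {
        "k": s.k,
        "f_min": float(s.f.min()),
        "f_max": float(s.f.max()),
        "n_weak": int(s.weak_flags.sum()),
        "total_r2": s.total_r2,
        "i2_gx": s.i2_gx,
        "q_gx": s.q_gx,
    }


def run_mr_suite_tables(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    *,
    secondary_exposures: Sequence[AssociationTable] = (),
    ld: Optional[LDMatrix] = None,
    exclusion: Optional[pd.DataFrame] = None,
    thresholds: Sequence[float] = DEFAULT_LADDER,
    nboot: int = 1000,
    n_sim: int = 1000,
    phi: float = 1.0,
    seed: int = 0,
    steiger: bool = True,
    presso: bool = True,
    education_trait: str = "years of education",
) -> dict:
    """Run the full battery on in-memory tables; returns the report dict."""
    cells = []
    for exposure in exposures:
        for threshold in sorted(set(thresholds)):
            cell_seed = _cell_seed(seed, exposure.trait_label, f"{threshold:g}")
            cells.append(
                _analyze_cell(
                    exposure,
                    outcome,
                    threshold,
                    ld=ld,
                    exclusion=exclusion,
                    secondary_tables=secondary_exposures,
                    nboot=nboot,
                    n_sim=n_sim,
                    phi=phi,
                    seed=cell_seed,
                    steiger=steiger,
                    presso=presso,
                    education_trait=education_trait,
                )
            )
    from causalmr import __version__

    return {
        "version": __version__,
        "seed": seed,
        "outcome": outcome.trait_label,
        "thresholds": [float(t) for t in sorted(set(thresholds))],
        "cells": cells,
    }


def run_mr_suite(manifest: AnalysisManifest) -> dict:
    """Validate the manifest, load every input, and run the battery."""
    manifest.validate()
    exposures = [s.load() for s in manifest.exposures]
    outcome = manifest.outcome.load()
    secondary = [s.load() for s in manifest.secondary_exposures]
    ld = read_ld_matrix(manifest.ld_path) if manifest.ld_path else None
    exclusion = (
        read_exclusion_table(manifest.exclusion_path) if manifest.exclusion_path else None
    )
    return run_mr_suite_tables(
        exposures,
        outcome,
        secondary_exposures=secondary,
        ld=ld,
        exclusion=exclusion,
        thresholds=manifest.thresholds,
        nboot=manifest.nboot,
        n_sim=manifest.n_sim,
        phi=manifest.phi,
        seed=manifest.seed,
        steiger=manifest.steiger,
        presso=manifest.presso,
        education_trait=manifest.education_trait,
    )


_ESTIMATE_KEYS = (
    "main_estimate",
    "ivw_fixed",
    "ivw_random",
    "weighted_median",
    "weighted_mode",
    "ivw_excl_education",
    "ivw_excl_all_traits",
)


def _iter_estimates(cell: dict):
    for key in _ESTIMATE_KEYS:
        est = cell.get(key)
        if est:
            yield key, est
    egger = cell.get("egger")
    if egger:
        yield "egger_slope", egger["slope"]
        yield "egger_intercept", egger["intercept"]
    presso = cell.get("presso")
    if presso:
        yield "presso_raw", presso["raw"]
        if presso.get("corrected"):
            yield "presso_corrected", presso["corrected"]
    for label, block in (cell.get("mvmr") or {}).items():
        mv = block.get("multivariable")
        if mv:
            yield f"mvmr_direct[{label}]", {
                "method": "mvmr_direct",
                "k": mv["k"],
                "beta": mv["direct_beta"][0],
                "se": mv["direct_se"][0],
                "p": mv["p"][0],
                "or": float(np.exp(mv["direct_beta"][0])),
                "or_low": float(np.exp(mv["direct_beta"][0] - 1.959963984540054 * mv["direct_se"][0])),
                "or_high": float(np.exp(mv["direct_beta"][0] + 1.959963984540054 * mv["direct_se"][0])),
                "seed": None,
            }


def render_report(report: dict, fmt: str, out_dir) -> list[Path]:
    """Serialize a suite report.

    ``json`` (canonical), ``tsv_bundle`` (one estimate table per cell), or
    ``markdown_summary`` (method / OR / CI / p table per cell).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = out / "mr_report.json"
        path.write_text(json.dumps(report, indent=2, default=_json_default))
        written.append(path)
    elif fmt == "tsv_bundle":
        for cell in report["cells"]:
            name = f"{cell['exposure']}_p{cell['threshold']:g}".replace(" ", "_")
            rows = [
                {"analysis": key, **{k: v for k, v in est.items() if not isinstance(v, (list, dict))}}
                for key, est in _iter_estimates(cell)
            ]
            path = out / f"{name}.tsv"
            if rows:
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            else:
                path.write_text("analysis\tstatus\n-\t%s\n" % cell.get("status", "no estimates"))
            written.append(path)
    elif fmt == "markdown_summary":
        lines = [f"# MR suite report (seed {report['seed']})", ""]
        for cell in report["cells"]:
            lines.append(f"## {cell['exposure']} @ P < {cell['threshold']:g}")
            if "status" in cell:
                lines.append(f"*{cell['status']}*")
                lines.append("")
                continue
            lines.append("")
            lines.append("| method | k | OR | 95% CI | p |")
            lines.append("|---|---|---|---|---|")
            for key, est in _iter_estimates(cell):
                or_ = est.get("or", np.exp(est["beta"]))
                lo = est.get("or_low", np.nan)
                hi = est.get("or_high", np.nan)
                lines.append(
                    f"| {key} | {est['k']} | {or_:.3f} | {lo:.3f}-{hi:.3f} | {est['p']:.3g} |"
                )
            lines.append("")
        path = out / "mr_report.md"
        path.write_text("\n".join(lines))
        written.append(path)
    else:
        raise ValueError(f"unknown format: {fmt}")
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
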