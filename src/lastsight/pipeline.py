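"""Full-analysis orchestration: filters → variants → estimators → densities.

`run_full_analysis` reproduces the whole desk analysis in one call: read a
record table, optionally calibrate it against a curve, apply the age-range
filter, build the three record variants (one per choice of duplicate
determination plus the conservative subset), run all requested estimators
per variant, fit and select record-density distributions, and — when a
proxy series is supplied — correlate the averaged density with the proxy.
The report renders as a methods-by-variants TSV (the familiar table shape)
or as lossless JSON.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .calib import CalCurve, calibrate_batch
from .climate import ProxySeries, correlate, make_grid
from .density import FAMILIES, averaged_density, select_best
from .errors import LastSightError, UsageError
from .estimators import METHODS
from .model import ExtinctionModel
from .records import VARIANTS, RecordSet, apply_range_filter, read_records, select_variant

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_report", "report_from_json"]

logger = logging.getLogger(__name__)

_RESAMPLED = ("briwm", "griwm")


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    iters: int = 10_000
    seed: int = 0
    k: int | None = None
    methods: tuple = METHODS
    variants: tuple = VARIANTS
    families: tuple = FAMILIES
    grid_step: float = 20.0
    window: tuple | None = None  # (older, younger) correlation window
    recalibrate: bool = False
    range_cutoff: float = 50_500.0


@dataclass
class AnalysisReport:
    """Per-(method, variant) estimates plus density and correlation summaries."""

    rows: list = field(default_factory=list)
    density: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _method_seed(base: int, variant: str, method: str) -> int:
    # Deterministic per-cell seed; stable across runs and row order.
    h = np.random.SeedSequence(
        [base, abs(hash_stable(variant)), abs(hash_stable(method))]
    )
    return int(h.generate_state(1)[0] % (2**31))


def hash_stable(s: str) -> int:
    """Process-independent string hash (Python's hash() is salted)."""
    v = 0
    for ch in s:
        v = (v * 131 + ord(ch)) % (2**31)
    return v


def run_full_analysis(
    records,
    curve: CalCurve | None = None,
    proxy: ProxySeries | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the complete analysis; see the module docstring.

    ``records`` may be a path or a :class:`RecordSet`.  A curve is required
    only when some record lacks calibrated summaries (or when
    ``config.recalibrate`` forces curve-based recomputation).  Every
    (method × variant) failure is reported in its own cell without
    aborting the rest.
    """
    cfg = config or AnalysisConfig()
    t_start = time.perf_counter()
    rs = records if isinstance(records, RecordSet) else read_records(records)
    report = AnalysisReport()
    report.metadata = {
        "version": __version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "iters": cfg.iters,
        "k": cfg.k,
        "methods": list(cfg.methods),
        "variants": list(cfg.variants),
        "families": list(cfg.families),
        "n_input": len(rs),
    }
    if len(rs) == 0:
        report.metadata["diagnostic"] = "empty record set; nothing to estimate"
        return report

    needs_cal = any(r.cal_mean is None for r in rs)
    if needs_cal or cfg.recalibrate:
        if curve is None:
            raise UsageError("records lack calibrated summaries and no curve was given")
        rs = calibrate_batch(rs, curve)
    rs = apply_range_filter(rs, cfg.range_cutoff)

    variant_sets: dict[str, RecordSet] = {}
    for variant in cfg.variants:
        vs = select_variant(rs, variant)
        variant_sets[variant] = vs
        model = ExtinctionModel.from_records(vs)
        for method in cfg.methods:
            seed = _method_seed(cfg.seed, variant, method)
            res = model.fit(
                methods=[method], alpha=cfg.alpha, iters=cfg.iters, seed=seed, k=cfg.k
            )
            row = {"method": method, "variant": variant, "n_used": len(vs)}
            if method in res.estimates:
                e = res.estimates[method]
                row.update(
                    bound95=e.bound95,
                    median=e.median,
                    ci_lo=e.ci_lo,
                    ci_hi=e.ci_hi,
                    alpha=e.alpha,
                    settings={k_: v for k_, v in e.settings.items()},
                    flag="no extinction signal" if e.no_extinction_signal else "",
                    error=None,
                )
            else:
                row.update(
                    bound95=None, median=None, ci_lo=None, ci_hi=None,
                    alpha=cfg.alpha, settings={}, flag="", error=res.errors[method],
                )
            report.rows.append(row)

        dates = np.array([r.cal_mean for r in vs], dtype=float)
        try:
            best = select_best(dates, cfg.families)
            report.density[variant] = {
                "family": best.family,
                "params": best.params,
                "loglik": best.loglik,
                "aic": best.aic,
                "bic": best.bic,
                "n": best.n,
                "error": None,
            }
        except LastSightError as exc:
            report.density[variant] = {"error": f"{type(exc).__name__}: {exc}"}

    # Averaged density over the two duplicate-date variants, then proxy
    # correlation on the evaluation grid.
    if {"include_poz", "include_gda"} <= set(variant_sets):
        da = np.array([r.cal_mean for r in variant_sets["include_poz"]], float)
        db = np.array([r.cal_mean for r in variant_sets["include_gda"]], float)
        all_dates = np.array([r.cal_mean for r in rs], float)
        older = float(all_dates.max() + 4 * np.std(all_dates))
        younger = max(0.0, float(all_dates.min() - 4 * np.std(all_dates)))
        grid = make_grid(older, younger, cfg.grid_step)
        try:
            dens = averaged_density(da, db, "lognormal", grid)
            report.density["averaged"] = {
                "family": "lognormal",
                "grid_older": older,
                "grid_younger": younger,
                "grid_step": cfg.grid_step,
                "argmax": float(grid[int(np.argmax(dens))]),
                "error": None,
            }
            if proxy is not None:
                window = cfg.window or (older, younger)
                cgrid = make_grid(window[0], window[1], cfg.grid_step)
                cdens = averaged_density(da, db, "lognormal", cgrid)
                cr = correlate(cgrid, cdens, proxy, window)
                report.correlations.append(
                    {"r": cr.r, "n": cr.n, "p": cr.p, "window": list(cr.window)}
                )
        except LastSightError as exc:
            report.density["averaged"] = {"error": f"{type(exc).__name__}: {exc}"}

    report.metadata["provenance"] = rs.provenance
    logger.info(
        "analysis finished in %.2f s (%d cells)",
        time.perf_counter() - t_start,
        len(report.rows),
    )
    return report


def _fmt_cell(row: dict) -> str:
    if row.get("error"):
        return "failed"
    if row["method"] in _RESAMPLED:
        return f"{row['median']:,.0f} ({row['ci_hi']:,.0f}–{row['ci_lo']:,.0f})"
    return f"{row['bound95']:,.0f}"


def render_report(rep: AnalysisReport, format: str = "tsv") -> str:
    """Render the report: methods-as-rows TSV or lossless JSON."""
    if format == "json":
        return json.dumps(asdict(rep), indent=2, sort_keys=True)
    if format != "tsv":
        raise UsageError(f"unknown format {format!r}; expected 'tsv' or 'json'")
    variants = list(dict.fromkeys(r["variant"] for r in rep.rows))
    methods = list(dict.fromkeys(r["method"] for r in rep.rows))
    cells = {(r["method"], r["variant"]): _fmt_cell(r) for r in rep.rows}
    lines = ["\t".join(["method"] + variants)]
    for m in methods:
        lines.append("\t".join([m] + [cells.get((m, v), "") for v in variants]))
    return "\n".join(lines) + "\n"


def report_from_json(text: str) -> AnalysisReport:
    """Rebuild an :class:`AnalysisReport` from its JSON rendering."""
    d = json.loads(text)
    return AnalysisReport(
        rows=d["rows"],
        density=d["density"],
        correlations=d["correlations"],
        metadata=d["metadata"],
    )
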