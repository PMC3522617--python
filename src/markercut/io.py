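"""Table ingestion, run configuration and the result bundle.

Input is a tab-separated table with a header row, rows = patients,
columns = variables. Soft size limits of 5000 rows x 50 columns are
enforced by default (historical limits of the original web workflow,
overridable). A run dispatches to the configured cutoff method and
writes a file bundle:

* ``results.json`` — selected cutoff, method, at-cutoff statistics,
  robustness diagnostics;
* ``scan.tsv``     — per-candidate-cutoff effect sizes, CIs, p-values;
* ``plots/``       — requested figures;
* ``run.log``      — seed, version, dropped-row accounting, warnings.

Two runs with the same configuration and seed produce byte-identical
``results.json`` and ``scan.tsv`` (timestamps only appear in the log).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .binary import (
    auto_orientation,
    binary_scan,
    constrained_cutoff,
    confusion_at,
    equivocal_zone,
    fisher_p,
    odds_ratio,
    optimize_binary_significance,
    optimize_roc,
    proportion_significant,
    roc_curve,
    wilson_ci,
)
from .dataset import CandidateGrid, CutoffResult, MarkerDataset, candidate_cutoffs
from .mixture import fit_mixture, mixture_cutoff
from .survival import cox_hr, logrank_p, optimize_survival_significance, survival_scan
from . import plots as _plots

__all__ = ["RunConfig", "RunResult", "load_table", "build_dataset", "run"]

MAX_ROWS = 5000
MAX_COLS = 50

METHODS = (
    "mixture",
    "binary_significance",
    "roc_euclidean",
    "roc_manhattan",
    "min_sensitivity",
    "min_specificity",
    "survival_significance",
    "manual",
)

_BINARY_METHODS = {"binary_significance", "roc_euclidean", "roc_manhattan", "min_sensitivity", "min_specificity"}


def load_table(path, no_limits: bool = False) -> pd.DataFrame:
    """Read a tab-separated patient table, enforcing the soft size limits."""
    df = pd.read_csv(path, sep="\t")
    if not no_limits:
        if len(df) > MAX_ROWS:
            raise ValueError(
                f"table has {len(df)} rows, above the {MAX_ROWS}-row limit (use no_limits to override)"
            )
        if df.shape[1] > MAX_COLS:
            raise ValueError(
                f"table has {df.shape[1]} columns, above the {MAX_COLS}-column limit (use no_limits to override)"
            )
    return df


def _numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based incl. header
        raise ValueError(f"column {name!r} has non-numeric values in file rows {rows[:20]}")
    return out


def build_dataset(
    df: pd.DataFrame,
    marker: str,
    outcome: Optional[str] = None,
    positive_level: Optional[str] = None,
    time: Optional[str] = None,
    event: Optional[str] = None,
    id_column: Optional[str] = None,
) -> tuple[MarkerDataset, dict]:
    """Build a MarkerDataset from named columns, dropping incomplete rows.

    Rows missing the marker are dropped; rows missing the outcome or the
    survival pair are dropped only when those variables are requested.
    Returns the dataset plus a per-column dropped-row accounting. When no
    positive outcome level is named, the lexicographically/numerically
    larger observed level is used (reported in the accounting).
    """
    for col in filter(None, (marker, outcome, time, event, id_column)):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in table")
    report: dict = {"n_input": int(len(df))}
    m = _numeric(df[marker], marker)
    keep = m.notna()
    report["dropped_missing_marker"] = int((~keep).sum())
    if outcome is not None:
        keep_o = df[outcome].notna()
        report["dropped_missing_outcome"] = int((keep & ~keep_o).sum())
        keep &= keep_o
    if time is not None:
        if event is None:
            raise ValueError("time column given without event column")
        keep_s = df[time].notna() & df[event].notna()
        report["dropped_missing_survival"] = int((keep & ~keep_s).sum())
        keep &= keep_s
    sub = df.loc[keep]
    report["n_used"] = int(len(sub))

    outcome_arr = None
    if outcome is not None:
        levels = sorted(sub[outcome].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"outcome column {outcome!r} has {len(levels)} observed levels, need 2")
        if positive_level is None:
            positive_level = levels[-1]
            report["positive_level_assumed"] = positive_level
        elif positive_level not in levels:
            raise ValueError(f"positive level {positive_level!r} not among observed levels {levels}")
        report["positive_level"] = positive_level
        outcome_arr = (sub[outcome].astype(str) == positive_level).to_numpy()

    time_arr = event_arr = None
    if time is not None:
        time_arr = _numeric(sub[time], time).to_numpy()
        event_arr = _numeric(sub[event], event).to_numpy().astype(int)

    ds = MarkerDataset(
        marker=m[keep].to_numpy(),
        outcome=outcome_arr,
        time=time_arr,
        event=event_arr,
        ids=sub[id_column].to_numpy() if id_column else None,
    )
    return ds, report


@dataclass
class RunConfig:
    """Everything one cutoff analysis needs; validated before computation."""

    input: str | Path
    marker: str
    method: str
    outcome: Optional[str] = None
    positive_level: Optional[str] = None
    time: Optional[str] = None
    event: Optional[str] = None
    id_column: Optional[str] = None
    manual_value: Optional[float] = None
    threshold: float = 0.9
    orientation: str = "auto"
    min_group: int = 1
    alpha: float = 0.05
    seed: int = 0
    plots: tuple[str, ...] = ()
    out_dir: str | Path = "markercut_out"
    no_limits: bool = False

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method in _BINARY_METHODS and self.outcome is None:
            raise ValueError(f"method {self.method!r} requires an outcome column")
        if self.method == "survival_significance" and (self.time is None or self.event is None):
            raise ValueError("method 'survival_significance' requires time and event columns")
        if self.method == "manual" and self.manual_value is None:
            raise ValueError("method 'manual' requires a cutoff value")
        if self.method in ("min_sensitivity", "min_specificity") and not 0 < self.threshold < 1:
            raise ValueError("constrained methods need a threshold in (0, 1)")
        if self.orientation not in ("auto", "high_positive", "low_positive"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for kind in self.plots:
            if kind not in _plots.PLOT_KINDS:
                raise ValueError(f"unknown plot kind {kind!r}")


@dataclass
class RunResult:
    """In-memory view of the written bundle."""

    cutoff_result: CutoffResult
    scan_table: pd.DataFrame
    summary: dict
    out_dir: Path
    log_lines: list[str] = field(default_factory=list)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else ("inf" if v > 0 else "-inf" if v < 0 else "nan")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    return obj


def run(config: RunConfig) -> RunResult:
    """Execute one configured cutoff analysis and write the file bundle."""
    config.validate()
    log: list[str] = [
        f"markercut {__version__}",
        f"method={config.method} seed={config.seed} min_group={config.min_group} alpha={config.alpha}",
    ]
    df = load_table(config.input, no_limits=config.no_limits)
    ds, report = build_dataset(
        df,
        marker=config.marker,
        outcome=config.outcome,
        positive_level=config.positive_level,
        time=config.time,
        event=config.event,
        id_column=config.id_column,
    )
    log.append(f"rows: {report}")

    orientation = config.orientation
    if ds.has_outcome and orientation == "auto":
        orientation = auto_orientation(ds)
        log.append(f"orientation resolved to {orientation} (empirical AUC >= 0.5)")

    grid = candidate_cutoffs(ds, config.min_group)
    log.append(f"candidate grid: {len(grid)} cutoffs")

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        result, bscan, sscan, mixfit = _dispatch(config, ds, grid, orientation)
        caught = sorted({str(w.message) for w in wrec})
    for msg in caught:
        log.append(f"warning: {msg}")

    # assemble the per-candidate scan table from whichever scans exist
    frames = []
    if bscan is not None:
        frames.append(bscan.to_frame())
    if sscan is not None:
        frames.append(sscan.to_frame())
    if frames:
        scan_table = frames[0]
        for other in frames[1:]:
            scan_table = scan_table.merge(other, on="cutoff", how="outer")
    else:
        scan_table = pd.DataFrame({"cutoff": grid.cutoffs})

    summary = {
        "version": __version__,
        "method": config.method,
        "seed": config.seed,
        "cutoff": result.cutoff,
        "orientation": orientation if ds.has_outcome else None,
        "min_group": config.min_group,
        "n_candidates": len(grid),
        "rows": report,
        "statistics": result.statistics,
        "warnings": result.warnings + caught,
    }
    if bscan is not None:
        summary["proportion_significant_binary"] = proportion_significant(bscan, config.alpha)
    if sscan is not None:
        summary["proportion_significant_survival"] = proportion_significant(sscan, config.alpha)
    if mixfit is not None:
        summary["mixture_fit"] = {
            "pi": [mixfit.pi1, mixfit.pi2],
            "mu": [mixfit.mu1, mixfit.mu2],
            "sigma": [mixfit.sigma1, mixfit.sigma2],
            "loglik": mixfit.loglik,
            "n_iter": mixfit.n_iter,
            "converged": mixfit.converged,
        }

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan_table.to_csv(out_dir / "scan.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out_dir / "results.json", "w") as fh:
        json.dump(_json_safe(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.plots:
        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        written = _make_plots(config.plots, plot_dir, ds, grid, orientation, result, bscan, sscan, mixfit)
        log.extend(f"plot: {p}" for p in written)

    log.append(f"finished {datetime.now().isoformat(timespec='seconds')}")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return RunResult(
        cutoff_result=result, scan_table=scan_table, summary=summary, out_dir=out_dir, log_lines=log
    )


def _at_cutoff_statistics(ds: MarkerDataset, cutoff: float, orientation: str, alpha: float) -> dict:
    """Cross-domain statistics at one fixed cutoff (used by mixture/manual/ROC)."""
    stats: dict = {}
    if ds.has_outcome:
        t = confusion_at(ds, cutoff, orientation)
        or_, lo, hi, p_wald, corrected = odds_ratio(t)
        stats.update(
            odds_ratio=or_,
            or_ci=(lo, hi),
            or_zero_cell_corrected=corrected,
            fisher_p=fisher_p(t),
            sensitivity=t.sensitivity,
            sens_ci=wilson_ci(t.tp, t.tp + t.fn) if t.tp + t.fn else None,
            specificity=t.specificity,
            spec_ci=wilson_ci(t.tn, t.tn + t.fp) if t.tn + t.fp else None,
        )
    if ds.has_survival:
        high = ds.marker >= cutoff
        if 0 < high.sum() < ds.n and ds.event.sum() > 0:
            fit = cox_hr(ds.time, ds.event, high)
            stats.update(
                hazard_ratio=fit.hr,
                hr_ci=(fit.ci_low, fit.ci_high),
                hr_flagged=fit.flagged,
                logrank_p=logrank_p(ds.time, ds.event, high),
            )
    return stats


def _dispatch(config: RunConfig, ds: MarkerDataset, grid: CandidateGrid, orientation: str):
    """Run the configured method; returns (result, binary_scan, survival_scan, mixture_fit)."""
    bscan = sscan = mixfit = None
    method = config.method

    if method == "mixture":
        mixfit = fit_mixture(ds, seed=config.seed)
        cut = mixture_cutoff(mixfit)
        result = CutoffResult(cutoff=cut, method="mixture")
    elif method == "binary_significance":
        result, bscan = optimize_binary_significance(ds, grid, orientation)
    elif method in ("roc_euclidean", "roc_manhattan"):
        roc = roc_curve(ds, grid, orientation)
        result = optimize_roc(roc, metric=method.removeprefix("roc_"))
    elif method in ("min_sensitivity", "min_specificity"):
        bscan = binary_scan(ds, grid, orientation)
        result = constrained_cutoff(bscan, method.removeprefix("min_"), config.threshold)
    elif method == "survival_significance":
        result, sscan = optimize_survival_significance(ds, grid)
    elif method == "manual":
        result = CutoffResult(cutoff=float(config.manual_value), method="manual")
    else:  # pragma: no cover - validated upstream
        raise ValueError(method)

    # fill scans that the chosen method did not itself produce
    if ds.has_outcome and bscan is None:
        bscan = binary_scan(ds, grid, orientation)
    if ds.has_survival and sscan is None and ds.event.sum() > 0:
        sscan = survival_scan(ds, grid)

    # complete at-cutoff statistics across all available variables
    extra = _at_cutoff_statistics(ds, result.cutoff, orientation, config.alpha)
    for key, val in extra.items():
        result.statistics.setdefault(key, val)
    return result, bscan, sscan, mixfit


def _make_plots(kinds, plot_dir: Path, ds, grid, orientation, result, bscan, sscan, mixfit):
    written = []
    cutoff = result.cutoff
    for kind in kinds:
        path = plot_dir / f"{kind}.png"
        try:
            if kind == "histogram_mixture":
                fit = mixfit if mixfit is not None else fit_mixture(ds)
                _plots.plot_histogram_mixture(ds, fit, cutoff, path)
            elif kind == "or_overview":
                _plots.plot_scan_overview(bscan, "or", ds, cutoff, path)
            elif kind == "hr_overview":
                _plots.plot_scan_overview(sscan, "hr", ds, cutoff, path)
            elif kind == "survdiff_overview":
                _plots.plot_scan_overview(sscan, "survdiff", ds, cutoff, path)
            elif kind == "roc":
                _plots.plot_roc(roc_curve(ds, grid, orientation), cutoff, path)
            elif kind == "waterfall":
                _plots.plot_waterfall(ds, cutoff, path)
            elif kind == "km":
                _plots.plot_km(ds, cutoff, path)
        except (ValueError, AttributeError, TypeError) as exc:
            warnings.warn(f"plot {kind!r} skipped: {exc}", stacklevel=2)
            continue
        written.append(str(path))
    return written
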