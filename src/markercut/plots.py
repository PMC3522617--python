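"""Diagnostic plots: overview curves across all cutoffs and at-cutoff plots.

Two families are produced. Overview plots summarize every candidate
cutoff — odds ratio, hazard ratio or RMST difference with 95% CI bands, a
vertical line at the selected cutoff, and a rug of the observed marker
values. At-cutoff plots describe one fixed dichotomization: histogram
with the fitted mixture density, ROC curve with the selected point,
waterfall of per-patient marker values, and Kaplan-Meier curves of the
two groups with the log-rank p.

Every function writes an image file (PNG/SVG by extension) when a path is
given and returns the numeric arrays it plotted, so tests can verify the
plotted data without pixel inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .binary import BinaryScan, ROCCurve
from .dataset import MarkerDataset, dichotomize
from .mixture import MixtureFit, mixture_density
from .survival import SurvivalScan, km_estimate, logrank_p

__all__ = [
    "PlotSpec",
    "plot_histogram_mixture",
    "plot_scan_overview",
    "plot_roc",
    "plot_waterfall",
    "plot_km",
]

PLOT_KINDS = (
    "histogram_mixture",
    "or_overview",
    "hr_overview",
    "survdiff_overview",
    "roc",
    "waterfall",
    "km",
)


@dataclass
class PlotSpec:
    """Request for one plot kind at an optional selected cutoff."""

    kind: str
    selected_cutoff: Optional[float] = None
    output_path: Optional[str] = None
    figsize: tuple[float, float] = (6.0, 4.5)
    dpi: int = 120

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_histogram_mixture(
    data: MarkerDataset,
    fit: MixtureFit,
    cutoff: Optional[float] = None,
    path=None,
    bins: int = 30,
    figsize=(6.0, 4.5),
) -> dict:
    """Marker histogram with the fitted mixture density and cutoff line."""
    if not fit.converged:
        raise ValueError("cannot plot a non-converged mixture fit")
    fig, ax = plt.subplots(figsize=figsize)
    counts, edges, _ = ax.hist(
        data.marker, bins=bins, density=True, color="lightgrey", edgecolor="grey"
    )
    xs = np.linspace(data.marker.min(), data.marker.max(), 400)
    dens = mixture_density(fit, xs)
    ax.plot(xs, dens, color="crimson", lw=2, label="two-Gaussian mixture")
    if cutoff is not None:
        ax.axvline(cutoff, color="black", ls="--", label=f"cutoff = {cutoff:.3g}")
    ax.set_xlabel("marker")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    _finish(fig, path)
    return {"counts": counts, "bin_edges": edges, "density_x": xs, "density_y": dens, "cutoff": cutoff}


def plot_scan_overview(
    scan: BinaryScan | SurvivalScan,
    effect: str,
    data: Optional[MarkerDataset] = None,
    selected_cutoff: Optional[float] = None,
    path=None,
    figsize=(6.0, 4.5),
) -> dict:
    """Effect size vs candidate cutoff with its 95% CI band.

    ``effect`` is one of ``or``, ``hr`` (log scale, unit reference line)
    or ``survdiff`` (linear scale, zero reference line). Arrays are taken
    from the scan unchanged; nothing is recomputed here.
    """
    if len(scan) == 0:
        raise ValueError("empty scan")
    if effect == "or":
        if not isinstance(scan, BinaryScan):
            raise ValueError("odds-ratio overview requires a binary scan")
        y, lo, hi = scan.odds_ratio, scan.or_low, scan.or_high
        label, ref, logscale = "odds ratio (high vs low)", 1.0, True
    elif effect == "hr":
        if not isinstance(scan, SurvivalScan):
            raise ValueError("hazard-ratio overview requires a survival scan")
        y, lo, hi = scan.hr, scan.hr_low, scan.hr_high
        label, ref, logscale = "hazard ratio (high vs low)", 1.0, True
    elif effect == "survdiff":
        if not isinstance(scan, SurvivalScan):
            raise ValueError("survival-difference overview requires a survival scan")
        y, lo, hi = scan.rmst_diff, scan.rmst_diff_low, scan.rmst_diff_high
        label, ref, logscale = "RMST difference (high - low)", 0.0, False
    else:
        raise ValueError(f"unknown effect {effect!r}")
    if np.all(np.isnan(y)):
        raise ValueError(f"scan carries no {effect} values")

    fig, ax = plt.subplots(figsize=figsize)
    x = scan.cutoffs
    ax.fill_between(x, lo, hi, color="steelblue", alpha=0.25, label="95% CI")
    ax.plot(x, y, color="steelblue", lw=2)
    ax.axhline(ref, color="grey", lw=1)
    if logscale:
        ax.set_yscale("log")
    if selected_cutoff is not None:
        ax.axvline(selected_cutoff, color="black", ls="--", label=f"optimum = {selected_cutoff:.3g}")
    if data is not None:
        ax.plot(
            data.marker,
            np.full(data.n, ax.get_ylim()[0]),
            "|",
            color="black",
            ms=8,
            alpha=0.4,
        )
    ax.set_xlabel("cutoff")
    ax.set_ylabel(label)
    ax.legend(frameon=False)
    _finish(fig, path)
    return {"cutoffs": x, "effect": y, "ci_low": lo, "ci_high": hi, "selected": selected_cutoff}


def plot_roc(
    roc: ROCCurve, selected_cutoff: Optional[float] = None, path=None, figsize=(5.0, 5.0)
) -> dict:
    """ROC staircase with the chance diagonal and the selected point."""
    fig, ax = plt.subplots(figsize=figsize)
    ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post", color="steelblue", lw=2)
    ax.plot([0, 1], [0, 1], color="grey", ls=":")
    sel_point = None
    if selected_cutoff is not None:
        idx = int(np.argmin(np.abs(roc.cutoffs - selected_cutoff)))
        fpr_i, tpr_i = roc.interior
        sel_point = (float(fpr_i[idx]), float(tpr_i[idx]))
        ax.plot(*sel_point, "o", color="crimson", ms=9, label=f"cutoff = {selected_cutoff:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    _finish(fig, path)
    return {"fpr": roc.fpr, "tpr": roc.tpr, "selected_point": sel_point}


def plot_waterfall(
    data: MarkerDataset, cutoff: float, path=None, figsize=(7.0, 4.0)
) -> dict:
    """Sorted per-patient marker bars, colored by group (and outcome)."""
    order = np.argsort(data.marker)[::-1]
    values = data.marker[order]
    high = dichotomize(data, cutoff)[order]
    fig, ax = plt.subplots(figsize=figsize)
    if data.outcome is not None:
        colors = np.where(data.outcome[order], "crimson", "steelblue")
        legend = "bar color = outcome (red positive)"
    else:
        colors = np.where(high, "crimson", "steelblue")
        legend = "bar color = group (red high)"
    ax.bar(np.arange(values.size), values, color=colors, width=1.0)
    ax.axhline(cutoff, color="black", ls="--", label=f"cutoff = {cutoff:.3g}")
    ax.set_xlabel(f"patients (sorted by marker); {legend}")
    ax.set_ylabel("marker")
    ax.legend(frameon=False)
    _finish(fig, path)
    return {"values": values, "high": high, "cutoff": cutoff}


def plot_km(
    data: MarkerDataset, cutoff: float, path=None, figsize=(6.0, 4.5)
) -> dict:
    """Kaplan-Meier curves of the two marker groups with the log-rank p."""
    if not data.has_survival:
        raise ValueError("Kaplan-Meier plot requires survival variables")
    high = dichotomize(data, cutoff)
    if high.all() or (~high).all():
        raise ValueError("cutoff leaves one group empty")
    fig, ax = plt.subplots(figsize=figsize)
    curves = {}
    for name, mask, color in (("high", high, "crimson"), ("low", ~high, "steelblue")):
        km = km_estimate(data.time[mask], data.event[mask])
        t = np.concatenate(([0.0], km.event_times, [km.max_time]))
        s = np.concatenate(([1.0], km.survival, [km.survival[-1] if km.survival.size else 1.0]))
        ax.plot(t, s, drawstyle="steps-post", color=color, lw=2, label=f"marker {name} (n={mask.sum()})")
        curves[name] = {"times": t, "survival": s}
    p = logrank_p(data.time, data.event, high)
    ax.text(0.55, 0.1, f"log-rank p = {p:.2g}", transform=ax.transAxes)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    _finish(fig, path)
    return {"curves": curves, "logrank_p": p, "cutoff": cutoff}
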