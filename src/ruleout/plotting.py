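"""Trade-off curve plots: error rate against caseload reduction.

Both plots put the caseload reduction rate on the x-axis so the reading
is operational: "at this workload saving, this is the error rate."  An
optional vertical marker shows the CRR of a selected threshold (e.g.
the Youden optimum), and bootstrap bands are drawn as shaded regions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import is_defined
from .sweep import SweepTable
from .uncertainty import BandTable


def _crr_axis(sweep: SweepTable) -> np.ndarray:
    return np.array([m.crr for m in sweep.metrics]) * 100.0


def _band_for(bands: BandTable | None, metric: str):
    if bands is None:
        return None
    sel = bands.frame[bands.frame["metric"] == metric].sort_values("threshold")
    return sel if not sel.empty else None


def plot_for_curves(
    sweep: SweepTable,
    path: str | Path,
    bands: BandTable | None = None,
    marker_crr: float | None = None,
) -> None:
    """False-omission-rate family (G-FOR, N-FOR, AN-FOR scenarios) vs CRR."""
    crr = _crr_axis(sweep)
    fig, ax = plt.subplots(figsize=(7, 4.5))

    series = [("g_for", "G-FOR", "solid", "tab:red"),
              ("n_for", "N-FOR", (0, (8, 3)), "tab:blue")]
    for f in sweep.fractions:
        series.append((f"an_for_{f:g}", f"AN-FOR {f:.0%}", (0, (3, 2)), None))

    for key, label, ls, color in series:
        if key.startswith("an_for"):
            frac = float(key.split("_")[-1])
            ys = np.array([m.an_for[frac] for m in sweep.metrics]) * 100.0
        else:
            ys = np.array([getattr(m, key) for m in sweep.metrics]) * 100.0
        ok = ~np.isnan(ys)
        ax.plot(crr[ok], ys[ok], label=label, linestyle=ls, color=color, lw=1.4)
        band = _band_for(bands, key)
        if band is not None:
            bc = np.array(
                [m.crr for t, m in zip(sweep.thresholds, sweep.metrics)
                 if t in set(band["threshold"])]
            ) * 100.0
            ax.fill_between(bc, band["lower"] * 100.0, band["upper"] * 100.0, alpha=0.15)

    if marker_crr is not None and is_defined(marker_crr):
        ax.axvline(marker_crr * 100.0, color="black", lw=0.8)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("Caseload reduction rate (%)")
    ax.set_ylabel("False omission rate (%)")
    ax.legend(fontsize=8, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fdr_curve(
    sweep: SweepTable,
    path: str | Path,
    bands: BandTable | None = None,
    marker_crr: float | None = None,
) -> None:
    """False discovery rate among retained exams vs CRR."""
    crr = _crr_axis(sweep)
    ys = np.array([m.fdr for m in sweep.metrics]) * 100.0
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ok = ~np.isnan(ys)
    ax.plot(crr[ok], ys[ok], color="black", lw=1.6, label="AI-FDR")
    band = _band_for(bands, "fdr")
    if band is not None:
        bc = np.array(
            [m.crr for t, m in zip(sweep.thresholds, sweep.metrics)
             if t in set(band["threshold"])]
        ) * 100.0
        ax.fill_between(bc, band["lower"] * 100.0, band["upper"] * 100.0,
                        alpha=0.2, color="tab:red")
    if marker_crr is not None and is_defined(marker_crr):
        ax.axvline(marker_crr * 100.0, color="black", lw=0.8)
    ax.set_xlabel("Caseload reduction rate (%)")
    ax.set_ylabel("False discovery rate (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
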