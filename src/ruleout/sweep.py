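"""Threshold sweeps, selection policies, and the avoidable-biopsy tally.

A sweep evaluates the stratified counts and full metric set at every
threshold of a grid, producing the table from which the trade-off
curves (FOR vs caseload reduction, FDR vs caseload reduction) are
drawn.  Two generalizable policies pick an operating point:

* ``select_youden`` — the classical diagnostic-performance optimum,
  maximizing J = sensitivity + specificity − 1 over candidate cutoffs;
* ``select_anfor_zero`` — an outcome-based policy: the largest grid
  threshold at which AN-FOR(f) is still at or below a target (default
  0), i.e. the maximal caseload reduction that introduces no net
  increase in missed cancers under scenario ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError, InputError
from .metrics import (
    DEFAULT_FRACTIONS,
    MetricSet,
    StratifiedCounts,
    as_percent,
    compute_metrics,
    is_defined,
    stratify,
)


def default_grid(start: float = 0.01, stop: float = 0.99, step: float = 0.01) -> np.ndarray:
    """Evenly spaced threshold grid, rounded to the step's precision."""
    if not (0.0 <= start <= stop <= 1.0) or step <= 0:
        raise ConfigurationError(f"invalid grid spec ({start}, {stop}, {step})")
    n = int(round((stop - start) / step)) + 1
    decimals = max(0, -int(np.floor(np.log10(step))) + 1)
    grid = np.round(start + step * np.arange(n), decimals)
    return grid[grid <= stop + 1e-12]


@dataclass
class SweepTable:
    """Ordered (threshold, counts, metrics) rows — one per grid point."""

    thresholds: np.ndarray
    counts: list[StratifiedCounts]
    metrics: list[MetricSet]
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.thresholds) == 0:
            raise ConfigurationError("sweep grid is empty")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ConfigurationError("sweep thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.thresholds)

    def row(self, threshold: float) -> tuple[StratifiedCounts, MetricSet]:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        if abs(self.thresholds[idx] - threshold) > 1e-9:
            raise KeyError(f"threshold {threshold} not on the sweep grid")
        return self.counts[idx], self.metrics[idx]

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """Render as a DataFrame in the conventional column order.

        Cell columns B–K plus the derived rates; with ``percent`` the
        rates are half-away-rounded percentages and undefined entries
        are left as NaN (written blank by :meth:`write_csv`).
        """
        rows = []
        conv = as_percent if percent else (lambda x: x)
        for t, ct, m in zip(self.thresholds, self.counts, self.metrics):
            row = {
                "Score": t,
                "B": ct.b, "C": ct.c, "D": ct.d, "E": ct.e, "F": ct.f,
                "G": ct.g, "H": ct.h, "I": ct.i, "J": ct.j, "K": ct.k,
                "Total": ct.n,
                "GFOR%": conv(m.g_for),
                "NFOR%": conv(m.n_for),
            }
            for f in self.fractions:
                row[f"AN-FOR {f:.0%}"] = conv(m.an_for[f])
            row["FDR%"] = conv(m.fdr)
            row["CRR%"] = conv(m.crr)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path, percent: bool = True) -> None:
        self.to_frame(percent=percent).to_csv(path, index=False)


def run_sweep(
    cohort: Cohort,
    grid: Sequence[float] | None = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> SweepTable:
    """Stratify and compute the metric set at every grid threshold.

    Counts are accumulated from a single sort of the scores (the cells
    are cumulative in the threshold), so the sweep costs one O(n log n)
    pass regardless of grid size.
    """
    grid = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ConfigurationError("sweep grid is empty")
    if np.any((grid < 0) | (grid > 1)):
        raise ConfigurationError("grid thresholds must lie in [0, 1]")
    if len(cohort) == 0:
        raise InputError("cannot sweep an empty cohort")

    df = cohort.df
    scores = df["ai_score"].to_numpy(dtype=float)
    rec = df["recall"].to_numpy(dtype=bool)
    can = df["cancer"].to_numpy(dtype=bool)

    # per (recall, cancer) group: sorted scores → cumulative rule-out counts
    groups = {
        "b": np.sort(scores[~rec & ~can]),
        "c": np.sort(scores[~rec & can]),
        "d": np.sort(scores[rec & ~can]),
        "e": np.sort(scores[rec & can]),
    }
    totals = {k: v.size for k, v in groups.items()}
    counts_list, metrics_list = [], []
    for t in grid:
        ro = {k: int(np.searchsorted(v, t, side="right")) for k, v in groups.items()}
        ct = StratifiedCounts(
            threshold=float(t),
            b=ro["b"], c=ro["c"], d=ro["d"], e=ro["e"],
            g=totals["b"] - ro["b"], h=totals["c"] - ro["c"],
            i=totals["d"] - ro["d"], j=totals["e"] - ro["e"],
        )
        counts_list.append(ct)
        metrics_list.append(compute_metrics(ct, fractions))
    return SweepTable(grid, counts_list, metrics_list, tuple(float(f) for f in fractions))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a threshold-selection policy."""

    policy: str  # "youden" | "anfor_zero"
    threshold: float | None  # None when no grid row satisfies the policy
    metrics: MetricSet | None
    f: float | None = None  # adjustment fraction (anfor_zero only)
    diagnostics: dict = field(default_factory=dict)

    @property
    def no_crossing(self) -> bool:
        return self.threshold is None


def select_youden(
    cohort: Cohort,
    grid: Sequence[float] | None = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> SelectionResult:
    """Maximize Youden's J over candidate rule-out thresholds.

    By default candidates are all distinct observed scores (cutoff =
    score value, rule-out at ≤), mirroring an ROC analysis on the full
    data; pass ``grid`` to restrict candidates to a fixed grid.  Ties
    break toward the smaller threshold (fewer exams ruled out).
    """
    can = cohort.df["cancer"].to_numpy(dtype=bool)
    if can.all() or not can.any():
        raise InputError("Youden selection needs at least one cancer and one non-cancer")
    scores = cohort.scores
    if grid is None:
        candidates = np.unique(scores)
    else:
        candidates = np.asarray(list(grid), dtype=float)

    pos = np.sort(scores[can])
    neg = np.sort(scores[~can])
    # rule-out at ≤ t: sensitivity = P(score > t | cancer), specificity = P(score ≤ t | ¬cancer)
    sens = 1.0 - np.searchsorted(pos, candidates, side="right") / pos.size
    spec = np.searchsorted(neg, candidates, side="right") / neg.size
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    t_star = float(candidates[best])
    ct = stratify(cohort, t_star)
    return SelectionResult(
        policy="youden",
        threshold=t_star,
        metrics=compute_metrics(ct, fractions),
        diagnostics={
            "candidates": candidates,
            "j_profile": j,
            "j_max": float(j[best]),
        },
    )


def select_anfor_zero(sweep: SweepTable, f: float, target: float = 0.0) -> SelectionResult:
    """Largest grid threshold with AN-FOR(f) at or below ``target``.

    Rationale: the maximal caseload reduction that does not increase the
    net number of missed cancers under detection scenario ``f``.  Rows
    where AN-FOR is undefined (nothing ruled out) are skipped.  If no
    row qualifies, a no-crossing result is returned (not an error).
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"adjustment fraction {f} outside [0, 1]")
    f = float(f)

    def anfor_at(idx: int) -> float:
        v = sweep.metrics[idx].an_for.get(f)
        if v is not None:
            return v
        ct = sweep.counts[idx]
        return (ct.e - f * ct.h) / ct.f if ct.f else float("nan")

    best_idx = None
    for idx in range(len(sweep)):
        v = anfor_at(idx)
        if is_defined(v) and v <= target:
            best_idx = idx
    if best_idx is None:
        return SelectionResult(policy="anfor_zero", threshold=None, metrics=None, f=f,
                               diagnostics={"target": target, "crossing": None})
    diag = {"target": target, "crossing": None}
    if best_idx + 1 < len(sweep):
        diag["crossing"] = (float(sweep.thresholds[best_idx]), float(sweep.thresholds[best_idx + 1]))
        diag["an_for_bracket"] = (anfor_at(best_idx), anfor_at(best_idx + 1))
    return SelectionResult(
        policy="anfor_zero",
        threshold=float(sweep.thresholds[best_idx]),
        metrics=sweep.metrics[best_idx],
        f=f,
        diagnostics=diag,
    )


def biopsies_avoided(cohort: Cohort, threshold: float) -> pd.DataFrame:
    """Benign and high-risk biopsies ruled out (avoidable) vs retained.

    Cross-tabulates biopsy outcome × rule-out status at ``threshold``
    among recalled exams.  Ruled-out counts are biopsies that would be
    avoided under the corresponding triage policy; retained counts stay
    in the downstream workflow.  Requires ``biopsy_outcome`` labels on
    every recalled exam.
    """
    df = cohort.df
    rec = df["recall"].astype(bool)
    missing = rec & df["biopsy_outcome"].isna()
    if missing.any():
        raise InputError(
            "biopsies_avoided requires biopsy_outcome on every recalled exam; "
            f"{int(missing.sum())} recalled exam(s) lack it"
        )
    ruled = df["ai_score"] <= threshold
    out = pd.DataFrame(
        0,
        index=pd.Index(["benign", "high_risk"], name="biopsy_outcome"),
        columns=pd.Index(["ruled_out", "retained"], name="stratum"),
    )
    for outcome in ("benign", "high_risk"):
        sel = rec & (df["biopsy_outcome"] == outcome)
        out.loc[outcome, "ruled_out"] = int((sel & ruled).sum())
        out.loc[outcome, "retained"] = int((sel & ~ruled).sum())
    return out
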