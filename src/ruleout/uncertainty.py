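"""Bootstrap confidence bands for the sweep-curve metrics.

Exam records are resampled with replacement at full cohort size
(records are treated as exchangeable; no patient clustering is
modeled), the sweep is recomputed per replicate, and percentile
intervals are taken per (threshold, metric).  Replicates at which a
metric is undefined (e.g. nothing ruled out, so FOR has an empty
denominator) are excluded from that cell's percentiles, with the
surviving replicate count reported.

Quantiles use inclusive linear interpolation between order statistics
(numpy's default), so bands are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError, InputError
from .metrics import DEFAULT_FRACTIONS

#: metric keys understood by the bootstrap
BOOT_METRICS = ("crr", "g_for", "n_for", "an_for", "fdr")


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling plan: replicate count, seed, coverage level, metrics."""

    replicates: int = 1000
    seed: int | None = None
    level: float = 0.95
    metrics: tuple[str, ...] = BOOT_METRICS
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS

    def __post_init__(self):
        if self.replicates < 2:
            raise ConfigurationError(f"bootstrap needs ≥ 2 replicates, got {self.replicates}")
        if not 0.0 < self.level < 1.0:
            raise ConfigurationError(f"coverage level must be in (0, 1), got {self.level}")
        unknown = set(self.metrics) - set(BOOT_METRICS)
        if unknown:
            raise ConfigurationError(f"unknown bootstrap metrics: {sorted(unknown)}")


@dataclass
class BandTable:
    """Long-format per-(threshold, metric) point estimate and band."""

    frame: pd.DataFrame  # threshold, metric, estimate, lower, upper, replicate_mean, sd, n_defined
    spec: BootstrapSpec
    diagnostics: dict = field(default_factory=dict)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _metric_arrays(
    ro: dict, tot: dict, fractions: Sequence[float]
) -> dict[str, np.ndarray]:
    """Vectorized metric curves from per-group ruled-out count arrays.

    ``ro[cell]`` holds ruled-out counts per grid threshold; ``tot`` the
    group totals.  Undefined entries come out as NaN.
    """
    b, c, d, e = (ro[k].astype(float) for k in "bcde")
    B, C, D, E = (float(tot[k]) for k in "bcde")
    f_tot = b + c + d + e
    k_tot = (B - b) + (C - c) + (D - d) + (E - e)
    n_tot = f_tot + k_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        out = {
            "crr": f_tot / n_tot,
            "g_for": np.where(f_tot > 0, (c + e) / np.where(f_tot > 0, f_tot, 1), np.nan),
            "n_for": np.where(f_tot > 0, e / np.where(f_tot > 0, f_tot, 1), np.nan),
            "fdr": np.where(
                k_tot > 0, ((B - b) + (D - d)) / np.where(k_tot > 0, k_tot, 1), np.nan
            ),
        }
        h = C - c
        for frac in fractions:
            out[f"an_for_{frac:g}"] = np.where(
                f_tot > 0, (e - frac * h) / np.where(f_tot > 0, f_tot, 1), np.nan
            )
    return out


def _ruled_out_counts(scores_by_group: dict[str, np.ndarray], grid: np.ndarray) -> dict:
    return {
        k: np.searchsorted(np.sort(v), grid, side="right")
        for k, v in scores_by_group.items()
    }


def bootstrap_bands(
    cohort: Cohort,
    grid: Sequence[float],
    spec: BootstrapSpec,
) -> BandTable:
    """Percentile bootstrap bands across the grid for the chosen metrics.

    Returns a :class:`BandTable` whose frame has one row per
    (threshold, metric): the full-cohort point estimate, the
    (1−level) percentile band over defined replicates, the replicate
    standard deviation, and the number of defined replicates.  Rows
    where the point estimate falls outside its band are flagged in
    ``diagnostics['point_outside_band']`` rather than raised.
    """
    if len(cohort) == 0:
        raise InputError("cannot bootstrap an empty cohort")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ConfigurationError("bootstrap grid is empty")

    df = cohort.df
    scores = df["ai_score"].to_numpy(dtype=float)
    rec = df["recall"].to_numpy(dtype=bool)
    can = df["cancer"].to_numpy(dtype=bool)
    masks = {
        "b": ~rec & ~can, "c": ~rec & can, "d": rec & ~can, "e": rec & can,
    }
    n = scores.size

    # expand requested metric names (an_for → one per fraction)
    names: list[str] = []
    for m in spec.metrics:
        if m == "an_for":
            names.extend(f"an_for_{f:g}" for f in spec.fractions)
        else:
            names.append(m)

    # point estimates from the full cohort
    groups_full = {k: scores[v] for k, v in masks.items()}
    tot_full = {k: v.size for k, v in groups_full.items()}
    est = _metric_arrays(_ruled_out_counts(groups_full, grid), tot_full, spec.fractions)

    rng = np.random.default_rng(spec.seed)
    reps = {name: np.empty((spec.replicates, grid.size)) for name in names}
    for r in range(spec.replicates):
        idx = rng.integers(0, n, size=n)
        s_r, rec_r, can_r = scores[idx], rec[idx], can[idx]
        groups = {
            "b": s_r[~rec_r & ~can_r], "c": s_r[~rec_r & can_r],
            "d": s_r[rec_r & ~can_r], "e": s_r[rec_r & can_r],
        }
        tot = {k: v.size for k, v in groups.items()}
        vals = _metric_arrays(_ruled_out_counts(groups, grid), tot, spec.fractions)
        for name in names:
            reps[name][r] = vals[name]

    alpha = 1.0 - spec.level
    rows = []
    outside = []
    for name in names:
        mat = reps[name]
        n_def = np.sum(~np.isnan(mat), axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices → NaN band
            lo = np.nanquantile(mat, alpha / 2, axis=0, method="linear")
            hi = np.nanquantile(mat, 1 - alpha / 2, axis=0, method="linear")
            sd = np.nanstd(mat, axis=0, ddof=1)
            mean = np.nanmean(mat, axis=0)
        for gi, t in enumerate(grid):
            point = float(est[name][gi])
            l, u = float(lo[gi]), float(hi[gi])
            if not (np.isnan(l) or np.isnan(u)):
                assert l <= u + 1e-15
                if not (l - 1e-12 <= point <= u + 1e-12) and not np.isnan(point):
                    outside.append((float(t), name))
            rows.append(
                {
                    "threshold": float(t), "metric": name, "estimate": point,
                    "lower": l, "upper": u,
                    "replicate_mean": float(mean[gi]), "sd": float(sd[gi]),
                    "n_defined_replicates": int(n_def[gi]),
                }
            )
    frame = pd.DataFrame(rows)
    return BandTable(frame, spec, diagnostics={"point_outside_band": outside})
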