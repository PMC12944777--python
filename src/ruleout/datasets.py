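"""Bundled example dataset: a published-scale screening sweep table.

``screening_sweep_counts.csv`` holds the stratified cell counts B–K of
a retrospective screening-mammography cohort (114,229 exams, 864
cancers, prevalence 0.76%) evaluated at rule-out thresholds 0.01–0.85
in steps of 0.01, together with the derived percentages as originally
printed (two decimals, half-away rounding).  It is the package's
primary worked example and golden fixture: every derived column is
recomputable from the cells.

Because only cumulative counts are published, :func:`load_cohort`
reconstructs a *pseudo-cohort* of individual exams that is exactly
consistent with them: the cell increments between consecutive
thresholds become exams whose score equals the bin's upper threshold,
and the residual retained cells of the last row become exams above it.
Stratifying the pseudo-cohort at any tabulated threshold reproduces the
printed cells bit-for-bit; scores between grid points are of course not
resolved.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Cohort, COLUMNS
from .metrics import StratifiedCounts

#: score given to exams never ruled out within the tabulated grid
RESIDUAL_SCORE = 0.90

_DERIVED_COLUMNS = (
    "gfor_pct", "nfor_pct", "anfor10_pct", "anfor30_pct",
    "anfor50_pct", "anfor70_pct", "fdr_pct", "crr_pct",
)


def load_table() -> pd.DataFrame:
    """The packaged sweep-count table (one row per tabulated threshold).

    Columns: ``threshold``, cells ``B``–``K`` and total ``N`` (integers),
    and the printed derived percentages (NaN where the original table
    leaves them blank because nothing is ruled out).
    """
    ref = resources.files("ruleout.data").joinpath("screening_sweep_counts.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    for col in list("BCDEFGHIJK") + ["N"]:
        df[col] = df[col].astype(int)
    return df


def counts_at(threshold: float, table: pd.DataFrame | None = None) -> StratifiedCounts:
    """The :class:`StratifiedCounts` of one tabulated threshold row."""
    table = load_table() if table is None else table
    row = table.loc[np.isclose(table["threshold"], threshold)]
    if row.empty:
        raise KeyError(f"threshold {threshold} not tabulated")
    r = row.iloc[0]
    return StratifiedCounts.from_cells(
        threshold=float(r["threshold"]),
        b=int(r["B"]), c=int(r["C"]), d=int(r["D"]), e=int(r["E"]),
        g=int(r["G"]), h=int(r["H"]), i=int(r["I"]), j=int(r["J"]),
        f=int(r["F"]), k=int(r["K"]), n=int(r["N"]),
    )


def load_cohort() -> Cohort:
    """Pseudo-cohort of individual exams consistent with the count table.

    Synthetic reconstruction (see module docstring): scores are placed
    at tabulated thresholds only, so any analysis on this cohort is
    exact at tabulated thresholds and undefined between them.
    """
    table = load_table().sort_values("threshold").reset_index(drop=True)
    cells = ("B", "C", "D", "E")
    flags = {"B": (False, False), "C": (False, True), "D": (True, False), "E": (True, True)}

    scores, recalls, cancers = [], [], []
    prev = {c: 0 for c in cells}
    for _, r in table.iterrows():
        t = float(r["threshold"])
        for c in cells:
            inc = int(r[c]) - prev[c]
            if inc < 0:
                raise ValueError(f"non-cumulative cell {c} at threshold {t}")
            if inc:
                rec, can = flags[c]
                scores.append(np.full(inc, t))
                recalls.append(np.full(inc, rec))
                cancers.append(np.full(inc, can))
            prev[c] = int(r[c])
    # residual retained exams of the last row, placed above the grid
    last = table.iloc[-1]
    for cell, (rec, can) in (("G", (False, False)), ("H", (False, True)),
                             ("I", (True, False)), ("J", (True, True))):
        cnt = int(last[cell])
        if cnt:
            scores.append(np.full(cnt, RESIDUAL_SCORE))
            recalls.append(np.full(cnt, rec))
            cancers.append(np.full(cnt, can))

    score = np.concatenate(scores)
    recall = np.concatenate(recalls)
    cancer = np.concatenate(cancers)
    n = score.size
    df = pd.DataFrame(
        {
            "exam_id": [f"px-{i:06d}" for i in range(n)],
            "ai_score": score,
            "recall": recall,
            "cancer": cancer,
            "cancer_type": None,
            "biopsy_outcome": None,
        },
        columns=COLUMNS,
    )
    return Cohort(df, metadata={"source": "ruleout.datasets.load_cohort (pseudo-cohort)"})


def tabulated_grid(table: pd.DataFrame | None = None) -> np.ndarray:
    """The thresholds covered by the packaged table (0.01–0.85)."""
    table = load_table() if table is None else table
    return np.sort(table["threshold"].to_numpy(dtype=float))
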