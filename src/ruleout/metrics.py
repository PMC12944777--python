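"""Stratified error metrics for AI rule-out triage at a single threshold.

Every exam is cross-classified three ways: ruled out by AI (score at or
below the threshold) versus retained; recalled by the radiologist under
standard practice versus not; cancer within follow-up versus not.  The
eight resulting cells carry the conventional letters

    ruled out:  B (¬recall, ¬cancer)  C (¬recall, cancer)
                D (recall,  ¬cancer)  E (recall,  cancer)
    retained:   G (¬recall, ¬cancer)  H (¬recall, cancer)
                I (recall,  ¬cancer)  J (recall,  cancer)

with totals F = B+C+D+E (ruled out), K = G+H+I+J (retained), N = F+K.

From these cells come the workload/error trade-off rates:

* CRR, caseload reduction rate = F/N — the fraction of exams removed
  from the radiologist's reading list;
* G-FOR, gross false omission rate = (C+E)/F = 1 − NPV — probability a
  ruled-out exam harbors cancer;
* N-FOR, net FOR = E/F — restricted to cancers the radiologist would
  have recalled anyway, i.e. excluding mutually missed (interval)
  cancers;
* AN-FOR(f) = (E − f·H)/F — N-FOR credited with a fraction ``f`` of the
  retained cancers the radiologist would otherwise have missed (reading
  a smaller, enriched pool plausibly improves detection); may be
  negative, meaning triage nets out ahead of standard practice;
* FDR = (G+I)/K = 1 − PPV among retained exams.

Metrics undefined at F = 0 or K = 0 are returned as the :data:`UNDEFINED`
sentinel (NaN), rendered blank in tables — never zero and never an
exception inside a sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort
from .errors import ConfigurationError, InputError

#: sentinel for metrics whose denominator is empty (blank in rendered tables)
UNDEFINED = float("nan")

#: AN-FOR adjustment fractions reported by default
DEFAULT_FRACTIONS = (0.10, 0.30, 0.50, 0.70)


def is_defined(x: float) -> bool:
    return not math.isnan(x)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of classic stats software).

    Python's builtin ``round`` is banker's rounding; printed tables in
    this domain use half-away (e.g. −0.375 → −0.38).
    """
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(x: float, ndigits: int = 2) -> float:
    """Proportion → percent, rounded half-away to ``ndigits`` decimals."""
    return round_half_away(100.0 * x, ndigits)


@dataclass(frozen=True)
class StratifiedCounts:
    """The eight cells of the rule-out × recall × cancer partition."""

    threshold: float
    b: int  # ruled out, not recalled, no cancer
    c: int  # ruled out, not recalled, cancer
    d: int  # ruled out, recalled, no cancer
    e: int  # ruled out, recalled, cancer
    g: int  # retained, not recalled, no cancer
    h: int  # retained, not recalled, cancer
    i: int  # retained, recalled, no cancer
    j: int  # retained, recalled, cancer

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold {self.threshold} outside [0, 1]")
        for name in "bcdeghij":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name.upper()} negative")

    @property
    def f(self) -> int:
        """Total ruled out."""
        return self.b + self.c + self.d + self.e

    @property
    def k(self) -> int:
        """Total retained."""
        return self.g + self.h + self.i + self.j

    @property
    def n(self) -> int:
        return self.f + self.k

    @property
    def cancers(self) -> int:
        return self.c + self.e + self.h + self.j

    @property
    def non_cancers(self) -> int:
        return self.b + self.d + self.g + self.i

    @classmethod
    def from_cells(
        cls,
        threshold: float,
        b: int, c: int, d: int, e: int,
        g: int, h: int, i: int, j: int,
        f: int | None = None,
        k: int | None = None,
        n: int | None = None,
    ) -> "StratifiedCounts":
        """Build from cells, cross-checking any supplied totals."""
        out = cls(threshold, b, c, d, e, g, h, i, j)
        for name, given, derived in (("F", f, out.f), ("K", k, out.k), ("N", n, out.n)):
            if given is not None and given != derived:
                raise ValueError(f"total {name}={given} inconsistent with cells ({derived})")
        return out


def stratify(cohort: Cohort, threshold: float) -> StratifiedCounts:
    """Assign every exam to one of the eight cells at ``threshold``.

    Rule-out convention: score ≤ threshold is ruled out, score >
    threshold retained; scores exactly at the threshold fall on the
    ruled-out side.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold {threshold} outside [0, 1]")
    if len(cohort) == 0:
        raise InputError("cannot stratify an empty cohort")
    df = cohort.df
    ruled = df["ai_score"].to_numpy(dtype=float) <= threshold
    rec = df["recall"].to_numpy(dtype=bool)
    can = df["cancer"].to_numpy(dtype=bool)

    def count(ro, r, ca):
        return int(np.sum((ruled == ro) & (rec == r) & (can == ca)))

    counts = StratifiedCounts(
        threshold=threshold,
        b=count(True, False, False), c=count(True, False, True),
        d=count(True, True, False), e=count(True, True, True),
        g=count(False, False, False), h=count(False, False, True),
        i=count(False, True, False), j=count(False, True, True),
    )
    assert counts.n == len(cohort)
    assert counts.cancers == cohort.n_cancer
    return counts


# -- rate formulas -------------------------------------------------------


def caseload_reduction_rate(counts: StratifiedCounts) -> float:
    """F/N: fraction of the reading workload removed by rule-out."""
    if counts.n == 0:
        raise InputError("empty counts")
    return counts.f / counts.n


def gross_for(counts: StratifiedCounts) -> float:
    """(C+E)/F: probability a ruled-out exam harbors cancer (1 − NPV)."""
    if counts.f == 0:
        return UNDEFINED
    return (counts.c + counts.e) / counts.f


def net_for(counts: StratifiedCounts) -> float:
    """E/F: ruled-out cancers the radiologist would have recalled."""
    if counts.f == 0:
        return UNDEFINED
    return counts.e / counts.f


def adjusted_net_for(counts: StratifiedCounts, f: float) -> float:
    """(E − f·H)/F: net FOR credited with extra detections in retained cases.

    ``f`` is the hypothesized fraction of radiologist-missed retained
    cancers (H) that would be caught thanks to the smaller, enriched
    reading pool.  The result may be negative.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"adjustment fraction {f} outside [0, 1]")
    if counts.f == 0:
        return UNDEFINED
    return (counts.e - f * counts.h) / counts.f


def net_missed_count(counts: StratifiedCounts, f: float, clamp: bool = False) -> int:
    """Round-to-nearest of E − f·H; optionally floored at zero.

    The unclamped signed value feeds tables and curves; the clamped form
    is the headline 'additional missed cancers' count (a negative net
    count means no additional misses, reported as 0).
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"adjustment fraction {f} outside [0, 1]")
    raw = round_half_away(counts.e - f * counts.h, 0)
    return int(max(raw, 0.0)) if clamp else int(raw)


def fdr(counts: StratifiedCounts) -> float:
    """(G+I)/K: probability a retained exam is cancer-free (1 − PPV)."""
    if counts.k == 0:
        return UNDEFINED
    return (counts.g + counts.i) / counts.k


def ppv(counts: StratifiedCounts) -> float:
    """(H+J)/K: probability a retained exam harbors cancer."""
    if counts.k == 0:
        return UNDEFINED
    return (counts.h + counts.j) / counts.k


def npv(counts: StratifiedCounts) -> float:
    """(B+D)/F: probability a ruled-out exam is cancer-free."""
    if counts.f == 0:
        return UNDEFINED
    return (counts.b + counts.d) / counts.f


def sensitivity_specificity(counts: StratifiedCounts) -> tuple[float, float]:
    """AI-level sensitivity and specificity (retained = test-positive).

    sensitivity = (H+J)/cancers, specificity = (B+D)/non-cancers.
    Either is the sentinel when its class is empty.
    """
    sens = (counts.h + counts.j) / counts.cancers if counts.cancers else UNDEFINED
    spec = (counts.b + counts.d) / counts.non_cancers if counts.non_cancers else UNDEFINED
    return sens, spec


def bayes_predictive(sensitivity: float, specificity: float, prevalence: float) -> tuple[float, float]:
    """Predictive values from (sensitivity, specificity, prevalence).

    ppv  = se·p / (se·p + (1−sp)(1−p))
    npv  = sp·(1−p) / (sp·(1−p) + (1−se)·p)

    Applied to count-derived operating characteristics these reproduce
    the count-ratio PPV/NPV exactly.  0/0 forms return the sentinel.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} {v} outside [0, 1]")
    p_num = sensitivity * prevalence
    p_den = p_num + (1.0 - specificity) * (1.0 - prevalence)
    n_num = specificity * (1.0 - prevalence)
    n_den = n_num + (1.0 - sensitivity) * prevalence
    return (
        p_num / p_den if p_den > 0 else UNDEFINED,
        n_num / n_den if n_den > 0 else UNDEFINED,
    )


@dataclass(frozen=True)
class MetricSet:
    """All derived rates at one threshold (proportions, not percents)."""

    crr: float
    g_for: float
    n_for: float
    an_for: Mapping[float, float]
    fdr: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    youden_j: float
    prevalence: float

    def as_dict(self) -> dict:
        d = {
            "crr": self.crr, "g_for": self.g_for, "n_for": self.n_for,
            "fdr": self.fdr, "ppv": self.ppv, "npv": self.npv,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "youden_j": self.youden_j, "prevalence": self.prevalence,
        }
        for f, v in self.an_for.items():
            d[f"an_for_{f:g}"] = v
        return d


def compute_metrics(
    counts: StratifiedCounts, fractions: Sequence[float] = DEFAULT_FRACTIONS
) -> MetricSet:
    """Evaluate the full metric set at one threshold's counts."""
    sens, spec = sensitivity_specificity(counts)
    j = sens + spec - 1.0 if is_defined(sens) and is_defined(spec) else UNDEFINED
    return MetricSet(
        crr=caseload_reduction_rate(counts),
        g_for=gross_for(counts),
        n_for=net_for(counts),
        an_for={float(f): adjusted_net_for(counts, f) for f in fractions},
        fdr=fdr(counts),
        ppv=ppv(counts),
        npv=npv(counts),
        sensitivity=sens,
        specificity=spec,
        youden_j=j,
        prevalence=counts.cancers / counts.n,
    )
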