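"""Synthetic screening cohorts with the joint structure the metrics assume.

Each exam is drawn independently:

* cancer ~ Bernoulli(prevalence);
* AI score ~ class-conditional Beta (support [0, 1] and flexible shape,
  which is why Beta is used; the true score distribution of any given
  AI model is a property of that model, not of this generator);
* radiologist recall ~ Bernoulli with a class-specific probability,
  optionally modulated by the score on the log-odds scale so that
  low-score cancers are missed more often — the pattern seen in real
  reading data, where interval cancers concentrate among AI-low exams.

Defaults are calibrated to a large retrospective screening-mammography
cohort: prevalence 0.76%, radiologist recall rate ≈ 8.1% among
non-cancers, radiologist detection ≈ 82.9% among cancers, and Beta shape
parameters chosen so the class-wise rule-out fractions at thresholds
0.05 and 0.20 match the observed 36%/75% (non-cancer) and 5.7%/25.8%
(cancer) splits.

With zero slopes the recall decision is independent of the score given
the class, and every sweep metric has a closed form
(:func:`expected_metrics`) used as the oracle for simulator tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .cohort import Cohort, COLUMNS
from .errors import ConfigurationError
from .metrics import MetricSet, UNDEFINED, DEFAULT_FRACTIONS

import pandas as pd


@dataclass(frozen=True)
class ScoreModel:
    """Class-conditional Beta parameters for the AI score."""

    a_noncancer: float = 0.659
    b_noncancer: float = 4.199
    a_cancer: float = 1.133
    b_cancer: float = 1.644

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not v > 0:
                raise ConfigurationError(f"Beta parameter {name} must be > 0, got {v}")

    def cdf(self, t: float, cancer: bool) -> float:
        if cancer:
            return float(stats.beta.cdf(t, self.a_cancer, self.b_cancer))
        return float(stats.beta.cdf(t, self.a_noncancer, self.b_noncancer))


@dataclass(frozen=True)
class RecallModel:
    """Radiologist recall under standard practice.

    ``recall_noncancer`` and ``detect_cancer`` are the marginal recall
    probabilities per class.  A nonzero slope makes recall depend on the
    AI score through logit(p) = c + slope·score, with the intercept c
    solved numerically so the class marginal stays at its stated value.
    Slopes calibrated to the reference cohort's coupling (interval
    cancers concentrated at low scores) are roughly 4.7 for cancers and
    2.2 for non-cancers.
    """

    recall_noncancer: float = 0.081
    detect_cancer: float = 0.829
    slope_noncancer: float = 0.0
    slope_cancer: float = 0.0

    def __post_init__(self):
        for name in ("recall_noncancer", "detect_cancer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class BiopsyModel:
    """Biopsy outcome probabilities for recalled exams.

    Recalled cancers biopsy as malignant.  Recalled non-cancers biopsy
    as benign or high-risk with the given probabilities (the remainder
    resolve without biopsy).  Non-recalled exams get ``"none"``.
    """

    p_benign: float = 0.15
    p_high_risk: float = 0.03

    def __post_init__(self):
        if min(self.p_benign, self.p_high_risk) < 0 or self.p_benign + self.p_high_risk > 1:
            raise ConfigurationError("biopsy probabilities must be ≥ 0 and sum to ≤ 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic screening cohort."""

    n: int = 114_229
    prevalence: float = 0.0076
    score_model: ScoreModel = field(default_factory=ScoreModel)
    recall_model: RecallModel = field(default_factory=RecallModel)
    biopsy_model: BiopsyModel | None = field(default_factory=BiopsyModel)
    p_invasive: float = 0.8  # fraction of cancers labeled invasive (vs in situ)
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError(f"cohort size n must be ≥ 1, got {self.n}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if not 0.0 <= self.p_invasive <= 1.0:
            raise ConfigurationError(f"p_invasive must be in [0, 1], got {self.p_invasive}")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "score_model" in d and d["score_model"] is not None:
            d["score_model"] = ScoreModel(**d["score_model"])
        if "recall_model" in d and d["recall_model"] is not None:
            d["recall_model"] = RecallModel(**d["recall_model"])
        if d.get("biopsy_model") is not None:
            d["biopsy_model"] = BiopsyModel(**d["biopsy_model"])
        return cls(**d)


def _recall_intercept(base: float, slope: float, a: float, b: float) -> float:
    """Intercept c with ∫ expit(c + slope·s) Beta(s; a, b) ds = base.

    Gauss–Legendre quadrature on [0, 1]; monotone in c, so brentq on a
    wide bracket is robust and deterministic.
    """
    if base in (0.0, 1.0):
        raise ConfigurationError("score-dependent recall needs a base probability in (0, 1)")
    nodes, weights = np.polynomial.legendre.leggauss(128)
    s = 0.5 * (nodes + 1.0)
    w = 0.5 * weights * stats.beta.pdf(s, a, b)
    w /= w.sum()

    def marginal(c):
        return float(np.sum(w * expit(c + slope * s))) - base

    return float(optimize.brentq(marginal, -60.0, 60.0, xtol=1e-12))


def _recall_prob(scores: np.ndarray, base: float, slope: float, a: float, b: float) -> np.ndarray:
    if slope == 0.0:
        return np.full(scores.shape, base)
    c = _recall_intercept(base, slope, a, b)
    return expit(c + slope * scores)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a synthetic cohort; byte-reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    sm, rm = config.score_model, config.recall_model

    cancer = rng.random(n) < config.prevalence
    scores = np.empty(n)
    n_pos = int(cancer.sum())
    scores[cancer] = rng.beta(sm.a_cancer, sm.b_cancer, size=n_pos)
    scores[~cancer] = rng.beta(sm.a_noncancer, sm.b_noncancer, size=n - n_pos)

    p_recall = np.empty(n)
    p_recall[cancer] = _recall_prob(
        scores[cancer], rm.detect_cancer, rm.slope_cancer, sm.a_cancer, sm.b_cancer
    )
    p_recall[~cancer] = _recall_prob(
        scores[~cancer], rm.recall_noncancer, rm.slope_noncancer, sm.a_noncancer, sm.b_noncancer
    )
    recall = rng.random(n) < p_recall

    cancer_type = np.where(
        cancer, np.where(rng.random(n) < config.p_invasive, "invasive", "in_situ"), None
    )

    biopsy = np.full(n, None, dtype=object)
    if config.biopsy_model is not None:
        bm = config.biopsy_model
        u = rng.random(n)
        biopsy[recall & cancer] = "malignant"
        neg_rec = recall & ~cancer
        biopsy[neg_rec] = np.select(
            [u[neg_rec] < bm.p_benign, u[neg_rec] < bm.p_benign + bm.p_high_risk],
            ["benign", "high_risk"],
            default="none",
        )
        biopsy[~recall] = "none"

    width = len(str(n))
    df = pd.DataFrame(
        {
            "exam_id": [f"exam-{i:0{width}d}" for i in range(n)],
            "ai_score": scores,
            "recall": recall,
            "cancer": cancer,
            "cancer_type": cancer_type,
            "biopsy_outcome": biopsy,
        },
        columns=COLUMNS,
    )
    meta = {"generator": "ruleout.synthetic", "seed": config.seed, "config": json.loads(config.to_json())}
    return Cohort(df, meta)


def expected_metrics(
    config: SimulationConfig,
    threshold: float,
    fractions=DEFAULT_FRACTIONS,
) -> MetricSet:
    """Analytic expectations of every sweep metric at ``threshold``.

    Requires score-independent recall (both slopes zero).  With
    p = prevalence, q_c = P(score ≤ t | cancer), q_n = P(score ≤ t | ¬cancer),
    and d = radiologist detection probability:

        CRR      = p·q_c + (1−p)·q_n
        G-FOR    = p·q_c / CRR
        N-FOR    = d · G-FOR
        AN-FOR(f)= (p·q_c·d − f·p·(1−q_c)(1−d)) / CRR
        FDR      = (1−p)(1−q_n) / (p(1−q_c) + (1−p)(1−q_n))
    """
    rm = config.recall_model
    if rm.slope_cancer != 0.0 or rm.slope_noncancer != 0.0:
        raise ConfigurationError("expected_metrics requires slope-free (score-independent) recall")
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold {threshold} outside [0, 1]")

    p = config.prevalence
    q_c = config.score_model.cdf(threshold, cancer=True)
    q_n = config.score_model.cdf(threshold, cancer=False)
    d = rm.detect_cancer

    f_mass = p * q_c + (1.0 - p) * q_n  # ruled-out probability mass
    k_mass = 1.0 - f_mass
    sens = 1.0 - q_c if p > 0 else UNDEFINED
    spec = q_n if p < 1 else UNDEFINED

    if f_mass > 0:
        g_for = p * q_c / f_mass
        n_for = d * g_for
        an_for = {
            float(f): (p * q_c * d - f * p * (1.0 - q_c) * (1.0 - d)) / f_mass
            for f in fractions
        }
        npv = 1.0 - g_for
    else:
        g_for = n_for = npv = UNDEFINED
        an_for = {float(f): UNDEFINED for f in fractions}
    if k_mass > 0:
        ppv = p * (1.0 - q_c) / k_mass
        fdr = 1.0 - ppv
    else:
        ppv = fdr = UNDEFINED

    j = sens + spec - 1.0 if p not in (0.0, 1.0) else UNDEFINED

    return MetricSet(
        crr=f_mass, g_for=g_for, n_for=n_for, an_for=an_for, fdr=fdr,
        ppv=ppv, npv=npv, sensitivity=sens, specificity=spec,
        youden_j=j, prevalence=p,
    )
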