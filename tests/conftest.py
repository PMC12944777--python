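import numpy as np
import pandas as pd
import pytest

from ruleout import Cohort, ExamRecord, SimulationConfig, simulate_cohort
from ruleout import datasets


@pytest.fixture(scope="session")
def ref_table() -> pd.DataFrame:
    """Packaged sweep-count table (85 thresholds, 114,229 exams)."""
    return datasets.load_table()


@pytest.fixture(scope="session")
def pseudo_cohort() -> Cohort:
    """Pseudo-cohort reconstructed from the packaged count table."""
    return datasets.load_cohort()


@pytest.fixture(scope="session")
def ref_grid(ref_table) -> np.ndarray:
    return datasets.tabulated_grid(ref_table)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Four exams spanning all rule-out × recall × cancer combinations."""
    return Cohort.from_records(
        [
            ExamRecord("a", 0.1, recall=False, cancer=False),
            ExamRecord("b", 0.1, recall=True, cancer=True),
            ExamRecord("c", 0.9, recall=False, cancer=True),
            ExamRecord("d", 0.9, recall=True, cancer=False),
        ]
    )


@pytest.fixture(scope="session")
def synth_cohort() -> Cohort:
    """Mid-sized synthetic cohort with default (study-calibrated) parameters."""
    return simulate_cohort(SimulationConfig(n=20_000, seed=424242))


def random_cohort(rng: np.random.Generator, n: int = 200) -> Cohort:
    """Small random cohort for property tests (labels independent of score)."""
    df = pd.DataFrame(
        {
            "exam_id": [f"r{i}" for i in range(n)],
            "ai_score": rng.random(n),
            "recall": rng.random(n) < 0.3,
            "cancer": rng.random(n) < 0.2,
            "cancer_type": None,
            "biopsy_outcome": None,
        }
    )
    return Cohort(df)
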