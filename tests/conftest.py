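import numpy as np
import pytest
from hypothesis import settings

from agreebench import ExperimentConfig, run_experiment

settings.register_profile("agreebench", deadline=None, derandomize=True)
settings.load_profile("agreebench")
from agreebench.simulate import DesignCell, RatingSession

#: Master seed for all stochastic fixtures.
MASTER_SEED = 1234


@pytest.fixture(scope="session")
def default_run():
    """One full default experiment (384 sessions), shared across tests."""
    return run_experiment(ExperimentConfig(), seed=MASTER_SEED)


def session_from_counts(
    n_agree_right: int,
    n_agree_wrong: int,
    n_disagree: int,
    n_categories: int = 2,
) -> RatingSession:
    """Build a truth-labeled session with the given agreement breakdown.

    Truth is category 1 throughout; agree-wrong pairs land on category 2,
    disagreeing pairs split 1 vs 2.
    """
    n = n_agree_right + n_agree_wrong + n_disagree
    truth = np.ones(n, dtype=np.int64)
    r1 = np.concatenate(
        [
            np.ones(n_agree_right, dtype=np.int64),
            np.full(n_agree_wrong, 2, dtype=np.int64),
            np.ones(n_disagree, dtype=np.int64),
        ]
    )
    r2 = np.concatenate(
        [
            np.ones(n_agree_right, dtype=np.int64),
            np.full(n_agree_wrong, 2, dtype=np.int64),
            np.full(n_disagree, 2, dtype=np.int64),
        ]
    )
    cell = DesignCell(
        n_categories=n_categories, skew=0.5, difficulty=0.0, n_items=n
    )
    return RatingSession(design=cell, rater1=r1, rater2=r2, truth=truth)


def enumerate_2x2_tables(max_items: int):
    """All 2×2 contingency tables with 1 ≤ n_items ≤ max_items.

    Yields (counts, rater1 list, rater2 list) with the raw rating lists
    that realize each table, for oracle comparisons.
    """
    for n in range(1, max_items + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    r1 = [1] * (a + b) + [2] * (c + d)
                    r2 = [1] * a + [2] * b + [1] * c + [2] * d
                    counts = np.array([[a, b], [c, d]], dtype=np.int64)
                    yield counts, r1, r2
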