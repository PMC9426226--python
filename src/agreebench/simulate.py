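"""Synthetic rating sessions with difficulty-driven involuntary guessing.

The generator emulates a controlled rating experiment: two raters judge
items whose true category is one of the two "confusable" categories
(1 and 2, e.g. the longest and second-longest of C bars).  On each item a
rater either recognizes the truth or — with a probability that grows with
task difficulty — guesses involuntarily, uniformly between the two
confusable categories.  Optionally a small rate of decisions lands on the
remaining "short-bar" categories 3..C.

The factorial design crosses category count C ∈ {2,4,6,8}, true-category
skew s_k ∈ {0.5, 0.75, 0.99} and eight difficulty levels
d_f = (8 − p_x)/7 for pixel differences p_x = 8..1, with 4 replicate
sessions of 100 items per cell: 4·8·3·4 = 384 sessions.

Closed-form moments of the clean model (no short-bar noise), with g the
guess probability at a session's difficulty:

    E[a_o]   = (1 − g/2)² + (g/2)²      observed agreement
    E[o_ae]  = g²/4                      agree-and-wrong
    E[o_ac]  = g²/2                      true chance agreement
    E[o_ri]  = 1 − g                     true reliability

None of these depend on C or s_k, so the manipulated factors stay
orthogonal to observed chance agreement by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DIFFICULTY_LEVELS",
    "OAC_CALIBRATION_LEVELS",
    "SHORT_BAR_RATES",
    "DesignCell",
    "RatingSession",
    "BehaviorModel",
    "default_calibration",
    "short_bar_noise_rate",
    "enumerate_design",
    "simulate_session",
    "simulate_design",
    "session_seed",
]

#: The eight design difficulties, (8 − p_x)/7 for p_x = 8..1.
DIFFICULTY_LEVELS: tuple[float, ...] = tuple((8 - p_x) / 7 for p_x in range(8, 0, -1))

#: Target mean observed chance agreement at each difficulty level, used to
#: calibrate the guess rate (g = sqrt(2·o_ac) inverts E[o_ac] = g²/2).
OAC_CALIBRATION_LEVELS: tuple[float, ...] = (
    0.020,
    0.021,
    0.036,
    0.062,
    0.116,
    0.168,
    0.236,
    0.380,
)

#: Observed fraction of rating decisions landing on short-bar categories,
#: by category count, for the optional noise mode.
SHORT_BAR_RATES: dict[int, float] = {2: 0.0, 4: 0.0111, 6: 0.0193, 8: 0.0553}


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial design."""

    n_categories: int
    skew: float
    difficulty: float
    replicates: int = 4
    n_items: int = 100

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("at least two categories required")
        if not 0.0 < self.skew < 1.0:
            raise ValueError("skew must lie in (0, 1)")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if self.replicates < 1 or self.n_items < 1:
            raise ValueError("replicates and n_items must be positive")


@dataclass(frozen=True)
class RatingSession:
    """Truth-labeled paired ratings for one session.

    ``truth`` may be None for sessions read from files without a truth
    column; such sessions support index computation but no golden
    standard.
    """

    design: DesignCell
    rater1: np.ndarray
    rater2: np.ndarray
    truth: np.ndarray | None = None
    replicate: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        r1 = np.asarray(self.rater1, dtype=np.int64)
        r2 = np.asarray(self.rater2, dtype=np.int64)
        if r1.shape != r2.shape or r1.ndim != 1:
            raise ValueError("rater vectors must be 1-D and equal length")
        C = self.design.n_categories
        for name, r in (("rater1", r1), ("rater2", r2)):
            if r.size and (r.min() < 1 or r.max() > C):
                raise ValueError(f"{name} labels must lie in 1..{C}")
        object.__setattr__(self, "rater1", r1)
        object.__setattr__(self, "rater2", r2)
        if self.truth is not None:
            t = np.asarray(self.truth, dtype=np.int64)
            if t.shape != r1.shape:
                raise ValueError("truth must match rater vectors in length")
            if t.size and (t.min() < 1 or t.max() > C):
                raise ValueError(f"truth labels must lie in 1..{C}")
            object.__setattr__(self, "truth", t)

    @property
    def n_items(self) -> int:
        return int(self.rater1.size)


@dataclass(frozen=True)
class BehaviorModel:
    """Rater behavior: guess rate by difficulty, short-bar rate by C.

    ``guess_rate`` maps difficulty in [0, 1] to the probability that a
    single rating decision is an involuntary uniform guess between the
    two confusable categories; it must be monotone non-decreasing over
    the design's difficulty levels.  ``short_bar_rate`` maps the category
    count to the probability that a decision lands uniformly on one of
    the non-confusable categories 3..C (0 when C = 2).
    """

    guess_rate: Callable[[float], float]
    short_bar_rate: Callable[[int], float] = field(default=lambda C: 0.0)


def default_calibration(short_bar_noise: bool = False) -> BehaviorModel:
    """Behavior model calibrated to the study's difficulty profile.

    The guess rate at the eight design difficulties is g = sqrt(2·o_ac)
    for the per-level mean chance agreements in
    :data:`OAC_CALIBRATION_LEVELS` (so g runs ≈ .200 at the easiest level
    to ≈ .872 at the hardest), with linear interpolation between levels.
    Short-bar noise is off by default; when enabled, decisions fall on
    categories 3..C at the empirical rates in :data:`SHORT_BAR_RATES`.
    """
    levels = np.asarray(DIFFICULTY_LEVELS)
    g_values = np.sqrt(2.0 * np.asarray(OAC_CALIBRATION_LEVELS))

    def guess_rate(difficulty: float) -> float:
        return float(np.interp(difficulty, levels, g_values))

    rate = short_bar_noise_rate if short_bar_noise else (lambda C: 0.0)
    return BehaviorModel(guess_rate=guess_rate, short_bar_rate=rate)


def short_bar_noise_rate(n_categories: int) -> float:
    """Empirical short-bar decision rate for a category count."""
    try:
        return SHORT_BAR_RATES[n_categories]
    except KeyError:
        # interpolate on C for non-design category counts
        cs = sorted(SHORT_BAR_RATES)
        return float(
            np.interp(n_categories, cs, [SHORT_BAR_RATES[c] for c in cs])
        )


def enumerate_design(
    categories: Sequence[int] = (2, 4, 6, 8),
    skews: Sequence[float] = (0.5, 0.75, 0.99),
    difficulties: Sequence[float] = DIFFICULTY_LEVELS,
    replicates: int = 4,
    n_items: int = 100,
) -> list[DesignCell]:
    """Cross the design factors into cells, in deterministic order.

    Order is category-major, then difficulty, then skew, so cell index i
    is stable for seeding.  Defaults give 96 cells / 384 sessions.
    """
    if not categories or not skews or not difficulties:
        raise ValueError("every design factor needs at least one level")
    return [
        DesignCell(
            n_categories=c,
            skew=s,
            difficulty=d,
            replicates=replicates,
            n_items=n_items,
        )
        for c in categories
        for d in difficulties
        for s in skews
    ]


def session_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-session seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), cell_index, replicate])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_session(
    cell: DesignCell,
    model: BehaviorModel,
    seed: int,
    replicate: int = 0,
) -> RatingSession:
    """Simulate one rating session.

    Per item the true category is 1 with probability ``cell.skew``, else
    2.  Each rater independently: with probability ε(C) reports a uniform
    short-bar category (only when C > 2); otherwise with probability
    g(d_f) guesses uniformly between categories 1 and 2; otherwise
    reports the truth.  Deterministic under (seed, cell).
    """
    rng = np.random.default_rng(seed)
    n = cell.n_items
    C = cell.n_categories
    g = float(model.guess_rate(cell.difficulty))
    if not 0.0 <= g <= 1.0:
        raise ValueError("guess rate must lie in [0, 1]")
    eps = float(model.short_bar_rate(C)) if C > 2 else 0.0

    truth = np.where(rng.random(n) < cell.skew, 1, 2).astype(np.int64)

    raters = []
    for _ in range(2):
        ratings = truth.copy()
        guesses = rng.random(n) < g
        ratings[guesses] = rng.integers(1, 3, size=int(guesses.sum()))
        if eps > 0.0:
            stray = rng.random(n) < eps
            ratings[stray] = rng.integers(3, C + 1, size=int(stray.sum()))
        raters.append(ratings)

    return RatingSession(
        design=cell,
        rater1=raters[0],
        rater2=raters[1],
        truth=truth,
        replicate=replicate,
        seed=seed,
    )


def simulate_design(
    cells: Sequence[DesignCell],
    model: BehaviorModel,
    master_seed: int,
) -> list[RatingSession]:
    """Simulate every replicate of every cell with independent streams."""
    sessions = []
    for i, cell in enumerate(cells):
        for rep in range(cell.replicates):
            seed = session_seed(master_seed, i, rep)
            sessions.append(simulate_session(cell, model, seed, replicate=rep))
    return sessions
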