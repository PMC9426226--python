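"""End-to-end factorial experiment: simulate, score, evaluate, tabulate.

The pipeline turns a factorial design into four report tables:

1. **records** — one row per session with its design factors, golden
   standard and all fourteen index/chance estimates (the unit of
   analysis).
2. **factor_effects** — dr² of every estimator against its estimand
   (o_ri or o_ac) and against the manipulated factors C, s_k, d_f, with
   pretest stars.
3. **evaluation** — per estimator: mean, sd, range, dr² vs the estimand,
   m_e and e_m with CIs, and benchmark verdicts.
4. **cell_means** — estimator means at ground zero (C = 2, even skew)
   and by level of each factor, plus the grand mean.

A ranking table (index vs dr² for reliability and chance prediction) and
the meta-correlation between the two accuracy columns over the six
chance-adjusted indices round off the report.

Everything is deterministic under the master seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .golden import observe
from .indices import (
    CHANCE_FIELDS,
    RELIABILITY_FIELDS,
    ContingencyTable,
    compute_all,
)
from .metrics import (
    DEFAULT_BENCHMARKS,
    Benchmarks,
    benchmark,
    directional_r2,
    error_of_means,
    mean_of_errors,
    pretest_stars,
)
from .simulate import (
    DIFFICULTY_LEVELS,
    DesignCell,
    RatingSession,
    default_calibration,
    enumerate_design,
    simulate_design,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "score_sessions",
    "evaluation_report",
    "factor_effects",
    "cell_means",
    "ranking_table",
    "read_sessions",
    "write_sessions",
]

logger = logging.getLogger(__name__)

#: (estimator column, estimand column) pairs scored by the evaluation.
ESTIMATOR_TARGETS: tuple[tuple[str, str], ...] = tuple(
    [(f, "o_ri") for f in RELIABILITY_FIELDS]
    + [(f, "o_ac") for f in CHANCE_FIELDS]
)

_SESSION_COLUMNS = [
    "session_id",
    "n_categories",
    "skew",
    "difficulty",
    "replicate",
    "item",
    "truth",
    "rater1",
    "rater2",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design factors, session size, behavior model and benchmarks."""

    categories: tuple[int, ...] = (2, 4, 6, 8)
    skews: tuple[float, ...] = (0.5, 0.75, 0.99)
    difficulties: tuple[float, ...] = DIFFICULTY_LEVELS
    replicates: int = 4
    n_items: int = 100
    short_bar_noise: bool = False
    benchmarks: Benchmarks = field(default_factory=Benchmarks)

    def __post_init__(self) -> None:
        if not self.categories or not self.skews or not self.difficulties:
            raise ValueError("every design factor needs at least one level")
        if min(self.categories) < 2:
            raise ValueError("at least two categories required")
        if self.replicates < 1 or self.n_items < 1:
            raise ValueError("replicates and n_items must be positive")

    @property
    def n_sessions(self) -> int:
        return (
            len(self.categories)
            * len(self.skews)
            * len(self.difficulties)
            * self.replicates
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bench = raw.pop("benchmarks", None)
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        if bench is not None:
            kwargs["benchmarks"] = Benchmarks(**bench)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "categories": list(self.categories),
            "skews": list(self.skews),
            "difficulties": list(self.difficulties),
            "replicates": self.replicates,
            "n_items": self.n_items,
            "short_bar_noise": self.short_bar_noise,
            "benchmarks": {
                "primary_dr2": self.benchmarks.primary_dr2,
                "tentative_dr2": self.benchmarks.tentative_dr2,
                "secondary_me": self.benchmarks.secondary_me,
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class ExperimentResult:
    """All outputs of one experiment run."""

    records: pd.DataFrame
    evaluation: pd.DataFrame
    factor_effects: pd.DataFrame
    cell_means: pd.DataFrame
    ranking: pd.DataFrame
    meta_dr2: float
    config: ExperimentConfig
    seed: int


def simulate_sessions(
    config: ExperimentConfig, seed: int
) -> list[RatingSession]:
    """Generate every session of the configured design."""
    cells = enumerate_design(
        categories=config.categories,
        skews=config.skews,
        difficulties=config.difficulties,
        replicates=config.replicates,
        n_items=config.n_items,
    )
    model = default_calibration(short_bar_noise=config.short_bar_noise)
    return simulate_design(cells, model, master_seed=seed)


def score_sessions(sessions: Sequence[RatingSession]) -> pd.DataFrame:
    """Golden standard plus index estimates, one row per session."""
    rows = []
    n_undefined = 0
    for i, session in enumerate(sessions):
        table = ContingencyTable.from_ratings(
            session.rater1, session.rater2, session.design.n_categories
        )
        estimates = compute_all(table)
        if estimates.undefined:
            n_undefined += 1
            logger.warning(
                "session %d: undefined estimates %s",
                i,
                estimates.undefined,
            )
        row = {
            "session_id": i,
            "n_categories": session.design.n_categories,
            "skew": session.design.skew,
            "difficulty": session.design.difficulty,
            "replicate": session.replicate,
        }
        if session.truth is not None:
            row.update(observe(session).as_dict())
        row.update(estimates.as_dict())
        rows.append(row)
    if n_undefined:
        logger.info("%d sessions had undefined estimates", n_undefined)
    return pd.DataFrame(rows)


def evaluation_report(
    records: pd.DataFrame, benchmarks: Benchmarks = DEFAULT_BENCHMARKS
) -> pd.DataFrame:
    """Score every estimator against its estimand across sessions."""
    rows = []
    for estimator, target in ESTIMATOR_TARGETS:
        x = records[estimator].to_numpy(dtype=float)
        y = records[target].to_numpy(dtype=float)
        corr = directional_r2(x, y)
        err = mean_of_errors(x, y)
        bias = error_of_means(x, y)
        verdicts = benchmark(corr.dr2, err.m_e, benchmarks)
        finite = x[np.isfinite(x)]
        rows.append(
            {
                "estimator": estimator,
                "target": target,
                "mean": float(finite.mean()),
                "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                "min": float(finite.min()),
                "max": float(finite.max()),
                "dr2": corr.dr2,
                "p_pretest": corr.p_pretest,
                "stars": pretest_stars(corr.p_pretest),
                "m_e": err.m_e,
                "m_e_sd": err.sd,
                "m_e_ci_low": err.ci_low,
                "m_e_ci_high": err.ci_high,
                "e_m": bias.e_m,
                "e_m_ci_low": bias.ci_low,
                "e_m_ci_high": bias.ci_high,
                "n_used": err.n_used,
                "primary": verdicts["primary"],
                "tentative": verdicts["tentative"],
                "secondary": verdicts["secondary"],
            }
        )
    return pd.DataFrame(rows)


def factor_effects(records: pd.DataFrame) -> pd.DataFrame:
    """dr² of each estimator against its estimand and the design factors."""
    blocks = [
        ("reliability", "o_ri", ("o_ri",) + RELIABILITY_FIELDS),
        ("chance", "o_ac", ("o_ac",) + CHANCE_FIELDS),
    ]
    predictors = [
        ("n_categories", "C"),
        ("skew", "s_k"),
        ("difficulty", "d_f"),
    ]
    rows = []
    for block, estimand, dependents in blocks:
        ivs = [(estimand, estimand)] + predictors
        for column, label in ivs:
            iv = records[column].to_numpy(dtype=float)
            row: dict[str, object] = {"block": block, "independent": label}
            for dep in dependents:
                corr = directional_r2(records[dep].to_numpy(dtype=float), iv)
                row[dep] = corr.dr2
                row[f"{dep}_stars"] = pretest_stars(corr.p_pretest)
            rows.append(row)
    return pd.DataFrame(rows)


def cell_means(records: pd.DataFrame) -> pd.DataFrame:
    """Estimator means at ground zero, by factor level, and overall.

    Ground zero is the reference condition C = 2 with an even (0.5) true
    distribution, pooled over difficulty.  Undefined estimates are
    excluded from the means.
    """
    cols = ["o_ri"] + list(RELIABILITY_FIELDS) + ["o_ac"] + list(CHANCE_FIELDS)
    cols = [c for c in cols if c in records.columns]

    def mean_row(label: str, level, frame: pd.DataFrame) -> dict:
        row: dict[str, object] = {"group": label, "level": level}
        row.update(frame[cols].mean(skipna=True).to_dict())
        row["n_sessions"] = len(frame)
        return row

    rows = [
        mean_row(
            "ground_zero",
            "",
            records[
                (records["n_categories"] == 2) & (records["skew"] == 0.5)
            ],
        )
    ]
    for column, label in (
        ("n_categories", "category"),
        ("skew", "skew"),
        ("difficulty", "difficulty"),
    ):
        for level in sorted(records[column].unique()):
            rows.append(
                mean_row(label, level, records[records[column] == level])
            )
    rows.append(mean_row("mean", "", records))
    return pd.DataFrame(rows)


#: The six indices that subtract an estimated chance agreement.
CHANCE_ADJUSTED = ("s", "i_r", "ac1", "pi", "kappa", "alpha")
_CHANCE_OF = {
    "a_o": "ao_ac",
    "s": "s_ac",
    "i_r": "ir_ac",
    "ac1": "ac1_ac",
    "pi": "pi_ac",
    "kappa": "kappa_ac",
    "alpha": "alpha_ac",
}


def ranking_table(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rank indices by predictive accuracy for reliability and chance.

    Returns the ranking table and the meta-correlation (dr²) between the
    two accuracy columns over the six chance-adjusted indices (percent
    agreement's constant chance estimate has no defined correlation, so
    it cannot enter the meta-correlation).
    """
    o_ri = records["o_ri"].to_numpy(dtype=float)
    o_ac = records["o_ac"].to_numpy(dtype=float)
    rows = []
    for index in RELIABILITY_FIELDS:
        rel = directional_r2(records[index].to_numpy(dtype=float), o_ri)
        cha = directional_r2(
            records[_CHANCE_OF[index]].to_numpy(dtype=float), o_ac
        )
        rows.append(
            {
                "index": index,
                "dr2_reliability": rel.dr2,
                "dr2_chance": cha.dr2,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("dr2_reliability", ascending=False)
        .reset_index(drop=True)
    )
    adjusted = table[table["index"].isin(CHANCE_ADJUSTED)]
    meta = directional_r2(
        adjusted["dr2_chance"].to_numpy(), adjusted["dr2_reliability"].to_numpy()
    )
    return table, meta.dr2


def run_experiment(
    config: ExperimentConfig | None = None, seed: int = 0
) -> ExperimentResult:
    """Simulate the design, score every session, and build all tables."""
    config = config or ExperimentConfig()
    sessions = simulate_sessions(config, seed)
    logger.info("simulated %d sessions", len(sessions))
    records = score_sessions(sessions)
    evaluation = evaluation_report(records, config.benchmarks)
    effects = factor_effects(records)
    means = cell_means(records)
    ranking, meta = ranking_table(records)
    return ExperimentResult(
        records=records,
        evaluation=evaluation,
        factor_effects=effects,
        cell_means=means,
        ranking=ranking,
        meta_dr2=meta,
        config=config,
        seed=seed,
    )


def write_sessions(
    sessions: Sequence[RatingSession], path: str | Path
) -> None:
    """Write sessions as CSV, one row per rated item."""
    frames = []
    for i, s in enumerate(sessions):
        frame = pd.DataFrame(
            {
                "session_id": i,
                "n_categories": s.design.n_categories,
                "skew": s.design.skew,
                "difficulty": s.design.difficulty,
                "replicate": s.replicate,
                "item": np.arange(1, s.n_items + 1),
                "truth": s.truth if s.truth is not None else pd.NA,
                "rater1": s.rater1,
                "rater2": s.rater2,
            }
        )
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sessions(path: str | Path) -> list[RatingSession]:
    """Read sessions from the CSV rating format, validating labels.

    A missing ``truth`` column is accepted (index computation does not
    need it); the golden standard will reject such sessions.
    """
    frame = pd.read_csv(path)
    required = set(_SESSION_COLUMNS) - {"truth"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    has_truth = "truth" in frame.columns
    sessions = []
    for sid, group in frame.groupby("session_id", sort=True):
        C = int(group["n_categories"].iloc[0])
        cell = DesignCell(
            n_categories=C,
            skew=float(group["skew"].iloc[0]),
            difficulty=float(group["difficulty"].iloc[0]),
            replicates=1,
            n_items=len(group),
        )
        for col in ("rater1", "rater2") + (("truth",) if has_truth else ()):
            values = group[col]
            bad = values.isna() | (values < 1) | (values > C)
            if bad.any():
                # +2: header line plus 1-based indexing
                line = int(group.index[bad.to_numpy()][0]) + 2
                raise ValueError(
                    f"line {line}: {col} label outside 1..{C} "
                    f"in session {sid}"
                )
        sessions.append(
            RatingSession(
                design=cell,
                rater1=group["rater1"].to_numpy(dtype=np.int64),
                rater2=group["rater2"].to_numpy(dtype=np.int64),
                truth=(
                    group["truth"].to_numpy(dtype=np.int64)
                    if has_truth
                    else None
                ),
                replicate=int(group["replicate"].iloc[0]),
            )
        )
    return sessions
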