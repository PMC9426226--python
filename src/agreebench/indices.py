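"""Chance-corrected interrater agreement indices for two raters, nominal data.

Seven reliability estimates and their chance-agreement estimators are
computed from a C×C contingency table of paired categorical ratings:

===================  ==============  =================================
Index                Chance model    Chance agreement estimator
===================  ==============  =================================
percent agreement    none            0 (a constant)
Bennett et al. S     category count  1/C
Perreault–Leigh I_r  category count  1/C (shares S's estimator)
Gwet AC1             category+skew   (1/(C-1)) Σ p̄_k (1 − p̄_k)
Scott pi             pooled margins  Σ p̄_k²
Cohen kappa          rater margins   Σ p_k1 p_k2
Krippendorff alpha   pooled margins  Σ n_k(n_k−1) / (n(n−1))
===================  ==============  =================================

where p̄_k is the pooled marginal proportion of category k over both
raters, p_k1/p_k2 the per-rater marginal proportions, and n = 2·n_items
the pooled number of rating values.  Every chance-adjusted index applies
the same correction  r = (a_o − a_c) / (1 − a_c);  I_r additionally takes
the square root of S (clamped at 0 for negative S).

The number of admissible categories C is always the *declared* category
set of the rating task, never the set of labels observed in the data:
empty categories lower 1/C and the AC1 estimator, and that sensitivity is
a property of the indices themselves.

A degenerate chance estimate a_c = 1 (e.g. both raters use a single
category for every item) makes the correction undefined; such estimates
are returned as NaN, never silently substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ContingencyTable",
    "IndexEstimates",
    "RELIABILITY_FIELDS",
    "CHANCE_FIELDS",
    "percent_agreement",
    "chance_s",
    "chance_pi",
    "chance_kappa",
    "chance_alpha",
    "chance_ac1",
    "chance_correct",
    "index_ir",
    "compute_all",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of two raters' category assignments.

    ``counts[j, k]`` is the number of items rater 1 assigned category
    ``j + 1`` and rater 2 assigned category ``k + 1`` (labels are
    1-based).  ``n_categories`` is the declared size of the category set;
    rows/columns for unused categories are present and zero.
    """

    counts: np.ndarray
    n_categories: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.n_categories < 2:
            raise ValueError("at least two categories required")
        if counts.shape[0] != self.n_categories:
            raise ValueError(
                f"counts is {counts.shape[0]}×{counts.shape[0]} but "
                f"n_categories={self.n_categories}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_ratings(
        cls, rater1, rater2, n_categories: int
    ) -> "ContingencyTable":
        """Cross-tabulate two equal-length vectors of 1-based labels."""
        r1 = np.asarray(rater1, dtype=np.int64)
        r2 = np.asarray(rater2, dtype=np.int64)
        if r1.shape != r2.shape or r1.ndim != 1:
            raise ValueError("rater vectors must be 1-D and equal length")
        if n_categories < 2:
            raise ValueError("at least two categories required")
        for name, r in (("rater1", r1), ("rater2", r2)):
            if r.size and (r.min() < 1 or r.max() > n_categories):
                raise ValueError(
                    f"{name} labels must lie in 1..{n_categories}"
                )
        counts = np.zeros((n_categories, n_categories), dtype=np.int64)
        np.add.at(counts, (r1 - 1, r2 - 1), 1)
        return cls(counts=counts, n_categories=n_categories)

    def pooled_proportions(self) -> np.ndarray:
        """Marginal proportions pooled over both raters, p̄_k."""
        self._require_items()
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        return (row + col) / (2.0 * self.n_items)

    def rater_proportions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-rater marginal proportions (p_k1, p_k2)."""
        self._require_items()
        n = self.n_items
        return self.counts.sum(axis=1) / n, self.counts.sum(axis=0) / n

    def _require_items(self) -> None:
        if self.n_items < 1:
            raise ValueError("no rated items")


# Reliability estimates and chance estimates, in the conventional order
# (percent agreement, Bennett S, Perreault-Leigh I_r, Gwet AC1, Scott pi,
# Cohen kappa, Krippendorff alpha).
RELIABILITY_FIELDS = ("a_o", "s", "i_r", "ac1", "pi", "kappa", "alpha")
CHANCE_FIELDS = (
    "ao_ac",
    "s_ac",
    "ir_ac",
    "ac1_ac",
    "pi_ac",
    "kappa_ac",
    "alpha_ac",
)


@dataclass(frozen=True)
class IndexEstimates:
    """Per-session values of the seven indices and their chance estimates.

    Undefined estimates (degenerate chance denominator) are NaN.
    ``ao_ac`` is identically 0 — percent agreement assumes no chance
    agreement — and ``ir_ac`` always equals ``s_ac``.
    """

    a_o: float
    s: float
    i_r: float
    ac1: float
    pi: float
    kappa: float
    alpha: float
    ao_ac: float
    s_ac: float
    ir_ac: float
    ac1_ac: float
    pi_ac: float
    kappa_ac: float
    alpha_ac: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def undefined(self) -> tuple[str, ...]:
        """Names of estimates flagged undefined (NaN)."""
        return tuple(
            f.name for f in fields(self) if math.isnan(getattr(self, f.name))
        )


def percent_agreement(table: ContingencyTable) -> float:
    """Observed proportion of items on which the raters agree, a_o."""
    table._require_items()
    return float(np.trace(table.counts)) / table.n_items


def chance_s(n_categories: int) -> float:
    """Chance agreement under the uniform-category model, 1/C.

    Used by Bennett et al.'s S and, identically, by Perreault and
    Leigh's I_r.  Depends only on the declared category count.
    """
    if n_categories < 2:
        raise ValueError("at least two categories required")
    return 1.0 / n_categories


def chance_pi(table: ContingencyTable) -> float:
    """Scott's chance agreement: Σ p̄_k² over pooled marginals."""
    p = table.pooled_proportions()
    return float(np.sum(p * p))


def chance_kappa(table: ContingencyTable) -> float:
    """Cohen's chance agreement: Σ p_k1·p_k2 over per-rater marginals."""
    p1, p2 = table.rater_proportions()
    return float(np.sum(p1 * p2))


def chance_alpha(table: ContingencyTable) -> float:
    """Krippendorff's chance agreement for two raters, nominal data.

    Σ n_k(n_k − 1) / (n(n − 1)) over pooled category counts n_k, with
    n = 2·n_items.  The finite-sample (n−1) correction makes this
    converge to :func:`chance_pi` from below as n grows.
    """
    table._require_items()
    row = table.counts.sum(axis=1)
    col = table.counts.sum(axis=0)
    n_k = (row + col).astype(np.float64)
    n = 2.0 * table.n_items
    if n < 2:
        raise ValueError("need at least two pooled rating values")
    return float(np.sum(n_k * (n_k - 1.0)) / (n * (n - 1.0)))


def chance_ac1(table: ContingencyTable) -> float:
    """Gwet's AC1 chance agreement: (1/(C−1)) Σ p̄_k (1 − p̄_k).

    A function of both the category count and the pooled skew; maximal
    at the even distribution and vanishing under extreme skew — the
    reverse of the skew response of pi/kappa/alpha.
    """
    if table.n_categories < 2:
        raise ValueError("at least two categories required")
    p = table.pooled_proportions()
    return float(np.sum(p * (1.0 - p)) / (table.n_categories - 1))


def chance_correct(a_o: float, a_c: float) -> float:
    """Remove estimated chance agreement: r = (a_o − a_c) / (1 − a_c).

    Returns NaN (undefined) when a_c = 1, where the correction has a
    zero denominator.  NaN inputs propagate.
    """
    if math.isnan(a_o) or math.isnan(a_c):
        return math.nan
    if not 0.0 <= a_o <= 1.0:
        raise ValueError("a_o must lie in [0, 1]")
    if not 0.0 <= a_c <= 1.0:
        raise ValueError("a_c must lie in [0, 1]")
    if a_c == 1.0:
        return math.nan
    return (a_o - a_c) / (1.0 - a_c)


def index_ir(s: float) -> float:
    """Perreault and Leigh's I_r = √S for S ≥ 0, 0 for S < 0.

    Undefined (NaN) S propagates.
    """
    if math.isnan(s):
        return math.nan
    return math.sqrt(s) if s >= 0.0 else 0.0


def compute_all(table: ContingencyTable) -> IndexEstimates:
    """All seven reliability estimates and chance estimates for a table."""
    a_o = percent_agreement(table)
    s_ac = chance_s(table.n_categories)
    ac1_ac = chance_ac1(table)
    pi_ac = chance_pi(table)
    kappa_ac = chance_kappa(table)
    alpha_ac = chance_alpha(table)

    s = chance_correct(a_o, s_ac)
    return IndexEstimates(
        a_o=a_o,
        s=s,
        i_r=index_ir(s),
        ac1=chance_correct(a_o, ac1_ac),
        pi=chance_correct(a_o, pi_ac),
        kappa=chance_correct(a_o, kappa_ac),
        alpha=chance_correct(a_o, alpha_ac),
        ao_ac=0.0,
        s_ac=s_ac,
        ir_ac=s_ac,
        ac1_ac=ac1_ac,
        pi_ac=pi_ac,
        kappa_ac=kappa_ac,
        alpha_ac=alpha_ac,
    )
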