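"""Observed ("golden standard") reliability from truth-labeled sessions.

When the truth of every item is known, the quantities the agreement
indices try to estimate can be observed directly.  With guessing confined
to two confusable categories, half of all chance agreements land on the
truth, so the observed chance agreement is twice the agree-and-wrong
proportion:

    o_ar = P(both raters right)        o_ae = P(agree but wrong)
    a_o  = o_ar + o_ae                 d_o  = 1 − a_o
    o_ac = 2·o_ae                      o_ri = a_o − o_ac = o_ar − o_ae

o_ac is a model-based estimate of chance agreement, not a probability: it
can exceed 1 (all items agree-wrong gives o_ac = 2), and o_ri can be
negative.  Neither is clamped.

The accuracy threshold t_h = o_ac / (1 − o_ri) is the chance-agreement
value at which the common correction r = (a_o − a_c)/(1 − a_c) returns
o_ri exactly; an index whose a_c exceeds t_h underestimates reliability
on that session, one below t_h overestimates.  Since t_h > o_ac whenever
o_ri·o_ac > 0, an index that estimates chance agreement *accurately*
necessarily underestimates reliability — the chance-removal paradox.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import RatingSession

__all__ = ["GoldenStandard", "observe", "threshold"]


@dataclass(frozen=True)
class GoldenStandard:
    """Observed agreement decomposition and reliability for one session."""

    o_ar: float  # agree and right
    o_ae: float  # agree and wrong
    a_o: float  # observed agreement
    d_o: float  # observed disagreement
    o_ac: float  # observed chance agreement, 2·o_ae
    o_ri: float  # observed reliability, a_o − o_ac
    t_h: float  # accuracy threshold, inf when o_ri = 1

    def as_dict(self) -> dict[str, float]:
        return {
            "o_ar": self.o_ar,
            "o_ae": self.o_ae,
            "a_o": self.a_o,
            "d_o": self.d_o,
            "o_ac": self.o_ac,
            "o_ri": self.o_ri,
            "t_h": self.t_h,
        }


def observe(session: RatingSession) -> GoldenStandard:
    """Compute the golden standard for a truth-labeled session."""
    if session.truth is None:
        raise ValueError("golden standard requires truth")
    if session.n_items < 1:
        raise ValueError("no rated items")
    truth = session.truth
    agree = session.rater1 == session.rater2
    n = session.n_items
    o_ar = float(np.sum(agree & (session.rater1 == truth))) / n
    o_ae = float(np.sum(agree & (session.rater1 != truth))) / n
    a_o = o_ar + o_ae
    o_ac = 2.0 * o_ae
    o_ri = a_o - o_ac
    return GoldenStandard(
        o_ar=o_ar,
        o_ae=o_ae,
        a_o=a_o,
        d_o=1.0 - a_o,
        o_ac=o_ac,
        o_ri=o_ri,
        t_h=threshold(o_ac, o_ri) if o_ri < 1.0 else math.inf,
    )


def threshold(o_ac: float, o_ri: float) -> float:
    """Chance-agreement level at which the correction is exact.

    t_h = o_ac / (1 − o_ri).  For a session with observed chance
    agreement o_ac and reliability o_ri, an index with a_c = t_h
    reproduces o_ri exactly through the chance correction; a_c > t_h
    underestimates, a_c < t_h overestimates.  Returns inf when o_ri = 1
    (the threshold is unbounded there).
    """
    if o_ri >= 1.0:
        return math.inf
    return o_ac / (1.0 - o_ri)
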