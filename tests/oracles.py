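"""Independent brute-force oracles, computed from raw rating lists.

Each oracle recomputes an index from the two raters' label lists using
the published closed form of that index (pure-Python loops, no
contingency table, no shared chance-correction helper), so the oracles
exercise a different algebraic route than the implementation:

* Bennett S via the original (C·a_o − 1)/(C − 1) form;
* Krippendorff alpha via the coincidence-matrix disagreement route,
  1 − D_o/D_e;
* pi/kappa/AC1 via their own expected-agreement forms.
"""

from __future__ import annotations

import math
from collections import Counter


def percent_agreement(r1, r2) -> float:
    return sum(1 for a, b in zip(r1, r2) if a == b) / len(r1)


def bennett_s(r1, r2, n_categories: int) -> float:
    a_o = percent_agreement(r1, r2)
    return (n_categories * a_o - 1.0) / (n_categories - 1.0)


def perreault_leigh_ir(r1, r2, n_categories: int) -> float:
    s = bennett_s(r1, r2, n_categories)
    return math.sqrt(s) if s >= 0.0 else 0.0


def scott_pi(r1, r2) -> float:
    n = len(r1)
    pooled = Counter(r1) + Counter(r2)
    a_e = sum((c / (2.0 * n)) ** 2 for c in pooled.values())
    a_o = percent_agreement(r1, r2)
    if a_e == 1.0:
        return math.nan
    return (a_o - a_e) / (1.0 - a_e)


def scott_chance(r1, r2) -> float:
    n = len(r1)
    pooled = Counter(r1) + Counter(r2)
    return sum((c / (2.0 * n)) ** 2 for c in pooled.values())


def cohen_kappa(r1, r2) -> float:
    n = len(r1)
    c1, c2 = Counter(r1), Counter(r2)
    a_e = sum(c1[k] * c2.get(k, 0) for k in c1) / (n * n)
    a_o = percent_agreement(r1, r2)
    if a_e == 1.0:
        return math.nan
    return (a_o - a_e) / (1.0 - a_e)


def cohen_chance(r1, r2) -> float:
    n = len(r1)
    c1, c2 = Counter(r1), Counter(r2)
    return sum(c1[k] * c2.get(k, 0) for k in c1) / (n * n)


def gwet_ac1(r1, r2, n_categories: int) -> float:
    a_e = gwet_chance(r1, r2, n_categories)
    a_o = percent_agreement(r1, r2)
    if a_e == 1.0:
        return math.nan
    return (a_o - a_e) / (1.0 - a_e)


def gwet_chance(r1, r2, n_categories: int) -> float:
    n = len(r1)
    pooled = Counter(r1) + Counter(r2)
    probs = [pooled.get(k, 0) / (2.0 * n) for k in range(1, n_categories + 1)]
    return sum(p * (1.0 - p) for p in probs) / (n_categories - 1.0)


def krippendorff_alpha(r1, r2) -> float:
    """Alpha via observed vs expected pairwise disagreement, 1 − D_o/D_e."""
    n_units = len(r1)
    n = 2 * n_units
    # coincidence counts: each unit contributes both ordered pairs
    disagreements = 0
    for a, b in zip(r1, r2):
        if a != b:
            disagreements += 2
    d_o = disagreements / n
    pooled = Counter(r1) + Counter(r2)
    d_e = sum(
        pooled[k] * pooled[l]
        for k in pooled
        for l in pooled
        if k != l
    ) / (n * (n - 1.0))
    if d_e == 0.0:
        return math.nan
    return 1.0 - d_o / d_e


def krippendorff_chance(r1, r2) -> float:
    n = 2 * len(r1)
    pooled = Counter(r1) + Counter(r2)
    return sum(c * (c - 1.0) for c in pooled.values()) / (n * (n - 1.0))
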