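import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agreebench.indices import (
    ContingencyTable,
    chance_ac1,
    chance_alpha,
    chance_correct,
    chance_kappa,
    chance_pi,
    chance_s,
    compute_all,
    index_ir,
    percent_agreement,
)

import oracles
from conftest import enumerate_2x2_tables


def table(counts, C=None):
    counts = np.asarray(counts)
    return ContingencyTable(counts=counts, n_categories=C or counts.shape[0])


# ---------------------------------------------------------------- examples


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([[100, 0], [0, 0]], 1.0),  # all pairs identical
        ([[40, 20], [12, 28]], 0.68),  # 68 of 100 on the diagonal
        ([[50, 20], [12, 18]], 0.68),  # diagonal (50,18), off (20,12)
    ],
)
def test_percent_agreement_counts(counts, expected):
    assert percent_agreement(table(counts)) == pytest.approx(expected)


@pytest.mark.parametrize("C, expected", [(2, 0.5), (4, 0.25), (8, 0.125)])
def test_uniform_category_chance(C, expected):
    assert chance_s(C) == pytest.approx(expected)


def test_chance_s_rejects_single_category():
    with pytest.raises(ValueError, match="two categories"):
        chance_s(1)


def test_scott_chance_from_pooled_marginals():
    # pooled marginals (.5, .5)
    assert chance_pi(table([[25, 25], [25, 25]])) == pytest.approx(0.5)
    # pooled marginals (.75, .25): both raters 75/25
    assert chance_pi(table([[55, 20], [20, 5]])) == pytest.approx(0.625)
    # total concentration
    assert chance_pi(table([[100, 0], [0, 0]])) == pytest.approx(1.0)


def test_cohen_chance_from_rater_marginals():
    assert chance_kappa(table([[25, 25], [25, 25]])) == pytest.approx(0.5)
    # marginals (.7,.3) and (.6,.4): .7*.6 + .3*.4 = .54
    assert chance_kappa(table([[42, 28], [18, 12]])) == pytest.approx(0.54)
    # disjoint support: rater 1 all category 1, rater 2 all category 2
    assert chance_kappa(table([[0, 10], [0, 0]])) == pytest.approx(0.0)


def test_krippendorff_chance_small_sample_correction():
    # pooled counts (100, 100): 2*100*99 / (200*199)
    t = table([[25, 25], [25, 25]])
    assert chance_alpha(t) == pytest.approx(19800 / 39800, abs=1e-12)
    assert chance_alpha(table([[100, 0], [0, 0]])) == pytest.approx(1.0)


def test_krippendorff_chance_converges_to_scott():
    n = 10_000
    t = table([[n // 2, n // 4], [n // 8, n - n // 2 - n // 4 - n // 8]])
    assert chance_alpha(t) == pytest.approx(chance_pi(t), abs=1e-3)


def test_gwet_chance_category_and_skew():
    assert chance_ac1(table([[25, 25], [25, 25]])) == pytest.approx(0.5)
    # C=2, pooled (.99, .01): 2 * .99 * .01
    assert chance_ac1(table([[98, 1], [1, 0]])) == pytest.approx(0.0198)
    # C=4, pooled uniform: (1/3) * 4 * (.25 * .75)
    t4 = table(np.diag([25, 25, 25, 25]))
    assert chance_ac1(t4) == pytest.approx(0.25)


@pytest.mark.parametrize(
    "a_o, a_c, expected",
    [(0.685, 0.0, 0.685), (0.8, 0.5, 0.6), (0.3, 0.3, 0.0)],
)
def test_chance_correction(a_o, a_c, expected):
    assert chance_correct(a_o, a_c) == pytest.approx(expected)


def test_chance_correction_degenerate_denominator_is_flagged():
    assert math.isnan(chance_correct(0.5, 1.0))


def test_chance_correction_rejects_out_of_range():
    with pytest.raises(ValueError):
        chance_correct(1.2, 0.5)
    with pytest.raises(ValueError):
        chance_correct(0.5, -0.1)


@pytest.mark.parametrize(
    "s, expected", [(0.64, 0.8), (-0.1, 0.0), (0.0, 0.0), (1.0, 1.0)]
)
def test_square_root_index(s, expected):
    assert index_ir(s) == pytest.approx(expected)


def test_square_root_index_propagates_undefined():
    assert math.isnan(index_ir(math.nan))


# ------------------------------------------------------------- compute_all


def test_perfect_balanced_agreement_gives_unit_estimates():
    est = compute_all(table([[50, 0], [0, 50]]))
    for name in ("a_o", "s", "i_r", "ac1", "pi", "kappa", "alpha"):
        assert getattr(est, name) == pytest.approx(1.0)


def test_ground_zero_chance_estimates_coincide_near_half():
    """At C=2 with even pooled margins all chance models agree at 0.5."""
    est = compute_all(table([[40, 10], [10, 40]]))
    for name in ("s_ac", "ir_ac", "ac1_ac", "pi_ac", "kappa_ac"):
        assert getattr(est, name) == pytest.approx(0.5)
    assert est.alpha_ac == pytest.approx(0.5, abs=0.005)
    assert est.ao_ac == 0.0
    assert est.ir_ac == est.s_ac


def test_degenerate_session_flags_undefined():
    """Both raters in one category: every skew-based estimate undefined."""
    est = compute_all(table([[100, 0], [0, 0]]))
    assert set(est.undefined) >= {"pi", "kappa", "alpha"}
    assert est.a_o == 1.0  # percent agreement is always defined


def test_empty_table_rejected():
    with pytest.raises(ValueError, match="no rated items"):
        percent_agreement(table([[0, 0], [0, 0]]))


def test_declared_categories_not_inferred():
    """Empty categories still lower the category-based chance estimates."""
    r1 = [1, 1, 2, 2]
    r2 = [1, 2, 1, 2]
    t2 = ContingencyTable.from_ratings(r1, r2, n_categories=2)
    t8 = ContingencyTable.from_ratings(r1, r2, n_categories=8)
    assert compute_all(t2).s_ac == pytest.approx(0.5)
    assert compute_all(t8).s_ac == pytest.approx(0.125)
    assert compute_all(t8).ac1_ac < compute_all(t2).ac1_ac
    # skew-based estimators ignore the declared category count
    assert compute_all(t8).pi_ac == compute_all(t2).pi_ac


def test_from_ratings_rejects_out_of_range_labels():
    with pytest.raises(ValueError, match="1..2"):
        ContingencyTable.from_ratings([1, 3], [1, 1], n_categories=2)


# ------------------------------------------------- oracle equivalence


def test_all_estimators_match_brute_force_on_enumerated_tables():
    """Every estimator equals an independent closed-form recomputation
    from raw rating lists, on all 2×2 tables with n ≤ 12."""
    for counts, r1, r2 in enumerate_2x2_tables(12):
        est = compute_all(ContingencyTable(counts=counts, n_categories=2))
        expect = {
            "a_o": oracles.percent_agreement(r1, r2),
            "s": oracles.bennett_s(r1, r2, 2),
            "i_r": oracles.perreault_leigh_ir(r1, r2, 2),
            "ac1": oracles.gwet_ac1(r1, r2, 2),
            "pi": oracles.scott_pi(r1, r2),
            "kappa": oracles.cohen_kappa(r1, r2),
            "alpha": oracles.krippendorff_alpha(r1, r2),
            "s_ac": 0.5,
            "ac1_ac": oracles.gwet_chance(r1, r2, 2),
            "pi_ac": oracles.scott_chance(r1, r2),
            "kappa_ac": oracles.cohen_chance(r1, r2),
            "alpha_ac": oracles.krippendorff_chance(r1, r2),
        }
        for name, want in expect.items():
            got = getattr(est, name)
            if math.isnan(want):
                assert math.isnan(got), (name, counts)
            else:
                assert got == pytest.approx(want, abs=1e-12), (name, counts)


def test_ordering_invariants_on_enumerated_tables():
    """S ≤ I_r when S ≥ 0, κ ≥ π, and α ≥ π (when defined) on all small
    2×2 tables — the systematic orderings among the index families."""
    for counts, _, _ in enumerate_2x2_tables(12):
        est = compute_all(ContingencyTable(counts=counts, n_categories=2))
        if not math.isnan(est.s) and est.s >= 0:
            assert est.s <= est.i_r + 1e-12
        if not math.isnan(est.pi) and not math.isnan(est.kappa):
            assert est.kappa >= est.pi - 1e-12
        if not math.isnan(est.pi) and not math.isnan(est.alpha):
            assert est.alpha >= est.pi - 1e-12


def test_alpha_approaches_pi_at_rate_one_over_n():
    """The finite-sample gap α − π shrinks like 1/n and is non-negative."""
    gaps = []
    for n in (10, 100, 1000):
        counts = np.array([[3 * n, n], [n, 5 * n]])
        est = compute_all(ContingencyTable(counts=counts, n_categories=2))
        assert est.alpha >= est.pi
        gaps.append((est.alpha - est.pi) * counts.sum())
    # scaled gaps stay bounded: O(1/n_items) decay
    assert max(gaps) < 2 * min(gaps) + 1e-9


# --------------------------------------------------------- property tests

rating_lists = st.integers(2, 5).flatmap(
    lambda C: st.tuples(
        st.just(C),
        st.lists(
            st.tuples(st.integers(1, C), st.integers(1, C)),
            min_size=2,
            max_size=40,
        ),
    )
)


@settings(deadline=None)
@given(rating_lists, st.randoms(use_true_random=False))
def test_permutation_invariance(data, rnd):
    """Relabeling categories (same C) leaves every estimate unchanged."""
    C, pairs = data
    r1, r2 = zip(*pairs)
    perm = list(range(1, C + 1))
    rnd.shuffle(perm)
    relabel = {k + 1: perm[k] for k in range(C)}
    t = ContingencyTable.from_ratings(r1, r2, C)
    tp = ContingencyTable.from_ratings(
        [relabel[x] for x in r1], [relabel[x] for x in r2], C
    )
    a, b = compute_all(t), compute_all(tp)
    for name, want in a.as_dict().items():
        got = getattr(b, name)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


@settings(deadline=None)
@given(rating_lists)
def test_pooled_chance_dominates_rater_specific_chance(data):
    """Σ p̄_k² ≥ Σ p_k1 p_k2 (AM–GM), hence π ≤ κ whenever both defined."""
    C, pairs = data
    r1, r2 = zip(*pairs)
    t = ContingencyTable.from_ratings(r1, r2, C)
    assert chance_pi(t) >= chance_kappa(t) - 1e-12


@settings(deadline=None)
@given(st.floats(0.0, 1.0))
def test_zero_chance_correction_is_identity(a_o):
    assert chance_correct(a_o, 0.0) == pytest.approx(a_o, abs=1e-15)
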