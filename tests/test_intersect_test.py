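"""The intersection significance procedure: ranking, FDR criterion, combining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlgsa.intersect_test import (
    TestConfig,
    bh_critical_value,
    combine_comparisons,
    intersect_sets,
    significance_step,
    sorted_pvalue_table,
)
from qtlgsa.io_formats import GeneSet, IntersectionResult


CFG = TestConfig(alpha=0.05, min_intersection=1)


# ---------------------------------------------------------------------------
# intersections
# ---------------------------------------------------------------------------


def test_intersect_basic_and_drop():
    pathways = [
        GeneSet("pwA", "M", ("g1", "g2", "g3")),
        GeneSet("pwB", "M", ("g7", "g8")),
    ]
    q = {"g2", "g3", "g9"}
    universe = [f"g{i}" for i in range(1, 10)]
    pairs = intersect_sets(pathways, q, universe, min_intersection=1)
    assert len(pairs) == 1
    assert pairs[0].gene_set.set_name == "pwA"
    assert pairs[0].sub_members == {"g2", "g3"}


def test_intersect_min_size_counts_m():
    pathways = [GeneSet(f"pw{i}", "M", (f"g{i}", "g0")) for i in range(1, 5)]
    q = {"g0", "g1"}
    universe = [f"g{i}" for i in range(5)]
    assert len(intersect_sets(pathways, q, universe, min_intersection=2)) == 1


def test_intersect_empty_q_errors():
    with pytest.raises(ValueError, match="QTL"):
        intersect_sets([GeneSet("pw", "M", ("g1",))], {"gX"}, ["g1"], 1)


def test_intersect_matches_bruteforce(rng):
    universe = [f"g{i}" for i in range(100)]
    for _ in range(50):
        pathways = [
            GeneSet(
                f"pw{k}",
                "M",
                tuple(f"g{i}" for i in rng.choice(120, size=rng.integers(1, 30), replace=False)),
            )
            for k in range(8)
        ]
        q = {f"g{i}" for i in rng.choice(120, size=40, replace=False)}
        pairs = {p.gene_set.set_name: p for p in intersect_sets(pathways, q, universe, 1)}
        for gs in pathways:
            expected = set(gs.members) & q & set(universe)
            if expected:
                assert pairs[gs.set_name].sub_members == expected
            else:
                assert gs.set_name not in pairs


# ---------------------------------------------------------------------------
# BH critical values
# ---------------------------------------------------------------------------


def test_bh_critical_values():
    assert bh_critical_value(1, 10, 0.05) == pytest.approx(0.005)
    assert bh_critical_value(10, 10, 0.05) == pytest.approx(0.05)
    for i in range(1, 11):
        assert bh_critical_value(i, 10, 0.05) == pytest.approx(i * 0.05 / 10)
    seq = [bh_critical_value(i, 10, 0.05) for i in range(1, 11)]
    assert all(a < b for a, b in zip(seq, seq[1:]))
    with pytest.raises(ValueError):
        bh_critical_value(0, 10, 0.05)
    with pytest.raises(ValueError):
        bh_critical_value(11, 10, 0.05)


# ---------------------------------------------------------------------------
# significance step
# ---------------------------------------------------------------------------


def test_step_worked_example_rank1():
    # sub 0.001 at rank 1 of m=10: min(whole 0.01, 1*0.05/10=0.005) = 0.005 > 0.001
    sub = [0.001] + [0.5] * 9
    whole = [0.01] + [0.6] * 9
    res = significance_step(sub, whole, CFG)
    assert res.flags[0] and res.rank[0] == 1
    assert res.critical_value[0] == pytest.approx(0.005)


def test_step_sub_must_beat_whole():
    res = significance_step([0.004], [0.002], TestConfig(alpha=0.9, min_intersection=1))
    assert not res.flags[0]  # whole pathway more significant than the sub-set


def test_step_matches_bruteforce(rng):
    for _ in range(100):
        n = int(rng.integers(1, 40))
        sub = rng.uniform(size=n)
        whole = rng.uniform(size=n)
        res = significance_step(sub, whole, CFG)
        order = np.argsort(sub, kind="stable")
        for rank, idx in enumerate(order, start=1):
            expected = sub[idx] < min(whole[idx], rank * CFG.alpha / n)
            assert res.flags[idx] == expected
            assert res.rank[idx] == rank


def test_step_flags_invariant_to_input_order(rng):
    sub = rng.uniform(size=25)
    whole = rng.uniform(size=25)
    names = [f"pw{i}" for i in range(25)]
    base = significance_step(sub, whole, CFG, set_names=names)
    perm = rng.permutation(25)
    permuted = significance_step(sub[perm], whole[perm], CFG, set_names=[names[i] for i in perm])
    np.testing.assert_array_equal(base.flags[perm], permuted.flags)
    np.testing.assert_array_equal(base.rank[perm], permuted.rank)


def test_step_length_mismatch_errors():
    with pytest.raises(ValueError, match="mismatch"):
        significance_step([0.1, 0.2], [0.1], CFG)


@given(
    pairs=st.lists(
        st.tuples(
            st.floats(0.0, 1.0, allow_nan=False), st.floats(0.0, 1.0, allow_nan=False)
        ),
        min_size=1,
        max_size=40,
    )
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_step_subset_of_bh_step_up_property(pairs):
    """For arbitrary p-vectors the per-rank rule never adds a discovery
    beyond the classic BH step-up rejection set."""
    sub = np.array([a for a, _ in pairs])
    whole = np.array([b for _, b in pairs])
    flags = significance_step(sub, whole, CFG).flags
    order = np.argsort(sub, kind="stable")
    m = len(sub)
    passing = [i for i in range(1, m + 1) if sub[order[i - 1]] <= i * CFG.alpha / m]
    k = max(passing, default=0)
    step_up = np.zeros(m, dtype=bool)
    step_up[order[:k]] = True
    assert not np.any(flags & ~step_up)


def test_discoveries_subset_of_plain_bh(rng):
    """The whole-pathway filter and per-rank rule only remove BH discoveries."""
    from statsmodels.stats.multitest import multipletests

    for _ in range(500):
        n = int(rng.integers(1, 60))
        sub = rng.uniform(size=n)
        whole = rng.uniform(size=n)
        ours = significance_step(sub, whole, CFG).flags
        bh = multipletests(sub, alpha=CFG.alpha, method="fdr_bh")[0]
        assert not np.any(ours & ~bh)


# ---------------------------------------------------------------------------
# combining comparisons
# ---------------------------------------------------------------------------


def _step_tuple(sub, whole, cfg=CFG):
    res = significance_step(sub, whole, cfg)
    return (np.asarray(sub, float), np.asarray(whole, float), res.flags)


def test_combine_single_comparison_is_identity(rng):
    sub = rng.uniform(size=15)
    whole = rng.uniform(size=15)
    comb = combine_comparisons({"c1": _step_tuple(sub, whole)}, CFG)
    np.testing.assert_array_equal(comb.max_sub_p, sub)
    np.testing.assert_array_equal(comb.max_whole_p, whole)
    np.testing.assert_array_equal(comb.overall, _step_tuple(sub, whole)[2] & comb.combined.flags)


def test_significant_in_three_of_four_not_overall():
    # pathway 0 passes in comparisons 1-3 but not in the 4th
    per = {}
    for i in range(4):
        sub = np.array([0.001 if i < 3 else 0.9, 0.5])
        whole = np.array([0.9, 0.6])
        per[f"c{i}"] = _step_tuple(sub, whole)
    comb = combine_comparisons(per, CFG)
    assert not comb.overall[0]


def test_combine_matches_max_and_intersect_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(2, 20))
        per = {}
        flags_all = []
        subs, wholes = [], []
        for c in range(3):
            sub = rng.uniform(size=n)
            whole = rng.uniform(size=n)
            tup = _step_tuple(sub, whole)
            per[f"c{c}"] = tup
            subs.append(sub)
            wholes.append(whole)
            flags_all.append(tup[2])
        comb = combine_comparisons(per, CFG)
        max_sub = np.max(subs, axis=0)
        max_whole = np.max(wholes, axis=0)
        np.testing.assert_array_equal(comb.max_sub_p, max_sub)
        np.testing.assert_array_equal(comb.max_whole_p, max_whole)
        expected = significance_step(max_sub, max_whole, CFG).flags & np.logical_and.reduce(flags_all)
        np.testing.assert_array_equal(comb.overall, expected)


def test_combine_universe_mismatch_errors(rng):
    per = {
        "c1": _step_tuple(rng.uniform(size=5), rng.uniform(size=5)),
        "c2": _step_tuple(rng.uniform(size=6), rng.uniform(size=6)),
    }
    with pytest.raises(ValueError, match="universes"):
        combine_comparisons(per, CFG)


# ---------------------------------------------------------------------------
# sorted p-value table
# ---------------------------------------------------------------------------


def _res(name, sub, whole):
    return IntersectionResult(
        set_name=name, category="M", n_genes=20, n_in_qtl=10, direction="U",
        max_sub_p=sub, max_whole_p=whole, rank=1, critical_value=0.01,
        significant=False, sub_p={"c": sub}, whole_p={"c": whole},
    )


def test_sorted_table_flags_and_order():
    tbl = sorted_pvalue_table([_res("a", 0.2, 0.1), _res("b", 0.01, 0.05)])
    assert list(tbl["set_name"]) == ["b", "a"]
    assert list(tbl["smaller"]) == ["sub", "whole"]
    assert list(tbl["rank"]) == [1, 2]


def test_sorted_table_tie_goes_to_whole():
    tbl = sorted_pvalue_table([_res("a", 0.3, 0.3)])
    assert list(tbl["smaller"]) == ["whole"]


def test_sorted_table_matches_independent_sort(rng):
    results = [_res(f"pw{i}", float(rng.uniform()), float(rng.uniform())) for i in range(30)]
    tbl = sorted_pvalue_table(results)
    expected = sorted(r.max_sub_p for r in results)
    assert list(tbl["max_sub_p"]) == expected
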