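"""Probe filtering, replicate merging, probe->gene collapse, set filtering."""

import numpy as np
import pandas as pd
import pytest

from qtlgsa.io_formats import ExpressionMatrix, FormatError, GeneSet
from qtlgsa.preprocess import (
    collapse_probes_to_genes,
    filter_control_probes,
    filter_gene_sets,
    merge_replicates,
)

from conftest import random_expression


def _expr(index, values, groups=None):
    n = len(values[0])
    cols = [f"s{i}" for i in range(n)]
    groups = groups or {c: "A" for c in cols}
    return ExpressionMatrix(pd.DataFrame(values, index=index, columns=cols), groups)


# ---------------------------------------------------------------------------
# control probes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "features, expected",
    [
        (["AFFX-ctrl1", "g1", "g2"], ["g1", "g2"]),
        (["g1", "g2"], ["g1", "g2"]),
        (["AFFX-a", "AFFX-b"], []),
    ],
)
def test_filter_control_probes(features, expected):
    expr = _expr(features, [[1.0, 2.0]] * len(features))
    out = filter_control_probes(expr)
    assert out.feature_ids == expected


def test_filter_control_prefix_configurable():
    expr = _expr(["CTRL_x", "g1"], [[1.0, 2.0]] * 2)
    assert filter_control_probes(expr, "CTRL_").feature_ids == ["g1"]


# ---------------------------------------------------------------------------
# replicate merging
# ---------------------------------------------------------------------------


def test_merge_replicates_means():
    expr = _expr(["g1", "g2"], [[8.0, 8.0, 8.0], [7.0, 8.0, 9.0]])
    merged = merge_replicates(expr, {"s0": "arr", "s1": "arr", "s2": "arr"})
    assert merged.sample_ids == ["arr"]
    assert merged.values.loc["g1", "arr"] == 8.0
    assert merged.values.loc["g2", "arr"] == 8.0


def test_merge_replicates_matches_per_cell_mean(rng):
    values = pd.DataFrame(
        rng.normal(8, 2, size=(30, 9)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(9)],
    )
    groups = {f"s{j}": f"strain{j // 3}" for j in range(9)}
    expr = ExpressionMatrix(values, groups)
    rep_map = {s: f"grp{i // 3}" for i, s in enumerate(expr.sample_ids)}
    merged = merge_replicates(expr, rep_map)
    for g in range(3):
        cols = [s for s in expr.sample_ids if rep_map[s] == f"grp{g}"]
        expected = expr.values[cols].to_numpy().mean(axis=1)
        np.testing.assert_allclose(merged.values[f"grp{g}"].to_numpy(), expected)


def test_merge_replicates_missing_sample_errors():
    expr = _expr(["g1"], [[1.0, 2.0]])
    with pytest.raises(FormatError, match="s1"):
        merge_replicates(expr, {"s0": "a"})


def test_merge_commutes_with_control_filter(rng):
    features = ["AFFX-1", "p1", "p2", "AFFX-2", "p3"]
    expr = _expr(features, rng.normal(size=(5, 6)).tolist())
    rep_map = {s: f"a{i // 2}" for i, s in enumerate(expr.sample_ids)}
    a = merge_replicates(filter_control_probes(expr), rep_map)
    b = filter_control_probes(merge_replicates(expr, rep_map))
    assert a.equals(b)


# ---------------------------------------------------------------------------
# probe -> gene collapse
# ---------------------------------------------------------------------------


def test_collapse_single_probe_relabelled():
    expr = _expr(["p1"], [[3.0, 4.0]])
    out = collapse_probes_to_genes(expr, {"p1": "gene1"})
    assert out.feature_ids == ["gene1"]
    np.testing.assert_array_equal(out.values.loc["gene1"], [3.0, 4.0])


def test_collapse_keeps_max_mean_probe():
    expr = _expr(["p_lo", "p_hi"], [[5.0, 5.0], [9.0, 9.0]])
    out = collapse_probes_to_genes(expr, {"p_lo": "g", "p_hi": "g"})
    np.testing.assert_array_equal(out.values.loc["g"], [9.0, 9.0])


def test_collapse_tie_breaks_lexicographically():
    expr = _expr(["pB", "pA"], [[5.0, 5.0], [4.0, 6.0]])  # equal means
    out = collapse_probes_to_genes(expr, {"pB": "g", "pA": "g"})
    np.testing.assert_array_equal(out.values.loc["g"], [4.0, 6.0])


def test_collapse_matches_bruteforce_argmax(rng):
    for _ in range(20):
        n_probes = int(rng.integers(5, 40))
        expr = random_expression(rng, n_features=n_probes, n_samples=5, prefix="p")
        pmap = {p: f"gene{rng.integers(0, max(2, n_probes // 3))}" for p in expr.feature_ids}
        out = collapse_probes_to_genes(expr, pmap)

        # brute force: per gene, scan probes for the max-mean row
        expected = {}
        for probe in expr.feature_ids:
            gene = pmap[probe]
            mean = expr.values.loc[probe].mean()
            if gene not in expected or (mean, expected[gene][0]) > (expected[gene][1], probe):
                expected[gene] = (probe, mean)
        assert set(out.feature_ids) == set(expected)
        for gene, (probe, _) in expected.items():
            np.testing.assert_array_equal(
                out.values.loc[gene].to_numpy(), expr.values.loc[probe].to_numpy()
            )


def test_collapse_rows_are_verbatim_input_rows(rng):
    expr = random_expression(rng, n_features=15, n_samples=4, prefix="p")
    pmap = {p: f"g{i % 4}" for i, p in enumerate(expr.feature_ids)}
    out = collapse_probes_to_genes(expr, pmap)
    input_rows = {tuple(r) for r in expr.values.to_numpy()}
    for row in out.values.to_numpy():
        assert tuple(row) in input_rows


def test_collapse_drops_unmapped(caplog):
    expr = _expr(["p1", "p2"], [[1.0, 1.0], [2.0, 2.0]])
    with caplog.at_level("INFO"):
        out = collapse_probes_to_genes(expr, {"p1": "g1"})
    assert out.feature_ids == ["g1"]


# ---------------------------------------------------------------------------
# gene set filtering
# ---------------------------------------------------------------------------


def _sets(*specs):
    return [GeneSet(n, c, tuple(m)) for n, c, m in specs]


def test_filter_gene_sets_size_bounds():
    universe = [f"g{i}" for i in range(20)]
    sets = _sets(
        ("too_small", "Metabolism", [f"g{i}" for i in range(9)]),
        ("boundary", "Metabolism", [f"g{i}" for i in range(10)]),
    )
    kept = filter_gene_sets(sets, universe)
    assert [s.set_name for s in kept] == ["boundary"]


def test_filter_counts_measured_genes_only():
    # 600 members, 450 on the array: kept because the bound counts measured genes
    universe = [f"g{i}" for i in range(450)]
    members = [f"g{i}" for i in range(600)]
    kept = filter_gene_sets(_sets(("big", "Metabolism", members)), universe)
    assert len(kept) == 1 and kept[0].size == 450


def test_filter_drops_category():
    universe = [f"g{i}" for i in range(30)]
    sets = _sets(
        ("disease", "Human Diseases", universe[:15]),
        ("ok", "Metabolism", universe[:15]),
    )
    kept = filter_gene_sets(sets, universe)
    assert [s.set_name for s in kept] == ["ok"]


def test_filter_is_idempotent(rng):
    universe = [f"g{i}" for i in range(300)]
    sets = []
    for i in range(30):
        size = int(rng.integers(3, 40))
        members = [f"g{j}" for j in rng.choice(400, size=size, replace=False)]
        sets.append(GeneSet(f"pw{i}", "Metabolism", tuple(members)))
    once = filter_gene_sets(sets, universe)
    twice = filter_gene_sets(once, universe)
    assert once == twice
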