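"""Pearson-distance comparison and UPGMA clustering of profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutprof.compare import (
    ProfileMatrix,
    compare_profiles,
    distance_matrix,
    heatmap_export,
    hierarchical_tree,
    leaf_order,
    pearson_distance,
)
from gutprof.exceptions import InconsistencyError, UndefinedCorrelationError

from oracles import upgma_bruteforce


# -- pearson distance -------------------------------------------------------


def test_identical_vectors_distance_zero():
    assert pearson_distance([1, 2, 3, 5], [1, 2, 3, 5]) == pytest.approx(0.0)


def test_anticorrelated_vectors_distance_two():
    x = [1.0, 2.0, 3.0]
    y = [-v + 10 for v in x]
    assert pearson_distance(x, y) == pytest.approx(2.0)


def test_product_moment_value():
    # frozen from exact rational arithmetic: r = 3 / sqrt(28/3)
    assert pearson_distance([1, 2, 3], [1, 2, 4]) == pytest.approx(
        1 - 0.9819805060619659, abs=1e-12
    )


def test_constant_vector_is_an_error():
    with pytest.raises(UndefinedCorrelationError):
        pearson_distance([1, 1, 1], [1, 2, 3])


@settings(derandomize=True, max_examples=50)
@given(
    x=st.lists(st.floats(min_value=0, max_value=100), min_size=3, max_size=12),
    a=st.floats(min_value=0.01, max_value=50),
    b=st.floats(min_value=-50, max_value=50),
)
def test_scale_invariance(x, a, b):
    if len(set(x)) < 2:
        return
    y = [a * v + b for v in x]
    base = [v * 2 + 1 for v in x]
    d1 = pearson_distance(base, x)
    d2 = pearson_distance(base, y)
    assert d1 == pytest.approx(d2, abs=1e-9)


# -- distance matrix --------------------------------------------------------


def _pm(values: dict[str, list[float]]) -> ProfileMatrix:
    features = [f"f{i}" for i in range(len(next(iter(values.values()))))]
    return ProfileMatrix.from_profiles(
        {s: dict(zip(features, v)) for s, v in values.items()}
    )


def test_distance_matrix_properties():
    pm = _pm({"A": [1, 2, 3], "B": [1, 2, 3], "C": [3, 1, 2]})
    dm = distance_matrix(pm)
    assert dm.shape == (3, 3)
    assert dm["A", "B"] == pytest.approx(0.0)
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
    assert np.all(dm.data >= 0) and np.all(dm.data <= 2)


def test_distance_matrix_names_constant_sample():
    pm = _pm({"A": [1, 2, 3], "flatliner": [5, 5, 5]})
    with pytest.raises(UndefinedCorrelationError, match="flatliner"):
        distance_matrix(pm)


def test_sample_permutation_consistency():
    vals = {"A": [1, 2, 3, 4], "B": [2, 1, 4, 3], "C": [4, 3, 2, 1]}
    dm1 = distance_matrix(_pm(vals))
    dm2 = distance_matrix(_pm({k: vals[k] for k in ["C", "A", "B"]}))
    for x in "ABC":
        for y in "ABC":
            assert dm1[x, y] == pytest.approx(dm2[x, y])


def test_feature_alignment_fills_absent_with_zero():
    pm = ProfileMatrix.from_profiles({"A": {"f1": 10.0}, "B": {"f2": 5.0}})
    assert pm.features == ["f1", "f2"]
    assert pm.data.loc["B", "f1"] == 0.0


# -- UPGMA tree -------------------------------------------------------------


def test_two_samples_merge_at_half_distance():
    pm = _pm({"A": [1, 2, 3], "B": [1, 3, 2]})
    dm = distance_matrix(pm)
    tree = hierarchical_tree(dm)
    (a, b) = tree.children
    assert a.length == pytest.approx(dm["A", "B"] / 2)
    assert b.length == pytest.approx(dm["A", "B"] / 2)


def test_nearest_pair_merges_first():
    from skbio import DistanceMatrix

    dm = DistanceMatrix([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]],
                        ids=["A", "B", "C"])
    tree = hierarchical_tree(dm)
    clades = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
    assert frozenset({"A", "B"}) in clades


def test_upgma_heights_monotone_and_match_oracle():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(3, 7))
        ids = [f"s{i}" for i in range(n)]
        raw = rng.uniform(0.05, 2.0, size=(n, n))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 0.0)
        from skbio import DistanceMatrix

        tree = hierarchical_tree(DistanceMatrix(mat, ids=ids))
        got = {
            frozenset(t.name for t in node.tips()):
                pytest.approx(_node_height(node), abs=1e-9)
            for node in tree.non_tips(include_self=True)
        }
        expect = dict(
            (clade, h) for clade, h in upgma_bruteforce(ids, mat.tolist())
        )
        assert set(got) == set(expect)
        for clade, h in expect.items():
            assert got[clade] == h
        # ultrametric: heights non-decreasing towards the root
        for node in tree.non_tips(include_self=True):
            for child in node.children:
                if child.children:
                    assert _node_height(child) <= _node_height(node) + 1e-12


def _node_height(node) -> float:
    h = 0.0
    cur = node
    while cur.children:
        cur = cur.children[0]
        h += cur.length
    return h


def test_known_group_structure_split_at_root():
    rng = np.random.default_rng(5)
    base1 = rng.uniform(0, 10, 20)
    base2 = rng.uniform(0, 10, 20)
    profiles = {}
    for i in range(3):
        profiles[f"g1_{i}"] = dict(
            zip(map(str, range(20)),
                np.clip(base1 + rng.normal(0, 0.05, 20), 0, None))
        )
        profiles[f"g2_{i}"] = dict(
            zip(map(str, range(20)),
                np.clip(base2 + rng.normal(0, 0.05, 20), 0, None))
        )
    _dm, tree = compare_profiles(profiles)
    left, right = tree.children
    sides = [frozenset(t.name for t in side.tips()) or frozenset([side.name])
             for side in (left, right)]
    assert {frozenset(f"g1_{i}" for i in range(3)),
            frozenset(f"g2_{i}" for i in range(3))} == set(sides)


def test_tree_needs_two_samples():
    from skbio import DistanceMatrix

    with pytest.raises(ValueError):
        hierarchical_tree(DistanceMatrix([[0.0]], ids=["A"]))


# -- heat-map export --------------------------------------------------------


def test_heatmap_rows_follow_leaf_order_and_roundtrip(tmp_path):
    import pandas as pd

    pm = _pm({"A": [1, 2, 3, 4], "B": [1.1, 2, 3, 4.2], "C": [9, 1, 0, 3]})
    dm, tree = compare_profiles(pm)
    out = tmp_path / "heat.tsv"
    nwk = tmp_path / "tree.nwk"
    ordered = heatmap_export(pm, tree, out, nwk)
    assert list(ordered.index) == leaf_order(tree)
    again = pd.read_csv(out, sep="\t", index_col=0)
    assert np.allclose(again.values, ordered.values)
    assert sorted(ordered.index) == ["A", "B", "C"]  # permutation only
    assert nwk.read_text().strip().endswith(";")


def test_heatmap_leaf_mismatch_is_error(tmp_path):
    pm1 = _pm({"A": [1, 2, 3], "B": [3, 2, 1]})
    pm2 = _pm({"A": [1, 2, 3], "X": [3, 2, 1]})
    _dm, tree = compare_profiles(pm1)
    with pytest.raises(InconsistencyError):
        heatmap_export(pm2, tree, tmp_path / "m.tsv")
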