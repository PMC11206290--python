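"""Euclidean distances, single-linkage dendrograms, nearest pairs."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from chromlip import (
    compound_vectors,
    nearest_pair,
    pairwise_distances,
    single_linkage,
    variable_vectors,
)
from chromlip.errors import ValidationError
from conftest import single_linkage_oracle


def test_distance_table_axioms():
    rng = np.random.default_rng(5)
    vectors = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
    d = pairwise_distances(vectors)
    arr = d.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0.0)
    for i in range(6):
        for j in range(6):
            for k in range(6):
                assert arr[i, j] <= arr[i, k] + arr[k, j] + 1e-12


def test_identical_vectors_and_unit_axes():
    vectors = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]], index=["a", "b", "c"])
    d = pairwise_distances(vectors)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "c"] == pytest.approx(math.sqrt(2))


def test_compound_5_vs_10_distance(fixtures):
    """Compounds 5 and 10 differ only in milogP (0.17) and the consensus
    column (0.02): distance sqrt(0.17^2 + 0.02^2) ~ 0.1712."""
    vectors = compound_vectors(fixtures.logp_matrix)
    d = pairwise_distances(vectors)
    assert d.loc[5, 10] == pytest.approx(0.1712, abs=2e-4)


def test_three_collinear_points():
    vectors = pd.DataFrame({"x": [0.0, 1.0, 3.0]}, index=["p0", "p1", "p3"])
    dendro = single_linkage(pairwise_distances(vectors))
    (a1, b1, h1), (a2, b2, h2) = dendro.merges
    assert {a1, b1} == {frozenset({"p0"}), frozenset({"p1"})}
    assert h1 == pytest.approx(1.0)
    assert {a2, b2} == {frozenset({"p0", "p1"}), frozenset({"p3"})}
    assert h2 == pytest.approx(2.0)


def test_first_merge_is_min_distance_and_heights_monotone():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(2, 10))
        vectors = pd.DataFrame(rng.normal(size=(n, 3)))
        d = pairwise_distances(vectors)
        dendro = single_linkage(d)
        off_diag = d.to_numpy()[np.triu_indices(n, k=1)]
        assert dendro.heights[0] == pytest.approx(off_diag.min())
        assert np.all(np.diff(dendro.heights) >= -1e-12)


def test_heights_match_brute_force_oracle():
    rng = np.random.default_rng(23)
    for _ in range(25):
        n = int(rng.integers(3, 9))
        vectors = pd.DataFrame(rng.normal(size=(n, 2)))
        d = pairwise_distances(vectors)
        dendro = single_linkage(d)
        oracle = single_linkage_oracle(d.to_numpy())
        assert [h for *_, h in oracle] == pytest.approx(list(dendro.heights))


def test_heights_invariant_under_item_permutation(fixtures):
    vectors = compound_vectors(fixtures.logp_matrix)
    base = single_linkage(pairwise_distances(vectors))
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(vectors))
    shuffled = single_linkage(pairwise_distances(vectors.iloc[perm]))
    assert list(shuffled.heights) == pytest.approx(list(base.heights))


def test_compound_dendrogram_first_merge_joins_5_and_10(fixtures):
    vectors = compound_vectors(fixtures.logp_matrix)
    dendro = single_linkage(pairwise_distances(vectors))
    a, b, _ = dendro.merges[0]
    assert a | b == frozenset({5, 10})
    # ... with or without the consensus column in the vectors
    bare = compound_vectors(fixtures.logp_matrix, include_average=False)
    a, b, _ = single_linkage(pairwise_distances(bare)).merges[0]
    assert a | b == frozenset({5, 10})


def test_two_cluster_cut_separates_low_lipophilicity_substituents(fixtures):
    """Cutting the compound dendrogram in two isolates the dimethylaminopropyl
    and pyrrolidinylethyl analogues {2,3,7,8,12,13} from the rest."""
    vectors = compound_vectors(fixtures.logp_matrix)
    dendro = single_linkage(pairwise_distances(vectors))
    clusters = {frozenset(c) for c in dendro.cut(2)}
    assert frozenset({2, 3, 7, 8, 12, 13}) in clusters


def test_variable_clustering_nearest_pair(fixtures):
    """Among the nine tabulated lipophilicity measures the closest pair is the
    ChemDraw logP and the consensus column (distance ~0.451 on the printed
    values); the identity also holds for recomputed full-precision means."""
    vectors = variable_vectors(
        fixtures.logp_matrix, average=fixtures.printed_consensus["logp_average"]
    )
    a, b, dist = nearest_pair(vectors)
    assert {a, b} == {"logP", "logp_average"}
    assert dist == pytest.approx(0.4513, abs=2e-4)
    a, b, _ = nearest_pair(variable_vectors(fixtures.logp_matrix))
    assert {a, b} == {"logP", "logp_average"}


def test_nearest_pair_duplicates_and_size_guard():
    vectors = pd.DataFrame([[0.0], [0.0], [5.0]], index=["a", "b", "c"])
    assert nearest_pair(vectors) == ("a", "b", 0.0)
    with pytest.raises(ValidationError):
        nearest_pair(vectors.iloc[:1])
    with pytest.raises(ValidationError):
        single_linkage(pairwise_distances(vectors.iloc[:1]))


def test_newick_export_is_parseable_ultrametric():
    rng = np.random.default_rng(9)
    vectors = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"t{i}" for i in range(6)])
    dendro = single_linkage(pairwise_distances(vectors))
    tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(vectors.index)
    # branch lengths are merge-height differences -> every leaf sits at the
    # root height (ultrametric)
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    assert max(depths) - min(depths) < 1e-6
    assert max(depths) == pytest.approx(dendro.heights[-1], abs=1e-6)


def test_merge_table_structure(fixtures):
    dendro = single_linkage(pairwise_distances(compound_vectors(fixtures.logp_matrix)))
    table = dendro.merge_table()
    assert list(table.columns) == ["step", "members_a", "members_b", "height"]
    assert len(table) == 14
    assert table.height.is_monotonic_increasing


def test_missing_coordinates_rejected():
    vectors = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"])
    with pytest.raises(ValidationError, match="a"):
        pairwise_distances(vectors)
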