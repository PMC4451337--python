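"""Symmetrical uncertainty, FCBF and cluster-PCA reduction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcistate.experiments import _naive_su, fcbf_oracle_agreement
from bcistate.selection import (SelectionMap, SelectionSpec, cluster_pca_reduce,
                                cluster_pca_fcbf_select, discretize,
                                equal_frequency_bins, fcbf_select,
                                symmetrical_uncertainty)


class TestSymmetricalUncertainty:
    def test_perfect_dependence(self):
        x = [0, 1, 0, 1, 2, 2]
        assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)
        # deterministic bijection, different labels
        y = [5, 9, 5, 9, 7, 7]
        assert symmetrical_uncertainty(x, y) == pytest.approx(1.0)

    def test_constant_sequence_defined_as_zero(self):
        assert symmetrical_uncertainty([1, 1, 1, 1], [0, 1, 0, 1]) == 0.0
        assert symmetrical_uncertainty([2, 2], [2, 2]) == 0.0

    def test_independent_sequences_near_zero(self, rng):
        x = rng.integers(0, 2, size=10_000)
        y = rng.integers(0, 2, size=10_000)
        assert symmetrical_uncertainty(x, y) < 0.01

    def test_matches_direct_entropy_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=50)
            y = rng.integers(0, 3, size=50)
            assert symmetrical_uncertainty(x, y) == pytest.approx(
                _naive_su(list(x), list(y)), abs=1e-12)

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30),
           st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, x, data):
        y = data.draw(st.lists(st.integers(0, 3), min_size=len(x),
                               max_size=len(x)))
        a = symmetrical_uncertainty(x, y)
        b = symmetrical_uncertainty(y, x)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b, abs=1e-12)


class TestFCBF:
    def test_label_copy_feature_ranked_first(self, rng):
        y = rng.integers(0, 2, size=40)
        X = rng.standard_normal((40, 6))
        X[:, 3] = y
        m = fcbf_select(X, y, SelectionSpec(method="fcbf", k=1))
        assert list(m.indices) == [3]

    def test_duplicated_informative_feature_removed_as_redundant(self, rng):
        y = rng.integers(0, 2, size=60)
        X = rng.standard_normal((60, 5))
        X[:, 0] = y + 0.05 * rng.standard_normal(60)
        X[:, 1] = X[:, 0]
        from bcistate.selection import discretize, fcbf_rank
        order, n_survivors, _ = fcbf_rank(discretize(X, 10), y)
        survivors = order[:n_survivors]
        # exactly one of the two duplicates survives the predominance screen
        assert (0 in survivors) != (1 in survivors)
        m = fcbf_select(X, y, SelectionSpec(method="fcbf", k=1))
        assert list(m.indices) == [0]

    def test_exact_match_with_bruteforce_reference(self):
        assert fcbf_oracle_agreement(seed=20250928, n_instances=60) == 1.0

    def test_column_permutation_invariance(self, rng):
        y = rng.integers(0, 2, size=50)
        X = rng.standard_normal((50, 8))
        X[:, 2] += y
        X[:, 5] += 0.5 * y
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = set(fcbf_select(X, y, SelectionSpec(method="fcbf", k=3)).indices)
            perm = rng.permutation(8)
            sel = fcbf_select(X[:, perm], y, SelectionSpec(method="fcbf", k=3)).indices
        assert {perm[i] for i in sel} == base

    def test_transform_yields_exactly_k_columns(self, rng):
        y = rng.integers(0, 2, size=30)
        X = rng.standard_normal((30, 20))
        for k in (1, 4, 12):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fcbf_select(X, y, SelectionSpec(method="fcbf", k=k))
            assert m.transform(X).shape == (30, k)


class TestClusterPCA:
    def test_recovers_planted_duplicate_groups(self, rng):
        """75 groups of 6 sign-flipped duplicates: clustering recovers the
        partition and each PC correlates |r| > 0.999 with its group."""
        n, g, reps = 80, 75, 6
        base = rng.standard_normal((n, g))
        signs = rng.choice([-1.0, 1.0], size=g * reps)
        X = np.repeat(base, reps, axis=1) * signs
        im = cluster_pca_reduce(X, n_intermediate=g)
        assert im.n_components == g
        truth = np.repeat(np.arange(g), reps)
        # planted groups must never be split across clusters
        for c in range(g):
            members = truth[im.clusters == c]
            assert len(set(members)) == 1
        Z = im.transform(X)
        for c in range(g):
            src = set(truth[im.clusters == c]).pop()
            r = np.corrcoef(Z[:, c], base[:, src])[0, 1]
            assert abs(r) > 0.999

    def test_no_compression_gives_standardized_originals(self, rng):
        X = rng.standard_normal((40, 10)) * 3 + 1
        im = cluster_pca_reduce(X, n_intermediate=10)
        Z = im.transform(X)
        expected = (X - X.mean(axis=0)) / X.std(axis=0)
        assert np.allclose(Z, expected)

    def test_first_pc_explains_at_least_any_member(self, rng):
        X = rng.standard_normal((100, 12))
        X[:, :6] += 2 * rng.standard_normal((100, 1))  # correlated block
        im = cluster_pca_reduce(X, n_intermediate=4)
        Z = (X[:, im.kept] - im.means[im.kept]) / im.stds[im.kept]
        comps = im.transform(X)
        for c in range(im.n_components):
            members = np.nonzero(im.clusters == c)[0]
            pc_var = comps[:, c].var()
            assert pc_var >= Z[:, members].var(axis=0).max() - 1e-9

    def test_loadings_unit_norm_and_sign_fixed(self, rng):
        X = rng.standard_normal((50, 20))
        im = cluster_pca_reduce(X, n_intermediate=5)
        for v in im.loadings:
            assert np.linalg.norm(v) == pytest.approx(1.0)
            assert v[np.argmax(np.abs(v))] > 0

    def test_constant_features_dropped_with_warning(self, rng):
        X = rng.standard_normal((30, 6))
        X[:, 4] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            im = cluster_pca_reduce(X, n_intermediate=5)
        assert 4 not in im.kept


def test_cluster_pca_fcbf_path_end_to_end(rng):
    y = rng.integers(0, 2, size=60)
    X = rng.standard_normal((60, 30))
    X[:, :3] += y[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = cluster_pca_fcbf_select(X, y, SelectionSpec(
            method="cluster_pca_fcbf", k=4, n_intermediate=10))
    assert m.transform(X).shape == (60, 4)


def test_selection_map_json_roundtrip(rng):
    y = rng.integers(0, 2, size=40)
    X = rng.standard_normal((40, 15))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in (fcbf_select(X, y, SelectionSpec(method="fcbf", k=3)),
                  cluster_pca_fcbf_select(X, y, SelectionSpec(
                      method="cluster_pca_fcbf", k=3, n_intermediate=8))):
            back = SelectionMap.from_json(m.to_json())
            assert np.allclose(back.transform(X), m.transform(X))


def test_equal_frequency_binning_balanced(rng):
    x = rng.standard_normal(1000)
    d = equal_frequency_bins(x, 10)
    counts = np.bincount(d)
    assert len(counts) == 10
    assert counts.min() >= 80 and counts.max() <= 120


def test_spec_validation():
    with pytest.raises(ValueError):
        SelectionSpec(method="fcbf", k=0)
    with pytest.raises(ValueError):
        SelectionSpec(method="fcbf", k=13)
    with pytest.raises(ValueError):
        SelectionSpec(method="wrapper", k=3)
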