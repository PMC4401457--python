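"""Selector correctness against brute-force oracles, documented tie-breaks,
and planted-signal behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import harselect as hs
from harselect.selection import (
    METHODS,
    cfs_exhaustive,
    cfs_merit,
    common_features,
    discretize_equal_frequency,
    select,
)
from harselect.synthetic import planted_feature_matrix

import oracles


def small_instance(seed, n=20, d=5, classes=2):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, classes, size=n)
    while len(np.unique(y)) < classes or np.bincount(y, minlength=classes).min() < 2:
        y = rng.integers(0, classes, size=n)
    X = rng.normal(size=(n, d)) + 0.8 * y[:, None] * (rng.random(d) > 0.5)
    return X, y


# -- Relief-F ----------------------------------------------------------------


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("classes", [2, 3])
def test_relief_matches_bruteforce_on_small_instances(seed, classes):
    X, y = small_instance(seed, n=24, classes=classes)
    w = hs.relief_f(X, y).w
    assert np.allclose(w, oracles.relief_f_bruteforce(X, y), atol=1e-10)


def test_relief_with_k_neighbors_matches_bruteforce():
    X, y = small_instance(3, n=30)
    w = hs.relief_f(X, y, n_neighbors=3).w
    assert np.allclose(w, oracles.relief_f_bruteforce(X, y, n_neighbors=3),
                       atol=1e-10)


def test_relief_constant_feature_gets_zero_weight():
    X, y = small_instance(1)
    X[:, 2] = 5.0
    assert hs.relief_f(X, y).w[2] == 0.0


def test_relief_hand_example_ranks_separating_feature_first():
    """Four points, two classes; feature 1 separates the classes, feature 2
    is pure within-class scatter."""
    X = np.array([[0.0, 0.1], [0.0, -0.1], [1.0, 0.1], [1.0, -0.1]])
    y = np.array([0, 0, 1, 1])
    w = hs.relief_f(X, y).w
    assert np.allclose(w, oracles.relief_f_bruteforce(X, y), atol=1e-12)
    assert w[0] > w[1]


def test_relief_on_duplicated_data_matches_bruteforce_rerun():
    X, y = small_instance(5)
    X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
    w = hs.relief_f(X2, y2).w
    assert np.allclose(w, oracles.relief_f_bruteforce(X2, y2), atol=1e-10)


def test_relief_single_class_rejected():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        hs.relief_f(X, np.zeros(10))


def test_top_k_ordering_and_tie_breaks():
    w = hs.FeatureWeights(w=np.array([0.5, 0.9, 0.5, 0.1]))
    assert hs.top_k(w, k=4).indices == (1, 0, 2, 3)  # rank order, tie -> low idx
    assert hs.top_k(w, k=2).indices == (1, 0)
    with pytest.raises(ValueError):
        hs.top_k(w, k=5)
    assert len(hs.top_k(hs.FeatureWeights(w=np.zeros(76)), k=10).indices) == 10


# -- symmetrical uncertainty & discretisation --------------------------------


def test_su_identical_independent_constant():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 4, 2000)
    assert hs.symmetrical_uncertainty(a, a) == pytest.approx(1.0)
    b = rng.integers(0, 4, 2000)  # independent by construction
    assert hs.symmetrical_uncertainty(a, b) == pytest.approx(0.0, abs=0.01)
    assert hs.symmetrical_uncertainty(np.zeros(100), a[:100]) == 0.0
    with pytest.raises(ValueError):
        hs.symmetrical_uncertainty(a, a[:-1])


def test_su_matches_plug_in_entropy_oracle():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 3, 300)
    b = (a + rng.integers(0, 2, 300)) % 3  # dependent
    assert hs.symmetrical_uncertainty(a, b) == pytest.approx(
        oracles.su(a.tolist(), b.tolist()), abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_su_is_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 5, 100)
    b = rng.integers(0, 3, 100)
    s = hs.symmetrical_uncertainty(a, b)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(hs.symmetrical_uncertainty(b, a), abs=1e-12)


def test_equal_frequency_discretisation():
    X = np.arange(100, dtype=float).reshape(-1, 1)
    disc = discretize_equal_frequency(X, n_bins=10)
    _, counts = np.unique(disc.codes[:, 0], return_counts=True)
    assert np.array_equal(counts, np.full(10, 10))
    const = discretize_equal_frequency(np.full((50, 1), 3.3), n_bins=10)
    assert np.array_equal(const.codes[:, 0], np.zeros(50))
    with pytest.raises(ValueError):
        discretize_equal_frequency(X, n_bins=1)


def test_monotone_transform_preserves_codes():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 1))
    codes = discretize_equal_frequency(X).codes
    codes_t = discretize_equal_frequency(np.exp(3 * X)).codes
    assert np.array_equal(codes, codes_t)


# -- CFS ---------------------------------------------------------------------


def test_cfs_merit_formula():
    # k=1 reduces to r_cf; the redundant pair gains nothing over a singleton
    assert cfs_merit(1, 0.8, 0.0) == pytest.approx(0.8)
    assert cfs_merit(2, 0.8, 1.0) == pytest.approx(1.6 / np.sqrt(4.0))


def test_cfs_redundant_pair_keeps_singleton():
    """A feature and its exact duplicate: merit(pair) == merit(singleton),
    so best-first (strict improvement) returns the singleton."""
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200)
    f = y + 0.3 * rng.normal(size=200)
    X = np.column_stack([f, f, rng.normal(size=200)])
    subset = hs.cfs(X, y)
    assert len(subset.indices) == 1 and subset.indices[0] in (0, 1)


@pytest.mark.parametrize("seed", range(5))
def test_cfs_bestfirst_matches_exhaustive_enumeration(seed):
    X, y = small_instance(seed, n=40, d=6)
    found = hs.cfs(X, y)
    codes = discretize_equal_frequency(X).codes
    _, y_codes = np.unique(y, return_inverse=True)
    best, best_merit = oracles.cfs_exhaustive(codes, y_codes)
    assert tuple(sorted(found.indices)) == best
    assert found.merit_or_score == pytest.approx(best_merit, abs=1e-10)


def test_cfs_exhaustive_helper_agrees_with_oracle():
    X, y = small_instance(11, n=35, d=6)
    codes = discretize_equal_frequency(X).codes
    _, y_codes = np.unique(y, return_inverse=True)
    assert tuple(sorted(cfs_exhaustive(X, y).indices)) == \
        oracles.cfs_exhaustive(codes, y_codes)[0]


def test_cfs_single_class_rejected():
    with pytest.raises(ValueError):
        hs.cfs(np.random.default_rng(0).normal(size=(10, 3)), np.zeros(10))


# -- FCBF --------------------------------------------------------------------


def test_fcbf_drops_exact_duplicate():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 300)
    f = y + 0.2 * rng.normal(size=300)
    X = np.column_stack([f, f.copy(), rng.normal(size=300)])
    subset = hs.fcbf(X, y)
    assert subset.indices == (0,)  # tie in SU rank -> lower index kept


def test_fcbf_all_irrelevant_yields_empty_subset():
    # constant columns have zero entropy, hence SU(f, class) = 0 for all
    y = np.repeat([0, 1], 20)
    X = np.full((40, 4), 1.0)
    assert hs.fcbf(X, y).indices == ()


@pytest.mark.parametrize("seed", range(5))
def test_fcbf_matches_pseudocode_trace(seed):
    X, y = small_instance(seed, n=50, d=5)
    subset = hs.fcbf(X, y)
    codes = discretize_equal_frequency(X).codes
    _, y_codes = np.unique(y, return_inverse=True)
    assert list(subset.indices) == oracles.fcbf_trace(codes, y_codes)


def test_fcbf_predominance_invariant(study_results):
    """No two retained features may correlate with each other at least as
    strongly as each does with the class."""
    grid = study_results.selection_grid
    rows = grid[grid["method"] == "fcbf"]
    checked = 0
    for _, row in rows.head(6).iterrows():
        ds = study_results.study.level_dataset(row["level"], row["population"])
        codes = discretize_equal_frequency(ds.X.to_numpy()).codes
        _, yc = np.unique(ds.y, return_inverse=True)
        kept = row["subset"].indices
        for a in kept:
            for b in kept:
                if a >= b:
                    continue
                mutual = hs.symmetrical_uncertainty(codes[:, a], codes[:, b])
                su_a = hs.symmetrical_uncertainty(codes[:, a], yc)
                su_b = hs.symmetrical_uncertainty(codes[:, b], yc)
                assert not (mutual >= su_a and mutual >= su_b)
                checked += 1
    assert checked > 0


# -- shared behaviour --------------------------------------------------------


@pytest.mark.parametrize("method", METHODS)
def test_selection_invariant_to_row_order(method):
    X, y = small_instance(9, n=40, d=6)
    perm = np.random.default_rng(0).permutation(len(y))
    a = select(method, X, y)
    b = select(method, X[perm], y[perm])
    assert sorted(a.indices) == sorted(b.indices)


@pytest.mark.parametrize("method", ["cfs", "fcbf"])
def test_su_methods_invariant_to_monotone_transforms(method):
    X, y = small_instance(10, n=40, d=6)
    a = select(method, X, y)
    b = select(method, np.exp(X), y)
    assert a.indices == b.indices


@pytest.mark.parametrize("method", METHODS)
def test_planted_features_recovered(method):
    X, y, informative = planted_feature_matrix(seed=123)
    inf = set(informative.tolist())
    if method == "relief_top10":
        got = set(select(method, X, y, k=len(inf)).indices)
    else:
        got = set(select(method, X, y).indices)
    assert got == inf


def test_selection_grid_and_common_features(study_results):
    grid = study_results.selection_grid
    assert set(grid["method"]) == set(METHODS)
    # 1-based registry ids within 1..76, no duplicates
    for ids in grid["feature_ids"]:
        assert all(1 <= i <= 76 for i in ids)
        assert len(set(ids)) == len(ids)
    relief = grid[grid["method"] == "relief_top10"]
    assert (relief["n_selected"] == 10).all()
    common = common_features(grid, "cfs")
    assert "populations" in common.columns
    pops = sorted(grid["population"].unique())
    assert len(common) == len(pops) * (len(pops) - 1) // 2 + 1


def test_identical_populations_have_identical_subsets(circuit_script):
    """Determinism: two cohorts from the same profile and seeds select the
    same features, so their intersection equals the subsets."""
    X, y, _ = planted_feature_matrix(seed=5)
    a = select("cfs", X, y)
    b = select("cfs", X.copy(), y.copy())
    assert a.indices == b.indices
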