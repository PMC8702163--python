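import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm

from detectcomp.errors import (
    DomainError,
    InconsistentTaxonomyError,
    SingularCovarianceError,
)
from detectcomp.taxonomy_pgls import (
    TaxonTree,
    brownian_vcv,
    build_taxonomy_tree,
    pgls_intercept,
)


def _prefix_shared(a, b):
    """Independent oracle: number of leading taxonomy levels two rows share."""
    shared = 0
    for x, y in zip(a, b):
        if x != y:
            break
        shared += 1
    return shared


def test_same_genus_pair_vcv():
    tree = build_taxonomy_tree([
        ("Carnivora", "Mustelidae", "Martes", "Martes americana"),
        ("Carnivora", "Mustelidae", "Martes", "Martes martes"),
    ])
    V = brownian_vcv(tree, ["Martes americana", "Martes martes"])
    assert np.allclose(V, [[4, 3], [3, 4]])


def test_different_order_pair_vcv():
    tree = build_taxonomy_tree([
        ("Carnivora", "Felidae", "Lynx", "Lynx rufus"),
        ("Rodentia", "Sciuridae", "Sciurus", "Sciurus niger"),
    ])
    V = brownian_vcv(tree, ["Lynx rufus", "Sciurus niger"])
    assert np.allclose(V, [[4, 0], [0, 4]])


def test_vcv_matches_prefix_count_oracle():
    rng = np.random.default_rng(17)
    for _ in range(10):
        rows = []
        for i in range(int(rng.integers(4, 12))):
            order = f"O{rng.integers(0, 3)}"
            family = f"{order}F{rng.integers(0, 2)}"
            genus = f"{family}G{rng.integers(0, 2)}"
            species = f"{genus}s{i}"
            rows.append((order, family, genus, species))
        tree = build_taxonomy_tree(rows)
        species = [r[3] for r in rows]
        V = brownian_vcv(tree, species)
        for i, j in itertools.combinations(range(len(rows)), 2):
            assert V[i, j] == pytest.approx(_prefix_shared(rows[i], rows[j]))
        assert np.allclose(np.diag(V), 4.0)
        # Brownian VCV must be positive semidefinite
        assert np.linalg.eigvalsh(V).min() > -1e-10


def test_every_tip_sits_at_depth_four():
    tree = build_taxonomy_tree([
        ("Carnivora", "Mustelidae", "Martes", "Martes americana"),
        ("Rodentia", "Muridae", "Rattus", "Rattus fuscipes"),
        ("Rodentia", "Muridae", "Apodemus", "Apodemus sylvaticus"),
    ])
    labels, depths = tree.shared_depths()
    assert np.allclose(np.diag(depths), 4.0)
    assert sorted(labels) == [
        "Apodemus sylvaticus", "Martes americana", "Rattus fuscipes",
    ]


def test_newick_round_trip_reproduces_vcv():
    rows = [
        ("Carnivora", "Mustelidae", "Martes", "Martes americana"),
        ("Carnivora", "Mustelidae", "Martes", "Martes martes"),
        ("Carnivora", "Felidae", "Lynx", "Lynx rufus"),
        ("Rodentia", "Sciuridae", "Sciurus", "Sciurus niger"),
    ]
    tree = build_taxonomy_tree(rows)
    species = [r[3] for r in rows]
    V = brownian_vcv(tree, species)
    back = TaxonTree.from_newick(tree.newick())
    assert np.allclose(brownian_vcv(back, species), V)
    assert back.taxonomy == tree.taxonomy


def test_repeated_species_get_jittered_covariance():
    tree = build_taxonomy_tree([
        ("Carnivora", "Mustelidae", "Martes", "Martes americana"),
        ("Carnivora", "Felidae", "Lynx", "Lynx rufus"),
    ])
    V = brownian_vcv(
        tree,
        ["Martes americana", "Martes americana", "Lynx rufus"],
        epsilon=1e-6,
    )
    assert V[0, 1] == pytest.approx(4 - 1e-6)
    assert np.linalg.eigvalsh(V).min() > 0  # positive definite
    singular = brownian_vcv(
        tree, ["Martes americana", "Martes americana", "Lynx rufus"], epsilon=0.0
    )
    with pytest.raises(SingularCovarianceError):
        pgls_intercept(np.array([0.1, -0.2, 0.3]), singular)


def test_inconsistent_taxonomy_rejected():
    with pytest.raises(InconsistentTaxonomyError, match="Martes americana"):
        build_taxonomy_tree([
            ("Carnivora", "Mustelidae", "Martes", "Martes americana"),
            ("Rodentia", "Mustelidae", "Martes", "Martes americana"),
        ])


def test_identity_covariance_reduces_to_mean_and_sem():
    rng = np.random.default_rng(8)
    y = rng.normal(0.3, 1.0, 12)
    res = pgls_intercept(y, np.eye(12))
    assert res.intercept == pytest.approx(float(y.mean()), abs=1e-12)
    assert res.se == pytest.approx(float(y.std(ddof=1) / math.sqrt(12)), abs=1e-12)
    assert res.df == 11


def test_star_phylogeny_equals_plain_mean():
    """Off-diagonal zeros (no shared history): GLS is the ordinary mean."""
    rng = np.random.default_rng(9)
    y = rng.normal(0, 1, 10)
    res = pgls_intercept(y, 4.0 * np.eye(10))
    assert res.intercept == pytest.approx(float(y.mean()), abs=1e-12)
    assert res.se == pytest.approx(float(y.std(ddof=1) / math.sqrt(10)), abs=1e-12)


def test_scaling_covariance_leaves_fit_unchanged():
    rng = np.random.default_rng(10)
    A = rng.normal(0, 1, (8, 8))
    V = A @ A.T + 8 * np.eye(8)
    y = rng.normal(0, 1, 8)
    a = pgls_intercept(y, V)
    b = pgls_intercept(y, 7.3 * V)
    assert b.intercept == pytest.approx(a.intercept, rel=1e-10)
    assert b.se == pytest.approx(a.se, rel=1e-10)
    assert b.sigma2 == pytest.approx(a.sigma2 / 7.3, rel=1e-10)


def test_pgls_matches_cholesky_whitening_oracle():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = int(rng.integers(4, 20))
        A = rng.normal(0, 1, (n, n))
        V = A @ A.T + n * np.eye(n)
        y = rng.normal(0, 1, n)
        res = pgls_intercept(y, V)
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, np.ones((n, 1)))
        ols = sm.OLS(yw, Xw).fit()
        assert res.intercept == pytest.approx(ols.params[0], abs=1e-10)
        assert res.se == pytest.approx(ols.bse[0], abs=1e-10)
        assert res.p_value == pytest.approx(ols.pvalues[0], abs=1e-10)


def test_dimension_mismatch_rejected():
    with pytest.raises(DomainError):
        pgls_intercept(np.ones(3), np.eye(4))
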