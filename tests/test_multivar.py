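"""Jaccard distances, PCoA, between-class analysis and co-inertia."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mhcpop import (
    between_class_analysis,
    coinertia,
    jaccard_s3_distance,
    principal_coordinates,
)
from mhcpop.multivar import Ordination


class TestJaccard:
    def test_identical_rows(self):
        B = pd.DataFrame([[1, 0, 1], [1, 0, 1]])
        assert jaccard_s3_distance(B).iloc[0, 1] == 0.0

    def test_disjoint_rows(self):
        B = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert jaccard_s3_distance(B).iloc[0, 1] == pytest.approx(1.0)

    def test_half_overlap(self):
        # a=1 shared, b=1, c=0 -> s=0.5, d=sqrt(0.5)
        B = pd.DataFrame([[1, 1], [1, 0]])
        assert jaccard_s3_distance(B).iloc[0, 1] == pytest.approx(math.sqrt(0.5))

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            jaccard_s3_distance(pd.DataFrame([[1, 0], [0, 0]]))


def euclidean(points):
    P = np.asarray(points, float)
    return pd.DataFrame(
        np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    )


class TestPCoA:
    def test_planar_roundtrip(self):
        pts = [(0, 0), (3, 0), (0, 4), (5, 5), (-2, 1)]
        D = euclidean(pts)
        ord_ = principal_coordinates(D)
        rec = euclidean(ord_.coordinates)
        assert np.allclose(rec.values, D.values, atol=1e-8)

    def test_equidistant_simplex(self):
        n = 5
        D = pd.DataFrame(1.0 - np.eye(n))
        ord_ = principal_coordinates(D)
        # regular simplex: all nontrivial eigenvalues equal
        assert np.allclose(ord_.eigenvalues, ord_.eigenvalues[0])
        assert len(ord_.eigenvalues) == n - 1

    def test_two_points(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]])
        ord_ = principal_coordinates(D)
        assert sorted(ord_.coordinates[:, 0]) == pytest.approx([-0.5, 0.5])

    def test_lingoes_fixes_non_euclidean(self):
        # Jaccard-style matrix that violates the Euclidean condition
        D = pd.DataFrame(
            [[0, 0.9, 0.1, 0.9], [0.9, 0, 0.9, 0.1],
             [0.1, 0.9, 0, 0.9], [0.9, 0.1, 0.9, 0]]
        )
        corrected = principal_coordinates(D, correction="lingoes")
        uncorrected = principal_coordinates(D, correction="none")
        assert any("lingoes" in w for w in corrected.warnings) or not any(
            "negative" in w for w in uncorrected.warnings
        )
        assert (corrected.eigenvalues > -1e-10).all()

    def test_asymmetric_matrix_errors(self):
        with pytest.raises(ValueError):
            principal_coordinates(pd.DataFrame([[0, 1], [2, 0]]))


def toy_ordination(coords, ids=None, groups=None):
    coords = np.asarray(coords, float)
    ids = ids or [f"r{i}" for i in range(len(coords))]
    return Ordination(ids, coords, np.ones(coords.shape[1]), "pcoa",
                      groups=groups)


class TestBetweenClass:
    def test_identical_centroids_zero_inertia(self):
        coords = [(1, 0), (-1, 0), (1, 0), (-1, 0)]
        groups = {"r0": "A", "r1": "A", "r2": "B", "r3": "B"}
        bca = between_class_analysis(toy_ordination(coords), groups)
        assert bca.between_inertia_fraction == pytest.approx(0.0, abs=1e-12)

    def test_separation_axis_alignment(self):
        rng = np.random.default_rng(1)
        n = 30
        coords = np.column_stack([
            np.r_[rng.normal(-4, 0.1, n), rng.normal(4, 0.1, n)],
            rng.normal(0, 0.1, 2 * n),
        ])
        ids = [f"r{i}" for i in range(2 * n)]
        groups = {i: ("A" if k < n else "B") for k, i in enumerate(ids)}
        bca = between_class_analysis(toy_ordination(coords, ids), groups)
        # first between-class axis must align with the separating axis
        scores = bca.coordinates[:, 0]
        cos = abs(np.corrcoef(scores, coords[:, 0])[0, 1])
        assert cos >= 0.99
        assert bca.between_inertia_fraction > 0.9

    def test_row_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(12, 3))
        ids = [f"r{i}" for i in range(12)]
        groups = {i: ("A" if k % 2 else "B") for k, i in enumerate(ids)}
        bca1 = between_class_analysis(toy_ordination(coords, ids), groups)
        perm = rng.permutation(12)
        bca2 = between_class_analysis(
            toy_ordination(coords[perm], [ids[i] for i in perm]), groups
        )
        s1 = pd.DataFrame(bca1.coordinates, index=ids)
        s2 = pd.DataFrame(bca2.coordinates, index=[ids[i] for i in perm])
        for j in range(s1.shape[1]):
            col1 = s1.iloc[:, j]
            col2 = s2.loc[s1.index].iloc[:, j]
            assert np.allclose(col1, col2, atol=1e-9) or np.allclose(
                col1, -col2, atol=1e-9
            )

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            between_class_analysis(
                toy_ordination([(0, 0), (1, 1)]), {"r0": "A", "r1": "A"}
            )


class TestCoinertia:
    def test_identity_gives_rv_one(self):
        rng = np.random.default_rng(3)
        X = toy_ordination(rng.normal(size=(20, 4)),
                           groups={f"r{i}": "A" if i < 10 else "B"
                                   for i in range(20)})
        res = coinertia(X, X, n_perm=0)
        assert res.rv == pytest.approx(1.0)
        assert np.allclose(res.vector_lengths, 0.0, atol=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(15, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        X = toy_ordination(coords)
        Y = toy_ordination(coords @ Q)
        assert coinertia(X, Y, n_perm=0).rv == pytest.approx(1.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(15, 3))
        X = toy_ordination(coords)
        Y = toy_ordination(coords * 17.0)
        assert coinertia(X, Y, n_perm=0).rv == pytest.approx(1.0)

    def test_eigenvalue_ordering_and_fractions(self):
        rng = np.random.default_rng(6)
        X = toy_ordination(rng.normal(size=(25, 4)))
        Y = toy_ordination(rng.normal(size=(25, 3)))
        res = coinertia(X, Y, n_perm=0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.eigenvalue_fractions.sum() == pytest.approx(1.0)
        assert 0 <= res.rv <= 1

    def test_null_p_uniform(self):
        # independent tables: permutation p must be approximately uniform
        rng = np.random.default_rng(7)
        ps = []
        for s in range(20):
            X = toy_ordination(rng.normal(size=(50, 3)))
            Y = toy_ordination(rng.normal(size=(50, 3)))
            ps.append(coinertia(X, Y, n_perm=199, seed=s).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_mismatched_rows_error(self):
        X = toy_ordination(np.zeros((4, 2)))
        Y = toy_ordination(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            coinertia(X, Y)


def test_pcoa_cross_check_against_skbio():
    """Independent implementation check on a Euclidean-embeddable matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(11)
    pts = rng.normal(size=(8, 3))
    D = euclidean(pts)
    mine = principal_coordinates(D, correction="none")
    theirs = skbio_pcoa(skbio.DistanceMatrix(D.values), number_of_dimensions=3)
    assert np.allclose(
        np.sort(mine.eigenvalues)[::-1][:3],
        np.sort(theirs.eigvals.values)[::-1][:3],
        atol=1e-8,
    )
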