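"""AMOVA, pairwise differentiation, Jost's D and binary encoding."""

import math

import numpy as np
import pandas as pd
import pytest

from mhcpop import (
    amova,
    binary_encode,
    jc69_distance,
    jost_dest,
    mhc_units,
    microsat_units,
    pairwise_fst,
    pairwise_phist,
)
from mhcpop.tables import MHCGenotypeTable, MicrosatGenotypeTable


class TestJC69:
    def test_identical(self):
        assert jc69_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form(self):
        a = "A" * 185
        b = "C" * 10 + "A" * 175
        p = 10 / 185
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert jc69_distance(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(0.0561, abs=1e-4)

    def test_saturation_errors(self):
        with pytest.raises(ValueError, match="saturated"):
            jc69_distance("A" * 4, "C" * 3 + "A")


def amova_oracle(d2, groups):
    """Direct sums-of-squares decomposition, no shortcuts."""
    groups = np.asarray(groups)
    N = len(groups)
    labels, counts = np.unique(groups, return_counts=True)
    ss_total = sum(d2[i, j] for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    for g, n_g in zip(labels, counts):
        idx = np.flatnonzero(groups == g)
        ss_within += sum(
            d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]
        ) / n_g
    ss_among = ss_total - ss_within
    k = len(labels)
    sw = ss_within / (N - k)
    n0 = (N - (counts ** 2).sum() / N) / (k - 1)
    sa = (ss_among / (k - 1) - sw) / n0
    return sa, sw, sa / (sa + sw)


class TestAMOVA:
    def test_components_match_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        # 3 pops x 4 units, random squared distances
        X = rng.random((12, 3))
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        res = amova(d2, groups, n_perm=0)
        sa, sw, phi = amova_oracle(d2, groups)
        assert res.sigma2_among == pytest.approx(sa, abs=1e-9)
        assert res.sigma2_within == pytest.approx(sw, abs=1e-9)
        assert res.phi_st == pytest.approx(phi, abs=1e-9)

    def test_unbalanced_oracle(self):
        rng = np.random.default_rng(8)
        d2 = rng.random((9, 9))
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        groups = ["A"] * 2 + ["B"] * 3 + ["C"] * 4
        res = amova(d2, groups, n_perm=0)
        sa, sw, phi = amova_oracle(d2, groups)
        assert res.phi_st == pytest.approx(phi, abs=1e-9)

    def test_fixed_difference(self):
        # two populations fixed for different haplotypes
        d2 = np.zeros((8, 8))
        d2[:4, 4:] = 1.0
        d2[4:, :4] = 1.0
        res = amova(d2, ["A"] * 4 + ["B"] * 4, n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(0)
        sig = 0
        n_seeds = 10
        for s in range(n_seeds):
            X = rng.random((16, 2))
            d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            res = amova(d2, ["A"] * 8 + ["B"] * 8, n_perm=99, seed=s)
            sig += res.p_value <= 0.05
        assert sig <= 2

    def test_population_of_one_errors(self):
        d2 = np.zeros((3, 3))
        with pytest.raises(ValueError, match="size 1"):
            amova(d2, ["A", "A", "B"])


@pytest.fixture(scope="module")
def two_marker_tables():
    rng = np.random.default_rng(42)
    pools = {"P": [0.6, 0.3, 0.1], "Q": [0.1, 0.3, 0.6], "R": [0.3, 0.4, 0.3]}
    alleles = ["a", "b", "c"]
    seqs = {"a": "A" * 60, "b": "A" * 57 + "CCC", "c": "A" * 54 + "GGGGGG"}
    mhc_rows, ms_rows = [], []
    inds, pops_map, geno = [], {}, {}
    for pop, freqs in pools.items():
        for j in range(8):
            ind = f"{pop}{j}"
            chosen = rng.choice(3, size=2, replace=False, p=freqs)
            mhc_rows.append((ind, pop, [alleles[c] for c in chosen]))
            pair = tuple(sorted(rng.choice([100, 102, 104], size=2, p=freqs)))
            inds.append(ind)
            pops_map[ind] = pop
            geno[ind] = {"L1": pair, "L2": pair}
    mhc = MHCGenotypeTable.from_records(mhc_rows)
    msat = MicrosatGenotypeTable(inds, pops_map, ["L1", "L2"], geno)
    return mhc, msat, seqs


class TestPairwise:
    def test_cells_equal_standalone_two_population_amova(self, two_marker_tables):
        mhc, msat, seqs = two_marker_tables
        pw = pairwise_phist(mhc, seqs, n_perm=0)
        d2, pops = mhc_units(mhc, seqs)
        for a, b in [("P", "Q"), ("P", "R"), ("Q", "R")]:
            mask = (pops == a) | (pops == b)
            solo = amova(d2[np.ix_(mask, mask)], pops[mask], n_perm=0)
            assert pw.statistic.loc[a, b] == pytest.approx(solo.phi_st)

    def test_matrix_symmetry_and_diagonal(self, two_marker_tables):
        _, msat, _ = two_marker_tables
        pw = pairwise_fst(msat, n_perm=49, seed=1)
        S = pw.statistic
        assert (S.values == S.values.T).all()
        assert (np.diag(S.values) == 0).all()
        assert (np.diag(pw.p_values.values) == 1).all()

    def test_identical_populations_near_zero(self):
        # same genotypes copied into two populations
        rows = []
        inds, pops_map, geno = [], {}, {}
        for pop in ("P", "Q"):
            for j in range(6):
                ind = f"{pop}{j}"
                inds.append(ind)
                pops_map[ind] = pop
                geno[ind] = {"L1": (100, 102) if j % 2 else (100, 100)}
        msat = MicrosatGenotypeTable(inds, pops_map, ["L1"], geno)
        pw = pairwise_fst(msat, n_perm=99, seed=3)
        assert pw.statistic.loc["P", "Q"] <= 1e-9
        assert pw.p_values.loc["P", "Q"] > 0.05


class TestJostD:
    def test_fixed_difference_is_one(self):
        counts = pd.DataFrame([[10, 0], [0, 10]])
        assert jost_dest(counts) == pytest.approx(1.0)

    def test_identical_counts_non_positive(self):
        counts = pd.DataFrame([[8, 2], [8, 2]])
        assert jost_dest(counts) <= 0.0

    def test_hand_computed_example(self):
        # pops (8,2) vs (2,8): Hs = 1 - 58/90 = 32/45; Ht = 1/2;
        # D = 2 * (13/90) / (58/90) = 26/58
        counts = pd.DataFrame([[8, 2], [2, 8]])
        assert jost_dest(counts) == pytest.approx(26 / 58)

    def test_saturated_heterozygosity_errors(self):
        counts = pd.DataFrame([[1, 1], [1, 1]])
        with pytest.raises(ValueError):
            jost_dest(counts)


class TestBinaryEncode:
    def test_encoding_rules(self, two_marker_tables):
        mhc, msat, _ = two_marker_tables
        bm, bs, log = binary_encode(mhc, msat)
        assert (bm.sum(axis=1) == 2).all()  # every individual carries 2 alleles
        assert set(bm.values.ravel()) <= {0, 1}
        # heterozygote -> two presence columns at the locus; homozygote -> one
        for ind in bs.index:
            pair = msat.genotypes[ind]["L1"]
            cols = [c for c in bs.columns if c.startswith("L1_")]
            assert bs.loc[ind, cols].sum() == len(set(pair))

    def test_intersection_and_errors(self):
        mhc = MHCGenotypeTable.from_records([("i1", "P", ["a", "b"])])
        msat = MicrosatGenotypeTable(
            ["i2"], {"i2": "P"}, ["L1"], {"i2": {"L1": (1, 2)}}
        )
        with pytest.raises(ValueError, match="shared"):
            binary_encode(mhc, msat)
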