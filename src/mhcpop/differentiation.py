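"""Population differentiation: AMOVA fixation indices and Jost's D.

One-level analysis of molecular variance on squared inter-unit
distances, in three flavours matching how each marker is scored:

* ``phist`` - MHC sequence mode: each individual contributes one unit per
  carried allele, and the squared distance between units is the
  Jukes-Cantor distance between the allele sequences (frequency-weighted
  haplotype AMOVA; loci are unresolvable, so allele carriages stand in
  for gene copies);
* ``fst`` - microsatellite mode: each individual contributes two
  pseudo-haplotype units, and the squared distance is the number of loci
  at which the units carry different alleles (the "number of different
  alleles" convention);
* ``binary_jaccard`` - dominant-marker mode on presence/absence rows
  with squared distance ``1 - S3``.

Significance is by permutation of units among populations with
``(b + 1)/(m + 1)`` smoothing.  Jost's D uses the k-population estimator
with nearly unbiased within-population gene diversities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import MHCGenotypeTable, MicrosatGenotypeTable


def jc69_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor corrected substitutions per site between two sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if not seq_a:
        raise ValueError("empty sequences")
    p = sum(x != y for x, y in zip(seq_a, seq_b)) / len(seq_a)
    if p >= 0.75:
        raise ValueError(f"mismatch proportion {p:.3f} >= 0.75: JC69 saturated")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class AMOVAResult:
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    phi_st: float
    p_value: float | None
    n_permutations: int
    populations: list[str]


def _group_ss(d2: np.ndarray, idx: np.ndarray) -> float:
    return d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))


def amova(
    d2: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> AMOVAResult:
    """One-level AMOVA on a matrix of squared inter-unit distances.

    Decomposes the total sum of squares into among- and within-population
    components (Excoffier's sums-of-squares identities on pairwise
    distances), estimates the variance components and Phi_ST, and tests
    significance by shuffling units among populations.
    """
    d2 = np.asarray(d2, dtype=float)
    groups = np.asarray(groups)
    N = len(groups)
    if d2.shape != (N, N):
        raise ValueError("distance matrix does not match the group labels")
    labels, counts = np.unique(groups, return_counts=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 populations")
    if counts.min() < 2:
        small = labels[counts < 2]
        raise ValueError(f"populations of size 1: {list(small)}")

    ss_total = d2.sum() / (2.0 * N)
    group_idx = [np.flatnonzero(groups == g) for g in labels]
    ss_within = sum(_group_ss(d2, idx) for idx in group_idx)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, N - k
    sigma_w = ss_within / df_within
    n0 = (N - (counts ** 2).sum() / N) / (k - 1)
    sigma_a = (ss_among / df_among - sigma_w) / n0
    total_var = sigma_a + sigma_w
    phi = sigma_a / total_var if total_var > 0 else 0.0

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = [len(idx) for idx in group_idx]
        hits = 0
        perm = np.arange(N)
        for _ in range(n_perm):
            rng.shuffle(perm)
            ssw = 0.0
            start = 0
            for n_g in sizes:
                idx = perm[start : start + n_g]
                ssw += _group_ss(d2, idx)
                start += n_g
            ssa = ss_total - ssw
            sw = ssw / df_within
            sa = (ssa / df_among - sw) / n0
            tv = sa + sw
            phi_p = sa / tv if tv > 0 else 0.0
            if phi_p >= phi - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)

    pct_among = 100.0 * phi
    return AMOVAResult(
        float(sigma_a), float(sigma_w), float(pct_among), float(phi),
        p, n_perm, list(map(str, labels)),
    )


# ---------------------------------------------------------------------------
# unit builders


def mhc_units(
    table: MHCGenotypeTable, allele_sequences: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Allele-carriage units and their squared JC69 distance matrix."""
    allele_ids = sorted({a for s in table.allele_sets.values() for a in s})
    aidx = {a: i for i, a in enumerate(allele_ids)}
    base = np.zeros((len(allele_ids), len(allele_ids)))
    for i, a in enumerate(allele_ids):
        for j in range(i + 1, len(allele_ids)):
            d = jc69_distance(allele_sequences[a], allele_sequences[allele_ids[j]])
            base[i, j] = base[j, i] = d
    unit_alleles, unit_pops = [], []
    for ind in table.individuals:
        for a in sorted(table.allele_sets[ind]):
            unit_alleles.append(aidx[a])
            unit_pops.append(table.populations[ind])
    ua = np.array(unit_alleles)
    return base[np.ix_(ua, ua)], np.array(unit_pops)


def microsat_units(table: MicrosatGenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Gene-copy pseudo-haplotype units with allele-identity distances.

    Each individual contributes two units (the unordered pair split in
    label order - phase is arbitrary); the squared distance between two
    units is the number of loci at which they differ, with loci missing
    in either unit skipped.
    """
    inds = table.individuals
    n_loci = len(table.loci)
    # allele matrix: 2 rows per individual, -1 for missing
    M = np.full((2 * len(inds), n_loci), -1, dtype=int)
    pops = np.empty(2 * len(inds), dtype=object)
    for i, ind in enumerate(inds):
        pops[2 * i] = pops[2 * i + 1] = table.populations[ind]
        for l, locus in enumerate(table.loci):
            pair = table.genotypes[ind].get(locus)
            if pair is not None:
                M[2 * i, l], M[2 * i + 1, l] = pair
    d2 = np.zeros((len(M), len(M)))
    for l in range(n_loci):
        col = M[:, l]
        valid = col >= 0
        diff = (col[:, None] != col[None, :]) & valid[:, None] & valid[None, :]
        d2 += diff
    return d2, pops


def binary_units(matrix: pd.DataFrame, populations: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Individuals' presence/absence rows with squared distance 1 - S3."""
    from .multivar import jaccard_s3_distance

    d = jaccard_s3_distance(matrix)
    d2 = np.asarray(d) ** 2
    pops = np.array([populations[i] for i in matrix.index])
    return d2, pops


# ---------------------------------------------------------------------------
# pairwise matrices


@dataclass
class PairwiseDifferentiation:
    populations: list[str]
    statistic: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    kind: str


def _pairwise_from_units(
    d2: np.ndarray,
    unit_pops: np.ndarray,
    pops: list[str],
    kind: str,
    n_perm: int,
    seed: int | None,
) -> PairwiseDifferentiation:
    stat = pd.DataFrame(0.0, index=pops, columns=pops)
    pval = pd.DataFrame(1.0, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            mask = (unit_pops == a) | (unit_pops == b)
            sub = d2[np.ix_(mask, mask)]
            res = amova(sub, unit_pops[mask], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
            stat.loc[a, b] = stat.loc[b, a] = res.phi_st
            if res.p_value is not None:
                pval.loc[a, b] = pval.loc[b, a] = res.p_value
    return PairwiseDifferentiation(pops, stat, pval, n_perm, kind)


def pairwise_phist(
    table: MHCGenotypeTable,
    allele_sequences: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> PairwiseDifferentiation:
    """Pairwise Phi_ST on MHC allele carriages with JC69 distances."""
    d2, unit_pops = mhc_units(table, allele_sequences)
    return _pairwise_from_units(d2, unit_pops, table.population_names,
                                "phist", n_perm, seed)


def pairwise_fst(
    table: MicrosatGenotypeTable,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PairwiseDifferentiation:
    """Pairwise microsatellite F_ST (number-of-different-alleles AMOVA)."""
    d2, unit_pops = microsat_units(table)
    return _pairwise_from_units(d2, unit_pops, table.population_names,
                                "fst", n_perm, seed)


# ---------------------------------------------------------------------------
# Jost's D


def jost_dest(counts: pd.DataFrame | np.ndarray) -> float:
    """Jost's actual-differentiation estimator over k populations.

    ``D = (k/(k-1)) * (H_T - H_S) / (1 - H_S)``, with each population's
    homozygosity estimated nearly unbiasedly as
    ``sum_i n_i (n_i - 1) / (n (n - 1))`` and H_T computed from the
    unweighted mean allele frequencies across populations.
    """
    C = np.asarray(counts, dtype=float)
    C = C[C.sum(axis=1) > 0]
    k = C.shape[0]
    if k < 2:
        raise ValueError("need counts for at least 2 populations")
    n = C.sum(axis=1)
    if (n < 2).any():
        raise ValueError("every population needs at least 2 allele copies")
    homoz = ((C * (C - 1)).sum(axis=1)) / (n * (n - 1))
    hs = 1 - homoz.mean()
    p_bar = (C / n[:, None]).mean(axis=0)
    ht = 1 - (p_bar ** 2).sum()
    if hs >= 1:
        raise ValueError("within-population heterozygosity is 1: D undefined")
    return float(k / (k - 1) * (ht - hs) / (1 - hs))


def pairwise_dest(
    counts: pd.DataFrame,
    per_individual: Mapping[str, Sequence] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> PairwiseDifferentiation:
    """Pairwise Jost's D from a population x allele count table.

    With ``n_perm > 0`` and ``per_individual`` (individual -> (population,
    allele multiset)) supplied, significance is assessed by permuting
    individuals between the two populations of each pair.
    """
    pops = list(counts.index)
    stat = pd.DataFrame(0.0, index=pops, columns=pops)
    pval = pd.DataFrame(1.0, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    items = None
    if per_individual is not None:
        items = [(ind, pop, list(alleles))
                 for ind, (pop, alleles) in per_individual.items()]
    alleles = list(counts.columns)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            obs = jost_dest(counts.loc[[a, b]])
            stat.loc[a, b] = stat.loc[b, a] = obs
            if n_perm > 0 and items is not None:
                pair_items = [(ind, pop, al) for ind, pop, al in items
                              if pop in (a, b)]
                labels = [pop for _, pop, _ in pair_items]
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(labels)
                    c = pd.DataFrame(0, index=[a, b], columns=alleles)
                    for (ind, _, als), lab in zip(pair_items, perm):
                        for al in als:
                            c.loc[lab, al] += 1
                    try:
                        d = jost_dest(c)
                    except ValueError:
                        continue
                    if d >= obs - 1e-12:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
                pval.loc[a, b] = pval.loc[b, a] = p
    return PairwiseDifferentiation(pops, stat, pval, n_perm, "dest")


# ---------------------------------------------------------------------------
# binary encoding


def binary_encode(
    mhc: MHCGenotypeTable, msat: MicrosatGenotypeTable
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Dominant 0/1 encoding of both markers over their shared individuals.

    Every distinct allele (per locus for microsatellites) becomes a
    column; a cell is 1 iff the individual carries at least one copy
    (dominance collapses dosage).  Returns the two matrices over the
    intersection of individuals plus a log of dropped ids.
    """
    shared = [i for i in mhc.individuals if i in set(msat.individuals)]
    if not shared:
        raise ValueError("no shared individuals between the two tables")
    dropped = sorted(
        (set(mhc.individuals) | set(msat.individuals)) - set(shared)
    )
    log = [f"dropped (not in both tables): {i}" for i in dropped]

    mhc_alleles = sorted({a for s in mhc.allele_sets.values() for a in s})
    mhc_mat = pd.DataFrame(
        [[1 if a in mhc.allele_sets[i] else 0 for a in mhc_alleles]
         for i in shared],
        index=shared, columns=mhc_alleles, dtype=int,
    )

    cols = []
    for locus in msat.loci:
        labels = sorted({
            a for i in shared
            for pair in [msat.genotypes[i].get(locus)] if pair is not None
            for a in pair
        })
        cols.extend((locus, a) for a in labels)
    data = np.zeros((len(shared), len(cols)), dtype=int)
    col_idx = {c: j for j, c in enumerate(cols)}
    for r, i in enumerate(shared):
        for locus in msat.loci:
            pair = msat.genotypes[i].get(locus)
            if pair is None:
                continue
            for a in pair:
                data[r, col_idx[(locus, a)]] = 1
    msat_mat = pd.DataFrame(
        data, index=shared, columns=[f"{l}_{a}" for l, a in cols]
    )
    return mhc_mat, msat_mat, log
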