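"""Per-population diversity statistics for both marker classes.

Microsatellites: observed/unbiased-expected heterozygosity and rarefied
allelic richness (exact hypergeometric rarefaction to a standard number
of gene copies).  MHC: nucleotide diversity over allele sequences
weighted by carrier frequency, relative allele frequencies, counts of
distinct within-individual allele combinations ("MHC-like genotypes"),
and the individual allele-diversity index (alleles carried / dataset
maximum).
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import MHCGenotypeTable, MicrosatGenotypeTable


def heterozygosity(
    table: MicrosatGenotypeTable, population: str
) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity, averaged over loci.

    H_o is the fraction of heterozygous individuals per locus; H_e is
    Nei's small-sample-corrected gene diversity
    ``(2n/(2n-1)) * (1 - sum p_i^2)``.  Missing genotypes are dropped per
    locus.
    """
    inds = table.individuals_in(population)
    if not inds:
        raise ValueError(f"population {population!r} absent from the table")
    ho_l, he_l = [], []
    for locus in table.loci:
        pairs = [table.genotypes[i][locus] for i in inds
                 if table.genotypes[i].get(locus) is not None]
        n = len(pairs)
        if n < 2:
            continue
        ho_l.append(sum(a != b for a, b in pairs) / n)
        counts = Counter(a for pair in pairs for a in pair)
        tot = 2 * n
        sum_p2 = sum((c / tot) ** 2 for c in counts.values())
        he_l.append(tot / (tot - 1) * (1 - sum_p2))
    if not ho_l:
        raise ValueError(f"population {population!r} has <2 genotyped "
                         "individuals at every locus")
    return float(np.mean(ho_l)), float(np.mean(he_l))


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness_from_counts(counts: Sequence[int], g: int) -> float:
    """Expected number of alleles in a random subsample of ``g`` gene copies.

    ``sum_i [1 - C(N - N_i, g) / C(N, g)]`` with N total copies and N_i
    copies of allele i; exact hypergeometric expectation, no simulation.
    """
    counts = [c for c in counts if c > 0]
    N = sum(counts)
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample of {N} gene copies")
    if g < 1:
        raise ValueError("g must be >= 1")
    total = 0.0
    for ni in counts:
        if N - ni < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(_log_comb(N - ni, g) - _log_comb(N, g))
    return total


def rarefied_allelic_richness(
    table: MicrosatGenotypeTable, g: int | None = None
) -> tuple[dict[str, float], int]:
    """Per-population rarefied allelic richness, averaged over loci.

    ``g`` defaults to the smallest number of gene copies observed in any
    population at any locus (so every population-locus can be rarefied);
    returns ``(population -> A_r, g used)``.
    """
    pops = table.population_names
    per_cell = {}
    min_copies = math.inf
    for pop in pops:
        for locus in table.loci:
            counts = table.allele_counts(pop, locus)
            n_copies = sum(counts.values())
            per_cell[(pop, locus)] = list(counts.values())
            if n_copies:
                min_copies = min(min_copies, n_copies)
    if g is None:
        g = int(min_copies)
    out = {}
    for pop in pops:
        vals = []
        for locus in table.loci:
            counts = per_cell[(pop, locus)]
            if not counts:
                continue
            if g > sum(counts):
                raise ValueError(
                    f"g={g} exceeds gene copies at {pop}/{locus} ({sum(counts)})"
                )
            vals.append(rarefied_richness_from_counts(counts, g))
        out[pop] = float(np.mean(vals))
    return out, g


def nucleotide_diversity(
    sequences: Mapping[str, str], counts: Mapping[str, int]
) -> float:
    """Nucleotide diversity per site from haplotype carrier counts.

    ``pi = (n/(n-1)) * sum_{i<j} 2 f_i f_j d_ij`` where f are
    carrier-count frequencies, d the per-site mismatch proportion and n
    the total carrier count.
    """
    ids = [a for a in counts if counts[a] > 0]
    n = sum(counts[a] for a in ids)
    if n < 2:
        return 0.0
    lengths = {len(sequences[a]) for a in ids}
    if len(lengths) != 1:
        raise ValueError("sequence length mismatch")
    L = lengths.pop()
    freqs = {a: counts[a] / n for a in ids}
    pi = 0.0
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = sum(x != y for x, y in zip(sequences[a], sequences[b])) / L
            pi += 2 * freqs[a] * freqs[b] * d
    return n / (n - 1) * pi


def relative_allele_frequencies(table: MHCGenotypeTable) -> pd.DataFrame:
    """Population x allele matrix of carrier-count relative frequencies.

    Numerator: individuals carrying the allele; denominator: total allele
    carriages in the region (sum of individual allele-set sizes), the
    carriage-count convention.
    """
    if not len(table):
        raise ValueError("empty genotype table")
    alleles = sorted({a for s in table.allele_sets.values() for a in s})
    rows = {}
    for pop in table.population_names:
        inds = table.individuals_in(pop)
        denom = sum(len(table.allele_sets[i]) for i in inds)
        carriers = Counter(a for i in inds for a in table.allele_sets[i])
        rows[pop] = [carriers.get(a, 0) / denom for a in alleles]
    return pd.DataFrame.from_dict(rows, orient="index", columns=alleles)


def mhc_allele_counts(table: MHCGenotypeTable) -> pd.DataFrame:
    """Population x allele carrier counts (for Jost's D etc.)."""
    alleles = sorted({a for s in table.allele_sets.values() for a in s})
    rows = {}
    for pop in table.population_names:
        carriers = Counter(
            a for i in table.individuals_in(pop) for a in table.allele_sets[i]
        )
        rows[pop] = [carriers.get(a, 0) for a in alleles]
    return pd.DataFrame.from_dict(rows, orient="index", columns=alleles)


def mhc_genotype_diversity(
    table: MHCGenotypeTable,
) -> tuple[pd.DataFrame, int]:
    """Distinct within-individual allele combinations per population.

    GT counts distinct allele sets within each population; P_GT counts
    those sets found in exactly one population.  Also returns the global
    number of unique MHC-like genotypes.
    """
    if not len(table):
        raise ValueError("empty genotype table")
    pops = table.population_names
    sets_by_pop = {
        pop: {table.allele_sets[i] for i in table.individuals_in(pop)}
        for pop in pops
    }
    occupancy = Counter(s for sets_ in sets_by_pop.values() for s in sets_)
    rows = []
    for pop in pops:
        gt = len(sets_by_pop[pop])
        pgt = sum(1 for s in sets_by_pop[pop] if occupancy[s] == 1)
        rows.append({"population": pop, "GT": gt, "P_GT": pgt})
    global_count = len({s for sets_ in sets_by_pop.values() for s in sets_})
    return pd.DataFrame(rows).set_index("population"), global_count


def allele_diversity_index(
    table: MHCGenotypeTable,
) -> tuple[pd.Series, pd.Series]:
    """Individual allele-diversity index A and its per-population mean.

    A = (alleles carried) / (maximum alleles carried by any individual in
    the dataset); with a 2-5 allele range and maximum 5 it spans 0.4-1.0.
    """
    if not len(table):
        raise ValueError("empty genotype table")
    max_alleles = max(len(s) for s in table.allele_sets.values())
    per_ind = pd.Series(
        {i: len(table.allele_sets[i]) / max_alleles for i in table.individuals},
        name="A",
    )
    per_pop = pd.Series(
        {
            pop: float(per_ind[table.individuals_in(pop)].mean())
            for pop in table.population_names
        },
        name="A",
    )
    return per_ind, per_pop


def diversity_report(
    mhc: MHCGenotypeTable,
    msat: MicrosatGenotypeTable,
    allele_sequences: Mapping[str, str],
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Assemble the per-population diversity table for both markers.

    Columns: H_o, H_e, A_r (microsatellites); H (number of MHC alleles),
    pi (nucleotide diversity), GT, P_GT, A (MHC).
    """
    ar, g = rarefied_allelic_richness(msat, rarefaction_g)
    gt_table, _ = mhc_genotype_diversity(mhc)
    _, a_pop = allele_diversity_index(mhc)
    counts = mhc_allele_counts(mhc)
    rows = []
    for pop in msat.population_names:
        ho, he = heterozygosity(msat, pop)
        pop_counts = counts.loc[pop]
        present = pop_counts[pop_counts > 0]
        pi = nucleotide_diversity(allele_sequences, pop_counts.to_dict())
        rows.append(
            {
                "population": pop,
                "n": len(msat.individuals_in(pop)),
                "H_o": ho,
                "H_e": he,
                "A_r": ar[pop],
                "H": int(len(present)),
                "pi": pi,
                "GT": int(gt_table.loc[pop, "GT"]),
                "P_GT": int(gt_table.loc[pop, "P_GT"]),
                "A": float(a_pop[pop]),
            }
        )
    df = pd.DataFrame(rows).set_index("population")
    df.attrs["rarefaction_g"] = g
    return df
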