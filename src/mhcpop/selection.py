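"""Desk-scale selection statistics for codon alignments.

Nei-Gojobori (1986) counting of synonymous and nonsynonymous sites and
differences with Jukes-Cantor correction, the one-sided Z-test of
positive selection (dN > dS) with a codon-bootstrap standard error, and
likelihood-ratio-test arithmetic for nested codon models whose maximized
log-likelihoods are supplied externally (full ML fitting of site models
is out of scope here - the module consumes fitted records).

Site-counting convention: each codon position contributes the fraction
of its three possible one-step changes that are synonymous; changes that
create stop codons count as nonsynonymous, so synonymous + nonsynonymous
sites always sum to 3 per codon.  Multi-substitution codons average
their differences over all shortest mutational pathways, excluding
pathways that pass through a stop codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genotyping import GENETIC_CODE

BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Equal-length, frame-trimmed coding sequences (length % 3 == 0)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length")
        L = lengths.pop()
        if L == 0 or L % 3:
            raise ValueError("alignment length must be a positive multiple of 3")
        for name, s in self.sequences.items():
            if set(s) - set(BASES):
                raise ValueError(f"{name}: non-ACGT characters")
        self.flagged_stops = [
            name
            for name, s in self.sequences.items()
            if any(GENETIC_CODE[s[i:i + 3]] == "*" for i in range(0, len(s), 3))
        ]

    @classmethod
    def from_fasta(cls, path, frame_offset: int = 0) -> "CodonAlignment":
        from Bio import SeqIO

        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            s = str(rec.seq).upper()[frame_offset:]
            s = s[: 3 * (len(s) // 3)]
            seqs[rec.id] = s
        return cls(seqs)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3


def synonymous_fraction(codon: str) -> float:
    """Fraction (out of 3) of one-step changes per codon that are synonymous."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        s_pos = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] == aa and GENETIC_CODE[mut] != "*":
                s_pos += 1
        syn += s_pos / 3.0
    return syn


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts; always sums to 3."""
    s = synonymous_fraction(codon)
    return s, 3.0 - s


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) differences over shortest pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, all pathways are used (classical fallback).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                blocked = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    use = results if results else blocked_results
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def pairwise_ng86(
    seq1: str, seq2: str, codon_indices: Sequence[int] | None = None
) -> tuple[float, float, float, float]:
    """NG86 counts for one sequence pair: (S, N, Sd, Nd).

    S and N are averaged over the two sequences; ``codon_indices``
    restricts (with multiplicity, for bootstrapping) the codons used.
    """
    n_codons = len(seq1) // 3
    idx = range(n_codons) if codon_indices is None else codon_indices
    S = N = Sd = Nd = 0.0
    for i in idx:
        c1, c2 = seq1[3 * i : 3 * i + 3], seq2[3 * i : 3 * i + 3]
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pathway_changes(c1, c2)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion >= 0.75: saturated")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class DnDsResult:
    dN: float
    dS: float
    z: float | None
    p_value: float | None
    n_pairs: int
    n_saturated: int
    bootstrap_reps: int
    seed: int | None


def ng86_dnds(
    aln: CodonAlignment,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> DnDsResult:
    """Overall dN/dS with the one-sided Z-test of positive selection.

    dN and dS are means over all sequence pairs of the Jukes-Cantor
    corrected proportions; the standard error of dN - dS comes from a
    seeded codon bootstrap, and p is the one-sided normal tail for
    dN > dS.  Saturated pairs (pS or pN >= 0.75) are excluded and
    counted.
    """
    names = list(aln.sequences)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    n_codons = aln.n_codons

    def mean_dn_ds(codon_indices=None) -> tuple[float, float, int]:
        dns, dss, saturated = [], [], 0
        for a, b in pairs:
            S, N, Sd, Nd = pairwise_ng86(
                aln.sequences[a], aln.sequences[b], codon_indices
            )
            if S == 0 or N == 0:
                saturated += 1
                continue
            try:
                ds = _jc_correct(Sd / S)
                dn = _jc_correct(Nd / N)
            except ValueError:
                saturated += 1
                continue
            dss.append(ds)
            dns.append(dn)
        if not dns:
            return math.nan, math.nan, saturated
        return float(np.mean(dns)), float(np.mean(dss)), saturated

    dN, dS, n_sat = mean_dn_ds()
    z = p = None
    if math.isfinite(dN) and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        diffs = []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, n_codons, size=n_codons)
            dn_b, ds_b, _ = mean_dn_ds(idx)
            if math.isfinite(dn_b):
                diffs.append(dn_b - ds_b)
        se = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
        if se > 0:
            z = (dN - dS) / se
            p = float(stats.norm.sf(z))
    return DnDsResult(dN, dS, z, p, len(pairs), n_sat, bootstrap_reps, seed)


# ---------------------------------------------------------------------------
# likelihood-ratio arithmetic


@dataclass
class ModelFit:
    """An externally fitted codon model: label, maximized lnL, and the
    number of parameters in the omega distribution."""

    label: str
    lnL: float
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class LRTResult:
    null: str
    alt: str
    statistic: float
    df: int
    p_value: float


def lrt(null: ModelFit, alt: ModelFit) -> LRTResult:
    """Likelihood-ratio test between nested codon models.

    statistic = 2 (lnL_alt - lnL_null), df = k_alt - k_null, with a
    chi-square upper tail.  The alternative must have more omega
    parameters and at least the null's likelihood (tiny negative slack
    tolerated for printed rounding).
    """
    if alt.k <= null.k:
        raise ValueError(
            f"models not nested: alt k={alt.k} must exceed null k={null.k}"
        )
    stat = 2.0 * (alt.lnL - null.lnL)
    if stat < -1e-6:
        raise ValueError("alternative model has lower likelihood than the null")
    stat = max(stat, 0.0)
    df = alt.k - null.k
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(null.label, alt.label, stat, df, p)


def load_model_fits(path) -> dict[str, ModelFit]:
    """Read model fits from CSV (label, lnL, k) or JSON."""
    import json
    from pathlib import Path

    path = Path(path)
    fits: dict[str, ModelFit] = {}
    if path.suffix.lower() == ".json":
        for rec in json.loads(path.read_text()):
            fits[rec["label"]] = ModelFit(rec["label"], float(rec["lnL"]),
                                          int(rec["k"]))
    else:
        import csv

        with open(path) as fh:
            for rec in csv.DictReader(fh):
                fits[rec["label"]] = ModelFit(
                    rec["label"], float(rec["lnL"]), int(rec["k"])
                )
    return fits
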