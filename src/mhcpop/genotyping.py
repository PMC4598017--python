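"""Amplicon-to-genotype calling for multi-locus MHC pyrosequencing data.

The procedure mirrors the threshold- and rule-based validation used for
454-style MHC amplicon surveys:

1. demultiplex pooled reads by exact MID tag pairs and primers, discarding
   reads with incomplete tags/primers, ambiguity codes or off-length
   inserts;
2. tabulate distinct insert sequences ("variants") with per-individual
   read counts and the maximum per-amplicon frequency (MPAF) - the
   largest within-individual read proportion a variant reaches in any
   carrier;
3. classify each variant through a deterministic decision ladder: true
   alleles live at MPAF >= 4% with a clean reading frame and independent
   carriers, whereas variants in the 0.1-4% window are triaged as 1-2 bp
   PCR/sequencing artifacts of a co-occurring parental allele, stop-codon
   or frameshift pseudogene amplicons, singletons, or replicate-
   unverified variants;
4. call per-individual allele sets for individuals with enough retained
   reads (>= 150 by default), and
5. score replicate concordance between independent sequencing runs.

Classification is fully deterministic given the variant table and
parameters; no clustering or quality scores are involved.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import revcomp

# classification labels
TRUE_ALLELE = "TRUE_ALLELE"
ONE_TWO_BP_ARTIFACT = "ONE_TWO_BP_ARTIFACT"
STOP_CODON = "STOP_CODON"
FRAMESHIFT = "FRAMESHIFT"
SINGLETON = "SINGLETON"
UNVERIFIED = "UNVERIFIED"
CANDIDATE = "CANDIDATE"
BELOW_FLOOR = "BELOW_FLOOR"

# discard reasons
REASON_TAG_PRIMER = "missing_tag_or_primer"
REASON_UNASSIGNED = "unassigned_tag_pair"
REASON_AMBIGUOUS = "ambiguous_base"
REASON_LENGTH = "length_mismatch"

_ACGT = frozenset("ACGT")

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class TagScheme:
    """MID tag pairs and primers mapping reads back to individuals."""

    forward_mids: list[str]
    reverse_mids: list[str]
    forward_primer: str
    reverse_primer: str
    assignment: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        if len(set(self.assignment)) != len(self.assignment):
            raise ValueError("duplicate tag pairs in assignment")
        if not self.forward_mids or not self.reverse_mids:
            raise ValueError("MID lists must be non-empty")
        flens = {len(t) for t in self.forward_mids}
        rlens = {len(t) for t in self.reverse_mids}
        if len(flens) != 1 or len(rlens) != 1:
            raise ValueError("MID tags must have uniform length per side")

    def min_tag_distance(self) -> int:
        """Smallest pairwise Hamming distance within either tag list."""
        best = math.inf
        for tags in (self.forward_mids, self.reverse_mids):
            for i, a in enumerate(tags):
                for b in tags[i + 1 :]:
                    best = min(best, sum(x != y for x, y in zip(a, b)))
        return int(best) if best < math.inf else 0

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#forward_primer={self.forward_primer}\n")
            fh.write(f"#reverse_primer={self.reverse_primer}\n")
            fh.write("individual,fwd_mid,rev_mid\n")
            for (f, r), ind in self.assignment.items():
                fh.write(f"{ind},{f},{r}\n")

    @classmethod
    def read_csv(cls, path: str | Path,
                 forward_primer: str | None = None,
                 reverse_primer: str | None = None) -> "TagScheme":
        fp, rp = forward_primer, reverse_primer
        assignment: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#forward_primer="):
                    fp = fp or line.split("=", 1)[1]
                elif line.startswith("#reverse_primer="):
                    rp = rp or line.split("=", 1)[1]
                elif line and not line.startswith(("individual,", "#")):
                    ind, f, r = line.split(",")
                    assignment[(f, r)] = ind
        if fp is None or rp is None:
            raise ValueError("primers not given and not found in the tag CSV")
        fwd = sorted({f for f, _ in assignment})
        rev = sorted({r for _, r in assignment})
        return cls(fwd, rev, fp, rp, assignment)


@dataclass
class Variant:
    """One distinct insert sequence with its per-individual read counts."""

    sequence: str
    per_individual_counts: dict[str, int]
    mpaf: float
    n_carriers: int


@dataclass
class VariantClassification:
    label: str
    evidence: str


@dataclass
class MHCGenotypeCall:
    individual: str
    population: str | None
    alleles: frozenset[str]
    total_retained_reads: int
    status: str  # CALLED | DISCARDED_LOW_DEPTH


# ---------------------------------------------------------------------------
# demultiplexing


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def demultiplex(
    reads: Iterable[tuple[str, str]],
    scheme: TagScheme,
    expected_length: int,
) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Assign reads to individuals by exact tag/primer matching.

    A read is retained iff its forward MID + forward primer prefix and
    reverse-complemented reverse primer + reverse MID suffix match
    exactly, the insert is pure ACGT, and the insert length equals
    ``expected_length``.  Returns per-individual insert lists and a
    discard log of ``(read id, reason)``; a structurally valid read whose
    tag pair is not in the assignment is logged as unassigned, not fatal.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    flen = len(scheme.forward_mids[0])
    rlen = len(scheme.reverse_mids[0])
    fset = set(scheme.forward_mids)
    rset = set(scheme.reverse_mids)
    fp, rp = scheme.forward_primer, scheme.reverse_primer
    rp_rc = revcomp(rp)
    lead, trail = flen + len(fp), len(rp_rc) + rlen

    by_ind: dict[str, list[str]] = {}
    discards: list[tuple[str, str]] = []
    for rid, seq in reads:
        if len(seq) < lead + trail:
            discards.append((rid, REASON_TAG_PRIMER))
            continue
        fmid = seq[:flen]
        rmid_rc = seq[-rlen:]
        rmid = revcomp(rmid_rc)
        if (
            fmid not in fset
            or rmid not in rset
            or seq[flen:lead] != fp
            or seq[-trail:-rlen] != rp_rc
        ):
            discards.append((rid, REASON_TAG_PRIMER))
            continue
        ind = scheme.assignment.get((fmid, rmid))
        if ind is None:
            discards.append((rid, REASON_UNASSIGNED))
            continue
        insert = seq[lead:-trail]
        if not _ACGT.issuperset(insert):
            discards.append((rid, REASON_AMBIGUOUS))
            continue
        if len(insert) != expected_length:
            discards.append((rid, REASON_LENGTH))
            continue
        by_ind.setdefault(ind, []).append(insert)
    return by_ind, discards


# ---------------------------------------------------------------------------
# variant table and MPAF


def tabulate_variants(inserts: Mapping[str, Sequence[str]]) -> list[Variant]:
    """Collapse retained inserts into a variant table with MPAF.

    MPAF of a variant is the maximum, over individuals carrying it, of
    its read count divided by that individual's *total* retained reads
    (all variants included in the denominator).  The table is sorted by
    total read count (descending) then sequence for determinism.
    """
    totals = {ind: len(seqs) for ind, seqs in inserts.items()}
    counts: dict[str, dict[str, int]] = {}
    for ind, seqs in inserts.items():
        for seq, c in Counter(seqs).items():
            counts.setdefault(seq, {})[ind] = c
    variants = []
    for seq, per_ind in counts.items():
        mpaf = max(c / totals[ind] for ind, c in per_ind.items())
        variants.append(Variant(seq, dict(per_ind), mpaf, len(per_ind)))
    variants.sort(key=lambda v: (-sum(v.per_individual_counts.values()), v.sequence))
    return variants


# ---------------------------------------------------------------------------
# translation


@dataclass
class TranslationFlags:
    protein: str
    has_internal_stop: bool
    frame_ok: bool


def translate_and_flag(sequence: str, frame_offset: int) -> TranslationFlags:
    """Translate in the given frame and flag stop/frameshift problems.

    Trims ``frame_offset`` leading bases and any trailing remainder,
    translates with the standard code, and reports an internal stop iff a
    stop codon occurs before the final codon.  ``frame_ok`` is False iff
    the frame-trimmed length is not a positive multiple of 3 (before
    remainder removal).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    if not sequence:
        raise ValueError("empty sequence")
    body = sequence[frame_offset:]
    frame_ok = len(body) > 0 and len(body) % 3 == 0
    n = len(body) // 3
    codons = [body[3 * i : 3 * i + 3] for i in range(n)]
    protein = "".join(GENETIC_CODE.get(c, "X") for c in codons)
    has_internal_stop = "*" in protein[:-1] if protein else False
    return TranslationFlags(protein, has_internal_stop, frame_ok)


# ---------------------------------------------------------------------------
# classification ladder


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def _replicate_partner(ind: str, replicate_pairs: Sequence[tuple[str, str]]) -> str | None:
    for a, b in replicate_pairs:
        if ind == a:
            return b
        if ind == b:
            return a
    return None


def classify_variants(
    variants: Sequence[Variant],
    mpaf_true_threshold: float = 0.04,
    mpaf_floor: float = 0.001,
    frame_offset: int = 2,
    replicate_pairs: Sequence[tuple[str, str]] | None = None,
    known_alleles: Mapping[str, str] | None = None,
) -> dict[str, VariantClassification]:
    """Apply the multi-step artifact-filtering ladder to every variant.

    Order of decisions per variant:

    1. MPAF below ``mpaf_floor`` (0.1% default): BELOW_FLOOR, discarded
       outright.
    2. Sequence in ``known_alleles`` (a previously characterized allele
       baseline): TRUE_ALLELE.
    3. MPAF >= ``mpaf_true_threshold`` (4% default), no internal stop in
       frame, and >= 2 carriers or confirmation in a replicate pair:
       TRUE_ALLELE.
    4. Otherwise triage, most-conservative-first: within 1-2
       substitutions of a TRUE_ALLELE present in *every* carrier ->
       ONE_TWO_BP_ARTIFACT; internal stop -> STOP_CODON; frame-trimmed
       length not a positive multiple of 3 -> FRAMESHIFT; exactly one
       carrier -> SINGLETON; replicate data exist but the variant is
       absent from a carrier's duplicate -> UNVERIFIED; else CANDIDATE
       (reported for manual review, never genotyped).

    Returns ``sequence -> VariantClassification``; the evidence string of
    every non-TRUE label cites the rule that fired.
    """
    if not 0 < mpaf_true_threshold < 1 or not 0 < mpaf_floor < mpaf_true_threshold:
        raise ValueError("need 0 < mpaf_floor < mpaf_true_threshold < 1")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    replicate_pairs = list(replicate_pairs or [])
    known = {seq: aid for aid, seq in (known_alleles or {}).items()}

    out: dict[str, VariantClassification] = {}

    def replicate_confirmed(v: Variant) -> bool:
        for ind in v.per_individual_counts:
            partner = _replicate_partner(ind, replicate_pairs)
            if partner is not None and partner in v.per_individual_counts:
                return True
        return False

    # pass 1: promote true alleles so artifacts can reference them
    true_seqs: dict[str, Variant] = {}
    for v in variants:
        if v.mpaf < mpaf_floor:
            continue
        if v.sequence in known:
            true_seqs[v.sequence] = v
            out[v.sequence] = VariantClassification(
                TRUE_ALLELE, f"whitelisted known allele {known[v.sequence]}"
            )
            continue
        flags = translate_and_flag(v.sequence, frame_offset)
        carriers_ok = v.n_carriers >= 2 or replicate_confirmed(v)
        if v.mpaf >= mpaf_true_threshold and not flags.has_internal_stop and \
                flags.frame_ok and carriers_ok:
            true_seqs[v.sequence] = v
            out[v.sequence] = VariantClassification(
                TRUE_ALLELE,
                f"mpaf={v.mpaf:.4f}>= {mpaf_true_threshold}, clean ORF, "
                f"{v.n_carriers} carriers",
            )

    # pass 2: triage everything else
    for v in variants:
        if v.sequence in out:
            continue
        if v.mpaf < mpaf_floor:
            out[v.sequence] = VariantClassification(
                BELOW_FLOOR, f"mpaf={v.mpaf:.5f} < floor {mpaf_floor}"
            )
            continue
        parental = _parental_true_allele(v, true_seqs)
        if parental is not None:
            out[v.sequence] = VariantClassification(
                ONE_TWO_BP_ARTIFACT,
                "within 1-2 substitutions of co-occurring true allele "
                f"(parental mpaf={true_seqs[parental].mpaf:.4f})",
            )
            continue
        flags = translate_and_flag(v.sequence, frame_offset)
        if flags.has_internal_stop:
            out[v.sequence] = VariantClassification(
                STOP_CODON, "premature stop codon in frame"
            )
            continue
        if not flags.frame_ok:
            out[v.sequence] = VariantClassification(
                FRAMESHIFT, "frame-trimmed length not a positive multiple of 3"
            )
            continue
        if v.n_carriers == 1:
            out[v.sequence] = VariantClassification(
                SINGLETON, "present in a single individual"
            )
            continue
        if replicate_pairs:
            unverified_for = None
            for ind in v.per_individual_counts:
                partner = _replicate_partner(ind, replicate_pairs)
                if partner is not None and partner not in v.per_individual_counts:
                    unverified_for = (ind, partner)
                    break
            if unverified_for is not None:
                out[v.sequence] = VariantClassification(
                    UNVERIFIED,
                    f"absent from duplicate {unverified_for[1]} of carrier "
                    f"{unverified_for[0]}",
                )
                continue
        out[v.sequence] = VariantClassification(
            CANDIDATE, "passes no artifact rule but below the true-allele bar"
        )
    return out


def _parental_true_allele(
    v: Variant, true_seqs: Mapping[str, Variant]
) -> str | None:
    """True allele within Hamming distance 2 carried by *every* carrier of v."""
    for seq, tv in true_seqs.items():
        if not _hamming_leq(v.sequence, seq, 2) or seq == v.sequence:
            continue
        if all(ind in tv.per_individual_counts for ind in v.per_individual_counts):
            return seq
    return None


# ---------------------------------------------------------------------------
# genotype calls


def call_genotypes(
    variants: Sequence[Variant],
    classifications: Mapping[str, VariantClassification],
    min_depth: int = 150,
    mpaf_true_threshold: float = 0.04,
    populations: Mapping[str, str] | None = None,
    allele_names: Mapping[str, str] | None = None,
) -> tuple[list[MHCGenotypeCall], list[str]]:
    """Call per-individual allele sets from classified variants.

    Individuals with fewer than ``min_depth`` retained reads are
    DISCARDED_LOW_DEPTH; otherwise the call is the set of TRUE_ALLELE
    variants whose within-individual read proportion reaches the MPAF
    threshold.  ``allele_names`` (sequence -> id) names called alleles;
    unnamed true alleles get a stable ``Var###`` id.  Returns the call
    table and a log flagging individuals with < 2 or > 5 called alleles.
    """
    totals: dict[str, int] = {}
    for v in variants:
        for ind, c in v.per_individual_counts.items():
            totals[ind] = totals.get(ind, 0) + c
    names: dict[str, str] = dict(allele_names or {})
    counter = 0
    for v in variants:
        if classifications[v.sequence].label == TRUE_ALLELE and v.sequence not in names:
            counter += 1
            names[v.sequence] = f"Var{counter:03d}"

    calls: list[MHCGenotypeCall] = []
    log: list[str] = []
    for ind in sorted(totals):
        pop = populations.get(ind) if populations else None
        total = totals[ind]
        if total < min_depth:
            calls.append(MHCGenotypeCall(ind, pop, frozenset(), total,
                                         "DISCARDED_LOW_DEPTH"))
            continue
        alleles = set()
        for v in variants:
            if classifications[v.sequence].label != TRUE_ALLELE:
                continue
            c = v.per_individual_counts.get(ind, 0)
            if c / total >= mpaf_true_threshold:
                alleles.add(names[v.sequence])
        if not 2 <= len(alleles) <= 5:
            log.append(f"{ind}: {len(alleles)} alleles called (expected 2-5)")
        calls.append(MHCGenotypeCall(ind, pop, frozenset(alleles), total, "CALLED"))
    return calls, log


def implied_min_loci(calls: Iterable[MHCGenotypeCall] | Iterable[frozenset[str]]) -> int:
    """Minimum number of diploid loci implied by the largest allele set.

    An individual carrying ``m`` distinct co-amplifying alleles must have
    at least ``ceil(m / 2)`` loci (each diploid locus contributes at most
    two distinct alleles).
    """
    sizes = []
    for c in calls:
        sizes.append(len(c.alleles) if isinstance(c, MHCGenotypeCall) else len(c))
    if not sizes:
        raise ValueError("no calls supplied")
    return math.ceil(max(sizes) / 2)


def replicate_concordance(
    calls_run1: Mapping[str, frozenset[str] | set[str]],
    calls_run2: Mapping[str, frozenset[str] | set[str]],
) -> dict[str, int]:
    """Concordance of allele profiles between duplicate sequencing runs.

    complete = identical sets; partial = overlapping but unequal; zero =
    disjoint.  ``complete_pct`` is rounded half away from zero to an
    integer percentage.
    """
    ids1, ids2 = set(calls_run1), set(calls_run2)
    if ids1 != ids2:
        raise ValueError(
            f"mismatched individual ids: only in run1 {sorted(ids1 - ids2)}, "
            f"only in run2 {sorted(ids2 - ids1)}"
        )
    complete = partial = zero = 0
    for ind in ids1:
        a, b = set(calls_run1[ind]), set(calls_run2[ind])
        if a == b:
            complete += 1
        elif a & b:
            partial += 1
        else:
            zero += 1
    n = len(ids1)
    pct = math.floor(100 * complete / n + 0.5) if n else 0
    return {
        "n_pairs": n,
        "complete_matches": complete,
        "partial_matches": partial,
        "zero_matches": zero,
        "complete_pct": pct,
    }


# ---------------------------------------------------------------------------
# tabular output


def variants_to_frame(
    variants: Sequence[Variant],
    classifications: Mapping[str, VariantClassification] | None = None,
) -> pd.DataFrame:
    import json as _json

    rows = []
    for v in variants:
        row = {
            "sequence": v.sequence,
            "mpaf": v.mpaf,
            "n_carriers": v.n_carriers,
            "total_reads": sum(v.per_individual_counts.values()),
            "per_individual_counts": _json.dumps(v.per_individual_counts,
                                                 sort_keys=True),
        }
        if classifications is not None:
            cl = classifications[v.sequence]
            row["label"] = cl.label
            row["evidence"] = cl.evidence
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[MHCGenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": [c.individual for c in calls],
            "population": [c.population for c in calls],
            "alleles": [";".join(sorted(c.alleles)) for c in calls],
            "depth": [c.total_retained_reads for c in calls],
            "status": [c.status for c in calls],
        }
    )
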