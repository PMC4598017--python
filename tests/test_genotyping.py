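"""Amplicon genotyper: demultiplexing, MPAF, the decision ladder, calls."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mhcpop import genotyping as gt
from mhcpop.genotyping import (
    CANDIDATE,
    ONE_TWO_BP_ARTIFACT,
    SINGLETON,
    STOP_CODON,
    TRUE_ALLELE,
    BELOW_FLOOR,
    TagScheme,
    Variant,
    call_genotypes,
    classify_variants,
    demultiplex,
    implied_min_loci,
    replicate_concordance,
    tabulate_variants,
    translate_and_flag,
)
from mhcpop.simulate import revcomp


def make_scheme():
    return TagScheme(
        forward_mids=["ACGTACGTAC", "TGCATGCATG"],
        reverse_mids=["GGTTCCAAGG", "AACCGGTTAA"],
        forward_primer="TCAATGGGAC",
        reverse_primer="CCGCTGCACA",
        assignment={
            ("ACGTACGTAC", "GGTTCCAAGG"): "i1",
            ("TGCATGCATG", "GGTTCCAAGG"): "i2",
        },
    )


def build_read(scheme, insert, fwd="ACGTACGTAC", rev="GGTTCCAAGG"):
    return (
        fwd + scheme.forward_primer + insert
        + revcomp(scheme.reverse_primer) + revcomp(rev)
    )


INSERT = ("ACGT" * 50)[:185]


class TestDemultiplex:
    def test_clean_read_retained_and_assigned(self):
        scheme = make_scheme()
        inserts, discards = demultiplex(
            [("r1", build_read(scheme, INSERT))], scheme, 185
        )
        assert inserts == {"i1": [INSERT]}
        assert discards == []

    def test_ambiguous_base_discarded(self):
        scheme = make_scheme()
        bad = INSERT[:90] + "N" + INSERT[91:]
        _, discards = demultiplex([("r1", build_read(scheme, bad))], scheme, 185)
        assert discards == [("r1", gt.REASON_AMBIGUOUS)]

    def test_wrong_length_discarded(self):
        scheme = make_scheme()
        _, discards = demultiplex(
            [("r1", build_read(scheme, INSERT[:184]))], scheme, 185
        )
        assert discards == [("r1", gt.REASON_LENGTH)]

    def test_broken_primer_discarded(self):
        scheme = make_scheme()
        read = build_read(scheme, INSERT)
        read = read[:12] + ("A" if read[12] != "A" else "C") + read[13:]
        _, discards = demultiplex([("r1", read)], scheme, 185)
        assert discards == [("r1", gt.REASON_TAG_PRIMER)]

    def test_unassigned_pair_logged_not_fatal(self):
        scheme = make_scheme()
        read = build_read(scheme, INSERT, fwd="ACGTACGTAC", rev="AACCGGTTAA")
        inserts, discards = demultiplex([("r1", read)], scheme, 185)
        assert inserts == {}
        assert discards == [("r1", gt.REASON_UNASSIGNED)]

    def test_read_conservation(self, demo_reads, demo_scheme, demo_config):
        inserts, discards = demultiplex(
            demo_reads.reads, demo_scheme, demo_config.amplicon_length
        )
        retained = sum(len(v) for v in inserts.values())
        assert retained + len(discards) == len(demo_reads.reads)


class TestVariantTable:
    def test_single_variant_amplicon(self):
        (v,) = tabulate_variants({"i1": [INSERT] * 100})
        assert v.mpaf == 1.0 and v.n_carriers == 1

    def test_mpaf_is_max_over_carriers(self):
        # 15/300 in i1 vs 60/400 in i2 -> max(0.05, 0.15) = 0.15
        other1 = "A" * 185
        other2 = "C" * 185
        inserts = {
            "i1": [INSERT] * 15 + [other1] * 285,
            "i2": [INSERT] * 60 + [other2] * 340,
        }
        variants = {v.sequence: v for v in tabulate_variants(inserts)}
        assert variants[INSERT].mpaf == pytest.approx(0.15)
        assert variants[INSERT].n_carriers == 2

    def test_order_invariance(self):
        inserts = {"i1": [INSERT] * 5 + ["A" * 185] * 7}
        rev = {"i1": list(reversed(inserts["i1"]))}
        assert tabulate_variants(inserts) == tabulate_variants(rev)

    @given(st.integers(2, 6))
    @settings(max_examples=10, deadline=None)
    def test_mpaf_invariant_to_duplicating_reads(self, k):
        inserts = {"i1": [INSERT] * 3 + ["A" * 185] * 9}
        base = {v.sequence: v.mpaf for v in tabulate_variants(inserts)}
        dup = {v.sequence: v.mpaf
               for v in tabulate_variants({"i1": inserts["i1"] * k})}
        assert dup == base
        assert all(0 < m <= 1 for m in base.values())


class TestTranslation:
    def test_canonical_orf_terminal_stop(self):
        t = translate_and_flag("ATGAAATAG", 0)
        assert (t.protein, t.has_internal_stop, t.frame_ok) == ("MK*", False, True)

    def test_internal_stop(self):
        assert translate_and_flag("ATGTAAAAA", 0).has_internal_stop

    def test_amplicon_frame_two(self):
        t = translate_and_flag("G" * 185, 2)
        assert len(t.protein) == 61 and t.frame_ok

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            translate_and_flag("", 0)


def codon_clean(n):
    """n codons of GGG: always translatable, never a stop."""
    return "GGG" * n


class TestClassification:
    def test_true_allele_promotion(self):
        v = Variant(codon_clean(10), {f"i{k}": 20 for k in range(12)}, 0.05, 12)
        cls = classify_variants([v], frame_offset=0)
        assert cls[v.sequence].label == TRUE_ALLELE

    def test_one_two_bp_artifact_with_cooccurring_parent(self):
        parent = codon_clean(10)
        child = "A" + parent[1:]  # 1 substitution, AGG = Arg, no stop
        vp = Variant(parent, {"i1": 200, "i2": 150}, 0.5, 2)
        vc = Variant(child, {"i1": 8}, 0.02, 1)
        cls = classify_variants([vp, vc], frame_offset=0)
        assert cls[parent].label == TRUE_ALLELE
        assert cls[child].label == ONE_TWO_BP_ARTIFACT

    def test_stop_codon_label(self):
        seq = "TAA" + codon_clean(9)
        v = Variant(seq, {"i1": 8, "i2": 8}, 0.02, 2)
        cls = classify_variants([v], frame_offset=0)
        assert cls[seq].label == STOP_CODON

    def test_singleton_label(self):
        seq = "AAA" + codon_clean(9)
        v = Variant(seq, {"i1": 8}, 0.02, 1)
        cls = classify_variants([v], frame_offset=0)
        assert cls[seq].label == SINGLETON

    def test_below_floor_discarded(self):
        seq = codon_clean(10)
        v = Variant(seq, {"i1": 1}, 0.0005, 1)
        cls = classify_variants([v], frame_offset=0)
        assert cls[seq].label == BELOW_FLOOR

    def test_candidate_fallthrough(self):
        seq = "AAA" + codon_clean(9)
        v = Variant(seq, {"i1": 8, "i2": 9}, 0.02, 2)
        cls = classify_variants([v], frame_offset=0)
        assert cls[seq].label == CANDIDATE

    def test_replicate_confirmation_promotes_single_sample(self):
        seq = codon_clean(10)
        v = Variant(seq, {"s1a": 50, "s1b": 40}, 0.10, 2)
        # without replicate info two carriers already promote; with the pair
        # collapsed to one biological sample the promotion must still hold
        cls = classify_variants(
            [v], frame_offset=0, replicate_pairs=[("s1a", "s1b")]
        )
        assert cls[seq].label == TRUE_ALLELE

    def test_unverified_when_absent_from_duplicate(self):
        seq = "AAA" + codon_clean(9)
        v = Variant(seq, {"s1a": 8, "s2a": 9}, 0.02, 2)
        cls = classify_variants(
            [v], frame_offset=0,
            replicate_pairs=[("s1a", "s1b"), ("s2a", "s2b")],
        )
        assert cls[seq].label == gt.UNVERIFIED

    def test_known_allele_whitelisted(self):
        seq = codon_clean(10)
        v = Variant(seq, {"i1": 5}, 0.02, 1)
        cls = classify_variants(
            [v], frame_offset=0, known_alleles={"Gu01": seq}
        )
        assert cls[seq].label == TRUE_ALLELE

    def test_deterministic(self, demo_reads, demo_scheme, demo_config):
        inserts, _ = demultiplex(
            demo_reads.reads, demo_scheme, demo_config.amplicon_length
        )
        variants = tabulate_variants(inserts)
        c1 = classify_variants(variants, frame_offset=demo_config.frame_offset)
        c2 = classify_variants(variants, frame_offset=demo_config.frame_offset)
        assert c1 == c2


class TestCalls:
    def test_low_depth_discarded(self):
        v = Variant(codon_clean(10), {"i1": 93, "i2": 300}, 0.93, 2)
        cls = classify_variants([v], frame_offset=0)
        calls, _ = call_genotypes([v], cls, min_depth=150)
        status = {c.individual: c.status for c in calls}
        assert status == {"i1": "DISCARDED_LOW_DEPTH", "i2": "CALLED"}

    def test_noiseless_recovery_is_exact(self, noiseless_bundle):
        cfg, pool, truth, reads = noiseless_bundle
        scheme = TagScheme(reads.forward_mids, reads.reverse_mids,
                           cfg.forward_primer, cfg.reverse_primer,
                           reads.assignment)
        inserts, _ = demultiplex(reads.reads, scheme, cfg.amplicon_length)
        variants = tabulate_variants(inserts)
        cls = classify_variants(variants, frame_offset=cfg.frame_offset)
        calls, _ = call_genotypes(
            variants, cls, min_depth=150,
            allele_names={s: a for a, s in pool.sequences.items()},
        )
        called = [c for c in calls if c.status == "CALLED"]
        assert called
        for c in called:
            assert c.alleles == truth.mhc.allele_sets[c.individual]

    def test_implied_min_loci(self):
        sets = [frozenset("ab"), frozenset("abcde")]
        assert implied_min_loci(sets) == 3
        assert implied_min_loci([frozenset("ab")]) == 1


class TestConcordance:
    def test_survey_scale_example(self):
        run1, run2 = {}, {}
        for i in range(37):
            run1[f"s{i}"] = run2[f"s{i}"] = frozenset({"a", "b"})
        for i in range(37, 42):
            run1[f"s{i}"] = frozenset({"a", "b"})
            run2[f"s{i}"] = frozenset({"a", "c"})
        res = replicate_concordance(run1, run2)
        assert res == {
            "n_pairs": 42, "complete_matches": 37, "partial_matches": 5,
            "zero_matches": 0, "complete_pct": 88,
        }

    def test_identity_and_disjoint(self):
        run1 = {"s1": frozenset("ab"), "s2": frozenset("cd")}
        assert replicate_concordance(run1, run1)["complete_pct"] == 100
        run2 = {"s1": frozenset("xy"), "s2": frozenset("zw")}
        res = replicate_concordance(run1, run2)
        assert res["zero_matches"] == 2 and res["complete_pct"] == 0

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError, match="s2"):
            replicate_concordance({"s1": frozenset("ab")},
                                  {"s2": frozenset("ab")})
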