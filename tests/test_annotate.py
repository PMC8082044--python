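"""Variant atoms, the window rule, repair-mechanism taxonomy, summaries,
background subtraction, KL profiles and subsampling."""

import math

import numpy as np
import pytest

from crispamp.annotate import (Atom, ReadCall, background_subtract,
                               call_variants, classify_deletion_mmej,
                               classify_frameshift, classify_hdr_read,
                               classify_insertion, deletion_position,
                               equivalent_deletion_placements,
                               insertion_position, subsample_reads,
                               summarize_target, symmetric_kl)
from crispamp.psnw import ScoringScheme, psnw
from crispamp.simulate import apply_atoms


class TestPositions:
    def test_insertion_position_is_five_prime_base(self):
        # insertion between reference bases 116 and 117 -> position 116
        assert insertion_position(Atom("INS", 117, "GT")) == 116

    def test_deletion_position_closest_to_cut(self):
        # 5-bp deletion of [112,117) with cut bond 117: closest missing
        # base is 116
        atom = Atom("DEL", 112, "AAAAA")
        assert deletion_position(atom, (117,)) == 116

    def test_deletion_position_with_multiple_nicks(self):
        atom = Atom("DEL", 100, "ACGTACGT")   # [100,108)
        assert deletion_position(atom, (110, 105)) == 104


class TestCallVariants:
    SCHEME = ScoringScheme()

    def _call(self, query, ref, window, cuts):
        aln = psnw(query, ref, self.SCHEME)
        return call_variants(aln, query, ref, window, cuts)

    def test_two_bp_insertion_recovered(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        atom = Atom("INS", 117, "GT")
        query = apply_atoms(ref, [atom])
        call = self._call(query, ref, (109, 125), (117,))
        assert call.edited
        ins = [a for a in call.retained if a.kind == "INS"]
        assert len(ins) == 1
        recovered = ins[0]
        # the placement may slide inside a repeat but stays equivalent
        assert apply_atoms(ref, [recovered]) == query
        assert len(recovered.seq) == 2

    def test_snp_only_read_not_edited(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        query = ref[:117] + ("A" if ref[117] != "A" else "C") + ref[118:]
        call = self._call(query, ref, (109, 125), (117,))
        assert not call.edited
        assert len(call.snps) == 1 and call.snps[0].start == 117

    def test_out_of_window_indel_not_retained(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        atom = Atom("DEL", 10, ref[10:13])
        query = apply_atoms(ref, [atom])
        call = self._call(query, ref, (109, 125), (117,))
        assert not call.edited
        assert any(a.kind == "DEL" for a in call.atoms)

    def test_oracle_single_edit_recovery(self, rng):
        """Reads built by applying one known edit are recovered exactly
        (up to repeat-equivalence) whenever the edit is in the window."""
        for _ in range(40):
            ref = "".join(rng.choice(list("ACGT"), size=120))
            cut = 60
            if rng.random() < 0.5:
                L = int(rng.integers(1, 9))
                atom = Atom("INS", cut + int(rng.integers(-3, 4)),
                            "".join(rng.choice(list("ACGT"), size=L)))
            else:
                L = int(rng.integers(1, 12))
                start = cut - int(rng.integers(0, L + 1))
                atom = Atom("DEL", start, ref[start:start + L])
            query = apply_atoms(ref, [atom])
            call = self._call(query, ref, (cut - 8, cut + 8), (cut,))
            assert call.edited
            assert len(call.retained) == 1
            got = call.retained[0]
            assert got.kind == atom.kind and len(got.seq) == len(atom.seq)
            assert apply_atoms(ref, [got]) == query


class TestInsertionTaxonomy:
    def test_templated_five_prime_duplication(self):
        #            0123456789
        ref = "ACGATTCGGAATC"
        # insertion of "TTC" right after ...GATTC (bond 7)
        assert classify_insertion(Atom("INS", 7, "TTC"), ref) == "templated"

    def test_templated_three_prime_duplication(self):
        ref = "ACGATTCGGAATC"
        assert classify_insertion(Atom("INS", 7, "GGA"), ref) == "templated"

    def test_gc_requires_more_than_one_base(self):
        ref = "ACGATTATTAATC"
        assert classify_insertion(Atom("INS", 7, "GCG"), ref) == "gc"
        assert classify_insertion(Atom("INS", 7, "G"), ref) == "other"

    def test_templated_takes_precedence_over_gc(self):
        ref = "AAAGCGTTTCCC"
        # "GCG" duplicates the 5' flank exactly -> templated, not gc
        assert classify_insertion(Atom("INS", 6, "GCG"), ref) == "templated"

    def test_other(self):
        ref = "ACGATTATTAATC"
        assert classify_insertion(Atom("INS", 7, "CAT"), ref) == "other"


class TestMmej:
    def test_tandem_repeat_deletion_is_mmej(self):
        #      0123456789012345
        ref = "CATGGTCAGTCATTAA"
        # delete one GTCA copy
        atom = Atom("DEL", 4, "GTCA")
        assert classify_deletion_mmej(atom, ref)

    def test_one_bp_deletion_never_mmej(self):
        ref = "CATGGTCAGTCATTAA"
        assert not classify_deletion_mmej(Atom("DEL", 4, "G"), ref)

    def test_single_base_homology_not_mmej(self):
        # brute-force over all equivalent placements confirms max
        # homology 1 for this construction
        ref = "ACGTAGCCAT"
        atom = Atom("DEL", 3, "TAG")   # deleted TAG, flank right = CCAT
        for s in equivalent_deletion_placements(ref, 3, 3):
            deleted = ref[s:s + 3]
            right = ref[s + 3:]
            left = ref[:s]
            assert not (deleted[:2] == right[:2])
            assert not (deleted[-2:] == left[-2:])
        assert not classify_deletion_mmej(atom, ref)

    def test_equivalence_class_maximization(self):
        # a tandem ACG repeat: every equivalent placement of the deletion
        # exposes the same >=2 bp microhomology
        ref = "TTAACGACGAATT"
        # deleting [3,6) ("ACG") == deleting [6,9): tandem ACG repeat
        atom = Atom("DEL", 3, "ACG")
        assert classify_deletion_mmej(atom, ref)


class TestFrameshift:
    @pytest.mark.parametrize("net,expected", [
        (-2, True), (3, False), (0, False), (4, True), (-6, False),
        (3 + 4 - 1 - 3, False),   # 4-bp INS + 1-bp DEL + ... net 3
    ])
    def test_net_length_rule(self, net, expected):
        assert classify_frameshift(net) is expected

    def test_multi_atom_net(self):
        call = ReadCall([], [Atom("INS", 50, "ACGT"), Atom("DEL", 60, "A")],
                        [], 1)
        assert call.net_indel_length == 3
        assert not classify_frameshift(call.net_indel_length)


class TestHdrPathway:
    def test_wild_type_and_nhej(self):
        clean = ReadCall([], [], [], 1)
        edited = ReadCall([Atom("DEL", 50, "AC")], [Atom("DEL", 50, "AC")],
                          [], 1)
        assert classify_hdr_read(clean, "wild_type", None, (50,)) \
            == "wild_type"
        assert classify_hdr_read(edited, "wild_type", None, (50,)) == "NHEJ"

    def test_exact_hdr_read_is_perfect(self):
        call = ReadCall([], [], [], 1)
        assert classify_hdr_read(call, "hdr_hypothetical", (40, 70),
                                 (55,)) == "HDR_perfect"

    def test_snp_inside_span_is_imperfect(self):
        snp = Atom("SNP", 60, "A")
        call = ReadCall([snp], [], [snp], 1)
        assert classify_hdr_read(call, "hdr_hypothetical", (40, 70),
                                 (55,)) == "HDR_imperfect"

    def test_snp_outside_span_still_perfect(self):
        snp = Atom("SNP", 5, "A")
        call = ReadCall([snp], [], [snp], 1)
        assert classify_hdr_read(call, "hdr_hypothetical", (40, 70),
                                 (55,)) == "HDR_perfect"


class TestSummaries:
    def _mk_calls(self, n_wt, n_edit, ref):
        calls = [ReadCall([], [], [], n_wt, pathway="wild_type")]
        atom = Atom("DEL", 99, ref[99:101])
        calls.append(ReadCall([atom], [atom], [], n_edit, pathway="NHEJ"))
        return calls

    def test_pct_indels(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        s = summarize_target("t", self._mk_calls(2000, 2000, ref), ref,
                             (100,), 100)
        assert s.pct_indels == 50.0

    def test_templated_fraction_of_insertions(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        calls = []
        for i in range(10):
            if i < 4:
                ins = ref[96:100]        # 5' duplication -> templated
            else:
                ins = "ATAT"
                if ref[96:100] == ins or ref[100:104] == ins:
                    ins = "TATA"
            atom = Atom("INS", 100, ins)
            calls.append(ReadCall([atom], [atom], [], 1, pathway="NHEJ"))
        s = summarize_target("t", calls, ref, (100,), 100)
        assert s.n_insertions == 10
        assert s.pct_templated_of_insertions == pytest.approx(40.0)

    def test_pathway_fractions_sum_to_one(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        s = summarize_target("t", self._mk_calls(3, 5, ref), ref, (100,),
                             100)
        assert sum(s.pathway_fractions.values()) == pytest.approx(1.0)

    def test_zero_reads_reports_no_data(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        s = summarize_target("t", [], ref, (100,), 100)
        assert s.no_data


class TestBackgroundSubtraction:
    def _summary(self, pct):
        from crispamp.annotate import TargetSummary
        s = TargetSummary("t")
        s.total_reads = 1000
        s.edited_reads = int(round(10 * pct))
        return s

    def test_simple_subtraction(self):
        assert background_subtract(self._summary(5.0), self._summary(0.3)) \
            == pytest.approx(4.7)

    def test_floored_at_zero(self):
        assert background_subtract(self._summary(0.2),
                                   self._summary(0.4)) == 0.0

    def test_equal_gives_zero(self):
        assert background_subtract(self._summary(1.0),
                                   self._summary(1.0)) == 0.0

    def test_missing_control_warns(self):
        t = self._summary(5.0)
        assert background_subtract(t, None) == pytest.approx(5.0)
        assert t.warn_no_control


class TestSymmetricKl:
    def test_identity_is_zero(self):
        assert symmetric_kl([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) \
            == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # direct summation of p*ln(p/q) in both directions with
        # pseudocount 1e-6 on the zero bin
        assert symmetric_kl([1.0, 0.0], [0.5, 0.5]) \
            == pytest.approx(6.907741463485395, rel=1e-9)

    def test_symmetry(self, rng):
        p = rng.random(8)
        q = rng.random(8)
        assert symmetric_kl(p, q) == pytest.approx(symmetric_kl(q, p))

    def test_dict_profiles(self):
        assert symmetric_kl({"a": 1.0}, {"a": 1.0}) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            symmetric_kl([], [])


class TestSubsampling:
    def test_full_sample_is_identity(self):
        items = list(range(100))
        assert sorted(subsample_reads(items, 100, 1)) == items

    def test_seed_reproducibility(self):
        items = list(range(1000))
        assert subsample_reads(items, 50, 7) == subsample_reads(items, 50, 7)
        assert subsample_reads(items, 50, 7) != subsample_reads(items, 50, 8)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_reads([1, 2, 3], 4, 0)

    def test_unbiased_recovery_of_pool_fraction(self):
        # 0.5%-edited pool: repeated subsampling recovers ~0.5% on average
        pool = [1] * 100 + [0] * 19900
        fracs = [np.mean(subsample_reads(pool, 1000, seed))
                 for seed in range(40)]
        assert np.mean(fracs) == pytest.approx(0.005, abs=0.001)
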