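"""Position-specific NW aligner vs an exhaustive enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crispamp.errors import OracleBoundError, SequenceTooLongError
from crispamp.psnw import (Alignment, BonusProfile, BonusVector,
                           ScoringScheme, build_bonus_vector,
                           enumerate_optimal_alignments, psnw)
from crispamp.targets import make_target

SCHEME = ScoringScheme()


def plain_score(cols, q, r, scheme=SCHEME):
    """Independent column-walk scorer used to grade oracle alignments."""
    base, prev, i, j = 0, None, 0, 0
    for op in cols:
        if op in "MX":
            base += scheme.match if (q[i] == r[j] and q[i] != "N") \
                else -scheme.mismatch
            i += 1
            j += 1
        elif op == "D":
            base -= scheme.gap_extend if prev == "D" else scheme.gap_open
            j += 1
        else:
            base -= scheme.gap_extend if prev == "I" else scheme.gap_open
            i += 1
        prev = op
    return base


def bonus_of(cols, bonus):
    """Total bonus collected by a column string."""
    total, prev, j = 0, None, 0
    n = len(bonus.extend_bonus)
    for op in cols:
        if op in "MX":
            j += 1
        elif op == "D":
            total += (bonus.extend_bonus[j] if prev == "D"
                      else bonus.open_bonus[j])
            j += 1
        else:
            total += (bonus.extend_bonus[min(j, n - 1)] if prev == "I"
                      else bonus.open_bonus[j])
        prev = op
    return int(total)


class TestPsnwBasics:
    def test_identity(self):
        aln = psnw("ACGTACGT", "ACGTACGT", SCHEME)
        assert aln.ops == (("M", 8),)
        assert aln.base_score == 8 * SCHEME.match
        assert aln.bonus_score == 0

    def test_n_scored_as_mismatch(self):
        aln = psnw("ACNT", "ACGT", SCHEME)
        assert aln.columns() == "MMXM"
        assert aln.base_score == 3 * SCHEME.match - SCHEME.mismatch

    def test_homopolymer_deletion_leftmost_without_bonus(self):
        # one T deleted from a 4-T run: all placements are co-optimal;
        # the zero-bonus tie-break is the leftmost placement
        aln = psnw("AAAATTTAAAA", "AAAATTTTAAAA", SCHEME)
        assert aln.columns() == "MMMM" + "D" + "MMM" + "MMMM"

    def test_bonus_pulls_deletion_to_cut_bond(self):
        # the repeat-region scenario: a bonus at bond 6 selects the
        # placement overlapping the cut instead of the leftmost one
        ref = "AAAATTTTAAAA"
        ob = np.zeros(len(ref) + 1, dtype=int)
        ob[6] = 50
        bv = BonusVector(ob, np.zeros(len(ref), dtype=int))
        plain = psnw("AAAATTTAAAA", ref, SCHEME)
        boosted = psnw("AAAATTTAAAA", ref, SCHEME, bv)
        assert plain.base_score == boosted.base_score
        assert boosted.columns() == "MMMMMM" + "D" + "MMMMM"
        assert boosted.bonus_score == 50

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            psnw("", "ACGT")

    def test_length_guard(self):
        with pytest.raises(SequenceTooLongError):
            psnw("A" * 100, "C" * 100, max_cells=100)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=0)
        with pytest.raises(ValueError):
            ScoringScheme(scalar=0)

    def test_bonus_must_stay_below_scalar(self):
        ob = np.zeros(5, dtype=int)
        ob[2] = SCHEME.scalar + 1
        bv = BonusVector(ob, np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            psnw("ACGT", "ACGT", SCHEME, bv)


class TestEnumerationOracle:
    def test_unique_alignment_without_repeats(self):
        assert enumerate_optimal_alignments("ACGT", "ACGT") == {"MMMM"}

    def test_homopolymer_deletion_has_four_placements(self):
        opts = enumerate_optimal_alignments("AAA", "AAAA")
        assert len(opts) == 4
        assert opts == {"DMMM", "MDMM", "MMDM", "MMMD"}

    def test_bound(self):
        with pytest.raises(OracleBoundError):
            enumerate_optimal_alignments("A" * 100, "C" * 100)


def _random_pair(rng, max_len=12):
    m = int(rng.integers(1, max_len + 1))
    n = int(rng.integers(1, max_len + 1))
    return ("".join(rng.choice(list("ACGT"), size=m)),
            "".join(rng.choice(list("ACGT"), size=n)))


class TestOracleAgreement:
    def test_base_score_equals_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            q, r = _random_pair(rng)
            opts = enumerate_optimal_alignments(q, r)
            best = max(plain_score(c, q, r) for c in opts)
            aln = psnw(q, r, SCHEME)
            assert aln.base_score == best
            assert aln.columns() in opts

    def test_bonus_maximal_among_co_optimals(self):
        rng = np.random.default_rng(8)
        for _ in range(120):
            q, r = _random_pair(rng, max_len=9)
            ob = rng.integers(0, 40, size=len(r) + 1)
            eb = rng.integers(0, 10, size=len(r))
            bv = BonusVector(ob, eb)
            opts = enumerate_optimal_alignments(q, r)
            aln = psnw(q, r, SCHEME, bv)
            assert aln.columns() in opts
            assert aln.bonus_score == max(bonus_of(c, bv) for c in opts)

    def test_reflection(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            q, r = _random_pair(rng)
            fwd = psnw(q, r, SCHEME)
            rev = psnw(q[::-1], r[::-1], SCHEME)
            assert fwd.base_score == rev.base_score

    @given(st.text(alphabet="ACGT", min_size=1, max_size=10),
           st.text(alphabet="ACGT", min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_score_consistency_property(self, q, r):
        """Reported scores always re-derive from the returned columns."""
        aln = psnw(q, r, SCHEME)
        assert plain_score(aln.columns(), q, r) == aln.base_score
        n_q = sum(ln for op, ln in aln.ops if op in "MXI")
        n_r = sum(ln for op, ln in aln.ops if op in "MXD")
        assert n_q == len(q) and n_r == len(r)


class TestBonusVector:
    def test_cas9_shape(self, cas9_target):
        bv = build_bonus_vector(cas9_target)
        c = cas9_target.primary_cut_bond
        ob = bv.open_bonus
        assert ob[c] == ob.max()
        assert ob[c - 2] > ob[c - 3] >= ob[c + 1]
        span = set(range(c - 20, c + 21))
        inside = [ob[k] for k in span if k not in
                  {c, c - 2, c - 3, c + 1}]
        assert all(0 < v < ob[c - 3] + 1 for v in inside)
        outside = [ob[k] for k in range(len(ob)) if k not in span]
        assert all(v == 0 for v in outside)

    def test_cas12a_nick_region_nonzero(self):
        proto = "ACGTACGTTGCAGGCATCATG"
        ref = ("GCATCGTACGATCGGATCCAGTCAGGCATGCCATGCAATTGCCATGCATCGA"
               "GCTTAAGCCGGTATCCAGTCAGGCA")
        ref = ref[:30] + "TTTA" + proto + ref[30:]
        t = make_target("c12", ref, proto, enzyme="cas12a")
        bv = build_bonus_vector(t)
        distal = t.primary_cut_bond
        proximal = [b for b in t.cut_bonds if b != distal]
        # non-zero from 5 bonds 5' of the proximal nick to 4 bonds 3' of
        # the distal nick
        for k in range(min(proximal) - 5, distal + 5):
            assert bv.open_bonus[k] > 0
        assert bv.open_bonus[distal] == bv.open_bonus.max()

    def test_clipping_near_amplicon_edge(self, rng):
        proto = "ACGTACGTTGCAGGCATCAT"
        ref = proto + "TGG" + "".join(rng.choice(list("ACGT"), size=180))
        t = make_target("edge", ref, proto)
        bv = build_bonus_vector(t)   # span extends past position 0
        assert len(bv.open_bonus) == len(ref) + 1
        assert bv.open_bonus[0] >= 0

    def test_tsv_round_trip(self, cas9_target, tmp_path):
        bv = build_bonus_vector(cas9_target)
        path = tmp_path / "bonus.tsv"
        bv.to_tsv(path)
        back = BonusVector.from_tsv(path)
        assert (back.open_bonus == bv.open_bonus).all()
        assert (back.extend_bonus == bv.extend_bonus).all()

    def test_monotone_shift_toward_boosted_bond(self):
        """Raising the bonus at a bond never moves a co-optimal gap off it."""
        # the deleted T can equivalently sit at bonds 3..7 (the T run)
        ref = "ACGTTTTTACGT"
        q = "ACGTTTTACGT"
        for b in range(3, 8):
            ob = np.zeros(len(ref) + 1, dtype=int)
            ob[b] = 30
            aln = psnw(q, ref, SCHEME, BonusVector(ob, np.zeros(len(ref),
                                                               dtype=int)))
            dels = [j for j, op in enumerate(_ref_ops(aln)) if op == "D"]
            assert dels == [b]


def _ref_ops(aln: Alignment):
    """Per-reference-position op letters."""
    out = []
    for op, ln in aln.ops:
        if op in "MXD":
            out.extend([op] * ln)
    return out
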