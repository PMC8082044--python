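"""HDR donor handling: reconstruct the theoretical perfect-HDR amplicon.

A dsDNA donor (homology arms around a payload) is aligned to every
candidate amplicon with a high gap-open, zero gap-extension scheme
(match +2, mismatch -1, open -30, extend 0) so the payload costs a single
gap open however long it is.  The best-scoring amplicon (both donor
orientations are tried) is chosen and the hypothetical perfect-HDR sequence
is the amplicon with the donor substituted between the matched arms.
Adding this sequence to the mappable reference set turns HDR-vs-NHEJ
pathway binning into a read-assignment decision.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .errors import DonorMismatchError
from .targets import AmpliconTarget, revcomp


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -1
    al.open_gap_score = -30
    al.extend_gap_score = 0
    return al


@dataclass(frozen=True)
class IntendedEdit:
    """The net donor-encoded change on wild-type coordinates."""

    ref_span: tuple[int, int]      # replaced wild-type interval (half-open)
    alt: str                       # replacement sequence (may be empty)

    @property
    def net_length(self) -> int:
        return len(self.alt) - (self.ref_span[1] - self.ref_span[0])

    @property
    def kind(self) -> str:
        d = self.net_length
        if d > 0:
            return "insertion"
        if d < 0:
            return "deletion"
        return "substitution"


@dataclass(frozen=True)
class HdrReference:
    """The hypothetical perfect-HDR amplicon with mapped annotations."""

    seq: str
    target_id: str
    edit_span: tuple[int, int]         # altered interval on HDR coordinates
    intended_edit: IntendedEdit
    cut_bonds: tuple[int, ...]         # wild-type cut bonds mapped to HDR
    primary_cut_bond: int
    window: tuple[int, int]            # variant window mapped to HDR coords
    inspection_span: tuple[int, int]   # hull of window and edit span


def _diff(wt: str, hyp: str) -> tuple[int, int]:
    """(lcp, lcs) of two strings with lcp+lcs <= min length."""
    lcp = 0
    n = min(len(wt), len(hyp))
    while lcp < n and wt[lcp] == hyp[lcp]:
        lcp += 1
    lcs = 0
    while lcs < n - lcp and wt[len(wt) - 1 - lcs] == hyp[len(hyp) - 1 - lcs]:
        lcs += 1
    return lcp, lcs


def _map_coord(pos: int, lcp: int, wt_len: int, lcs: int,
               delta: int) -> int:
    """Map a wild-type bond/position onto HDR coordinates."""
    if pos <= lcp:
        return pos
    if pos >= wt_len - lcs:
        return pos + delta
    return lcp  # inside the replaced region: clamp to its left edge


def apply_edit(wt: str, edit: IntendedEdit) -> str:
    s, e = edit.ref_span
    return wt[:s] + edit.alt + wt[e:]


def reconstruct_perfect_hdr(donor_seq: str, targets: list[AmpliconTarget],
                            min_arm_identity: float = 0.8,
                            arm_probe: int = 15
                            ) -> tuple[HdrReference, AmpliconTarget]:
    """Choose the donor's target and build its perfect-HDR reference.

    Both donor orientations are aligned to every candidate amplicon and the
    best score wins.  The donor's outer ``arm_probe`` bases on each side
    must align with identity >= ``min_arm_identity`` (contiguous-arm check).
    """
    donor_seq = donor_seq.upper()
    al = _aligner()
    best = None
    for target in targets:
        for donor in (donor_seq, revcomp(donor_seq)):
            aln = al.align(donor, target.ref_seq)[0]
            if best is None or aln.score > best[0]:
                best = (aln.score, aln, donor, target)
    _score, aln, donor, target = best
    wt = target.ref_seq

    # The high-open / zero-extend scheme leaves many co-optimal traces
    # (a trailing gap is free wherever it sits), so the chosen trace cannot
    # be trusted for reconstruction.  Anchor the homology arms instead:
    # the longest donor prefix and suffix occurring exactly in the amplicon
    # delimit the replaced interval.
    def _max_prefix() -> tuple[int, int]:
        best_k, best_a = 0, -1
        for k in range(arm_probe, len(donor) + 1):
            a = wt.find(donor[:k])
            if a < 0:
                break
            best_k, best_a = k, a
        return best_k, best_a

    k1, a = _max_prefix()
    if k1 < arm_probe:
        raise DonorMismatchError("donor does not match target: 5' homology "
                                 "arm not found")
    k2, b_end = 0, -1
    for k in range(arm_probe, len(donor) + 1):
        p = wt.find(donor[len(donor) - k:], a)
        if p < 0:
            break
        k2, b_end = k, p + k
    if k2 < arm_probe:
        raise DonorMismatchError("donor does not match target: 3' homology "
                                 "arm not found downstream of the 5' arm")
    if min(k1, k2) / arm_probe < min_arm_identity:
        raise DonorMismatchError("donor does not match target: homology arm "
                                 "identity below floor")

    hyp = wt[:a] + donor + wt[b_end:]
    lcp, lcs = _diff(wt, hyp)
    delta = len(hyp) - len(wt)
    edit = IntendedEdit((lcp, len(wt) - lcs), hyp[lcp:len(hyp) - lcs])
    edit_span = (lcp, len(hyp) - lcs)

    bonds = tuple(_map_coord(b, lcp, len(wt), lcs, delta)
                  for b in target.cut_bonds)
    primary = _map_coord(target.primary_cut_bond, lcp, len(wt), lcs, delta)
    # the window keeps its half-width, centered on the mapped cut
    half = (target.window[1] - target.window[0]) // 2
    center_wt = (target.window[0] + target.window[1]) // 2
    center = _map_coord(center_wt, lcp, len(wt), lcs, delta)
    window = (max(0, center - half), min(len(hyp), center + half))
    inspection = (min(window[0], edit_span[0]),
                  max(window[1], edit_span[1]))
    ref = HdrReference(hyp, target.target_id, edit_span, edit, bonds,
                       primary, window, inspection)
    return ref, target
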