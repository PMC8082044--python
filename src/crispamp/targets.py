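"""Target model: amplicons, guides, enzyme cut geometry and variant windows.

An :class:`AmpliconTarget` ties together a reference amplicon, the located
guide (protospacer + PAM), the enzyme-specific cut/nick bonds, and the
variant-detection window.  All coordinates are 0-based, half-open; cut sites
are *bond* indices, where bond ``k`` is the junction between reference
positions ``k-1`` and ``k`` (so valid bonds run from 0 to ``len(ref)``).

Enzyme geometry
---------------
Cas9 makes a blunt cut 3 bp from the PAM-proximal (3') end of the
protospacer.  Cas12a nicks twice, producing a staggered cut: by default the
PAM-distal nick sits 23 bonds from the protospacer 5' start and two
PAM-proximal nick positions at 18 and 19 bonds are considered (5 bp and 4 bp
overhangs).  The variant window is centered on the primary cut bond
(Cas9: the blunt cut, half-width 8; Cas12a: the PAM-distal nick shifted
3 bp toward the guide 5' end, half-width 9).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import (
    AmbiguousGuideError,
    CutSiteOutsideAmpliconError,
    GuideNotFoundError,
    TargetFileError,
    UnpairedGuideError,
)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

# IUPAC code -> set of concrete bases it matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_match(pattern: str, text: str) -> bool:
    if len(pattern) != len(text):
        return False
    return all(t in IUPAC.get(p, "") for p, t in zip(pattern, text))


@dataclass(frozen=True)
class EnzymeModel:
    """Cut geometry and default window for one nuclease.

    ``cut_offsets`` are bond indices measured from the PAM-proximal end of
    the protospacer, walking toward the PAM-distal end.  ``primary_cut``
    indexes the offset that anchors the scoring vector and the window.
    ``window_center_shift`` is signed along the guide 5'->3' orientation.
    """

    name: str
    pam: str
    pam_side: str                 # "three_prime" (Cas9) or "five_prime" (Cas12a)
    cut_offsets: tuple[int, ...]
    primary_cut: int
    window_half_width: int
    window_center_shift: int

    def __post_init__(self):
        if self.window_half_width <= 0:
            raise ValueError("window_half_width must be > 0")
        if self.name == "cas9" and len(self.cut_offsets) != 1:
            raise ValueError("cas9 has exactly one cut offset")
        if self.name == "cas12a" and len(self.cut_offsets) < 2:
            raise ValueError("cas12a needs a distal offset and >=1 proximal offsets")

    def bonds_in_guide_coords(self, protospacer_len: int) -> list[int]:
        """Cut bonds measured from the protospacer 5' start along the guide."""
        if self.pam_side == "three_prime":
            # PAM-proximal end is the 3' end of the protospacer
            return [protospacer_len - off for off in self.cut_offsets]
        # Cas12a: PAM-proximal end is the 5' start
        return list(self.cut_offsets)


CAS9 = EnzymeModel("cas9", "NGG", "three_prime", (3,), 0, 8, 0)
# distal nick at 23 from the 5' start; proximal nicks 18/19 -> 5 bp / 4 bp overhangs
CAS12A = EnzymeModel("cas12a", "TTTV", "five_prime", (23, 18, 19), 0, 9, -3)

ENZYMES = {"cas9": CAS9, "cas12a": CAS12A}


@dataclass(frozen=True)
class GuideSpec:
    protospacer: str
    enzyme: EnzymeModel
    pam: str | None = None        # defaults to the enzyme's canonical PAM

    def __post_init__(self):
        if len(self.protospacer) < 15:
            raise ValueError("protospacer length must be >= 15")
        for ch in self.protospacer + (self.pam or ""):
            if ch.upper() not in IUPAC:
                raise ValueError(f"non-IUPAC character {ch!r}")
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        if self.pam is not None:
            object.__setattr__(self, "pam", self.pam.upper())

    @property
    def pam_pattern(self) -> str:
        return self.pam if self.pam is not None else self.enzyme.pam


@dataclass(frozen=True)
class AmpliconTarget:
    """One reference amplicon with located guide, cut bonds and window."""

    target_id: str
    ref_seq: str
    guide: GuideSpec
    guide_start: int
    guide_strand: str
    cut_bonds: tuple[int, ...]          # reference bond coordinates
    primary_cut_bond: int
    window: tuple[int, int]             # half-open interval of positions
    donor_seq: str | None = None

    @property
    def enzyme(self) -> EnzymeModel:
        return self.guide.enzyme


def locate_guide(ref_seq: str, guide: GuideSpec,
                 mismatch_budget: int = 0) -> tuple[int, str]:
    """Find the unique best PAM-adjacent protospacer placement.

    Returns ``(guide_start, strand)`` with ``guide_start`` the 0-based start
    of the protospacer on ``ref_seq``.  Both strands are scanned; among
    PAM-compatible placements the one with the fewest protospacer mismatches
    wins.  A tie raises :class:`AmbiguousGuideError`.
    """
    ref = ref_seq.upper()
    proto = guide.protospacer
    pam = guide.pam_pattern
    P, Q = len(proto), len(pam)
    if len(ref) < P + Q:
        raise GuideNotFoundError("reference shorter than protospacer+PAM")

    def scan(strand_seq: str):
        hits = []
        L = len(strand_seq)
        for s in range(0, L - P + 1):
            if guide.enzyme.pam_side == "three_prime":
                p0, p1 = s + P, s + P + Q
            else:
                p0, p1 = s - Q, s
            if p0 < 0 or p1 > L:
                continue
            if not _iupac_match(pam, strand_seq[p0:p1]):
                continue
            mm = sum(1 for a, b in zip(proto, strand_seq[s:s + P])
                     if b not in IUPAC.get(a, ""))
            if mm <= mismatch_budget:
                hits.append((mm, s))
        return hits

    rc = revcomp(ref)
    candidates = [(mm, s, "+") for mm, s in scan(ref)]
    # a hit at s on the reverse complement occupies ref[L-s-P, L-s)
    candidates += [(mm, len(ref) - s - P, "-") for mm, s in scan(rc)]
    if not candidates:
        raise GuideNotFoundError(
            f"guide not found within {mismatch_budget} mismatches")
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best = [c for c in candidates if c[0] == candidates[0][0]]
    if len(best) > 1:
        raise AmbiguousGuideError(
            f"ambiguous guide placement: {len(best)} equally good sites")
    _, start, strand = best[0]
    return start, strand


def compute_cut_bonds(ref_len: int, guide: GuideSpec, guide_start: int,
                      guide_strand: str) -> tuple[list[int], int]:
    """Map enzyme cut offsets onto reference bond coordinates.

    Returns ``(bonds, primary_bond)``.  For a minus-strand guide the bond
    coordinates are mirrored (bond g along the guide maps to
    ``guide_end - g``).
    """
    P = len(guide.protospacer)
    gbonds = guide.enzyme.bonds_in_guide_coords(P)
    if guide_strand == "+":
        bonds = [guide_start + g for g in gbonds]
    else:
        bonds = [guide_start + P - g for g in gbonds]
    for b in bonds:
        if not (0 < b < ref_len):
            raise CutSiteOutsideAmpliconError(
                f"cut site bond {b} outside amplicon of length {ref_len}")
    return bonds, bonds[guide.enzyme.primary_cut]


def compute_window(ref_len: int, guide: GuideSpec, primary_cut_bond: int,
                   guide_strand: str,
                   window_half_width: int | None = None) -> tuple[int, int]:
    """Half-open interval of reference positions eligible for variant starts.

    The window is centered on the primary cut bond, shifted by the enzyme's
    ``window_center_shift`` along the guide orientation, and clipped to the
    amplicon.  A position ``p`` is in the window iff
    ``center - w <= p < center + w``.
    """
    w = window_half_width if window_half_width is not None \
        else guide.enzyme.window_half_width
    shift = guide.enzyme.window_center_shift
    center = primary_cut_bond + (shift if guide_strand == "+" else -shift)
    return max(0, center - w), min(ref_len, center + w)


def make_target(target_id: str, ref_seq: str, protospacer: str,
                enzyme: str | EnzymeModel = CAS9, pam: str | None = None,
                donor_seq: str | None = None, mismatch_budget: int = 0,
                window_half_width: int | None = None) -> AmpliconTarget:
    """Locate the guide and assemble a fully annotated target."""
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme.lower()]
    guide = GuideSpec(protospacer, enzyme, pam)
    ref = ref_seq.upper()
    start, strand = locate_guide(ref, guide, mismatch_budget)
    bonds, primary = compute_cut_bonds(len(ref), guide, start, strand)
    window = compute_window(len(ref), guide, primary, strand,
                            window_half_width)
    return AmpliconTarget(target_id, ref, guide, start, strand,
                          tuple(bonds), primary, window, donor_seq)


def with_window(target: AmpliconTarget, half_width: int) -> AmpliconTarget:
    """Copy of ``target`` with the window recomputed at ``half_width``."""
    window = compute_window(len(target.ref_seq), target.guide,
                            target.primary_cut_bond, target.guide_strand,
                            half_width)
    return replace(target, window=window)


# ---------------------------------------------------------------------------
# file ingestion


def load_manifest(path: str | Path, enzyme: str | None = None,
                  **kwargs) -> list[AmpliconTarget]:
    """Load targets from a CSV manifest.

    Columns: ``target_id, amplicon_seq, guide_seq`` and optionally
    ``pam, enzyme, donor_seq``.  ``enzyme`` given here overrides the column.
    """
    targets = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"target_id", "amplicon_seq", "guide_seq"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TargetFileError(f"manifest {path} missing columns "
                                  f"{sorted(required)}")
        for i, row in enumerate(reader, start=2):
            enz = enzyme or row.get("enzyme") or "cas9"
            donor = row.get("donor_seq") or None
            try:
                targets.append(make_target(
                    row["target_id"], row["amplicon_seq"], row["guide_seq"],
                    enzyme=enz, pam=row.get("pam") or None,
                    donor_seq=donor, **kwargs))
            except (KeyError, ValueError) as exc:
                raise TargetFileError(f"{path} line {i}: {exc}") from exc
    return targets


def load_targets(genome_fasta: str | Path, bed6: str | Path,
                 enzyme: str | EnzymeModel = CAS9,
                 **kwargs) -> list[AmpliconTarget]:
    """Build targets from a genome FASTA and a 6-column BED.

    The BED mixes amplicon and guide intervals; an interval strictly
    contained in another interval on the same contig is treated as a guide
    and paired with its containing amplicon.  Sequences are extracted
    strand-aware (a minus-strand amplicon is reverse-complemented, and
    coordinates are mapped accordingly).
    """
    import pyfaidx

    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme.lower()]
    rows = []
    with open(bed6) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise TargetFileError(f"{bed6} line {ln}: expected 6 columns, "
                                      f"got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise TargetFileError(f"{bed6} line {ln}: non-integer "
                                      f"coordinates") from exc
            if end <= start:
                raise TargetFileError(f"{bed6} line {ln}: end <= start")
            if strand not in "+-":
                raise TargetFileError(f"{bed6} line {ln}: bad strand "
                                      f"{strand!r}")
            rows.append((chrom, start, end, name, strand, ln))

    # classify: guides are intervals properly contained in a larger
    # interval, or guide-sized intervals (<= 35 bp) even when orphaned
    amplicons, guides = [], []
    for r in rows:
        container = any(o is not r and o[0] == r[0]
                        and o[1] <= r[1] and r[2] <= o[2]
                        and (o[2] - o[1]) > (r[2] - r[1]) for o in rows)
        (guides if container or (r[2] - r[1]) <= 35 else
         amplicons).append(r)

    fasta = pyfaidx.Fasta(str(genome_fasta))
    targets = []
    for g in guides:
        parents = [a for a in amplicons if a[0] == g[0]
                   and a[1] <= g[1] and g[2] <= a[2]]
        if not parents:
            raise UnpairedGuideError(
                f"{bed6} line {g[5]}: guide {g[3]} not contained in any "
                f"amplicon")
        amp = parents[0]
        amp_seq = str(fasta[amp[0]][amp[1]:amp[2]])
        guide_seq = str(fasta[g[0]][g[1]:g[2]])
        if amp[4] == "-":
            amp_seq = revcomp(amp_seq)
        # orientation of the guide relative to the extracted amplicon is
        # re-derived by locate_guide; supply the plus-strand genomic guide
        # sequence oriented along its own BED strand
        if g[4] == "-":
            guide_seq = revcomp(guide_seq)
        targets.append(make_target(amp[3], amp_seq, guide_seq,
                                   enzyme=enzyme, **kwargs))
    if not targets:
        raise TargetFileError(f"{bed6}: no guide/amplicon pairs found")
    return targets
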