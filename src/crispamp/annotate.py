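"""Variant calling and repair-outcome classification.

Position conventions (0-based reference coordinates):

* insertion position = the reference base directly 5' of the inserted
  bases, i.e. ``bond - 1`` for an insertion at bond ``b``;
* deletion position = the deleted reference base closest to the nearest
  cut/nick bond (distance of base ``p`` to bond ``b`` is ``|p + 0.5 - b|``);
* a deletion intersects the cut when the base directly 5' of a cut/nick
  bond (in guide orientation) is missing.

An indel atom is *retained* — counts toward editing — iff its position lies
in the target's variant-detection window.  A read is edited iff it carries
at least one retained indel; SNP-only reads are recorded but never counted
as indel-edited.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .psnw import Alignment


@dataclass(frozen=True)
class Atom:
    """One atomic difference against the reference.

    ``start``: INS -> bond index; DEL -> first deleted position;
    SNP -> position.  ``seq``: inserted bases / deleted bases / alt base.
    """

    kind: str           # "INS" | "DEL" | "SNP"
    start: int
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq) if self.kind != "SNP" else 0


def extract_atoms(aln: Alignment, query: str, ref: str) -> list[Atom]:
    """Decompose an alignment into INS/DEL/SNP atoms."""
    atoms = []
    i = j = 0
    for op, ln in aln.ops:
        if op == "M":
            i += ln
            j += ln
        elif op == "X":
            for k in range(ln):
                atoms.append(Atom("SNP", j + k, query[i + k]))
            i += ln
            j += ln
        elif op == "D":
            atoms.append(Atom("DEL", j, ref[j:j + ln]))
            j += ln
        else:
            atoms.append(Atom("INS", j, query[i:i + ln]))
            i += ln
    return atoms


def insertion_position(atom: Atom) -> int:
    return atom.start - 1


def deletion_position(atom: Atom, cut_bonds) -> int:
    """Deleted base closest to the nearest cut bond (ties: leftmost)."""
    span = range(atom.start, atom.start + atom.length)
    return min(span, key=lambda p: (min(abs(p + 0.5 - b)
                                        for b in cut_bonds), p))


def indel_position(atom: Atom, cut_bonds) -> int:
    if atom.kind == "INS":
        return insertion_position(atom)
    return deletion_position(atom, cut_bonds)


def deletion_intersects_cut(atom: Atom, cut_bonds, guide_strand: str = "+"
                            ) -> bool:
    """True when the base directly 5' (guide orientation) of any cut/nick
    bond is deleted."""
    span = range(atom.start, atom.start + atom.length)
    for b in cut_bonds:
        p5 = b - 1 if guide_strand == "+" else b
        if p5 in span:
            return True
    return False


@dataclass
class ReadCall:
    """Per-unique-read variant call against its assigned reference."""

    atoms: list[Atom]
    retained: list[Atom]            # indel atoms inside the window
    snps: list[Atom]
    count: int
    pathway: str = "wild_type"      # wild_type | NHEJ | HDR_perfect | HDR_imperfect
    read_ids: list[str] = field(default_factory=list)

    @property
    def edited(self) -> bool:
        return bool(self.retained)

    @property
    def net_indel_length(self) -> int:
        return sum(a.length if a.kind == "INS" else -a.length
                   for a in self.retained)

    @property
    def signature(self) -> tuple:
        return tuple((a.kind, a.start, a.seq) for a in self.retained)


def call_variants(aln: Alignment, query: str, ref: str,
                  window: tuple[int, int], cut_bonds,
                  count: int = 1, read_ids=None) -> ReadCall:
    """Extract atoms and apply the window-retention rule."""
    atoms = extract_atoms(aln, query, ref)
    w0, w1 = window
    retained = [a for a in atoms if a.kind in ("INS", "DEL")
                and w0 <= indel_position(a, cut_bonds) < w1]
    snps = [a for a in atoms if a.kind == "SNP"]
    return ReadCall(atoms, retained, snps, count,
                    read_ids=list(read_ids or []))


# ---------------------------------------------------------------------------
# mechanistic classification


def classify_insertion(atom: Atom, ref: str) -> str:
    """'templated' (exact duplication of the adjacent reference on either
    side), else 'gc' (>1 nt, only G/C), else 'other'."""
    b, ins = atom.start, atom.seq
    k = len(ins)
    if b - k >= 0 and ref[b - k:b] == ins:
        return "templated"
    if b + k <= len(ref) and ref[b:b + k] == ins:
        return "templated"
    if k > 1 and set(ins) <= {"G", "C"}:
        return "gc"
    return "other"


def equivalent_deletion_placements(ref: str, start: int, length: int
                                   ) -> list[int]:
    """All start offsets whose deletion of ``length`` bases yields the same
    edited sequence (the repeat-equivalence class of the deletion)."""
    placements = [start]
    s = start
    while s > 0 and ref[s - 1] == ref[s - 1 + length]:
        s -= 1
        placements.append(s)
    s = start
    while s + length < len(ref) and ref[s] == ref[s + length]:
        s += 1
        placements.append(s)
    return sorted(placements)


def _homology(a: str, b: str) -> int:
    h = 0
    while h < min(len(a), len(b)) and a[h] == b[h]:
        h += 1
    return h


def classify_deletion_mmej(atom: Atom, ref: str,
                           min_homology: int = 2) -> bool:
    """Microhomology-mediated end joining: deletion longer than 1 nt whose
    deleted prefix matches the 3' flank, or deleted suffix matches the 5'
    flank, by >= ``min_homology`` exact bases — maximized over all
    equivalent (shifted) placements of the deletion."""
    L = atom.length
    if L <= 1:
        return False
    best = 0
    for s in equivalent_deletion_placements(ref, atom.start, L):
        deleted = ref[s:s + L]
        right = ref[s + L:]
        left = ref[:s]
        best = max(best,
                   _homology(deleted, right),
                   _homology(deleted[::-1], left[::-1]))
    return best >= min_homology


def classify_frameshift(net_indel_length: int) -> bool:
    """Net indel length not a multiple of 3."""
    return net_indel_length % 3 != 0


# ---------------------------------------------------------------------------
# HDR pathway labels


def classify_hdr_read(call: ReadCall, assigned_kind: str,
                      inspection_span: tuple[int, int] | None,
                      cut_bonds) -> str:
    """Pathway of one read given its assignment and variant call.

    Wild-type-assigned reads are NHEJ iff they carry a retained indel.
    HDR-assigned reads are perfect iff no SNP or indel falls inside the
    inspection span (the hull of the variant window and the intended-edit
    span, both on HDR-reference coordinates).
    """
    if assigned_kind == "wild_type":
        return "NHEJ" if call.edited else "wild_type"
    s0, s1 = inspection_span
    for a in call.atoms:
        if a.kind == "SNP":
            pos = a.start
        else:
            pos = indel_position(a, cut_bonds)
        if s0 <= pos < s1:
            return "HDR_imperfect"
    return "HDR_perfect"


# ---------------------------------------------------------------------------
# per-target summaries


@dataclass
class TargetSummary:
    target_id: str
    total_reads: int = 0
    edited_reads: int = 0
    frameshift_reads: int = 0
    pathway_reads: dict = field(default_factory=lambda: defaultdict(int))
    ins_positions: Counter = field(default_factory=Counter)   # offset to cut
    del_positions: Counter = field(default_factory=Counter)
    ins_sizes: Counter = field(default_factory=Counter)
    del_sizes: Counter = field(default_factory=Counter)
    n_insertions: int = 0
    n_templated: int = 0
    n_gc: int = 0
    n_deletions_pure: int = 0        # deletion-only events (for MMEJ stats)
    n_mmej: int = 0
    insufficient_reads: bool = False
    no_data: bool = False
    warn_no_control: bool = False
    corrected_pct_indels: float | None = None

    @property
    def pct_indels(self) -> float:
        return 100.0 * self.edited_reads / self.total_reads \
            if self.total_reads else float("nan")

    @property
    def pct_frameshift(self) -> float:
        return 100.0 * self.frameshift_reads / self.total_reads \
            if self.total_reads else float("nan")

    @property
    def pathway_fractions(self) -> dict:
        tot = self.total_reads or 1
        return {k: v / tot for k, v in sorted(self.pathway_reads.items())}

    @property
    def pct_templated_of_insertions(self) -> float:
        return 100.0 * self.n_templated / self.n_insertions \
            if self.n_insertions else float("nan")

    @property
    def pct_gc_of_insertions(self) -> float:
        return 100.0 * self.n_gc / self.n_insertions \
            if self.n_insertions else float("nan")

    @property
    def pct_mmej_of_deletions(self) -> float:
        return 100.0 * self.n_mmej / self.n_deletions_pure \
            if self.n_deletions_pure else float("nan")


def summarize_target(target_id: str, calls: list[ReadCall], ref: str,
                     cut_bonds, primary_cut_bond: int,
                     min_reads: int = 0) -> TargetSummary:
    """Aggregate per-read calls into the target-level report."""
    s = TargetSummary(target_id)
    for call in calls:
        s.total_reads += call.count
        s.pathway_reads[call.pathway] += call.count
        if not call.edited:
            continue
        s.edited_reads += call.count
        if classify_frameshift(call.net_indel_length):
            s.frameshift_reads += call.count
        has_ins = any(a.kind == "INS" for a in call.retained)
        has_del = any(a.kind == "DEL" for a in call.retained)
        for a in call.retained:
            pos = indel_position(a, cut_bonds)
            if a.kind == "INS":
                s.ins_positions[pos - primary_cut_bond] += call.count
                s.ins_sizes[a.length] += call.count
                s.n_insertions += call.count
                mech = classify_insertion(a, ref)
                if mech == "templated":
                    s.n_templated += call.count
                elif mech == "gc":
                    s.n_gc += call.count
            else:
                s.del_positions[pos - primary_cut_bond] += call.count
                s.del_sizes[a.length] += call.count
                if not has_ins:
                    # events mixing insertions and deletions are excluded
                    # from the MMEJ denominator
                    s.n_deletions_pure += call.count
                    if classify_deletion_mmej(a, ref):
                        s.n_mmej += call.count
    if s.total_reads == 0:
        s.no_data = True
    elif s.total_reads <= min_reads:
        s.insufficient_reads = True
    return s


def background_subtract(treated: TargetSummary,
                        control: TargetSummary | None) -> float:
    """Corrected percent indels: max(0, treated - control)."""
    if control is None or math.isnan(control.pct_indels):
        treated.warn_no_control = True
        treated.corrected_pct_indels = treated.pct_indels
        return treated.pct_indels
    corrected = max(0.0, treated.pct_indels - control.pct_indels)
    treated.corrected_pct_indels = corrected
    return corrected


def subtract_event_frequencies(treated: dict, control: dict) -> dict:
    """Per-event background subtraction of frequency dictionaries."""
    out = {}
    for key, f in treated.items():
        out[key] = max(0.0, f - control.get(key, 0.0))
    return out


# ---------------------------------------------------------------------------
# profile comparison and subsampling


def symmetric_kl(p, q, pseudocount: float = 1e-6) -> float:
    """Symmetric Kullback-Leibler divergence KL(p||q) + KL(q||p).

    ``p``/``q`` are frequency profiles over the same outcome set: parallel
    array-likes, or dicts keyed by outcome (the union of keys is used).
    Zero bins receive ``pseudocount`` before renormalization; natural log.
    """
    if isinstance(p, dict) or isinstance(q, dict):
        keys = sorted(set(p) | set(q))
        p = np.array([p.get(k, 0.0) for k in keys], dtype=float)
        q = np.array([q.get(k, 0.0) for k in keys], dtype=float)
    else:
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
    if p.size == 0 or q.size == 0 or p.size != q.size:
        raise ValueError("profiles must be non-empty and of equal size")
    p = np.where(p <= 0, pseudocount, p)
    q = np.where(q <= 0, pseudocount, q)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def subsample_reads(items, n: int, seed: int):
    """Uniform sample of ``n`` items without replacement (reproducible)."""
    items = list(items)
    if n > len(items):
        raise ValueError(f"cannot subsample {n} from {len(items)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(items), size=n, replace=False)
    return [items[i] for i in sorted(idx)]
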