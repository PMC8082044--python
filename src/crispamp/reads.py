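"""Read processing: QC, adapter trimming, pair merging, dimer screening,
exact-sequence collapsing, and best-reference assignment.

Every read pair lands in exactly one accounting bucket:
``input = filtered + merge_failed + merged`` and
``merged = dimers + ambiguous + assigned``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import edlib
import numpy as np

from . import _kernels
from .errors import ConfigError
from .psnw import ScoringScheme
from .targets import revcomp

# Illumina TruSeq-style 3' adapters (R1 / R2)
ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

# scheme used for read:reference assignment (mapping-stage scores)
ASSIGN_SCHEME = ScoringScheme(match=2, mismatch=4, gap_open=8, gap_extend=5,
                              scalar=1)


def read_fastq(path):
    """Yield (read_id, seq, qual) from a FASTQ or FASTQ.gz file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def write_fastq(path, records) -> None:
    """Write (read_id, seq, qual) triples as FASTQ.

    ``.gz`` paths are gzip-compressed with a zeroed header timestamp so
    identical data always produces identical bytes.
    """
    if str(path).endswith(".gz"):
        import io
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw,
                               mtime=0) as gz:
                fh = io.TextIOWrapper(gz, encoding="ascii")
                for rid, seq, qual in records:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                fh.flush()
        return
    with open(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def trim_adapter(seq: str, qual: str, adapter: str,
                 min_overlap: int = 4) -> tuple[str, str]:
    """Remove a 3' adapter by exact internal match or exact suffix overlap."""
    pos = seq.find(adapter)
    if pos >= 0:
        return seq[:pos], qual[:pos]
    lim = min(len(adapter), len(seq))
    for k in range(lim, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[:-k], qual[:-k]
    return seq, qual


def quality_filter(seq: str, qual: str, max_n: int = 10,
                   q_threshold: int = 15,
                   max_low_quality_fraction: float = 0.30) -> bool:
    """True if the read passes: N-count <= max_n and at most 30% of bases
    below Q15 (Phred+33).  Length filtering is deliberately disabled."""
    if not seq:
        return False
    if seq.count("N") > max_n:
        return False
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    low = int((arr < 33 + q_threshold).sum())
    return low <= max_low_quality_fraction * len(seq)


def merge_pair(r1_seq: str, r1_qual: str, r2_seq: str, r2_qual: str,
               min_overlap: int = 10,
               max_mismatch_density: float = 0.25
               ) -> tuple[str, str] | None:
    """Merge a pair into one fragment via its best ungapped overlap.

    R2 is reverse-complemented; the overlap with the lowest mismatch
    fraction (ties: longest) is chosen; disagreeing overlap bases take the
    higher-quality call.  Read-through ("outie") layouts are supported with
    overhang trimming.  Returns (seq, qual) or None when no acceptable
    overlap exists.
    """
    rc2 = revcomp(r2_seq)
    rq2 = r2_qual[::-1]
    a1 = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    q1 = np.frombuffer(r1_qual.encode(), dtype=np.uint8)
    q2 = np.frombuffer(rq2.encode(), dtype=np.uint8)
    off, ov, _mm = _kernels.merge_scan(a1, a2, min_overlap,
                                       max_mismatch_density)
    if ov < 0:
        return None
    out_seq = np.empty(len(a1) + len(a2), dtype=np.uint8)
    out_qual = np.empty_like(out_seq)
    k = _kernels.build_merged(a1, q1, a2, q2, off, out_seq, out_qual)
    return (out_seq[:k].tobytes().decode("ascii"),
            out_qual[:k].tobytes().decode("ascii"))


def filter_primer_dimers(seq: str, primers=None, size_limit: int = 60
                         ) -> tuple[bool, str | None]:
    """Flag fragments shorter than ``size_limit`` as primer dimers.

    ``primers`` maps target_id -> (fwd, rev); when provided, a flagged
    fragment is annotated with the best-matching primer pair by homology.
    """
    if len(seq) >= size_limit:
        return False, None
    annot = None
    if primers:
        best = None
        for tid, (fwd, rev) in primers.items():
            probe = fwd + revcomp(rev)
            d = edlib.align(seq, probe, mode="NW", task="distance")[
                "editDistance"]
            if best is None or d < best[0]:
                best = (d, tid)
        if best is not None:
            annot = best[1]
    return True, annot


@dataclass
class CollapsedRead:
    """A unique fragment sequence with its multiplicity and assignment."""

    seq: str
    count: int
    read_ids: list[str]
    qual: str                       # representative quality string
    assigned_ref: int | None = None
    ambiguous: bool = False


def collapse_reads(frags) -> list[CollapsedRead]:
    """Collapse (read_id, seq, qual) triples by exact sequence identity."""
    table: dict[str, CollapsedRead] = {}
    for rid, seq, qual in frags:
        cr = table.get(seq)
        if cr is None:
            table[seq] = CollapsedRead(seq, 1, [rid], qual)
        else:
            cr.count += 1
            cr.read_ids.append(rid)
    return list(table.values())


@dataclass(frozen=True)
class Reference:
    ref_id: str
    target_id: str
    kind: str          # "wild_type" | "hdr_hypothetical"
    seq: str


class ReferenceSet:
    """Candidate amplicon references with a k-mer prescreen index.

    Assignment semantics: each fragment goes to the reference with the best
    global affine alignment score under the mapping scheme (match 2,
    mismatch 4, gap open 8, gap extend 5); a score tie across *different*
    targets marks the fragment ambiguous.  A k-mer index plus edit-distance
    prescreen avoids scoring hopeless candidates; candidates within a safe
    edit-distance margin of the best are scored exactly.
    """

    def __init__(self, references: list[Reference], k: int = 21,
                 scheme: ScoringScheme = ASSIGN_SCHEME):
        if not references:
            raise ConfigError("empty reference set")
        self.references = references
        self.k = k
        self.scheme = scheme
        self._exact = {}
        self._index: dict[str, set[int]] = {}
        for idx, ref in enumerate(references):
            self._exact.setdefault(ref.seq, idx)
            s = ref.seq
            for p in range(0, max(1, len(s) - k + 1)):
                self._index.setdefault(s[p:p + k], set()).add(idx)

    def _candidates(self, seq: str) -> set[int]:
        cand: set[int] = set()
        k = self.k
        step = max(1, k // 2)
        for p in range(0, max(1, len(seq) - k + 1), step):
            cand |= self._index.get(seq[p:p + k], set())
        if not cand:
            cand = set(range(len(self.references)))
        return cand

    def _nw(self, seq: str, ref_seq: str) -> int:
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        return int(_kernels.nw_score(a, b, self.scheme.match,
                                     self.scheme.mismatch,
                                     self.scheme.gap_open,
                                     self.scheme.gap_extend))

    def assign(self, seq: str) -> tuple[int | None, bool]:
        """Returns (reference index or None, ambiguous flag)."""
        idx = self._exact.get(seq)
        if idx is not None:
            return idx, False
        cand = self._candidates(seq)
        dists = []
        for i in cand:
            d = edlib.align(seq, self.references[i].seq, mode="NW",
                            task="distance")["editDistance"]
            dists.append((d, i))
        dists.sort()
        best_d = dists[0][0]
        margin = 2 * best_d + 1
        contenders = [i for d, i in dists if d <= margin]
        if len(contenders) == 1:
            return contenders[0], False
        scored = sorted(((self._nw(seq, self.references[i].seq), i)
                         for i in contenders), key=lambda t: (-t[0], t[1]))
        top_score = scored[0][0]
        top = [i for s, i in scored if s == top_score]
        top_targets = {self.references[i].target_id for i in top}
        if len(top_targets) > 1:
            return None, True
        # same target (e.g. wild-type vs HDR tie): prefer wild_type
        for i in top:
            if self.references[i].kind == "wild_type":
                return i, False
        return top[0], False

    def assign_all(self, collapsed: list[CollapsedRead]) -> None:
        for cr in collapsed:
            idx, amb = self.assign(cr.seq)
            cr.assigned_ref = idx
            cr.ambiguous = amb


@dataclass
class ReadAccounting:
    """Per-sample read bookkeeping across pipeline stages."""

    input_reads: int = 0
    filtered: int = 0
    merge_failed: int = 0
    merged: int = 0
    dimers: int = 0
    ambiguous: int = 0
    assigned: int = 0
    per_target: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        total = max(self.input_reads, 1)
        return {
            "input_reads": self.input_reads,
            "filtered": self.filtered,
            "merge_failed": self.merge_failed,
            "merged": self.merged,
            "dimers": self.dimers,
            "ambiguous": self.ambiguous,
            "assigned": self.assigned,
            "pct_passing_filter": round(
                100 * (self.input_reads - self.filtered) / total, 4),
            "pct_merged": round(100 * self.merged / total, 4),
            "pct_dimers": round(100 * self.dimers / total, 4),
            "per_target_reads": dict(sorted(self.per_target.items())),
        }


def process_fastq(r1_path, r2_path=None, adapters=(ADAPTER_R1, ADAPTER_R2),
                  min_overlap: int = 10, max_mismatch_density: float = 0.25,
                  dimer_size_limit: int = 60, primers=None
                  ) -> tuple[list[CollapsedRead], list[CollapsedRead],
                             ReadAccounting]:
    """FASTQ (pair) -> (collapsed analyzable fragments, dimers, accounting).

    Single-end input skips merging: each passing read is its own fragment
    (assumed to span the amplicon's variant window).
    """
    acct = ReadAccounting()
    frags = []
    dimer_frags = []

    def handle_fragment(rid, seq, qual):
        is_dimer, _annot = filter_primer_dimers(seq, primers,
                                                dimer_size_limit)
        if is_dimer:
            acct.dimers += 1
            dimer_frags.append((rid, seq, qual))
        else:
            frags.append((rid, seq, qual))

    if r2_path is not None:
        it1 = read_fastq(r1_path)
        it2 = read_fastq(r2_path)
        for (rid1, s1, q1), (_rid2, s2, q2) in zip(it1, it2):
            acct.input_reads += 1
            s1, q1 = trim_adapter(s1, q1, adapters[0])
            s2, q2 = trim_adapter(s2, q2, adapters[1])
            if not (quality_filter(s1, q1) and quality_filter(s2, q2)):
                acct.filtered += 1
                continue
            merged = merge_pair(s1, q1, s2, q2, min_overlap,
                                max_mismatch_density)
            if merged is None:
                acct.merge_failed += 1
                continue
            acct.merged += 1
            handle_fragment(rid1, merged[0], merged[1])
    else:
        for rid, s, q in read_fastq(r1_path):
            acct.input_reads += 1
            s, q = trim_adapter(s, q, adapters[0])
            if not quality_filter(s, q):
                acct.filtered += 1
                continue
            acct.merged += 1
            handle_fragment(rid, s, q)

    return collapse_reads(frags), collapse_reads(dimer_frags), acct
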