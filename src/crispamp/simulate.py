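"""Synthetic amplicon-sequencing datasets with exact ground truth.

Three generators mirror the validation designs the pipeline is accepted
against:

* a *specificity* dataset — many targets, 4,000 reads each, half carrying
  modeled indel events (100 unique insertions of 1-15 bp and 100 unique
  deletions of 1-25 bp per target, 10 reads per unique event);
* an *HDR* dataset — per target a 40-bp-arm dsDNA donor (deletion of
  3/10/20/40 bp or insertion of 3/25/50/100 bp near the cut) and a
  heterogeneous read mixture: 15% wild type, 25% NHEJ indels (10 unique),
  15% donor integrations (1 perfect + 4 imperfect), 15% imperfect HDR
  (5 unique), 30% perfect HDR;
* a *titration* series — a known edited pool (10 deletions : 10 insertions
  : 3 SNPs at read mass 43.5 : 43.5 : 13) serially diluted into wild-type
  reads.

Indel positions and sizes are drawn from mutation-probability vectors
encoding the observed repair profiles (insertions overwhelmingly at the
blunt cut for Cas9, spread across the staggered nick region for Cas12a).
Sequencing noise is a parametric substitution model whose per-base error
rises linearly along each read, with Phred qualities consistent with the
local rate; indel sequencing errors are off by default.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import Atom, deletion_position, insertion_position
from .errors import ConfigError
from .reads import write_fastq
from .targets import AmpliconTarget, make_target, revcomp

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# error model


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base substitutions; probability rises linearly from
    ``p5`` at the read's 5' end to ``p3`` at its 3' end."""

    p5: float = 0.001
    p3: float = 0.01

    def rates(self, read_len: int) -> np.ndarray:
        if read_len == 1:
            return np.array([self.p5])
        return np.linspace(self.p5, self.p3, read_len)

    def quals(self, read_len: int) -> str:
        p = self.rates(read_len)
        with np.errstate(divide="ignore"):
            q = np.where(p > 0, np.rint(-10 * np.log10(
                np.maximum(p, 1e-10))), 40.0)
        q = np.clip(q, 2, 40).astype(int)
        return "".join(chr(33 + int(v)) for v in q)


NOISELESS = ErrorModel(0.0, 0.0)
# effective post-QC noise of the 2x250 chemistry used for the HDR design
HDR_ERROR_MODEL = ErrorModel(2e-4, 5e-4)


def apply_error_model(read: str, model: ErrorModel,
                      rng: np.random.Generator) -> tuple[str, str]:
    """Returns (noisy read, quality string)."""
    qual = model.quals(len(read))
    if model.p5 == 0 and model.p3 == 0:
        return read, qual
    p = model.rates(len(read))
    hits = np.nonzero(rng.random(len(read)) < p)[0]
    if len(hits) == 0:
        return read, qual
    arr = list(read)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), qual


# ---------------------------------------------------------------------------
# reference construction


def random_amplicon(rng: np.random.Generator, length: int,
                    homopolymer_cap: int | None = 6) -> str:
    """Random sequence with homopolymer runs capped (None disables)."""
    seq = list(rng.choice(_BASES, size=length))
    if homopolymer_cap:
        run = 1
        for i in range(1, length):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            while run > homopolymer_cap:
                seq[i] = str(rng.choice(_BASES))
                run = 1 if seq[i] != seq[i - 1] else run
    return "".join(seq)


def simulate_target(rng: np.random.Generator, target_id: str,
                    enzyme: str = "cas9", length: int = 250,
                    homopolymer_cap: int | None = 6) -> AmpliconTarget:
    """Random amplicon with a planted guide whose cut sits near the center."""
    for _attempt in range(50):
        seq = list(random_amplicon(rng, length, homopolymer_cap))
        if enzyme == "cas9":
            # protospacer [gs, gs+20) + NGG; blunt cut at gs+17
            gs = length // 2 - 17
            proto = "".join(rng.choice(_BASES, size=20))
            seq[gs:gs + 20] = proto
            seq[gs + 20:gs + 23] = [str(rng.choice(_BASES)), "G", "G"]
        else:
            # TTTV PAM + 21-nt spacer; PAM-distal nick at gs+23
            gs = length // 2 - 23
            proto = "".join(rng.choice(_BASES, size=21))
            seq[gs - 4:gs] = ["T", "T", "T", str(rng.choice(list("ACG")))]
            seq[gs:gs + 21] = proto
        ref = "".join(seq)
        try:
            return make_target(target_id, ref, proto, enzyme=enzyme)
        except Exception:
            continue
    raise ConfigError(f"could not plant a unique guide for {target_id}")


# ---------------------------------------------------------------------------
# mutation probability vectors


@dataclass(frozen=True)
class MutationProbabilityVector:
    """Distributions describing where and how big modeled indels are.

    Insertion positions are bond offsets from the primary cut bond (guide
    orientation); deletions cover the cut bond with probability
    ``del_cover_cut`` and otherwise start within a few bases of it.  All
    supports are chosen so every modeled event starts inside the default
    variant window.
    """

    ins_position_probs: dict = field(default_factory=dict)
    ins_length_probs: dict = field(default_factory=dict)
    del_length_probs: dict = field(default_factory=dict)
    del_cover_cut: float = 0.8
    mech_mix: tuple[float, float, float] = (0.10, 0.16, 0.74)  # templated/gc/other

    def __post_init__(self):
        for d in (self.ins_position_probs, self.ins_length_probs,
                  self.del_length_probs):
            total = sum(d.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("distribution does not sum to 1")


def _geom(support, decay, head=None):
    probs = {}
    if head:
        probs.update(head)
    rest = [L for L in support if L not in probs]
    mass = 1.0 - sum(probs.values())
    raw = np.array([decay ** i for i in range(len(rest))])
    raw = raw / raw.sum() * mass
    for L, p in zip(rest, raw):
        probs[L] = float(p)
    return probs


def default_mpv(enzyme: str = "cas9") -> MutationProbabilityVector:
    if enzyme == "cas9":
        # insertion prevalence: cut 95%, -2 2.6%, -3 0.7%, +1 0.4%
        pos = {0: 0.95, -2: 0.026, -3: 0.007, 1: 0.004,
               -1: 0.005, 2: 0.004, -4: 0.004}
    else:
        # staggered nicks: distal (offset 0), proximal (-5/-4), and a broad
        # spread between/around (-5 bp proximal .. +4 bp distal)
        pos = {0: 0.24, -5: 0.12, -4: 0.12,
               -3: 0.10, -2: 0.10, -1: 0.10,
               1: 0.08, 2: 0.06, 3: 0.04, -6: 0.04}
        pos[4] = round(1.0 - sum(pos.values()), 10)
    ins_len = _geom(range(1, 16), 0.55, head={1: 0.35, 2: 0.40})
    del_len = _geom(range(1, 26), 0.75)
    return MutationProbabilityVector(pos, ins_len, del_len)


def _draw(rng, probs: dict):
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


# ---------------------------------------------------------------------------
# ground-truth events


@dataclass
class GroundTruthEvent:
    """One unique simulated allele and the reads emitted for it."""

    target_id: str
    event_id: str
    event_class: str   # wild_type | nhej_indel | donor_integration_perfect |
    #                    donor_integration_imperfect | hdr_perfect | hdr_imperfect
    #                    | snp_only
    atoms: tuple       # Atom tuples on wild-type coordinates
    seq: str           # full edited amplicon sequence
    reads: int = 0

    @property
    def is_indel_edited(self) -> bool:
        return self.event_class in ("nhej_indel",)


def apply_atoms(ref: str, atoms) -> str:
    """Apply INS/DEL/SNP atoms (sorted, non-overlapping) right-to-left."""
    seq = ref
    for a in sorted(atoms, key=lambda a: -a.start):
        if a.kind == "INS":
            seq = seq[:a.start] + a.seq + seq[a.start:]
        elif a.kind == "DEL":
            seq = seq[:a.start] + seq[a.start + len(a.seq):]
        else:
            seq = seq[:a.start] + a.seq + seq[a.start + 1:]
    return seq


def sample_indel_event(target: AmpliconTarget, mpv: MutationProbabilityVector,
                       rng: np.random.Generator, kind: str | None = None,
                       seen: set | None = None,
                       max_tries: int = 500) -> GroundTruthEvent:
    """Draw one unique in-window indel event for ``target``."""
    c = target.primary_cut_bond
    w0, w1 = target.window
    sign = 1 if target.guide_strand == "+" else -1
    for _ in range(max_tries):
        k = kind or ("INS" if rng.random() < 0.5 else "DEL")
        if k == "INS":
            off = _draw(rng, mpv.ins_position_probs)
            bond = c + off * sign
            L = _draw(rng, mpv.ins_length_probs)
            ins = "".join(rng.choice(_BASES, size=L))
            atom = Atom("INS", bond, ins)
            pos = insertion_position(atom)
        else:
            L = _draw(rng, mpv.del_length_probs)
            if rng.random() < mpv.del_cover_cut:
                start = c - int(rng.integers(0, L + 1))
            else:
                start = c - L // 2 + int(rng.integers(-4, 5))
            start = max(0, min(len(target.ref_seq) - L, start))
            atom = Atom("DEL", start, target.ref_seq[start:start + L])
            pos = deletion_position(atom, target.cut_bonds)
        if not (w0 <= pos < w1):
            continue
        key = (atom.kind, atom.start, atom.seq)
        if seen is not None:
            if key in seen:
                continue
            seen.add(key)
        seq = apply_atoms(target.ref_seq, [atom])
        eid = f"{atom.kind.lower()}{atom.start}_{len(atom.seq)}_" \
              f"{zlib.crc32(atom.seq.encode()) % 10 ** 6}"
        return GroundTruthEvent(target.target_id, eid, "nhej_indel",
                                (atom,), seq)
    raise ConfigError(
        f"could not sample a unique in-window event for "
        f"{target.target_id} after {max_tries} tries")


# ---------------------------------------------------------------------------
# datasets


@dataclass
class SimulatedDataset:
    """Reads plus ground truth for one simulated run."""

    targets: list
    events: list                  # GroundTruthEvent, incl. wild-type rows
    reads_r1: list                # (read_id, seq, qual)
    reads_r2: list
    donors: dict = field(default_factory=dict)      # target_id -> donor seq
    params: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.reads_r1)

    def truth_class(self, read_id: str) -> str:
        """Ground-truth class encoded in the read id."""
        return read_id.split("|")[2]

    def truth_indel(self, read_id: str) -> bool:
        return self.truth_class(read_id) == "nhej_indel"

    def write(self, out_dir: str | Path, gzip_fastq: bool = True) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gzip_fastq else ".fastq"
        paths = {"r1": out / f"reads_R1{suffix}",
                 "r2": out / f"reads_R2{suffix}",
                 "targets": out / "targets.csv",
                 "truth": out / "ground_truth.tsv",
                 "spec": out / "run_spec.json"}
        write_fastq(paths["r1"], self.reads_r1)
        if self.reads_r2:
            write_fastq(paths["r2"], self.reads_r2)
        with open(paths["targets"], "w") as fh:
            fh.write("target_id,amplicon_seq,guide_seq,enzyme,donor_seq\n")
            for t in self.targets:
                donor = self.donors.get(t.target_id, "")
                fh.write(f"{t.target_id},{t.ref_seq},{t.guide.protospacer},"
                         f"{t.enzyme.name},{donor}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("target_id\tevent_id\tclass\treads\tatoms\n")
            for ev in self.events:
                atoms = ";".join(f"{a.kind}:{a.start}:{a.seq}"
                                 for a in ev.atoms)
                fh.write(f"{ev.target_id}\t{ev.event_id}\t{ev.event_class}"
                         f"\t{ev.reads}\t{atoms}\n")
        with open(paths["spec"], "w") as fh:
            json.dump(self.params, fh, indent=1, sort_keys=True)
        if self.donors:
            paths["donors"] = out / "donors.fasta"
            with open(paths["donors"], "w") as fh:
                for tid, seq in self.donors.items():
                    fh.write(f">{tid}\n{seq}\n")
        return paths


def _emit_reads(dataset: SimulatedDataset, event: GroundTruthEvent,
                n_reads: int, read_len: int, model: ErrorModel,
                rng: np.random.Generator) -> None:
    frag = event.seq
    if len(frag) < read_len:
        raise ConfigError("unspannable design: fragment shorter than read")
    r1_t = frag[:read_len]
    r2_t = revcomp(frag[-read_len:])
    for i in range(n_reads):
        rid = f"{event.target_id}|{event.event_id}|{event.event_class}|" \
              f"{event.reads + i}"
        s1, q1 = apply_error_model(r1_t, model, rng)
        s2, q2 = apply_error_model(r2_t, model, rng)
        dataset.reads_r1.append((rid, s1, q1))
        dataset.reads_r2.append((rid, s2, q2))
    event.reads += n_reads


def _spread(total: int, n: int) -> list[int]:
    """Split ``total`` reads over ``n`` events as evenly as possible."""
    base = total // n
    counts = [base] * n
    for i in range(total - base * n):
        counts[i] += 1
    return counts


def generate_specificity_dataset(n_targets: int, reads_per_target: int = 4000,
                                 edited_fraction: float = 0.5,
                                 n_insertions: int = 100,
                                 n_deletions: int = 100,
                                 read_len: int = 150,
                                 amplicon_len: int = 250,
                                 enzyme: str = "cas9",
                                 error_model: ErrorModel = ErrorModel(),
                                 homopolymer_cap: int | None = 6,
                                 seed: int = 0,
                                 emit_reads: bool = True
                                 ) -> SimulatedDataset:
    """The multiplex specificity design: per target, ``n_insertions`` +
    ``n_deletions`` unique events split the edited read mass evenly
    (depth 10 at the 4,000-read, 50%-edited defaults)."""
    rng = np.random.default_rng(seed)
    mpv = default_mpv(enzyme)
    ds = SimulatedDataset([], [], [], [], params={
        "mode": "specificity", "n_targets": n_targets,
        "reads_per_target": reads_per_target,
        "edited_fraction": edited_fraction, "read_len": read_len,
        "amplicon_len": amplicon_len, "enzyme": enzyme,
        "error_model": [error_model.p5, error_model.p3],
        "homopolymer_cap": homopolymer_cap, "seed": seed})
    n_events = n_insertions + n_deletions
    edited_total = int(round(reads_per_target * edited_fraction))
    for t_idx in range(n_targets):
        tid = f"T{t_idx:04d}"
        target = simulate_target(rng, tid, enzyme, amplicon_len,
                                 homopolymer_cap)
        ds.targets.append(target)
        seen: set = set()
        events = [sample_indel_event(target, mpv, rng, "INS", seen)
                  for _ in range(n_insertions)]
        events += [sample_indel_event(target, mpv, rng, "DEL", seen)
                   for _ in range(n_deletions)]
        wt = GroundTruthEvent(tid, "wt", "wild_type", (), target.ref_seq)
        counts = _spread(edited_total, n_events) if n_events else []
        if emit_reads:
            _emit_reads(ds, wt, reads_per_target - edited_total, read_len,
                        error_model, rng)
            for ev, cnt in zip(events, counts):
                _emit_reads(ds, ev, cnt, read_len, error_model, rng)
        else:
            wt.reads = reads_per_target - edited_total
            for ev, cnt in zip(events, counts):
                ev.reads = cnt
        ds.events.append(wt)
        ds.events.extend(events)
    return ds


HDR_DESIGNS = (("DEL", 3), ("DEL", 10), ("DEL", 20), ("DEL", 40),
               ("INS", 3), ("INS", 25), ("INS", 50), ("INS", 100))

# read-mass fractions: wild type / NHEJ / donor integration / imperfect HDR
# / perfect HDR
HDR_MIXTURE = (0.15, 0.25, 0.15, 0.15, 0.30)


def _design_donor(target: AmpliconTarget, design: tuple[str, int],
                  rng: np.random.Generator, arm_len: int = 40,
                  max_cut_distance: int = 8
                  ) -> tuple[str, Atom]:
    """Build a dsDNA donor (arms + payload) encoding the intended edit."""
    kind, size = design
    c = target.primary_cut_bond
    wt = target.ref_seq
    if kind == "INS":
        off = int(rng.integers(-4, 5))
        bond = c + off
        payload = "".join(rng.choice(_BASES, size=size))
        donor = wt[bond - arm_len:bond] + payload + wt[bond:bond + arm_len]
        atom = Atom("INS", bond, payload)
    else:
        off = int(rng.integers(-3, 4))
        start = max(1, c - size // 2 + off)
        donor = wt[start - arm_len:start] + wt[start + size:
                                               start + size + arm_len]
        atom = Atom("DEL", start, wt[start:start + size])
    edit_pos = atom.start if atom.kind == "INS" else atom.start
    if abs(edit_pos - c) > max_cut_distance + size:
        raise ConfigError("donor edit too far from cut")
    return donor, atom


def generate_hdr_dataset(n_targets: int = 16, reads_per_target: int = 4000,
                         read_len: int = 250, amplicon_len: int = 300,
                         arm_len: int = 40, enzyme: str = "cas9",
                         error_model: ErrorModel = HDR_ERROR_MODEL,
                         homopolymer_cap: int | None = 6,
                         seed: int = 0) -> SimulatedDataset:
    """The heterogeneous HDR design, cycling through the eight donor types."""
    rng = np.random.default_rng(seed)
    mpv = default_mpv(enzyme)
    ds = SimulatedDataset([], [], [], [], params={
        "mode": "hdr", "n_targets": n_targets,
        "reads_per_target": reads_per_target, "read_len": read_len,
        "amplicon_len": amplicon_len, "arm_len": arm_len,
        "error_model": [error_model.p5, error_model.p3], "seed": seed})
    fracs = HDR_MIXTURE
    class_reads = [int(round(reads_per_target * f)) for f in fracs]
    class_reads[-1] = reads_per_target - sum(class_reads[:-1])
    for t_idx in range(n_targets):
        tid = f"H{t_idx:04d}"
        target = simulate_target(rng, tid, enzyme, amplicon_len,
                                 homopolymer_cap)
        design = HDR_DESIGNS[t_idx % len(HDR_DESIGNS)]
        donor, edit_atom = _design_donor(target, design, rng, arm_len)
        ds.targets.append(target)
        ds.donors[tid] = donor
        wt = target.ref_seq
        c = target.primary_cut_bond
        hdr_seq = apply_atoms(wt, [edit_atom])

        events = []
        # wild type
        events.append((GroundTruthEvent(tid, "wt", "wild_type", (), wt),
                       [class_reads[0]]))
        # NHEJ indels: 10 unique; an NHEJ event whose edited sequence
        # equals the perfect-HDR allele would be unrecoverable ground
        # truth (indistinguishable by sequencing), so such draws are
        # rejected
        seen: set = set()
        nhej = []
        while len(nhej) < 10:
            ev = sample_indel_event(target, mpv, rng, None, seen)
            if ev.seq != hdr_seq:
                nhej.append(ev)
        nhej_counts = _spread(class_reads[1], 10)
        for k, ev in enumerate(nhej):
            ev.event_id = f"nhej{k}_{ev.event_id}"
            events.append((ev, [nhej_counts[k]]))
        # donor integrations: 1 perfect + 4 imperfect
        integ_counts = _spread(class_reads[2], 5)
        perfect_int = wt[:c] + donor + wt[c:]
        events.append((GroundTruthEvent(
            tid, "int_perfect", "donor_integration_perfect",
            (Atom("INS", c, donor),), perfect_int), [integ_counts[0]]))
        for k in range(4):
            if rng.random() < 0.5:
                max_trunc = int(0.4 * len(donor))
                t5 = int(rng.integers(0, max_trunc + 1))
                t3 = int(rng.integers(0, max_trunc - t5 + 1))
                piece = donor[t5:len(donor) - t3] if t5 + t3 < len(donor) \
                    else donor[:1]
            else:
                piece = _mutate(donor, int(rng.integers(1, 4)), rng)
            seq = wt[:c] + piece + wt[c:]
            events.append((GroundTruthEvent(
                tid, f"int_imperfect{k}", "donor_integration_imperfect",
                (Atom("INS", c, piece),), seq), [integ_counts[k + 1]]))
        # imperfect HDR: 5 unique
        imp_counts = _spread(class_reads[3], 5)
        for k in range(5):
            seq = _imperfect_hdr_sequence(wt, hdr_seq, edit_atom, rng)
            events.append((GroundTruthEvent(
                tid, f"hdr_imperfect{k}", "hdr_imperfect", (), seq),
                [imp_counts[k]]))
        # perfect HDR
        events.append((GroundTruthEvent(tid, "hdr_perfect", "hdr_perfect",
                                        (edit_atom,), hdr_seq),
                       [class_reads[4]]))

        for ev, (cnt,) in events:
            _emit_reads(ds, ev, cnt, read_len, error_model, rng)
            ds.events.append(ev)
    return ds


def _mutate(seq: str, n_snps: int, rng: np.random.Generator) -> str:
    """Substitute ``n_snps`` distinct positions (result always differs)."""
    arr = list(seq)
    for p in rng.choice(len(arr), size=min(n_snps, len(arr)),
                        replace=False):
        arr[p] = str(rng.choice([b for b in "ACGT" if b != arr[p]]))
    return "".join(arr)


def _imperfect_hdr_sequence(wt: str, hdr_seq: str, edit_atom: Atom,
                            rng: np.random.Generator) -> str:
    """A donor-derived allele deviating inside the intended-edit region:
    a truncated incorporation or SNP-bearing payload."""
    if edit_atom.kind == "INS":
        bond, payload = edit_atom.start, edit_atom.seq
        if len(payload) > 1 and rng.random() < 0.5:
            # truncated payload incorporation
            k = int(rng.integers(1, len(payload)))
            return wt[:bond] + payload[:k] + wt[bond:]
        arr = _mutate(payload, int(rng.integers(1, 3)), rng)
        return wt[:bond] + arr + wt[bond:]
    # deletion donor: partial (truncated) deletion
    start, L = edit_atom.start, len(edit_atom.seq)
    if L > 1:
        k = int(rng.integers(1, L))   # delete only k of the L bases
        return wt[:start] + wt[start + k:]
    # 1-bp deletion donor: deviate with a SNP next to the junction instead
    arr = list(wt[:start] + wt[start + 1:])
    arr[start] = str(rng.choice([b for b in "ACGT" if b != arr[start]]))
    return "".join(arr)


def generate_titration(level: float, total_reads: int = 20000,
                       read_len: int = 150, amplicon_len: int = 250,
                       enzyme: str = "cas9",
                       error_model: ErrorModel = ErrorModel(),
                       seed: int = 0,
                       target: AmpliconTarget | None = None
                       ) -> SimulatedDataset:
    """Dilute a known edited pool (10 deletions : 10 insertions : 3 SNPs at
    read mass 43.5 : 43.5 : 13) into wild-type reads at ``level``."""
    if not 0 <= level <= 1:
        raise ConfigError("titration level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mpv = default_mpv(enzyme)
    ds = SimulatedDataset([], [], [], [], params={
        "mode": "titration", "level": level, "total_reads": total_reads,
        "seed": seed, "error_model": [error_model.p5, error_model.p3]})
    if target is None:
        target = simulate_target(rng, "TITR", enzyme, amplicon_len)
    ds.targets.append(target)
    edited = int(round(total_reads * level))
    del_reads = int(round(edited * 0.435))
    ins_reads = int(round(edited * 0.435))
    snp_reads = edited - del_reads - ins_reads
    wt_reads = total_reads - edited

    wt = GroundTruthEvent(target.target_id, "wt", "wild_type", (),
                          target.ref_seq)
    _emit_reads(ds, wt, wt_reads, read_len, error_model, rng)
    ds.events.append(wt)
    seen: set = set()
    for kind, n_ev, mass in (("DEL", 10, del_reads), ("INS", 10, ins_reads)):
        if mass == 0:
            continue
        evs = [sample_indel_event(target, mpv, rng, kind, seen)
               for _ in range(n_ev)]
        for ev, cnt in zip(evs, _spread(mass, n_ev)):
            _emit_reads(ds, ev, cnt, read_len, error_model, rng)
            ds.events.append(ev)
    if snp_reads:
        w0, w1 = target.window
        snps = []
        positions = rng.choice(np.arange(w0, w1), size=3, replace=False)
        for k, p in enumerate(sorted(int(x) for x in positions)):
            alt = str(rng.choice([b for b in "ACGT"
                                  if b != target.ref_seq[p]]))
            atom = Atom("SNP", p, alt)
            snps.append(GroundTruthEvent(
                target.target_id, f"snp{k}", "snp_only", (atom,),
                apply_atoms(target.ref_seq, [atom])))
        for ev, cnt in zip(snps, _spread(snp_reads, 3)):
            _emit_reads(ds, ev, cnt, read_len, error_model, rng)
            ds.events.append(ev)
    return ds
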