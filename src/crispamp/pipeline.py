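"""End-to-end orchestration: FASTQ -> QC/merge -> assignment -> cut-site
aware realignment -> variant classification -> per-target reports.

The run is deterministic for fixed inputs: no randomness is used anywhere
in analysis, all outputs are emitted in sorted order, and reruns are
byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, reads as reads_mod
from .annotate import ReadCall, TargetSummary, call_variants, classify_hdr_read
from .errors import ConfigError
from .hdr import HdrReference, reconstruct_perfect_hdr
from .psnw import BonusProfile, ScoringScheme, build_bonus_vector, psnw, \
    BonusVector
from .reads import CollapsedRead, Reference, ReferenceSet
from .targets import AmpliconTarget, load_manifest, load_targets, with_window


@dataclass
class RunConfig:
    """Configuration for one analysis run."""

    r1: str | Path
    r2: str | Path | None = None
    targets: list[AmpliconTarget] | None = None
    manifest: str | Path | None = None
    bed: str | Path | None = None
    genome: str | Path | None = None
    enzyme: str = "cas9"
    window_half_width: int | None = None
    donors: dict | None = None            # target_id -> donor sequence
    control_r1: str | Path | None = None
    control_r2: str | Path | None = None
    out_dir: str | Path | None = None
    min_reads: int = 100
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    bonus_profile: BonusProfile = field(default_factory=BonusProfile)
    keep_per_read: bool = True

    def resolve_targets(self) -> list[AmpliconTarget]:
        if self.targets:
            targets = list(self.targets)
        elif self.manifest:
            targets = load_manifest(self.manifest, enzyme=None)
        elif self.bed and self.genome:
            targets = load_targets(self.genome, self.bed, enzyme=self.enzyme)
        else:
            raise ConfigError("no targets: provide targets, a manifest, or "
                              "BED + genome")
        if self.window_half_width is not None:
            if self.window_half_width <= 0:
                raise ConfigError("window override must be positive")
            targets = [with_window(t, self.window_half_width)
                       for t in targets]
        for path in (self.r1, self.r2, self.control_r1, self.control_r2):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")
        return targets


@dataclass
class TargetContext:
    """Per-reference calling context (wild-type or HDR hypothetical)."""

    target: AmpliconTarget
    kind: str
    ref_seq: str
    window: tuple[int, int]
    cut_bonds: tuple[int, ...]
    primary_cut_bond: int
    inspection_span: tuple[int, int] | None
    bonus: BonusVector


@dataclass
class RunReport:
    summaries: dict                      # target_id -> TargetSummary
    accounting: reads_mod.ReadAccounting
    calls: dict                          # target_id -> list[ReadCall]
    hdr_refs: dict                       # target_id -> HdrReference
    per_read: pd.DataFrame | None
    control: "RunReport | None" = None

    def per_target_frame(self) -> pd.DataFrame:
        rows = []
        for tid in sorted(self.summaries):
            s = self.summaries[tid]
            frac = s.pathway_fractions
            rows.append({
                "target_id": tid,
                "total_reads": s.total_reads,
                "pct_indels": round(s.pct_indels, 4),
                "corrected_pct_indels": (
                    round(s.corrected_pct_indels, 4)
                    if s.corrected_pct_indels is not None else ""),
                "pct_frameshift": round(s.pct_frameshift, 4),
                "frac_wild_type": round(frac.get("wild_type", 0.0), 6),
                "frac_nhej": round(frac.get("NHEJ", 0.0), 6),
                "frac_hdr_perfect": round(frac.get("HDR_perfect", 0.0), 6),
                "frac_hdr_imperfect": round(frac.get("HDR_imperfect", 0.0),
                                            6),
                "pct_templated_of_insertions": round(
                    s.pct_templated_of_insertions, 4),
                "pct_gc_of_insertions": round(s.pct_gc_of_insertions, 4),
                "pct_mmej_of_deletions": round(s.pct_mmej_of_deletions, 4),
                "insufficient_reads": s.insufficient_reads,
                "no_data": s.no_data,
            })
        return pd.DataFrame(rows)

    def allele_frame(self) -> pd.DataFrame:
        rows = []
        for tid in sorted(self.calls):
            total = self.summaries[tid].total_reads or 1
            by_sig = {}
            for call in self.calls[tid]:
                key = (call.pathway, call.signature)
                agg = by_sig.setdefault(key, [0, call])
                agg[0] += call.count
            for (pathway, sig), (count, call) in sorted(
                    by_sig.items(), key=lambda kv: (-kv[1][0], str(kv[0]))):
                rows.append({
                    "target_id": tid,
                    "allele": ";".join(f"{k}:{s}:{q}" for k, s, q in sig)
                              or "reference",
                    "count": count,
                    "frequency": round(count / total, 6),
                    "pathway": pathway,
                    "net_indel_length": call.net_indel_length,
                    "frameshift": annotate.classify_frameshift(
                        call.net_indel_length),
                })
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "per_target": out / "per_target.tsv",
            "per_allele": out / "per_allele.tsv",
            "qc": out / "qc.json",
        }
        self.per_target_frame().to_csv(paths["per_target"], sep="\t",
                                       index=False)
        self.allele_frame().to_csv(paths["per_allele"], sep="\t",
                                   index=False)
        qc = self.accounting.as_dict()
        with open(paths["qc"], "w") as fh:
            json.dump(qc, fh, indent=1, sort_keys=True)
        if self.per_read is not None:
            paths["per_read"] = out / "per_read.tsv"
            self.per_read.to_csv(paths["per_read"], sep="\t", index=False)
        return paths


def _hamming_atoms(seq: str, ref: str) -> list[annotate.Atom] | None:
    """SNP-only atom list when a gapless alignment is provably optimal
    (equal lengths, <= 2 mismatches under the 2/4/8/5 scheme)."""
    if len(seq) != len(ref):
        return None
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(ref.encode(), dtype=np.uint8)
    diff = np.nonzero(a != b)[0]
    if len(diff) > 2:
        return None
    return [annotate.Atom("SNP", int(i), seq[int(i)]) for i in diff]


def _build_contexts(targets, donors, profile) -> tuple[list[Reference],
                                                       list[TargetContext],
                                                       dict]:
    refs: list[Reference] = []
    ctxs: list[TargetContext] = []
    hdr_refs: dict[str, HdrReference] = {}
    for t in targets:
        refs.append(Reference(f"{t.target_id}:wt", t.target_id,
                              "wild_type", t.ref_seq))
        ctxs.append(TargetContext(t, "wild_type", t.ref_seq, t.window,
                                  t.cut_bonds, t.primary_cut_bond, None,
                                  build_bonus_vector(t, profile)))
    for t in targets:
        donor = (donors or {}).get(t.target_id) or t.donor_seq
        if not donor:
            continue
        hdr_ref, chosen = reconstruct_perfect_hdr(donor, targets)
        hdr_refs[chosen.target_id] = hdr_ref
        refs.append(Reference(f"{chosen.target_id}:hdr", chosen.target_id,
                              "hdr_hypothetical", hdr_ref.seq))
        pseudo = AmpliconTarget(
            chosen.target_id, hdr_ref.seq, chosen.guide, chosen.guide_start,
            chosen.guide_strand, hdr_ref.cut_bonds, hdr_ref.primary_cut_bond,
            hdr_ref.window)
        ctxs.append(TargetContext(chosen, "hdr_hypothetical", hdr_ref.seq,
                                  hdr_ref.window, hdr_ref.cut_bonds,
                                  hdr_ref.primary_cut_bond,
                                  hdr_ref.inspection_span,
                                  build_bonus_vector(pseudo, profile)))
    return refs, ctxs, hdr_refs


def _call_fragment(cr: CollapsedRead, ctx: TargetContext,
                   scheme: ScoringScheme) -> ReadCall | None:
    """Variant call for one unique fragment; None = insufficient span."""
    if cr.seq == ctx.ref_seq:
        return ReadCall([], [], [], cr.count, read_ids=cr.read_ids)
    atoms = _hamming_atoms(cr.seq, ctx.ref_seq)
    if atoms is not None:
        call = ReadCall(atoms, [], [a for a in atoms], cr.count,
                        read_ids=cr.read_ids)
        return call
    aln = psnw(cr.seq, ctx.ref_seq, scheme, ctx.bonus)
    call = call_variants(aln, cr.seq, ctx.ref_seq, ctx.window,
                         ctx.cut_bonds, cr.count, cr.read_ids)
    # terminal deletions mean the fragment did not span that reference
    # region (single-end / short fragments): tolerated outside the window,
    # disqualifying if the unspanned region reaches into it
    terminal = []
    if call.atoms and call.atoms[0].kind == "DEL" \
            and call.atoms[0].start == 0:
        terminal.append(call.atoms[0])
    if call.atoms and call.atoms[-1].kind == "DEL" and \
            call.atoms[-1].start + call.atoms[-1].length == len(ctx.ref_seq):
        terminal.append(call.atoms[-1])
    for a in terminal:
        if a.length < 20:
            continue  # short terminal deletions are treated as real
        span = range(a.start, a.start + a.length)
        w0, w1 = ctx.window
        if span.start < w1 and span.stop > w0:
            return None
        call.atoms.remove(a)
        if a in call.retained:
            call.retained.remove(a)
    return call


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and (optionally) write reports."""
    targets = config.resolve_targets()
    by_id = {t.target_id: t for t in targets}
    if len(by_id) != len(targets):
        raise ConfigError("duplicate target ids")

    refs, ctxs, hdr_refs = _build_contexts(targets, config.donors,
                                           config.bonus_profile)
    refset = ReferenceSet(refs)
    collapsed, _dimers, acct = reads_mod.process_fastq(config.r1, config.r2)
    refset.assign_all(collapsed)

    ctx_by_ref = {i: ctx for i, ctx in enumerate(ctxs)}
    # map reference index -> context index (refs and ctxs built in sync)
    assert len(refs) == len(ctxs)

    calls: dict[str, list[ReadCall]] = {t.target_id: [] for t in targets}
    per_read_rows = []
    for cr in collapsed:
        if cr.ambiguous or cr.assigned_ref is None:
            acct.ambiguous += cr.count
            continue
        ctx = ctx_by_ref[cr.assigned_ref]
        call = _call_fragment(cr, ctx, config.scheme)
        if call is None:
            acct.ambiguous += cr.count   # counted with excluded fragments
            continue
        acct.assigned += cr.count
        tid = ctx.target.target_id
        acct.per_target[tid] = acct.per_target.get(tid, 0) + cr.count
        has_donor = tid in hdr_refs
        if has_donor:
            call.pathway = classify_hdr_read(
                call, ctx.kind, ctx.inspection_span, ctx.cut_bonds)
        else:
            call.pathway = "NHEJ" if call.edited else "wild_type"
        calls[tid].append(call)
        if config.keep_per_read:
            for rid in cr.read_ids:
                per_read_rows.append((rid, tid, call.edited, call.pathway))

    summaries = {}
    for t in targets:
        wt_ctx = next(c for c in ctxs
                      if c.target.target_id == t.target_id
                      and c.kind == "wild_type")
        # mechanism histograms come from wild-type-assigned calls; HDR
        # hypothetical assignments contribute reads/pathways/editing only
        wt_calls = [c for c in calls[t.target_id]
                    if c.pathway in ("wild_type", "NHEJ")]
        hdr_calls = [c for c in calls[t.target_id]
                     if c.pathway not in ("wild_type", "NHEJ")]
        s = annotate.summarize_target(
            t.target_id, wt_calls, t.ref_seq, t.cut_bonds,
            t.primary_cut_bond, min_reads=0)
        for call in hdr_calls:
            s.total_reads += call.count
            s.pathway_reads[call.pathway] += call.count
            if call.edited:
                s.edited_reads += call.count
                if annotate.classify_frameshift(call.net_indel_length):
                    s.frameshift_reads += call.count
        if s.total_reads == 0:
            s.no_data = True
        elif s.total_reads < config.min_reads:
            s.insufficient_reads = True
        summaries[t.target_id] = s

    per_read = None
    if config.keep_per_read:
        per_read = pd.DataFrame(
            sorted(per_read_rows),
            columns=["read_id", "target_id", "edited", "pathway"])

    report = RunReport(summaries, acct, calls, hdr_refs, per_read)

    if config.control_r1 is not None:
        ctrl_cfg = RunConfig(
            r1=config.control_r1, r2=config.control_r2, targets=targets,
            window_half_width=None, donors=None,
            min_reads=config.min_reads, scheme=config.scheme,
            bonus_profile=config.bonus_profile, keep_per_read=False)
        report.control = run_pipeline(ctrl_cfg)
        for tid, s in summaries.items():
            annotate.background_subtract(
                s, report.control.summaries.get(tid))

    if config.out_dir is not None:
        report.write(config.out_dir)
    return report
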