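# Methods

## Problem and scope

`crispamp` quantifies the allele population produced by CRISPR genome
editing from targeted amplicon resequencing.  Given demultiplexed Illumina
FASTQ reads, amplicon/guide definitions (strings, a CSV manifest, or BED6 +
genome FASTA), and optionally an HDR donor per target and an unedited
control sample, it reports per-target editing frequency, repair-pathway
utilization (wild type / NHEJ / perfect HDR / imperfect HDR), frameshift
frequency, mechanistic indel classes (templated and GC insertions, MMEJ
deletions), positional and size histograms, and per-allele tables.  A
synthetic-read simulator with exact ground truth validates the whole stack.

## Coordinate conventions

All coordinates are 0-based, half-open.  Cut sites are integer *bond*
indices: bond `k` is the junction between reference positions `k-1` and
`k`, which makes insertion placement unambiguous.  Cas9 cuts bluntly 3
bonds from the PAM-proximal (3') end of the protospacer.  For Cas12a,
whose cleavage position is not sharply defined, the defaults place the
PAM-distal nick 23 bonds from the protospacer 5' start and consider two
PAM-proximal nicks at bonds 18 and 19 (5-bp and 4-bp overhangs); all three
offsets are configurable, since they were chosen empirically from where
insertions accumulate.

## Variant-detection window

Variants count toward editing only when they *start* inside a window around
the cut: the insertion position is the reference base directly 5' of the
inserted bases; the deletion position is the deleted base closest to the
nearest cut bond.  Defaults are half-width 8 centered on the Cas9 blunt
cut, and half-width 9 centered 3 bp 5' (guide orientation) of the Cas12a
PAM-distal nick.  These are the window sizes at which, in the experiments
the tool models, treatment-minus-control indel signal stops changing by
more than 0.1%, so the window suppresses preparation/sequencing noise
while retaining true repair products.  The window is a half-open interval
of positions (`center - w` to `center + w`), clipped at the amplicon ends;
enlarging it never removes positions.

## Position-specific alignment (the core)

Reads carrying an indel inside repetitive sequence have many co-optimal
global alignments, and an arbitrary tie-break frequently places the indel
outside the window, corrupting quantification.  The aligner therefore
maximizes

    scalar * (affine base score) + position bonuses

where the base scheme is match +2, mismatch -4, gap open -8, gap extend -5
(the same scores used for read:target assignment), `scalar` = 100,000, and
the bonuses are small integers attached to reference coordinates: a
gap-open bonus per bond and a gap-extension bonus per position.  Because
every bonus (and in practice every achievable bonus sum) is far below one
scalar unit, the returned alignment is always among the base-score optima;
among those it carries maximal bonus, and remaining ties resolve to the
leftmost placement by a gap left-normalization pass.  An exhaustive
enumeration oracle (`enumerate_optimal_alignments`, a memoized top-down
recursion, structurally independent of the iterative kernel) verifies both
properties in the test suite on thousands of random instances.

The default enzyme-specific vectors encode observed insertion-position
prevalence.  Cas9: peak 5000 at the cut bond, then 800 / 400 / 200 at the
-2 / -3 / +1 bonds (observed prevalences: ~95% at the cut, ~2.6% at -2,
~0.7% at -3, ~0.4% at +1 — only the ordering is constrained, so the values
are a ranked parameterization).  Cas12a: peak at the PAM-distal nick, 3000
at each PAM-proximal nick, 1000 on the bonds between and just beyond the
nicks (indels are observed from 5 bp outside the proximal nick to 4 bp
outside the distal one).  Every other bond within +/-20 of a cut carries a
*graded* floor, 1 at the span edge rising to 20 beside the cut.  The
gradient matters: a flat floor leaves all placements of an indel inside a
repeat tied on bonus, and the leftmost tie-break can then carry a true
in-window variant out of the window; the gradient resolves every
co-optimal placement toward the cut, which is the selection behavior the
span-wide bonuses exist to provide.  Vectors serialize to/from TSV for
reproducibility.

## Read processing

Adapter trimming (two standard Illumina 3' adapter sequences, exact
internal or suffix-overlap match) and quality filtering (fail when more
than 30% of bases are below Q15 or more than 10 Ns; no length filter)
precede merging.  Paired reads merge by the best ungapped overlap of R1
against reverse-complemented R2 — lowest mismatch fraction (max 0.25),
ties to the longest overlap, minimum overlap 10 — taking the
higher-quality base where the mates disagree; read-through ("outie")
layouts are recognized and overhangs trimmed.  Unmerged pairs are dropped
and counted.  Merged fragments shorter than 60 bp are flagged primer
dimers (annotated against supplied primer pairs by homology) and excluded.
Fragments are collapsed by exact sequence identity and each unique
fragment is assigned to the best-scoring reference (wild-type amplicons
plus any reconstructed perfect-HDR sequences) under the 2/4/8/5 scheme; a
score tie across different targets marks the fragment ambiguous and
excludes it.  Assignment uses a k-mer candidate index and an
edit-distance prescreen so that full scoring runs only when more than one
candidate is close; this changes nothing semantically at panel scale.
Read accounting is a partition: input = filtered + merge-failed + merged;
merged = dimers + ambiguous/excluded + assigned.

Single-end input skips merging; each read is its own fragment and must
span the variant window (alignments whose terminal unspanned region
reaches the window are excluded and counted).

## HDR model

A dsDNA donor is aligned to every candidate amplicon (both orientations)
with match +2, mismatch -1, gap open -30, gap extension 0 — the zero
extension lets an arbitrarily long payload cost a single open, and the -1
mismatch is the only non-degenerate reading of the scheme.  The
best-scoring amplicon wins.  Because zero-extension leaves many co-optimal
traces, reconstruction does not trust the returned trace: the longest
donor prefix and suffix occurring exactly in the amplicon anchor the
homology arms, and the hypothetical perfect-HDR sequence is the amplicon
with the spanned interval replaced by the donor.  Round-trip identities
(applying the intended edit to the wild type reproduces the HDR reference;
diffing recovers exactly the edit) are enforced by tests.  Cut bonds and
the window map onto HDR coordinates (the window keeps its half-width,
centered on the mapped cut).  Reads assigned to the HDR reference are
perfect HDR iff no SNP or indel falls inside the *inspection span* — the
hull of the mapped window and the intended-edit span, so an incomplete
edit (e.g. 3 of 4 SNPs incorporated) or a junction error is imperfect,
while a stray mismatch far outside both is ignored.  Wild-type-assigned
reads are NHEJ iff they carry a retained indel; non-HDR donor
integrations surface as NHEJ or imperfect-HDR alleles (never perfect),
consistent with counting them among edited cells.

## Variant taxonomy

Atoms (INS/DEL/SNP) come from the psnw alignment.  A read is edited iff it
carries at least one retained (in-window) indel; SNP-only reads are
recorded but never counted as indel-edited.  Insertions are *templated*
when the inserted bases exactly duplicate the adjacent reference on either
side (checked before the GC rule, so a G/C duplication is templated), else
*GC* when longer than 1 nt and composed only of G/C, else other.
Deletions longer than 1 nt are MMEJ when >=2 bp of exact microhomology
links the deleted prefix to the 3' flank or the deleted suffix to the 5'
flank, maximized over all repeat-equivalent placements of the deletion;
alleles mixing insertions and deletions are excluded from the MMEJ
denominator.  Frameshift is decided on the net retained indel length
(insertions minus deletions) not divisible by 3 — the only self-consistent
reading for multi-atom alleles.  Mechanistic percentages are normalized
within their category (of all insertions, of all pure deletions).

Editing percentages are reported per target for samples with at least 100
merged reads (configurable); background subtraction against a matched
unedited control is `max(0, treated - control)` on percent indels, with
per-event subtraction available.  Profile similarity uses the symmetric
Kullback-Leibler divergence (natural log, pseudocount 1e-6 on zero bins).
Subsampling is uniform without replacement under a caller-supplied seed.

## Simulator

The simulator emits every dataset used for validation, with a manifest
pairing each read (via its identifier) to its ground-truth event.

* **Targets** are seeded random amplicons with a planted guide whose cut
  sits at the center; homopolymer runs are capped at 6 by default (the
  documented failure mode of overlap merging is long homopolymers; a
  stress mode removes the cap).  Defaults: 250 bp for the 2x150 layout.
  For the 2x250 HDR layout the default is 300 bp — chosen so that a
  perfect integration of the largest donor (100-bp insert + two 40-bp
  arms) still yields a fragment (480 bp) that 2x250 reads span and merge;
  with longer amplicons whole ground-truth classes would silently fail
  merging and the truth fractions would be unrecoverable by any analysis.
* **Indel events** draw from mutation-probability vectors: Cas9 insertion
  bonds 0 / -2 / -3 / +1 relative to the cut at 95 / 2.6 / 0.7 / 0.4%
  (remainder spread nearby), Cas12a insertions spread across the staggered
  nick region; insertion lengths 1-15 (mode 2 bp), deletion lengths 1-25
  (geometric); deletions cover the cut with probability 0.8.  Supports are
  constrained to start inside the default window so manifest truth and
  window-filtered calls can agree exactly.  Uniqueness is enforced per
  target by rejection.
* **Specificity design**: per target 4,000 reads, 50% edited as 100 unique
  insertions + 100 unique deletions at depth 10, 2x150 reads.
* **HDR design**: per target a 40-bp-arm donor (deletion 3/10/20/40 or
  insertion 3/25/50/100 bp within 8 bp of the cut) and 4,000 2x250 reads:
  15% wild type, 25% NHEJ (10 unique events), 15% donor integration (one
  perfect full-donor ligation at the cut + four imperfect with truncations
  up to 40% of donor length or donor-internal SNPs), 15% imperfect HDR
  (five unique truncated or SNP-bearing incorporations deviating inside
  the intended-edit region), 30% perfect HDR.  Alleles that would be
  byte-identical to the perfect-HDR sequence are rejected during
  sampling: such collisions (an NHEJ deletion equal to the donor edit; a
  SNP draw restoring the original base) are literally the same molecule
  and make the ground truth unrecoverable in principle.
* **Titration**: an edited pool of 10 deletions, 10 insertions and 3 SNPs
  at read mass 43.5 : 43.5 : 13, diluted into wild-type reads at any
  level.
* **Error model**: independent per-base substitutions with probability
  rising linearly along the read, qualities consistent with the local rate
  (Q = -10 log10 p); indel errors off by default.  This replaces empirical
  instrument error profiles with a parametric stand-in that preserves the
  property the window filter exploits (position-dependent substitution
  noise).  Defaults are 1e-3 -> 1e-2 for the 2x150 specificity chemistry.
  For the 2x250 HDR datasets the default is 2e-4 -> 5e-4: the perfect-HDR
  readout is directly sensitive to the substitution rate inside the
  inspection span, and the benchmark this design reproduces shows
  perfect-HDR depressed by only 1-2% over ~100-bp inserts, which pins the
  effective post-QC rate near 5e-4/base; the higher 2x150 default would
  misstate that chemistry's effective noise several-fold.

What passing simulator-based tests shows — and does not.  The simulator
emulates read structure, repeat-context indel placement, class mixtures
and position-dependent substitution noise.  It does not emulate PCR
chimeras/jackpots, indel-type sequencing errors, coverage non-uniformity
across a panel, or genuine biological background indels; conclusions about
those regimes require real control samples and the background-subtraction
path.

## Numerical and design choices

* Affine gaps everywhere: a length-k indel costs open + (k-1)*extend.
* 'N' never matches, including against 'N'.
* Equal-length fragments with <=2 mismatches are called as SNPs without a
  DP pass (gapless is provably optimal under 2/4/8/5 for <=2 mismatches:
  any gapped alternative pays >=16 to recover <=12).
* Deterministic throughout: fixed tie-break orders, sorted outputs,
  seedable generators, zeroed gzip timestamps; identical inputs give
  byte-identical outputs.
* Guide location requires an exact protospacer+PAM match by default
  (budget configurable up to 3 mismatches); two equally good placements
  are an error, not a guess.
* Oracle enumeration is bounded (default length product 2,500) and the DP
  guards its problem size (default 3x10^7 cells).

## Benchmarks reproduced by `scripts/acceptance.py`

From scratch, per run: the 603-target manifest count (120,600 unique
events); percent indels at one default-noise 50%-edited target; the
fraction of 60 targets within 0.1 points of 50% and the maximum deviation;
mean per-target precision of edited-read calls; perfect-HDR percent at a
25-bp-insertion site and the fraction of 16 sites (all eight donor
designs) within 2 points of the 30% truth; and the SD of percent indels
over 30 seeded 1,000-pair subsamples of a 0.5%-edited 20,000-read pool.
The 60-target panel (not 603) and 16 HDR sites (not 91) keep a full run
in minutes on one CPU; the generative design is otherwise identical.  Note
that the subsampling SD is itself a hypergeometric sampling quantity with
true value ~0.217 points under this design; measured values fluctuate
around it with the replicate seed.

## Known limitations

Large structural outcomes (translocations, kb-scale deletions, vector
backbone integration beyond the supplied donor sequence) are out of scope,
as are base/prime-editing-specific reports, UMI error correction and
demultiplexing.  Single-end reads must span the window.  The Cas12a nick
offsets and the published bonus-vector magnitudes are not printed in the
modeled experiments' main text; only their orderings are constrained, and
both are exposed as parameters.
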