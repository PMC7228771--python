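# Methods

This note records the models, conventions and deliberate choices behind the
package, at the level of detail a maintainer or reviewer needs.

## Coordinate and break model

All intervals are 0-based half-open on the plus strand; 1-based inclusive
coordinates appear only in human-facing reports, with conversion helpers
tested in both directions. A double-strand break is a single integer: the
plus-strand index of the first base 3′ of the break. The Cas9 break is
modeled as blunt, 3 bp 5′ of the PAM on the target strand (between
protospacer bases 17 and 18); the ~1-nt staggered ends SpCas9 can leave are
deliberately not modeled, since every downstream computation here consumes a
single break position. TALEN breaks are placed at the floor of the spacer
midpoint with a configurable signed offset, because the FokI cut position
within the spacer is not a fixed constant; the midpoint is the conventional
approximation.

Guide location requires an exact protospacer match (mismatch tolerance
belongs only to the off-target scan). `N` anywhere in a region used for
arms, junctions or protospacers is a hard error, not a warning: an ambiguous
base in an oligo order or a homology computation is never acceptable.

## Donor architecture and cloning model

The vector model follows the pGTag layout: cargo flanked by two Type IIS
cloning sites occupied by stuffers, then a 3-nt buffer, then a
universal-guide (UgRNA) Cas9 site on each side with the PAM facing the
cargo. Enzyme geometry ships as editable data: BfuAI `ACCTGC(4/8)` (4-nt 5′
overhang) and BspQI `GCTCTTC(1/4)` (3-nt 5′ overhang) — standard enzyme
definitions, replaceable by user-defined enzymes.

Digestion is simulated on both strands with full circular topology (n sites
on a circle give n fragments); fragments carry explicit 5′-overhang
sequences. Ligation is exact-complementarity string matching — no
mismatch-tolerant ligation, no kinetics, no concatemers. Assembly digests
the vector with both enzymes, discards every fragment that still carries a
recognition site (the stuffers), and chains backbone, 5′-arm duplex, cargo
and 3′-arm duplex by their sticky ends. Consequences that are checked rather
than assumed:

- *Golden Gate completeness*: a successful assembly contains zero intact
  recognition sites of either cloning enzyme. An arm carrying an internal
  site is rejected (it would be re-digested in the one-pot reaction) unless
  explicitly overridden; a ligation junction that would *recreate* a site is
  likewise rejected.
- *Buffer geometry*: the sticky ends are placed so that each arm directly
  abuts its buffer on the UgRNA side and the cargo on the other. For the 5′
  arm the left overhang is therefore the final PAM base plus the 3-nt
  buffer; for the 3′ arm the right overhang is the buffer itself. This ties
  the buffer length to the overhang length (3 nt on both sides), which is
  also the length that keeps the programmed homology exact.

The buffer lives in the vector scaffold, not in the arm oligos: the arms are
the only user-supplied fragments, and oligos are always
`overhang + arm` / `overhang + revcomp(arm)`. Whether deposited donors carry
a 3′-side buffer symmetric to the 5′ one is not settled by the written
description; the model gives each side an independent buffer and defaults
both to `AAA`.

Liberation applies the blunt-cut rule at both UgRNA sites of the circular
donor, yielding exactly two fragments. Under the default inward-PAM
orientation the cargo fragment carries, outside each arm, a fixed
non-homologous residual: 3 protospacer bases + 3-bp PAM + 3-nt buffer.
Residuals are modeled, not trimmed — end resection during HMEJ is biology,
not construct sequence. Orientation is per-side configurable in the vector
spec since only the 5′-side layout is fully pinned down.

The bundled vector registry (`src/geneweld/vectors/`) names three pGTag-style
cassettes; their payloads are **synthetic placeholders** of realistic length,
marked as such in the files, to be replaced with deposited maps before real
use. No test depends on the placeholder payload content. The off-target scan
(Hamming distance within a budget, default 3 mismatches, PAM held exact)
supports whole-genome FASTA input but the test suite exercises it only on
synthetic genomes; no scoring model beyond the mismatch count is attempted.

## Frame and validation checks

A cut's reading-frame phase is the number of coding bases from the CDS start
to the break, modulo 3, computed over concatenated exons in transcription
direction; intronic and outside-gene cuts raise distinct errors. Frame
compatibility compares that phase with the phase the vector's 2A junction
declares; promoter-driven cargos are "not applicable". The check is
report-only: the tool never pads arms to fix frame, because padding would
break the homology it just designed.

Arm validation also reports *effective homology extension*: the run of
vector scaffold bases immediately outside the arm (buffer, then PAM, then
protospacer remnant, in liberated order) that happens to match the genome
continuing beyond the arm. A nonzero value means the real homology is longer
than programmed — the situation the buffer exists to prevent — and is
surfaced as a warning with the effective length.

## Junction classification

The precision rule is: a junction is precise iff the homology arm contains
no mismatch and there is no insertion or deletion in the scored window.
Three operationalizations were required where the rule is qualitative:

- **Scoring scheme.** Reads are oriented (forward vs reverse complement,
  better global alignment wins) and globally aligned with match +1,
  mismatch −1, gap open −2, gap extend −1, taking the aligner's first
  reported alignment as the deterministic tie-break. The rule is the
  specification; the scheme is an implementation choice, overridable via
  `ClassifyParams`.
- **Window.** "No indels up- or downstream" is unbounded as stated; it is
  operationalized as the full reference window, default 40 bp on each side
  of the junction, recorded in the reference object.
- **Duplication.** An insertion of ≥ 80 % of the arm length whose sequence
  is a tandem rotation of the arm, adjacent to the programmed copy, is
  labeled `arm_duplication` (the NHEJ-derived allele class); the threshold
  avoids false calls on short repeat-adjacent insertions and is
  configurable.

Mismatches *outside* the arm but inside the window do not break precision —
the rule constrains mismatches only within the homology domain — and are
reported as warnings. Reads whose per-column alignment identity falls below
0.6 get a single `unalignable` event: measured on random sequence this
metric sits near 0.45–0.55, versus ≥ 0.95 for genuine junction reads with a
few edits, so the floor separates cleanly.

## Synthetic fixtures

The simulator fabricates the full experiment from one seed: a uniform random
genome with a unique planted protospacer+`AGG` at the midpoint, a donor
built around a random cargo, the designed plan, and 5′-junction reads drawn
from a labeled event mix (precise / single-base junction insertion /
junction deletion of 1–5 bp / in-arm mismatch / tandem arm duplication),
with optional uniform per-base error and random read orientation. Defaults —
10-kb genome, 1.5-kb cargo, 24-bp arms, a 95:5 precise:duplication mix —
mirror the short-arm study conditions this package models (24-bp arms with
19/20 precise junctions, the one imprecise allele a homology-domain
duplication).

Generated scaffolds and genomes exclude the BfuAI/BspQI recognition motifs
and the UgRNA site, as engineered donor backbones must and as a usable
target region does; real genomes, by contrast, contain such motifs, and real
arms that carry one are rejected at assembly rather than silently cloned.
What passing simulator-based tests therefore show is correctness of the
*design arithmetic and classification logic* under clean sequence — not
robustness to repetitive genomes, polymorphism between the reference and the
injected animal, sequencing artifacts beyond uniform substitution error, or
amplification bias. NGS-scale amplicon processing (trimming, merging, UMIs,
indel-spectrum deconvolution) is out of scope.

## Numerical and degenerate-input choices

- Deterministic outputs everywhere: features sorted by (start, label) before
  GenBank emission; identical inputs give byte-identical files; every
  stochastic path takes a mandatory seed (NumPy `default_rng`).
- Linear molecules whose Type IIS cut would fall off the end are left uncut
  at that site; zero sites return the molecule intact with an INFO notice.
- Two enzymes cutting at the same coordinate keep the first definition
  (pathological overlap, not seen in practice).
- Arm length is bounded only by the contig (`min(cut, len − cut)`), so 1-kb
  arms for long-arm comparison designs are expressible.
- An empty event-mix probability vector, a non-unit mix sum, or an arm that
  cannot fit around the planted cut are hard errors in the simulator.

## Known limitations

- Cloning is sequence-exact: star activity, partial digestion and ligation
  efficiency are not modeled.
- The classifier assumes reads span the window; partial reads shorter than
  the minimum overlap (default 30 nt) are rejected rather than clipped.
- TALEN cut placement is an approximation (see above); downstream arithmetic
  is exact given the chosen position.
- The off-target scan is a Hamming scan with an exact PAM, not an activity
  model; it answers "is there a near-match" rather than "would it cut".
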