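# Methods

## Model

`stacktail` treats an SV junction as a novel adjacency between two
reference *breakends*. A breakend is a triple (chromosome, position,
side): side `right` means the reference bases ending at the position abut
the junction, side `left` means the bases starting there do. Every
junction class is a side pair — on one chromosome, (right, left) is a
colinear deletion-type join, (left, right) a duplication-type join,
(right, right)/(left, left) the two edges of an inversion; across
chromosomes any side pair is a translocation junction.

The evidence model is intentionally simple: a read spanning the junction
aligns partially to the reference (soft-clipped), and once realigned to
the reconstructed junction sequence it covers l_A bases on one side and
l_B on the other. Its evidence is Q·min(l_A, l_B): the overhang into the
partner flank, weighted by alignment quality. The junction support
S = Σ Q·min(l_A, l_B) grows linearly with both spanning-read count and
overhang length, so at coverage c and read length L a true junction has
E[S] ≈ c·L/8 · (1+o(1)) per strandless read set (for 30× and 250-bp reads,
S ≈ 10³, i.e. log₁₀S ≈ 3), while a junction with one wrong flank collects
only chance overhangs of a base or two. Thresholds operate on log₁₀(S).

### Alignment quality Q

Q is defined as the Smith–Waterman score divided by the maximum
attainable score for the read (match score × read length), clipped to
[0, 1]. A perfect full-length alignment has Q = 1, so its contribution is
exactly the overhang in bases; mismatches and gaps discount the read's
vote. Base qualities are not folded into Q (they enter only through tail
trimming, below); this keeps the statistic scale-interpretable.

### Orientations are determined by clip sides

For the junction sequence flankA + flankB, the slot-A flank is forward
when its breakend side is `right` and reverse-complemented when `left`
(and the mirror rule for slot B). Clip-side compatibility in targeted
pairing follows: a forward A-flank can only be supported by a right-clip
stack, an inversion search pairs two same-side stacks, and so on. Because
side and orientation are bijective per slot, junction identity is stored
canonically as the sorted breakend pair; swapping slots merely
reverse-complements the junction sequence, which the strand-symmetric
aligner treats identically.

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_tail` | 10 bp | shortest soft clip worth realigning; shorter tails rarely anchor uniquely |
| `qual_trim` | Q3 | bases below this Phred score at a tail's far end are trimmed (sequencing chemistry degrades read ends) |
| `min_stack_reads` | 2 | weakest reading of a "recurrent" clip coordinate |
| `fuzz` | 0 | clip-coordinate clustering radius; 0 for clean/simulated data, 2 recommended for real aligner output |
| `flank_len` | max read length + 50 | every junction-spanning read can align fully inside the candidate sequence |
| match/mismatch/gap open/extend | +1/−3/−5/−2 | conventional short-read local-alignment scheme; first gap base costs the open score, each further base the extend score |
| `min_align_score` | 20 | random 40-mers against a 200-bp junction essentially never reach this |
| threshold | log₁₀S scale, trainable | midpoint between lowest true positive and the false positive below it; fallback t/2 when no false positive lies below |
| `collapse_window` / `comparison_window` | 500 bp | near-duplicate predictions and call-set comparisons are windowed at this radius |
| `coverage_k` | 10 | breakends in regions deeper than k × median depth are excluded (repeats) |

Coverage adjustment (whole-genome mode) uses
S_adj = S · baseline / max(local, baseline): proportional down-weighting
in deeper-than-baseline regions, never up-weighting shallow ones. The
functional form is recorded in each run's output metadata.

## Calling policy

Threshold comparisons are closed (a score exactly at threshold passes).
Collapsing is single-linkage within a key of (SV class, side pair,
chromosome pair), so a deletion and an inversion sharing coordinates, or
the two derivatives of a reciprocal translocation, never merge; the
highest-scoring member represents its cluster and the operation is
idempotent. Call-set comparison matches greedily on total breakpoint
distance with each call used once, making the intersection count
symmetric. A sample-level SV type is the type of the top-ranked passed
call — ranking matters because a wrong-partner junction can score weakly
positive through its shared flank but is dominated by the correct one.

## Simulator

The generator emulates targeted and whole-genome short-read experiments:
i.i.d. uniform ACGT chromosomes (optionally with planted tandem-repeat
blocks), donor genomes realized as segment lists over the reference, and
uniformly sampled single- or paired-end reads with substitution errors
and configurable quality profiles. Truth alignments place each read at
its donor origin mapped back to reference coordinates; junction-crossing
reads get the longer segment as their primary alignment with the shorter
side soft-clipped exactly at the junction. Separate RNG streams drive
genome, positions, strands and errors, so changing the error rate leaves
read positions fixed; every output is byte-deterministic given a seed.

The replica preset models a targeted leukemia translocation panel: 8
capture regions scaled to 10 kb (one mini-chromosome per fusion partner of
t(1;19), t(4;11), t(9;22), t(12;21)), a 4-sample training cohort with 7
junctions (3 reciprocal + 1 single) and a 23-sample test cohort with 31
junctions (8 reciprocal + 15 single; 23×8 − 31 = 153 unrearranged region
instances), 250-bp single-end reads at 30× coverage. Region size, read
length and coverage are the package's own scaled-down choices for a
desk-scale experiment; they reproduce the log₁₀S ≈ 3 support regime of a
real targeted panel while keeping a full cohort run under a minute.

What the simulator does **not** model: platform-specific error profiles
(homopolymer errors, quality decay calibration), indel sequencing errors
(optional substitutions only, which keeps truth CIGARs simple), alignment
ambiguity in repeats (truth alignments are placed by construction), and
library-preparation artifacts. Passing the replica therefore demonstrates
the correctness of the stacking, junction-construction, scoring and
calling machinery — not robustness to real aligner behavior in repetitive
sequence, where soft-clips can be replaced by mismatch pile-ups and this
class of caller is known to lose sensitivity.

A note on conservation: deletions, duplications, inversions and
reciprocal translocations conserve donor length exactly (± the planted
indel lengths). A *non-reciprocal* translocation builds a single fusion
chromosome and drops the two unjoined arms, so total length shrinks by
construction; the truth table still records exactly one junction for it.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally, 1-based in all
  user-facing tables; BED/BEDPE exports are 0-based half-open.
- Stack clustering picks the modal clip position, ties to the smallest
  coordinate; with `fuzz=0` it is an exact group-by.
- The density filter caps candidates per fixed 1-kb tile (top-k by read
  count, ties to smallest position) — a deterministic concretization of
  "per kilobase".
- Local alignment tries both strands and keeps the higher score (tie →
  plus strand); hits below `min_align_score` are discarded. Alignment is
  delegated to Biopython's `PairwiseAligner`; the test suite checks it
  against an independent hand-written affine-gap dynamic program, itself
  validated by exhaustive path enumeration on very small inputs.
- A read clipped at both ends contributes once per junction; by default a
  read may support several junctions (the statistic sums per junction),
  with a winner-takes-all mode available.
- S = 0 is reported as log₁₀S = −inf and can never pass a finite
  threshold. Empty regions, empty candidate lists and zero-call runs are
  normal outcomes (exit 0), with warnings.
- External BEDPE candidates use interval midpoints until refined to the
  best-supported nearby stack; a spec with no stack on either side keeps
  its midpoints and is flagged low-confidence. Unknown orientations
  expand to all four side pairs rather than guessing — wrong orientations
  score ≈ 0 and are cheap at candidate scale.
- Discordant-pair orientation votes map opposite-strand pairs to the
  colinear forward/forward join and like-strand pairs to one
  reverse-complemented flank (+/+ → B-flank, −/− → A-flank); ties and
  zero votes are undetermined.

## Known limitations

- Insertions of novel sequence approaching the read length cannot be
  represented as a two-flank junction and are out of scope.
- Complex events with multiple nearby breakpoints are not resolved
  recursively; a read crossing two junctions is truth-aligned to its
  longest single segment and flagged.
- Germline/somatic status is not assigned.
- The scoring loop is quadratic in (stacked reads × candidate junctions);
  whole-genome use therefore expects an external candidate list (or the
  built-in discordant-pair clustering) to bound the junction library, plus
  the repeat-coverage exclusion to protect the combinatorics.
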