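"""Candidate junction construction.

A structural variant joins two reference "breakends".  Each breakend is a
(chrom, pos, side) triple where ``side`` says which reference flank abuts
the novel adjacency: ``right`` means the bases ending at ``pos`` (the
segment extends leftward from the junction), ``left`` means the bases
starting at ``pos``.  A candidate junction concatenates the two oriented
flanks; reads spanning the true junction align across the concatenation
point and contribute support.

Slot conventions (fixed throughout the package):

* slot A (left half of the junction sequence): side ``right`` ⇒ flank is
  the forward-strand bases ending at pos; side ``left`` ⇒ flank is the
  reverse complement of the bases starting at pos.
* slot B (right half): side ``left`` ⇒ forward bases starting at pos;
  side ``right`` ⇒ reverse complement of the bases ending at pos.

Orientation (forward / reverse-complement) is therefore determined by the
breakend side once the slot is fixed, and swapping slots reverse-
complements the junction — the same adjacency either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import fetch_reference, revcomp, _chrom_seq_len

log = logging.getLogger(__name__)

FORWARD = "forward"
REVCOMP = "reverse-complement"

#: distance beyond which a same-chromosome colinear junction is reported as
#: an intra-chromosomal translocation rather than a deletion/duplication
INTRA_TRANSLOCATION_MIN_DIST = 1_000_000


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    pos: int
    side: str  # "left" | "right"


@dataclass
class JunctionSpec:
    """An ordered, oriented pair of breakends (junction before sequence).

    Stored canonically: breakends sorted by (chrom, pos, side).  The
    orientation of each flank follows from its side and slot (see module
    docstring) and is exposed through ``orientationA``/``orientationB``.
    """

    bpA: Breakend
    bpB: Breakend
    source: str = "targeted"  # targeted | external | discordant | truth
    orientation_known: bool = True
    low_confidence: bool = False
    # provisional intervals for externally supplied candidates
    intervalA: Optional[Tuple[int, int]] = None
    intervalB: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        if (self.bpB.chrom, self.bpB.pos, self.bpB.side) < (
            self.bpA.chrom,
            self.bpA.pos,
            self.bpA.side,
        ):
            self.bpA, self.bpB = self.bpB, self.bpA
            self.intervalA, self.intervalB = self.intervalB, self.intervalA

    @property
    def orientationA(self) -> str:
        return FORWARD if self.bpA.side == "right" else REVCOMP

    @property
    def orientationB(self) -> str:
        return FORWARD if self.bpB.side == "left" else REVCOMP

    @property
    def key(self):
        return (self.bpA.chrom, self.bpA.pos, self.bpA.side,
                self.bpB.chrom, self.bpB.pos, self.bpB.side)


def classify(bpA: Breakend, bpB: Breakend,
             intra_min: int = INTRA_TRANSLOCATION_MIN_DIST) -> str:
    """SV class from junction geometry alone."""
    if bpA.chrom != bpB.chrom:
        return "inter-translocation"
    sides = (bpA.side, bpB.side)
    if sides in (("right", "right"), ("left", "left")):
        return "inversion"
    dist = abs(bpB.pos - bpA.pos)
    if dist >= intra_min:
        return "intra-translocation"
    return "deletion" if sides == ("right", "left") else "insertion/duplication"


@dataclass
class CandidateJunction:
    """A junction spec with its constructed sequence (the scored object)."""

    spec: JunctionSpec
    seq: str
    breakpoint_offset: int  # index of the first base from slot B
    flankA_len: int
    flankB_len: int
    sv_class: str

    @property
    def junction_id(self) -> str:
        a, b = self.spec.bpA, self.spec.bpB
        return f"{a.chrom}:{a.pos}:{a.side}|{b.chrom}:{b.pos}:{b.side}"


_SIDE_FOR_SLOT_A = {FORWARD: "right", REVCOMP: "left"}
_SIDE_FOR_SLOT_B = {FORWARD: "left", REVCOMP: "right"}

_ORIENT_ALIASES = {
    "forward": FORWARD, "fwd": FORWARD, "+": FORWARD, "f": FORWARD,
    "reverse-complement": REVCOMP, "rc": REVCOMP, "-": REVCOMP, "revcomp": REVCOMP,
}


def _norm_orient(o: str) -> str:
    try:
        return _ORIENT_ALIASES[o.lower()]
    except KeyError:
        raise ValueError(f"unknown orientation {o!r}") from None


def pair_candidates_targeted(
    candidates: Sequence,
    region_pairs: Sequence[Tuple],
) -> List[JunctionSpec]:
    """Pair breakpoint candidates across user-specified region pairs.

    Each region pair is ``((chromA, startA, endA), (chromB, startB, endB),
    orientationA, orientationB)``.  A candidate joins slot A only if its
    clip side matches the requested orientation (forward slot-A flank needs
    a right clip; a reverse-complemented flank flips the side), likewise for
    slot B.  The side-compatible Cartesian product is emitted, deduplicated
    on canonical junction identity.
    """
    specs = {}
    for (regA, regB, oA, oB) in region_pairs:
        oA, oB = _norm_orient(oA), _norm_orient(oB)
        sideA = _SIDE_FOR_SLOT_A[oA]
        sideB = _SIDE_FOR_SLOT_B[oB]
        inA = [c for c in candidates
               if c.chrom == regA[0] and regA[1] <= c.pos < regA[2] and c.clip_side == sideA]
        inB = [c for c in candidates
               if c.chrom == regB[0] and regB[1] <= c.pos < regB[2] and c.clip_side == sideB]
        if not inA or not inB:
            log.warning("region pair %s/%s (%s/%s): no compatible candidates on %s side",
                        regA, regB, oA, oB, "A" if not inA else "B")
            continue
        for ca in inA:
            for cb in inB:
                a = Breakend(ca.chrom, ca.pos, ca.clip_side)
                b = Breakend(cb.chrom, cb.pos, cb.clip_side)
                if a == b:
                    continue  # degenerate self-fold
                spec = JunctionSpec(a, b, source="targeted")
                specs.setdefault(spec.key, spec)
    return [specs[k] for k in sorted(specs)]


def flank_sequence(reference, bp: Breakend, slot: str, flank_len: int) -> str:
    """Oriented reference flank of a breakend for a junction slot."""
    n = _chrom_seq_len(reference, bp.chrom)
    leftward = (bp.side == "right")  # flank occupies [pos-f, pos)
    if leftward:
        lo, hi = max(0, bp.pos - flank_len), bp.pos
    else:
        lo, hi = bp.pos, min(n, bp.pos + flank_len)
    if hi <= lo:
        return ""
    seq = fetch_reference(reference, bp.chrom, lo, hi)
    forward_slot = (slot == "A" and bp.side == "right") or (slot == "B" and bp.side == "left")
    return seq if forward_slot else revcomp(seq)


def build_junction_sequence(
    spec: JunctionSpec,
    flank_len: int,
    reference,
) -> Optional[CandidateJunction]:
    """Construct the candidate junction sequence for a spec.

    Concatenates ``flank_len`` oriented reference bases on each side of the
    junction; flanks are truncated at chromosome ends (lengths recorded).
    Returns None (with a warning) if either flank is empty.
    """
    fA = flank_sequence(reference, spec.bpA, "A", flank_len)
    fB = flank_sequence(reference, spec.bpB, "B", flank_len)
    if not fA or not fB:
        log.warning("junction %s: flank outside chromosome; skipped", spec.key)
        return None
    return CandidateJunction(
        spec=spec,
        seq=fA + fB,
        breakpoint_offset=len(fA),
        flankA_len=len(fA),
        flankB_len=len(fB),
        sv_class=classify(spec.bpA, spec.bpB),
    )


def load_external_candidates(path) -> List[JunctionSpec]:
    """Parse a BEDPE-like candidate list into provisional junction specs.

    Requires >= 6 tab-separated columns (chromA, startA, endA, chromB,
    startB, endB); columns 9/10, when present, are breakend strands
    (slot A: ``+`` = right clip; slot B: ``+`` = left clip).  Interval
    midpoints serve as provisional positions until stack refinement.
    Malformed rows are skipped with a counted warning.
    """
    specs: List[JunctionSpec] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chromA, sA, eA, chromB, sB, eB = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                if eA <= sA or eB <= sB:
                    raise ValueError("empty interval")
            except (ValueError, IndexError):
                n_bad += 1
                continue
            known = len(f) >= 10 and f[8] in "+-" and f[9] in "+-"
            sideA = ("right" if f[8] == "+" else "left") if known else "right"
            sideB = ("left" if f[9] == "+" else "right") if known else "left"
            specs.append(
                JunctionSpec(
                    Breakend(chromA, (sA + eA) // 2, sideA),
                    Breakend(chromB, (sB + eB) // 2, sideB),
                    source="external",
                    orientation_known=known,
                    intervalA=(sA, eA),
                    intervalB=(sB, eB),
                )
            )
    if n_bad:
        log.warning("%s: skipped %d malformed BEDPE rows", path, n_bad)
    if not specs:
        raise ValueError(f"no parseable candidate rows in {path}")
    return specs


def expand_orientations(spec: JunctionSpec) -> List[JunctionSpec]:
    """All four side combinations of a spec with unknown orientation."""
    if spec.orientation_known:
        return [spec]
    out = {}
    for sideA in ("right", "left"):
        for sideB in ("left", "right"):
            s = JunctionSpec(
                Breakend(spec.bpA.chrom, spec.bpA.pos, sideA),
                Breakend(spec.bpB.chrom, spec.bpB.pos, sideB),
                source=spec.source,
                orientation_known=False,
                intervalA=spec.intervalA,
                intervalB=spec.intervalB,
            )
            out.setdefault(s.key, s)
    return [out[k] for k in sorted(out)]


# strand-combination vote → (orientationA, orientationB); see the
# breakend-side conventions in the module docstring.
_STRAND_VOTE = {
    ("+", "-"): (FORWARD, FORWARD),
    ("-", "+"): (FORWARD, FORWARD),
    ("+", "+"): (FORWARD, REVCOMP),
    ("-", "-"): (REVCOMP, FORWARD),
}


def infer_orientation_from_discordant_pairs(
    reads: Iterable,
    bpA: Breakend,
    bpB: Breakend,
    window: int = 1000,
    max_concordant_insert: int = 10_000,
) -> Optional[Tuple[str, str]]:
    """Vote on junction orientation from discordant read pairs.

    A pair is discordant when the mates map to different chromosomes, share
    a strand, or span an implausibly large insert.  Pairs with one mate
    within ``window`` of each breakend vote with their (A-side strand,
    B-side strand) combination: opposite strands indicate a colinear
    forward/forward join, like strands indicate one reverse-complemented
    flank.  Plurality wins; a tie or zero votes returns None (undetermined).
    """
    from collections import Counter

    votes = Counter()
    for r in reads:
        if not r.is_paired or r.mate_chrom is None:
            continue
        discordant = (
            r.mate_chrom != r.chrom
            or r.mate_strand == r.strand
            or abs((r.mate_start or 0) - r.ref_start) > max_concordant_insert
        )
        if not discordant:
            continue
        near_a = r.chrom == bpA.chrom and abs(r.ref_start - bpA.pos) <= window
        mate_near_b = r.mate_chrom == bpB.chrom and abs(r.mate_start - bpB.pos) <= window
        near_b = r.chrom == bpB.chrom and abs(r.ref_start - bpB.pos) <= window
        mate_near_a = r.mate_chrom == bpA.chrom and abs(r.mate_start - bpA.pos) <= window
        if near_a and mate_near_b:
            votes[(r.strand, r.mate_strand)] += 1
        elif near_b and mate_near_a:
            votes[(r.mate_strand, r.strand)] += 1
    if not votes:
        return None
    best = votes.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        return None
    return _STRAND_VOTE[best[0][0]]


def exclude_high_coverage_regions(
    specs: Sequence[JunctionSpec],
    coverage,
    k: float = 10.0,
    halfwin: int = 500,
    sample_step: int = 10,
) -> List[JunctionSpec]:
    """Drop specs whose breakends sit in excessively deep (repetitive) regions.

    ``coverage`` maps chromosome → per-base depth array.  The baseline is the
    median depth over positions sampled every ``sample_step`` bases genome-
    wide; a spec is dropped when the mean depth within ±``halfwin`` of either
    breakend exceeds ``k`` × baseline.
    """
    if k <= 1:
        raise ValueError("k must be > 1")
    sampled = np.concatenate([arr[::sample_step] for arr in coverage.values()])
    baseline = float(np.median(sampled))
    if baseline <= 0:
        log.warning("zero baseline coverage; high-coverage filter disabled")
        return list(specs)

    def mean_depth(bp: Breakend) -> float:
        arr = coverage.get(bp.chrom)
        if arr is None:
            return 0.0
        lo, hi = max(0, bp.pos - halfwin), min(len(arr), bp.pos + halfwin)
        return float(arr[lo:hi].mean()) if hi > lo else 0.0

    kept = []
    for spec in specs:
        dA, dB = mean_depth(spec.bpA), mean_depth(spec.bpB)
        if max(dA, dB) > k * baseline:
            log.info("excluding %s: depth %.1f/%.1f vs baseline %.1f (k=%g)",
                     spec.key, dA, dB, baseline, k)
        else:
            kept.append(spec)
    return kept


def refine_spec_positions(
    spec: JunctionSpec,
    candidates: Sequence,
    halfwin: int = 500,
) -> JunctionSpec:
    """Snap a provisional external spec to nearby soft-clip stacks.

    For each breakend, the best-supported candidate with the matching clip
    side within ±``halfwin`` replaces the provisional position; if neither
    end finds a stack the spec is kept at its midpoints and flagged
    low-confidence.
    """

    def snap(bp: Breakend):
        near = [c for c in candidates
                if c.chrom == bp.chrom and c.clip_side == bp.side
                and abs(c.pos - bp.pos) <= halfwin]
        if not near:
            return None
        best = min(near, key=lambda c: (-c.n_reads, abs(c.pos - bp.pos), c.pos))
        return Breakend(bp.chrom, best.pos, bp.side)

    a, b = snap(spec.bpA), snap(spec.bpB)
    low_conf = a is None and b is None
    return JunctionSpec(
        a or spec.bpA,
        b or spec.bpB,
        source=spec.source,
        orientation_known=spec.orientation_known,
        low_confidence=low_conf,
        intervalA=spec.intervalA,
        intervalB=spec.intervalB,
    )


def library_to_fasta(junctions: Sequence[CandidateJunction], path) -> None:
    """FASTA export of a junction library; headers encode breakends + offset."""
    with open(path, "w") as fh:
        for j in junctions:
            a, b = j.spec.bpA, j.spec.bpB
            header = (f"{a.chrom}:{a.pos}:{j.spec.orientationA}"
                      f"|{b.chrom}:{b.pos}:{j.spec.orientationB}|{j.breakpoint_offset}")
            fh.write(f">{header}\n{j.seq}\n")
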